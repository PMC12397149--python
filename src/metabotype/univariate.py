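"""Univariate feature screening and the correlation/clustering view.

Wilcoxon rank-sum (Mann-Whitney U) tests per feature between the two
phenotype classes, Benjamini-Hochberg FDR adjustment, and the pairwise
Pearson-correlation matrix between two blocks with hierarchical-clustering
leaf orders for heatmap-style display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .blocks import ClassLabelSet, FeatureBlock

__all__ = [
    "UnivariateResult",
    "wilcoxon_screen",
    "bh_adjust",
    "CorrelationCluster",
    "correlation_cluster",
]

# per-class size above which the normal approximation (with midranks and tie
# correction) replaces exact enumeration
_EXACT_LIMIT = 25


@dataclass
class UnivariateResult:
    feature_name: str
    statistic: float  # Mann-Whitney U of the first class
    p_value: float
    fdr_q: float
    direction: int  # sign of median(first class) - median(second class)


def wilcoxon_screen(
    block: FeatureBlock, labels: ClassLabelSet
) -> list[UnivariateResult]:
    """Two-sided Wilcoxon rank-sum test per feature between the two classes.

    Exact enumeration when both classes have <= 25 members, midrank normal
    approximation with tie correction otherwise.  The block must be aligned
    to the retained subjects of ``labels`` and fully observed.
    """
    X = block.values
    if np.isnan(X).any():
        raise ValueError("wilcoxon_screen requires fully observed data")
    if X.shape[0] != len(labels.labels):
        raise ValueError(
            f"block has {X.shape[0]} samples but labels cover {len(labels.labels)}"
        )
    a, b = labels.class_names
    in_a = labels.labels == a
    in_b = labels.labels == b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each class needs at least 2 members")
    method = "exact" if max(in_a.sum(), in_b.sum()) <= _EXACT_LIMIT else "asymptotic"
    stats, ps, dirs = [], [], []
    for j in range(X.shape[1]):
        xa, xb = X[in_a, j], X[in_b, j]
        res = mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        stats.append(float(res.statistic))
        ps.append(float(min(res.pvalue, 1.0)))
        dirs.append(int(np.sign(np.median(xa) - np.median(xb))))
    qs = bh_adjust(ps)
    return [
        UnivariateResult(f, s, p, q, d)
        for f, s, p, q, d in zip(block.feature_names, stats, ps, qs, dirs)
    ]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CorrelationCluster:
    """Pairwise Pearson correlations between two blocks plus display orders.

    ``matrix`` is features-of-A x features-of-B in the original orders;
    ``row_order``/``col_order`` are hierarchical-clustering leaf orders
    (average linkage on 1 - R within each block's own correlation
    structure).  Constant features have their correlations reported as 0 and
    are flagged.
    """

    matrix: pd.DataFrame
    row_order: np.ndarray
    col_order: np.ndarray
    constant_rows: list[str]
    constant_cols: list[str]

    @property
    def reordered(self) -> pd.DataFrame:
        return self.matrix.iloc[self.row_order, self.col_order]


def _safe_standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    Z = (X - X.mean(axis=0)) / np.where(const, 1.0, sd)
    Z[:, const] = 0.0
    return Z, const


def _leaf_order(Z: np.ndarray) -> np.ndarray:
    p = Z.shape[1]
    if p < 3:
        return np.arange(p)
    n = Z.shape[0]
    R = Z.T @ Z / (n - 1)
    np.fill_diagonal(R, 1.0)
    D = np.clip(1.0 - R, 0.0, 2.0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return leaves_list(average(squareform(D, checks=False)))


def correlation_cluster(
    block_a: FeatureBlock, block_b: FeatureBlock
) -> CorrelationCluster:
    """Pearson R between every feature of A and every feature of B.

    Subjects must be aligned and fully observed; the leaf orders come from
    average-linkage clustering on correlation distance within each block.
    """
    if block_a.n_subjects != block_b.n_subjects or (
        block_a.subject_ids != block_b.subject_ids
    ).any():
        raise ValueError("blocks must share an identical subject ordering")
    Xa, Xb = block_a.values, block_b.values
    if np.isnan(Xa).any() or np.isnan(Xb).any():
        raise ValueError("correlation_cluster requires fully observed blocks")
    n = Xa.shape[0]
    Za, const_a = _safe_standardize(Xa)
    Zb, const_b = _safe_standardize(Xb)
    R = Za.T @ Zb / (n - 1)
    R = np.clip(R, -1.0, 1.0)
    matrix = pd.DataFrame(R, index=block_a.feature_names, columns=block_b.feature_names)
    return CorrelationCluster(
        matrix=matrix,
        row_order=_leaf_order(Za),
        col_order=_leaf_order(Zb),
        constant_rows=[f for f, c in zip(block_a.feature_names, const_a) if c],
        constant_cols=[f for f, c in zip(block_b.feature_names, const_b) if c],
    )
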