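"""Missing-value handling, scaling, class-label derivation and data fusion.

The scaling steps are scikit-learn transformers so they compose with
pipelines and are refit per resampling inside the validation harness:

* :class:`Autoscaler` — per-feature mean 0 / SD 1 (sample SD, ddof=1);
* :class:`BlockScaler` — autoscaling followed by dividing each block by
  sqrt(p_block), equalizing total variance across fused blocks;
* :class:`KNNBlockImputer` — distance-weighted KNN imputation.

Module-level functions (`filter_missing`, `knn_impute`, `autoscale`,
`block_scale`, `make_class_labels`) are thin wrappers operating on
:class:`~metabotype.blocks.FeatureBlock` objects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .blocks import ClassLabelSet, FeatureBlock, MultiblockMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "filter_missing",
    "KNNBlockImputer",
    "knn_impute",
    "Autoscaler",
    "autoscale",
    "BlockScaler",
    "block_scale",
    "make_class_labels",
]


# ---------------------------------------------------------------------------
# missing-value filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    dropped_samples: list[str]
    dropped_features: list[str]
    max_fraction: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "dropped_samples": self.dropped_samples,
                    "dropped_features": self.dropped_features,
                    "max_fraction": self.max_fraction,
                },
                fh,
                indent=2,
            )


def filter_missing(
    block: FeatureBlock, max_fraction: float = 1.0 / 3.0
) -> tuple[FeatureBlock, FilterReport]:
    """Drop samples, then variables, with missing fraction > ``max_fraction``.

    Samples are removed first; variable missing fractions are then recomputed
    on the surviving samples.  Fractions strictly greater than the threshold
    are removed (a sample missing exactly one third of its variables is
    kept).  Idempotent: re-running on the output changes nothing.
    """
    if not (0.0 < max_fraction < 1.0):
        raise ValueError("max_fraction must be in (0, 1)")
    mask = block.missing_mask
    row_frac = mask.mean(axis=1)
    keep_rows = row_frac <= max_fraction
    dropped_samples = [str(s) for s in block.data.index[~keep_rows]]
    sub = block.data.loc[keep_rows]
    if sub.shape[0] == 0:
        raise ValueError("all samples removed by missing-value filtering")
    col_frac = sub.isna().to_numpy().mean(axis=0)
    keep_cols = col_frac <= max_fraction
    dropped_features = [str(c) for c in sub.columns[~keep_cols]]
    sub = sub.loc[:, keep_cols]
    if sub.shape[1] == 0:
        raise ValueError("all variables removed by missing-value filtering")
    report = FilterReport(dropped_samples, dropped_features, max_fraction)
    return FeatureBlock(sub.copy(), block.name), report


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------


class KNNBlockImputer(TransformerMixin, BaseEstimator):
    """Distance-weighted K-nearest-neighbour imputation.

    Each missing entry is replaced by the inverse-distance-weighted mean of
    that feature over the ``n_neighbors`` nearest samples that observe it,
    with distance the Euclidean norm over the mutually observed, autoscaled
    features.  A sample sharing no observed feature with any donor falls
    back to the feature median (logged).  Observed entries are never
    altered.

    Parameters
    ----------
    n_neighbors : int, default=10
        Number of donor samples per missing entry.
    weighted : bool, default=True
        Inverse-distance weighting; if False, a plain mean of the k donors.
    """

    def __init__(self, n_neighbors: int = 10, weighted: bool = True):
        self.n_neighbors = n_neighbors
        self.weighted = weighted

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite="allow-nan", dtype=float)
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.n_neighbors >= X.shape[0]:
            raise ValueError("n_neighbors must be smaller than the number of samples")
        self.X_fit_ = X
        with np.errstate(invalid="ignore"):
            self.means_ = np.nanmean(X, axis=0)
            self.medians_ = np.nanmedian(X, axis=0)
            self.sds_ = np.nanstd(X, axis=0, ddof=1)
        self.sds_ = np.where(self.sds_ > 0, self.sds_, 1.0)
        return self

    def transform(self, X):
        check_is_fitted(self, "X_fit_")
        X = check_array(X, ensure_all_finite="allow-nan", dtype=float, copy=True)
        donors = self.X_fit_
        Zd = (donors - self.means_) / self.sds_
        Z = (X - self.means_) / self.sds_
        obs_d = ~np.isnan(donors)
        for i in np.where(np.isnan(X).any(axis=1))[0]:
            obs_i = ~np.isnan(Z[i])
            miss_j = np.where(np.isnan(X[i]))[0]
            # squared Euclidean distance over mutually observed features;
            # a donor missing the target feature is never a candidate, so a
            # sample can't donate to itself when imputing the training data
            diff = np.where(obs_d[:, obs_i], Zd[:, obs_i] - Z[i, obs_i], 0.0)
            d2 = (diff**2).sum(axis=1)
            n_shared = obs_d[:, obs_i].sum(axis=1)
            for j in miss_j:
                cand = obs_d[:, j] & (n_shared > 0)
                idx = np.where(cand)[0]
                if idx.size == 0:
                    X[i, j] = self.medians_[j]
                    logger.warning(
                        "sample %d shares no observed feature with any donor; "
                        "feature %d imputed by median",
                        i,
                        j,
                    )
                    continue
                order = idx[np.argsort(d2[idx], kind="stable")]
                nn = order[: self.n_neighbors]
                vals = donors[nn, j]
                if self.weighted:
                    w = 1.0 / (np.sqrt(d2[nn]) + 1e-12)
                    X[i, j] = float(np.sum(w * vals) / np.sum(w))
                else:
                    X[i, j] = float(np.mean(vals))
        return X


def knn_impute(block: FeatureBlock, k: int = 10, weighted: bool = True) -> FeatureBlock:
    """Impute a block's missing entries in place of NaN; see :class:`KNNBlockImputer`."""
    imp = KNNBlockImputer(n_neighbors=k, weighted=weighted).fit(block.values)
    vals = imp.transform(block.values)
    df = pd.DataFrame(vals, index=block.data.index, columns=block.data.columns)
    return FeatureBlock(df, block.name)


# ---------------------------------------------------------------------------
# autoscaling
# ---------------------------------------------------------------------------


class Autoscaler(TransformerMixin, BaseEstimator):
    """Scale each feature to mean 0 and sample SD 1 (ddof=1).

    Features with zero SD are centred and left unscaled (divisor 1), with
    ``zero_sd_flags_`` raised.  Unlike ``StandardScaler`` the variance uses
    the n-1 denominator, consistent with the variance bookkeeping of block
    scaling and Q².
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("autoscaling needs at least 2 samples")
        self.means_ = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        # numerically constant columns (SD at rounding-error level)
        self.zero_sd_flags_ = sds <= 1e-10 * np.maximum(1.0, np.abs(self.means_))
        self.sds_ = np.where(self.zero_sd_flags_, 1.0, sds)
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        X = check_array(X, dtype=float)
        return (X - self.means_) / self.sds_


def autoscale(
    train: FeatureBlock, others: list[FeatureBlock] | None = None
) -> tuple[FeatureBlock, list[FeatureBlock], Autoscaler]:
    """Autoscale ``train``; apply the same parameters to each block in ``others``."""
    scaler = Autoscaler().fit(train.values)
    out_train = FeatureBlock(
        pd.DataFrame(
            scaler.transform(train.values),
            index=train.data.index,
            columns=train.data.columns,
        ),
        train.name,
    )
    out_others = []
    for blk in others or []:
        if blk.feature_names != train.feature_names:
            raise ValueError("feature mismatch between train and companion block")
        out_others.append(
            FeatureBlock(
                pd.DataFrame(
                    scaler.transform(blk.values),
                    index=blk.data.index,
                    columns=blk.data.columns,
                ),
                blk.name,
            )
        )
    return out_train, out_others, scaler


# ---------------------------------------------------------------------------
# multiblock fusion: block scaling
# ---------------------------------------------------------------------------


class BlockScaler(TransformerMixin, BaseEstimator):
    """Block scaling for fused (concatenated) matrices.

    Each block is autoscaled per feature, then the whole block is divided by
    sqrt(p_block), so every block contributes total variance exactly 1 and a
    wide block cannot dominate a narrow one.

    Parameters
    ----------
    block_sizes : sequence of int
        Feature counts of the consecutive blocks in the concatenated input.
    """

    def __init__(self, block_sizes=(1,)):
        self.block_sizes = block_sizes

    def _slices(self):
        out, start = [], 0
        for p in self.block_sizes:
            out.append(slice(start, start + int(p)))
            start += int(p)
        return out, start

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        slices, total = self._slices()
        if total != X.shape[1]:
            raise ValueError(
                f"block sizes sum to {total} but X has {X.shape[1]} columns"
            )
        self.scaler_ = Autoscaler().fit(X)
        self.divisors_ = np.empty(X.shape[1])
        for sl, p in zip(slices, self.block_sizes):
            self.divisors_[sl] = np.sqrt(float(p))
        return self

    def transform(self, X):
        check_is_fitted(self, "scaler_")
        return self.scaler_.transform(X) / self.divisors_


def block_scale(blocks: list[FeatureBlock]) -> MultiblockMatrix:
    """Fuse >= 2 aligned blocks into one block-scaled matrix.

    Raises an alignment error listing offending subject IDs if the blocks do
    not share an identical subject ordering.
    """
    if len(blocks) < 2:
        raise ValueError("block_scale needs at least 2 blocks")
    ref = blocks[0].subject_ids
    for blk in blocks[1:]:
        if len(blk.subject_ids) != len(ref) or (blk.subject_ids != ref).any():
            bad = sorted(
                set(map(str, ref)).symmetric_difference(map(str, blk.subject_ids))
            )
            raise ValueError(
                f"subject misalignment between blocks "
                f"{blocks[0].name!r} and {blk.name!r}: {bad[:10]}"
            )
    X = np.hstack([b.values for b in blocks])
    if np.isnan(X).any():
        raise ValueError("block_scale requires fully observed blocks")
    sizes = [b.n_features for b in blocks]
    bs = BlockScaler(block_sizes=sizes).fit(X)
    scaled = bs.transform(X)
    cols = []
    for b in blocks:
        cols.extend(f"{b.name}:{f}" for f in b.feature_names)
    values = pd.DataFrame(scaled, index=blocks[0].data.index, columns=cols)
    slices, _ = bs._slices()
    return MultiblockMatrix(
        values=values,
        block_slices={b.name: sl for b, sl in zip(blocks, slices)},
        feature_means=bs.scaler_.means_,
        feature_sds=bs.scaler_.sds_,
        block_divisors={b.name: float(np.sqrt(b.n_features)) for b in blocks},
        zero_sd_flags=bs.scaler_.zero_sd_flags_,
    )


# ---------------------------------------------------------------------------
# class labels
# ---------------------------------------------------------------------------

_CLASS_NAMES = {
    "sex": ("male", "female"),
    "age": ("young", "old"),
    "bmi": ("lean", "obese"),
}


def make_class_labels(phenos: PhenotypeTable, trait: str) -> ClassLabelSet:
    """Derive binary class labels for one trait.

    sex: male vs female, everyone retained.  age: under 50 vs older than 65
    (ages in [50, 65] excluded).  bmi: <= 25 vs > 30 (BMI in (25, 30]
    excluded).
    """
    if trait not in _CLASS_NAMES:
        raise ValueError(f"trait must be one of {sorted(_CLASS_NAMES)}, got {trait!r}")
    names = _CLASS_NAMES[trait]
    if trait == "sex":
        retained = np.ones(len(phenos), dtype=bool)
        labels = phenos.sex.astype(object)
    elif trait == "age":
        age = phenos.age
        retained = (age < 50.0) | (age > 65.0)
        labels = np.where(age[retained] < 50.0, "young", "old").astype(object)
    else:
        bmi = phenos.bmi
        retained = (bmi <= 25.0) | (bmi > 30.0)
        labels = np.where(bmi[retained] <= 25.0, "lean", "obese").astype(object)
    labels = np.asarray(labels, dtype=object)
    for cls in names:
        if (labels == cls).sum() == 0:
            raise ValueError(f"degenerate labels: class {cls!r} has no members")
    return ClassLabelSet(
        trait=trait,
        labels=labels,
        retained_mask=retained,
        class_names=names,
        subject_ids=phenos.subject_ids[retained],
    )
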