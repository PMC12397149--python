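"""Data containers shared across the pipeline.

A :class:`FeatureBlock` is one sample-by-feature matrix (clinical chemistry
or one metabolomics assay) carried as a :class:`pandas.DataFrame` indexed by
subject ID, with missing values stored as NaN.  A :class:`PhenotypeTable`
holds per-subject sex, age and BMI.  Both round-trip losslessly through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureBlock",
    "PhenotypeTable",
    "MultiblockMatrix",
    "ClassLabelSet",
]


@dataclass
class FeatureBlock:
    """One sample-by-feature matrix with block identity.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by subject ID (index name ``subject_id``), one column
        per feature.  Missing values are NaN.
    name : str
        Block identity, e.g. ``"clinical"``, ``"GCMS"``.
    """

    data: pd.DataFrame
    name: str = "block"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate subject IDs in block %r" % self.name)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "subject_id"

    # -- convenience views ------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True where the value is missing."""
        return self.data.isna().to_numpy()

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "FeatureBlock":
        return FeatureBlock(self.data.copy(), self.name)

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write as CSV: header row, first column ``subject_id``."""
        self.data.to_csv(path, index=True)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "FeatureBlock":
        df = pd.read_csv(path, index_col="subject_id")
        df.index = df.index.astype(str)
        if name is None:
            import os

            name = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(df, name)


@dataclass
class PhenotypeTable:
    """Per-subject phenotypes: sex ({male, female}), age (years), BMI (kg/m2)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "age", "bmi"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate subject IDs in phenotype table")
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "subject_id"
        bad = set(self.data["sex"].unique()) - {"male", "female"}
        if bad:
            raise ValueError(f"unrecognised sex labels: {sorted(bad)}")
        if (self.data["bmi"] <= 0).any():
            raise ValueError("bmi must be positive")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def sex(self) -> np.ndarray:
        return self.data["sex"].to_numpy()

    @property
    def age(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    @property
    def bmi(self) -> np.ndarray:
        return self.data["bmi"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=True)

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        df = pd.read_csv(path, index_col="subject_id")
        df.index = df.index.astype(str)
        return cls(df)


@dataclass
class MultiblockMatrix:
    """Aligned, block-scaled concatenation of two or more feature blocks.

    ``values`` holds the concatenated scaled matrix; ``block_slices`` maps
    each block name to its column range; ``feature_means``/``feature_sds``
    are the per-feature autoscaling parameters and ``block_divisors`` the
    per-block sqrt(p) divisors, so the transform can be re-applied to new
    samples.
    """

    values: pd.DataFrame
    block_slices: dict[str, slice]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    block_divisors: dict[str, float]
    zero_sd_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def block_names(self) -> list[str]:
        return list(self.block_slices)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()


@dataclass
class ClassLabelSet:
    """Binary class labels for one trait, with the retention mask.

    ``labels`` covers retained subjects only (values drawn from
    ``class_names``); ``retained_mask`` indexes the full cohort.
    """

    trait: str
    labels: np.ndarray
    retained_mask: np.ndarray
    class_names: tuple[str, str]
    subject_ids: np.ndarray

    @property
    def counts(self) -> dict[str, int]:
        names, n = np.unique(self.labels, return_counts=True)
        return {str(a): int(b) for a, b in zip(names, n)}
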