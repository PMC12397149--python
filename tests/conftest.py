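import numpy as np
import pandas as pd
import pytest

from metabotype import CohortConfig, FeatureBlock, PhenotypeTable, generate_cohort

SMALL_GRID = {"n_components": [1, 2, 3]}


@pytest.fixture(scope="session")
def cohort_500():
    """One medium cohort with default planted effects, clinical block complete."""
    config = CohortConfig(
        n_subjects=500, seed=42, missing_rate=0.0, block_sizes={"GCMS": 40}
    )
    phenos, blocks = generate_cohort(config)
    return config, phenos, blocks


@pytest.fixture(scope="session")
def null_cohort_300():
    """Signal-free cohort: no planted effects anywhere."""
    config = CohortConfig(
        n_subjects=300, seed=7, missing_rate=0.0, block_sizes={}
    ).with_null_effects()
    phenos, blocks = generate_cohort(config)
    return config, phenos, blocks


def toy_block(values, name="toy", features=None, ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    features = features or [f"f{j}" for j in range(p)]
    ids = ids or [f"S{i}" for i in range(n)]
    df = pd.DataFrame(values, index=pd.Index(ids, name="subject_id"), columns=features)
    return FeatureBlock(df, name)


def toy_phenotypes(sex=None, age=None, bmi=None):
    n = max(len(x) for x in (sex, age, bmi) if x is not None)
    df = pd.DataFrame(
        {
            "sex": sex if sex is not None else ["male"] * (n // 2) + ["female"] * (n - n // 2),
            "age": age if age is not None else np.full(n, 40.0),
            "bmi": bmi if bmi is not None else np.full(n, 24.0),
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="subject_id"),
    )
    return PhenotypeTable(df)
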