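"""Metabolic phenotyping from clinical chemistry and metabolomics data.

Predict sex, age class and BMI class (and quantitative age/BMI) from
sample-by-feature tables, with bootstrap + permutation-NULL validation,
class balancing, multiblock data fusion and VIP panel selection, plus a
synthetic cohort generator for end-to-end testing.
"""

from .blocks import ClassLabelSet, FeatureBlock, MultiblockMatrix, PhenotypeTable
from .preprocess import (
    Autoscaler,
    BlockScaler,
    KNNBlockImputer,
    autoscale,
    block_scale,
    filter_missing,
    knn_impute,
    make_class_labels,
)
from .supervised import (
    ConfusionMatrix,
    FittedModel,
    ModelSpec,
    PLSDAClassifier,
    RegressionMetrics,
    balanced_accuracy,
    fit_model,
    predict_confusion,
    random_undersample,
    regression_metrics,
    select_vip,
    vip_scores,
)
from .synthetic import (
    CohortConfig,
    generate_clinical_block,
    generate_cohort,
    generate_metabolomics_block,
    generate_phenotypes,
    inject_missing,
)
from .univariate import bh_adjust, correlation_cluster, wilcoxon_screen
from .validation import (
    LearningCurve,
    ValidationSummary,
    bootstrap_validate,
    empirical_pvalue,
    learning_curve,
)

__version__ = "0.1.0"
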