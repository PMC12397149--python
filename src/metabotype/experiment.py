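"""Configuration-driven end-to-end runs.

Reproduces the full experiment grid — every data block and fused
(clinical + metabolomics) matrix, for each trait (sex, age class, BMI class)
and model kind — with the bootstrap/permutation validation harness, plus
quantitative PLS regression of age and BMI, writing a classification results
table (balanced accuracy with significance stars), a regression table
(median Q2 / RMSEP) and per-run JSON artifacts.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .blocks import FeatureBlock, PhenotypeTable
from .preprocess import filter_missing, knn_impute, make_class_labels
from .supervised import ModelSpec
from .synthetic import CohortConfig, generate_cohort
from .validation import ValidationSummary, bootstrap_validate

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "significance_stars",
    "load_cohort_inputs",
    "run_experiment",
    "summarize",
]

CLASS_TRAITS = ("sex", "age", "bmi")
REGRESSION_TRAITS = ("age", "bmi")
CLASSIFIER_KINDS = ("plsda", "svm_linear", "random_forest")


def _run_seed(seed: int, *parts: str) -> int:
    """Stable per-run seed derived from the master seed and the run identity."""
    tag = zlib.crc32("/".join(parts).encode()) % 10000
    return (int(seed) + tag) % (2**31 - 1)


def significance_stars(p: float) -> str:
    """Significance bins: *** p<0.001, ** p<0.01, * p<0.05, none otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ExperimentConfig:
    """One experiment grid.

    Either ``cohort`` (synthetic mode) or ``pheno_path`` + ``block_paths``
    must be provided.  ``fuse`` adds clinical+metabolomics fused matrices.
    Defaults scale the full grid down (small B, reduced component grid) so
    it completes in minutes on one CPU; pass larger ``B`` and
    ``max_components`` for publication-scale runs.
    """

    cohort: CohortConfig | None = None
    pheno_path: str | None = None
    block_paths: dict[str, str] = field(default_factory=dict)
    traits: tuple[str, ...] = CLASS_TRAITS
    models: tuple[str, ...] = CLASSIFIER_KINDS
    fuse: bool = True
    regress: bool = True
    B: int = 100
    max_components: int = 5
    rf_trees: int = 200
    cv_folds: int = 7
    seed: int = 0
    outdir: str = "metabotype_results"

    def __post_init__(self) -> None:
        if self.cohort is None and not self.block_paths:
            raise ValueError("provide a synthetic cohort config or block paths")
        for t in self.traits:
            if t not in CLASS_TRAITS:
                raise ValueError(f"unknown trait {t!r}")
        for m in self.models:
            if m not in CLASSIFIER_KINDS:
                raise ValueError(f"unknown classifier kind {m!r}")

    def model_spec(self, kind: str, seed: int) -> ModelSpec:
        if kind in ("plsda", "plsr"):
            grid = {"n_components": list(range(1, self.max_components + 1))}
        elif kind == "svm_linear":
            grid = {"C": [0.01, 0.1, 1.0, 10.0, 100.0]}
        else:
            grid = {"n_estimators": [self.rf_trees],
                    "max_features": ["sqrt", "quarter", "half"]}
        return ModelSpec(kind, grid, self.cv_folds, seed)

    # -- YAML round trip --------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw and raw["cohort"] is not None:
            c = dict(raw["cohort"])
            if "age_range" in c:
                c["age_range"] = tuple(c["age_range"])
            raw["cohort"] = CohortConfig(**c)
        for key in ("traits", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key, val in (raw.get("block_paths") or {}).items():
            if not Path(val).exists():
                raise FileNotFoundError(f"block file for {key!r} not found: {val}")
        return cls(**raw)


def load_cohort_inputs(
    config: ExperimentConfig,
) -> tuple[PhenotypeTable, dict[str, FeatureBlock]]:
    """Simulate or load the phenotypes and raw feature blocks."""
    if config.cohort is not None:
        return generate_cohort(config.cohort)
    phenos = PhenotypeTable.from_csv(config.pheno_path)
    blocks = {}
    for name, path in config.block_paths.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"block file for {name!r} not found: {path}")
        blocks[name] = FeatureBlock.from_csv(path, name)
    return phenos, blocks


def preprocess_cohort(
    phenos: PhenotypeTable, blocks: dict[str, FeatureBlock]
) -> tuple[PhenotypeTable, dict[str, FeatureBlock], dict]:
    """Missing-value filter + KNN imputation; align everything to survivors."""
    report: dict = {}
    processed: dict[str, FeatureBlock] = {}
    surviving = set(map(str, phenos.subject_ids))
    for name, blk in blocks.items():
        if blk.missing_mask.any():
            filtered, rep = filter_missing(blk)
            n_missing = int(filtered.missing_mask.sum())
            imputed = knn_impute(filtered, k=min(10, filtered.n_subjects - 1))
            processed[name] = imputed
            report[name] = {
                "dropped_samples": rep.dropped_samples,
                "dropped_features": rep.dropped_features,
                "imputed_cells": n_missing,
                "imputed_fraction": n_missing
                / (filtered.n_subjects * filtered.n_features),
            }
        else:
            processed[name] = blk
            report[name] = {"dropped_samples": [], "dropped_features": [],
                            "imputed_cells": 0, "imputed_fraction": 0.0}
        surviving &= set(map(str, processed[name].subject_ids))
    keep = [s for s in map(str, phenos.subject_ids) if s in surviving]
    phenos = PhenotypeTable(phenos.data.loc[keep].copy())
    processed = {
        name: FeatureBlock(blk.data.loc[keep].copy(), name)
        for name, blk in processed.items()
    }
    return phenos, processed, report


def _datasets(
    config: ExperimentConfig, blocks: dict[str, FeatureBlock]
) -> dict[str, list[str]]:
    """Dataset name -> list of member block names (singletons then fusions)."""
    names = list(blocks)
    out = {name: [name] for name in names}
    if config.fuse and "clinical" in blocks:
        for name in names:
            if name != "clinical":
                out[f"clinical+{name}"] = ["clinical", name]
    return out


def _dataset_matrix(
    member_names: list[str], blocks: dict[str, FeatureBlock], mask: np.ndarray
):
    """Raw (unscaled) matrix for a dataset restricted to retained subjects.

    Returns (X, block_sizes) where block_sizes is None for a single block
    (plain autoscaling in the harness) and the per-block widths for a fused
    matrix (block scaling in the harness).
    """
    mats = [blocks[m].values[mask] for m in member_names]
    X = np.hstack(mats)
    sizes = [blocks[m].n_features for m in member_names]
    return X, (sizes if len(sizes) > 1 else None)


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full grid; returns the result bundle and writes artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phenos, raw_blocks = load_cohort_inputs(config)
    phenos, blocks, prep_report = preprocess_cohort(phenos, raw_blocks)
    datasets = _datasets(config, blocks)

    bundle: dict = {
        "config": {"B": config.B, "seed": config.seed,
                   "traits": list(config.traits), "models": list(config.models)},
        "preprocess": prep_report,
        "classification": {},
        "regression": {},
    }
    cls_rows = []
    for trait in config.traits:
        labels = make_class_labels(phenos, trait)
        balance = trait in ("age", "bmi")
        for kind in config.models:
            for ds_name, members in datasets.items():
                t0 = time.time()
                X, sizes = _dataset_matrix(members, blocks, labels.retained_mask)
                run_seed = _run_seed(config.seed, trait, kind, ds_name)
                summary = bootstrap_validate(
                    X,
                    labels.labels,
                    config.model_spec(kind, run_seed),
                    B=config.B,
                    balance=balance,
                    seed=run_seed,
                    class_names=labels.class_names,
                    block_sizes=sizes,
                )
                key = f"{trait}/{kind}/{ds_name}"
                bundle["classification"][key] = summary.to_dict()
                _write_summary_files(outdir, "classification", key, summary)
                cls_rows.append(
                    {
                        "trait": trait,
                        "model": kind,
                        "dataset": ds_name,
                        "balanced_accuracy": summary.mean_metric,
                        "sd": summary.metric_sd,
                        "empirical_p": summary.empirical_p,
                        "stars": significance_stars(summary.empirical_p),
                    }
                )
                logger.info(
                    "classification %s: BA=%.3f p=%s (%.1fs)",
                    key, summary.mean_metric, summary.p_label, time.time() - t0,
                )

    reg_rows = []
    if config.regress:
        for trait in REGRESSION_TRAITS:
            y = phenos.age if trait == "age" else phenos.bmi
            all_mask = np.ones(len(phenos), dtype=bool)
            for ds_name, members in datasets.items():
                t0 = time.time()
                X, sizes = _dataset_matrix(members, blocks, all_mask)
                run_seed = _run_seed(config.seed, trait, "plsr", ds_name)
                summary = bootstrap_validate(
                    X, y, config.model_spec("plsr", run_seed),
                    B=config.B, seed=run_seed, block_sizes=sizes,
                )
                key = f"{trait}/plsr/{ds_name}"
                bundle["regression"][key] = summary.to_dict()
                _write_summary_files(outdir, "regression", key, summary)
                reg_rows.append(
                    {
                        "trait": trait,
                        "dataset": ds_name,
                        "median_q2": summary.median_q2,
                        "median_rmsep": summary.median_rmsep,
                        "empirical_p": summary.empirical_p,
                        "stars": significance_stars(summary.empirical_p),
                    }
                )
                logger.info(
                    "regression %s: Q2=%.3f RMSEP=%.3f (%.1fs)",
                    key, summary.median_q2, summary.median_rmsep, time.time() - t0,
                )

    bundle["classification_table"] = _pivot_classification(cls_rows)
    bundle["regression_table"] = _pivot_regression(reg_rows)
    with open(outdir / "results.json", "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=2)
    pd.DataFrame(cls_rows).to_csv(outdir / "classification_runs.csv", index=False)
    if reg_rows:
        pd.DataFrame(reg_rows).to_csv(outdir / "regression_runs.csv", index=False)
    return bundle


def _write_summary_files(outdir: Path, kind: str, key: str, summary: ValidationSummary):
    safe = key.replace("/", "__")
    sub = outdir / kind
    sub.mkdir(parents=True, exist_ok=True)
    with open(sub / f"{safe}.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
    per_iter = pd.DataFrame(
        {
            "observed": [it.observed_metric for it in summary.iterations],
            "null": [it.null_metric for it in summary.iterations],
        }
    )
    per_iter.to_csv(sub / f"{safe}_iterations.csv", index=False)
    # histogram data so observed-vs-null distribution plots are reproducible
    both = np.concatenate([per_iter["observed"], per_iter["null"]])
    edges = np.histogram_bin_edges(both[np.isfinite(both)], bins=20)
    obs_h, _ = np.histogram(per_iter["observed"], bins=edges)
    null_h, _ = np.histogram(per_iter["null"], bins=edges)
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:],
         "observed": obs_h, "null": null_h}
    ).to_csv(sub / f"{safe}_histogram.csv", index=False)


def _pivot_classification(rows: list[dict]) -> dict:
    if not rows:
        return {}
    df = pd.DataFrame(rows)
    df["cell"] = df.apply(
        lambda r: f"{100 * r.balanced_accuracy:.1f}%{r.stars}", axis=1
    )
    wide = df.pivot_table(
        index=["trait", "model"], columns="dataset", values="cell", aggfunc="first"
    )
    return {"index": [list(i) for i in wide.index],
            "columns": list(wide.columns),
            "cells": wide.to_numpy().tolist()}


def _pivot_regression(rows: list[dict]) -> dict:
    if not rows:
        return {}
    df = pd.DataFrame(rows)
    df["cell"] = df.apply(
        lambda r: f"Q2={r.median_q2:.4f} RMSEP={r.median_rmsep:.4f}{r.stars}", axis=1
    )
    wide = df.pivot_table(
        index=["trait"], columns="dataset", values="cell", aggfunc="first"
    )
    return {"index": list(wide.index), "columns": list(wide.columns),
            "cells": wide.to_numpy().tolist()}


def summarize(bundle: dict, outdir) -> Path:
    """Write a markdown report of the result bundle; returns the file path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["# Metabotyping results", ""]
    ct = bundle.get("classification_table") or {}
    if ct:
        lines += ["## Balanced accuracies (bootstrap means, test sets)", ""]
        header = ["trait", "model"] + list(ct["columns"])
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for idx, row in zip(ct["index"], ct["cells"]):
            lines.append(
                "| " + " | ".join(list(idx) + [str(c) for c in row]) + " |"
            )
        lines.append("")
    rt = bundle.get("regression_table") or {}
    if rt:
        lines += ["## Quantitative prediction (median over bootstraps)", ""]
        header = ["trait"] + list(rt["columns"])
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for idx, row in zip(rt["index"], rt["cells"]):
            lines.append("| " + " | ".join([idx] + [str(c) for c in row]) + " |")
        lines.append("")
    lines.append("Stars: *** p < 0.001, ** p < 0.01, * p < 0.05 (empirical,")
    lines.append("fraction of bootstrap iterations where the permutation NULL")
    lines.append("model beat the observed model).")
    path = outdir / "summary.md"
    path.write_text("\n".join(lines))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
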