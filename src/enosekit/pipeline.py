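"""End-to-end orchestration: simulate -> features -> stats/PCA -> LDA-SA ->
MLR-SA -> XPT validation, with a YAML-configurable, seed-reproducible run.

A single top-level seed deterministically derives per-stage seeds
(``seed + stage index``), so one integer reproduces an entire run.  All
intermediate tables are written as CSV and the run is summarized in a
versioned JSON document.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from ._anneal import SAParams
from .features import METHODS, FeatureTable, extract_features, select_method_view
from .group_stats import compare_table, results_frame
from .lda import sa_select_features
from .mlr import TARGETS, sa_select_regression
from .pca import fit_pca, separation_score
from .synthetic import GeneratorConfig, generate_cohort
from .xpt import validate_models

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

SCHEMA_VERSION = 1

logger = logging.getLogger("enosekit.pipeline")

# stage-seed offsets
_STAGE_GENERATE, _STAGE_LDA, _STAGE_MLR = 0, 1, 2


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    feature_method: str = "MEAN"
    sa_classification: SAParams = field(
        default_factory=lambda: SAParams(max_subset_size=6)
    )
    sa_regression: SAParams = field(
        default_factory=lambda: SAParams(max_subset_size=29)
    )
    targets: tuple[str, ...] = TARGETS
    alpha: float = 0.05
    outdir: str | Path = "enose_run"
    seed: int = 0

    def validate(self) -> None:
        if self.feature_method not in METHODS:
            raise ValueError(f"unknown feature method {self.feature_method!r}")
        unknown = set(self.targets) - set(TARGETS)
        if unknown:
            raise ValueError(f"unknown quantitation target(s): {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.sa_classification.validate()
        self.sa_regression.validate()
        self.generator.validate()


def _target_vector(profiles, ids, target: str) -> np.ndarray:
    by_id = {p.sample_id: p for p in profiles}
    if target == "total":
        return np.array([by_id[s].total for s in ids])
    return np.array([by_id[s].contents[target] for s in ids])


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and return (and write) the run summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str) -> None:
        logger.info("[%s] %s", time.strftime("%H:%M:%S"), name)

    # 1. simulate
    stage("simulate")
    gen = replace(config.generator, seed=config.seed + _STAGE_GENERATE)
    curves, profiles, labels = generate_cohort(gen)
    eio.write_sensor_curves(curves, outdir / "sensor_curves.csv")
    eio.write_volatile_profiles(profiles, outdir / "volatiles.csv")
    eio.write_labels(labels, outdir / "labels.csv")

    # 2. features
    stage("features")
    full = extract_features(curves)
    full.to_frame().to_csv(outdir / "features.csv", index=False)
    view = select_method_view(full, config.feature_method)

    # 3. group statistics on the volatile classes
    stage("group statistics")
    vol_frame = pd.DataFrame(
        {c: [p.contents[c] for p in profiles] for c in eio.VOLATILE_CLASSES}
        | {"total": [p.total for p in profiles]},
        index=pd.Index([p.sample_id for p in profiles], name="sample_id"),
    )
    stats_results = compare_table(vol_frame, labels)
    results_frame(stats_results).to_csv(outdir / "group_stats.csv", index=False)

    # 4. PCA on the selected method view
    stage("pca")
    pca_result = fit_pca(view.features, scale=True)
    pca_result.scores.to_csv(outdir / "pca_scores.csv")
    sep = separation_score(pca_result, labels)

    # 5. LDA-SA classification on the selected method view
    stage("lda-sa")
    sa_cls = replace(config.sa_classification, seed=config.seed + _STAGE_LDA)
    subset_model = sa_select_features(view, sa_cls)
    confusion = subset_model.loocv_summary

    # 6. MLR-SA quantitation per region x target, on the full 63-feature pool
    stage("mlr-sa")
    models = []
    for r_i, region in enumerate(eio.REGIONS):
        mask = labels == region
        sub = FeatureTable(
            features=full.features.loc[mask], labels=full.labels.loc[mask]
        )
        for t_i, target in enumerate(config.targets):
            y = _target_vector(profiles, sub.sample_ids, target)
            sa_reg = replace(
                config.sa_regression,
                seed=config.seed + _STAGE_MLR + 10 * r_i + 100 * t_i,
            )
            models.append(
                sa_select_regression(sub, y, sa_reg, target=target, region=region)
            )

    # 7. XPT slope/intercept validation of every quantitation model
    stage("xpt validation")
    reports = validate_models(models, full, profiles, alpha=config.alpha)

    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "stage_seeds": {
            "generator": config.seed + _STAGE_GENERATE,
            "lda_sa": config.seed + _STAGE_LDA,
            "mlr_sa_base": config.seed + _STAGE_MLR,
        },
        "cohort": {
            "n_total": len(labels),
            "n_coa": int((labels == "Coa").sum()),
            "n_douro": int((labels == "Douro").sum()),
        },
        "group_stats": {
            r.variable: {"p_value": r.p_value, "test": r.test_used}
            for r in stats_results
        },
        "pca": {
            "cumulative_3pc": pca_result.cumulative_3pc,
            "separation_score": sep,
        },
        "classification": {
            "selected_features": list(subset_model.selected_features),
            "confusion": confusion.confusion.astype(int).tolist(),
            "overall_sensitivity": confusion.overall_sensitivity,
            "overall_specificity": confusion.overall_specificity,
            "energy": subset_model.energy,
        },
        "quantitation": [
            {
                "region": m.region,
                "target": m.target,
                "n_features": len(m.selected_features),
                "selected_features": list(m.selected_features),
                "loocv_R2": m.loocv_R2,
                "loocv_RMSE": m.loocv_RMSE,
            }
            for m in models
        ],
        "validation": [
            {
                "region": rep.region,
                "target": rep.target,
                "slope": rep.slope,
                "intercept": rep.intercept,
                "ci_slope": list(rep.ci_slope),
                "ci_intercept": list(rep.ci_intercept),
                "verdict": "pass" if rep.verdict else "fail",
            }
            for rep in reports
        ],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


# ---------------------------------------------------------------------------
# YAML configuration


def _sa_from_dict(d: dict[str, Any], default: SAParams) -> SAParams:
    return replace(default, **d)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration (missing keys fall back to defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    config = RunConfig()
    if "generator" in raw:
        gen_kwargs = dict(raw["generator"])
        for key in ("sensitivity_matrix", "baseline_resistances", "tau"):
            if key in gen_kwargs:
                gen_kwargs[key] = np.asarray(gen_kwargs[key], dtype=float)
        if "truncation_ranges" in gen_kwargs:
            gen_kwargs["truncation_ranges"] = {
                k: tuple(v) for k, v in gen_kwargs["truncation_ranges"].items()
            }
        config = replace(config, generator=GeneratorConfig(**gen_kwargs))
    if "sa_classification" in raw:
        config = replace(
            config,
            sa_classification=_sa_from_dict(
                raw["sa_classification"], config.sa_classification
            ),
        )
    if "sa_regression" in raw:
        config = replace(
            config,
            sa_regression=_sa_from_dict(raw["sa_regression"], config.sa_regression),
        )
    for key in ("feature_method", "alpha", "outdir", "seed"):
        if key in raw:
            config = replace(config, **{key: raw[key]})
    if "targets" in raw:
        config = replace(config, targets=tuple(raw["targets"]))
    config.validate()
    return config
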