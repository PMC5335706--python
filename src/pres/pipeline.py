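"""End-to-end orchestration: screen -> train -> calibrate -> assign.

``fit_pres`` fits the three per-regimen response models on a training
dataset, computes nested out-of-fold probabilities for the training
patients of each arm, and builds the per-regimen probability-interval
tables.  ``assign_training`` then scores every training patient under all
three models — using the out-of-fold probability for the patient's own
arm and the full model for the other arms — and applies the selection
rule.  ``run_all`` writes the whole run (simulation, screening, models,
calibration, assignment, leave-one-study-out validation) to a directory
of TSV/JSON artifacts.

Seeds: every stage consumes a child seed derived from the run seed and a
stage label (crc32-keyed), so individual stages can be re-run
reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import simulate as sim
from .assignment import AssignmentResult, assign_cohort, bootstrap_ci
from .calibration import PITable, calibration_curve, compute_pi_table, npv_ppv_report
from .datasets import REGIMENS, CohortDataset, write_clinical, write_expression
from .models import (
    RegimenResponseModel,
    design_matrix,
    out_of_fold_probabilities,
)

MIN_ARM_SIZE = 20  # arms smaller than this (or single-class) are skipped


def child_seed(seed: int, label: str) -> int:
    """Stable per-stage seed below 2**31."""
    return int(
        np.random.SeedSequence(
            [int(seed), zlib.crc32(label.encode())]
        ).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class PipelineConfig:
    """All tunables of a PRES run."""

    alpha: float = 0.05
    rss_draws: int = 200
    rss_fraction: float = 0.7
    rss_max_probes: int = 200
    rss_top_q: int = 50
    rss_trees: int = 200
    k_grid: tuple[int, ...] = (0, 2, 4, 8, 13, 16, 24, 32, 50, 100)
    select_folds: int = 5
    threshold: float = 0.5
    n_trees: int = 1000
    oof_folds: int = 10
    toxicity_margin: float = 0.01
    n_boot: int = 1000
    min_arm_size: int = MIN_ARM_SIZE

    def model_params(self) -> dict:
        return dict(
            alpha=self.alpha,
            rss_draws=self.rss_draws,
            rss_fraction=self.rss_fraction,
            rss_max_probes=self.rss_max_probes,
            rss_top_q=self.rss_top_q,
            rss_trees=self.rss_trees,
            k_grid=tuple(self.k_grid),
            select_folds=self.select_folds,
            threshold=self.threshold,
            n_trees=self.n_trees,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_grid"] = list(self.k_grid)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs = dict(d)
        if "k_grid" in kwargs:
            kwargs["k_grid"] = tuple(kwargs["k_grid"])
        return cls(**kwargs)

    #: scaled-down profile for desk-scale runs and simulations
    @classmethod
    def desk_scale(cls) -> "PipelineConfig":
        return cls(
            rss_draws=30,
            rss_trees=25,
            k_grid=(0, 4, 13, 30),
            select_folds=3,
            n_trees=100,
            oof_folds=3,
            n_boot=200,
        )


@dataclass
class PresFit:
    """Fitted PRES state on one training dataset."""

    models: dict[str, RegimenResponseModel]
    oof_probabilities: dict[str, pd.Series]
    pi_tables: dict[str, PITable]
    skipped_regimens: dict[str, str] = field(default_factory=dict)


def _arm_trainable(dataset: CohortDataset, regimen: str, config: PipelineConfig) -> str | None:
    ids = [r for r in dataset.clinical if r.regimen == regimen]
    if len(ids) < max(config.min_arm_size, config.oof_folds):
        return f"arm has {len(ids)} patients (< {max(config.min_arm_size, config.oof_folds)})"
    n_pcr = sum(1 for r in ids if r.response == "pCR")
    if n_pcr < config.oof_folds or len(ids) - n_pcr < config.oof_folds:
        return f"arm has {n_pcr} pCR / {len(ids) - n_pcr} RD; too few per class"
    return None


def fit_pres(
    dataset: CohortDataset, config: PipelineConfig, seed: int
) -> PresFit:
    """Fit per-regimen models, OOF probabilities and PI tables."""
    models: dict[str, RegimenResponseModel] = {}
    oof: dict[str, pd.Series] = {}
    tables: dict[str, PITable] = {}
    skipped: dict[str, str] = {}
    for regimen in REGIMENS:
        reason = _arm_trainable(dataset, regimen, config)
        if reason is not None:
            skipped[regimen] = reason
            continue
        group = dataset.regimen_subset(regimen)
        X = design_matrix(group)
        y = group.response_vector()
        model = RegimenResponseModel(
            random_state=child_seed(seed, f"fit:{regimen}"),
            **config.model_params(),
        )
        model.fit(X, y)
        probs = out_of_fold_probabilities(
            model,
            X,
            y,
            folds=config.oof_folds,
            random_state=child_seed(seed, f"oof:{regimen}"),
        )
        models[regimen] = model
        oof[regimen] = probs
        tables[regimen] = compute_pi_table(probs.to_numpy(), y, regimen=regimen)
    if not models:
        raise ValueError("no regimen arm was trainable")
    return PresFit(
        models=models, oof_probabilities=oof, pi_tables=tables, skipped_regimens=skipped
    )


def probability_matrix(
    dataset: CohortDataset, fit: PresFit, training: bool = True
) -> pd.DataFrame:
    """Samples x regimens predicted pCR probabilities.

    For training patients (``training=True``) the patient's own arm uses
    the out-of-fold probability; every other arm uses the full model.
    External patients use full models throughout.
    """
    X = design_matrix(dataset)
    probs = pd.DataFrame(
        np.nan, index=list(dataset.sample_ids), columns=list(REGIMENS)
    )
    for regimen, model in fit.models.items():
        probs[regimen] = model.predict_pcr_probability(X)
    if training:
        for regimen, series in fit.oof_probabilities.items():
            for sid, p in series.items():
                if sid in probs.index:
                    probs.at[sid, regimen] = p
    return probs


def assign_patients(
    dataset: CohortDataset,
    fit: PresFit,
    config: PipelineConfig,
    mode: str = "toxicity",
    training: bool = True,
) -> AssignmentResult:
    probs = probability_matrix(dataset, fit, training=training)
    originals = [r.regimen for r in dataset.clinical]
    return assign_cohort(
        probs,
        fit.pi_tables,
        originals,
        mode=mode,
        toxicity_margin=config.toxicity_margin,
    )


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "pres_run"
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    run_loso: bool = True


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_all(config: RunConfig) -> Path:
    """Run the full workflow on a simulated dataset; returns the run dir."""
    from .validation import loso_validate  # avoid import cycle

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_config = dataclasses.replace(
        config.simulation, seed=child_seed(config.seed, "simulate")
    )
    dataset, truth = sim.simulate(sim_config)
    write_expression(dataset.expression, out / "expression.tsv")
    write_clinical(dataset.clinical, out / "clinical.tsv")
    _write_json(
        out / "ground_truth.json",
        {
            "signatures": {
                r: [[p, b] for p, b in sig] for r, sig in truth.signatures.items()
            },
            "true_probabilities": truth.true_probabilities.round(6).to_dict(),
        },
    )

    fit = fit_pres(dataset, config.pipeline, child_seed(config.seed, "fit"))
    for regimen, model in fit.models.items():
        model.cv_trace_.to_csv(out / f"cv_trace_{regimen}.tsv", sep="\t", index=False)
        fit.oof_probabilities[regimen].to_csv(out / f"oof_{regimen}.tsv", sep="\t")
        fit.pi_tables[regimen].to_frame().to_csv(
            out / f"pi_table_{regimen}.tsv", sep="\t", index=False
        )
        calibration_curve(fit.pi_tables[regimen]).to_csv(
            out / f"calibration_curve_{regimen}.tsv", sep="\t", index=False
        )

    summary: dict = {
        "seed": config.seed,
        "pipeline": config.pipeline.to_dict(),
        "skipped_regimens": fit.skipped_regimens,
        "models": {
            r: {
                "k_star": m.k_star_,
                "selected_probes": list(m.selected_probes_),
                "clinical_only_f05": float(
                    m.cv_trace_.loc[m.cv_trace_["k"] == 0, "mean_f05"].iloc[0]
                )
                if (m.cv_trace_["k"] == 0).any()
                else None,
                "best_f05": float(m.cv_trace_["mean_f05"].max()),
            }
            for r, m in fit.models.items()
        },
        "npv_ppv": {
            r: npv_ppv_report(t) for r, t in fit.pi_tables.items()
        },
    }

    for mode in ("toxicity", "max_score"):
        result = assign_patients(dataset, fit, config.pipeline, mode=mode)
        result.patients.to_csv(out / f"assignment_{mode}.tsv", sep="\t")
        lo, hi = bootstrap_ci(
            result,
            fit.pi_tables,
            n_boot=config.pipeline.n_boot,
            seed=child_seed(config.seed, f"boot:{mode}"),
        )
        s = result.summary()
        s["ci_95"] = [lo, hi]
        s["oracle_policy_value"] = sim.oracle_policy_value(
            truth, result.patients["assigned_regimen"]
        )
        summary[f"assignment_{mode}"] = s
    summary["oracle_single_regimen_values"] = sim.single_regimen_values(truth)

    if config.run_loso:
        report = loso_validate(
            dataset, config.pipeline, seed=child_seed(config.seed, "loso")
        )
        report.table().to_csv(out / "loso_report.tsv", sep="\t", index=False)
        summary["loso"] = report.to_dict()

    _write_json(out / "summary.json", summary)
    return out
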