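"""Evaluation harnesses: leave-one-study-out validation, receptor-status
stratified reruns, and the cell-line sensitivity check of the paclitaxel
(TA) model.

In leave-one-study-out (LOSO) validation each cohort is held out in turn;
models, probability-interval tables and the assignment rule are rebuilt on
the remaining cohorts only, and the held-out patients are scored with the
full training models and mapped through the training-derived tables — no
held-out information enters any training statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import assign_cohort, bootstrap_ci
from .datasets import REGIMENS, CohortDataset, ExpressionMatrix, encode_clinical
from .models import RegimenResponseModel
from .pipeline import PipelineConfig, PresFit, child_seed, fit_pres, probability_matrix


@dataclass
class LOSOCohortResult:
    cohort: str
    n_patients: int
    assignment_counts: dict[str, int]
    expected_pcr_rate: float
    ci_95: tuple[float, float]
    original_arm_rates: dict[str, float]
    skipped_regimens: dict[str, str]

    def best_original_rate(self) -> float:
        rates = [v for v in self.original_arm_rates.values() if not np.isnan(v)]
        return max(rates) if rates else float("nan")


@dataclass
class LOSOReport:
    cohorts: list[LOSOCohortResult] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for c in self.cohorts:
            row = {"cohort": c.cohort, "n": c.n_patients}
            for r in REGIMENS:
                row[f"assigned_{r}"] = c.assignment_counts.get(r, 0)
                row[f"original_rate_{r}"] = c.original_arm_rates.get(r, float("nan"))
            row["expected_pcr_rate"] = c.expected_pcr_rate
            row["ci_lo"], row["ci_hi"] = c.ci_95
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            c.cohort: {
                "n": c.n_patients,
                "assignment_counts": c.assignment_counts,
                "expected_pcr_rate": c.expected_pcr_rate,
                "ci_95": list(c.ci_95),
                "original_arm_rates": c.original_arm_rates,
                "skipped_regimens": c.skipped_regimens,
            }
            for c in self.cohorts
        }


def loso_validate(
    dataset: CohortDataset,
    config: PipelineConfig,
    seed: int = 0,
    mode: str = "toxicity",
) -> LOSOReport:
    """Leave-one-study-out validation across the dataset's cohorts."""
    cohorts = dataset.cohorts()
    if len(cohorts) < 2:
        raise ValueError("LOSO needs at least two cohorts")
    report = LOSOReport()
    for cohort in sorted(cohorts):
        training = dataset.drop_cohort(cohort)
        held_out = dataset.only_cohort(cohort)
        fit = fit_pres(
            training, config, seed=child_seed(seed, f"loso:{cohort}")
        )
        probs = probability_matrix(held_out, fit, training=False)
        result = assign_cohort(
            probs,
            fit.pi_tables,
            [r.regimen for r in held_out.clinical],
            mode=mode,
            toxicity_margin=config.toxicity_margin,
        )
        lo, hi = bootstrap_ci(
            result,
            fit.pi_tables,
            n_boot=config.n_boot,
            seed=child_seed(seed, f"loso-boot:{cohort}"),
        )
        original_rates = {}
        for r in REGIMENS:
            arm = [c for c in held_out.clinical if c.regimen == r]
            original_rates[r] = (
                sum(1 for c in arm if c.response == "pCR") / len(arm)
                if arm
                else float("nan")
            )
        report.cohorts.append(
            LOSOCohortResult(
                cohort=cohort,
                n_patients=held_out.n_samples,
                assignment_counts=result.regimen_counts(),
                expected_pcr_rate=result.expected_pcr_rate,
                ci_95=(lo, hi),
                original_arm_rates=original_rates,
                skipped_regimens=fit.skipped_regimens,
            )
        )
    return report


STRATA = ("HER2neg", "HER2neg_ERneg")


def stratum_dataset(dataset: CohortDataset, strata_spec: str) -> CohortDataset:
    """Filter to a receptor-status stratum.

    ``HER2neg`` keeps HER2-negative patients; ``HER2neg_ERneg`` keeps the
    double negatives and additionally drops the anthracycline-only arm
    (that comparison is restricted to the two taxane regimens).
    """
    if strata_spec not in STRATA:
        raise ValueError(f"unknown stratum {strata_spec!r}; choose from {STRATA}")

    def keep(rec) -> bool:
        if rec.her2_status != "negative":
            return False
        if strata_spec == "HER2neg_ERneg":
            return rec.er_status == "negative" and rec.regimen in ("TA", "TxA")
        return True

    ids = [r.sample_id for r in dataset.clinical if keep(r)]
    if not ids:
        raise ValueError(f"stratum {strata_spec!r} is empty")
    return dataset.subset(ids)


def stratified_run(
    dataset: CohortDataset,
    strata_spec: str,
    config: PipelineConfig,
    seed: int = 0,
    mode: str = "toxicity",
):
    """Re-run the whole pipeline on one receptor-status stratum.

    Identical to fitting and assigning on the pre-filtered dataset (the
    stratified run shares every code path with the whole-data run).
    """
    from .pipeline import assign_patients

    stratum = stratum_dataset(dataset, strata_spec)
    fit = fit_pres(stratum, config, seed=child_seed(seed, f"stratum:{strata_spec}"))
    result = assign_patients(stratum, fit, config, mode=mode, training=True)
    return fit, result


@dataclass(frozen=True)
class CellLinePanel:
    """Expression of drug-sensitivity-profiled cell lines over model probes."""

    line_ids: tuple[str, ...]
    labels: tuple[str, ...]  # 'sensitive' | 'resistant'
    expression: ExpressionMatrix

    def __post_init__(self) -> None:
        if set(self.labels) - {"sensitive", "resistant"}:
            raise ValueError("labels must be 'sensitive' or 'resistant'")
        if len(set(self.labels)) < 2:
            raise ValueError("panel needs both sensitive and resistant lines")
        if list(self.expression.sample_ids) != list(self.line_ids):
            raise ValueError("expression columns must match line_ids")


def cellline_test(
    panel: CellLinePanel, ta_model: RegimenResponseModel
) -> dict:
    """One-sided Welch test that resistant lines have lower predicted pCR
    probability than sensitive lines (H1: mean_resistant < mean_sensitive).

    Cell lines have no clinical record, so the clinical covariates enter as
    all-unknown statuses with the model's training-median age.
    """
    expr = panel.expression.to_frame().T
    n = len(panel.line_ids)
    clin = pd.DataFrame(
        {
            "age": ta_model.age_median_,
            "er_pos": 0.0,
            "er_known": 0.0,
            "pr_pos": 0.0,
            "pr_known": 0.0,
            "her2_pos": 0.0,
            "her2_known": 0.0,
        },
        index=list(panel.line_ids),
    )
    X = pd.concat([clin, expr], axis=1)
    probs = ta_model.predict_pcr_probability(X)
    labels = np.asarray(panel.labels)
    p_sens = probs[labels == "sensitive"]
    p_res = probs[labels == "resistant"]
    if p_sens.size < 2 or p_res.size < 2:
        raise ValueError("need at least two lines per sensitivity group")
    vs, vr = p_sens.var(ddof=1), p_res.var(ddof=1)
    if vs == 0.0 and vr == 0.0:
        # degenerate: all predictions tied within groups
        t = 0.0 if p_res.mean() == p_sens.mean() else np.sign(
            p_res.mean() - p_sens.mean()
        ) * np.inf
        p_one = 0.5 if t == 0.0 else (0.0 if t < 0 else 1.0)
        df = float(p_sens.size + p_res.size - 2)
    else:
        sr = vr / p_res.size
        ss = vs / p_sens.size
        t = (p_res.mean() - p_sens.mean()) / np.sqrt(sr + ss)
        df = (sr + ss) ** 2 / (
            sr**2 / (p_res.size - 1) + ss**2 / (p_sens.size - 1)
        )
        p_one = float(stats.t.cdf(t, df))  # H1: resistant < sensitive
    return {
        "t": float(t),
        "df": float(df),
        "p_one_sided": float(p_one),
        "mean_sensitive": float(p_sens.mean()),
        "mean_resistant": float(p_res.mean()),
        "n_sensitive": int(p_sens.size),
        "n_resistant": int(p_res.size),
    }


def simulate_cellline_panel(
    truth_signature: tuple[tuple[str, float], ...],
    all_probes: tuple[str, ...],
    n_sensitive: int = 18,
    n_resistant: int = 3,
    effect: float = 1.0,
    seed: int | None = None,
) -> CellLinePanel:
    """Synthetic panel in which sensitive lines carry the TA signature
    shifted in its pCR direction and resistant lines in the opposite one."""
    rng = np.random.default_rng(seed)
    n = n_sensitive + n_resistant
    values = rng.standard_normal((len(all_probes), n))
    probe_idx = {p: j for j, p in enumerate(all_probes)}
    group = np.array([1] * n_sensitive + [-1] * n_resistant)
    for probe, beta in truth_signature:
        direction = np.sign(beta)
        values[probe_idx[probe], :] += 0.5 * effect * direction * group
    line_ids = tuple(
        [f"SENS{i:02d}" for i in range(n_sensitive)]
        + [f"RES{i:02d}" for i in range(n_resistant)]
    )
    labels = tuple(["sensitive"] * n_sensitive + ["resistant"] * n_resistant)
    return CellLinePanel(
        line_ids=line_ids,
        labels=labels,
        expression=ExpressionMatrix(
            probe_ids=all_probes, sample_ids=line_ids, values=values
        ),
    )
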