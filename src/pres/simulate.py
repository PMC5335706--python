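"""Synthetic multi-cohort generator with known per-regimen response truth.

The generator emulates the structure of the seven public GEO neoadjuvant
breast-cancer cohorts this method was developed on: three unbalanced
treatment arms (anthracycline alone ``A``, paclitaxel + anthracycline
``TA``, docetaxel + anthracycline ``TxA``), low and arm-dependent pCR
prevalence, sparse per-regimen expression signatures driving response,
cohort-level batch shifts, and receptor-status covariates correlated with
response.

Generative model
----------------
Each patient i carries one latent chemosensitivity per regimen,
``z_ir ~ N(0, 1)``, independent across regimens.  The true pCR
probability under regimen r is logistic in that latent plus the clinical
covariates:

    logit p_ir = alpha_r + lambda * z_ir + gamma . c_i

and regimen r's signature probes load on the same latent, so expression is

    x_ij = mu_j + b_cj + s_rj * effect * z_ir + eps_ij,   eps ~ N(0, 1)

for probe j in signature S_r with sign s_rj (x_ij = mu_j + b_cj + eps_ij
for non-signature probes), with cohort-by-probe batch shifts
``b_cj ~ N(0, batch_sd^2)``.  ``effect`` is therefore the log2 shift of a
signature probe per standard deviation of sensitivity; between observed
pCR and RD patients of the arm this induces a shift of roughly
``effect * E[z|pCR] - E[z|RD] ~ 1.3-1.7 * effect``.

Because the latent and clinical terms spread the logit, a fixed intercept
would not hit the configured arm prevalence; ``alpha_r`` is solved
numerically so the mean of p over the arm's patients equals the target.
With zero latent strength and no clinical effects this reduces to
``alpha_r = logit(prevalence)``.

The observed regimen is assigned independently of expression
(randomized-like), so the observed arm is non-informative about the
counterfactual probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .datasets import (
    REGIMENS,
    ClinicalRecord,
    CohortDataset,
    ExpressionMatrix,
    encode_clinical,
)

# ---------------------------------------------------------------------------
# The published multi-cohort design: per-cohort arm sizes and printed pCR
# percentages.  ``None`` marks an absent arm.  Besides seeding the default
# simulation layout, this table supports exact reconstruction of the pooled
# response rates from the printed per-cell percentages.

COHORT_DESIGN: tuple[tuple[str, dict[str, tuple[int, float] | None]], ...] = (
    ("GSE20194", {"A": (4, 0.0), "TA": (257, 20.6), "TxA": (8, 12.5)}),
    ("GSE20271", {"A": (85, 8.2), "TA": (91, 20.9), "TxA": None}),
    ("GSE22093", {"A": (50, 10.0), "TA": None, "TxA": None}),
    ("GSE23988", {"A": None, "TA": None, "TxA": (61, 32.8)}),
    ("GSE25055", {"A": None, "TA": (290, 18.3), "TxA": None}),
    ("GSE25065", {"A": None, "TA": (92, 20.7), "TxA": (88, 26.1)}),
    ("GSE42822", {"A": None, "TA": None, "TxA": (53, 37.7)}),
)


def reconstruct_pcr_counts() -> pd.DataFrame:
    """Integer pCR counts per cohort-arm cell, from n x printed percentage.

    Each cell's count is ``round(n * pct / 100)`` (half away from zero,
    matching how the percentages were printed from integer counts).
    """
    rows = []
    for cohort, arms in COHORT_DESIGN:
        for regimen in REGIMENS:
            cell = arms[regimen]
            if cell is None:
                continue
            n, pct = cell
            count = int(math.floor(n * pct / 100.0 + 0.5))
            rows.append(
                {"cohort": cohort, "regimen": regimen, "n": n, "n_pcr": count}
            )
    return pd.DataFrame(rows)


def marginal_pcr_rates(decimals: int = 1) -> dict[str, float]:
    """Pooled per-arm and total pCR rates (%) implied by the design table."""
    table = reconstruct_pcr_counts()
    out: dict[str, float] = {}
    for regimen, grp in table.groupby("regimen"):
        out[regimen] = round(100.0 * grp["n_pcr"].sum() / grp["n"].sum(), decimals)
    out["total"] = round(100.0 * table["n_pcr"].sum() / table["n"].sum(), decimals)
    return out


def cohort_pcr_rates(decimals: int = 1) -> dict[str, float]:
    """Per-cohort pooled pCR rates (%) implied by the design table."""
    table = reconstruct_pcr_counts()
    return {
        str(cohort): round(100.0 * grp["n_pcr"].sum() / grp["n"].sum(), decimals)
        for cohort, grp in table.groupby("cohort")
    }


# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generator.

    Defaults mirror the published cohort layout (7 cohorts; arm totals
    A=139 / TA=730 / TxA=210) and arm prevalences 8.6 / 19.7 / 30.5 %, with
    per-regimen signature sizes 4 / 13 / 30 probes.
    """

    n_probes: int = 2000
    cohort_design: tuple = COHORT_DESIGN
    signature_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"A": 4, "TA": 13, "TxA": 30}
    )
    effect_size: float = 0.8
    latent_strength: float = 2.0
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.086, "TA": 0.197, "TxA": 0.305}
    )
    batch_sd: float = 0.3
    clinical_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": -0.01,  # per year, centred at 50
            "er_pos": -0.5,
            "her2_pos": 0.3,
        }
    )
    frac_status_unknown: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        total_sig = sum(self.signature_sizes.get(r, 0) for r in REGIMENS)
        if total_sig > self.n_probes:
            raise ValueError("signatures exceed probe count")
        for r in REGIMENS:
            p = self.prevalence[r]
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {r} must be in (0,1), got {p}")
        for _, arms in self.cohort_design:
            for cell in arms.values():
                if cell is not None and cell[0] <= 0:
                    raise ValueError("arm sizes must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Oracle knowledge about a simulated dataset."""

    signatures: Mapping[str, tuple[tuple[str, float], ...]]  # probe, signed beta
    sample_ids: tuple[str, ...]
    true_probabilities: pd.DataFrame  # samples x regimens

    def __post_init__(self) -> None:
        probs = self.true_probabilities.to_numpy()
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("true probabilities outside [0,1]")

    def optimal_regimen(self) -> pd.Series:
        return self.true_probabilities.idxmax(axis=1)

    def signature_probes(self, regimen: str) -> tuple[str, ...]:
        return tuple(p for p, _ in self.signatures[regimen])


def _solve_intercept(linear: np.ndarray, target: float) -> float:
    """alpha such that mean(sigmoid(alpha + linear)) == target."""

    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + linear))) - target

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"prevalence target {target} unattainable with configured effects"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))


def simulate(config: SimulationConfig) -> tuple[CohortDataset, GroundTruth]:
    """Draw one multi-cohort dataset plus its ground truth.

    Deterministic given ``config.seed``; each patient's observed response is
    Bernoulli from their true probability under the regimen they received.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    # patient layout: cohort and observed regimen, independent of expression
    cohort_ids: list[str] = []
    regimens: list[str] = []
    for cohort, arms in config.cohort_design:
        for regimen in REGIMENS:
            cell = arms.get(regimen)
            if cell is None:
                continue
            cohort_ids.extend([cohort] * cell[0])
            regimens.extend([regimen] * cell[0])
    n = len(cohort_ids)
    sample_ids = tuple(f"S{i:04d}" for i in range(n))
    cohorts = tuple(dict.fromkeys(cohort_ids))

    probe_ids = tuple(f"P{j:05d}" for j in range(config.n_probes))

    # disjoint signatures with random signs
    order = rng.permutation(config.n_probes)
    signatures: dict[str, tuple[tuple[str, float], ...]] = {}
    pos = 0
    for regimen in REGIMENS:
        size = int(config.signature_sizes.get(regimen, 0))
        chosen = order[pos : pos + size]
        pos += size
        signs = rng.choice([-1.0, 1.0], size=size)
        signatures[regimen] = tuple(
            (probe_ids[j], float(s * config.effect_size))
            for j, s in zip(chosen, signs)
        )

    # per-patient, per-regimen latent chemosensitivity
    latent = rng.standard_normal((n, len(REGIMENS)))

    # expression: baseline + cohort x probe batch shift + latent signature
    # loadings + unit noise
    mu = rng.normal(0.0, 0.5, size=config.n_probes)
    batch = {
        c: rng.normal(0.0, config.batch_sd, size=config.n_probes) for c in cohorts
    }
    values = np.empty((config.n_probes, n))
    noise = rng.standard_normal((config.n_probes, n))
    for i, c in enumerate(cohort_ids):
        values[:, i] = mu + batch[c] + noise[:, i]
    probe_index = {p: j for j, p in enumerate(probe_ids)}
    for k, regimen in enumerate(REGIMENS):
        for probe, beta in signatures[regimen]:
            values[probe_index[probe], :] += beta * latent[:, k]

    # clinical covariates
    age = np.round(rng.normal(50.0, 10.0, size=n), 1)

    def draw_status(p_pos: float) -> np.ndarray:
        status = np.where(rng.random(n) < p_pos, "positive", "negative")
        unknown = rng.random(n) < config.frac_status_unknown
        return np.where(unknown, "unknown", status)

    er = draw_status(0.6)
    pr = draw_status(0.5)
    her2 = draw_status(0.2)

    records_wo_response = [
        dict(
            sample_id=sample_ids[i],
            cohort_id=cohort_ids[i],
            regimen=regimens[i],
            age=float(age[i]),
            er_status=str(er[i]),
            pr_status=str(pr[i]),
            her2_status=str(her2[i]),
        )
        for i in range(n)
    ]

    # clinical contribution to the logit, using the indicator encoding
    tmp_records = [
        ClinicalRecord(response="RD", **kw) for kw in records_wo_response
    ]
    design = encode_clinical(tmp_records)
    clin_lin = np.zeros(n)
    for name, gamma in config.clinical_effects.items():
        col = design[name].to_numpy(dtype=float)
        if name == "age":
            col = col - 50.0
        clin_lin += gamma * col

    # per-regimen linear predictors and calibrated intercepts
    reg_arr = np.asarray(regimens)
    true_probs = np.empty((n, len(REGIMENS)))
    for k, regimen in enumerate(REGIMENS):
        lin = clin_lin + config.latent_strength * latent[:, k]
        arm = reg_arr == regimen
        target = float(config.prevalence[regimen])
        if arm.any():
            alpha = _solve_intercept(lin[arm], target)
        else:
            alpha = float(logit(target))
        true_probs[:, k] = expit(alpha + lin)

    # observed response: Bernoulli at the received regimen's probability
    received = np.array(
        [true_probs[i, REGIMENS.index(regimens[i])] for i in range(n)]
    )
    is_pcr = rng.random(n) < received

    records = tuple(
        ClinicalRecord(response="pCR" if is_pcr[i] else "RD", **kw)
        for i, kw in enumerate(records_wo_response)
    )
    dataset = CohortDataset(
        expression=ExpressionMatrix(
            probe_ids=probe_ids, sample_ids=sample_ids, values=values
        ),
        clinical=records,
    )
    truth = GroundTruth(
        signatures=signatures,
        sample_ids=sample_ids,
        true_probabilities=pd.DataFrame(
            true_probs, index=list(sample_ids), columns=list(REGIMENS)
        ),
    )
    return dataset, truth


def oracle_policy_value(
    truth: GroundTruth, assignment: Mapping[str, str] | pd.Series
) -> float:
    """Expected true pCR rate of a policy: mean over patients of the true
    probability under the regimen the policy assigned them."""
    if isinstance(assignment, pd.Series):
        assignment = assignment.to_dict()
    total = 0.0
    for sid in truth.sample_ids:
        regimen = assignment[sid]
        total += float(truth.true_probabilities.at[sid, regimen])
    return total / len(truth.sample_ids)


def single_regimen_values(truth: GroundTruth) -> dict[str, float]:
    """Oracle value of assigning every patient one fixed regimen."""
    return {
        r: float(truth.true_probabilities[r].mean()) for r in REGIMENS
    }


def small_design(
    arm_sizes: Mapping[str, int], n_cohorts: int = 2
) -> tuple[tuple[str, dict], ...]:
    """Evenly split arm totals across ``n_cohorts`` synthetic cohorts.

    Convenience for desk-scale runs; prevalences are taken from the
    simulation config, so the per-cell percentage slot is unused (0.0).
    """
    design = []
    for c in range(n_cohorts):
        arms: dict[str, tuple[int, float] | None] = {}
        for r in REGIMENS:
            total = int(arm_sizes.get(r, 0))
            share = total // n_cohorts + (1 if c < total % n_cohorts else 0)
            arms[r] = (share, 0.0) if share > 0 else None
        design.append((f"SIM{c:02d}", arms))
    return tuple(design)
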