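"""The regimen-selection rule and its cohort-level evaluation.

Each patient has a predicted pCR probability under each of the three
regimen models; every probability maps through that regimen's
probability-interval table to a pCR score.  The assigned regimen is the
one whose mapped score is highest, with a toxicity adjustment: if the
anthracycline-only (A) score is within 0.01 of the best taxane score, the
less toxic A is assigned.  An exact TA/TxA tie keeps the patient's
original regimen when it is one of the tied pair, otherwise TA.

The expected number of pCR cases of an assignment is the sum of the
assigned pCR scores; its confidence interval comes from redrawing every
bin's score from a truncated Gaussian centred on the score with the
binomial standard error of the bin's proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .calibration import PITable, bin_index
from .datasets import REGIMENS

UNDEFINED = float("nan")


def map_to_score(probability: float, pi_table: PITable) -> float:
    """pCR score of the PI bin containing ``probability`` (with the
    nearest-defined-bin fallback for empty bins)."""
    return pi_table.score_for(probability)


def assign(
    patient_scores: Mapping[str, float],
    toxicity_margin: float = 0.01,
    original_regimen: str | None = None,
    mode: str = "toxicity",
) -> str:
    """Pick a regimen from per-regimen pCR scores.

    ``patient_scores`` maps regimen -> score; missing regimens or NaN
    scores are treated as undefined.  ``mode='toxicity'`` applies the
    +/- ``toxicity_margin`` preference for A; ``mode='max_score'`` is the
    pure argmax.  Ties that include the patient's original regimen keep
    it; otherwise the less toxic regimen (A, then TA) wins.
    """
    if mode not in ("toxicity", "max_score"):
        raise ValueError(f"unknown mode {mode!r}")
    scores = {
        r: float(patient_scores[r])
        for r in REGIMENS
        if r in patient_scores
        and patient_scores[r] is not None
        and not math.isnan(float(patient_scores[r]))
    }
    if not scores:
        raise ValueError("all regimen scores undefined")

    if mode == "toxicity" and "A" in scores:
        others = [scores[r] for r in ("TA", "TxA") if r in scores]
        if not others or scores["A"] >= max(others) - toxicity_margin:
            return "A"

    best = max(scores.values())
    tied = [r for r in REGIMENS if r in scores and scores[r] == best]
    if len(tied) == 1:
        return tied[0]
    if original_regimen in tied:
        return original_regimen
    return tied[0]  # REGIMENS order: A before TA before TxA


def assign_many(
    score_matrix: np.ndarray,
    toxicity_margin: float = 0.01,
    original_regimens: Sequence[str] | None = None,
    mode: str = "toxicity",
) -> np.ndarray:
    """Vectorised :func:`assign` over an n x 3 score matrix (columns in
    ``REGIMENS`` order; NaN marks an undefined score)."""
    s = np.asarray(score_matrix, dtype=float)
    if s.ndim != 2 or s.shape[1] != len(REGIMENS):
        raise ValueError("score matrix must be n x 3")
    defined = ~np.isnan(s)
    if not defined.any(axis=1).all():
        raise ValueError("all regimen scores undefined for some patient")
    neg = np.where(defined, s, -np.inf)
    n = s.shape[0]
    out = np.empty(n, dtype=object)

    a_def = defined[:, 0]
    best_tax = np.maximum(neg[:, 1], neg[:, 2])
    choose_a = np.zeros(n, dtype=bool)
    if mode == "toxicity":
        choose_a = a_def & (neg[:, 0] >= best_tax - toxicity_margin)
    elif mode != "max_score":
        raise ValueError(f"unknown mode {mode!r}")
    out[choose_a] = "A"

    rest = ~choose_a
    best = neg[rest].max(axis=1)
    tied = neg[rest] == best[:, None]
    originals = (
        np.asarray(original_regimens, dtype=object)[rest]
        if original_regimens is not None
        else np.full(rest.sum(), None, dtype=object)
    )
    reg_arr = np.asarray(REGIMENS, dtype=object)
    picks = np.empty(rest.sum(), dtype=object)
    first_tied = tied.argmax(axis=1)  # lowest index among ties (A < TA < TxA)
    single = tied.sum(axis=1) == 1
    picks[single] = reg_arr[first_tied[single]]
    multi = ~single
    if multi.any():
        orig_idx = np.array(
            [
                list(REGIMENS).index(o) if o in REGIMENS else -1
                for o in originals[multi]
            ]
        )
        rows = np.flatnonzero(multi)
        keep = (orig_idx >= 0) & tied[rows, np.clip(orig_idx, 0, 2)]
        picks[rows[keep]] = originals[multi][keep]
        picks[rows[~keep]] = reg_arr[first_tied[rows[~keep]]]
    out[rest] = picks
    return out.astype(str)


@dataclass
class AssignmentResult:
    """Per-patient assignments with cohort-level summary statistics."""

    patients: pd.DataFrame  # per-patient table, see assign_cohort
    mode: str
    toxicity_margin: float

    @property
    def expected_pcr_count(self) -> float:
        return float(self.patients["assigned_score"].sum())

    @property
    def expected_pcr_rate(self) -> float:
        return self.expected_pcr_count / len(self.patients)

    def regimen_counts(self) -> dict[str, int]:
        counts = self.patients["assigned_regimen"].value_counts()
        return {r: int(counts.get(r, 0)) for r in REGIMENS}

    def overtreated_fraction(self) -> float:
        """Received a taxane regimen although A scored at least as well."""
        p = self.patients
        taxane = p["original_regimen"].isin(["TA", "TxA"])
        a_score = p["score_A"]
        received = np.where(
            p["original_regimen"] == "TA", p["score_TA"], p["score_TxA"]
        )
        over = taxane & a_score.notna() & (a_score >= received)
        return float(over.sum()) / len(p)

    def undertreated_fraction(self) -> float:
        """Received A although some taxane regimen scored strictly better."""
        p = self.patients
        on_a = p["original_regimen"] == "A"
        best_tax = p[["score_TA", "score_TxA"]].max(axis=1)
        under = on_a & p["score_A"].notna() & (best_tax > p["score_A"])
        return float(under.sum()) / len(p)

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "n_patients": int(len(self.patients)),
            "expected_pcr_count": self.expected_pcr_count,
            "expected_pcr_rate": self.expected_pcr_rate,
            "regimen_counts": self.regimen_counts(),
            "overtreated_fraction": self.overtreated_fraction(),
            "undertreated_fraction": self.undertreated_fraction(),
        }


def assign_cohort(
    probabilities: pd.DataFrame,
    pi_tables: Mapping[str, PITable],
    original_regimens: Sequence[str],
    mode: str = "toxicity",
    toxicity_margin: float = 0.01,
) -> AssignmentResult:
    """Assign every patient a regimen from their probability triple.

    ``probabilities``: samples x regimens DataFrame of predicted pCR
    probabilities (NaN where a regimen's model is unavailable); each
    probability is mapped through that regimen's PI table before the rule
    is applied.
    """
    missing = [r for r in probabilities.columns if r not in REGIMENS]
    if missing:
        raise ValueError(f"unknown regimen columns {missing}")
    n = len(probabilities)
    scores = np.full((n, len(REGIMENS)), np.nan)
    bins = np.full((n, len(REGIMENS)), -1)
    for k, r in enumerate(REGIMENS):
        if r not in probabilities.columns or r not in pi_tables:
            continue
        col = probabilities[r].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        table = pi_tables[r]
        scores[ok, k] = [table.score_for(v) for v in col[ok]]
        bins[ok, k] = bin_index(col[ok])
    assigned = assign_many(
        scores,
        toxicity_margin=toxicity_margin,
        original_regimens=list(original_regimens),
        mode=mode,
    )
    reg_idx = {r: k for k, r in enumerate(REGIMENS)}
    assigned_scores = scores[np.arange(n), [reg_idx[r] for r in assigned]]
    patients = pd.DataFrame(
        {
            "sample_id": list(probabilities.index),
            "original_regimen": list(original_regimens),
            **{f"prob_{r}": probabilities.get(r, pd.Series(np.nan, index=probabilities.index)) .to_numpy() for r in REGIMENS},
            **{f"score_{r}": scores[:, reg_idx[r]] for r in REGIMENS},
            **{f"bin_{r}": bins[:, reg_idx[r]] for r in REGIMENS},
            "assigned_regimen": assigned,
            "assigned_score": assigned_scores,
        }
    ).set_index("sample_id")
    return AssignmentResult(
        patients=patients, mode=mode, toxicity_margin=toxicity_margin
    )


def bootstrap_ci(
    result: AssignmentResult,
    pi_tables: Mapping[str, PITable],
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Confidence interval for the expected pCR rate.

    Per replicate, every defined bin's score is redrawn from a Gaussian
    centred on the score with sd sqrt(score(1-score)/n_bin), truncated to
    [0, 1]; each assigned patient's contribution is their assigned bin's
    redrawn score, and the replicate rate is the mean.  The CI is the
    (2.5, 97.5) percentile pair at the default level.
    """
    rng = np.random.default_rng(seed)
    p = result.patients
    n = len(p)
    # group patients by (assigned regimen, assigned bin of that regimen)
    reg_of = p["assigned_regimen"].to_numpy()
    bin_of = np.array(
        [p[f"bin_{r}"].iloc[i] for i, r in enumerate(reg_of)], dtype=int
    )
    # pre-compute per (regimen, bin): count of patients, score, n_bin
    cells: list[tuple[float, float, int]] = []
    counts: list[int] = []
    for r in REGIMENS:
        if r not in pi_tables:
            continue
        table = pi_tables[r]
        mask_r = reg_of == r
        for b in range(len(table.scores)):
            m = int((mask_r & (bin_of == b)).sum())
            if m == 0:
                continue
            # the assigned score may come from a fallback bin; use the score
            # actually assigned to these patients and that bin's size
            score = float(
                p.loc[mask_r & (bin_of == b), "assigned_score"].iloc[0]
            )
            n_bin = int(table.n_patients[b]) if table.defined[b] else 1
            # locate the defined bin whose score was used for the fallback
            if not table.defined[b]:
                defined = np.flatnonzero(table.defined)
                nearest = defined[np.abs(defined - b) == np.abs(defined - b).min()].min()
                n_bin = int(table.n_patients[nearest])
            cells.append((score, max(n_bin, 1), m))
            counts.append(m)
    totals = np.zeros(n_boot)
    for score, n_bin, m in cells:
        sd = math.sqrt(score * (1 - score) / n_bin)
        if sd == 0.0:
            totals += score * m
        else:
            a, b_ = (0.0 - score) / sd, (1.0 - score) / sd
            draws = truncnorm.rvs(
                a, b_, loc=score, scale=sd, size=n_boot, random_state=rng
            )
            totals += draws * m
    rates = totals / n
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(rates, [alpha, 1 - alpha])
    return float(lo), float(hi)
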