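"""Probability-interval calibration: from out-of-fold probabilities to
per-regimen pCR scores.

Predicted probabilities are partitioned into five equal-width bins on
[0, 1] — [0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1.0] — and
each bin's pCR score is the observed pCR fraction among its patients, the
maximum-likelihood estimate of the expected pCR rate for a patient whose
predicted probability lands in that bin.  Empty bins carry an undefined
score; mapping a probability into an undefined bin falls back to the
nearest defined bin (ties toward the lower bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.proportion import proportion_confint

N_BINS = 5
BIN_EDGES = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])


def bin_index(probabilities: np.ndarray) -> np.ndarray:
    """Bin membership on [0,1]; boundaries belong to the upper bin, except
    1.0 which stays in the last bin."""
    p = np.asarray(probabilities, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0,1]")
    return np.minimum((p * N_BINS).astype(int), N_BINS - 1)


@dataclass
class PITable:
    """Per-regimen probability-interval table of pCR scores."""

    regimen: str
    n_patients: np.ndarray  # length 5
    n_pcr: np.ndarray
    scores: np.ndarray  # nan where undefined
    defined: np.ndarray  # bool

    def __post_init__(self) -> None:
        ok = self.defined
        if (self.n_patients.sum() <= 0) or not ok.any():
            raise ValueError("PI table needs at least one populated bin")
        s = self.scores[ok]
        if (s < 0).any() or (s > 1).any():
            raise ValueError("pCR scores outside [0,1]")

    @property
    def total_patients(self) -> int:
        return int(self.n_patients.sum())

    @property
    def total_pcr(self) -> int:
        return int(self.n_pcr.sum())

    def score_for(self, probability: float) -> float:
        """pCR score of the bin containing ``probability``; nearest defined
        bin when that bin is empty (ties -> lower bin)."""
        b = int(bin_index(np.array([probability]))[0])
        if self.defined[b]:
            return float(self.scores[b])
        defined = np.flatnonzero(self.defined)
        dist = np.abs(defined - b)
        nearest = defined[dist == dist.min()].min()
        return float(self.scores[nearest])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": BIN_EDGES[:-1],
                "bin_hi": BIN_EDGES[1:],
                "n_patients": self.n_patients,
                "n_pcr": self.n_pcr,
                "pcr_score": self.scores,
                "defined": self.defined,
            }
        )


class ProbabilityIntervalCalibrator(BaseEstimator, TransformerMixin):
    """Fit a :class:`PITable` from probabilities and observed responses and
    transform probabilities into pCR scores."""

    def __init__(self, regimen: str = ""):
        self.regimen = regimen

    def fit(self, X, y):
        p = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y).astype(int).ravel()
        if p.size == 0 or p.size != y.size:
            raise ValueError("need equal-length, non-empty probabilities and responses")
        idx = bin_index(p)
        n = np.bincount(idx, minlength=N_BINS).astype(int)
        npcr = np.bincount(idx, weights=y, minlength=N_BINS).astype(int)
        with np.errstate(invalid="ignore"):
            scores = np.where(n > 0, npcr / np.maximum(n, 1), np.nan)
        self.table_ = PITable(
            regimen=self.regimen,
            n_patients=n,
            n_pcr=npcr,
            scores=scores,
            defined=n > 0,
        )
        return self

    def transform(self, X) -> np.ndarray:
        p = np.asarray(X, dtype=float).ravel()
        return np.array([self.table_.score_for(v) for v in p])


def compute_pi_table(
    oof_probabilities: np.ndarray, responses: np.ndarray, regimen: str = ""
) -> PITable:
    """Bin out-of-fold probabilities and compute per-bin pCR scores.

    ``responses`` may be binary (1 = pCR) or pCR/RD strings.
    """
    y = np.asarray(responses)
    if y.dtype.kind in "UO":
        y = (y == "pCR").astype(int)
    cal = ProbabilityIntervalCalibrator(regimen=regimen)
    cal.fit(oof_probabilities, y)
    return cal.table_


def npv_ppv_report(table: PITable, negative_bins: int = 1) -> dict:
    """NPV over the first ``negative_bins`` bins (negative calls) and PPV per
    remaining bin (a bin's PPV is its pCR score)."""
    if not 1 <= negative_bins < N_BINS:
        raise ValueError("negative_bins must be a proper prefix of the bins")
    n_neg = int(table.n_patients[:negative_bins].sum())
    pcr_neg = int(table.n_pcr[:negative_bins].sum())
    npv = (n_neg - pcr_neg) / n_neg if n_neg > 0 else float("nan")
    ppv = {
        int(b): float(table.scores[b])
        for b in range(negative_bins, N_BINS)
        if table.defined[b]
    }
    return {
        "regimen": table.regimen,
        "negative_bins": negative_bins,
        "n_negative_calls": n_neg,
        "npv": npv,
        "npv_defined": n_neg > 0,
        "ppv_per_bin": ppv,
    }


def calibration_curve(table: PITable, ci_level: float = 0.95) -> pd.DataFrame:
    """Observed pCR rate per populated bin with a Wilson score interval."""
    rows = []
    for b in range(N_BINS):
        if not table.defined[b]:
            continue
        lo, hi = proportion_confint(
            int(table.n_pcr[b]),
            int(table.n_patients[b]),
            alpha=1 - ci_level,
            method="wilson",
        )
        rows.append(
            {
                "bin_midpoint": float((BIN_EDGES[b] + BIN_EDGES[b + 1]) / 2),
                "observed_rate": float(table.scores[b]),
                "ci_lo": float(lo),
                "ci_hi": float(hi),
                "n": int(table.n_patients[b]),
            }
        )
    return pd.DataFrame(rows)
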