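"""Two-stage probe screening within a treatment arm.

Stage 1 is a per-probe Welch two-sample t-test between pCR and RD patients
at significance level 0.05 (inclusive).  Stage 2, random sampling screening
(RSS), repeatedly subsamples patients (stratified by response) and probe
subsets, fits a random forest per draw, and ranks probes by how often they
land in the top ``q`` of a draw's importance ranking — a stability-style
shortlist of the t-test passers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .datasets import CohortDataset


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p-value.

    Uses the Welch-Satterthwaite degrees of freedom.  Raises for groups
    with fewer than two observations or zero variance in both groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    sx = vx / x.size
    sy = vy / y.size
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (
        sx**2 / (x.size - 1) + sy**2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def _welch_t_table(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch test across probe rows.

    ``x``/``y``: probes x samples blocks for the two response groups.
    Returns (t, p, testable); probes with zero variance in either group are
    flagged untestable.
    """
    nx, ny = x.shape[1], y.shape[1]
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    testable = (vx > 0) & (vy > 0)
    sx = vx / nx
    sy = vy / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sx + sy)
        df = (sx + sy) ** 2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(testable, t, np.nan)
    p = np.where(testable, np.minimum(p, 1.0), np.nan)
    return t, p, testable


@dataclass
class ScreenResult:
    """Screening output for one regimen group."""

    regimen: str
    probes_tested: int
    probes_passing_t: pd.DataFrame  # probe_id, t_statistic, p_value; by p asc
    excluded_probes: tuple[str, ...] = ()
    rss_table: pd.DataFrame | None = None
    final_ranked_candidates: tuple[str, ...] = ()

    def passers(self) -> tuple[str, ...]:
        return tuple(self.probes_passing_t["probe_id"])

    def to_frame(self) -> pd.DataFrame:
        frame = self.probes_passing_t.copy()
        if self.rss_table is not None:
            frame = frame.merge(self.rss_table, on="probe_id", how="left")
        rank = {p: i for i, p in enumerate(self.final_ranked_candidates)}
        frame["final_rank"] = [rank.get(p, np.nan) for p in frame["probe_id"]]
        return frame


class WelchTScreen(BaseEstimator):
    """Per-probe Welch-t differential-expression filter.

    Parameters
    ----------
    alpha : significance level; probes with p <= alpha are retained
            (boundary inclusive).
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        """X: samples x probes array/DataFrame; y: binary, 1 = pCR."""
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if (y == 1).sum() < 2 or (y == 0).sum() < 2:
            raise ValueError("need at least two samples in each response class")
        block = X.to_numpy(dtype=float).T  # probes x samples
        t, p, testable = _welch_t_table(block[:, y == 1], block[:, y == 0])
        self.feature_names_ = np.asarray(X.columns, dtype=object)
        self.t_statistic_ = t
        self.p_value_ = p
        self.testable_ = testable
        self.support_ = testable & (p <= self.alpha)
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def passers_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "support_")
        frame = pd.DataFrame(
            {
                "probe_id": self.feature_names_[self.support_],
                "t_statistic": self.t_statistic_[self.support_],
                "p_value": self.p_value_[self.support_],
            }
        )
        return frame.sort_values(
            ["p_value", "probe_id"], kind="mergesort"
        ).reset_index(drop=True)


class RandomSamplingScreen(BaseEstimator):
    """Random sampling screening over a set of candidate probes.

    Each of ``n_draws`` draws takes a response-stratified patient subsample
    (fraction ``subsample_fraction``) and a random probe subset of size
    ``min(n_candidates, max_probes)``, fits a random forest, and records
    each drawn probe's impurity-importance rank.  ``selection_frequency``
    is the fraction of a probe's draws in which it ranked in the top
    ``top_q``; candidates are ordered by descending frequency, ties by mean
    rank, then by t-test p-value, then lexicographically.
    """

    def __init__(
        self,
        n_draws: int = 200,
        subsample_fraction: float = 0.7,
        max_probes: int = 200,
        top_q: int = 50,
        n_trees: int = 200,
        random_state: int | None = None,
    ):
        self.n_draws = n_draws
        self.subsample_fraction = subsample_fraction
        self.max_probes = max_probes
        self.top_q = top_q
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y, p_values: Sequence[float] | None = None):
        """X: samples x candidate-probes DataFrame; y binary (1 = pCR).

        ``p_values`` (aligned with X's columns) feed the tie-break chain.
        """
        X = pd.DataFrame(X)
        y = np.asarray(y)
        probes = list(X.columns)
        if not probes:
            raise ValueError("no candidate probes to screen")
        if self.n_draws < 1:
            raise ValueError("n_draws must be positive")
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        n_pos = max(2, int(round(self.subsample_fraction * pos.size)))
        n_neg = max(2, int(round(self.subsample_fraction * neg.size)))
        if pos.size < 2 or neg.size < 2:
            raise ValueError("subsample cannot contain both classes twice")
        m = min(len(probes), self.max_probes)
        values = X.to_numpy(dtype=float)

        top_counts = np.zeros(len(probes))
        drawn_counts = np.zeros(len(probes))
        rank_sums = np.zeros(len(probes))
        for b in range(self.n_draws):
            rows = np.concatenate(
                [
                    rng.choice(pos, size=n_pos, replace=False),
                    rng.choice(neg, size=n_neg, replace=False),
                ]
            )
            cols = rng.choice(len(probes), size=m, replace=False)
            forest = RandomForestClassifier(
                n_estimators=self.n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(values[np.ix_(rows, cols)], y[rows])
            # rank 1 = most important within this draw
            order = np.argsort(-forest.feature_importances_, kind="mergesort")
            ranks = np.empty(m)
            ranks[order] = np.arange(1, m + 1)
            drawn_counts[cols] += 1
            rank_sums[cols] += ranks
            top_counts[cols[ranks <= self.top_q]] += 1

        with np.errstate(invalid="ignore"):
            freq = np.where(drawn_counts > 0, top_counts / drawn_counts, 0.0)
            mean_rank = np.where(
                drawn_counts > 0, rank_sums / drawn_counts, np.inf
            )
        pv = (
            np.asarray(p_values, dtype=float)
            if p_values is not None
            else np.ones(len(probes))
        )
        table = pd.DataFrame(
            {
                "probe_id": probes,
                "selection_frequency": freq,
                "mean_importance_rank": mean_rank,
                "p_value": pv,
            }
        )
        order = table.sort_values(
            by=["selection_frequency", "mean_importance_rank", "p_value", "probe_id"],
            ascending=[False, True, True, True],
            kind="mergesort",
        )
        self.rss_table_ = table.drop(columns="p_value")
        self.ranking_ = tuple(order["probe_id"])
        return self


# ---------------------------------------------------------------------------
# dataset-level wrappers


def t_screen(dataset: CohortDataset, regimen: str, alpha: float = 0.05) -> ScreenResult:
    """Stage-1 screen of one regimen group: Welch test pCR vs RD per probe,
    retain p <= alpha ordered by ascending p."""
    group = dataset.regimen_subset(regimen)
    y = group.response_vector()
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError(
            f"regimen {regimen!r} needs >=2 pCR and >=2 RD samples "
            f"(got {(y == 1).sum()} / {(y == 0).sum()})"
        )
    X = group.expression.to_frame().T
    screen = WelchTScreen(alpha=alpha).fit(X, y)
    excluded = tuple(screen.feature_names_[~screen.testable_])
    return ScreenResult(
        regimen=regimen,
        probes_tested=int(screen.testable_.sum()),
        probes_passing_t=screen.passers_frame(),
        excluded_probes=excluded,
    )


def rss_rank(
    dataset: CohortDataset,
    regimen: str,
    screen_result: ScreenResult,
    n_draws: int = 200,
    subsample_fraction: float = 0.7,
    max_probes: int = 200,
    top_q: int = 50,
    n_trees: int = 200,
    seed: int | None = None,
) -> ScreenResult:
    """Stage-2 RSS ranking of the stage-1 passers; fills ``rss_table`` and
    ``final_ranked_candidates`` on a copy of ``screen_result``."""
    passers = screen_result.passers()
    if not passers:
        return ScreenResult(
            regimen=screen_result.regimen,
            probes_tested=screen_result.probes_tested,
            probes_passing_t=screen_result.probes_passing_t,
            excluded_probes=screen_result.excluded_probes,
            rss_table=pd.DataFrame(
                columns=["probe_id", "selection_frequency", "mean_importance_rank"]
            ),
            final_ranked_candidates=(),
        )
    group = dataset.regimen_subset(regimen)
    X = group.expression.to_frame().T[list(passers)]
    y = group.response_vector()
    pmap = dict(
        zip(screen_result.probes_passing_t["probe_id"],
            screen_result.probes_passing_t["p_value"])
    )
    rss = RandomSamplingScreen(
        n_draws=n_draws,
        subsample_fraction=subsample_fraction,
        max_probes=max_probes,
        top_q=top_q,
        n_trees=n_trees,
        random_state=seed,
    ).fit(X, y, p_values=[pmap[p] for p in passers])
    return ScreenResult(
        regimen=screen_result.regimen,
        probes_tested=screen_result.probes_tested,
        probes_passing_t=screen_result.probes_passing_t,
        excluded_probes=screen_result.excluded_probes,
        rss_table=rss.rss_table_,
        final_ranked_candidates=rss.ranking_,
    )
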