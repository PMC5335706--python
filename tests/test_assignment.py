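"""The regimen-selection rule, its dominance guarantees and the bootstrap
confidence interval."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pres.assignment import (
    AssignmentResult,
    assign,
    assign_cohort,
    assign_many,
    bootstrap_ci,
    map_to_score,
)
from pres.calibration import compute_pi_table
from pres.datasets import REGIMENS


def rule_oracle(a, ta, txa, margin=0.01, original=None, mode="toxicity"):
    """Independent brute-force restatement of the selection rule for fully
    defined score triples."""
    if mode == "toxicity" and a >= max(ta, txa) - margin:
        return "A"
    best = max(a, ta, txa)
    tied = [r for r, s in zip(REGIMENS, (a, ta, txa)) if s == best]
    if len(tied) == 1:
        return tied[0]
    if original in tied:
        return original
    return tied[0]


class TestAssignRule:
    def test_toxicity_margin_prefers_anthracycline(self):
        # A within 0.01 of the best taxane score -> A
        assert assign({"A": 0.30, "TA": 0.305, "TxA": 0.29}) == "A"

    def test_clear_argmax(self):
        assert assign({"A": 0.10, "TA": 0.20, "TxA": 0.50}) == "TxA"

    def test_taxane_tie_keeps_original_regimen(self):
        scores = {"A": 0.00, "TA": 0.40, "TxA": 0.40}
        assert assign(scores, original_regimen="TxA") == "TxA"
        assert assign(scores, original_regimen="TA") == "TA"
        assert assign(scores, original_regimen="A") == "TA"
        assert assign(scores) == "TA"

    def test_max_score_mode_ignores_margin(self):
        scores = {"A": 0.30, "TA": 0.305, "TxA": 0.29}
        assert assign(scores, mode="max_score") == "TA"

    def test_undefined_scores_skipped(self):
        assert assign({"TA": float("nan"), "TxA": 0.3}) == "TxA"
        assert assign({"A": 0.1}) == "A"

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            assign({"A": float("nan")})

    @settings(derandomize=True, max_examples=300)
    @given(
        a=st.integers(0, 200),
        ta=st.integers(0, 200),
        txa=st.integers(0, 200),
        original=st.sampled_from(REGIMENS),
        mode=st.sampled_from(["toxicity", "max_score"]),
    )
    def test_rule_matches_brute_force_oracle(self, a, ta, txa, original, mode):
        sa, sta, stxa = a / 200, ta / 200, txa / 200
        got = assign(
            {"A": sa, "TA": sta, "TxA": stxa},
            original_regimen=original,
            mode=mode,
        )
        assert got == rule_oracle(sa, sta, stxa, original=original, mode=mode)

    def test_vectorised_rule_matches_scalar(self):
        rng = np.random.default_rng(21)
        scores = rng.integers(0, 201, size=(5000, 3)) / 200.0
        originals = rng.choice(REGIMENS, size=5000)
        vec = assign_many(scores, original_regimens=originals)
        for i in range(0, 5000, 7):
            scalar = assign(
                dict(zip(REGIMENS, scores[i])), original_regimen=originals[i]
            )
            assert vec[i] == scalar


class TestMapToScore:
    def table(self):
        return compute_pi_table(
            np.array([0.1, 0.15, 0.3, 0.85, 0.9]),
            np.array([0, 1, 0, 1, 1]),
        )

    def test_score_of_containing_bin(self):
        assert map_to_score(0.15, self.table()) == 0.5

    def test_boundary_half_open(self):
        # 0.2 falls in the second bin, whose score is 0
        assert map_to_score(0.2, self.table()) == 0.0

    def test_empty_bin_uses_nearest_neighbour(self):
        assert map_to_score(0.65, self.table()) == 1.0


def random_assignment(seed=0, n=400, mode="toxicity"):
    rng = np.random.default_rng(seed)
    probs = pd.DataFrame(
        rng.uniform(0, 1, size=(n, 3)),
        columns=list(REGIMENS),
        index=[f"S{i}" for i in range(n)],
    )
    tables = {}
    for r in REGIMENS:
        p = rng.uniform(0, 1, size=300)
        y = (rng.uniform(size=300) < p).astype(int)
        tables[r] = compute_pi_table(p, y, regimen=r)
    originals = rng.choice(REGIMENS, size=n)
    result = assign_cohort(probs, tables, originals, mode=mode)
    return result, tables, probs


class TestAssignCohort:
    def test_expected_count_is_sum_of_assigned_scores(self):
        result, _, _ = random_assignment(seed=1)
        assert result.expected_pcr_count == pytest.approx(
            result.patients["assigned_score"].sum(), abs=1e-12
        )
        assert result.expected_pcr_rate == pytest.approx(
            result.expected_pcr_count / len(result.patients), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_max_score_dominates_single_regimen_scores(self, seed):
        """Exact algebraic dominance: the argmax assignment's expected pCR is
        at least the expected pCR of any fixed-regimen assignment, computed
        from the same tables."""
        result, _, _ = random_assignment(seed=seed, mode="max_score")
        p = result.patients
        for r in REGIMENS:
            assert result.expected_pcr_count >= p[f"score_{r}"].sum() - 1e-9

    @pytest.mark.parametrize("seed", range(3))
    def test_toxicity_mode_loss_bounded_by_margin(self, seed):
        result, _, _ = random_assignment(seed=seed, mode="toxicity")
        p = result.patients
        best_single = max(p[f"score_{r}"].sum() for r in REGIMENS)
        margin = result.toxicity_margin
        assert result.expected_pcr_count >= best_single - margin * len(p) - 1e-9
        # per-patient: assigned within margin of the patient's best score
        best_each = p[[f"score_{r}" for r in REGIMENS]].max(axis=1)
        assert (p["assigned_score"] >= best_each - margin - 1e-12).all()

    def test_max_score_rate_at_least_toxicity_rate(self):
        tox, _, _ = random_assignment(seed=5, mode="toxicity")
        mx, _, _ = random_assignment(seed=5, mode="max_score")
        assert mx.expected_pcr_rate >= tox.expected_pcr_rate - 1e-12

    def test_identical_score_triples_get_identical_regimen(self):
        probs = pd.DataFrame(
            np.tile([0.1, 0.5, 0.3], (10, 1)),
            columns=list(REGIMENS),
            index=[f"S{i}" for i in range(10)],
        )
        _, tables, _ = random_assignment(seed=2)
        result = assign_cohort(probs, tables, ["TA"] * 10)
        assert result.patients["assigned_regimen"].nunique() == 1

    def test_over_and_undertreatment_definitions(self):
        tables = {
            r: compute_pi_table(
                np.linspace(0.01, 0.99, 50), (np.linspace(0.01, 0.99, 50) > 0.5).astype(int), regimen=r
            )
            for r in REGIMENS
        }
        probs = pd.DataFrame(
            [[0.9, 0.1, 0.1], [0.1, 0.9, 0.9]],
            columns=list(REGIMENS),
            index=["over", "under"],
        )
        result = assign_cohort(probs, tables, ["TA", "A"])
        # patient 'over' received TA though A scores at least as well
        assert result.overtreated_fraction() == 0.5
        # patient 'under' received A though a taxane scores strictly better
        assert result.undertreated_fraction() == 0.5


class TestBootstrapCI:
    def test_reproducible_given_seed(self):
        result, tables, _ = random_assignment(seed=3)
        ci1 = bootstrap_ci(result, tables, n_boot=200, seed=11)
        ci2 = bootstrap_ci(result, tables, n_boot=200, seed=11)
        assert ci1 == ci2

    def test_interval_contains_rate_and_stays_in_unit_interval(self):
        result, tables, _ = random_assignment(seed=4)
        lo, hi = bootstrap_ci(result, tables, n_boot=500, seed=1)
        assert 0.0 <= lo <= hi <= 1.0
        assert lo <= result.expected_pcr_rate <= hi

    def test_huge_bins_shrink_interval(self):
        rng = np.random.default_rng(6)
        n_cal = 200_000
        p = rng.uniform(0, 1, size=n_cal)
        y = (rng.uniform(size=n_cal) < p).astype(int)
        tables = {r: compute_pi_table(p, y, regimen=r) for r in REGIMENS}
        probs = pd.DataFrame(
            rng.uniform(0, 1, size=(100, 3)),
            columns=list(REGIMENS),
            index=[f"S{i}" for i in range(100)],
        )
        result = assign_cohort(probs, tables, ["TA"] * 100)
        lo, hi = bootstrap_ci(result, tables, n_boot=300, seed=2)
        assert hi - lo < 0.01
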