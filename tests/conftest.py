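"""Shared fixtures: a micro-scale pipeline profile and a small simulated
multi-cohort dataset with its fitted PRES state, reused across test files."""

from __future__ import annotations

import pytest

from pres.pipeline import PipelineConfig, fit_pres
from pres.simulate import SimulationConfig, simulate, small_design


def micro_profile() -> PipelineConfig:
    """Smallest pipeline settings that still exercise every stage."""
    return PipelineConfig(
        rss_draws=10,
        rss_trees=10,
        rss_max_probes=50,
        rss_top_q=10,
        k_grid=(0, 2, 4, 8),
        select_folds=2,
        n_trees=25,
        oof_folds=3,
        n_boot=100,
        min_arm_size=10,
    )


@pytest.fixture(scope="session")
def profile() -> PipelineConfig:
    return micro_profile()


@pytest.fixture(scope="session")
def small_sim():
    """Two-cohort dataset with planted signatures, plus its ground truth."""
    config = SimulationConfig(
        seed=42,
        n_probes=150,
        effect_size=1.2,
        signature_sizes={"A": 3, "TA": 5, "TxA": 5},
        cohort_design=small_design({"A": 60, "TA": 60, "TxA": 60}, n_cohorts=2),
    )
    return simulate(config)


@pytest.fixture(scope="session")
def small_fit(small_sim, profile):
    dataset, _ = small_sim
    return fit_pres(dataset, profile, seed=7)
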