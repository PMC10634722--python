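"""Shared fixtures: small simulated cohorts and fixture clocks.

Everything is generated programmatically; no data files are stored.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from eaakit.clocks import score_all
from eaakit.simulate import SimConfig, make_fixture_clocks, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)

ZERO_SHIFT = {"healthy": 0.0, "normal": 0.0, "tumour": 0.0, "adenoma": 0.0}
HN_ONLY = {"healthy": 0.5, "normal": 0.5, "tumour": 0.0, "adenoma": 0.0}


def hn_config(**kw) -> SimConfig:
    """Healthy/normal-only cohort config with compact defaults."""
    base = dict(
        n_datasets=2,
        samples_per_dataset=100,
        tissue_proportions=HN_ONLY,
        group_shift={**ZERO_SHIFT, "normal": -5.0},
        age_range_years=(30.0, 88.0),
        n_cpgs=80,
        clock_cpg_fraction=0.25,
        batch_sd=1.0,
        platform_effect=0.0,
        noise_sd=0.02,
        seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    """Default four-tissue cohort with all planted effects on."""
    cfg = SimConfig(seed=7)
    beta, sheet, gt = simulate_cohort(cfg)
    return cfg, beta, sheet, gt


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, batch-free, shift-free cohort for exactness checks."""
    cfg = SimConfig(
        seed=11, noise_sd=0.0, batch_sd=0.0, platform_effect=0.0,
        group_shift=dict(ZERO_SHIFT),
    )
    beta, sheet, gt = simulate_cohort(cfg)
    return cfg, beta, sheet, gt


@pytest.fixture(scope="session")
def scored_cohort(cohort):
    cfg, beta, sheet, gt = cohort
    clocks = make_fixture_clocks(gt.clock_cpg_ids, gt)
    scoreset = score_all(beta, clocks)
    return cfg, beta, sheet, gt, clocks, scoreset
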