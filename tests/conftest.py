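"""Shared fixtures: small simulated slices/cohorts, all generated at test time."""

import numpy as np
import pytest

from measlice.synthetic import CohortConfig, simulate_slice


@pytest.fixture(scope="session")
def default_cfg() -> CohortConfig:
    return CohortConfig(seed=1)


@pytest.fixture(scope="session")
def sim_slice(default_cfg):
    """One default IHKA DG slice with truth (seed 42)."""
    return simulate_slice(default_cfg, "IHKA_a00", "IHKA_a00_s0", "IHKA", seed=42)


@pytest.fixture(scope="session")
def noiseless_slice():
    """Noiseless slice with PS guaranteed at every intensity."""
    from measlice.synthetic import GroupParams, default_group_params
    import dataclasses
    gp = dataclasses.replace(default_group_params("IHKA", "DG"),
                             ps_logistic_a=10.0, slope_intercept=0.15)
    cfg = CohortConfig(seed=3, noise_sd_uv=0.0, n_repeats=1,
                       artifact_amp_mv=0.0,
                       slice_sd_intercept=0.0, slice_sd_gain=0.0,
                       animal_sd_intercept=0.0, ps_slice_sd_logit=0.0,
                       ps_animal_sd_logit=0.0, ppr_slice_sd=0.0,
                       group_params={"IHKA": gp,
                                     "control": default_group_params("control", "DG")})
    return simulate_slice(cfg, "A", "S", "IHKA", seed=7), cfg


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
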