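import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neurocystometry import (CohortConfig, aa_params, generate_recording,
                             saline_params, simulate_pressure)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_cohort_config(**kwargs) -> CohortConfig:
    """Scaled-down study configuration for cheap tests.

    Nerve channel at 2.5 kHz (rate ratio 100) and a 0.1 ml capacity keep a
    full recording around half a million nerve samples while preserving
    every structural feature of the default conditions.
    """
    defaults = dict(n_per_condition=2, seed=0, nerve_rate_hz=2500.0)
    defaults.update(kwargs)
    return CohortConfig(**defaults)


def small_params(label="saline", crushed=True, **overrides):
    base = saline_params if label == "saline" else aa_params
    overrides.setdefault("capacity_ml", 0.1 if label == "saline" else 0.069)
    overrides.setdefault("carrier_band_hz", (200.0, 1000.0))
    return base(crushed=crushed, **overrides)


@pytest.fixture(scope="session")
def small_recording():
    """One scaled-down crushed-nerve saline recording with ground truth."""
    cfg = small_cohort_config()
    rec, truth = generate_recording(small_params(), cfg, seed=11)
    return rec, truth, cfg


@pytest.fixture(scope="session")
def default_pressure():
    """One full-scale saline pressure trace with ground truth."""
    cfg = CohortConfig(n_per_condition=1, seed=0,
                       conditions=(saline_params(crushed=True),))
    p, truth = simulate_pressure(saline_params(crushed=True), cfg, seed=21)
    return p, truth


@pytest.fixture(scope="session")
def crushed_cohorts():
    """Full-scale crushed-nerve recordings at the printed condition values.

    10 acetic-acid and 9 saline recordings, master seed 0, seeded the same
    way as generate_cohort.  Session-scoped because generation dominates
    the cost of every recovery test that uses them.
    """
    cfg = CohortConfig(n_per_condition=10, seed=0)
    aa = []
    for i in range(10):
        seed = (cfg.seed * 65536 + i * 2) % 2**31
        aa.append(generate_recording(aa_params(crushed=True), cfg, seed))
    saline = []
    for i in range(9):
        seed = (cfg.seed * 65536 + (10 + i) * 2) % 2**31
        saline.append(generate_recording(saline_params(crushed=True), cfg, seed))
    return {"AA": aa, "saline": saline}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
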