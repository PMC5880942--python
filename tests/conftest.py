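"""Shared fixtures.

The heavy condition batches (full-size network, tens of trials) are
session-scoped and lazily built, so every test that needs the default
condition shares one set of 30 paired trials.
"""

from __future__ import annotations

import numpy as np
import pytest

from dynsyn import Condition, NetworkParams, PeriodSet, run_condition

BASE_SEED = 1000
N_TRIALS_DEFAULT = 30
N_TRIALS_CONTROL = 30
N_TRIALS_VARIANT = 20


@pytest.fixture()
def small_params() -> NetworkParams:
    """A scaled-down network for fast dynamical tests."""
    return NetworkParams(N_E=80, N_I=20, T=1200.0)


@pytest.fixture()
def short_periods() -> PeriodSet:
    """Periods fitting inside the short trials of ``small_params``."""
    return PeriodSet({"Pre-adp": (-400.0, -200.0), "Adp": (100.0, 300.0),
                      "Post-adp": (400.0, 600.0)})


@pytest.fixture(scope="session")
def default_batch():
    """30 paired trials of the full default condition (Table-of-defaults)."""
    return run_condition("default", N_TRIALS_DEFAULT, BASE_SEED, progress=True)


@pytest.fixture(scope="session")
def static_batch():
    return run_condition("static", N_TRIALS_CONTROL, BASE_SEED, progress=True)


@pytest.fixture(scope="session")
def transient_batch():
    return run_condition("transient", N_TRIALS_CONTROL, BASE_SEED, progress=True)


@pytest.fixture(scope="session")
def variant_batches():
    return {
        name: run_condition(Condition.from_name("stp_variant", name),
                            N_TRIALS_VARIANT, BASE_SEED, progress=True)
        for name in ("tf1000", "tf400", "tf50")
    }
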