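"""Shared fixtures: large simulated cohorts reused across test modules.

The million-record cohorts back the large-sample consistency checks; they
are session-scoped so each is simulated exactly once per test run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hetmr import (
    Cohort,
    method1_scenario,
    method2_scenario,
    shared_scenario,
    simulate_cohort,
)

N_LARGE = 1_000_000


@pytest.fixture(scope="session")
def m1_cohort():
    """Million-record cohort under Method-1-compatible conditions (G-S effect on)."""
    return simulate_cohort(method1_scenario(N_LARGE, seed=11))


@pytest.fixture(scope="session")
def m2_cohort():
    """Million-record cohort under Method-2-compatible conditions (pleiotropy on)."""
    return simulate_cohort(method2_scenario(N_LARGE, seed=12))


@pytest.fixture(scope="session")
def clean_cohort():
    """Million-record cohort with every moderator violation switched off."""
    return simulate_cohort(shared_scenario(N_LARGE, seed=13))


@pytest.fixture
def toy_cells():
    """Deterministic 4-cell cohort with known means per (S, G) cell.

    Exposed means 3300 (G=1) and 3450 (G=0); unexposed means both 3600,
    so GMEE(1) = -150, GMEE(0) = 0, RGMEE = -150.
    """
    rows = []
    for s, g, mean in [(1, 1, 3300.0), (1, 0, 3450.0), (0, 1, 3600.0), (0, 0, 3600.0)]:
        for delta in (-10.0, 10.0):
            rows.append(dict(y=mean + delta, s=s, g=g, g2=float(g != s)))
    frame = pd.DataFrame(rows)
    return Cohort.from_frame(frame)


def make_deterministic_toy(n: int = 400, seed: int = 5) -> Cohort:
    """Noise-free cohort with s = g2 exactly and y = 3500 - 100*s."""
    rng = np.random.default_rng(seed)
    g2 = (rng.random(n) < 0.4).astype(float)
    g = (rng.random(n) < 0.5).astype(float)
    s = g2.copy()
    y = 3500.0 - 100.0 * s
    return Cohort(y=y, s=s, g=g, g2=g2)
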