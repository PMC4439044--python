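import numpy as np
import pandas as pd
import pytest

from otoscape import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced-scale season (~50k outmigrants) shared by read-only tests."""
    return syn.generate_cohort(
        pulses=[("2000-02-15", 30_000), ("2000-04-10", 15_000)],
        baseline_total=5_000, seed=101)


@pytest.fixture(scope="session")
def references():
    """Known-origin isoscape reference table (5 sites)."""
    return syn.make_isoscape_references(seed=202)


@pytest.fixture(scope="session")
def calibration_exact():
    """Noise-free OR–FL calibration pairs (refit recovers the line exactly)."""
    return syn.generate_calibration(n=60, resid_sd_mm=0.0, seed=303)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def season_2000():
    return pd.date_range("2000-01-01", "2000-06-30", freq="D")
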