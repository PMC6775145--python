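import numpy as np
import pytest

from hrvstage.io import IBISeries
from hrvstage.synthetic import DEFAULT_PROFILES, SimConfig, simulate_hypnogram, simulate_ibi


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def short_night():
    """One simulated 15-min recording (30 epochs) with its true hypnogram."""
    cfg = SimConfig(tib_hours=1.0)
    hyp = simulate_hypnogram(cfg, seed=11)
    hyp.stages = hyp.stages[:30]
    series = simulate_ibi(hyp, DEFAULT_PROFILES, seed=12)
    return hyp, series


def make_series(rr_ms: np.ndarray) -> IBISeries:
    """Series with beat times accumulated from the given intervals."""
    rr_ms = np.asarray(rr_ms, dtype=float)
    t = np.cumsum(rr_ms) / 1000.0
    return IBISeries(t, rr_ms, np.ones(rr_ms.size, bool))
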