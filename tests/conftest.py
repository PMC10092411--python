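import numpy as np
import pytest

from fretkit.spectra import gaussian_spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def dcm_bands():
    """DCM-like donor emission / acceptor absorption Gaussian bands."""
    grid = np.arange(300.0, 801.0, 1.0)
    emission = gaussian_spectrum(590.0, 95.0, 1.0, grid, "emission")
    absorption = gaussian_spectrum(457.0, 90.0, 48700.0, grid, "absorption")
    return emission, absorption


def sample_markov_chain(T: np.ndarray, n: int, seed: int, start: int = 0) -> np.ndarray:
    """Simulate a discrete-time Markov chain via geometric dwell sampling."""
    T = np.asarray(T, dtype=float)
    rng = np.random.default_rng(seed)
    k = T.shape[0]
    out = np.empty(n, dtype=np.int64)
    s = start
    i = 0
    p_stay = np.diag(T)
    jump = T.copy()
    np.fill_diagonal(jump, 0.0)
    rows = jump.sum(axis=1)
    jump = jump / rows[:, None]
    cum = np.cumsum(jump, axis=1)
    while i < n:
        escape = 1.0 - p_stay[s]
        dwell = rng.geometric(escape) if escape > 0 else n - i
        dwell = min(dwell, n - i)
        out[i:i + dwell] = s
        i += dwell
        if i < n:
            s = int(np.searchsorted(cum[s], rng.random()))
    return out
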