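import numpy as np
import pytest

from rrisim import BeatSeries, Epoch, RRITachogram, beats_to_rri


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


def tachogram_from_rri(rri_ms, start_ms=0.0):
    """Build a tachogram from an RRI sequence via cumulative beat times."""
    rri = np.asarray(rri_ms, dtype=float)
    beats = start_ms + np.concatenate([[0.0], np.cumsum(rri)])
    return beats_to_rri(BeatSeries("t", "maternal", beats))


def epoch_from_rri(m_rri, f_rri, start_ms=0.0, end_ms=None):
    """Epoch whose maternal/fetal slices come from explicit RRI lists."""
    m = tachogram_from_rri(m_rri, start_ms)
    f = tachogram_from_rri(f_rri, start_ms)
    if end_ms is None:
        end_ms = start_ms + min(m.times[-1], f.times[-1]) + 1.0
    return Epoch(start_ms, end_ms,
                 m.slice(start_ms, end_ms), f.slice(start_ms, end_ms))


@pytest.fixture
def clean_epoch():
    """3-min epoch: maternal beats every 150 ms, fetal every 500 ms, with
    deterministic low-amplitude structure so normalization is defined."""
    n_m = 180_000 // 150
    m_rri = 150.0 + 10.0 * np.sin(2 * np.pi * 0.05 * np.arange(n_m) * 0.15)
    n_f = 180_000 // 500
    f_rri = 500.0 + 30.0 * np.sin(2 * np.pi * 0.05 * np.arange(n_f) * 0.5)
    return epoch_from_rri(m_rri, f_rri, 0.0, 180_000.0)
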