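"""Beat-series ingestion, RR-interval tachograms and epoch selection.

Inputs are per-subject beat data for one simultaneously recorded
maternal-fetal pair: either R-peak timestamps or RR-interval (RRI)
sequences, both in milliseconds on a shared recording clock. The module
converts beats to tachograms and scans the paired record for artifact-free
3-minute analysis epochs, skipping the first minute of the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

EPOCH_LEN_MS = 180_000
SETTLE_MS = 60_000  # first minute discarded as unstable


class IngestError(ValueError):
    """Raised for invalid beat data or impossible epoch requests."""


@dataclass(frozen=True)
class BeatSeries:
    """Ordered R-peak times for one subject, ms from recording start."""

    subject_id: str
    role: str  # "maternal" | "fetal"
    beat_times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.beat_times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise IngestError("BeatSeries needs at least 2 beats")
        if t[0] < 0:
            raise IngestError("beat times must be >= 0")
        d = np.diff(t)
        if np.any(d <= 0):
            idx = int(np.argmax(d <= 0)) + 1
            raise IngestError(f"non-monotone beat times at index {idx}")
        if self.role not in ("maternal", "fetal"):
            raise IngestError(f"role must be maternal|fetal, got {self.role!r}")
        object.__setattr__(self, "beat_times", t)

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def duration_ms(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass(frozen=True)
class RRITachogram:
    """Successive RR intervals with their terminating-beat times (ms).

    Irregularly sampled by construction: interval ``rri[i]`` ends at
    ``times[i]``.
    """

    times: np.ndarray
    rri: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.rri, dtype=float)
        if t.size != r.size:
            raise IngestError("times and rri must have equal length")
        if np.any(r <= 0):
            raise IngestError("all RRI must be positive")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise IngestError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rri", r)

    def slice(self, start_ms: float, end_ms: float) -> "RRITachogram":
        """Intervals whose terminating beat falls in [start_ms, end_ms)."""
        m = (self.times >= start_ms) & (self.times < end_ms)
        return RRITachogram(self.times[m], self.rri[m])


@dataclass(frozen=True)
class Epoch:
    """A shared artifact-free window with simultaneous tachogram slices."""

    start_ms: float
    end_ms: float
    maternal: RRITachogram
    fetal: RRITachogram

    def __post_init__(self):
        if self.end_ms <= self.start_ms:
            raise IngestError("epoch end must exceed start")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class QualityConfig:
    """Deterministic stand-in for visual noise/arrhythmia screening.

    A window fails if any RRI deviates from the window median by more than
    ``max_median_deviation`` (fractional) or falls outside the subject's
    physiological band. Default bands: maternal 50-300 ms; fetal
    200-1,100 ms (the observed fetal mean-RRI range is 306-981 ms).
    """

    max_median_deviation: float = 0.30
    maternal_band_ms: tuple = (50.0, 300.0)
    fetal_band_ms: tuple = (200.0, 1100.0)
    min_beats: int = 10

    def band_for(self, role: str) -> tuple:
        return self.maternal_band_ms if role == "maternal" else self.fetal_band_ms


def read_beats(path, schema: str = "beats", units: str = "ms",
               subject_id: str | None = None, role: str = "maternal",
               start_time: float = 0.0) -> BeatSeries:
    """Read a one-column CSV/TSV of beat times or RR intervals.

    Parameters
    ----------
    schema : {"beats", "rri"}
        ``beats`` expects a ``t_ms`` (or single) column of timestamps;
        ``rri`` expects ``rri_ms`` intervals, converted to beat times by
        cumulative sum from ``start_time``.
    units : {"ms", "s"}
        Seconds are converted to milliseconds on read.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if schema == "beats":
        col = "t_ms" if "t_ms" in df.columns else df.columns[0]
        vals = df[col].to_numpy(dtype=float)
    elif schema == "rri":
        col = "rri_ms" if "rri_ms" in df.columns else df.columns[0]
        rri = df[col].to_numpy(dtype=float)
        if units == "s":
            rri = rri * 1000.0
        if np.any(rri <= 0):
            idx = int(np.argmax(rri <= 0))
            raise IngestError(f"non-positive RRI at index {idx}")
        vals = start_time + np.concatenate([[0.0], np.cumsum(rri)])
        return BeatSeries(subject_id or path.stem, role, vals)
    else:
        raise IngestError(f"unknown schema {schema!r}")
    if units == "s":
        vals = vals * 1000.0
    return BeatSeries(subject_id or path.stem, role, vals)


def beats_to_rri(beats: BeatSeries) -> RRITachogram:
    """First differences of beat times; interval i ends at beat i+1."""
    if beats.n_beats < 2:
        raise IngestError("need at least 2 beats to form intervals")
    t = beats.beat_times
    return RRITachogram(times=t[1:], rri=np.diff(t))


def detect_r_peaks(ecg: np.ndarray, fs: float, refractory_ms: float = 50.0,
                   subject_id: str = "ecg", role: str = "maternal") -> BeatSeries:
    """Adaptive-threshold local-maximum R-peak detector for toy ECG.

    Intended for round-trip tests against synthetically generated traces,
    not for real recordings. Threshold: median + 40% of the median-to-max
    excursion; minimum peak separation set by the refractory period.
    """
    x = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise IngestError("sampling rate must be >= 100 Hz")
    if x.size < 2 * fs:
        raise IngestError("trace shorter than 2 s")
    med = np.median(x)
    excursion = x.max() - med
    if excursion <= 0:
        raise IngestError("no peaks found: flat trace")
    height = med + 0.4 * excursion
    distance = max(1, int(round(refractory_ms * fs / 1000.0)))
    peaks, _ = find_peaks(x, height=height, distance=distance)
    if peaks.size < 2:
        raise IngestError("no peaks found above adaptive threshold")
    return BeatSeries(subject_id, role, peaks * 1000.0 / fs)


def _window_clean(tach: RRITachogram, start: float, end: float,
                  band: tuple, quality: QualityConfig) -> bool:
    seg = tach.slice(start, end)
    if seg.rri.size < quality.min_beats:
        return False
    lo, hi = band
    if np.any(seg.rri < lo) or np.any(seg.rri > hi):
        return False
    med = np.median(seg.rri)
    return not np.any(np.abs(seg.rri - med) > quality.max_median_deviation * med)


def select_epochs(maternal: RRITachogram, fetal: RRITachogram,
                  epoch_len_ms: float = EPOCH_LEN_MS, n_epochs: int = 2,
                  quality: QualityConfig | None = None,
                  step_ms: float = 1_000.0):
    """Scan a paired record for clean shared epochs after the first minute.

    Slides a window in 1-s steps from the 60-s mark and takes the earliest
    window where both subjects pass screening, then the earliest passing
    window after it, preferring consecutive placement. Returns
    ``(epochs, complete)`` where ``complete`` is False when fewer than
    ``n_epochs`` clean windows exist (the caller may then exclude the dyad).
    """
    quality = quality or QualityConfig()
    record_end = min(maternal.times[-1], fetal.times[-1])
    if record_end < SETTLE_MS + epoch_len_ms:
        raise IngestError(
            f"record too short: need {SETTLE_MS + epoch_len_ms} ms after start, "
            f"have {record_end:.0f} ms")
    epochs: list[Epoch] = []
    cursor = float(SETTLE_MS)
    while len(epochs) < n_epochs and cursor + epoch_len_ms <= record_end:
        start = cursor
        found = None
        while start + epoch_len_ms <= record_end:
            end = start + epoch_len_ms
            ok = (_window_clean(maternal, start, end,
                                quality.band_for("maternal"), quality)
                  and _window_clean(fetal, start, end,
                                    quality.band_for("fetal"), quality))
            if ok:
                found = Epoch(start, end, maternal.slice(start, end),
                              fetal.slice(start, end))
                break
            start += step_ms
        if found is None:
            break
        epochs.append(found)
        cursor = found.end_ms
    return epochs, len(epochs) >= n_epochs


def epoch_manifest(epochs: list, mother_id: str, fetus_id: str,
                   complete: bool) -> pd.DataFrame:
    """Tabular record of selected epochs for one dyad."""
    rows = [{"mother_id": mother_id, "fetus_id": fetus_id,
             "epoch_index": i, "start_ms": ep.start_ms, "end_ms": ep.end_ms,
             "passed_quality": complete}
            for i, ep in enumerate(epochs)]
    return pd.DataFrame(rows, columns=["mother_id", "fetus_id", "epoch_index",
                                       "start_ms", "end_ms", "passed_quality"])
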