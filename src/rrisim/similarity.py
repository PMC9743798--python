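"""Similarity coefficients for one maternal-fetal epoch pair.

Pipeline: resample each tachogram onto a uniform 2-s grid (mean RRI per
bin; a 3-min epoch yields 90 samples at 0.5 Hz), normalize each series to
zero mean and unit maximum absolute deviation,

    x_norm = (x - mean(x)) / max|x - mean(x)|,

then score similarity two ways:

* time domain — the normalized pair is cut into consecutive
  non-overlapping 10-sample windows and the zero-lag normalized
  cross-correlation r_w = sum(m f) / sqrt(sum m^2 sum f^2) is computed per
  window (9 coefficients per 3-min epoch). CC1 is the mean of |r_w|, CC2
  the signed mean.
* frequency domain — Welch magnitude-squared coherence (segment length 10,
  Hamming taper, 50% overlap, nfft 256, fs 0.5 Hz; maximum frequency
  0.25 Hz), band-averaged over LF (0.04-0.15) Hz and HF (0.15-0.25) Hz to
  give CLF and CHF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .ingest import Epoch, RRITachogram


class SimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class UniformSeries:
    """RRI means on a fixed grid; dimensionless once normalized."""

    values: np.ndarray
    fs: float = 0.5
    normalized: bool = False

    def __post_init__(self):
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))

    def __len__(self):
        return self.values.size


@dataclass(frozen=True)
class WindowedCC:
    """Per-window zero-lag correlation coefficients; NaN marks a window
    where a coefficient is undefined (all-zero signal)."""

    coefficients: np.ndarray
    window_len: int = 10

    @property
    def valid(self) -> np.ndarray:
        return self.coefficients[~np.isnan(self.coefficients)]

    @property
    def n_valid(self) -> int:
        return int(self.valid.size)


@dataclass(frozen=True)
class CoherenceSpectrum:
    freqs: np.ndarray
    msc: np.ndarray


@dataclass(frozen=True)
class BandDefinition:
    """Half-open LF band, closed-top HF band; the shared 0.15 Hz edge is
    counted once (in HF)."""

    lf: tuple = (0.04, 0.15)
    hf: tuple = (0.15, 0.25)


@dataclass(frozen=True)
class SimilarityScores:
    cc1: float
    cc2: float
    clf: float
    chf: float
    n_valid_windows: int = 9


@dataclass
class SimilarityConfig:
    """Tunable analysis parameters with the defaults used throughout."""

    bin_width_ms: float = 2_000.0
    window_len: int = 10
    fs: float = 0.5
    bands: BandDefinition = field(default_factory=BandDefinition)
    lag_policy: str = "zero"      # {"zero", "max_abs"}
    center_windows: bool = False  # Eq-style global centering only, by default
    welch_taper: str = "hamming"
    welch_overlap: float = 0.5
    welch_nfft: int = 256


def resample_uniform(tach: RRITachogram, epoch: Epoch,
                     bin_width_ms: float = 2_000.0) -> UniformSeries:
    """Mean RRI per fixed-width bin across the epoch.

    Bin k collects intervals whose terminating beat time falls in
    [start + k*bin, start + (k+1)*bin). An empty bin raises a gap error;
    bins must be wide enough to hold at least one interval of the slowest
    plausible heart (2 s accommodates fetal RRI up to ~1 s).
    """
    n_bins = int(np.floor(epoch.duration_ms / bin_width_ms))
    if n_bins < 1:
        raise SimilarityError("epoch shorter than one bin")
    seg = tach.slice(epoch.start_ms, epoch.start_ms + n_bins * bin_width_ms)
    if seg.rri.size == 0:
        raise SimilarityError("tachogram does not cover the epoch")
    idx = np.floor((seg.times - epoch.start_ms) / bin_width_ms).astype(int)
    sums = np.bincount(idx, weights=seg.rri, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise SimilarityError(f"empty resampling bin at index {empty[0]}")
    return UniformSeries(sums / counts, fs=1000.0 / bin_width_ms,
                         normalized=False)


def normalize(series: UniformSeries) -> UniformSeries:
    """Zero-mean, unit-max-absolute normalization of a resampled series."""
    if series.normalized:
        raise SimilarityError("series already normalized")
    x = series.values
    dev = x - x.mean()
    peak = np.max(np.abs(dev))
    if peak == 0:
        raise SimilarityError("degenerate signal: constant input")
    return UniformSeries(dev / peak, fs=series.fs, normalized=True)


def _window_pairs(m: np.ndarray, f: np.ndarray, window_len: int):
    n = m.size
    n_win = n // window_len
    if n % window_len:
        warnings.warn(f"dropping {n % window_len} trailing samples "
                      f"(length {n} not divisible by {window_len})")
    mw = m[:n_win * window_len].reshape(n_win, window_len)
    fw = f[:n_win * window_len].reshape(n_win, window_len)
    return mw, fw


def windowed_cc(m: UniformSeries, f: UniformSeries,
                window_len: int = 10, lag_policy: str = "zero",
                center_windows: bool = False) -> WindowedCC:
    """Per-window normalized cross-correlation of two normalized series.

    ``lag_policy="zero"`` keeps the zero-lag coefficient (the default: the
    only choice whose sign carries the direction of co-variation);
    ``"max_abs"`` keeps the coefficient with the largest magnitude over all
    lags within the window.
    """
    if not (m.normalized and f.normalized):
        raise SimilarityError("both series must be normalized first")
    if len(m) != len(f):
        raise SimilarityError("series lengths differ")
    mw, fw = _window_pairs(m.values, f.values, window_len)
    if center_windows:
        mw = mw - mw.mean(axis=1, keepdims=True)
        fw = fw - fw.mean(axis=1, keepdims=True)
    em = np.einsum("ij,ij->i", mw, mw)
    ef = np.einsum("ij,ij->i", fw, fw)
    coeffs = np.full(mw.shape[0], np.nan)
    ok = (em > 0) & (ef > 0)
    if lag_policy == "zero":
        num = np.einsum("ij,ij->i", mw, fw)
        coeffs[ok] = num[ok] / np.sqrt(em[ok] * ef[ok])
    elif lag_policy == "max_abs":
        for i in np.flatnonzero(ok):
            cc = sps.correlate(mw[i], fw[i], mode="full")
            cc = cc / np.sqrt(em[i] * ef[i])
            coeffs[i] = cc[np.argmax(np.abs(cc))]
    else:
        raise SimilarityError(f"unknown lag_policy {lag_policy!r}")
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{n_bad} window(s) had an all-zero signal; "
                      "coefficients recorded as missing")
    return WindowedCC(coeffs, window_len=window_len)


def cc_scores(wcc: WindowedCC) -> tuple[float, float]:
    """(CC1, CC2): mean absolute and signed mean of valid coefficients."""
    v = wcc.valid
    if v.size == 0:
        raise SimilarityError("no valid window coefficients")
    return float(np.mean(np.abs(v))), float(np.mean(v))


def msc_spectrum(m: UniformSeries, f: UniformSeries, window_len: int = 10,
                 fs: float = 0.5, taper: str = "hamming",
                 overlap: float = 0.5, nfft: int = 256) -> CoherenceSpectrum:
    """Welch-averaged magnitude-squared coherence of the normalized pair."""
    if not (m.normalized and f.normalized):
        raise SimilarityError("both series must be normalized first")
    if len(m) != len(f):
        raise SimilarityError("series lengths differ")
    noverlap = int(round(window_len * overlap))
    step = window_len - noverlap
    n_seg = (len(m) - window_len) // step + 1
    if n_seg < 2:
        raise SimilarityError(
            "fewer than 2 averaging segments: single-segment coherence "
            "is identically 1")
    freqs, msc = sps.coherence(m.values, f.values, fs=fs,
                               window=taper, nperseg=window_len,
                               noverlap=noverlap, nfft=nfft)
    return CoherenceSpectrum(freqs, np.clip(msc, 0.0, 1.0))


def band_coherence(spec: CoherenceSpectrum,
                   bands: BandDefinition | None = None) -> tuple[float, float]:
    """(CLF, CHF): mean coherence over the LF and HF bands."""
    bands = bands or BandDefinition()
    lf_mask = (spec.freqs >= bands.lf[0]) & (spec.freqs < bands.lf[1])
    hf_mask = (spec.freqs >= bands.hf[0]) & (spec.freqs <= bands.hf[1])
    for name, mask in (("LF", lf_mask), ("HF", hf_mask)):
        if not mask.any():
            df = spec.freqs[1] - spec.freqs[0] if spec.freqs.size > 1 else float("nan")
            raise SimilarityError(
                f"{name} band contains no bins (bin spacing {df:.4g} Hz)")
    return float(spec.msc[lf_mask].mean()), float(spec.msc[hf_mask].mean())


def score_epoch(epoch: Epoch,
                config: SimilarityConfig | None = None) -> SimilarityScores:
    """Full chain: resample -> normalize -> windowed CC + band coherence."""
    cfg = config or SimilarityConfig()
    try:
        m = normalize(resample_uniform(epoch.maternal, epoch, cfg.bin_width_ms))
        f = normalize(resample_uniform(epoch.fetal, epoch, cfg.bin_width_ms))
    except SimilarityError as e:
        raise SimilarityError(f"resample/normalize stage: {e}") from e
    try:
        wcc = windowed_cc(m, f, cfg.window_len, cfg.lag_policy,
                          cfg.center_windows)
        cc1, cc2 = cc_scores(wcc)
    except SimilarityError as e:
        raise SimilarityError(f"cross-correlation stage: {e}") from e
    try:
        spec = msc_spectrum(m, f, cfg.window_len, cfg.fs, cfg.welch_taper,
                            cfg.welch_overlap, cfg.welch_nfft)
        clf, chf = band_coherence(spec, cfg.bands)
    except SimilarityError as e:
        raise SimilarityError(f"coherence stage: {e}") from e
    return SimilarityScores(cc1=cc1, cc2=cc2, clf=clf, chf=chf,
                            n_valid_windows=wcc.n_valid)
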