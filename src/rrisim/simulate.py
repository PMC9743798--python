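"""Synthetic coupled maternal-fetal dyads with known ground truth.

No public recordings exist for this kind of experiment, so the pipeline is
validated against simulated beat data. The generator produces a maternal
instantaneous-RRI process (mean level plus LF/HF oscillations plus slow
AR(1) noise) and a fetal process whose fluctuation is a mixture of the
standardized maternal fluctuation (weight rho, with a sign) and an
independent AR(1) process (weight sqrt(1-rho^2)); the mixture keeps the
expected zero-lag correlation between the two fluctuations equal to rho.
Beat times are obtained by integrating the instantaneous RRI and
quantizing to 1 ms, mirroring 1 kHz acquisition.

Cohort scenarios reproduce the two study designs: a developmental cohort
with coupling strength increasing across embryonic days (ED13.5-ED18.5),
and a two-arm cohort where a VPA-exposed group's coupling lags behind its
saline controls at ED15.5 and has largely caught up by ED18.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import BeatSeries

FETAL_MEAN_RANGE_MS = (306.0, 981.0)  # observed range of average fetal RRI


@dataclass
class DyadParams:
    """Generator parameters for one maternal-fetal pair.

    All RRI quantities in ms, frequencies in Hz. ``coupling_rho`` in [0, 1]
    sets the expected per-window correlation between the normalized
    tachograms; ``coupling_sign`` its direction. ``fetal_fluct_sd`` is the
    total SD of the fetal fluctuation; the independent component gets
    sqrt(1-rho^2) of it so that coupling strength and overall variability
    are decoupled knobs. The default (None) scales it to 5% of the fetal
    mean RRI, since heart-rate-variability magnitude grows with the mean
    interval.
    """

    maternal_mean_rri: float = 130.0
    fetal_mean_rri: float | None = None  # None -> uniform draw in observed range
    coupling_rho: float = 0.5
    coupling_sign: int = 1
    lf_freq: float = 0.08
    hf_freq: float = 0.20
    maternal_osc_amp: float = 8.0
    maternal_noise_sd: float = 2.5
    fetal_fluct_sd: float | None = None  # None -> 0.05 * fetal mean RRI
    ar_coeff: float = 0.9
    rho_drift_sd: float = 0.15  # slow within-record wander of the coupling
    duration_s: float = 900.0
    lag_ms: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must be in [0, 1]")
        if self.coupling_sign not in (1, -1):
            raise ValueError("coupling_sign must be +1 or -1")
        if self.maternal_mean_rri <= 0:
            raise ValueError("maternal mean RRI must be positive")
        if self.fetal_mean_rri is not None and not (
                200.0 < self.fetal_mean_rri < 1100.0):
            raise ValueError("fetal mean RRI outside plausible (200, 1100) ms")


def _ar1(rng: np.ndarray, n: int, coeff: float, generator) -> np.ndarray:
    """Unit-SD stationary AR(1) path."""
    innov_sd = np.sqrt(1.0 - coeff ** 2)
    x = np.empty(n)
    x[0] = generator.normal()
    e = generator.normal(scale=innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = coeff * x[i - 1] + e[i - 1]
    return x


def _integrate_beats(grid_t: np.ndarray, inst_rri_ms: np.ndarray,
                     duration_s: float, mean_rri: float) -> np.ndarray:
    """Next beat at t + RRI(t)/1000; clip pathological RRI at 10% of mean."""
    floor = 0.1 * mean_rri
    times = []
    t = 0.0
    while t < duration_s:
        rri = float(np.interp(t, grid_t, inst_rri_ms))
        if rri < floor:
            rri = floor
        t += rri / 1000.0
        if t >= duration_s:
            break
        times.append(t)
    beats = np.round(np.array([0.0] + times) * 1000.0)  # 1 ms quantization
    return np.unique(beats)


_GRID_DT = 0.1  # fluctuation grid resolution, s


def _maternal_process(params: DyadParams, rng: np.random.Generator):
    """Grid times, standardized maternal fluctuation, instantaneous RRI."""
    n = int(np.ceil(params.duration_s / _GRID_DT)) + 2
    grid_t = np.arange(n) * _GRID_DT
    phase = rng.uniform(0, 2 * np.pi)
    osc = (np.sin(2 * np.pi * params.lf_freq * grid_t)
           + 0.5 * np.sin(2 * np.pi * params.hf_freq * grid_t + phase))
    m_noise = params.maternal_noise_sd * _ar1(grid_t, n, params.ar_coeff, rng)
    m_fluct = params.maternal_osc_amp * osc + m_noise
    sd_m = m_fluct.std()
    s = m_fluct / sd_m if sd_m > 0 else m_fluct
    return grid_t, s, params.maternal_mean_rri + m_fluct


def _fetal_process(params: DyadParams, grid_t: np.ndarray, s: np.ndarray,
                   rng: np.random.Generator):
    """Fetal instantaneous RRI coupled to the standardized maternal path."""
    rho, sign = params.coupling_rho, params.coupling_sign
    w = _ar1(grid_t, grid_t.size, params.ar_coeff, rng)
    w = (w - w.mean()) / w.std()
    coupled = s
    if params.lag_ms:
        coupled = np.interp(grid_t - params.lag_ms / 1000.0, grid_t, s)
    fetal_mean = params.fetal_mean_rri
    if fetal_mean is None:
        fetal_mean = rng.uniform(*FETAL_MEAN_RANGE_MS)
    fluct_sd = params.fetal_fluct_sd
    if fluct_sd is None:
        fluct_sd = 0.05 * fetal_mean
    rho_t = rho
    if params.rho_drift_sd > 0:
        # coupling is not constant over a long record: let it wander slowly
        # so distinct analysis epochs sample genuinely different strengths
        drift = _ar1(grid_t, grid_t.size, 0.999, rng)
        rho_t = np.clip(rho + params.rho_drift_sd * drift, 0.0, 1.0)
    f_fluct = fluct_sd * (
        sign * rho_t * coupled + np.sqrt(1.0 - rho_t ** 2) * w)
    return fetal_mean + f_fluct, fetal_mean


def simulate_dyad(params: DyadParams,
                  rng: np.random.Generator | None = None,
                  subject_prefix: str = "dyad") -> tuple[BeatSeries, BeatSeries]:
    """Generate one coupled pair of beat series. Same seed, same output."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    grid_t, s, m_rri = _maternal_process(params, rng)
    f_rri, fetal_mean = _fetal_process(params, grid_t, s, rng)
    m_beats = _integrate_beats(grid_t, m_rri, params.duration_s,
                               params.maternal_mean_rri)
    f_beats = _integrate_beats(grid_t, f_rri, params.duration_s, fetal_mean)
    return (BeatSeries(f"{subject_prefix}_m", "maternal", m_beats),
            BeatSeries(f"{subject_prefix}_f", "fetal", f_beats))


# Fetus counts per stage after the study's quality exclusions.
DEV_COUNTS = {13.5: 10, 15.5: 10, 17.5: 17, 18.5: 11}
DEV_MOTHERS = {13.5: 6, 15.5: 6, 17.5: 10, 18.5: 7}
ASD_COUNTS = {15.5: 13, 18.5: 7}
ASD_MOTHERS = {15.5: 8, 18.5: 5}

DEV_RHO_SCHEDULE = {13.5: 0.2, 15.5: 0.4, 17.5: 0.6, 18.5: 0.8}
VPA_RHO_MULTIPLIER = {15.5: 0.3, 18.5: 0.96}  # delayed, then mostly caught up
P_POSITIVE_SIGN = 0.8
RHO_JITTER_SD = 0.08  # between-fetus coupling heterogeneity


@dataclass
class CohortScenario:
    """Cohort design: dyad counts per stage, coupling schedule, arms."""

    name: str = "development"  # {"development", "asd"}
    fetus_counts: dict = None
    mother_counts: dict = None
    rho_schedule: dict = field(default_factory=lambda: dict(DEV_RHO_SCHEDULE))
    vpa_multiplier: dict = field(default_factory=lambda: dict(VPA_RHO_MULTIPLIER))
    p_positive: float = P_POSITIVE_SIGN
    rho_jitter_sd: float = RHO_JITTER_SD
    duration_s: float = 900.0
    dyad_params: DyadParams = field(default_factory=DyadParams)

    def __post_init__(self):
        if self.name not in ("development", "asd"):
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.fetus_counts is None:
            self.fetus_counts = dict(
                DEV_COUNTS if self.name == "development" else ASD_COUNTS)
        if self.mother_counts is None:
            self.mother_counts = dict(
                DEV_MOTHERS if self.name == "development" else ASD_MOTHERS)
        for rho in self.rho_schedule.values():
            if not 0.0 <= rho <= 1.0:
                raise ValueError("schedule rho values must be in [0, 1]")


@dataclass
class DyadRecord:
    """One simulated dyad plus its cohort metadata."""

    mother_id: str
    fetus_id: str
    ed: float
    group: str
    maternal: BeatSeries
    fetal: BeatSeries
    true_rho: float
    true_sign: int


def _assign_fetuses(n_mothers: int, n_fetuses: int) -> list[int]:
    """Distribute fetuses over mothers, at most 2 per mother, all >= 1."""
    per = [1] * n_mothers
    extra = n_fetuses - n_mothers
    for i in range(min(extra, n_mothers)):
        per[i] += 1
    return per


def generate_cohort(scenario: CohortScenario, seed: int) -> list[DyadRecord]:
    """Simulate all dyads of a scenario in memory.

    Fetuses of one mother share that mother's maternal beat series (they
    are recorded simultaneously) but have independent fetal processes,
    signs and coupling noise.
    """
    rng = np.random.default_rng(seed)
    groups = (["development"] if scenario.name == "development"
              else ["saline", "vpa"])
    records: list[DyadRecord] = []
    for ed in sorted(scenario.fetus_counts):
        base_rho = scenario.rho_schedule[ed]
        for group in groups:
            rho = base_rho
            if group == "vpa":
                rho = base_rho * scenario.vpa_multiplier.get(ed, 1.0)
            per_mother = _assign_fetuses(scenario.mother_counts[ed],
                                         scenario.fetus_counts[ed])
            for mi, n_fet in enumerate(per_mother):
                mother_id = f"{group}_ed{ed}_m{mi:02d}"
                base = replace(scenario.dyad_params,
                               duration_s=scenario.duration_s,
                               coupling_rho=rho, seed=None)
                # one maternal process per mother, shared across its fetuses
                m_rng = np.random.default_rng(rng.integers(2 ** 31))
                grid_t, s, m_rri = _maternal_process(base, m_rng)
                m_beats = _integrate_beats(grid_t, m_rri, base.duration_s,
                                           base.maternal_mean_rri)
                maternal = BeatSeries(f"{mother_id}", "maternal", m_beats)
                for fi in range(n_fet):
                    sign = 1 if rng.random() < scenario.p_positive else -1
                    # fetuses vary around the stage's scheduled coupling
                    fetus_rho = float(np.clip(
                        rng.normal(rho, scenario.rho_jitter_sd), 0.0, 1.0))
                    params = replace(base, coupling_sign=sign,
                                     coupling_rho=fetus_rho)
                    f_rng = np.random.default_rng(rng.integers(2 ** 31))
                    f_rri, fetal_mean = _fetal_process(params, grid_t, s, f_rng)
                    f_beats = _integrate_beats(grid_t, f_rri, base.duration_s,
                                               fetal_mean)
                    f = BeatSeries(f"{mother_id}_f{fi}", "fetal", f_beats)
                    records.append(DyadRecord(
                        mother_id=mother_id,
                        fetus_id=f"{mother_id}_f{fi}",
                        ed=ed, group=group,
                        maternal=maternal, fetal=f,
                        true_rho=fetus_rho, true_sign=sign))
    return records


def simulate_cohort(scenario: CohortScenario, seed: int, outdir,
                    overwrite: bool = False) -> pd.DataFrame:
    """Write per-subject beat CSVs plus a dyad manifest; return the manifest."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists (pass overwrite=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_cohort(scenario, seed)
    rows = []
    written_mothers = set()
    for rec in records:
        m_file = f"{rec.mother_id}_maternal.csv"
        f_file = f"{rec.fetus_id}_fetal.csv"
        if rec.mother_id not in written_mothers:
            pd.DataFrame({"t_ms": rec.maternal.beat_times}).to_csv(
                outdir / m_file, index=False)
            written_mothers.add(rec.mother_id)
        pd.DataFrame({"t_ms": rec.fetal.beat_times}).to_csv(
            outdir / f_file, index=False)
        rows.append({"mother_id": rec.mother_id, "fetus_id": rec.fetus_id,
                     "ed": rec.ed, "group": rec.group,
                     "maternal_file": m_file, "fetal_file": f_file})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def synth_ecg(beats: BeatSeries, fs: float = 1000.0, bump_width_ms: float = 5.0,
              noise_sd: float = 0.02, amplitude: float = 1.0,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Toy ECG: a Gaussian R-wave bump at each beat over baseline noise."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(np.ceil(beats.beat_times[-1] * fs / 1000.0)) + int(fs)
    t_ms = np.arange(n) * 1000.0 / fs
    trace = np.zeros(n)
    for bt in beats.beat_times:
        lo = np.searchsorted(t_ms, bt - 5 * bump_width_ms)
        hi = np.searchsorted(t_ms, bt + 5 * bump_width_ms)
        trace[lo:hi] += amplitude * np.exp(
            -0.5 * ((t_ms[lo:hi] - bt) / bump_width_ms) ** 2)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        trace += rng.normal(scale=noise_sd * amplitude, size=n)
    return trace
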