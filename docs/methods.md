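# Methods

## Signal model and analysis chain

The unit of analysis is a *dyad*: one maternal and one fetal RR-interval
(RRI) tachogram recorded simultaneously on a shared millisecond clock.
All internal times are milliseconds; seconds are converted at I/O. The
chain is: epoch selection → 2-s resampling → peak-normalization →
windowed cross-correlation and Welch coherence → cohort statistics.

### Epoch selection

The first 60 s of every recording are discarded as unstable. A 180-s
window is accepted when, for both subjects, (a) every RRI lies inside a
physiological band (maternal 50–300 ms, fetal 200–1,100 ms; the fetal
band brackets the observed 306–981 ms range of average fetal RRI), and
(b) no RRI deviates from the window median by more than 30%. These
thresholds are a deterministic stand-in for visual noise/arrhythmia
screening; they are configurable (`QualityConfig`). The search slides in
1-s steps and takes the earliest passing window, then the earliest
passing window after it, so two clean epochs come out consecutive
whenever the record allows. Dyads with fewer than the requested number of
clean epochs are flagged for exclusion rather than silently dropped.

### Resampling and normalization

Each tachogram is averaged per 2-s bin over the epoch (bin k collects the
intervals whose terminating beat falls in `[start+2k s, start+2(k+1) s)`),
giving 90 samples per 3-min epoch at 0.5 Hz. The 2-s bin width is the
minimum that cannot produce an empty bin for the slowest plausible fetal
heart (mean RRI up to ~1 s); an empty bin is an error, not interpolated.
Normalization subtracts the epoch mean of the *resampled* series and
divides by the maximum absolute deviation, so every epoch has mean 0 and
peak 1 regardless of its physical RRI scale. Constant input is rejected
as degenerate rather than mapped to zeros.

### Windowed cross-correlation (CC1, CC2)

The normalized pair is split into consecutive non-overlapping 10-sample
windows (nine per standard epoch; a non-multiple length drops the tail
with a warning). Per window the zero-lag normalized cross-correlation
`r_w = Σ m·f / √(Σ m² Σ f²)` is computed **without re-centering the
window** — the series was already centered at epoch level, and the
epoch-level pipeline order (normalize, then window) is preserved. The
zero-lag coefficient is the default because it is the only per-window
statistic whose sign carries the direction of co-variation, which CC2
needs; `lag_policy="max_abs"` exposes the maximum-magnitude-over-lags
alternative, and `center_windows=True` the re-centered variant. CC1 is
the mean absolute coefficient, CC2 the signed mean; windows with an
all-zero signal are excluded from both means (never imputed). By
Cauchy–Schwarz and the triangle inequality, `|CC2| ≤ CC1 ≤ 1` always.

### Band coherence (CLF, CHF)

Magnitude-squared coherence is estimated by Welch averaging with segment
length 10, Hamming taper, 50% overlap and FFT length 256 (bin spacing
fs/256 ≈ 0.002 Hz) — the conventional defaults for this estimator; a
90-sample epoch yields 17 averaged segments. Fewer than two segments is
an error, since single-segment coherence is identically 1. The spectrum
runs from 0 to fs/2 = 0.25 Hz. CLF is the mean coherence over
[0.04, 0.15) Hz and CHF over [0.15, 0.25] Hz; the shared 0.15 Hz edge is
counted once (in HF) so no bin is double-counted. The mean across band
bins is used as the band summary because it keeps both scores in [0, 1].
The human LF/HF band edges are used since no fetal-mouse autonomic bands
are established and fetal mean RRI lies in a human-like range.

### Cohort statistics

`CohortModel(table).fit(design)` runs the battery on a scores table with
one row per (mother, fetus, epoch). Every test is gated by a Shapiro–Wilk
normality test at α = 0.05: correlations with embryonic day use Pearson
when both variables pass, Spearman otherwise (embryonic day takes four
discrete values, so in practice the Spearman branch is used); group
comparisons use one-way ANOVA when every group passes, otherwise the
two-sample rank-sum (Mann–Whitney) for two groups or Kruskal–Wallis for
the four-stage omnibus. "Wilcoxon" style signed-rank tests are not
applicable because all comparisons are between independent groups.
Pairwise stage contrasts are reported unadjusted by default (an optional
Holm adjustment is available). Embryonic day is treated as a numeric
covariate (days), not as ordinal ranks.

**Known caveat.** The default design treats each (fetus, epoch) row as an
independent observation, although two epochs of one fetus and fetuses
sharing a mother are correlated. Measured on simulated cohorts with
identical arms, this inflates the two-group null rejection rate from the
nominal 5% to roughly 8–13%. The `aggregate="epoch_mean"` /
`"fetus_mean"` options average within fetus or mother first; mixed-effects
modeling of the mother-level clustering is out of scope.

## Synthetic dyad generator

No recordings are publicly available for this design, so validation uses
simulated dyads whose ground truth is known.

* **Maternal process**: instantaneous RRI(t) = mean (130 ms, a typical
  anesthetized-mouse placeholder exposed as a parameter) + oscillation
  `A·[sin(2π·0.08·t) + 0.5·sin(2π·0.2·t + φ)]` (A = 8 ms, φ random per
  mother) + AR(1) noise (SD 2.5 ms, coefficient 0.9 on a 0.1-s grid).
  The two frequencies sit in the centers of the LF and HF analysis bands.
* **Fetal process**: mean RRI drawn uniformly from the observed
  306–981 ms range (or fixed); fluctuation
  `σ_f · [sign·ρ(t)·s(t) + √(1−ρ(t)²)·w(t)]`, where `s` is the
  standardized maternal fluctuation, `w` an independent unit-SD AR(1)
  process, and σ_f defaults to 5% of the fetal mean (variability scales
  with the mean interval). This mixture makes the expected zero-lag
  correlation between the two fluctuations equal ρ, so the coupling knob
  is directly interpretable. The independent component deliberately
  contains no deterministic sinusoid: two phase-locked sinusoids at the
  same frequency would make even "decoupled" dyads fully coherent.
* **Coupling drift**: ρ(t) wanders slowly around its nominal value
  (AR(1), coefficient 0.999 at 0.1 s, SD 0.15, clipped to [0, 1]),
  reflecting the intermittency of maternal–fetal synchronization; without
  it the two epochs of a fetus are near-duplicates and cohort tests
  become strongly anticonservative.
* **Beats**: next beat at `t + RRI(t)/1000`; instantaneous RRI below 10%
  of the mean is clipped; beat times are quantized to 1 ms, mirroring
  1 kHz acquisition. Identical seeds give byte-identical output.

### Cohort scenarios

* `development`: fetus counts per stage 10/10/17/11 (ED13.5/15.5/17.5/
  18.5) over 6/6/10/7 mothers, coupling schedule ρ = 0.2/0.4/0.6/0.8.
* `asd`: two arms at ED15.5 (13 fetuses per arm over 8 mothers) and
  ED18.5 (7 per arm over 5 mothers); the saline arm follows the
  development schedule, the VPA arm multiplies ρ by 0.3 at ED15.5 and
  0.96 at ED18.5 — strongly reduced coupling mid-gestation that has
  largely caught up by late gestation, so the late contrast is a small
  true effect that the small arms cannot reliably detect.

Per fetus, coupling is jittered around the stage value (normal, SD 0.08,
clipped to [0, 1]) to reproduce realistic within-stage spread, and the
coupling sign is positive with probability 0.8 (both positive and
negative tracking occur in real dyads). Fetuses of one mother share her
maternal beat series, as in a simultaneous recording.

**What the generator does not emulate**: anesthetic heart-rate drift,
fetal behavioral states, gender effects, ectopy/arrhythmia, measurement
noise in R-peak detection, or any physiological mechanism of the
coupling. Passing tests therefore demonstrate that the pipeline recovers
known coupling structure from beat data with realistic rates and noise —
not that any specific biological claim holds in real recordings.

## Numerical choices and degenerate inputs

* Problem sizes: the coupling-recovery experiment uses 50 dyads per ρ at
  300-s records (one epoch each); cohort experiments use full 900-s
  records (two epochs). Null calibration uses 1,000–2,000 replicates of
  13-per-group draws.
* Tolerances: normalization identities are asserted at 1e−10 (mean) and
  1e−12 (peak); oracle equivalence of windowed coefficients at 1e−10;
  self-coherence at 1e−9.
* Ties and degenerate cases: all-zero windows yield missing coefficients
  (excluded from means); constant series cannot be normalized; a single
  Welch segment is an error; empty resampling bins are errors naming the
  bin; records shorter than 60 s + epoch length are rejected.
* Determinism: every stochastic routine takes a seed or Generator; the
  CLI records seeds and config hashes in `run_metadata.json`.

## Limitations

* The per-window correlation is computed at zero lag; systematic
  maternal→fetal latencies would attenuate all scores (the generator's
  `lag_ms` parameter exists to probe this).
* Band coherence from 90-sample epochs with 10-sample segments has very
  coarse spectral resolution; CHF in particular rests on ~2 independent
  frequency degrees of freedom per segment.
* The statistical battery mirrors a row-per-epoch design and inherits its
  pseudo-replication caveat (see above).
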