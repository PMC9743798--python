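# rrisim

Maternal–fetal heart-rate similarity analysis for simultaneously recorded
RR-interval (RRI) tachograms, with a synthetic coupled-dyad generator for
validation.

## The problem

During gestation the fetal autonomic nervous system matures, and one
observable signature is that fluctuations of the fetal RR interval start
to track fluctuations of the maternal RR interval. Quantifying that
tracking from paired electrocardiogram recordings — e.g. in fetal mice
across embryonic days (ED) 13.5–18.5, or in a valproic-acid (VPA) autism
model versus saline controls — requires comparing two tachograms that beat
at very different rates and are irregularly sampled.

`rrisim` implements the full analysis chain for such dyads:

1. **Ingest** — read beat timestamps or RRI sequences (ms), convert to
   tachograms, and select artifact-free 3-minute epochs after discarding
   the first minute of the recording. A window is accepted only if every
   RRI stays inside a physiological band and within 30% of the window
   median for both subjects.
2. **Resample** — average RRI per 2-s bin so that both signals share a
   uniform 0.5 Hz grid (90 samples per 3-minute epoch). The 2-s bin is the
   smallest that always contains at least one fetal beat.
3. **Normalize** — per epoch,
   `x_norm = (x − mean(x)) / max|x − mean(x)|`, giving a zero-mean series
   with unit peak amplitude.
4. **Score** — four similarity coefficients per epoch:
   * **CC1, CC2**: the normalized pair is cut into nine consecutive
     10-sample windows; in each, the zero-lag normalized cross-correlation
     `r_w = Σ m·f / √(Σ m² · Σ f²)` is computed. CC1 is the mean of
     `|r_w|` (strength regardless of direction), CC2 the signed mean
     (direction-aware).
   * **CLF, CHF**: Welch magnitude-squared coherence
     `C(f) = |P_mf|² / (P_mm · P_ff)` (segment length 10, Hamming taper,
     50% overlap, fs = 0.5 Hz, maximum frequency 0.25 Hz), averaged over
     the low-frequency (0.04–0.15 Hz) and high-frequency (0.15–0.25 Hz)
     bands.
5. **Cohort statistics** — Shapiro–Wilk-gated correlation of each
   coefficient with embryonic day (Pearson/Spearman) and gated group
   comparisons (one-way ANOVA / two-sample rank-sum), via a
   `CohortModel.fit() → CohortResults` interface.

Because no public recordings exist for this design, the package ships a
generator of synthetic coupled dyads with known coupling strength, sign,
developmental schedule and treatment arms, used by the test-suite and the
acceptance script.

## Worked example

```python
from rrisim import DyadParams, simulate_dyad, score_dyad

p = DyadParams(coupling_rho=0.8, coupling_sign=1, fetal_mean_rri=520.0, seed=7)
maternal, fetal = simulate_dyad(p)
scored, complete = score_dyad(maternal, fetal)
for idx, s in scored:
    print(f"epoch {idx}: CC1={s.cc1:.3f} CC2={s.cc2:.3f} "
          f"CLF={s.clf:.3f} CHF={s.chf:.3f}")
```

prints

```
epoch 0: CC1=0.832 CC2=0.832 CLF=0.718 CHF=0.602
epoch 1: CC1=0.795 CC2=0.795 CLF=0.744 CHF=0.620
```

A dyad simulated with strong positive coupling (`coupling_rho=0.8`) scores
high on all four coefficients, and CC2 equals CC1 because every window
correlates positively. Cohort-level statistics follow the same pattern:

```python
from rrisim import CohortModel, CohortScenario, analyze_records, generate_cohort

records = generate_cohort(CohortScenario(name="development"), seed=0)
scores = analyze_records(records)
results = CohortModel(scores[~scores.excluded]).fit("development")
print(results.summary())
```

```
Trend with embryonic day
----------------------------------------------------
coef  method           r           p     n
cc1   spearman     0.770    5.06e-20    96
cc2   spearman     0.633    4.41e-12    96
clf   spearman     0.777    1.27e-20    96
chf   spearman     0.734     1.8e-17    96
```

All four coefficients rise significantly with embryonic day, as expected
from the generator's increasing coupling schedule (ρ = 0.2 → 0.8 across
ED13.5 → ED18.5).

## Command line

```bash
rrisim simulate --scenario development --seed 7 --outdir data/
rrisim analyze  --manifest data/manifest.csv --outdir out/
rrisim stats    --scores out/scores.csv --design development --outdir out/
```

`analyze` writes one row per (dyad, epoch) with the four coefficients;
`stats` writes the trend/comparison tables and a plain-text report.

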