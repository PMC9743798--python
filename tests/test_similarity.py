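import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from rrisim import (BandDefinition, CoherenceSpectrum, SimilarityConfig,
                    SimilarityError, UniformSeries, band_coherence, cc_scores,
                    msc_spectrum, normalize, resample_uniform, score_epoch,
                    windowed_cc)
from rrisim.similarity import WindowedCC

from conftest import epoch_from_rri


def norm_series(values):
    return normalize(UniformSeries(np.asarray(values, float)))


nonconstant = arrays(np.float64, st.integers(20, 90),
                     elements=st.floats(-100, 100, allow_nan=False,
                                        width=32)).filter(
    lambda a: np.ptp(a) > 1e-6)


class TestResample:
    def test_three_minute_epoch_gives_90_samples(self, clean_epoch):
        s = resample_uniform(clean_epoch.maternal, clean_epoch)
        assert len(s) == 90
        assert s.fs == 0.5

    def test_constant_rri_gives_constant_bins(self):
        ep = epoch_from_rri([150.0] * 1200, [500.0] * 360, 0, 180_000)
        s = resample_uniform(ep.maternal, ep)
        np.testing.assert_allclose(s.values, 150.0)

    def test_matches_brute_force_bin_means(self, clean_epoch):
        s = resample_uniform(clean_epoch.maternal, clean_epoch)
        tach = clean_epoch.maternal
        for k in range(90):
            lo, hi = k * 2000.0, (k + 1) * 2000.0
            mask = (tach.times >= lo) & (tach.times < hi)
            np.testing.assert_allclose(s.values[k], tach.rri[mask].mean())

    def test_alternating_rri_averages_within_bins(self):
        rri = np.tile([100.0, 200.0], 700)  # pairs sum to 300 ms
        ep = epoch_from_rri(rri, [500.0] * 360, 0, 180_000)
        s = resample_uniform(ep.maternal, ep)
        # each 2-s bin holds 13-14 alternating intervals; means near 150
        assert np.all(np.abs(s.values - 150.0) < 8.0)

    def test_gap_raises_with_bin_index(self):
        # fetal beats stop after 100 s -> later bins empty
        ep = epoch_from_rri([150.0] * 1200, [500.0] * 180, 0, 180_000)
        with pytest.raises(SimilarityError, match="bin"):
            resample_uniform(ep.fetal, ep)


class TestNormalize:
    def test_simple_example(self):
        out = norm_series([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out.values, [-1.0, 0.0, 1.0])

    def test_constant_input_errors(self):
        with pytest.raises(SimilarityError, match="constant"):
            norm_series([5.0, 5.0, 5.0])

    def test_double_normalize_rejected(self):
        with pytest.raises(SimilarityError, match="already"):
            normalize(norm_series([1.0, 2.0, 3.0]))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(nonconstant)
    def test_mean_zero_peak_one(self, vals):
        out = norm_series(vals)
        assert abs(out.values.mean()) < 1e-10
        assert np.max(np.abs(out.values)) == pytest.approx(1.0, abs=1e-12)


class TestWindowedCC:
    def test_self_correlation_all_ones(self, rng):
        x = norm_series(rng.normal(size=90))
        wcc = windowed_cc(x, x)
        assert wcc.coefficients.size == 9
        np.testing.assert_allclose(wcc.coefficients, 1.0, atol=1e-12)

    def test_anticorrelation_all_minus_ones(self, rng):
        x = norm_series(rng.normal(size=90))
        y = UniformSeries(-x.values, fs=x.fs, normalized=True)
        np.testing.assert_allclose(windowed_cc(x, y).coefficients, -1.0,
                                   atol=1e-12)

    def test_matches_brute_force_formula(self, rng):
        for _ in range(50):
            m = norm_series(rng.normal(size=90))
            f = norm_series(rng.normal(size=90))
            wcc = windowed_cc(m, f)
            for w in range(9):
                a = m.values[w * 10:(w + 1) * 10]
                b = f.values[w * 10:(w + 1) * 10]
                expected = np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b))
                assert wcc.coefficients[w] == pytest.approx(expected, abs=1e-10)

    def test_symmetry_in_arguments(self, rng):
        m = norm_series(rng.normal(size=90))
        f = norm_series(rng.normal(size=90))
        np.testing.assert_allclose(windowed_cc(m, f).coefficients,
                                   windowed_cc(f, m).coefficients)

    def test_unnormalized_input_rejected(self, rng):
        raw = UniformSeries(rng.normal(size=90))
        with pytest.raises(SimilarityError, match="normalized"):
            windowed_cc(raw, raw)

    def test_trailing_samples_dropped_with_warning(self, rng):
        m = norm_series(rng.normal(size=95))
        f = norm_series(rng.normal(size=95))
        with pytest.warns(UserWarning, match="trailing"):
            wcc = windowed_cc(m, f)
        assert wcc.coefficients.size == 9

    def test_max_abs_lag_policy_dominates_zero_lag(self, rng):
        m = norm_series(rng.normal(size=90))
        f = norm_series(rng.normal(size=90))
        z = windowed_cc(m, f, lag_policy="zero").coefficients
        mx = windowed_cc(m, f, lag_policy="max_abs").coefficients
        assert np.all(np.abs(mx) >= np.abs(z) - 1e-12)


class TestCCScores:
    @pytest.mark.parametrize("coeffs, cc1, cc2", [
        (np.ones(9), 1.0, 1.0),
        (-np.ones(9), 1.0, -1.0),
        (np.array([0.5, -0.5] * 4 + [0.5]), 0.5, 0.5 / 9),
    ])
    def test_examples(self, coeffs, cc1, cc2):
        got1, got2 = cc_scores(WindowedCC(coeffs))
        assert got1 == pytest.approx(cc1)
        assert got2 == pytest.approx(cc2)

    def test_missing_coefficients_excluded(self):
        coeffs = np.array([1.0, np.nan, -1.0])
        got1, got2 = cc_scores(WindowedCC(coeffs))
        assert (got1, got2) == (1.0, 0.0)

    def test_all_missing_errors(self):
        with pytest.raises(SimilarityError, match="valid"):
            cc_scores(WindowedCC(np.full(9, np.nan)))

    def test_cc2_never_exceeds_cc1(self, rng):
        for _ in range(200):
            coeffs = rng.uniform(-1, 1, size=9)
            cc1, cc2 = cc_scores(WindowedCC(coeffs))
            assert abs(cc2) <= cc1 + 1e-12 and cc1 <= 1.0 + 1e-12


class TestMSC:
    def test_self_coherence_is_one_everywhere(self, rng):
        x = norm_series(rng.normal(size=90))
        spec = msc_spectrum(x, x)
        assert spec.freqs[-1] == pytest.approx(0.25)
        np.testing.assert_allclose(spec.msc, 1.0, atol=1e-9)

    def test_values_bounded_and_max_freq(self, rng):
        for _ in range(20):
            m = norm_series(rng.normal(size=90))
            f = norm_series(rng.normal(size=90))
            spec = msc_spectrum(m, f)
            assert np.all((spec.msc >= 0) & (spec.msc <= 1))
            assert spec.freqs[0] == 0.0 and spec.freqs[-1] == pytest.approx(0.25)

    def test_scaling_invariance(self, rng):
        m = norm_series(rng.normal(size=90))
        f = norm_series(rng.normal(size=90))
        f2 = UniformSeries(3.7 * f.values, fs=f.fs, normalized=True)
        np.testing.assert_allclose(msc_spectrum(m, f).msc,
                                   msc_spectrum(m, f2).msc, atol=1e-12)

    def test_independent_noise_has_low_mean_coherence(self, rng):
        # Monte-Carlo null: mean MSC for independent pairs stays well below
        # the self-coherence value; threshold from the segment count (17
        # averaged segments -> expected null level ~1/10, allow slack)
        means = []
        for _ in range(200):
            m = norm_series(rng.normal(size=90))
            f = norm_series(rng.normal(size=90))
            means.append(msc_spectrum(m, f).msc.mean())
        assert np.mean(means) < 0.2

    def test_too_short_for_two_segments(self, rng):
        m = norm_series(rng.normal(size=10))
        with pytest.raises(SimilarityError, match="segments"):
            msc_spectrum(m, m)


class TestBandCoherence:
    @pytest.mark.parametrize("level", [1.0, 0.5])
    def test_flat_spectrum(self, level):
        freqs = np.linspace(0, 0.25, 129)
        clf, chf = band_coherence(CoherenceSpectrum(freqs,
                                                    np.full(129, level)))
        assert clf == pytest.approx(level) and chf == pytest.approx(level)

    def test_shared_hf_component_ranks_bands(self, rng):
        # both series share only a 0.2 Hz sinusoid (HF band) over noise
        t = np.arange(90) * 2.0
        shared = np.sin(2 * np.pi * 0.2 * t)
        m = norm_series(shared + 0.5 * rng.normal(size=90))
        f = norm_series(shared + 0.5 * rng.normal(size=90))
        clf, chf = band_coherence(msc_spectrum(m, f))
        assert chf > clf

    def test_band_edges_partition_at_015(self):
        freqs = np.linspace(0, 0.25, 129)
        b = BandDefinition()
        lf = (freqs >= b.lf[0]) & (freqs < b.lf[1])
        hf = (freqs >= b.hf[0]) & (freqs <= b.hf[1])
        assert not np.any(lf & hf)

    def test_unresolvable_band_errors(self):
        spec = CoherenceSpectrum(np.array([0.0, 0.25]), np.array([1.0, 1.0]))
        with pytest.raises(SimilarityError, match="band"):
            band_coherence(spec)


class TestScoreEpoch:
    def test_coupled_epoch_scores_high(self):
        # fetal RRI fluctuation is a scaled copy of the maternal one
        n_m, n_f = 1500, 450
        tm = np.cumsum(np.full(n_m, 150.0))
        mf = 10 * np.sin(2 * np.pi * 0.05 * tm / 1000.0)
        m_rri = 150.0 + mf
        tf = np.cumsum(np.full(n_f, 500.0))
        f_rri = 500.0 + 40 * np.sin(2 * np.pi * 0.05 * tf / 1000.0)
        ep = epoch_from_rri(m_rri, f_rri, 0, 180_000)
        s = score_epoch(ep)
        assert s.cc1 > 0.9 and s.cc2 > 0.9
        assert s.clf > 0.8 and s.n_valid_windows == 9

    def test_anticoupled_epoch_flips_cc2(self):
        n_m, n_f = 1500, 450
        tm = np.cumsum(np.full(n_m, 150.0))
        m_rri = 150.0 + 10 * np.sin(2 * np.pi * 0.05 * tm / 1000.0)
        tf = np.cumsum(np.full(n_f, 500.0))
        f_rri = 500.0 - 40 * np.sin(2 * np.pi * 0.05 * tf / 1000.0)
        ep = epoch_from_rri(m_rri, f_rri, 0, 180_000)
        s = score_epoch(ep)
        assert s.cc2 < -0.9 and s.cc1 > 0.9

    def test_stage_error_identifies_stage(self):
        ep = epoch_from_rri([150.0] * 1200, [500.0] * 360, 0, 180_000)
        with pytest.raises(SimilarityError, match="resample/normalize"):
            score_epoch(ep)  # constant signals: normalization degenerate
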