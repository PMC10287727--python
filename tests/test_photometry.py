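"""Photometry preprocessing and diurnal-statistic checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chronoplex import photometry as ph
from chronoplex import synthdata as sd
from chronoplex.datatypes import PhotometryTrace, WTEnvelope


def make_trace(time_h, value, **kw):
    return PhotometryTrace(time_h=np.asarray(time_h, float), value=np.asarray(value, float), **kw)


class TestBinMedian:
    def test_constant_trace(self):
        t = np.arange(0, 2, 1 / 300)  # 5 Hz-ish over 2 h
        out = ph.bin_median(make_trace(t, np.full(t.size, 3.0)))
        assert np.allclose(out.value, 3.0)
        assert out.time_h.size == 12

    def test_median_rejects_spike(self):
        t = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        out = ph.bin_median(make_trace(t, [1.0, 1.0, 1.0, 1.0, 100.0]))
        assert out.value[0] == 1.0

    def test_24h_5hz_gives_144_bins(self):
        trace, _ = sd.gen_photometry(sd.PhotometrySimParams(noise_sd=0.0))
        assert ph.bin_median(trace).time_h.size == 144

    def test_empty_bins_interpolated(self):
        t = np.array([0.01, 0.02, 0.5, 0.51])  # gap leaves bin 1 empty
        out = ph.bin_median(make_trace(t, [0.0, 0.0, 3.0, 3.0]), bin_min=10.0)
        assert np.all(np.isfinite(out.value))
        assert out.value[1] == pytest.approx(1.5)

    def test_empty_trace_errors(self):
        with pytest.raises(ValueError):
            ph.bin_median(make_trace([], []))


class TestStretchedExponentialFit:
    def test_constant_trace(self):
        t = np.linspace(0, 10, 61)
        fit = ph.fit_stretched_exponential(make_trace(t, np.full(61, 5.0)))
        assert fit.alpha + fit.beta == pytest.approx(5.0, abs=1e-6)
        assert abs(fit.beta) < 1e-3 or fit.rss < 1e-10

    def test_noiseless_parameter_recovery(self):
        trace, _ = sd.gen_photometry(sd.PhotometrySimParams(
            alpha=1.0, beta=0.5, gamma=0.05, delta=0.7, signal_amplitude=0.0, noise_sd=0.0))
        fit = ph.fit_stretched_exponential(ph.bin_median(trace))
        for got, want in [(fit.alpha, 1.0), (fit.beta, 0.5), (fit.gamma, 0.05), (fit.delta, 0.7)]:
            assert abs(got - want) / want < 1e-3

    def test_model_identity_at_zero(self):
        trace, _ = sd.gen_photometry(sd.PhotometrySimParams(signal_amplitude=0.0, noise_sd=0.01, seed=3))
        fit = ph.fit_stretched_exponential(ph.bin_median(trace))
        assert fit.model(np.array([0.0]))[0] == pytest.approx(fit.alpha + fit.beta, rel=1e-12)

    def test_too_short_errors(self):
        t = np.linspace(0, 2, 13)
        with pytest.raises(ValueError, match="floor"):
            ph.fit_stretched_exponential(make_trace(t, np.ones(13)))


class TestCorrectPhotobleach:
    def test_exact_fit_gives_zeros(self):
        from chronoplex.datatypes import BleachFit
        fit = BleachFit(alpha=1.0, beta=0.5, gamma=0.05, delta=0.7, rss=0.0, converged=True)
        t = np.linspace(0, 24, 145)[1:]
        trace = make_trace(t, fit.model(t))
        out = ph.correct_photobleach(trace, fit)
        assert np.allclose(out.value, 0.0, atol=1e-12)

    def test_involution(self):
        trace, _ = sd.gen_photometry(sd.PhotometrySimParams(noise_sd=0.01, seed=2))
        binned = ph.bin_median(trace)
        fit = ph.fit_bleach_light_anchored(binned)
        corrected = ph.correct_photobleach(binned, fit)
        restored = corrected.with_values(corrected.value + fit.model(corrected.time_h))
        assert np.allclose(restored.value, binned.value, atol=1e-12)

    def test_corrected_equals_sigmoid(self, noiseless_reporter):
        """With the light-anchored fit, the corrected noiseless trace is the
        diurnal sigmoid to within the fit's extrapolation error."""
        trace, gt = noiseless_reporter
        binned = ph.bin_median(trace)
        fit = ph.fit_bleach_light_anchored(binned)
        corrected = ph.correct_photobleach(binned, fit)
        assert np.allclose(corrected.value, gt.signal(binned.time_h), atol=5e-3)

    def test_nonconverged_fit_rejected(self):
        from chronoplex.datatypes import BleachFit
        fit = BleachFit(1.0, 0.5, 0.05, 0.7, rss=0.0, converged=False)
        trace, _ = sd.gen_photometry(sd.PhotometrySimParams(noise_sd=0.0))
        with pytest.raises(ValueError):
            ph.correct_photobleach(ph.bin_median(trace), fit)


class TestComputeDff:
    def test_constant_traces_give_zero(self):
        t = np.linspace(0, 6, 37)
        out = ph.compute_dff(make_trace(t, np.zeros(37)), make_trace(t, np.full(37, 2.0)))
        assert np.allclose(out.dff, 0.0)
        assert out.f0 == 2.0

    def test_first_hour_centering(self):
        t = np.arange(0.05, 6, 0.1)
        raw = make_trace(t, 1.0 + 0.1 * t)
        out = ph.compute_dff(raw, raw)
        first = out.time_h <= out.time_h[0] + 1.0
        assert np.mean(out.dff[first]) == pytest.approx(0.0, abs=1e-12)
        assert np.all(out.dff[t > 2.0] > 0)

    def test_plateau_amplitude(self, noiseless_reporter):
        trace, gt = noiseless_reporter
        norm = ph.preprocess(trace)
        f0 = np.mean(gt.bleach(np.linspace(0, 1, 50)))
        plateau = norm.dff[(norm.time_h > 10) & (norm.time_h < 14)].mean()
        assert plateau == pytest.approx(gt.plateau / f0, rel=0.01)

    def test_scale_invariance(self):
        trace, _ = sd.gen_photometry(sd.PhotometrySimParams(noise_sd=0.01, seed=9))
        binned = ph.bin_median(trace)
        a = ph.compute_dff(binned, binned)
        scaled = binned.with_values(binned.value * 7.0)
        b = ph.compute_dff(scaled, scaled)
        assert np.allclose(a.dff, b.dff, atol=1e-12)

    def test_nonpositive_f0_errors(self):
        t = np.linspace(0, 6, 37)
        with pytest.raises(ValueError, match="baseline"):
            ph.compute_dff(make_trace(t, np.zeros(37)), make_trace(t, np.full(37, -1.0)))


class TestPeakResponse:
    def test_constant(self):
        trace, _ = sd.gen_photometry(sd.PhotometrySimParams(noise_sd=0.0))
        norm = ph.preprocess(trace, correct_bleach=False)
        norm.dff = np.full_like(norm.dff, 0.3)
        assert ph.peak_response(norm) == pytest.approx(0.3)

    def test_clock_ramp_averages_half(self):
        trace, _ = sd.gen_photometry(sd.PhotometrySimParams(noise_sd=0.0))
        norm = ph.preprocess(trace, correct_bleach=False)
        clock = norm.clock_h
        ramp = np.clip((clock - 20.5), 0, 1.0)
        ramp[(norm.time_h > 9)] = 0  # keep only the first window occurrence
        norm.dff = ramp
        assert ph.peak_response(norm) == pytest.approx(0.5, abs=1 / 6 / 2)

    def test_uncovered_window_errors(self):
        t = np.linspace(0.05, 2, 12)
        norm = ph.compute_dff(make_trace(t, np.ones(12)), make_trace(t, np.ones(12)))
        with pytest.raises(ValueError, match="window"):
            ph.peak_response(norm)


class TestClassification:
    ENV = WTEnvelope(lo=-0.05, hi=0.05, n_wt=5)

    @pytest.mark.parametrize("peak,expected", [
        (0.05, "wild_type_like"),   # boundary tie is inclusive
        (-0.05, "wild_type_like"),
        (0.2, "strong"),
        (-0.2, "dropping"),
    ])
    def test_rules(self, peak, expected):
        assert ph.classify_responders([peak], self.ENV) == [expected]

    def test_empty_list(self):
        assert ph.classify_responders([], self.ENV) == []

    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=10))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_peak(self, peaks):
        """Raising a peak response never demotes its class."""
        order = {"dropping": 0, "wild_type_like": 1, "strong": 2}
        classes = ph.classify_responders(sorted(peaks), self.ENV)
        ranks = [order[c] for c in classes]
        assert ranks == sorted(ranks)


class TestTimeToFraction:
    def _norm_with(self, dff_fn):
        trace, _ = sd.gen_photometry(sd.PhotometrySimParams(noise_sd=0.0))
        norm = ph.preprocess(trace, correct_bleach=False)
        norm.dff = dff_fn(norm)
        return norm

    def test_step_crossing(self):
        norm = self._norm_with(lambda n: np.where(n.time_h >= 5.0, 1.0, 0.0))  # clock 18.0
        t20, ant = ph.time_to_fraction_of_peak(norm, peak=1.0)
        assert ant == pytest.approx(60.0, abs=10.0)

    def test_linear_ramp_inversion(self):
        """Ramp 0→peak over clock 17–21 crosses 20% at clock 17.8 (72 min lead)."""
        norm = self._norm_with(lambda n: np.clip((n.time_h - 4.0) / 4.0, 0, 1))
        t20, ant = ph.time_to_fraction_of_peak(norm, peak=1.0)
        assert t20 == pytest.approx(17.8, abs=1 / 6)
        assert ant == pytest.approx(72.0, abs=10.0)

    def test_no_crossing_flagged(self):
        norm = self._norm_with(lambda n: np.zeros_like(n.dff))
        t20, ant = ph.time_to_fraction_of_peak(norm, peak=1.0)
        assert t20 is None and ant is None

    def test_sustained_rule_skips_single_spike(self):
        def dff(n):
            out = np.where(n.time_h >= 5.0, 1.0, 0.0)
            out[10] = 1.0  # isolated spike well before the rise
            return out
        norm = self._norm_with(dff)
        t20_sust, _ = ph.time_to_fraction_of_peak(norm, peak=1.0, sustained_bins=3)
        t20_inst, _ = ph.time_to_fraction_of_peak(norm, peak=1.0, sustained_bins=1)
        assert t20_sust == pytest.approx(18.0, abs=0.1)
        assert t20_inst < t20_sust  # instantaneous rule trips on the spike


class TestDailyModulation:
    def test_constant_gives_zero(self):
        trace, _ = sd.gen_photometry(sd.PhotometrySimParams(
            beta=0.0, signal_amplitude=0.0, noise_sd=0.0, duration_h=48.0))
        norm = ph.preprocess(trace, correct_bleach=False)
        amps = ph.daily_modulation_amplitude(norm)
        assert len(amps) == 2
        assert np.allclose(amps, 0.0, atol=1e-12)

    def test_sinusoid_interpercentile_factor(self):
        trace, _ = sd.gen_photometry(sd.PhotometrySimParams(
            beta=0.0, signal_amplitude=0.0, noise_sd=0.0, duration_h=48.0))
        norm = ph.preprocess(trace, correct_bleach=False)
        amp = 0.4
        norm.dff = amp * np.sin(2 * np.pi * norm.time_h / 24.0)
        # numerically evaluated 5-95 interpercentile factor of a sampled sinusoid
        phase = np.linspace(0, 2 * np.pi, 100000, endpoint=False)
        factor = np.percentile(np.sin(phase), 95) - np.percentile(np.sin(phase), 5)
        amps = ph.daily_modulation_amplitude(norm)
        assert amps == pytest.approx([amp * factor] * 2, rel=0.02)

    def test_short_recording_empty(self):
        trace, _ = sd.gen_photometry(sd.PhotometrySimParams(noise_sd=0.0, duration_h=12.0))
        norm = ph.preprocess(trace, correct_bleach=False)
        assert ph.daily_modulation_amplitude(norm) == []

    def test_reporter_vs_wildtype_cycle2_amplitudes(self):
        """Second-day modulation amplitudes separate reporter from wild-type
        cohorts (n=8 each) at the generator's effect size."""
        from scipy.stats import mannwhitneyu
        rep, wt = [], []
        for i in range(8):
            tr_r, _ = sd.gen_photometry(sd.PhotometrySimParams(
                duration_h=48.0, noise_sd=0.01, seed=100 + i))
            tr_w, _ = sd.gen_photometry(sd.PhotometrySimParams(
                duration_h=48.0, signal_amplitude=0.0, noise_sd=0.01, seed=200 + i))
            rep.append(ph.daily_modulation_amplitude(ph.preprocess(tr_r, correct_bleach=False))[1])
            wt.append(ph.daily_modulation_amplitude(ph.preprocess(tr_w, correct_bleach=False))[1])
        assert mannwhitneyu(rep, wt, alternative="greater").pvalue < 0.05
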