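import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from metastable import empirical as emp
from metastable import synth


class TestPupilCleaning:
    def test_artifact_free_trace_preserved(self):
        t = np.arange(0, 60, 0.001)
        d = 0.6 + 0.2 * np.sin(2 * np.pi * t / 30)
        out = emp.clean_pupil_trace(t, d)
        assert out["removed"].mean() == 0.0
        assert np.nanmax(out["diameter"]) == pytest.approx(1.0)
        # smoothing only: shape preserved
        ref = d / d.max()
        assert np.nanmax(np.abs(out["diameter"] - ref[:out["diameter"].size])) < 0.01

    def test_injected_step_removed_with_margins(self):
        t = np.arange(0, 30, 0.001)
        d = np.full(t.size, 0.7)
        d[15000:15300] += 0.2    # normalized jump ~ 0.22 > 0.08
        out = emp.clean_pupil_trace(t, d)
        # [-250 ms, +500 ms] around both edges is removed
        assert out["removed"][14800:15700].all()
        assert not out["removed"][:14000].any()

    def test_below_threshold_jump_kept(self):
        t = np.arange(0, 30, 0.001)
        d = np.full(t.size, 0.8)
        d[15000:] += 0.04        # 5% of max: below the 8% threshold
        out = emp.clean_pupil_trace(t, d)
        assert out["removed"].mean() == 0.0

    def test_fully_removed_raises(self):
        t = np.arange(0, 2, 0.001)
        d = np.where((np.arange(t.size) // 100) % 2 == 0, 0.2, 1.0)
        with pytest.raises(ValueError):
            emp.clean_pupil_trace(t, d)


class TestUnitQC:
    def test_stable_unit_retained(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 1800, 9000))
        amps = synth.gen_template_amplitudes("stable", 1800, times, rng)
        rep = emp.unit_qc(times, amps, 1800, overall_rate=5.0)
        assert rep.retained

    def test_bimodal_unit_rejected(self):
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0, 1800, 9000))
        amps = synth.gen_template_amplitudes("bimodal", 1800, times, rng)
        rep = emp.unit_qc(times, amps, 1800, overall_rate=5.0)
        assert rep.multimodal and not rep.retained

    def test_floor_drift_unit_rejected(self):
        rng = np.random.default_rng(2)
        times = np.sort(rng.uniform(0, 1800, 9000))
        amps = synth.gen_template_amplitudes("floor_drift", 1800, times, rng)
        rep = emp.unit_qc(times, amps, 1800, overall_rate=5.0)
        assert not rep.retained
        assert rep.max_peak_location_difference >= 25.0

    def test_low_rate_rejected(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 1800, 200))
        amps = synth.gen_template_amplitudes("stable", 1800, times, rng)
        rep = emp.unit_qc(times, amps, 1800, overall_rate=0.1)
        assert rep.low_rate and not rep.retained

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        times = np.sort(rng.uniform(0, 1800, 5000))
        amps = synth.gen_template_amplitudes("stable", 1800, times, rng)
        a = emp.unit_qc(times, amps, 1800, 3.0)
        b = emp.unit_qc(times, amps, 1800, 3.0)
        assert a.retained == b.retained
        assert a.max_peak_location_difference == b.max_peak_location_difference


class TestMWUVectorized:
    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for lam_e in (0.5, 2.0, 5.0):
            ev = rng.poisson(lam_e, size=(20, 30))
            base = rng.poisson(1.0, 500)
            mine = emp._mwu_pvalues_counts(ev, base)
            ref = mannwhitneyu(ev, base[None, :], axis=1,
                               method="asymptotic").pvalue
            np.testing.assert_allclose(mine, ref, atol=1e-12)


class TestToneResponsiveness:
    def make_unit(self, rng, gain, n_ev=120, lam0=4.0):
        ev = np.arange(5.0, 5.0 + 0.8 * n_ev, 0.8)
        base = np.sort(rng.uniform(0, ev[-1] + 5, rng.poisson(lam0 * (ev[-1] + 5))))
        extra = []
        for t0 in ev:
            n = rng.poisson(gain * lam0 * 0.05)
            extra.append(t0 + 0.01 + rng.exponential(0.03, n))
        return np.sort(np.concatenate([base] + extra)), ev

    def test_strong_response_detected(self):
        rng = np.random.default_rng(6)
        st, ev = self.make_unit(rng, gain=8.0)
        res = emp.tone_responsiveness(st, ev, np.full(ev.size, 4000.0))
        assert res[4000.0]

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(7)
        fp = 0
        n_units = 200
        for _ in range(n_units):
            st, ev = self.make_unit(rng, gain=0.0, n_ev=60)
            res = emp.tone_responsiveness(st, ev, np.full(ev.size, 8000.0))
            fp += res[8000.0]
        # Bonferroni + 5 ms run requirement keeps FP below nominal 5%
        assert fp / n_units <= 0.05

    def test_short_run_not_responsive(self):
        """A significance run shorter than 5 ms does not qualify."""
        rng = np.random.default_rng(8)
        st, ev = self.make_unit(rng, gain=8.0)
        out = emp.tone_responsiveness(st, ev, np.full(ev.size, 2000.0),
                                      min_run_ms=10**6)
        assert not out[2000.0]

    def test_degenerate_all_zero(self):
        ev = np.arange(5, 60, 0.8)
        res = emp.tone_responsiveness(np.array([]), ev, np.full(ev.size, 2000.0))
        assert not res[2000.0]


class TestRatePupilModulation:
    def trace(self):
        t = np.arange(0, 600, 0.001)
        pupil = 0.5 + 0.4 * np.sin(2 * np.pi * t / 120)
        return t, pupil

    def make_spikes(self, rng, pupil_fn, t, pupil):
        lam = pupil_fn(pupil)
        lam_max = lam.max()
        cand = np.sort(rng.uniform(0, 600, rng.poisson(lam_max * 600)))
        keep = rng.random(cand.size) < np.interp(cand, t, lam) / lam_max
        return cand[keep]

    def test_positive_and_negative_and_none(self):
        rng = np.random.default_rng(9)
        t, pupil = self.trace()
        blocks = [(0.0, 600.0)]
        st = self.make_spikes(rng, lambda p: 2 + 8 * p, t, pupil)
        assert emp.rate_pupil_modulation(st, t, pupil, blocks)["label"] == "positive"
        st = self.make_spikes(rng, lambda p: 10 - 8 * p, t, pupil)
        assert emp.rate_pupil_modulation(st, t, pupil, blocks)["label"] == "negative"

    def test_independent_unit_sign_rate(self):
        rng = np.random.default_rng(10)
        t, pupil = self.trace()
        blocks = [(0.0, 600.0)]
        labels = []
        for _ in range(60):
            st = np.sort(rng.uniform(0, 600, rng.poisson(5 * 600)))
            labels.append(emp.rate_pupil_modulation(st, t, pupil, blocks)["label"])
        frac_sig = np.mean([l != "none" for l in labels])
        assert frac_sig <= 0.15    # ~5% nominal, slack for autocorrelation


class TestArousalModulationModel:
    def test_mean_modulation_only_positive(self):
        rng = np.random.default_rng(11)
        grid = np.linspace(0, 0.4, 9)
        rates = 5.0 * (1 + 2.0 * grid)[None, :] * (1 + 0.01 * rng.standard_normal((50, 9)))
        out = emp.arousal_modulation_model(rates, grid)
        assert out["frac_positive"] > 0.9
        assert out["frac_negative"] == 0.0

    def test_mixed_modulation_both_signs(self):
        rng = np.random.default_rng(12)
        grid = np.linspace(0, 0.4, 9)
        slopes = np.where(rng.random(60) < 0.5, 3.0, -1.5)
        rates = np.clip(5.0 + slopes[:, None] * grid[None, :]
                        + 0.05 * rng.standard_normal((60, 9)), 0.0, None)
        out = emp.arousal_modulation_model(rates, grid)
        assert out["frac_positive"] > 0.3 and out["frac_negative"] > 0.3

    def test_constant_cells_none(self):
        grid = np.linspace(0, 0.4, 9)
        rates = np.full((5, 9), 4.0)
        out = emp.arousal_modulation_model(rates, grid)
        assert out["frac_positive"] == 0.0 and out["frac_negative"] == 0.0
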