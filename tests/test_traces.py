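import numpy as np
import pytest

from vesiclequant import (
    NoiseModel,
    ROITrace,
    apply_bleach_correction,
    compute_dff,
    field_average,
    fit_background_bleach,
    normalize_trace,
    screen_rois,
    simulate_field,
)
from vesiclequant.traces import (
    corrected_background_slope_ci,
    process_field,
    subtract_background,
)

from .conftest import analytic_dff, exact_priors


def _trace(intensity, time=None, role="synaptic", flags=("raw",)):
    intensity = np.asarray(intensity, dtype=float)
    time = np.arange(intensity.size, dtype=float) if time is None else time
    return ROITrace("roi", role, time, intensity, frozenset(flags))


class TestBleachFit:
    def test_exact_recovery_noiseless(self):
        t = np.arange(0.0, 140.0)
        tr = _trace(50.0 * np.exp(-t / 600.0), time=t, role="background")
        model = fit_background_bleach([tr], nh4cl_onset=140.0)
        assert model.amplitude == pytest.approx(50.0, rel=1e-6)
        assert model.rate == pytest.approx(1 / 600.0, rel=1e-6)

    def test_constant_background_gives_zero_rate(self):
        tr = _trace(np.full(140, 37.0), role="background")
        model = fit_background_bleach([tr], nh4cl_onset=140.0)
        assert model.rate == pytest.approx(0.0, abs=1e-12)

    def test_nondecaying_background_clipped_to_zero(self):
        t = np.arange(0.0, 140.0)
        tr = _trace(50.0 + 0.05 * t, time=t, role="background")
        model = fit_background_bleach([tr], nh4cl_onset=140.0)
        assert model.rate == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_background_rejected(self):
        tr = _trace(np.zeros(140), role="background")
        with pytest.raises(ValueError, match="all zero"):
            fit_background_bleach([tr], nh4cl_onset=140.0)

    def test_too_few_frames_rejected(self):
        tr = _trace(np.full(140, 10.0), role="background")
        with pytest.raises(ValueError, match=">= 10 frames"):
            fit_background_bleach([tr], nh4cl_onset=5.0)

    def test_noisy_rate_recovery(self):
        """Across repeated noisy fits the decay rate lands within 15% of truth."""
        t = np.arange(0.0, 140.0)
        truth = 1 / 600.0
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            f = 50.0 * np.exp(-t * truth) + rng.normal(0, 2.0, t.size)
            model = fit_background_bleach(
                [_trace(f, time=t, role="background")], nh4cl_onset=140.0)
            errs.append(abs(model.rate - truth) / truth)
        assert np.median(errs) < 0.15


class TestBleachCorrection:
    def test_zero_rate_is_identity(self):
        tr = _trace(np.full(140, 37.0), role="background")
        model = fit_background_bleach([tr], nh4cl_onset=140.0)
        out = apply_bleach_correction(tr, model)
        assert np.allclose(out.intensity, tr.intensity)

    def test_double_correction_rejected(self):
        tr = _trace(np.full(140, 37.0), role="background")
        model = fit_background_bleach([tr], nh4cl_onset=140.0)
        once = apply_bleach_correction(tr, model)
        with pytest.raises(ValueError, match="already bleach-corrected"):
            apply_bleach_correction(once, model)

    def test_recovers_bleach_free_trace(self, pool_protocol):
        """Corrected synaptic traces match the bleach-free generative trace."""
        from vesiclequant import simulate_bouton_trace

        priors = exact_priors()
        gt = priors.center()
        bleached = NoiseModel(sigma_rel=0.0, background_level=50.0, bleach_tau=600.0)
        clean = NoiseModel(sigma_rel=0.0, background_level=50.0, bleach_tau=np.inf)
        tr_b = simulate_bouton_trace(gt, pool_protocol, bleached)
        tr_c = simulate_bouton_trace(gt, pool_protocol, clean)
        from vesiclequant.synthetic import simulate_background_trace

        bg = simulate_background_trace(pool_protocol, bleached)
        model = fit_background_bleach([bg], pool_protocol.nh4cl.t_start)
        corrected = apply_bleach_correction(tr_b, model)
        rmse = np.sqrt(np.mean((corrected.intensity - tr_c.intensity) ** 2))
        assert rmse / np.mean(tr_c.intensity) < 0.005

    def test_corrected_background_slope_ci_contains_zero(self, pool_protocol):
        noise = NoiseModel(sigma_rel=0.02, background_level=50.0,
                           bleach_tau=600.0, seed=7)
        from vesiclequant.synthetic import simulate_background_trace

        rng = np.random.default_rng(7)
        bgs = [simulate_background_trace(pool_protocol, noise, rng=rng)
               for _ in range(4)]
        model = fit_background_bleach(bgs, pool_protocol.nh4cl.t_start)
        corrected = apply_bleach_correction(bgs[0], model)
        slope, lo, hi = corrected_background_slope_ci(
            corrected, pool_protocol.nh4cl.t_start)
        assert lo <= 0.0 <= hi


class TestDff:
    def test_simple_ratio(self):
        tr = _trace([100, 100, 100, 100, 100, 150, 200], flags=("raw", "bleach_corrected"))
        out = compute_dff(tr, stim_onset=5.0)
        assert out.intensity[5] == pytest.approx(0.5)
        assert out.intensity[6] == pytest.approx(1.0)

    def test_constant_trace_is_all_zero(self):
        tr = _trace(np.full(20, 80.0))
        assert np.allclose(compute_dff(tr, stim_onset=10.0).intensity, 0.0)

    def test_baseline_is_mean_of_last_five_frames(self):
        tr = _trace([999, 90, 100, 110, 100, 100, 200])
        out = compute_dff(tr, stim_onset=6.0)  # F0 = mean(90..100) = 100
        assert out.intensity[6] == pytest.approx(1.0)

    def test_nonpositive_baseline_rejected(self):
        tr = _trace([0, 0, 0, 0, 0, 10])
        with pytest.raises(ValueError, match="F0"):
            compute_dff(tr, stim_onset=5.0)

    def test_too_short_baseline_rejected(self):
        tr = _trace([1, 2, 3, 4, 5, 6])
        with pytest.raises(ValueError, match="before stimulation"):
            compute_dff(tr, stim_onset=3.0)


class TestScreen:
    @staticmethod
    def _field(n_resp, n_dead, seed=0, sigma=0.02):
        noise = NoiseModel(sigma_rel=sigma, background_level=50.0, bleach_tau=600.0)
        from vesiclequant import get_preset

        protocol = get_preset("pool_1200ap")
        fr = simulate_field(n_resp, n_dead, 4, exact_priors(), protocol, noise,
                            seed=seed)
        return process_field(fr, protocol), protocol, fr

    def test_dead_roi_excluded_with_reason(self):
        proc, _, _ = self._field(21, 3, seed=5)
        excluded = proc.qc.roi_status[~proc.qc.roi_status["included"]]
        assert (excluded["reason"] == "no_stim_response").all()
        assert len(excluded) == 3

    def test_field_pass_requires_strictly_more_than_20(self):
        proc20, _, _ = self._field(20, 5, seed=1)
        assert proc20.qc.n_responsive == 20
        assert not proc20.qc.field_pass
        proc21, _, _ = self._field(21, 5, seed=1)
        assert proc21.qc.n_responsive == 21
        assert proc21.qc.field_pass

    def test_sensitivity_and_specificity(self):
        """Screen decisions against the generator's responsive labels."""
        hits = misses = rejects = false_alarms = 0
        for seed in range(10):
            proc, _, fr = self._field(25, 5, seed=seed)
            truth = fr.ground_truth.set_index("roi_id")["responsive"]
            status = proc.qc.roi_status.set_index("roi_id")["included"]
            for roi, inc in status.items():
                if truth[roi]:
                    hits += inc
                    misses += not inc
                else:
                    rejects += not inc
                    false_alarms += inc
        assert hits / (hits + misses) >= 0.95
        assert rejects / (rejects + false_alarms) >= 0.95

    def test_monotone_in_noise_k(self):
        proc, protocol, _ = self._field(25, 5, seed=3)
        counts = [screen_rois(proc.dff_traces, protocol, noise_k=k).n_responsive
                  for k in (0.5, 2.0, 5.0, 20.0)]
        assert counts == sorted(counts, reverse=True)


class TestAverageAndNormalize:
    def test_average_of_identical_rois(self, pool_protocol):
        proc, protocol, _ = TestScreen._field(25, 0, seed=2, sigma=0.0)
        one = proc.dff_traces[0]
        assert np.allclose(proc.mean_dff.intensity, one.intensity, atol=1e-9)

    def test_failed_field_cannot_be_averaged(self):
        proc, protocol, _ = TestScreen._field(10, 0, seed=2, sigma=0.0)
        with pytest.raises(ValueError, match="field excluded"):
            field_average(proc.dff_traces, proc.qc)

    def test_normalization_arithmetic(self, pool_protocol):
        t = pool_protocol.frame_times
        # plateaus at 0.6 well before stimulation ends, NH4Cl maximum 1.2
        y = np.where(t < 0, 0.0, np.minimum(0.6, 0.006 * np.maximum(t, 0)))
        y = np.where(pool_protocol.nh4cl.contains(t), 1.2, y)
        tr = ROITrace("m", "synaptic", t, y, frozenset({"dff"}))
        stim_norm = normalize_trace(tr, "stim_peak", pool_protocol)
        i_end = pool_protocol.frames_in(pool_protocol.stim_window)[-1]
        assert stim_norm.intensity[i_end] == pytest.approx(1.0)
        nh4_norm = normalize_trace(tr, "nh4cl_peak", pool_protocol)
        assert nh4_norm.intensity[i_end] == pytest.approx(0.5)

    def test_renormalization_is_idempotent(self, pool_protocol):
        proc, protocol, _ = TestScreen._field(25, 0, seed=4, sigma=0.0)
        once = normalize_trace(proc.mean_dff, "nh4cl_peak", protocol)
        twice = normalize_trace(once, "nh4cl_peak", protocol)
        assert np.array_equal(once.intensity, twice.intensity)

    def test_nh4cl_normalized_trace_bounded(self):
        proc, protocol, _ = TestScreen._field(25, 5, seed=6)
        norm = normalize_trace(proc.mean_dff, "nh4cl_peak", protocol)
        assert norm.intensity.min() > -0.25
        assert norm.intensity.max() <= 1.0 + 1e-9


class TestPipelineIdentity:
    def test_bleach_free_noiseless_chain_matches_analytic_dff(self, pool_protocol):
        """The correction→subtraction→ΔF/F0 chain is exact on clean input."""
        noise = NoiseModel(sigma_rel=0.0, background_level=50.0, bleach_tau=np.inf)
        priors = exact_priors()
        fr = simulate_field(25, 0, 2, priors, pool_protocol, noise, seed=0)
        proc = process_field(fr, pool_protocol)
        gt = priors.center()
        expected = analytic_dff(pool_protocol.frame_times, gt.surface_frac,
                                gt.vesicular_quench, gt.recycling_frac,
                                gt.tau_true, pool_protocol)
        assert np.allclose(proc.mean_dff.intensity, expected, rtol=1e-9, atol=1e-9)


def test_subtract_background_shape_mismatch():
    tr = _trace(np.ones(10))
    with pytest.raises(ValueError, match="length"):
        subtract_background(tr, np.ones(5))


def test_trace_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        ROITrace("r", "synaptic", [0.0, 0.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="finite"):
        ROITrace("r", "synaptic", [0.0, 1.0], [1.0, np.nan])
    with pytest.raises(ValueError, match="roi_role"):
        ROITrace("r", "other", [0.0, 1.0], [1.0, 2.0])
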