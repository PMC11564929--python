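import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesiclequant import (
    BoutonGroundTruth,
    NoiseModel,
    PhenotypeLink,
    cumulative_fused_fraction,
    simulate_bouton_trace,
    simulate_cohort_phenotypes,
    simulate_field,
    simulate_line_profile,
    simulate_partitioning_trace,
    spearman_r,
    visible_fraction,
)
from vesiclequant.io import write_trace_table
from vesiclequant.synthetic import MeasureLink

from .conftest import exact_priors

gt_strategy = st.builds(
    BoutonGroundTruth,
    total_units=st.floats(100.0, 5000.0),
    surface_frac=st.floats(0.0, 1.0),
    recycling_frac=st.floats(0.1, 1.0),
    rrp_frac=st.just(0.05),
    tau_true=st.floats(1.0, 100.0),
    vesicular_quench=st.floats(0.0, 0.2),
)


class TestGroundTruthValidation:
    def test_rrp_subset_of_recycling(self):
        with pytest.raises(ValueError, match="rrp_frac"):
            BoutonGroundTruth(recycling_frac=0.3, rrp_frac=0.4)

    @pytest.mark.parametrize("kw", [dict(tau_true=0.0), dict(total_units=-1.0),
                                    dict(surface_frac=1.5)])
    def test_invalid_parameters(self, kw):
        with pytest.raises(ValueError):
            BoutonGroundTruth(**kw)


class TestBoutonTrace:
    def test_pure_fusion_curve(self, pool_protocol):
        """With everything else off, the stim-window trace IS T*(1-exp(-t/tau))."""
        gt = BoutonGroundTruth(total_units=1000.0, surface_frac=0.0,
                               recycling_frac=1.0, rrp_frac=0.05, tau_true=20.0,
                               vesicular_quench=0.0)
        noise = NoiseModel(sigma_rel=0.0, background_level=0.0, bleach_tau=np.inf)
        tr = simulate_bouton_trace(gt, pool_protocol, noise)
        t = tr.time_s
        stim = (t >= 0) & (t < 120)
        expected = 1000.0 * (1 - np.exp(-t[stim] / 20.0))
        assert np.allclose(tr.intensity[stim], expected, rtol=1e-12)
        i_tau = np.argmin(np.abs(t - 20.0))
        assert tr.intensity[i_tau] == pytest.approx(1000.0 * (1 - np.e**-1))

    def test_unresponsive_bouton(self, pool_protocol):
        gt = BoutonGroundTruth(surface_frac=0.0, vesicular_quench=0.0,
                               responsive=False)
        noise = NoiseModel(sigma_rel=0.0, background_level=30.0, bleach_tau=np.inf)
        tr = simulate_bouton_trace(gt, pool_protocol, noise)
        stim = pool_protocol.frames_in(pool_protocol.stim_window)
        assert np.allclose(tr.intensity[stim], 30.0)  # flat at background
        nh4 = pool_protocol.frames_in(pool_protocol.nh4cl)
        assert np.allclose(tr.intensity[nh4], 30.0 + gt.total_units)

    def test_protocol_without_nh4cl_rejected(self):
        from vesiclequant.protocols import Protocol, StimSegment

        p = Protocol("x", np.arange(-5.0, 130.0),
                     [StimSegment(1200, 10.0, 0.0)])
        with pytest.raises(ValueError, match="NH4Cl"):
            simulate_bouton_trace(BoutonGroundTruth(), p, NoiseModel())

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(gt=gt_strategy)
    def test_fusion_monotone_and_visibility_bounded(self, gt):
        """c(t) never decreases under bafilomycin; V(t) stays in [0,1] with
        NH4Cl as its supremum."""
        from vesiclequant import get_preset

        protocol = get_preset("pool_1200ap")
        t = protocol.frame_times
        c = cumulative_fused_fraction(gt, protocol, t)
        assert np.all(np.diff(c) >= -1e-12)
        v = visible_fraction(gt, protocol, t)
        assert np.all((v >= -1e-12) & (v <= 1 + 1e-12))
        nh4 = protocol.frames_in(protocol.nh4cl)
        assert np.all(v[nh4] >= v.max() - 1e-12)

    def test_rrp_kinetics_shape(self, rrp_protocol):
        """Linear rise over the burst, plateau through the gap, then one-phase
        resumption toward the recycling fraction."""
        gt = BoutonGroundTruth(recycling_frac=0.5, rrp_frac=0.1, tau_true=20.0)
        t = rrp_protocol.frame_times
        c = cumulative_fused_fraction(gt, rrp_protocol, t)
        gap = (t >= 2.0) & (t < 5.0)
        assert np.allclose(c[gap], 0.1)
        i1 = np.argmin(np.abs(t - 1.0))
        assert c[i1] == pytest.approx(0.05, abs=1e-9)  # halfway through burst
        # resumed kinetics: c(5 + u) = R - (R - rrp) exp(-u/tau)
        i60 = np.argmin(np.abs(t - 60.0))
        assert c[i60] == pytest.approx(0.5 - 0.4 * np.exp(-55.0 / 20.0), rel=1e-9)


class TestField:
    def test_roi_bookkeeping(self, pool_protocol, default_noise):
        fr = simulate_field(25, 5, 4, exact_priors(), pool_protocol,
                            default_noise, seed=1)
        assert len(fr.traces) == 34
        assert len(fr.synaptic_traces) == 30
        assert len(fr.background_traces) == 4
        assert int(fr.ground_truth["responsive"].sum()) == 25

    def test_requires_background_roi(self, pool_protocol, default_noise):
        with pytest.raises(ValueError, match="background"):
            simulate_field(5, 0, 0, exact_priors(), pool_protocol,
                           default_noise, seed=1)

    def test_deterministic_output(self, tmp_path, pool_protocol, default_noise):
        """Identical seeds give byte-identical trace CSVs."""
        paths = []
        for name in ("a.csv", "b.csv"):
            fr = simulate_field(5, 1, 2, exact_priors(), pool_protocol,
                                default_noise, seed=42)
            p = tmp_path / name
            write_trace_table([fr], p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestPartitioningTrace:
    def test_exact_surface_ratio(self, part_protocol):
        gt = BoutonGroundTruth(surface_frac=0.3, vesicular_quench=0.0)
        noise = NoiseModel(sigma_rel=0.0, background_level=0.0, bleach_tau=np.inf)
        tr = simulate_partitioning_trace(gt, part_protocol, noise, q_mes=0.0)
        mean_in = lambda b: np.mean(  # noqa: E731
            tr.intensity[part_protocol.frames_in(part_protocol.perfusion[b])])
        ratio = (mean_in("saline") - mean_in("mes")) / (mean_in("nh4cl") - mean_in("mes"))
        assert ratio == pytest.approx(0.30, abs=1e-12)

    def test_all_surface_boundary(self, part_protocol):
        gt = BoutonGroundTruth(surface_frac=1.0, vesicular_quench=0.0)
        noise = NoiseModel(sigma_rel=0.0, background_level=0.0, bleach_tau=np.inf)
        tr = simulate_partitioning_trace(gt, part_protocol, noise, q_mes=0.0)
        sal = np.mean(tr.intensity[part_protocol.frames_in(part_protocol.perfusion["saline"])])
        nh4 = np.mean(tr.intensity[part_protocol.frames_in(part_protocol.perfusion["nh4cl"])])
        assert sal / nh4 == pytest.approx(1.0)

    def test_missing_window_rejected(self, pool_protocol):
        with pytest.raises(ValueError, match="lacks windows"):
            simulate_partitioning_trace(BoutonGroundTruth(), pool_protocol,
                                        NoiseModel())


class TestLineProfile:
    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="60"):
            simulate_line_profile(100, 5, 100.0, 10.0, 0.0)

    def test_flat_profile(self):
        p = simulate_line_profile(300, 0, 0.0, 50.0, 0.0, seed=0)
        assert np.allclose(p, 50.0)

    def test_puncta_raise_variability(self):
        flat = simulate_line_profile(300, 0, 0.0, 50.0, 0.0, seed=1)
        punctate = simulate_line_profile(300, 10, 200.0, 50.0, 0.0, seed=1)
        cv = lambda x: np.std(x, ddof=1) / np.mean(x)  # noqa: E731
        assert cv(punctate) > cv(flat)


class TestCohortPhenotypes:
    @staticmethod
    def _metrics(n=6):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "initial_rate": rng.uniform(0.005, 0.03, n),
            "tau_s": rng.uniform(15, 50, n),
            "frac_fused_200AP_pct": rng.uniform(10, 40, n),
        }, index=[f"V{i}" for i in range(n)])

    def test_noiseless_link_gives_perfect_rank_correlation(self):
        link = PhenotypeLink(
            links={"VABS_motor": MeasureLink("frac_fused_200AP_pct", 1.0, 40.0)},
            null_measures=("CVI_total",),
            noise_sd={m: 0.0 for m in ("VABS_motor", "VABS_communication",
                                       "CVI_total", "movement_disorder_count",
                                       "DBC_self_injury")},
        )
        metrics = self._metrics()
        table = simulate_cohort_phenotypes(metrics, link, seed=0)
        rho = spearman_r(metrics["frac_fused_200AP_pct"], table["VABS_motor"])
        assert rho == pytest.approx(1.0)

    def test_duplicate_variant_labels_rejected(self):
        metrics = self._metrics()
        metrics.index = ["V0"] * len(metrics)
        with pytest.raises(ValueError, match="duplicated"):
            simulate_cohort_phenotypes(metrics, PhenotypeLink.vabs_deficit_default(),
                                       seed=0)

    def test_ordinal_measures_respect_instrument_ranges(self):
        table = simulate_cohort_phenotypes(
            self._metrics(8), PhenotypeLink.vabs_deficit_default(), seed=3)
        assert (table["movement_disorder_count"] >= 0).all()
        assert table["movement_disorder_count"].eq(
            table["movement_disorder_count"].round()).all()
        assert table["DBC_self_injury"].between(0, 10).all()

    def test_measure_cannot_be_linked_and_null(self):
        with pytest.raises(ValueError, match="both linked and null"):
            PhenotypeLink(
                links={"VABS_motor": MeasureLink("tau_s", 1.0, 0.0)},
                null_measures=("VABS_motor",),
            )
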