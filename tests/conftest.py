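import numpy as np
import pytest

from vesiclequant import GroundTruthPriors, NoiseModel, get_preset


@pytest.fixture(scope="session")
def pool_protocol():
    return get_preset("pool_1200ap")


@pytest.fixture(scope="session")
def rrp_protocol():
    return get_preset("rrp_40ap")


@pytest.fixture(scope="session")
def part_protocol():
    return get_preset("partitioning")


@pytest.fixture(scope="session")
def quiet_noise():
    """No noise, no bleach: the generative model's deterministic core."""
    return NoiseModel(sigma_rel=0.0, background_level=50.0, bleach_tau=np.inf)


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel(seed=0)


def exact_priors(tau=20.0, recycling=0.55, surface=0.25, rrp=0.08, qv=0.06):
    """Degenerate (zero-jitter) priors so every bouton shares one ground truth."""
    return GroundTruthPriors.for_variant(
        tau=tau, recycling=recycling, surface=surface, rrp=rrp,
        tau_rel_jitter=0.0, frac_jitter=0.0, rrp_jitter=0.0,
        total_units=(1000.0, 1000.0), vesicular_quench=qv,
    )


def analytic_pool_c(t, recycling, tau, stim_end=120.0):
    """Closed-form cumulative fused fraction for the sustained-stim assay."""
    t = np.asarray(t, dtype=float)
    return recycling * (1.0 - np.exp(-np.clip(t, 0.0, stim_end) / tau))


def analytic_dff(t, gt_surface, gt_qv, recycling, tau, protocol):
    """Analytic ΔF/F0 trace for a noiseless, bleach-free pool-assay bouton."""
    t = np.asarray(t, dtype=float)
    c = analytic_pool_c(t, recycling, tau, protocol.stim_end)
    s, qv = gt_surface, gt_qv
    v = s + (1 - s) * (c + qv * (1 - c))
    v = np.where(protocol.nh4cl.contains(t), 1.0, v)
    v_b = s + (1 - s) * qv
    return (v - v_b) / v_b
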