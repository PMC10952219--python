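"""WSS metrics: worked limits, brute-force oracles and invariant suites."""
import math

import numpy as np
import pytest

import swirlwell as sw
from swirlwell.metrics import TWO_OVER_PI

from conftest import random_series

N_PROPERTY_SEEDS = 100


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation path)
# ---------------------------------------------------------------------------

ORACLE_STEP_DEG = 0.05


def oracle_axis_minimum(vectors, normalize=False, step_deg=ORACLE_STEP_DEG):
    """Exhaustive grid minimization of the axis objective over [0, pi)."""
    v = np.asarray(vectors, dtype=float)
    if normalize:
        mags = np.linalg.norm(v, axis=1)
        v = v[mags > 0] / mags[mags > 0, None]
    phis = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    perp = np.stack([-np.sin(phis), np.cos(phis), np.zeros_like(phis)], axis=1)
    vals = np.abs(v @ perp.T).mean(axis=0)
    i = vals.argmin()
    return float(vals[i]), float(phis[i])


def assert_matches_oracle(val, expected, lipschitz):
    """The minimized value must agree with the grid oracle within 1e-4 above
    and within the oracle's own resolution error below (the true minimum can
    fall between grid points; |f'| <= the mean vector magnitude)."""
    half_step = math.radians(ORACLE_STEP_DEG) / 2
    assert val <= expected + 1e-4 * max(1.0, expected)
    assert val >= expected - lipschitz * half_step - 1e-9


def test_oracle_matches_analytic_circular_limit(circular_series):
    val, _ = oracle_axis_minimum(circular_series.vectors)
    assert val == pytest.approx(TWO_OVER_PI, abs=1e-3)


# ---------------------------------------------------------------------------
# worked examples per metric
# ---------------------------------------------------------------------------

def test_tawss_examples(circular_series, steady_series, uniaxial_series):
    assert sw.tawss(circular_series) == pytest.approx(1.0, abs=1e-12)
    assert sw.tawss(steady_series) == pytest.approx(0.5, abs=1e-12)
    # mean of |sin| over a cycle -> 2/pi, within quadrature tolerance
    assert sw.tawss(uniaxial_series) == pytest.approx(2 / math.pi, abs=1e-3)


def test_mag_mean_examples(circular_series, steady_series, uniaxial_series):
    assert sw.mag_mean_wss(circular_series) <= 1e-12
    assert sw.mag_mean_wss(steady_series) == pytest.approx(0.5, abs=1e-12)
    assert sw.mag_mean_wss(uniaxial_series) <= 1e-12


def test_osi_examples(circular_series, steady_series, uniaxial_series):
    assert sw.osi(circular_series) == pytest.approx(0.5, abs=1e-9)
    assert sw.osi(steady_series) == pytest.approx(0.0, abs=1e-12)
    # purely oscillatory flow reaches the OSI ceiling...
    assert sw.osi(uniaxial_series) == pytest.approx(0.5, abs=1e-9)


def test_osi_undefined_for_zero_series():
    zero = sw.make_locus(sw.steady((0.0, 0.0, 0.0)), n_samples=16)
    with pytest.raises(sw.UndefinedMetricError):
        sw.osi(zero)


def test_transwss_steady_zero(steady_series):
    assert sw.transwss(steady_series) == pytest.approx(0.0, abs=1e-12)


def test_transwss_circular_offset_limit():
    """As the steady offset vanishes, transWSS/TAWSS -> 2/pi for a circular locus."""
    ratios = []
    for eps in (1e-2, 1e-4):
        s = sw.make_locus(sw.circular(1.0, steady_offset=(eps, 0, 0)), n_samples=360)
        ratios.append(sw.transwss(s) / sw.tawss(s))
    assert ratios[-1] == pytest.approx(2 / math.pi, abs=1e-3)
    assert abs(ratios[1] - 2 / math.pi) <= abs(ratios[0] - 2 / math.pi) + 1e-12


def test_transwss_perpendicular_oscillation():
    """Oscillation perpendicular to a tiny steady mean: the cross component
    is the whole oscillation, so transWSS ~ TAWSS of the oscillation."""
    osc = sw.make_locus(sw.uniaxial(1.0, steady_offset=(1e-6, 0, 0)), n_samples=360)
    expected = np.abs(osc.vectors @ np.array([0.0, 1.0, 0.0])).mean()  # brute force
    assert sw.transwss(osc) == pytest.approx(expected, rel=1e-6)
    assert sw.transwss(osc) == pytest.approx(2 / math.pi, abs=1e-3)


def test_transwss_degenerate_reference(circular_series):
    with pytest.raises(sw.DegenerateReferenceError):
        sw.transwss(circular_series)
    with pytest.raises(sw.DegenerateReferenceError):
        sw.cfi(circular_series)


def test_cfi_examples(steady_series):
    assert sw.cfi(steady_series) == pytest.approx(0.0, abs=1e-12)
    s = sw.make_locus(sw.circular(1.0, steady_offset=(1e-6, 0, 0)), n_samples=360)
    assert round(sw.cfi(s), 2) == 0.64
    # uniaxial oscillation aligned with its mean has no cross-flow
    aligned = sw.make_locus(sw.uniaxial(1.0, steady_offset=(0, 0.3, 0)), n_samples=360)
    assert sw.cfi(aligned) == pytest.approx(0.0, abs=1e-9)


def test_transwss_min_examples(circular_series, steady_series, uniaxial_series):
    val, axis = sw.transwss_min(steady_series)
    assert val == pytest.approx(0.0, abs=1e-12)
    # axis parallel to the steady flow direction (mod pi); the (0.3, 0.4)
    # local offset maps to (0.3, -0.4) globally (tangential is -y here)
    flow_axis = math.atan2(-0.4, 0.3) % math.pi
    assert axis == pytest.approx(flow_axis, abs=1e-6)

    val, _ = sw.transwss_min(circular_series)
    assert val / sw.tawss(circular_series) == pytest.approx(2 / math.pi, abs=1e-3)

    val, axis = sw.transwss_min(uniaxial_series)
    assert val == pytest.approx(0.0, abs=1e-12)
    assert axis == pytest.approx(math.pi / 2, abs=1e-6)  # tangential axis


def test_cfi_min_examples(circular_series, uniaxial_series):
    val, _ = sw.cfi_min(uniaxial_series)
    assert val == pytest.approx(0.0, abs=1e-12)
    val, _ = sw.cfi_min(circular_series)
    assert round(val, 2) == 0.64


def test_cfi_min_elliptic_matches_grid_oracle():
    s = sw.make_locus(sw.elliptic(2.0, 1.0), n_samples=360)
    val, _ = sw.cfi_min(s)
    expected, _ = oracle_axis_minimum(s.vectors, normalize=True)
    assert val == pytest.approx(expected, abs=1e-4)


def test_modal_direction_examples(circular_series, steady_series):
    angle, tie = sw.modal_direction(steady_series)
    assert not tie
    flow = math.atan2(-0.4, 0.3)  # global direction of the local (0.3, 0.4) offset
    assert abs((angle - flow + math.pi) % (2 * math.pi) - math.pi) < math.pi / 18
    # uniform circular sweep with n_samples a multiple of n_bins: all bins tie
    _, tie = sw.modal_direction(circular_series, n_bins=18)
    assert tie


def test_modal_direction_biased_locus():
    s = sw.make_locus(sw.elliptic(1.0, 0.1, asymmetry=0.6), n_samples=360)
    angle, _ = sw.modal_direction(s)
    # dominant direction is the negative tangential one: -e_t = +y here
    tang_angle = math.atan2(-s.frame.tangential[1], -s.frame.tangential[0]) % (2 * math.pi)
    assert abs((angle - tang_angle + math.pi) % (2 * math.pi) - math.pi) <= math.pi / 9


def test_compute_metric_set_circular(circular_series):
    ms = sw.compute_metric_set(circular_series)
    assert ms.osi == pytest.approx(0.5, abs=1e-9)
    assert ms.mag_mean_wss <= 1e-12
    assert round(ms.cfi_min, 2) == 0.64
    assert ms.transwss_min == pytest.approx(TWO_OVER_PI * ms.tawss, abs=1e-3)
    # the mean-referenced metrics have no reference here, and say so
    assert "transwss" in ms.undefined and "cfi" in ms.undefined
    assert math.isnan(ms.transwss) and math.isnan(ms.cfi)


def test_compute_metric_set_steady(steady_series):
    ms = sw.compute_metric_set(steady_series)
    assert ms.osi == 0.0
    for v in (ms.transwss, ms.cfi, ms.transwss_min, ms.cfi_min):
        assert v == pytest.approx(0.0, abs=1e-12)
    flow = math.atan2(-0.4, 0.3) % (2 * math.pi)  # local offset in global frame
    assert ms.dir_mean == pytest.approx(flow, abs=1e-12)
    assert abs((ms.dir_modal - flow + math.pi) % (2 * math.pi) - math.pi) < math.pi / 18
    assert not ms.undefined


# ---------------------------------------------------------------------------
# property suites (explicit 100-seed loops)
# ---------------------------------------------------------------------------

def test_inequality_chain_100_seeds():
    """MagMean <= TAWSS, transWSSmin <= transWSS <= TAWSS, CFImin <= CFI,
    OSI <= 0.5 on randomized loci."""
    for seed in range(N_PROPERTY_SEEDS):
        s = random_series(seed)
        ms = sw.compute_metric_set(s)
        tol = 1e-12 * max(ms.tawss, 1.0)
        assert ms.mag_mean_wss <= ms.tawss + tol
        assert ms.transwss_min <= ms.tawss + tol
        if not math.isnan(ms.transwss):
            assert ms.transwss_min <= ms.transwss + tol
            assert ms.transwss <= ms.tawss + tol
        if not math.isnan(ms.cfi):
            assert ms.cfi_min <= ms.cfi + 1e-12
            assert ms.cfi <= 1.0 + 1e-12
        if not math.isnan(ms.osi):
            assert 0.0 <= ms.osi <= 0.5


def test_scale_invariance_100_seeds():
    """Scaling every vector by k scales the Pa metrics by k and leaves the
    dimensionless ones unchanged (the viscosity-change behaviour)."""
    for seed in range(N_PROPERTY_SEEDS):
        s = random_series(seed, n_samples=64)
        if sw.tawss(s) == 0.0:
            continue
        k = 1.0 + (seed % 17) / 4.0
        a, b = sw.compute_metric_set(s), sw.compute_metric_set(s.scaled(k))
        assert b.tawss == pytest.approx(k * a.tawss, rel=1e-9)
        assert b.mag_mean_wss == pytest.approx(k * a.mag_mean_wss, rel=1e-9, abs=1e-12)
        assert b.transwss_min == pytest.approx(k * a.transwss_min, rel=1e-6, abs=1e-9)
        if not math.isnan(a.osi):
            assert b.osi == pytest.approx(a.osi, abs=1e-12)
        if not math.isnan(a.cfi):
            assert b.cfi == pytest.approx(a.cfi, abs=1e-9)
        assert b.cfi_min == pytest.approx(a.cfi_min, abs=1e-6)


def test_rotation_equivariance_100_seeds():
    """In-plane rotation leaves all scalar metrics fixed and shifts angles."""
    for seed in range(N_PROPERTY_SEEDS):
        s = random_series(seed, n_samples=64)
        if sw.tawss(s) == 0.0:
            continue
        rot = math.radians(30.0)
        a, b = sw.compute_metric_set(s), sw.compute_metric_set(s.rotated(rot))
        assert b.tawss == pytest.approx(a.tawss, rel=1e-12)
        assert b.mag_mean_wss == pytest.approx(a.mag_mean_wss, rel=1e-9, abs=1e-14)
        assert b.transwss_min == pytest.approx(a.transwss_min, rel=1e-6, abs=1e-9)
        assert b.cfi_min == pytest.approx(a.cfi_min, abs=1e-6)
        if not math.isnan(a.dir_mean):
            shift = (b.dir_mean - a.dir_mean) % (2 * math.pi)
            assert shift == pytest.approx(rot, abs=1e-9)


def test_minimizing_axis_rotation_equivariance():
    """The minimizing axes shift with an in-plane rotation when the
    objective has a unique minimum (strongly elongated locus)."""
    s = sw.make_locus(sw.elliptic(2.0, 0.3), n_samples=180)
    rot = math.radians(30.0)
    _, axis_a = sw.transwss_min(s)
    _, axis_b = sw.transwss_min(s.rotated(rot))
    assert (axis_b - axis_a) % math.pi == pytest.approx(rot, abs=1e-4)
    _, caxis_a = sw.cfi_min(s)
    _, caxis_b = sw.cfi_min(s.rotated(rot))
    assert (caxis_b - caxis_a) % math.pi == pytest.approx(rot, abs=1e-4)


def test_axis_minimization_matches_grid_oracle_100_seeds():
    """transwss_min and cfi_min agree with exhaustive 0.05-degree grid search."""
    for seed in range(N_PROPERTY_SEEDS):
        s = random_series(seed, n_samples=64)
        val, _ = sw.transwss_min(s)
        expected, _ = oracle_axis_minimum(s.vectors)
        assert_matches_oracle(val, expected, lipschitz=sw.tawss(s))
        if np.linalg.norm(s.vectors, axis=1).max() > 0:
            val, _ = sw.cfi_min(s)
            expected, _ = oracle_axis_minimum(s.vectors, normalize=True)
            assert_matches_oracle(val, expected, lipschitz=1.0)


def test_quadrature_convergence_doubling_samples():
    """Doubling the sampling changes metrics of smooth loci by < 1e-4 relative."""
    for spec in [sw.circular(1.0), sw.elliptic(1.5, 0.5, asymmetry=0.4),
                 sw.uniaxial(1.0, steady_offset=(0.1, 0.0, 0.0))]:
        a = sw.compute_metric_set(sw.make_locus(spec, n_samples=360))
        b = sw.compute_metric_set(sw.make_locus(spec, n_samples=720))
        for key in ("tawss", "mag_mean_wss", "osi", "transwss_min", "cfi_min"):
            x, y = getattr(a, key), getattr(b, key)
            if math.isnan(x):
                assert math.isnan(y)
            else:
                assert y == pytest.approx(x, rel=1e-4, abs=1e-6)
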