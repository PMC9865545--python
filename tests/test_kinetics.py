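"""Release-kinetics module: forward models against a finite-difference PDE
oracle, power-law reference fits, decomposition and mechanism classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from collamat.kinetics import (
    ANALYTE_D_OVER_A2,
    DecompositionWeights,
    Geometry,
    Mechanism,
    ReferenceCurve,
    Regime,
    ReleaseSeries,
    case2_fraction,
    classify_mechanism,
    decompose_release,
    fickian_fraction,
    fit_power_law,
    generalized_case2_fraction,
    reference_fit,
    time_to_fraction,
    truncate_to_fraction,
)
from collamat.synthetic import GeneratorConfig, gen_release_series


def radial_diffusion_release(times, d_over_a2, nr=400):
    """Crank-Nicolson finite-difference solution of radial diffusion out of
    a cylinder (uniform initial concentration, zero surface concentration),
    returning the released fraction 1 - mean(c).  Independent oracle for
    the small-time expansion."""
    from scipy.linalg import solve_banded

    a = 1.0
    D = d_over_a2 * a**2
    r = np.linspace(0.0, a, nr + 1)
    dr = r[1] - r[0]
    c = np.ones(nr + 1)
    c[-1] = 0.0
    dt = min(0.05 / d_over_a2 / 4000, 0.5)
    lam = D * dt / (2 * dr**2)

    # banded matrices for (I - lam L) c_new = (I + lam L) c_old
    n = nr  # unknowns: i = 0..nr-1 (surface fixed at 0)
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    for i in range(n):
        if i == 0:
            # symmetry at r=0: dc/dr = 0, Laplacian ~ 4(c1 - c0)/dr^2
            diag[i] = 4.0
            upper[i] = -4.0
        else:
            ri = r[i]
            diag[i] = 2.0
            lower[i] = -(1.0 - dr / (2 * ri))
            upper[i] = -(1.0 + dr / (2 * ri))
    ab = np.zeros((3, n))
    ab[0, 1:] = lam * upper[:-1]
    ab[1, :] = 1.0 + lam * diag
    ab[2, :-1] = lam * lower[1:]

    def step(ci):
        rhs = np.empty(n)
        interior = ci[:n]
        rhs[0] = interior[0] + lam * (-diag[0] * interior[0] - upper[0] * ci[1])
        for i in range(1, n):
            rhs[i] = interior[i] + lam * (
                -lower[i] * ci[i - 1] - diag[i] * interior[i] - upper[i] * ci[i + 1]
            )
        new = solve_banded((1, 1), ab, rhs)
        out = ci.copy()
        out[:n] = new
        return out

    released = []
    t_now = 0.0
    for t_target in times:
        while t_now < t_target - 1e-9:
            c = step(c)
            t_now += dt
        # mass by trapezoid of c*r dr over the disc
        mass = np.trapezoid(c * r, r) / np.trapezoid(np.ones_like(r) * r, r)
        released.append(1.0 - mass)
    return np.array(released)


class TestForwardModels:
    def test_fickian_zero_at_zero(self):
        curve = ReferenceCurve(1 / 1440, Regime.FICKIAN)
        assert fickian_fraction(0.0, curve) == 0.0

    def test_fickian_leading_term_limit(self):
        curve = ReferenceCurve(1 / 1440, Regime.FICKIAN)
        t = 1e-4 * 1440  # x = 1e-4
        lead = 4 / np.sqrt(np.pi) * np.sqrt(1e-4)
        assert fickian_fraction(t, curve) / lead == pytest.approx(1.0, abs=0.01)

    def test_sixty_percent_crossing_near_140_min(self):
        curve = ReferenceCurve(1 / 1440, Regime.FICKIAN)
        assert time_to_fraction(curve, 0.6) == pytest.approx(140, abs=1)

    def test_fickian_matches_pde_oracle_below_60pct(self):
        curve = ReferenceCurve(1 / 1440, Regime.FICKIAN)
        times = np.array([5.0, 20.0, 50.0, 90.0, 130.0])
        oracle = radial_diffusion_release(times, 1 / 1440)
        model = fickian_fraction(times, curve)
        assert model == pytest.approx(oracle, rel=0.01)

    def test_case2_closed_form_points(self):
        curve = ReferenceCurve(1 / 1440, Regime.CASE2)
        assert case2_fraction(720.0, curve) == pytest.approx(0.75, abs=1e-12)
        assert case2_fraction(1440.0, curve) == pytest.approx(1.0, abs=1e-12)

    def test_case2_exhausted_front_warns_and_saturates(self):
        curve = ReferenceCurve(1 / 1440, Regime.CASE2)
        with pytest.warns(UserWarning):
            assert case2_fraction(2000.0, curve) == 1.0

    def test_generalized_case2_reduces_to_cylinder_form(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 100)
        curve = ReferenceCurve(1.0, Regime.CASE2)
        for xi in x:
            assert generalized_case2_fraction(xi, 1.0, Geometry.CYLINDER) == (
                pytest.approx(case2_fraction(xi, curve), abs=1e-12)
            )

    @given(doa2=st.floats(1e-4, 1e-2), regime=st.sampled_from(list(Regime)))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, doa2, regime):
        curve = ReferenceCurve(doa2, regime)
        t = np.linspace(0, 0.99 / doa2, 200)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = curve.fraction(t)
        assert np.all(f >= -1e-12) and np.all(f <= 1 + 1e-12)
        assert np.all(np.diff(f) >= -1e-12)

    def test_negative_time_rejected(self):
        curve = ReferenceCurve(1 / 1440, Regime.FICKIAN)
        with pytest.raises(ValueError):
            fickian_fraction(-1.0, curve)


class TestTruncate:
    def test_below_cutoff_unchanged(self):
        s = ReleaseSeries(time=np.arange(1.0, 6.0), fraction=np.linspace(0.1, 0.5, 5))
        assert len(truncate_to_fraction(s)) == 5

    def test_constructed_crossing_index(self):
        curve = ReferenceCurve(1 / 1440, Regime.CASE2)
        t = np.arange(1.0, 800.0)
        f = np.clip(curve.fraction(t), 0, 1)
        s = truncate_to_fraction(ReleaseSeries(time=t, fraction=f))
        crossing = np.nonzero(f > 0.6)[0][0]
        assert len(s) == crossing
        assert np.all(s.fraction <= 0.6)

    def test_fickian_prefix_ends_near_140(self):
        curve = ReferenceCurve(1 / 1440, Regime.FICKIAN)
        t = np.arange(1.0, 300.0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = np.clip(curve.fraction(t), 0, 1)
        s = truncate_to_fraction(ReleaseSeries(time=t, fraction=f))
        assert s.time[-1] == pytest.approx(139, abs=1)


class TestPowerLawFit:
    def test_fickian_reference_constants(self, ta_fickian_ref):
        # tabulated: k = 6.569e-2 +/- 0.087e-2, n = 0.4497 +/- 0.0030
        assert ta_fickian_ref.k == pytest.approx(6.569e-2, abs=0.087e-2)
        assert ta_fickian_ref.n == pytest.approx(0.4497, abs=0.0030)
        assert ta_fickian_ref.r_squared > 0.99

    def test_case2_reference_constants(self, ta_case2_ref):
        # tabulated: k = 2.34e-3 +/- 0.02e-3, n = 0.88703 +/- 0.00167
        assert ta_case2_ref.k == pytest.approx(2.34e-3, abs=0.02e-3)
        assert ta_case2_ref.n == pytest.approx(0.88703, abs=0.00167)
        assert ta_case2_ref.r_squared == pytest.approx(0.99938, abs=5e-4)

    def test_k_scaling_law_across_analytes(self, ta_fickian_ref):
        # halving D/a^2 by factor r rescales k by r^n exactly for a power law
        chdg_ref = reference_fit(
            ReferenceCurve(ANALYTE_D_OVER_A2["CHDG"], Regime.FICKIAN)
        )
        r = ANALYTE_D_OVER_A2["TA"] / ANALYTE_D_OVER_A2["CHDG"]
        assert ta_fickian_ref.k / chdg_ref.k == pytest.approx(
            r**ta_fickian_ref.n, rel=0.005
        )

    def test_exact_power_law_recovered(self):
        t = np.arange(1.0, 120.0)
        s = ReleaseSeries(time=t, fraction=np.clip(0.05 * t**0.6, 0, 1))
        fit = fit_power_law(s, window="full")
        assert fit.k == pytest.approx(0.05, abs=1e-8)
        assert fit.n == pytest.approx(0.6, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_full_window_lowers_exponent_for_fickian_curves(self):
        curve = ReferenceCurve(1 / 1440, Regime.FICKIAN)
        t = np.arange(1.0, 660.0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = np.clip(curve.fraction(t), 0, 1)
        s = ReleaseSeries(time=t, fraction=np.maximum.accumulate(f))
        assert fit_power_law(s, window="full").n < fit_power_law(s, window="first60").n

    def test_too_few_points_raises(self):
        s = ReleaseSeries(time=np.arange(1.0, 4.0), fraction=np.array([0.1, 0.2, 0.3]))
        with pytest.raises(ArithmeticError):
            fit_power_law(s)


class TestDecomposition:
    def test_pure_basis_members_recovered(self, ta_fickian_ref, ta_case2_ref):
        t = np.arange(1.0, 140.0)
        for truth, ref in ((1, 0), (0, 1)):
            f = truth * ta_fickian_ref.predict(t) + (1 - truth) * ta_case2_ref.predict(t)
            s = ReleaseSeries(time=t, fraction=np.clip(f, 0, 1))
            w = decompose_release(s, ta_fickian_ref, ta_case2_ref)
            assert w.w_fickian == pytest.approx(truth, abs=1e-6)
            assert w.w_case2 == pytest.approx(1 - truth, abs=1e-6)

    def test_mixture_recovery_under_noise(self, ta_fickian_ref, ta_case2_ref):
        # 30/70 mixture, 5% multiplicative noise, mean over 20 seeds
        truth = DecompositionWeights(0.3, 0.7)
        recovered = []
        for seed in range(20):
            cfg = GeneratorConfig(seed=seed, noise_rsd_release=0.05)
            series, _ = gen_release_series(
                truth, ANALYTE_D_OVER_A2["TA"], cfg,
                time=np.arange(5.0, 660.0, 5.0), analyte="TA",
            )
            w = decompose_release(series, ta_fickian_ref, ta_case2_ref)
            recovered.append(w.pct_case2)
        assert np.mean(recovered) == pytest.approx(70.0, abs=5.0)

    def test_constant_series_rejected(self, ta_fickian_ref, ta_case2_ref):
        s = ReleaseSeries(time=np.arange(1.0, 10.0), fraction=np.full(9, 0.3))
        with pytest.raises(ArithmeticError):
            decompose_release(s, ta_fickian_ref, ta_case2_ref)


class TestClassifyMechanism:
    @pytest.mark.parametrize(
        "n,geometry,expected",
        [
            (0.4497, Geometry.CYLINDER, Mechanism.FICKIAN),
            (0.595, Geometry.CYLINDER, Mechanism.ANOMALOUS),
            (0.673, Geometry.CYLINDER, Mechanism.ANOMALOUS),
            (0.88703, Geometry.CYLINDER, Mechanism.CASE2),
            (0.95, Geometry.CYLINDER, Mechanism.SUPER_CASE2),
            (0.50, Geometry.SLAB, Mechanism.FICKIAN),
            (0.75, Geometry.SLAB, Mechanism.ANOMALOUS),
            (1.0, Geometry.SLAB, Mechanism.CASE2),
        ],
    )
    def test_classes(self, n, geometry, expected):
        assert classify_mechanism(n, geometry) is expected

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            classify_mechanism(-0.1)
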