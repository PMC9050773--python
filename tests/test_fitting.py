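"""Fitting engine: branch sub-fits, profile/brute-force agreement, recovery."""

import numpy as np
import pytest

from heelfit import (
    FitError,
    FitOptions,
    StressStrainCurve,
    fit_bilinear,
    fit_combined,
    fit_heel_region,
    fit_linear_region,
    fit_piecewise,
    generate_curve,
    r_squared,
    strain_grid,
)
from heelfit.fitting import _fit_heel, _ols_line
from heelfit.models import PiecewiseParams
from heelfit.synthetic import NoiseSpec, TENDON_PIECEWISE


class TestRSquared:
    def test_perfect_fit(self):
        y = [1.0, 2.0, 5.0]
        assert r_squared(y, y) == 1.0

    def test_null_model(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, y.mean())) == 0.0

    def test_hand_example(self):
        # SS_res = 1, SS_tot = 2
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0], [1.0, 3.0])

    def test_variants_coincide_for_ols_line(self):
        """1 - SS_res/SS_tot equals SS_reg/SS_tot for an OLS line with intercept."""
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 40)
        y = 2.0 * x + 0.5 + rng.normal(0, 0.1, 40)
        slope, b = _ols_line(x, y)
        pred = slope * x + b
        assert r_squared(y, pred) == pytest.approx(
            r_squared(y, pred, kind="regression"), rel=1e-10
        )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [1.0, 2.0], kind="adjusted")


class TestLinearRegion:
    def test_exact_line_recovered(self):
        eps = np.linspace(0.03, 0.06, 40)
        curve = StressStrainCurve(eps, 377.2 * (eps - 0.022))
        E, eps_th = fit_linear_region(curve)
        assert E == pytest.approx(377.2, rel=1e-12)
        assert eps_th == pytest.approx(0.022, rel=1e-12)

    def test_two_points_interpolate(self):
        curve = StressStrainCurve([0.03, 0.05], [1.0, 2.0])
        E, eps_th = fit_linear_region(curve)
        assert E == pytest.approx(50.0)
        assert E * (0.03 - eps_th) == pytest.approx(1.0)

    def test_noisy_line_recovery(self):
        rng = np.random.default_rng(11)
        eps = np.linspace(0.03, 0.06, 1000)
        sig = 377.2 * (eps - 0.022) + rng.normal(0, 0.1, eps.size)
        E, eps_th = fit_linear_region(StressStrainCurve(eps, sig))
        assert E == pytest.approx(377.2, rel=0.01)

    def test_all_strains_equal_rejected(self):
        with pytest.raises(ValueError):
            _ols_line(np.array([0.03, 0.03]), np.array([1.0, 2.0]))


class TestHeelRegion:
    def test_exact_power_law_recovered(self):
        eps = np.linspace(0.001, 0.027, 60)
        curve = StressStrainCurve(eps, 22820.0 * eps**2.58)
        k1, n = fit_heel_region(curve)
        assert k1 == pytest.approx(22820.0, rel=1e-6)
        assert n == pytest.approx(1.58, rel=1e-6)

    def test_closed_form_k1_matches_refinement(self):
        """With n known, k1 has the closed form sum(sig*eps^(n+1))/sum(eps^(2(n+1)));
        on noiseless data the free refinement must land on the same optimum."""
        eps = np.linspace(0.002, 0.025, 40)
        sig = 22820.0 * eps**2.58
        k1_closed = np.sum(sig * eps**2.58) / np.sum(eps ** (2 * 2.58))
        k1, n = fit_heel_region(StressStrainCurve(eps, sig))
        assert k1 == pytest.approx(k1_closed, rel=1e-6)

    def test_too_few_positive_points_rejected(self):
        with pytest.raises(FitError):
            _fit_heel(np.array([0.0, 0.01]), np.array([0.0, -1.0]))


def _brute_force_piecewise(curve, mpb=3):
    """Independent oracle: exhaustive search over every admissible split."""
    eps, sig = curve.strain, curve.stress
    best = (np.inf, None)
    for i in range(mpb, len(curve) - mpb + 1):
        try:
            k1, n, ssr_h, _, _ = _fit_heel(eps[:i], sig[:i])
            E, eps_th = fit_linear_region(StressStrainCurve(eps[i:], sig[i:]))
        except (FitError, ValueError):
            continue
        ssr = ssr_h + float(np.sum((sig[i:] - E * (eps[i:] - eps_th)) ** 2))
        if ssr < best[0]:
            best = (ssr, i)
    return best


def _brute_force_bilinear(curve, mpb=3):
    eps, sig = curve.strain, curve.stress
    best = (np.inf, None)
    for i in range(mpb, len(curve) - mpb + 1):
        s1, b1 = _ols_line(eps[:i], sig[:i])
        s2, b2 = _ols_line(eps[i:], sig[i:])
        if s1 == s2:
            continue
        ssr = float(
            np.sum((sig[:i] - s1 * eps[:i] - b1) ** 2)
            + np.sum((sig[i:] - s2 * eps[i:] - b2) ** 2)
        )
        if ssr < best[0]:
            best = (ssr, i)
    return best


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
@pytest.mark.parametrize("n_points", [18, 30])
def test_profile_matches_brute_force_split_search(seed, n_points):
    """The profile stage must find the same split (and objective to 1e-12
    relative) as exhaustive enumeration of every admissible split."""
    grid = strain_grid(0.06, n_points)
    curve = generate_curve(
        "piecewise", TENDON_PIECEWISE, grid, NoiseSpec("gaussian_relative_to_max", 0.02, seed)
    )
    opts = FitOptions(eps_c_range=(grid[0], grid[-1]))
    res = fit_piecewise(curve, opts)
    ssr_bf, _ = _brute_force_piecewise(curve)
    assert res.profile_objective == pytest.approx(ssr_bf, rel=1e-12)

    res_b = fit_bilinear(curve, opts)
    ssr_bb, _ = _brute_force_bilinear(curve)
    assert res_b.profile_objective == pytest.approx(ssr_bb, rel=1e-12)


class TestFitPiecewise:
    def test_tendon_recovery(self, tendon_curve):
        res = fit_piecewise(tendon_curve)
        p = res.params
        for name, truth in [("k1", 22820.0), ("n", 1.58), ("eps_c", 0.028),
                            ("eps_th", 0.022), ("E", 377.2)]:
            assert getattr(p, name) == pytest.approx(truth, rel=5e-3), name
        assert res.r_squared > 0.99999
        assert res.converged

    def test_ligament_recovery(self, ligament_curve):
        p = fit_piecewise(ligament_curve).params
        assert p.E == pytest.approx(492.1, rel=5e-3)
        assert p.eps_c == pytest.approx(0.048, rel=5e-3)

    def test_refinement_never_worse_than_profile(self):
        grid = strain_grid(0.06, 80)
        curve = generate_curve(
            "piecewise", TENDON_PIECEWISE, grid,
            NoiseSpec("gaussian_relative_to_max", 0.02, 9),
        )
        res = fit_piecewise(curve)
        assert res.objective <= res.profile_objective * (1 + 1e-12)
        pred = curve.stress - res.residuals
        assert res.r_squared >= r_squared(curve.stress, pred) - 1e-12

    def test_stress_rescaling_invariance(self):
        """Scaling all stresses by c scales k1 and E by c and leaves the
        dimensionless parameters and R^2 unchanged."""
        grid = strain_grid(0.06, 120)
        curve = generate_curve(
            "piecewise", TENDON_PIECEWISE, grid,
            NoiseSpec("gaussian_relative_to_max", 0.01, 21),
        )
        c = 3.7
        r1 = fit_piecewise(curve)
        r2 = fit_piecewise(curve.scaled(c))
        assert r2.params.k1 == pytest.approx(c * r1.params.k1, rel=1e-6)
        assert r2.params.E == pytest.approx(c * r1.params.E, rel=1e-6)
        assert r2.params.n == pytest.approx(r1.params.n, rel=1e-6)
        assert r2.params.eps_c == pytest.approx(r1.params.eps_c, rel=1e-9)
        assert r2.params.eps_th == pytest.approx(r1.params.eps_th, rel=1e-6)
        assert r2.r_squared == pytest.approx(r1.r_squared, abs=1e-9)

    def test_enforced_continuity_closes_gap(self, tendon_curve):
        res = fit_piecewise(tendon_curve, FitOptions(enforce_continuity=True))
        assert abs(res.continuity_gap) < 1e-10
        assert res.params.E == pytest.approx(377.2, rel=0.02)

    def test_quick_noisy_sanity(self):
        """Modulus and threshold strain are robust to 1%-of-max noise."""
        grid = strain_grid(0.06, 200)
        for seed in (1, 2, 3):
            curve = generate_curve(
                "piecewise", TENDON_PIECEWISE, grid,
                NoiseSpec("gaussian_relative_to_max", 0.01, seed),
            )
            p = fit_piecewise(curve).params
            assert p.E == pytest.approx(377.2, rel=0.02)
            assert p.eps_th == pytest.approx(0.022, rel=0.05)

    def test_curve_too_short(self):
        curve = StressStrainCurve([0.01, 0.02, 0.03], [0.1, 0.3, 0.9])
        with pytest.raises(FitError):
            fit_piecewise(curve)


class TestFitCombined:
    def test_recovery_from_own_model(self, tendon_combined_curve):
        res = fit_combined(tendon_combined_curve)
        assert res.params.E == pytest.approx(194.8, rel=5e-3)
        assert res.params.k1 == pytest.approx(2330.0, rel=0.02)
        assert res.params.n == pytest.approx(1.02, rel=0.02)

    def test_understates_modulus_on_piecewise_data(self, tendon_curve):
        """On data with a genuinely linear upper region, the combined model's
        always-on power-law term absorbs part of the slope, so its fitted E
        is strictly below the true linear-region modulus."""
        res = fit_combined(tendon_curve)
        assert res.params.E < TENDON_PIECEWISE.E

    def test_degenerate_linear_data_drives_k1_to_zero(self):
        eps = np.linspace(0.001, 0.06, 120)
        sig = np.where(eps > 0.02, 500.0 * (eps - 0.02), 0.0)
        res = fit_combined(StressStrainCurve(eps, sig))
        assert res.params.E == pytest.approx(500.0, rel=0.01)
        assert res.params.k1 * 0.06 ** (res.params.n + 1) < 0.01 * sig.max()


class TestFitBilinear:
    def test_exact_two_lines(self):
        eps = np.linspace(0.005, 0.08, 60)
        ec, E = 0.049, 525.4
        sig = np.where(eps >= ec, E * (eps - ec) + 2.0, (2.0 / ec) * eps)
        res = fit_bilinear(StressStrainCurve(eps, sig))
        assert res.params.eps_c == pytest.approx(ec, rel=1e-9)
        assert res.params.E == pytest.approx(E, rel=1e-9)
        assert res.objective == pytest.approx(0.0, abs=1e-18)

    def test_single_line_rejected_as_parallel(self):
        eps = np.linspace(0.01, 0.06, 30)
        with pytest.raises(FitError, match="parallel"):
            fit_bilinear(StressStrainCurve(eps, 300.0 * eps + 1.0))

    def test_noisy_two_lines(self):
        rng = np.random.default_rng(5)
        eps = np.linspace(0.005, 0.08, 80)
        ec = 0.049
        sig = np.where(eps >= ec, 525.4 * (eps - ec) + 2.0, (2.0 / ec) * eps)
        sig = sig + rng.normal(0, 0.01 * sig.max(), sig.size)
        res = fit_bilinear(StressStrainCurve(eps, sig))
        assert res.params.eps_c == pytest.approx(ec, rel=0.10)


def test_report_schema(tendon_curve):
    report = fit_piecewise(tendon_curve).to_dict()
    assert report["model"] == "piecewise"
    assert set(report["params"]) == {"k1", "n", "eps_c", "eps_th", "E"}
    for key in ("r_squared", "continuity_gap_MPa", "objective", "converged", "options"):
        assert key in report
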