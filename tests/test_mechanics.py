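"""Series-spring, thin-shell and Hertz models; simulation and bracketing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shellmech import (
    CARBOXYSOME_SHELL,
    P22_SHELL,
    CantileverSpec,
    GeneratorConfig,
    ShellSpec,
    aggregate_particle_fits,
    baseline_correct,
    bracket_modulus,
    detect_contact_point,
    fit_hertz,
    fit_linear_stiffness,
    gen_composite_curve,
    gen_hertz_curve,
    hertz_force,
    simulate_hertz_curve,
    thin_shell_modulus,
    to_indentation,
)
from shellmech.curves import ForceCurve
from shellmech.mechanics import HertzFitError, StiffnessFitError, series_spring, series_total


def indentation_of(curve, noise_sd=1e-9):
    corrected = baseline_correct(curve)
    return to_indentation(corrected, detect_contact_point(corrected, noise_sd=noise_sd))


# ---------------------------------------------------------------------------
# Springs in series
# ---------------------------------------------------------------------------

class TestSeriesSpring:
    def test_slope_inversion_recovers_20(self, cantilever):
        z = np.linspace(0, 20, 100)
        F = 18.9189 * z  # series slope of a 20 pN/nm particle on a 350 pN/nm lever
        curve = ForceCurve(z, F, cantilever=cantilever)
        res = fit_linear_stiffness(curve, cantilever, force_window=(50, 150))
        assert res.k_total == pytest.approx(18.9189, rel=1e-6)
        assert res.k_particle == pytest.approx(20.0, rel=1e-4)
        assert res.r_squared == pytest.approx(1.0)

    def test_symmetric_springs(self):
        assert series_spring(175.0, 350.0) == pytest.approx(350.0)

    def test_stiffer_than_cantilever_rejected(self, cantilever):
        z = np.linspace(0, 1, 100)
        curve = ForceCurve(z, 400.0 * z, cantilever=cantilever)
        with pytest.raises(StiffnessFitError, match="stiffer than cantilever"):
            fit_linear_stiffness(curve, cantilever, force_window=(50, 150))

    def test_too_few_points_in_window(self, cantilever):
        z = np.linspace(0, 20, 100)
        curve = ForceCurve(z, 1.0 * z, cantilever=cantilever)  # max force 20 pN
        with pytest.raises(StiffnessFitError, match="too few points"):
            fit_linear_stiffness(curve, cantilever, force_window=(50, 150))

    @given(
        k_cant=st.floats(1.0, 1e4),
        ratio=st.floats(1e-3, 0.999),
    )
    def test_forward_backward_round_trip_machine_precision(self, k_cant, ratio):
        k_total = ratio * k_cant
        k_particle = series_spring(k_total, k_cant)
        assert series_total(k_particle, k_cant) == pytest.approx(k_total, rel=1e-12)

    def test_composite_generator_recovery_50_replicates(self):
        recovered = [
            fit_linear_stiffness(
                gen_composite_curve(GeneratorConfig(seed=s, noise_sd=2.0), k_CB=20.0)
            ).k_particle
            for s in range(50)
        ]
        assert np.mean(recovered) == pytest.approx(20.0, rel=0.05)

    def test_window_sensitivity_on_pure_hertz(self, quiet_cfg, cantilever):
        """Linear fit over 50-150 pN of a pure Hertz curve tracks the local
        analytic slope dF/dz at the window midpoint within 15%."""
        curve = gen_hertz_curve(quiet_cfg, E=0.59)
        res = fit_linear_stiffness(curve, cantilever, force_window=(50, 150))
        c = hertz_force(1.0, 0.59, 0.5, 20.0)
        d_mid = (100.0 / c) ** (2 / 3)
        dfdd = 1.5 * c * np.sqrt(d_mid)
        analytic = dfdd / (1.0 + dfdd / 350.0)  # chain rule through z = z0 + d + F/k
        assert res.k_total == pytest.approx(analytic, rel=0.15)


# ---------------------------------------------------------------------------
# Thin shell
# ---------------------------------------------------------------------------

class TestThinShell:
    def test_carboxysome_printed_means(self):
        # k = 20 pN/nm, R = 75 nm, h = 4.5 nm -> 74.07 MPa
        assert thin_shell_modulus(20.0, CARBOXYSOME_SHELL) == pytest.approx(74.07, abs=0.01)

    def test_p22_printed_means(self):
        assert thin_shell_modulus(192.38, P22_SHELL) == pytest.approx(102.6, abs=0.1)

    def test_doubling_thickness_quarters_modulus(self):
        thin = ShellSpec(R=75, h=4.5)
        thick = ShellSpec(R=75, h=9.0)
        assert thin_shell_modulus(20, thin) == pytest.approx(4 * thin_shell_modulus(20, thick))

    @given(
        k=st.floats(1.0, 500.0),
        R=st.floats(30.0, 200.0),
        h=st.floats(1.0, 9.0),
        c=st.floats(1.5, 3.0),
    )
    def test_scaling_linear_in_k_and_R_inverse_square_in_h(self, k, R, h, c):
        base = thin_shell_modulus(k, ShellSpec(R=R, h=h))
        assert thin_shell_modulus(c * k, ShellSpec(R=R, h=h)) == pytest.approx(c * base, rel=1e-9)
        assert thin_shell_modulus(k, ShellSpec(R=c * R, h=h)) == pytest.approx(c * base, rel=1e-9)
        assert thin_shell_modulus(k, ShellSpec(R=R, h=c * h)) == pytest.approx(base / c**2, rel=1e-9)


# ---------------------------------------------------------------------------
# Hertz
# ---------------------------------------------------------------------------

class TestHertz:
    def test_forward_evaluation_at_10nm(self):
        # (4/3) * (0.59/0.75) * sqrt(20) * 10^1.5 = 148.3 pN
        assert hertz_force(10.0, 0.59, 0.5, 20.0) == pytest.approx(148.3, abs=0.1)

    def test_noiseless_round_trip_to_1e6(self, quiet_cfg, cantilever):
        curve = gen_hertz_curve(quiet_cfg, E=0.59)
        res = fit_hertz(indentation_of(curve), cantilever)
        assert res.E_hertz == pytest.approx(0.59, rel=1e-6)

    @pytest.mark.parametrize("E_true", [0.5, 0.59, 1.0, 5.0, 50.0])
    def test_parameter_recovery_under_noise(self, E_true, cantilever):
        fits = []
        for seed in range(25):
            cfg = GeneratorConfig(seed=seed, noise_sd=2.0)
            curve = baseline_correct(gen_hertz_curve(cfg, E=E_true))
            ind = to_indentation(curve, detect_contact_point(curve, noise_sd=2.0))
            fits.append(fit_hertz(ind, cantilever).E_hertz)
        assert np.median(fits) == pytest.approx(E_true, rel=0.10)

    def test_zero_indentation_rejected(self, cantilever):
        from shellmech import IndentationCurve

        ind = IndentationCurve(np.zeros(20), np.zeros(20), z_0=0.0)
        with pytest.raises(HertzFitError, match="insufficient support"):
            fit_hertz(ind, cantilever)

    def test_refined_z0_reported_near_truth(self, cantilever):
        cfg = GeneratorConfig(seed=2, noise_sd=2.0, z_0=50.0)
        curve = baseline_correct(gen_hertz_curve(cfg))
        ind = to_indentation(curve, detect_contact_point(curve, noise_sd=2.0))
        res = fit_hertz(ind, cantilever)
        assert res.z_0_refined == pytest.approx(50.0, abs=1.0)


class TestSimulateHertz:
    def test_reduced_modulus_close_to_rigid_tip_for_soft_sample(self, cantilever):
        d = np.linspace(0, 10, 50)
        _, F = simulate_hertz_curve(0.5, 0.5, cantilever, d)
        F_rigid = hertz_force(d, 0.5, 0.5, cantilever.R_tip)
        assert np.max(np.abs(F - F_rigid) / np.maximum(F_rigid, 1e-12)) < 1e-4

    def test_linear_in_modulus_at_rigid_tip_limit(self):
        rigid = CantileverSpec(k_cantilever=350, R_tip=20, E_tip=1e12)
        d = np.linspace(0.1, 10, 30)
        _, F1 = simulate_hertz_curve(1.0, 0.5, rigid, d)
        _, F2 = simulate_hertz_curve(2.0, 0.5, rigid, d)
        np.testing.assert_allclose(F2, 2 * F1, rtol=1e-9)

    def test_zero_indentation_gives_zero_force(self, cantilever):
        _, F = simulate_hertz_curve(5.0, 0.5, cantilever, np.array([0.0]))
        assert F[0] == 0.0

    def test_negative_indentation_rejected(self, cantilever):
        with pytest.raises(ValueError):
            simulate_hertz_curve(5.0, 0.5, cantilever, np.array([-1.0]))

    @given(
        E_pair=st.tuples(st.floats(0.1, 400.0), st.floats(0.1, 400.0)).filter(
            lambda p: abs(p[0] - p[1]) > 1e-3
        ),
        d=st.floats(0.5, 30.0),
    )
    def test_force_strictly_increasing_in_E_and_d(self, E_pair, d):
        cant = CantileverSpec(k_cantilever=350, R_tip=20)
        lo, hi = sorted(E_pair)
        _, f_lo = simulate_hertz_curve(lo, 0.5, cant, np.array([d]))
        _, f_hi = simulate_hertz_curve(hi, 0.5, cant, np.array([d, d * 1.5]))
        assert f_lo[0] < f_hi[0] < f_hi[1]


# ---------------------------------------------------------------------------
# Bracketing
# ---------------------------------------------------------------------------

class TestBracket:
    GRID = [0.5, 1.0, 5.0, 50.0, 500.0]

    def test_soft_shell_brackets_between_half_and_one(self, quiet_cfg, cantilever):
        curve = gen_hertz_curve(quiet_cfg, E=0.59)
        res = bracket_modulus(indentation_of(curve), cantilever, 0.5, self.GRID)
        assert (res.E_low, res.E_high) == (0.5, 1.0)
        assert not res.is_open

    def test_exact_grid_hit_ties_to_next_higher(self, quiet_cfg, cantilever):
        curve = gen_hertz_curve(quiet_cfg, E=5.0)
        res = bracket_modulus(indentation_of(curve), cantilever, 0.5, self.GRID)
        assert (res.E_low, res.E_high) == (5.0, 50.0)

    def test_out_of_grid_flags_open_bracket(self, quiet_cfg, cantilever):
        curve = gen_hertz_curve(quiet_cfg, E=1000.0)
        res = bracket_modulus(indentation_of(curve), cantilever, 0.5, self.GRID)
        assert res.open_high and res.E_high is None

    def test_fit_consistent_with_bracket(self, cantilever):
        cfg = GeneratorConfig(seed=4, noise_sd=2.0)
        curve = baseline_correct(gen_hertz_curve(cfg, E=0.59))
        ind = to_indentation(curve, detect_contact_point(curve, noise_sd=2.0))
        res = bracket_modulus(ind, cantilever, 0.5, self.GRID)
        fitted = fit_hertz(ind, cantilever).E_hertz
        assert res.E_low <= fitted <= res.E_high


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

class TestAggregate:
    def test_hand_arithmetic(self):
        out = aggregate_particle_fits([{"E": 74.0}, {"E": 78.0}, {"E": 82.0}])
        row = out.loc["E"]
        assert row["mean"] == pytest.approx(78.0)
        assert row["sd"] == pytest.approx(4.0)
        assert row["n"] == 3

    def test_single_value_flagged(self):
        out = aggregate_particle_fits([{"k": 20.0}])
        assert out.loc["k", "sd"] == 0.0
        assert bool(out.loc["k", "single_observation"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_particle_fits([])

    def test_normal_population_mean_within_clt_bound(self, rng):
        vals = rng.normal(20.0, 9.0, size=25)
        out = aggregate_particle_fits([{"k": v} for v in vals])
        assert abs(out.loc["k", "mean"] - 20.0) < 3 * 9.0 / np.sqrt(25)
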