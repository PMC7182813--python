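"""Acid-base surface-energy decomposition: solver, round trips, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adhesurf import (
    FORMAMIDE,
    METHYLENE_IODIDE,
    WATER,
    ContactAngleMeasurement,
    HydrophobicityClass,
    SurfaceEnergyComponents,
    TestLiquid,
    acid_base_component,
    apolar_lw_diagnostic,
    classify_hydrophobicity,
    forward_contact_angle,
    propagate_uncertainty,
    solve_components,
    total_energy,
)
from adhesurf.energetics import ConditioningError, residuals

LIQUIDS = [WATER, FORMAMIDE, METHYLENE_IODIDE]


class TestSolveComponents:
    def test_pet_row_reproduced(self, pet_components):
        """The printed PET decomposition follows from its printed angles."""
        c = pet_components
        assert round(c.gamma_lw, 1) == 47.6
        assert round(c.gamma_plus, 1) == 0.2
        assert round(c.gamma_minus, 1) == 8.1
        assert round(c.gamma_ab, 1) == 2.8
        # the printed total is the sum of the rounded components
        assert round(c.gamma_lw, 1) + round(c.gamma_ab, 1) == 50.4
        assert c.negative_root_flags == (False, True, False)

    def test_complete_wetting_by_apolar_liquid(self):
        """theta_M = 0 forces gamma_LW equal to the liquid's own 50.8."""
        angles = [
            ContactAngleMeasurement(WATER, 30.0),
            ContactAngleMeasurement(FORMAMIDE, 20.0),
            ContactAngleMeasurement(METHYLENE_IODIDE, 0.0),
        ]
        comp = solve_components(angles)
        assert comp.gamma_lw == pytest.approx(50.8, abs=1e-9)

    def test_forward_then_solve_recovers_components(self):
        truth = SurfaceEnergyComponents("synthetic", 40.0, 1.0, 30.0)
        angles = [
            ContactAngleMeasurement(liq, forward_contact_angle(truth, liq))
            for liq in LIQUIDS
        ]
        rec = solve_components(angles)
        assert rec.gamma_lw == pytest.approx(40.0, rel=1e-6)
        assert rec.gamma_plus == pytest.approx(1.0, rel=1e-6)
        assert rec.gamma_minus == pytest.approx(30.0, rel=1e-6)
        assert np.all(np.abs(residuals(rec, angles)) < 1e-9)

    def test_residual_contract_on_pet(self, pet_components, pet_angles):
        assert np.all(np.abs(residuals(pet_components, pet_angles)) < 1e-9)

    def test_requires_two_polar_liquids(self):
        apolar2 = TestLiquid("alkane", 25.0, 25.0, 0.0, 0.0)
        angles = [
            ContactAngleMeasurement(METHYLENE_IODIDE, 40.0),
            ContactAngleMeasurement(apolar2, 10.0),
            ContactAngleMeasurement(WATER, 80.0),
        ]
        with pytest.raises(ValueError, match="polar"):
            solve_components(angles)

    def test_degenerate_triplet_rejected(self):
        near_water = TestLiquid("water2", 72.8, 21.8, 25.5, 25.5)
        angles = [
            ContactAngleMeasurement(WATER, 70.0),
            ContactAngleMeasurement(near_water, 70.0),
            ContactAngleMeasurement(FORMAMIDE, 50.0),
        ]
        with pytest.raises(ConditioningError, match="condition number"):
            solve_components(angles)

    def test_angle_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ContactAngleMeasurement(WATER, 190.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        glw=st.floats(20, 60),
        gp=st.floats(0, 5),
        gm=st.floats(0, 40),
    )
    def test_round_trip_property(self, glw, gp, gm):
        """Forward-model angles from all-positive components, solve, recover."""
        truth = SurfaceEnergyComponents("rt", glw, gp, gm)
        try:
            angles = [
                ContactAngleMeasurement(liq, forward_contact_angle(truth, liq))
                for liq in LIQUIDS
            ]
        except ValueError:
            return  # forward angle undefined for this corner of the box
        rec = solve_components(angles)
        for got, want in (
            (rec.gamma_lw, glw),
            (rec.gamma_plus, gp),
            (rec.gamma_minus, gm),
        ):
            assert got == pytest.approx(want, rel=1e-6, abs=1e-6)

    def test_apolar_decoupling(self, pet_angles):
        """gamma_LW depends only on the apolar-liquid angle."""
        base = solve_components(pet_angles).gamma_lw
        perturbed = [
            ContactAngleMeasurement(WATER, 60.0),
            ContactAngleMeasurement(FORMAMIDE, 40.0),
            pet_angles[2],
        ]
        assert solve_components(perturbed).gamma_lw == pytest.approx(base, rel=1e-12)

    def test_overdetermined_least_squares(self, pet_angles):
        """A consistent fourth liquid leaves the solution unchanged."""
        comp3 = solve_components(pet_angles)
        glycerol = TestLiquid("glycerol", 64.0, 34.0, 3.92, 57.4)
        theta_g = forward_contact_angle(comp3, glycerol)
        comp4 = solve_components(pet_angles + [ContactAngleMeasurement(glycerol, theta_g)])
        assert comp4.gamma_lw == pytest.approx(comp3.gamma_lw, rel=1e-9)
        assert comp4.gamma_plus == pytest.approx(comp3.gamma_plus, rel=1e-6)


class TestForwardContactAngle:
    def test_pet_water_round_trip(self, pet_components):
        assert forward_contact_angle(pet_components, WATER) == pytest.approx(77.8, abs=0.1)

    def test_apolar_surface_wets_its_twin(self):
        comp = SurfaceEnergyComponents("apolar", 50.8, 0.0, 0.0)
        assert forward_contact_angle(comp, METHYLENE_IODIDE) == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_hand_evaluation(self):
        comp = SurfaceEnergyComponents("synthetic", 40.0, 1.0, 30.0)
        x, y, z = math.sqrt(40.0), math.sqrt(1.0), math.sqrt(30.0)
        cos = -1 + 2 * (
            x * math.sqrt(FORMAMIDE.gamma_lw)
            + y * math.sqrt(FORMAMIDE.gamma_minus)
            + z * math.sqrt(FORMAMIDE.gamma_plus)
        ) / FORMAMIDE.gamma_total
        expected = math.degrees(math.acos(cos))
        assert forward_contact_angle(comp, FORMAMIDE) == pytest.approx(expected, abs=1e-12)

    def test_domain_error_reports_value(self):
        high = SurfaceEnergyComponents("super", 200.0, 50.0, 50.0)
        with pytest.raises(ValueError, match="cos"):
            forward_contact_angle(high, METHYLENE_IODIDE)


class TestScalarHelpers:
    @pytest.mark.parametrize(
        "gp, gm, expected",
        [
            (0.2446, 8.095, 2.81),  # unrounded PET solve, rounds to printed 2.8
            (0.0, 123.0, 0.0),
            (25.5, 25.5, 51.0),  # water's own AB component
        ],
    )
    def test_acid_base_component(self, gp, gm, expected):
        assert acid_base_component(gp, gm) == pytest.approx(expected, abs=5e-3)

    def test_acid_base_rejects_negative(self):
        with pytest.raises(ValueError):
            acid_base_component(-1.0, 2.0)

    @pytest.mark.parametrize(
        "lw, ab, expected", [(45.2, 44.6, 89.8), (47.6, 2.8, 50.4), (0.0, 0.0, 0.0)]
    )
    def test_total_energy(self, lw, ab, expected):
        assert total_energy(lw, ab) == pytest.approx(expected)


class TestClassification:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            (16.6, HydrophobicityClass.HYDROPHILIC),  # glass
            (35.0, HydrophobicityClass.INTERMEDIATELY_HYDROPHOBIC),
            (77.8, HydrophobicityClass.HYDROPHOBIC),  # PET
            (90.5, HydrophobicityClass.HYDROPHOBIC),  # polystyrene
            (97.3, HydrophobicityClass.HYDROPHOBIC),  # Teflon
            (0.0, HydrophobicityClass.HYDROPHILIC),
            (20.0, HydrophobicityClass.INTERMEDIATELY_HYDROPHOBIC),  # boundary up
            (50.0, HydrophobicityClass.HYDROPHOBIC),  # boundary up
            (180.0, HydrophobicityClass.HYDROPHOBIC),
        ],
    )
    def test_bands(self, theta, expected):
        assert classify_hydrophobicity(theta) is expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_hydrophobicity(-1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(theta=st.floats(0, 180))
    def test_total_function_with_two_breakpoints(self, theta):
        cls = classify_hydrophobicity(theta)
        if theta < 20:
            assert cls is HydrophobicityClass.HYDROPHILIC
        elif theta < 50:
            assert cls is HydrophobicityClass.INTERMEDIATELY_HYDROPHOBIC
        else:
            assert cls is HydrophobicityClass.HYDROPHOBIC


class TestColumnIntegrityDiagnostic:
    def test_glass_lw_follows_from_formamide_column(self):
        """The printed glass gamma_LW (35.6) is implied by the 47.6-deg angle
        treated as the apolar measurement, not by the 51.8-deg one — the
        formamide / methylene iodide columns of that row read as transposed."""
        swapped = apolar_lw_diagnostic([ContactAngleMeasurement(METHYLENE_IODIDE, 47.6)])
        printed = apolar_lw_diagnostic([ContactAngleMeasurement(METHYLENE_IODIDE, 51.8)])
        assert round(swapped["methylene iodide"], 1) == 35.6
        assert round(printed["methylene iodide"], 1) != 35.6

    @pytest.mark.parametrize("order", ["printed", "swapped"])
    def test_glass_polar_components_not_recoverable(self, order):
        """Neither column assignment reproduces the printed glass g+/g-."""
        f, m = (47.6, 51.8) if order == "printed" else (51.8, 47.6)
        comp = solve_components(
            [
                ContactAngleMeasurement(WATER, 16.6),
                ContactAngleMeasurement(FORMAMIDE, f),
                ContactAngleMeasurement(METHYLENE_IODIDE, m),
            ]
        )
        assert (round(comp.gamma_plus, 1), round(comp.gamma_minus, 1)) != (17.4, 19.6)


class TestPropagateUncertainty:
    def test_zero_sd_degenerates_to_point_solve(self, pet_components):
        angles = [
            ContactAngleMeasurement(WATER, 77.8, 0.0),
            ContactAngleMeasurement(FORMAMIDE, 58.2, 0.0),
            ContactAngleMeasurement(METHYLENE_IODIDE, 20.5, 0.0),
        ]
        u = propagate_uncertainty(angles, n_draws=200, seed=0)
        assert u.sd["gamma_lw"] == 0.0
        assert u.mean["gamma_lw"] == pytest.approx(pet_components.gamma_lw)
        assert u.failure_fraction == 0.0

    def test_means_match_bias_corrected_point_solve(self, pet_angles, pet_components):
        """MC means of squared roots carry the Jensen bias E[r^2]=r0^2+Var(r);
        the delta-method prediction of that bias is the independent oracle."""
        liqs = [a.liquid for a in pet_angles]
        A = np.array(
            [
                [math.sqrt(l.gamma_lw), math.sqrt(l.gamma_minus), math.sqrt(l.gamma_plus)]
                for l in liqs
            ]
        )
        M = np.linalg.inv(A)
        th = np.radians([a.theta_mean for a in pet_angles])
        sd = np.radians([a.theta_sd for a in pet_angles])
        db = -np.sin(th) * np.array([l.gamma_total for l in liqs]) / 2 * sd
        var_roots = np.diag(M @ np.diag(db**2) @ M.T)
        point = np.array(
            [pet_components.gamma_lw, pet_components.gamma_plus, pet_components.gamma_minus]
        )
        predicted = point + var_roots

        u = propagate_uncertainty(pet_angles, n_draws=10_000, seed=0)
        for key, pred in zip(("gamma_lw", "gamma_plus", "gamma_minus"), predicted):
            se = u.sd[key] / math.sqrt(u.n_draws)
            assert abs(u.mean[key] - pred) <= max(3 * se, 5e-3 * pred)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_doubling_noise_increases_all_sds(self, pet_angles, seed):
        u1 = propagate_uncertainty(pet_angles, n_draws=2000, seed=seed)
        doubled = [
            ContactAngleMeasurement(a.liquid, a.theta_mean, 2 * a.theta_sd)
            for a in pet_angles
        ]
        u2 = propagate_uncertainty(doubled, n_draws=2000, seed=seed)
        assert all(u2.sd[k] > u1.sd[k] for k in u1.sd)

    def test_reproducible_under_seed(self, pet_angles):
        u1 = propagate_uncertainty(pet_angles, n_draws=500, seed=42)
        u2 = propagate_uncertainty(pet_angles, n_draws=500, seed=42)
        assert u1.mean == u2.mean and u1.sd == u2.sd

    def test_negative_root_fraction_tracked(self, pet_angles):
        u = propagate_uncertainty(pet_angles, n_draws=1000, seed=0)
        # PET's sqrt(gamma+) root is negative at the point solve and stays so
        # for most draws at the printed angle noise
        assert u.negative_root_fraction["gamma_plus"] > 0.5
        assert u.negative_root_fraction["gamma_lw"] == 0.0
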