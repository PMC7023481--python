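import numpy as np
import pytest

from pbbm.physchem import AcidSolubilityProfile
from pbbm.gis import (
    GISParameters,
    SubjectPhysiology,
    dissolution_rate,
    gastric_fraction_remaining,
    ph_at,
    simulate_gis,
)

from _oracles import rk4_gis

DOSE = 8e5  # 800 mg in ug


class TestPhInterpolation:
    def test_knot_query_returns_knot_value(self):
        series = [[0.0, 5.0], [1.0, 6.0], [2.0, 7.0]]
        assert ph_at(series, 1.0) == 6.0

    def test_midpoint_is_linear(self):
        assert ph_at([[1.0, 5.0], [2.0, 7.0]], 1.5) == pytest.approx(6.0)

    def test_constant_extrapolation(self):
        series = [[0.0, 5.5], [3.0, 6.5]]
        assert ph_at(series, 10.0) == 6.5
        assert ph_at(series, -1.0) == 5.5

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ph_at(np.empty((0, 2)), 1.0)


class TestDissolutionRate:
    def test_no_solid_no_dissolution(self, ibu_solubility):
        assert dissolution_rate(0.0, 10.0, 6.0, 1.5e-3, ibu_solubility) == 0.0

    def test_saturated_lumen_stalls(self, ibu_solubility):
        cs = ibu_solubility.solubility(6.0)
        assert dissolution_rate(1e5, cs, 6.0, 1.5e-3, ibu_solubility) == 0.0

    def test_supersaturation_clamped_to_zero(self, ibu_solubility):
        cs = ibu_solubility.solubility(6.0)
        assert dissolution_rate(1e5, 2 * cs, 6.0, 1.5e-3, ibu_solubility) == 0.0

    def test_bilinear_arithmetic(self):
        # K_Diss [mL/(ug h)] * M [ug] * gap [ug/mL] -> ug/h
        prof = AcidSolubilityProfile(s0_ug_per_ml=100.0, pka=4.54, cap=1.0)
        rate = dissolution_rate(1e5, 0.0, 6.0, 0.0015, prof)
        assert rate == pytest.approx(0.0015 * 1e5 * 100.0)

    def test_negative_inputs_rejected(self, ibu_solubility):
        with pytest.raises(ValueError):
            dissolution_rate(-1.0, 0.0, 6.0, 1e-3, ibu_solubility)


class TestSimulateGis:
    def test_mass_balance_closure(self, median_params, flat_ph_physiology,
                                  ibu_solubility, dense_grid):
        traj = simulate_gis(median_params, flat_ph_physiology, DOSE, dense_grid,
                            "gisplus", ibu_solubility)
        assert traj.mass_balance_error() <= 1e-6

    def test_phase3_bolus_empties_stomach(self, median_params, flat_ph_physiology,
                                          ibu_solubility):
        """Gastric solid follows the first-order closed form up to TMMC and
        is transferred to the duodenum in one bolus at TMMC."""
        phys = flat_ph_physiology
        kempt = 0.5
        params = GISParameters(kempt, 0.47, 0.081, k_diss_ml_per_ug_h=1.52e-3)
        eps = 1e-9
        grid = np.array([0.0, 1.0, phys.tmmc_h - eps, phys.tmmc_h, 3.0])
        traj = simulate_gis(params, phys, DOSE, grid, "gisplus", ibu_solubility)
        ms = traj.amounts_ug["m_stomach_solid"]
        assert ms[2] == pytest.approx(DOSE * np.exp(-kempt * phys.tmmc_h), rel=1e-6)
        assert ms[3] == 0.0
        assert ms[4] == 0.0

    def test_zero_dissolution_keeps_plasma_empty(self, flat_ph_physiology,
                                                 ibu_solubility, dense_grid):
        params = GISParameters(0.18, 0.47, 0.081, k_diss_ml_per_ug_h=0.0)
        traj = simulate_gis(params, flat_ph_physiology, DOSE, dense_grid,
                            "gisplus", ibu_solubility)
        assert np.all(traj.c_plasma == 0.0)
        solids = (traj.amounts_ug["m_stomach_solid"] + traj.amounts_ug["m_duodenum_solid"]
                  + traj.amounts_ug["m_jejunum_solid"] + traj.cumulative_distal_transit_ug)
        assert solids[-1] == pytest.approx(DOSE, rel=1e-6)

    def test_sink_limit_matches_basic_model(self, dense_grid):
        """Far from saturation the pH-driven law collapses to first-order
        dissolution with rate K_Diss * Cs, i.e. the basic model (phase-III
        event pushed past the grid so only the dissolution laws differ)."""
        phys = SubjectPhysiology(
            tmmc_h=100.0, ph_duodenum=[[0.0, 6.0]], ph_jejunum=[[0.0, 6.6]],
            v1_ml=123.24, v2_ml=49.99, kel_per_h=0.5, v3_ml=8100.0)
        cs = 1e6
        prof = AcidSolubilityProfile(s0_ug_per_ml=cs, pka=4.54, cap=1.0)
        k_diss = 1.5e-6
        plus = simulate_gis(
            GISParameters(0.18, 0.47, 0.081, k_diss_ml_per_ug_h=k_diss),
            phys, DOSE, dense_grid, "gisplus", prof)
        basic = simulate_gis(
            GISParameters(0.18, 0.47, 0.081, kd_simple_per_h=k_diss * cs,
                          ka_per_h=12.0),
            phys, DOSE, dense_grid, "gis")
        np.testing.assert_allclose(plus.c_plasma, basic.c_plasma, rtol=1e-4,
                                   atol=1e-6)

    def test_invalid_inputs_rejected(self, median_params, flat_ph_physiology,
                                     ibu_solubility):
        with pytest.raises(ValueError):
            simulate_gis(median_params, flat_ph_physiology, -1.0,
                         np.array([0.0, 1.0]), "gisplus", ibu_solubility)
        with pytest.raises(ValueError):
            simulate_gis(median_params, flat_ph_physiology, DOSE,
                         np.array([1.0, 2.0]), "gisplus", ibu_solubility)
        with pytest.raises(ValueError):
            GISParameters(-0.1, 0.4, 0.08, k_diss_ml_per_ug_h=1e-3)


class TestGastricFraction:
    def test_starts_at_one_and_zero_after_tmmc(self, median_params,
                                               flat_ph_physiology):
        grid = np.array([0.0, 1.0, 2.04, 3.0])
        frac = gastric_fraction_remaining(median_params, flat_ph_physiology,
                                          grid, "gisplus")
        assert frac[0] == 1.0
        assert frac[2] == 0.0 and frac[3] == 0.0

    def test_basic_model_halves_at_ln2(self, flat_ph_physiology):
        params = GISParameters(1.0, 0.47, 0.081, kd_simple_per_h=1.0)
        frac = gastric_fraction_remaining(params, flat_ph_physiology,
                                          np.array([0.0, np.log(2.0)]), "gis")
        assert frac[1] == pytest.approx(0.5, rel=1e-12)

    def test_non_increasing(self, median_params, flat_ph_physiology, dense_grid):
        frac = gastric_fraction_remaining(median_params, flat_ph_physiology,
                                          dense_grid, "gisplus")
        assert np.all(np.diff(frac) <= 0)


class TestProperties:
    def test_states_non_negative_on_random_draws(self, ibu_solubility):
        """No state goes negative across 200 random parameter draws."""
        rng = np.random.default_rng(42)
        grid = np.linspace(0.0, 8.0, 33)
        for _ in range(200):
            params = GISParameters(
                kempt_per_h=10 ** rng.uniform(-2, 0.6),
                k_td_per_h=10 ** rng.uniform(-1.5, 1.0),
                k_tj_per_h=10 ** rng.uniform(-3, 0.5),
                k_diss_ml_per_ug_h=10 ** rng.uniform(-4, -1),
            )
            phys = SubjectPhysiology(
                tmmc_h=rng.uniform(0.2, 6.0),
                ph_duodenum=[[0.0, rng.uniform(4.5, 7.0)]],
                ph_jejunum=[[0.0, rng.uniform(4.5, 7.5)]],
                v1_ml=rng.uniform(20, 400),
                v2_ml=rng.uniform(5, 300),
                kel_per_h=rng.uniform(0.2, 1.0),
                v3_ml=rng.uniform(3000, 12000),
            )
            traj = simulate_gis(params, phys, DOSE, grid, "gisplus",
                                ibu_solubility, rtol=1e-6, atol=1e-8)
            for arr in traj.amounts_ug.values():
                assert np.all(arr >= 0.0)
            assert traj.mass_balance_error() <= 1e-6

    def test_absorption_monotone_in_dissolution_coefficient(
            self, flat_ph_physiology, ibu_solubility, dense_grid):
        """Halving K_Diss never increases cumulative absorbed mass."""
        absorbed = []
        for k_diss in (1.52e-3, 7.6e-4, 3.8e-4):
            params = GISParameters(0.18, 0.47, 0.081, k_diss_ml_per_ug_h=k_diss)
            traj = simulate_gis(params, flat_ph_physiology, DOSE, dense_grid,
                                "gisplus", ibu_solubility)
            absorbed.append(traj.amounts_ug["m_plasma"]
                            + traj.cumulative_eliminated_ug)
        tol = DOSE * 1e-9
        assert np.all(absorbed[0] >= absorbed[1] - tol)
        assert np.all(absorbed[1] >= absorbed[2] - tol)

    def test_earlier_phase3_raises_cmax(self, ibu_solubility, dense_grid):
        """An earlier house-keeper wave empties the stomach sooner and can
        only raise the plasma peak."""
        cmax = []
        for tmmc in (0.5, 1.0, 2.0, 3.0):
            phys = SubjectPhysiology(
                tmmc_h=tmmc, ph_duodenum=[[0.0, 6.0]], ph_jejunum=[[0.0, 6.6]],
                v1_ml=123.24, v2_ml=49.99, kel_per_h=0.5, v3_ml=8100.0)
            params = GISParameters(0.18, 0.47, 0.081, k_diss_ml_per_ug_h=1.52e-3)
            traj = simulate_gis(params, phys, DOSE, dense_grid, "gisplus",
                                ibu_solubility)
            cmax.append(traj.c_plasma.max())
        assert np.all(np.diff(cmax) <= 0)

    def test_matches_fixed_step_rk4_oracle(self, ibu_solubility):
        """Adaptive integration agrees with an independent RK4 at dt=1e-3 h
        to 0.1% on a reference parameter set with fluctuating pH."""
        phys = SubjectPhysiology(
            tmmc_h=2.0,
            ph_duodenum=[[0.0, 6.5], [1.0, 5.0], [2.0, 6.8], [4.0, 5.5], [8.0, 6.2]],
            ph_jejunum=[[0.0, 6.8], [1.5, 5.2], [3.0, 7.0], [8.0, 6.5]],
            v1_ml=123.24, v2_ml=49.99, kel_per_h=0.5, v3_ml=8100.0)
        params = GISParameters(0.3, 0.47, 0.081, k_diss_ml_per_ug_h=1.52e-3)
        dt = 1e-3
        t_oracle, y_oracle = rk4_gis(params, phys, DOSE, 8.0, dt, "gisplus",
                                     ibu_solubility)
        grid = np.round(np.arange(0.5, 8.01, 0.5), 10)
        grid = np.concatenate([[0.0], grid])
        traj = simulate_gis(params, phys, DOSE, grid, "gisplus", ibu_solubility)
        idx = np.searchsorted(np.round(t_oracle, 9), np.round(grid, 9))
        for i, name in enumerate(traj.amounts_ug):
            ours = traj.amounts_ug[name]
            ref = y_oracle[idx, i]
            scale = np.maximum(np.abs(ref), DOSE * 1e-4)
            assert np.max(np.abs(ours - ref) / scale) < 1e-3, name
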