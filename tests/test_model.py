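"""Unit and property tests of the mechanistic rate laws and the RHS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from pd1sim import (ModelParameters, ModelState, PKParameters,
                    peptide_mhc_loading, synapse_occupancy, killing_rate,
                    priming_rates, tumor_diameter)
from pd1sim.model import ModelError, TumorImmuneModel, tumor_volume_mm3


# ---------------------------------------------------------------------------
# peptide-MHC competition
# ---------------------------------------------------------------------------

class TestPeptideMhcLoading:
    def test_single_species_half_saturation(self):
        out = peptide_mhc_loading([30.0], [30.0], 1000.0)
        assert out == pytest.approx([500.0])

    def test_no_peptide_no_presentation(self):
        assert peptide_mhc_loading([0.0, 0.0], [1.0, 2.0], 1000.0) == (
            pytest.approx([0.0, 0.0]))

    def test_two_species_competition_closed_form(self):
        # P/Kd = [2, 2]: each gets 1000*2/(1+4) = 400
        out = peptide_mhc_loading([2.0, 2.0], [1.0, 1.0], 1000.0)
        assert out == pytest.approx([400.0, 400.0])

    def test_errors(self):
        with pytest.raises(ModelError):
            peptide_mhc_loading([1.0], [1.0, 2.0], 100.0)
        with pytest.raises(ModelError):
            peptide_mhc_loading([-1.0], [1.0], 100.0)
        with pytest.raises(ModelError):
            peptide_mhc_loading([1.0], [0.0], 100.0)

    @given(st.lists(st.floats(0.0, 1e4), min_size=1, max_size=6),
           st.data())
    @settings(max_examples=100, deadline=None)
    def test_total_presented_below_capacity(self, pools, data):
        kds = data.draw(st.lists(st.floats(0.1, 1e4),
                                 min_size=len(pools), max_size=len(pools)))
        m = peptide_mhc_loading(pools, kds, 2000.0)
        assert np.all(m >= 0.0)
        assert m.sum() < 2000.0

    def test_monotone_in_own_and_competing_pool(self):
        base = peptide_mhc_loading([5.0, 5.0], [10.0, 10.0], 1000.0)
        more_self = peptide_mhc_loading([5.0, 9.0], [10.0, 10.0], 1000.0)
        more_own = peptide_mhc_loading([9.0, 5.0], [10.0, 10.0], 1000.0)
        assert more_own[0] > base[0]           # increasing in own pool
        assert more_self[0] < base[0]          # decreasing in competitor


# ---------------------------------------------------------------------------
# synapse occupancy
# ---------------------------------------------------------------------------

def _fixed_point_engaged(R, L1, L2, Kd1, Kd2, tol=1e-15):
    """Brute-force damped fixed-point solution of the two-ligand equilibrium.

    Iterates rf <- (1-lam)*rf + lam*(R - x(rf) - y(rf)) with
    lam = 1/(1 + L1/Kd1 + L2/Kd2), which makes the map a monotone
    contraction on [0, R]; engaged density is R - rf at the fixed point.
    """
    if R <= 0:
        return 0.0
    lam = 1.0 / (1.0 + L1 / Kd1 + L2 / Kd2)
    rf = R
    for _ in range(2_000_000):
        bound = rf * L1 / (Kd1 + rf) + rf * L2 / (Kd2 + rf)
        rf_new = (1 - lam) * rf + lam * (R - bound)
        if abs(rf_new - rf) < tol * R:
            rf = rf_new
            break
        rf = rf_new
    return R - rf


class TestSynapseOccupancy:
    def test_blockade_limit(self, params):
        occ = synapse_occupancy(1e9, params)
        assert occ.inhibition < 1e-6
        assert occ.frac_pd1_free_of_ab < 1e-6

    def test_half_blockade_at_kd(self, params):
        occ = synapse_occupancy(params.Kd_ab, params)
        assert occ.frac_pd1_free_of_ab == pytest.approx(0.5)

    def test_single_ligand_quadratic_closed_form(self):
        # R = L1 = Kd1 = K, no PD-L2: (K-x)^2 = K*x has root K*(3-sqrt 5)/2
        K = 80.0
        p = ModelParameters(rho_PD1=K, rho_PDL1=K, Kd_PDL1=K,
                            rho_PDL2=1e-12, Kd_PDL2=1.0)
        occ = synapse_occupancy(0.0, p)
        assert occ.engaged_density == pytest.approx(K * (3 - math.sqrt(5)) / 2,
                                                    rel=1e-9)

    def test_engaged_density_bounds(self, params, rng):
        for _ in range(200):
            p = ModelParameters(
                rho_PD1=rng.uniform(1, 500), rho_PDL1=rng.uniform(1, 500),
                rho_PDL2=rng.uniform(0.1, 100), Kd_PDL1=rng.uniform(0.5, 200),
                Kd_PDL2=rng.uniform(0.5, 200))
            occ = synapse_occupancy(rng.uniform(0, 100), p)
            assert 0 <= occ.engaged_density <= min(
                p.rho_PD1, p.rho_PDL1 + p.rho_PDL2) + 1e-9

    def test_blockade_monotonicity(self, params):
        abs_grid = np.logspace(-3, 4, 60)
        inhib = [synapse_occupancy(a, params).inhibition for a in abs_grid]
        assert np.all(np.diff(inhib) <= 1e-12)

    def test_matches_fixed_point_oracle(self, rng):
        for _ in range(100):
            p = ModelParameters(
                rho_PD1=rng.uniform(1, 500), rho_PDL1=rng.uniform(1, 500),
                rho_PDL2=rng.uniform(0.1, 100), Kd_PDL1=rng.uniform(0.5, 200),
                Kd_PDL2=rng.uniform(0.5, 200))
            ab = rng.uniform(0, 50)
            occ = synapse_occupancy(ab, p)
            oracle = _fixed_point_engaged(
                p.rho_PD1 / (1 + ab / p.Kd_ab), p.rho_PDL1, p.rho_PDL2,
                p.Kd_PDL1, p.Kd_PDL2)
            assert occ.engaged_density == pytest.approx(oracle, rel=1e-8)


# ---------------------------------------------------------------------------
# killing & priming
# ---------------------------------------------------------------------------

class TestKillingRate:
    def test_zero_when_no_effectors_or_cells(self, params):
        occ = synapse_occupancy(0.0, params)
        assert killing_rate(1e9, 0.0, occ, params) == 0.0
        assert killing_rate(0.0, 1e6, occ, params) == 0.0

    def test_fully_inhibited_synapse_blocks_killing(self, params):
        from pd1sim.model import SynapseOccupancy
        occ = SynapseOccupancy(1.0, 100.0, 1.0)
        assert killing_rate(1e9, 1e6, occ, params) == 0.0

    def test_saturation_limit(self, params):
        from pd1sim.model import SynapseOccupancy
        occ = SynapseOccupancy(1.0, 0.0, 0.0)
        flux = killing_rate(1e12, 1e6, occ, params)
        assert flux == pytest.approx(params.k_kill * 1e6, rel=1e-3)

    def test_decreasing_in_inhibition(self, params):
        from pd1sim.model import SynapseOccupancy
        fluxes = [killing_rate(1e9, 1e6, SynapseOccupancy(1.0, 0.0, i),
                               params) for i in (0.0, 0.3, 0.9)]
        assert fluxes[0] > fluxes[1] > fluxes[2]


class TestPrimingRates:
    def test_no_mapc_no_priming(self, params):
        s = ModelState(mAPC_LN=0.0, A_LN=5.0)
        teff, _ = priming_rates(s, 50.0, params)
        assert teff == 0.0

    def test_linear_in_clone_count(self, params):
        s = ModelState(mAPC_LN=1e5, A_LN=2.0)
        f1, _ = priming_rates(s, 50.0, params)
        f2, _ = priming_rates(s, 50.0, params.replace(
            n_clones=2 * params.n_clones))
        assert f2 == pytest.approx(2 * f1)

    def test_half_saturation_at_km(self, params):
        s = ModelState(mAPC_LN=1e5, A_LN=0.0)
        f, _ = priming_rates(s, params.K_M, params)
        full = (params.k_prime * 1e5 * params.n_clones
                * params.rho_nCD8 / params.rho_ref)
        assert f == pytest.approx(0.5 * full)


# ---------------------------------------------------------------------------
# tumor geometry
# ---------------------------------------------------------------------------

class TestTumorDiameter:
    def test_zero_cells_zero_diameter(self, params):
        assert tumor_diameter(0.0, params) == 0.0

    def test_unit_volume_sphere(self):
        p = ModelParameters(f_cellularity=1.0)
        c_unit = 1.0 / p.vol_cell   # cells occupying 1 mm^3
        assert tumor_diameter(c_unit, p) == pytest.approx(
            (6 / math.pi) ** (1 / 3), rel=1e-12)

    def test_cube_root_scaling(self, params):
        assert tumor_diameter(8e9, params) == pytest.approx(
            2 * tumor_diameter(1e9, params))


# ---------------------------------------------------------------------------
# assembled RHS
# ---------------------------------------------------------------------------

class TestRhs:
    def test_empty_system_is_fixed_point(self, params, pk):
        model = TumorImmuneModel(params, pk)
        dy = model.rhs(0.0, np.zeros(model.n_states))
        assert np.all(dy == 0.0)

    def test_logistic_limit_matches_closed_form(self, pk):
        # no killing, no immune coupling: pure logistic growth
        p = ModelParameters(k_kill=1e-12, k_death0=1e-12, k_prime=1e-12,
                            k_prime_reg=1e-12, k_apc_in=1e-12)
        model = TumorImmuneModel(p, pk)
        c0 = p.C_max / 100
        y0 = np.zeros(model.n_states)
        y0[model.index["C"]] = c0
        sol = solve_ivp(model.rhs, (0, 400), y0, method="LSODA",
                        rtol=1e-9, atol=1e-6,
                        t_eval=np.linspace(0, 400, 21))
        t = sol.t
        expected = p.C_max / (1 + (p.C_max / c0 - 1)
                              * np.exp(-p.k_growth * t))
        np.testing.assert_allclose(sol.y[model.index["C"]], expected,
                                   rtol=1e-6)

    def test_directional_derivative_consistency(self, params, pk, rng):
        """Finite differences agree with the RHS's directional sensitivity."""
        model = TumorImmuneModel(params, pk)
        y = rng.uniform(0.5, 2.0, model.n_states) * 1e4
        y[model.index["C"]] = 1e9
        f0 = model.rhs(0.0, y)
        for i in rng.choice(model.n_states, size=6, replace=False):
            h = max(1e-6 * abs(y[i]), 1e-9)
            e = np.zeros_like(y)
            e[i] = h
            num = (model.rhs(0.0, y + e) - f0) / h
            num2 = (model.rhs(0.0, y + 2 * e) - f0) / (2 * h)
            # Richardson consistency: halving the step moves the estimate
            # toward a common limit (smooth vector field)
            richardson = 2 * num - num2
            scale = np.abs(f0) + np.abs(num) * h + 1.0
            assert np.all(np.abs(num - richardson) / scale < 1e-3)

    def test_nonnegativity_under_random_parameters(self, pk, rng):
        """Integrated states stay nonnegative for random admissible draws."""
        from pd1sim import Scenario, simulate
        from pd1sim.pk import build_regimen
        sc = Scenario(label="s", regimen=build_regimen(3.0, 14.0, 7.0, 2),
                      horizon=60.0, output_grid=np.arange(0.0, 61.0, 5.0))
        for _ in range(50):
            p = ModelParameters(
                n_clones=int(rng.integers(5, 300)),
                Kd_ag=float(rng.uniform(5, 800)),
                k_growth=float(rng.uniform(0.005, 0.05)),
                k_kill=float(rng.uniform(1, 40)),
                rho_nCD8=float(rng.uniform(1e5, 2e6)),
                n_treg_clones=float(rng.uniform(5, 200)),
            )
            res = simulate(p, pk, sc)
            assert (res.states.drop(columns="time").to_numpy() >= 0).all()

    def test_nonfinite_state_rejected(self, params, pk):
        model = TumorImmuneModel(params, pk)
        y = np.zeros(model.n_states)
        y[0] = np.nan
        with pytest.raises(ModelError):
            model.rhs(0.0, y)


class TestPerCloneMode:
    def test_layout_and_runs(self, params, pk):
        model = TumorImmuneModel(params, pk, n_clone_states=4)
        assert model.n_states == 14 + 5 * 4
        y0 = model.initial_state(diameter_mm=20.0)
        dy = model.rhs(0.0, y0)
        assert np.all(np.isfinite(dy))

    def test_clonality_bounds_and_equal_distribution(self, params, pk):
        model = TumorImmuneModel(params, pk, n_clone_states=3,
                                 clone_dominance=1.0)
        y = np.zeros(model.n_states)
        i0 = model.index["Teff_C_0"]
        y[i0:i0 + 3] = 100.0
        assert model.clonality(y) == pytest.approx(0.0, abs=1e-12)
        y[i0:i0 + 3] = [300.0, 1e-12, 1e-12]
        assert 0.9 < model.clonality(y) <= 1.0

    def test_metastasis_layout(self, params, pk):
        model = TumorImmuneModel(params, pk, metastasis=True)
        assert model.n_states == 27
        y0 = model.initial_state(diameter_mm=30.0, met_volume_mm3=1.0)
        assert tumor_volume_mm3(y0[model.index["C_m"]], params) == (
            pytest.approx(1.0))
        assert np.all(model.rhs(0.0, np.zeros(27)) == 0.0)
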