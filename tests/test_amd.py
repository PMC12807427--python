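"""Boost potential, aMD parameter heuristics, toy sampling, reweighting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from ythdyn import amd
from ythdyn.amd import (
    AMDParameters,
    ThermoState,
    ToySystem,
    basin_barrier,
    boost_delta_v,
    boosted_force_factor,
    count_transitions,
    estimate_amd_parameters,
    fes,
    reweight,
    run_langevin,
)

THERMO = ThermoState(300.0)


class TestBoost:
    @pytest.mark.parametrize(
        "V, E, alpha, expected",
        [
            (100.0, 100.0, 10.0, 0.0),        # at threshold
            (110.0, 100.0, 10.0, 0.0),        # gated above threshold
            (80.0, 100.0, 10.0, 400.0 / 30.0),  # (E-V)^2/(alpha+E-V)
        ],
    )
    def test_boost_values(self, V, E, alpha, expected):
        assert boost_delta_v(V, E, alpha) == pytest.approx(expected)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            boost_delta_v(1.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            boosted_force_factor(1.0, 2.0, -1.0)

    @pytest.mark.parametrize(
        "V, expected", [(100.0, 1.0), (120.0, 1.0), (80.0, 1.0 / 9.0)]
    )
    def test_force_factor_values(self, V, expected):
        assert boosted_force_factor(V, 100.0, 10.0) == pytest.approx(expected)

    def test_force_factor_matches_numerical_derivative(self):
        E, alpha = 100.0, 10.0
        V = np.linspace(50.0, 99.0, 50)
        h = 1e-5
        num = ((V + h + boost_delta_v(V + h, E, alpha))
               - (V - h + boost_delta_v(V - h, E, alpha))) / (2 * h)
        np.testing.assert_allclose(boosted_force_factor(V, E, alpha), num,
                                   atol=1e-6)

    def test_continuity_and_smoothness_at_threshold(self):
        E, alpha = 100.0, 10.0
        assert abs(boost_delta_v(E, E, alpha)) < 1e-12
        assert abs(boosted_force_factor(E, E, alpha) - 1.0) < 1e-8
        eps = 1e-7
        assert boost_delta_v(E - eps, E, alpha) < 1e-12

    @given(
        v=st.floats(-200.0, 99.9), e=st.floats(100.0, 100.0),
        alpha=st.floats(0.5, 50.0),
    )
    @settings(deadline=None, max_examples=60)
    def test_boosted_surface_flattens_below_threshold(self, v, e, alpha):
        """V + dV stays below E and is strictly increasing in V below E."""
        dv = boost_delta_v(v, e, alpha)
        assert dv > 0
        assert v + dv < e
        v2 = v + 0.1
        assert v2 + boost_delta_v(v2, e, alpha) > v + dv

    def test_dual_boost_order(self):
        params = AMDParameters(E_tot=0.0, alpha_tot=4.0, E_dih=10.0, alpha_dih=2.0)
        dv_dih, dv_tot = amd.dual_boost(5.0, -20.0, params)
        assert dv_dih == pytest.approx(25.0 / 7.0)
        # total boost sees the dihedral-boosted total potential
        boosted_total = -20.0 + dv_dih
        assert dv_tot == pytest.approx(
            boost_delta_v(boosted_total, 0.0, 4.0))


class TestParameterEstimation:
    @pytest.mark.parametrize(
        "inputs, expected",
        [
            # worked examples: methylated complex, apo receptor, double mutant
            ((-68357.0, 2016.0, 22552, 162),
             {"E_tot": -64749, "alpha_tot": 4510, "E_dih": 2583,
              "alpha_dih": 113}),
            ((-59185.0, 1933.0, 19702, 156),
             {"E_tot": -56033, "alpha_tot": 3940, "E_dih": 2479,
              "alpha_dih": 109}),
            ((-68087.0, 2042.0, 22455, 162),
             {"E_tot": -64494, "alpha_tot": 4491, "E_dih": 2609,
              "alpha_dih": 113}),
        ],
    )
    def test_worked_examples_at_integer_reporting(self, inputs, expected):
        assert estimate_amd_parameters(*inputs).report() == expected

    def test_unit_counts_expose_coefficients(self):
        p = estimate_amd_parameters(0.0, 0.0, 1, 1)
        assert (p.E_tot, p.alpha_tot, p.E_dih, p.alpha_dih) == (
            pytest.approx(0.16), pytest.approx(0.2), pytest.approx(3.5),
            pytest.approx(0.7))

    def test_linearity_in_counts(self):
        p1 = estimate_amd_parameters(0.0, 0.0, 100, 10)
        p2 = estimate_amd_parameters(0.0, 0.0, 200, 20)
        assert p2.alpha_tot == pytest.approx(2 * p1.alpha_tot)
        assert p2.E_tot == pytest.approx(2 * p1.E_tot)
        assert p2.alpha_dih == pytest.approx(2 * p1.alpha_dih)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_amd_parameters(0.0, 0.0, 0, 5)


class TestLangevin:
    def test_determinism_same_seed(self):
        sys_ = ToySystem()
        a = run_langevin(sys_, THERMO, 500, seed=42)
        b = run_langevin(sys_, THERMO, 500, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.V, b.V)

    def test_boost_below_all_sampled_energies_is_identity(self):
        sys_ = ToySystem()
        plain = run_langevin(sys_, THERMO, 500, seed=1)
        gated = run_langevin(
            sys_, THERMO, 500, seed=1,
            params=AMDParameters(E_tot=-100.0, alpha_tot=1.0, E_dih=0.0,
                                 alpha_dih=1.0))
        np.testing.assert_array_equal(plain.samples, gated.samples)
        assert np.all(gated.deltaV == 0.0)

    def test_boltzmann_distribution_total_variation(self):
        """Long unboosted run matches the analytic Boltzmann density."""
        sys_ = ToySystem(barrier_height=3.0)
        traj = run_langevin(sys_, THERMO, 100_000, stride=10, seed=9)
        edges = np.linspace(-2.0, 2.0, 41)
        hist, _ = np.histogram(traj.samples[:, 0], bins=edges)
        p_emp = hist / hist.sum()
        beta = THERMO.beta
        u = lambda x: sys_.energy(np.array([[x]]))[0]
        p_ref = np.array([
            integrate.quad(lambda x: np.exp(-beta * u(x)), lo, hi)[0]
            for lo, hi in zip(edges[:-1], edges[1:])
        ])
        p_ref /= p_ref.sum()
        tv = 0.5 * np.abs(p_emp - p_ref).sum()
        assert tv < 0.05

    def test_boosted_runs_cross_barrier_more_often(self):
        sys_ = ToySystem(barrier_height=3.0)
        params = AMDParameters(E_tot=3.0, alpha_tot=1.0, E_dih=0.0,
                               alpha_dih=1.0)
        for rep in range(5):
            plain = run_langevin(sys_, THERMO, 3000, stride=10, seed=100 + rep)
            boosted = run_langevin(sys_, THERMO, 3000, stride=10,
                                   seed=100 + rep, params=params)
            assert (count_transitions(boosted.samples[:, 0])
                    > count_transitions(plain.samples[:, 0]))

    def test_divergence_guard(self):
        sys_ = ToySystem(barrier_height=3.0)
        with pytest.raises(amd.DivergenceError):
            run_langevin(sys_, THERMO, 100, seed=0, guard_radius=1.05,
                         x0=np.array([[1.0]]))

    def test_2d_system_samples_both_dimensions(self):
        sys_ = ToySystem(potential="double_basin_2d")
        traj = run_langevin(sys_, THERMO, 2000, seed=4)
        assert traj.samples.shape == (2000, 2)
        assert traj.samples[:, 1].std() > 0.1


class TestReweight:
    def test_zero_boost_gives_uniform_weights(self):
        w = reweight(np.zeros(10), THERMO)
        np.testing.assert_allclose(w, 0.1)

    def test_kt_ln2_gives_weight_ratio_two(self):
        dv = np.array([0.0, THERMO.kT * np.log(2.0)])
        w = reweight(dv, THERMO)
        assert w[1] / w[0] == pytest.approx(2.0)

    def test_maclaurin_converges_to_exponential(self):
        rng = np.random.default_rng(0)
        dv = rng.uniform(0.0, 5.0 * THERMO.kT, size=200)
        w_exp = reweight(dv, THERMO, method="exponential")
        w_mac = reweight(dv, THERMO, method="maclaurin", order=30)
        assert np.abs(w_exp - w_mac).max() < 1e-6

    def test_large_boosts_do_not_overflow(self):
        dv = np.array([0.0, 5000.0])
        w = reweight(dv, THERMO)
        assert np.isfinite(w).all() and w[1] == pytest.approx(1.0)

    def test_negative_boost_rejected(self):
        with pytest.raises(ValueError):
            reweight(np.array([-1.0]), THERMO)


class TestFES:
    def test_uniform_samples_give_flat_surface(self):
        rng = np.random.default_rng(0)
        surf = fes(rng.uniform(0, 1, 200_000), THERMO, bins=10,
                   range_=[(0.0, 1.0)])
        g = surf.free_energy
        assert g.max() - g.min() < 0.05

    def test_min_shift_and_empty_bins(self):
        surf = fes(np.array([0.1, 0.1, 0.9]), THERMO, bins=4,
                   range_=[(0.0, 1.0)])
        assert surf.free_energy[surf.occupied].min() == 0.0
        assert np.isinf(surf.free_energy[1])

    def test_degenerate_single_bin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fes(np.full(10, 0.5), THERMO, bins=4, range_=[(0.0, 1.0)])


class TestBasinBarrier:
    @staticmethod
    def _surface_from_potential(u, lo=-2.0, hi=2.0, bins=200):
        xs = np.linspace(lo, hi, bins)
        G = np.array([u(x) for x in xs])
        G = G - G.min()
        edges = np.linspace(lo, hi, bins + 1)
        return amd.FreeEnergySurface(
            bin_edges=[edges], free_energy=G, counts=np.ones(bins),
            weight_sums=np.ones(bins))

    def test_symmetric_double_well_deltag_zero(self):
        u = lambda x: 3.0 * (x * x - 1.0) ** 2
        surf = self._surface_from_potential(u)
        dg, barrier = basin_barrier(surf, (-2.0, -0.3), (0.3, 2.0))
        assert dg == pytest.approx(0.0, abs=1e-6)
        assert barrier == pytest.approx(3.0, abs=1e-3)

    def test_antisymmetry_under_basin_swap(self):
        u = lambda x: 3.0 * (x * x - 1.0) ** 2 + 0.5 * x
        surf = self._surface_from_potential(u)
        dg_ab, bar_ab = basin_barrier(surf, (-2.0, -0.3), (0.3, 2.0))
        dg_ba, bar_ba = basin_barrier(surf, (0.3, 2.0), (-2.0, -0.3))
        assert dg_ba == pytest.approx(-dg_ab)
        # same saddle seen from the other minimum
        assert bar_ba == pytest.approx(bar_ab - dg_ab, abs=1e-9)

    def test_disjointness_and_occupancy_validated(self):
        u = lambda x: x * x
        surf = self._surface_from_potential(u)
        with pytest.raises(ValueError, match="disjoint"):
            basin_barrier(surf, (-1.0, 0.5), (0.0, 1.0))

    def test_2d_lowest_saddle(self):
        """Two basins joined by a low channel; the minimax path finds it."""
        x = np.linspace(-2, 2, 41)
        y = np.linspace(-2, 2, 41)
        X, Y = np.meshgrid(x, y, indexing="ij")
        G = 3.0 * (X ** 2 - 1) ** 2 + 2.0 * Y ** 2   # saddle at (0, 0), G=3
        G = G - G.min()
        edges = np.linspace(-2, 2, 42)
        surf = amd.FreeEnergySurface([edges, edges], G, np.ones_like(G),
                                     np.ones_like(G))
        dg, barrier = basin_barrier(surf, [(-1.5, -0.5), (-2.0, 2.0)],
                                    [(0.5, 1.5), (-2.0, 2.0)])
        assert dg == pytest.approx(0.0, abs=1e-9)
        assert barrier == pytest.approx(3.0, abs=0.05)


def test_count_transitions_hysteresis():
    x = np.array([-1.0, -0.2, 0.2, -0.2, 1.0, -1.0, 1.0])
    # only full crossings count: -1 -> 1, 1 -> -1, -1 -> 1
    assert count_transitions(x) == 3
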