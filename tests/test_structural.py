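"""Lotka-Volterra transform, feasibility, domain volume and stability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import coexar as cx
from coexar.structural import FEASIBILITY_TOL

from conftest import random_community


class TestGrowthRateTransform:
    @pytest.mark.parametrize(
        "log_lambda, g, s, expected",
        [
            (1.0, 1.0, 0.4, 1.0),  # no seed bank: r = ln(lambda)
            (np.log(3.0), 0.5, 0.5, np.log(2.0)),
            # boundary of persistence: lambda exactly at the invasion threshold
            (np.log((1 - (1 - 0.3) * 0.6) / 0.3), 0.3, 0.6, 0.0),
        ],
    )
    def test_invasion_convention_values(self, log_lambda, g, s, expected):
        assert cx.lv_growth_rate(log_lambda, g, s) == pytest.approx(expected)

    def test_printed_convention_differs(self):
        r_inv = cx.lv_growth_rate(1.0, 0.5, 0.5, convention="invasion")
        r_pr = cx.lv_growth_rate(1.0, 0.5, 0.5, convention="printed")
        assert r_pr == pytest.approx(np.log(1.5) + np.e)
        assert r_inv != r_pr

    def test_invalid_vital_rates_rejected(self):
        with pytest.raises(ValueError):
            cx.lv_growth_rate(1.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            cx.lv_growth_rate(1.0, 0.5, 1.0)


class TestEquilibrium:
    def test_symmetric_pair(self):
        comm = cx.LVCommunity(("a", "b"), np.array([1.0, 1.0]),
                              np.array([[1.0, 0.5], [0.5, 1.0]]))
        res = cx.equilibrium_abundances(comm, ("a", "b"))
        assert res.feasible and not res.singular
        np.testing.assert_allclose(res.equilibrium, [2 / 3, 2 / 3])

    def test_negative_growth_infeasible(self):
        comm = cx.LVCommunity(("a", "b"), np.array([1.0, -0.5]), np.eye(2))
        res = cx.equilibrium_abundances(comm, ("a", "b"))
        assert not res.feasible
        np.testing.assert_allclose(res.equilibrium, [1.0, -0.5])

    def test_facilitation_rescue(self):
        comm = cx.LVCommunity(("a", "b"), np.array([-0.2, 1.0]),
                              np.array([[1.0, -0.5], [0.1, 1.0]]))
        res = cx.equilibrium_abundances(comm, ("a", "b"))
        assert res.feasible
        np.testing.assert_allclose(res.equilibrium, [0.28571, 0.97143], rtol=1e-4)

    def test_singular_matrix_flagged(self):
        comm = cx.LVCommunity(("a", "b"), np.array([1.0, 1.0]), np.ones((2, 2)))
        res = cx.equilibrium_abundances(comm, ("a", "b"))
        assert res.singular and not res.feasible

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariance(self, seed):
        """Relabeling species permutes N* and never changes feasibility."""
        rng = np.random.default_rng(seed)
        comm = random_community(rng, 4)
        perm = rng.permutation(4)
        subset = tuple(comm.species)
        permuted = tuple(comm.species[i] for i in perm)
        res = cx.equilibrium_abundances(comm, subset)
        res_p = cx.equilibrium_abundances(comm, permuted)
        assert res.feasible == res_p.feasible
        if not res.singular:
            np.testing.assert_allclose(res_p.equilibrium, res.equilibrium[perm])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_row_scaling_invariance(self, seed):
        """Multiplying row i of A and r_i by c > 0 leaves N* unchanged."""
        rng = np.random.default_rng(seed)
        comm = random_community(rng, 3)
        c = rng.uniform(0.1, 10.0)
        A2 = comm.A.copy()
        r2 = comm.r.copy()
        A2[1] *= c
        r2[1] *= c
        scaled = cx.LVCommunity(comm.species, r2, A2)
        res = cx.equilibrium_abundances(comm, comm.species)
        res2 = cx.equilibrium_abundances(scaled, comm.species)
        assert res.feasible == res2.feasible
        if not res.singular:
            np.testing.assert_allclose(res2.equilibrium, res.equilibrium, rtol=1e-8)


class TestFeasibilityDomainVolume:
    def test_identity_dim2_exact(self):
        assert cx.feasibility_domain_volume(np.eye(2)) == pytest.approx(0.25)

    def test_dim1(self):
        assert cx.feasibility_domain_volume(np.array([[2.0]])) == pytest.approx(0.5)

    def test_column_angle_closed_form(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        expected = np.arccos(0.8) / (2 * np.pi)
        assert cx.feasibility_domain_volume(A) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1024, abs=1e-4)

    @pytest.mark.parametrize("dim", [3, 4])
    def test_identity_orthant_fraction(self, dim):
        """Omega(identity, d) = 2^-d: the positive orthant's share of the sphere."""
        n = 100_000
        omega = cx.feasibility_domain_volume(np.eye(dim), n, seed=5)
        p = 2.0**-dim
        assert omega == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / n))

    def test_monte_carlo_matches_closed_form_dim2_embedding(self):
        # a 3-species community of two independent blocks: omega multiplies
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 0.5
        expected = (np.arccos(0.8) / (2 * np.pi)) * 0.5
        n = 200_000
        omega = cx.feasibility_domain_volume(A, n, seed=6)
        assert omega == pytest.approx(expected, abs=3 * np.sqrt(expected / n))

    def test_column_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        A = np.eye(3) + rng.uniform(0, 0.4, (3, 3))
        scale = rng.uniform(0.5, 4.0, 3)
        o1 = cx.feasibility_domain_volume(A, 50_000, seed=9)
        o2 = cx.feasibility_domain_volume(A * scale[None, :], 50_000, seed=9)
        assert o1 == pytest.approx(o2, abs=0.01)

    def test_singular_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            cx.feasibility_domain_volume(np.ones((2, 2)))


class TestLocalStability:
    def test_weak_competition_stable(self):
        comm = cx.LVCommunity(("a", "b"), np.array([1.0, 1.0]),
                              np.array([[1.0, 0.5], [0.5, 1.0]]))
        res = cx.equilibrium_abundances(comm, ("a", "b"))
        assert cx.local_stability(res, comm)

    def test_strong_competition_feasible_but_unstable(self):
        comm = cx.LVCommunity(("a", "b"), np.array([1.0, 1.0]),
                              np.array([[1.0, 2.0], [2.0, 1.0]]))
        res = cx.equilibrium_abundances(comm, ("a", "b"))
        assert res.feasible
        assert not cx.local_stability(res, comm)

    def test_singleton_always_stable(self):
        comm = cx.LVCommunity(("a",), np.array([0.7]), np.array([[0.3]]))
        res = cx.equilibrium_abundances(comm, ("a",))
        assert cx.local_stability(res, comm)

    def test_requires_feasible(self):
        comm = cx.LVCommunity(("a",), np.array([-0.7]), np.array([[0.3]]))
        res = cx.equilibrium_abundances(comm, ("a",))
        with pytest.raises(ValueError):
            cx.local_stability(res, comm)


def test_dynamics_converge_to_predicted_equilibrium():
    """Numerical LV integration agrees with the linear-solve equilibrium.

    For feasible and locally stable random 2-3 species communities, interior
    trajectories of dN/dt = N*(r - A N) must converge to N*.
    """
    rng = np.random.default_rng(123)
    checked = 0
    while checked < 20:
        size = int(rng.integers(2, 4))
        comm = random_community(rng, size)
        res = cx.equilibrium_abundances(comm, comm.species)
        if not res.feasible or not cx.local_stability(res, comm):
            continue

        def lv(_, n):
            return n * (comm.r - comm.A @ n)

        # integrate in windows: slow modes (eigenvalues near zero) can need
        # very long horizons even though convergence is certain
        state = rng.uniform(0.2, 1.0, size) * res.equilibrium
        for _ in range(50):
            sol = solve_ivp(lv, (0.0, 500.0), state, rtol=1e-9, atol=1e-12)
            assert sol.success
            state = sol.y[:, -1]
            err = np.abs(state - res.equilibrium) / res.equilibrium
            if np.all(err < 1e-3):
                break
        assert np.all(err < 1e-3), (comm.A, comm.r)
        checked += 1
    assert checked == 20


def test_feasibility_tolerance_applied():
    comm = cx.LVCommunity(("a",), np.array([FEASIBILITY_TOL / 2]), np.array([[1.0]]))
    res = cx.equilibrium_abundances(comm, ("a",))
    assert not res.feasible
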