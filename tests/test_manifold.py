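"""Symbolic center-manifold reduction: transforms, coefficients, branches."""

import numpy as np
import pytest
import sympy as sp

from cmstab import (
    back_transform,
    build_suspended_system,
    center_manifold_reduction,
    critical_p_exact,
    find_critical_p,
    fixed_point_branches,
    fluct_rhs,
    generic_suspended_system,
    solve_invariance_equation,
    steady_state,
    transform_to_eigenbasis,
)
from cmstab.manifold import NonSemisimpleError, eps, u, v, x, z


@pytest.fixture(scope="module")
def fig2_system(fig2):
    return build_suspended_system(fig2, variant="paper_eq")


@pytest.fixture(scope="module")
def fig2_exact(fig2_system):
    return solve_invariance_equation(
        transform_to_eigenbasis(fig2_system, "exact"))


@pytest.fixture(scope="module")
def fig2_approx(fig2_system):
    return solve_invariance_equation(
        transform_to_eigenbasis(fig2_system, "paper_approx"))


class TestCriticalPointExact:
    def test_agrees_with_bisection(self, fig2):
        p_exact = critical_p_exact(fig2, "paper_eq")
        p_bisect = find_critical_p(fig2, "paper_eq", bracket=(1e-3, 0.05)).p_c
        assert float(sp.N(p_exact)) == pytest.approx(p_bisect, abs=1e-9)

    def test_determinant_vanishes_exactly(self, fig2_system):
        assert sp.simplify(fig2_system.Lc.det()) == 0


class TestSuspendedSystem:
    def test_zero_offset_recovers_critical_field(self, fig2, fig2_system):
        """Setting eps = 0 reproduces fluct_rhs at p = p_c exactly."""
        pc = float(sp.N(fig2_system.p_c))
        params = fig2.replace(p=pc)
        ss = steady_state(params)
        for state in [(1e-4, -3e-4), (0.01, 0.02)]:
            fx, fz = fig2_system.rhs_at(state[0], state[1], 0)
            ref = fluct_rhs(state, params, ss, "paper_eq")
            assert float(sp.N(fx)) == pytest.approx(ref[0], rel=1e-9)
            assert float(sp.N(fz)) == pytest.approx(ref[1], rel=1e-9)

    def test_origin_fixed_for_all_offsets(self, fig2_system):
        for e in (0, sp.Rational(1, 1000), -sp.Rational(1, 500)):
            assert fig2_system.rhs_at(0, 0, e) == (0, 0)

    def test_feedback_off_leaves_only_linear_and_eps_cross_terms(self, fig2):
        params = fig2.replace(a=0.0, b=0.0, c=0.0, d=0.0)
        system = build_suspended_system(params, p_c=sp.Rational(1, 100),
                                        variant="paper_eq")
        for expr, sign in ((system.fx, 1), (system.fz, -1)):
            poly = sp.Poly(sp.expand(expr), x, z, eps)
            for (i, j, l), coeff in poly.terms():
                assert i + j + l <= 2
                if l == 1:
                    assert (i, j) == (0, 1)
                    assert coeff == sign  # the +eps*z / -eps*z suspension pair


class TestEigenbasisTransform:
    def test_exact_mode_diagonalizes(self, fig2_system):
        tr = transform_to_eigenbasis(fig2_system, "exact")
        D = sp.simplify(tr.Tinv * fig2_system.Lc * tr.T)
        assert sp.simplify(D[0, 1]) == 0 and sp.simplify(D[1, 0]) == 0
        assert sp.simplify(D[0, 0] - tr.lam) == 0
        assert sp.simplify(D[1, 1]) == 0

    def test_hyperbolic_eigenvalue_value(self, fig2_system):
        tr = transform_to_eigenbasis(fig2_system, "exact")
        assert float(sp.N(tr.lam)) == pytest.approx(5.8694910016699e-4,
                                                    rel=1e-9)

    def test_approx_matrix_and_inverse(self):
        system = generic_suspended_system("paper_eq")
        tr = transform_to_eigenbasis(system, "paper_approx")
        a, Xe = sp.symbols("a X_e", positive=True)
        aXe = a * Xe
        expected_inv = sp.Matrix([[-1, 1], [aXe, aXe]]) / (2 * aXe)
        assert sp.simplify(tr.Tinv - expected_inv) == sp.zeros(2, 2)
        at_values = tr.T.subs({a: 150, Xe: sp.Rational(2, 1000)})
        assert at_values == sp.Matrix([[sp.Rational(-3, 10), 1],
                                       [sp.Rational(3, 10), 1]])

    def test_repeated_eigenvalue_rejected(self, fig2):
        # force trace = 0 at the supplied "critical" point: A = p
        system = build_suspended_system(fig2, p_c=sp.Rational(1, 100),
                                        variant="paper_eq")
        hacked = system.__class__(
            fx=system.fx, fz=system.fz,
            Lc=sp.Matrix([[sp.Rational(1, 100), sp.S.One],
                          [sp.S.Zero, -sp.Rational(1, 100)]]),
            p_c=sp.Rational(1, 100), Xe=system.Xe, Ye=system.Ye,
            variant=system.variant, a_coeff=system.a_coeff)
        with pytest.raises(NonSemisimpleError):
            transform_to_eigenbasis(hacked, "exact")


class TestInvarianceSolve:
    def test_structural_zeros_exact_mode(self, fig2_exact):
        """No pure-eps forcing: a3, a7, n3, n7 vanish exactly."""
        a, n = fig2_exact.a, fig2_exact.n
        assert a[2] == 0 and a[6] == 0
        assert n[2] == 0 and n[6] == 0

    def test_published_vanishing_set_in_approx_mode(self, fig2_approx):
        a, n = fig2_approx.a, fig2_approx.n
        assert a[2] == 0 and a[6] == 0
        assert n[2] == 0 and n[5] == 0 and n[6] == 0

    def test_eps_forcing_survives_in_exact_mode(self, fig2_exact):
        # the left center eigenvector is not orthogonal to the eps-forcing,
        # so the v*eps^2 coefficient is genuinely nonzero in the exact basis
        assert fig2_exact.n[5] != 0

    def test_approx_mode_quadratic_coefficient_closed_form(self, fig2_approx):
        # n1 = (a - b + 2c)/2 under the (1/2, 1/2) projection
        assert fig2_approx.n_floats[0] == pytest.approx(-2.9, rel=1e-12)

    def test_tangency(self, fig2_exact):
        h = fig2_exact.h_expr()
        assert h.subs({v: 0, eps: 0}) == 0
        assert sp.diff(h, v).subs({v: 0, eps: 0}) == 0
        assert sp.diff(h, eps).subs({v: 0, eps: 0}) == 0

    def test_invariance_residual_is_higher_order(self, fig2_exact,
                                                 fig2_approx):
        assert fig2_exact.residual_min_degree() >= 4
        assert fig2_approx.residual_min_degree() >= 4

    def test_linear_system_has_no_reduced_dynamics(self, fig2):
        """Linear critical system (D1 = 0, no feedback): dv/dt vanishes.

        The manifold itself is not flat: the suspension couples eps to the
        hyperbolic direction through the eps*z forcing, giving the closed
        form a2 = k / (p (k + p)) with every pure-v coefficient zero.
        """
        params = fig2.replace(D1=0.0, a=0.0, b=0.0, c=0.0, d=0.0)
        system = build_suspended_system(params, p_c=sp.Rational(1, 100),
                                        variant="paper_eq")
        assert sp.simplify(system.Lc.det()) == 0
        result = solve_invariance_equation(
            transform_to_eigenbasis(system, "exact"))
        assert all(c == 0 for c in result.n)
        a1, a2, a3, a4, a5, a6, a7 = result.a
        assert a1 == a3 == a4 == a5 == a7 == 0
        k, p = sp.Rational(1, 200), sp.Rational(1, 100)
        assert sp.simplify(a2 - k / (p * (k + p))) == 0
        assert a6 != 0

    def test_generic_symbolic_zeros_code_variant(self):
        """The vanishing set holds for free symbols, not just the preset."""
        system = generic_suspended_system("fig2_code")
        result = solve_invariance_equation(
            transform_to_eigenbasis(system, "paper_approx"))
        assert sp.simplify(result.a[2]) == 0
        assert sp.simplify(result.a[6]) == 0
        for idx in (1, 2, 5, 6):  # n2, n3, n6, n7
            assert sp.simplify(result.n[idx]) == 0


class TestManifoldDynamics:
    def test_trajectories_started_on_manifold_stay_on_it(self, fig2,
                                                         fig2_exact):
        """Deviation from the manifold scales like the quartic remainder."""
        from scipy.integrate import solve_ivp

        tr = fig2_exact.transform
        T = np.array(sp.N(tr.T, 30).tolist(), dtype=float)
        Tinv = np.array(sp.N(tr.Tinv, 30).tolist(), dtype=float)
        a = fig2_exact.a_floats

        def h(vv):
            return a[0] * vv**2 + a[3] * vv**3

        pc = float(sp.N(tr.system.p_c))
        params = fig2.replace(p=pc)
        ss = steady_state(params)

        def rhs(t, s):
            return fluct_rhs(s, params, ss, "paper_eq")

        deviations = []
        for v0 in (1e-9, 2e-9):
            xz0 = T @ np.array([h(v0), v0])
            sol = solve_ivp(rhs, (0, 500), xz0, rtol=1e-13, atol=1e-24,
                            dense_output=True, max_step=5.0)
            devs = [abs((Tinv @ sol.sol(t))[0] - h((Tinv @ sol.sol(t))[1]))
                    for t in np.linspace(0.0, 500.0, 10)]
            deviations.append(max(devs))
        assert deviations[0] < 1e-16
        assert 10.0 < deviations[1] / deviations[0] < 22.0  # ~2^4


class TestBranches:
    def test_trivial_and_nontrivial_roots_at_criticality(self, fig2_exact):
        branches = fixed_point_branches(fig2_exact)
        assert len(branches.branches) == 3
        at_zero = sorted((float(sp.N(b.v_exact.subs(eps, 0)))
                          for b in branches.branches), key=abs)
        n1, n4 = fig2_exact.n_floats[0], fig2_exact.n_floats[3]
        assert at_zero[0] == pytest.approx(0.0, abs=1e-22)
        assert at_zero[1] == pytest.approx(0.0, abs=1e-22)
        assert at_zero[2] == pytest.approx(-n1 / n4, rel=1e-9)

    def test_branches_annihilate_reduced_dynamics(self, fig2_approx):
        """In the approximate mode n3 = n6 = n7 = 0, so the quadratic
        factorisation used for the branches is the exact truncated dynamics
        and the roots must annihilate it identically."""
        reduced = fig2_approx.reduced_rhs_expr()
        branches = fixed_point_branches(fig2_approx)
        n = fig2_approx.n_floats
        e0 = sp.Rational(1, 10**9)
        scale = abs(n[0] / n[3]) ** 2  # branch amplitude scale
        for b in branches.branches:
            v0 = b.v_exact.subs(eps, e0)
            val = reduced.subs({v: v0, eps: e0})
            assert abs(float(sp.N(val, 60))) < 1e-25 * max(scale, 1.0)

    def test_series_match_exact_roots_to_second_order(self, fig2_exact):
        branches = fixed_point_branches(fig2_exact)
        for b in branches.branches:
            if b.name == "trivial":
                continue
            errs = []
            for e0 in (1e-8, 2e-8):
                exact = float(sp.N(b.v_exact.subs(eps, e0), 40))
                series = float(sp.N(b.v_series.subs(eps, e0), 40))
                denom = max(abs(exact), 1e-300)
                errs.append(abs(exact - series) / denom)
            assert errs[0] < 1e-3
            # error shrinks at least one order in eps faster than the value
            assert errs[1] / errs[0] > 1.8

    def test_discriminant_positive_at_criticality_and_roots_annihilate(
            self, fig2_exact):
        branches = fixed_point_branches(fig2_exact)
        n1 = fig2_exact.n[0]
        assert sp.simplify(branches.discriminant.subs(eps, 0) - n1**2) == 0
        roots = branches.discriminant_roots()
        assert 1 <= len(roots) <= 2
        for r in roots:
            assert abs(complex(sp.N(branches.discriminant.subs(eps, r),
                                    40))) < 1e-30

    def test_degenerate_without_quadratic_terms(self, fig2):
        params = fig2.replace(D1=0.0, a=0.0, b=0.0, c=0.0, d=0.0)
        result = solve_invariance_equation(transform_to_eigenbasis(
            build_suspended_system(params, p_c=sp.Rational(1, 100),
                                   variant="paper_eq"), "exact"))
        branches = fixed_point_branches(result)
        assert branches.degenerate
        assert len(branches.branches) == 1


class TestBackTransform:
    def test_center_direction_maps_through_second_column(self, fig2_exact):
        tr = fig2_exact.transform
        branches = fixed_point_branches(fig2_exact)
        trivial = [b for b in branches.branches if b.name == "trivial"][0]
        mapped = back_transform(
            type(branches)(branches=(trivial,), discriminant=sp.S.Zero,
                           degenerate=True, result=fig2_exact), tr)
        assert mapped[0].x_expr == 0

    def test_approx_transform_identifies_x_with_v(self):
        system = generic_suspended_system("paper_eq")
        tr = transform_to_eigenbasis(system, "paper_approx")
        s = sp.Symbol("s")
        xz = tr.T * sp.Matrix([0, s])
        assert sp.simplify(xz[0] - s) == 0 and sp.simplify(xz[1] - s) == 0

    def test_two_distinct_amplitudes(self, fig2_exact):
        """The hallmark of the bifurcation: two nontrivial x levels."""
        branches = fixed_point_branches(fig2_exact)
        xspace = back_transform(branches, fig2_exact.transform)
        n = fig2_exact.n_floats
        e0 = 1e-3 * (n[0] / n[3]) ** 2
        values = sorted(float(sp.N(b.x_expr.subs(eps, e0), 40))
                        for b in xspace)
        assert len(set(np.round(values, 20))) == 3  # 0 and two amplitudes

    def test_discrepancy_tracks_approximation(self, fig2_approx):
        branches = fixed_point_branches(fig2_approx)
        xspace = back_transform(branches, fig2_approx.transform)
        for b in xspace:
            assert sp.simplify(b.x_discrepancy -
                               (b.x_expr - b.x_approx)) == 0


def test_end_to_end_reduction_matches_staged_calls(fig2, fig2_exact):
    direct = center_manifold_reduction(fig2, "paper_eq", "exact")
    assert direct.a == fig2_exact.a
    assert direct.n == fig2_exact.n
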