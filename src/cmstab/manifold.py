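"""Symbolic center-manifold reduction at the critical cofactor supply.

At p = p_c the fluctuation Jacobian has a zero eigenvalue: the dynamics near
the origin is governed by a one-dimensional invariant manifold tangent to the
center eigenspace.  The reduction follows the standard suspension recipe:

1.  Suspend the bifurcation parameter deviation eps = p - p_c as an extra
    state with d(eps)/dt = 0; the fluctuation field becomes polynomial in
    (x, z, eps), with the steady state frozen at its critical value (eps
    enters only through the explicit p-dependence of the z-column).
2.  Change coordinates to the eigenbasis [l1 l2] of the critical Jacobian
    L_c, so that u spans the hyperbolic direction (eigenvalue lambda != 0)
    and v spans the center direction (eigenvalue 0).
3.  Substitute the cubic ansatz u = h(v, eps) = a1 v^2 + a2 v eps + a3 eps^2
    + a4 v^3 + a5 v^2 eps + a6 v eps^2 + a7 eps^3 into the invariance
    condition du/dt = (dh/dv) dv/dt and solve the triangular linear system
    for a1..a7, order by order.
4.  Substitute h into the v-equation to obtain the reduced dynamics
    dv/dt = n1 v^2 + n2 v eps + n3 eps^2 + n4 v^3 + n5 v^2 eps + n6 v eps^2
    + n7 eps^3, whose fixed-point branches v(eps) exhibit the bifurcation.

Two transform modes are provided.  ``exact`` (default) uses the true
eigenvectors of L_c; in that basis the coefficients a3, a7, n3, n7 vanish
identically (the suspended field has no pure-eps forcing), but n6 does not:
the left center eigenvector is not orthogonal to the eps-forcing direction.
``paper_approx`` uses the small-rate asymptotic transform
[[-a*Xe, 1], [a*Xe, 1]] with linear part diag(a*Xe, 0) (valid when D1, k, p
are all small against a*Xe); its v-row (1/2)(1, 1) annihilates the
eps-forcing +eps*z, -eps*z exactly, so n2, n3, n6 and n7 all vanish in that
mode.  All arithmetic is exact (rationals and radicals) so the vanishing
statements are algebraic identities, not numerical zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import sympy as sp

from .fluctuation import Variant
from .params import ModelParams

__all__ = [
    "x", "z", "eps", "u", "v",
    "SuspendedSystem",
    "TransformedSystem",
    "CenterManifoldResult",
    "Branch",
    "BifurcationBranches",
    "NonSemisimpleError",
    "SingularInvarianceError",
    "critical_p_exact",
    "build_suspended_system",
    "transform_to_eigenbasis",
    "solve_invariance_equation",
    "fixed_point_branches",
    "back_transform",
    "center_manifold_reduction",
    "generic_suspended_system",
]

# state and suspension symbols shared by every expression this module builds
x, z, eps = sp.symbols("x z epsilon")
u, v = sp.symbols("u v")

_A_NAMES = tuple(f"a{i}" for i in range(1, 8))
_N_NAMES = tuple(f"n{i}" for i in range(1, 8))
#: ansatz/reduced-dynamics monomials in (v, eps), in coefficient order 1..7
_MONOMIALS = ((2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3))


class NonSemisimpleError(ValueError):
    """The critical linear part cannot be diagonalized (repeated eigenvalue)."""


class SingularInvarianceError(ValueError):
    """The order-by-order solve hit a monomial with no solvable unknown."""


def _exactify(value):
    """Convert a float to the exact rational its decimal literal denotes."""
    if isinstance(value, sp.Expr):
        return sp.nsimplify(value, rational=False) if value.is_Float else value
    if isinstance(value, float):
        return sp.Rational(repr(value))
    return sp.Integer(value) if isinstance(value, int) else sp.sympify(value)


def _steady_exprs(params: dict, p_sym):
    D1, D2, M, W, k = (params[s] for s in ("D1", "D2", "M", "W", "k"))
    den = D2 * k + D2 * p_sym + D1 * D2 * W + D1 * p_sym * W
    Xe = D2 * M * p_sym / den
    Ye = D1 * M * p_sym * W / den
    Ze = D2 * M * (k + D1 * W) / den
    return Xe, Ye, Ze


def critical_p_exact(params: ModelParams, variant=Variant.paper_eq):
    """Exact root of det L(p) = 0 with p-dependent steady states.

    The determinant's numerator is a polynomial in p with p = 0 always a root
    (the steady state collapses onto Z at zero cofactor supply); the critical
    supply is the smallest positive real root of the remaining factor.
    """
    variant = Variant.coerce(variant)
    P = {name: _exactify(getattr(params, name))
         for name in ("D1", "D2", "a", "b", "c", "d", "k", "M", "W")}
    p_sym = sp.Symbol("p", positive=True)
    Xe, Ye, _ = _steady_exprs(P, p_sym)
    A = -P["D1"] + P["a"] * Xe - P["k"]
    B = -P["b"] * Xe + p_sym
    C = P["k"] - P["c"] * Ye if variant is Variant.paper_eq else P["k"]
    det = sp.together(A * (-p_sym) - C * B)
    num = sp.fraction(det)[0]
    reduced = sp.cancel(num / p_sym)
    roots = sp.Poly(reduced, p_sym).all_roots()
    positive = [r for r in roots if r.is_real and r.is_positive]
    if not positive:
        raise ValueError("det L(p) has no positive critical root for these parameters")
    return sorted(positive, key=lambda r: sp.N(r))[0]


@dataclass(frozen=True)
class SuspendedSystem:
    """Polynomial fluctuation field in (x, z, eps) with d(eps)/dt = 0."""

    fx: sp.Expr
    fz: sp.Expr
    Lc: sp.Matrix
    p_c: sp.Expr
    Xe: sp.Expr
    Ye: sp.Expr
    variant: str
    #: quadratic coefficients (a, b and the z-equation pair) kept for the
    #: approximate-transform mode, which needs a*Xe explicitly
    a_coeff: sp.Expr = sp.S.Zero

    def rhs_at(self, x_val, z_val, eps_val):
        subs = {x: x_val, z: z_val, eps: eps_val}
        return (self.fx.subs(subs), self.fz.subs(subs))


def build_suspended_system(params: ModelParams, p_c=None,
                           variant=Variant.paper_eq) -> SuspendedSystem:
    """Suspend the fluctuation system at its critical point.

    ``p_c`` may be given (a number or exact sympy expression); by default it
    is solved exactly via :func:`critical_p_exact`.  The steady state is
    evaluated at p_c, so the fluctuations are measured about the critical
    steady state and eps enters only where p appears explicitly (the
    z-coefficients of both equations).
    """
    variant = Variant.coerce(variant)
    if p_c is None:
        p_c = critical_p_exact(params, variant)
    else:
        p_c = _exactify(p_c)
    P = {name: _exactify(getattr(params, name))
         for name in ("D1", "D2", "a", "b", "c", "d", "k", "M", "W")}
    Xe, Ye, _ = _steady_exprs(P, p_c)
    Xe, Ye = sp.cancel(Xe), sp.cancel(Ye)
    A = sp.cancel(-P["D1"] + P["a"] * Xe - P["k"])
    B = sp.cancel(-P["b"] * Xe + p_c)
    C = sp.cancel(P["k"] - P["c"] * Ye) if variant is Variant.paper_eq else P["k"]
    fx = A * x + (B + eps) * z + P["a"] * x**2 - P["b"] * x * z
    if variant is Variant.fig2_code:
        fz = C * x - (p_c + eps) * z + P["c"] * x**2 + P["d"] * x * z
    else:
        fz = C * x - (p_c + eps) * z + P["c"] * x**2 + P["c"] * x * z
    Lc = sp.Matrix([[A, B], [C, -p_c]])
    return SuspendedSystem(fx=fx, fz=fz, Lc=Lc, p_c=p_c, Xe=Xe, Ye=Ye,
                           variant=variant.value, a_coeff=P["a"])


def generic_suspended_system(variant=Variant.paper_eq) -> SuspendedSystem:
    """Suspended system with fully symbolic parameters at criticality.

    Rates, feedback coefficients and the critical steady state are free
    positive symbols; det L_c = 0 is imposed by eliminating one feedback
    coefficient (c for the paper-equation variant, b for the simulation-code
    variant), which leaves every other parameter arbitrary.  Used to prove
    coefficient identities independently of numerical values.
    """
    variant = Variant.coerce(variant)
    D1, a, b, c, d, k, p, Xe, Ye = sp.symbols(
        "D1 a b c d k p X_e Y_e", positive=True)
    A = -D1 + a * Xe - k
    if variant is Variant.paper_eq:
        # det = -A p - (k - c Ye) B = 0  =>  k - c Ye = -A p / B
        B = -b * Xe + p
        c_crit = (k + A * p / B) / Ye
        C = -A * p / B
        fz = C * x - (p + eps) * z + c_crit * x**2 + c_crit * x * z
    else:
        # det = -A p - k B = 0  =>  B = -A p / k, i.e. b = (p - B)/Xe
        B = -A * p / k
        b = sp.cancel((p - B) / Xe)
        C = k
        fz = C * x - (p + eps) * z + c * x**2 + d * x * z
    fx = A * x + (B + eps) * z + a * x**2 - b * x * z
    Lc = sp.Matrix([[A, B], [C, -p]])
    return SuspendedSystem(fx=fx, fz=fz, Lc=Lc, p_c=p, Xe=Xe, Ye=Ye,
                           variant=variant.value, a_coeff=a)


# ---------------------------------------------------------------------------
# Eigenbasis transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransformedSystem:
    """The suspended field in eigen-coordinates (u, v, eps).

    ``cu``/``cv`` map monomial exponents (u-power, v-power, eps-power) to
    exact coefficients of du/dt and dv/dt.  The linear part is diagonal:
    cu[(1,0,0)] = lambda (hyperbolic), the v-equation has no linear terms
    (center direction).
    """

    cu: dict
    cv: dict
    T: sp.Matrix
    Tinv: sp.Matrix
    lam: sp.Expr
    mode: str
    system: SuspendedSystem

    def fu_expr(self) -> sp.Expr:
        return sp.Add(*[cf * u**i * v**j * eps**l
                        for (i, j, l), cf in self.cu.items()])

    def fv_expr(self) -> sp.Expr:
        return sp.Add(*[cf * u**i * v**j * eps**l
                        for (i, j, l), cf in self.cv.items()])


def _field_coeffs(expr):
    return {m: sp.cancel(cf) for m, cf in sp.Poly(expr, u, v, eps).terms()
            if sp.cancel(cf) != 0}


def transform_to_eigenbasis(system: SuspendedSystem,
                            mode: str = "exact") -> TransformedSystem:
    """Rotate the suspended field into the eigenbasis of L_c.

    ``exact``: columns l1 = (B, -p_c) (eigenvalue lambda = A - p_c) and
    l2 = (B, -A) (eigenvalue 0) of L_c = [[A, B], [C, -p_c]]; the transformed
    linear part is exactly diag(lambda, 0).

    ``paper_approx``: the asymptotic transform [[-a*Xe, 1], [a*Xe, 1]] with
    the linear part replaced by its small-(D1, k, p) limit diag(a*Xe, 0).
    This is the published construction; the matrix is not an eigenbasis of
    the full L_c, so the replacement is what makes the tangency assumption
    u = O(|v, eps|^2) self-consistent.
    """
    A, B = system.Lc[0, 0], system.Lc[0, 1]
    p_c = system.p_c
    if mode == "exact":
        lam = sp.cancel(A - p_c)  # trace: the other eigenvalue is 0
        if sp.simplify(lam) == 0:
            raise NonSemisimpleError(
                "repeated zero eigenvalue: the critical linear part is not "
                "diagonalizable")
        if sp.simplify(B) == 0:
            raise NonSemisimpleError(
                "degenerate eigenvector (B = 0); the standard eigenbasis "
                "columns (B, -p), (B, -A) collapse")
        T = sp.Matrix([[B, B], [-p_c, -A]])
    elif mode == "paper_approx":
        aXe = sp.cancel(system.a_coeff * system.Xe)
        lam = aXe
        T = sp.Matrix([[-aXe, 1], [aXe, 1]])
    else:
        raise ValueError(f"unknown transform mode {mode!r}")

    detT = sp.cancel(T.det())
    adj = sp.Matrix([[T[1, 1], -T[0, 1]], [-T[1, 0], T[0, 0]]])
    xs = T[0, 0] * u + T[0, 1] * v
    zs = T[1, 0] * u + T[1, 1] * v
    sub = {x: xs, z: zs}
    fxs = system.fx.subs(sub, simultaneous=True)
    fzs = system.fz.subs(sub, simultaneous=True)
    cu = _field_coeffs(sp.expand((adj[0, 0] * fxs + adj[0, 1] * fzs) / detT))
    cv = _field_coeffs(sp.expand((adj[1, 0] * fxs + adj[1, 1] * fzs) / detT))

    if mode == "exact":
        # the linear part must come out exactly diag(lam, 0)
        for coeffs, key in ((cu, (0, 1, 0)), (cv, (1, 0, 0)), (cv, (0, 1, 0))):
            stray = coeffs.pop(key, sp.S.Zero)
            if stray != 0 and sp.simplify(stray) != 0:
                raise NonSemisimpleError(
                    f"transformed linear part not diagonal: stray "
                    f"coefficient {stray} at {key} (is p_c exact?)")
        cu[(1, 0, 0)] = lam
    else:
        # replace the linear block by its asymptotic limit diag(a*Xe, 0)
        for key in ((1, 0, 0), (0, 1, 0)):
            cu.pop(key, None)
            cv.pop(key, None)
        cu[(1, 0, 0)] = lam
    return TransformedSystem(cu=cu, cv=cv, T=T, Tinv=sp.cancel(adj / detT),
                             lam=lam, mode=mode, system=system)


# ---------------------------------------------------------------------------
# Invariance equation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CenterManifoldResult:
    """Manifold coefficients a1..a7, reduced dynamics n1..n7 (exact)."""

    a: tuple
    n: tuple
    lam: sp.Expr
    order: int
    mode: str
    variant: str
    transform: TransformedSystem

    @property
    def a_floats(self):
        return tuple(float(sp.N(c)) for c in self.a)

    @property
    def n_floats(self):
        return tuple(float(sp.N(c)) for c in self.n)

    def h_expr(self) -> sp.Expr:
        """The manifold graph u = h(v, eps)."""
        return sp.Add(*[c * v**j * eps**l
                        for c, (j, l) in zip(self.a, _MONOMIALS)])

    def reduced_rhs_expr(self) -> sp.Expr:
        """dv/dt on the manifold, truncated at total degree 3."""
        return sp.Add(*[c * v**j * eps**l
                        for c, (j, l) in zip(self.n, _MONOMIALS)])

    def invariance_residual(self) -> sp.Expr:
        """Full residual du/dt - (dh/dv) dv/dt on the manifold (polynomial)."""
        h = self.h_expr()
        fu_h = self.transform.fu_expr().subs(u, h)
        fv_h = self.transform.fv_expr().subs(u, h)
        return sp.expand(fu_h - sp.diff(h, v) * fv_h)

    def residual_min_degree(self) -> int:
        res = self.invariance_residual()
        if res == 0:
            return -1
        # pull the (v, eps)-free coefficient denominators out, then replace
        # surviving square roots in the numerator by fresh symbols: the zero
        # test on each monomial becomes a cheap rational-polynomial check.
        # Poly over the raw radical expressions would instead route
        # zero-testing through minimal-polynomial computations that try to
        # factor the huge integers an exact p_c produces.
        num, den = sp.fraction(sp.together(res))
        if den.has(v, eps):  # pragma: no cover - coefficients are state-free
            num = res
        num = sp.expand(num)
        reps = {pw: sp.Dummy(positive=True) for pw in num.atoms(sp.Pow)
                if pw.exp is sp.S.Half}
        poly = sp.Poly(num.xreplace(reps), v, eps, *reps.values())
        degrees = [m[0] + m[1] for m, cf in poly.terms() if cf != 0]
        return min(degrees) if degrees else -1


def _substituted_coeffs(coeffs, h_terms, order=3):
    """Coefficients of f(h(v,eps), v, eps) truncated to total degree <= order.

    ``h_terms`` is a list of (coefficient, (v-deg, eps-deg)) pairs; the field
    coefficients carry u-powers 0..2 and u = h is O(2), so u^2 terms fall
    beyond cubic order and are dropped.
    """
    out = {}
    for (i, j, l), cf in coeffs.items():
        if i == 0:
            if j + l <= order:
                out[(j, l)] = out.get((j, l), 0) + cf
        elif i == 1:
            for hc, (hj, hl) in h_terms:
                jj, ll = j + hj, l + hl
                if jj + ll <= order:
                    out[(jj, ll)] = out.get((jj, ll), 0) + cf * hc
        # i >= 2: h^i = O(4), beyond the retained order
    return out


def solve_invariance_equation(transformed: TransformedSystem,
                              order: int = 3) -> CenterManifoldResult:
    """Solve for the manifold and reduced-dynamics coefficients.

    Substitutes the cubic ansatz into the invariance condition
    fu(h, v, eps) = (dh/dv) fv(h, v, eps), collects monomials v^j eps^l of
    total degree <= order, and solves the triangular linear system: each
    equation introduces exactly one new unknown multiplied by the hyperbolic
    eigenvalue, so the solve proceeds degree by degree.
    """
    if order != 3:
        raise NotImplementedError("truncation order is fixed at 3")
    a_syms = sp.symbols(" ".join(f"_cm_{n}" for n in _A_NAMES))
    h_terms = [(s, m) for s, m in zip(a_syms, _MONOMIALS)]

    fu_h = _substituted_coeffs(transformed.cu, h_terms, order)
    # (dh/dv) * fv(h, v, eps): dh/dv is O(1), so fv(h) is needed to O(2)
    fv_h2 = _substituted_coeffs(transformed.cv, h_terms, order - 1)
    dh_dv = [(s * j, (j - 1, l)) for s, (j, l) in h_terms if j > 0]
    inv = dict(fu_h)
    for hc, (hj, hl) in dh_dv:
        for (j, l), gc in fv_h2.items():
            jj, ll = j + hj, l + hl
            if jj + ll <= order:
                inv[(jj, ll)] = inv.get((jj, ll), 0) - hc * gc

    eqs = sorted(((m, cf) for m, cf in inv.items() if m[0] + m[1] >= 2),
                 key=lambda t: (t[0][0] + t[0][1], -t[0][0]))
    sol = {}
    for mono, eq in eqs:
        eq = sp.cancel(sp.expand(eq.subs(sol)))
        present = [s for s in a_syms if eq.has(s)]
        if not present:
            if sp.simplify(eq) != 0:
                raise SingularInvarianceError(
                    f"invariance equation at monomial v^{mono[0]}*eps^{mono[1]} "
                    f"has no unknown but nonzero residual {eq}; the u-direction "
                    f"is not hyperbolic here")
            continue
        unknown = present[0]
        poly = sp.Poly(eq, unknown)
        if poly.degree() != 1:
            raise SingularInvarianceError(
                f"equation at v^{mono[0]}*eps^{mono[1]} is not linear in "
                f"{unknown}")
        c1, c0 = poly.all_coeffs()
        if sp.simplify(c1) == 0:
            raise SingularInvarianceError(
                f"singular solve at monomial v^{mono[0]}*eps^{mono[1]}: "
                f"unknown {unknown} has zero pivot (non-hyperbolic u-direction)")
        sol[unknown] = sp.cancel(-c0 / c1)
    a_coeffs = tuple(sp.radsimp(sp.cancel(sol.get(s, sp.S.Zero)))
                     for s in a_syms)

    solved_terms = [(c, m) for c, m in zip(a_coeffs, _MONOMIALS)]
    n_dict = _substituted_coeffs(transformed.cv, solved_terms, order)
    n_coeffs = tuple(
        sp.radsimp(sp.cancel(sp.expand(n_dict.get(m, sp.S.Zero))))
        for m in _MONOMIALS)
    return CenterManifoldResult(
        a=a_coeffs, n=n_coeffs, lam=transformed.lam, order=order,
        mode=transformed.mode, variant=transformed.system.variant,
        transform=transformed)


# ---------------------------------------------------------------------------
# Bifurcation branches
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Branch:
    name: str
    v_exact: sp.Expr
    v_series: sp.Expr  # first-order Taylor expansion in eps
    u_on_manifold: sp.Expr


@dataclass(frozen=True)
class BifurcationBranches:
    branches: tuple
    discriminant: sp.Expr
    degenerate: bool
    result: CenterManifoldResult

    def discriminant_roots(self):
        """eps values where the number of real nontrivial branches changes.

        The discriminant is at most quadratic in eps, so its roots are
        written with the quadratic formula directly; ``sp.solve`` struggles
        with the large radical coefficients the exact mode produces.
        """
        if eps not in self.discriminant.free_symbols:
            return []
        poly = sp.Poly(self.discriminant, eps)
        coeffs = poly.all_coeffs()
        if len(coeffs) == 2:
            c1, c0 = coeffs
            return [sp.cancel(-c0 / c1)]
        c2, c1, c0 = coeffs
        root = sp.sqrt(c1**2 - 4 * c2 * c0)
        return [(-c1 + root) / (2 * c2), (-c1 - root) / (2 * c2)]


def fixed_point_branches(result: CenterManifoldResult) -> BifurcationBranches:
    """Fixed points v(eps) of the reduced dynamics.

    Setting dv/dt = 0 and factoring out v leaves the quadratic
    n4 v^2 + (n1 + n5 eps) v + n2 eps = 0, giving the trivial branch v = 0
    plus two roots (-(n1 + n5 eps) +/- sqrt((n1 + n5 eps)^2 - 4 n2 n4 eps))
    / (2 n4).  First-order series about eps = 0 are computed by regular
    perturbation of the quadratic: the branch through 0 is
    v = -(n2/n1) eps and the branch through -n1/n4 is
    v = -n1/n4 + (n2/n1 - n5/n4) eps.  When n4 = 0 the nontrivial branch is
    v = -n2 eps / (n1 + n5 eps).
    """
    n1, n2, _, n4, n5, _, _ = result.n
    h = result.h_expr()

    def mk(name, v_expr, v_ser):
        return Branch(name=name, v_exact=v_expr, v_series=v_ser,
                      u_on_manifold=sp.cancel(h.subs(v, v_expr))
                      if not v_expr.free_symbols - {eps} else h.subs(v, v_expr))

    trivial = Branch("trivial", sp.S.Zero, sp.S.Zero, sp.S.Zero)
    if n4 == 0 and n1 == 0:
        disc = sp.S.Zero
        return BifurcationBranches(branches=(trivial,), discriminant=disc,
                                   degenerate=True, result=result)
    if n4 == 0:
        v_expr = sp.cancel(-n2 * eps / (n1 + n5 * eps))
        ser = -n2 / n1 * eps
        return BifurcationBranches(
            branches=(trivial, mk("linear", v_expr, ser)),
            discriminant=(n1 + n5 * eps) ** 2, degenerate=False, result=result)

    lin = n1 + n5 * eps
    disc = lin**2 - 4 * n2 * n4 * eps
    root = sp.sqrt(disc)
    v_plus = (-lin + root) / (2 * n4)
    v_minus = (-lin - root) / (2 * n4)
    # regular perturbation: r0 = 0 and r0 = -n1/n4; which sign reaches which
    # r0 depends on sign(n1), so series are attached by value at eps = 0
    ser_zero = -n2 / n1 * eps
    ser_nontrivial = -n1 / n4 + (n2 / n1 - n5 / n4) * eps
    branches = [trivial]
    for name, v_expr in (("plus", v_plus), ("minus", v_minus)):
        at0 = v_expr.subs(eps, 0)
        if at0.free_symbols:
            through_zero = sp.simplify(sp.cancel(at0)) == 0
        else:
            # (-n1 +/- sqrt(n1^2)) / (2 n4): one root is 0 and the other is
            # -n1/n4; separate them by magnitude relative to the nonzero root
            through_zero = (abs(complex(sp.N(at0, 50)))
                            < abs(complex(sp.N(n1 / n4, 50))) / 2)
        ser = ser_zero if through_zero else ser_nontrivial
        branches.append(mk(name, v_expr, ser))
    return BifurcationBranches(branches=tuple(branches), discriminant=disc,
                               degenerate=False, result=result)


@dataclass(frozen=True)
class XSpaceBranch:
    name: str
    x_expr: sp.Expr
    z_expr: sp.Expr
    x_approx: sp.Expr      # the small-rate shorthand x ~ v
    x_discrepancy: sp.Expr  # exact x minus the shorthand


def back_transform(branches: BifurcationBranches,
                   transformed: TransformedSystem) -> tuple:
    """Map (u, v) branches back to fluctuation space via [l1 l2].

    Also reports the asymptotic shorthand x ~ v and its exact discrepancy
    x - v (which quantifies the quality of the small-rate approximation).
    """
    T = transformed.T
    out = []
    for br in branches.branches:
        uu, vv = br.u_on_manifold, br.v_exact
        x_expr = T[0, 0] * uu + T[0, 1] * vv
        z_expr = T[1, 0] * uu + T[1, 1] * vv
        out.append(XSpaceBranch(
            name=br.name,
            x_expr=x_expr,
            z_expr=z_expr,
            x_approx=vv,
            x_discrepancy=sp.expand(x_expr - vv),
        ))
    return tuple(out)


def center_manifold_reduction(params: ModelParams,
                              variant=Variant.paper_eq,
                              mode: str = "exact",
                              p_c=None) -> CenterManifoldResult:
    """End-to-end reduction: suspend, transform, solve the invariance equation."""
    system = build_suspended_system(params, p_c=p_c, variant=variant)
    transformed = transform_to_eigenbasis(system, mode=mode)
    return solve_invariance_equation(transformed)
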