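# Methods

## Model

Monomer cycles through three pools — activated/cofactor-bound `X`, oligomer-
bound `Y`, released `Z` — with a constant oligomer concentration `W` and
total monomer `M = X + Y + Z` conserved. Transport between pools uses
concentration-dependent diffusion coefficients, which after lumping leaves
the rate equations

```
dX/dt = −(D1 + a·X)·X·W' + p·Z − k·X + b(X)-terms      (addition to oligomer,
dY/dt = +(addition) − (D2-release)                       re-supply, release)
dZ/dt = k·X + (release) − p·Z
```

with lumped constants `D1, D2, a, b, c, d, k, p` (see `cmstab.params` for
the exact polynomial forms; `lump_parameters` maps microscopic rate and
diffusion constants onto them). `p` is the cofactor-supply rate and the
bifurcation parameter throughout.

## Steady state

Setting the rates to zero and eliminating with `X+Y+Z = M` gives the closed
form over the common denominator `den = D2·k + D2·p + D1·D2·W + D1·p·W`:

```
Xe = D2·M·p / den        Ye = D1·M·p·W / den        Ze = D2·M·(k + D1·W) / den
```

The three expressions sum to `M` identically, so conservation of the
reconstructed trajectories (`X = Xe + x`, `Y = Ye − x − z`, `Z = Ze + z`)
is exact by construction, not a numerical property.

## Fluctuation dynamics and variants

Fluctuations `(x, z)` about the steady state (with `y = −x − z`) obey

```
dx/dt = (−D1 + a·Xe − k)·x + (p − b·Xe)·z + a·x² − b·x·z
dz/dt = C·x − p·z + c·x² + (xz-term)
```

Two variants of the z-equation are carried side by side because the two
published statements of the model disagree: `paper_eq` uses
`C = k − c·Ye` and reuses `c` for the `x·z` coefficient; `fig2_code` uses
`C = k` and an independent coefficient `d`. All analysis functions take the
variant explicitly; nothing silently mixes them.

## Critical point

The steady state loses stability where `det L(p) = 0` with the steady state
recomputed at every trial `p` (freezing `Xe, Ye` at a reference `p` moves or
destroys the root — one test demonstrates this). Two implementations agree
to 1e-9:

- **Numeric**: plain bisection on the determinant sign change (the function
  is smooth and the bracket is cheap to scan), tolerance 1e-10.
- **Exact** (`critical_p_exact`): the determinant's numerator is a
  polynomial in `p` with `p = 0` always a root; factoring it out leaves a
  quadratic whose smallest positive root is taken exactly. All later
  symbolic work uses this root, so every coefficient lives in the real
  quadratic field `Q(√disc)` and vanishing statements are algebraic
  identities, not small floats.

Float inputs are converted with `Rational(repr(v))`, i.e. the exact rational
the decimal literal denotes.

## Center-manifold reduction

At `p = p_c` one eigenvalue of `L_c` is zero. The offset `ε = p − p_c` is
suspended as a state with `dε/dt = 0`; because the steady state is frozen at
`p_c`, `ε` enters only through the explicit `p` in the two `z`-coefficients,
contributing the forcing pair `(+ε·z, −ε·z)`. After transforming to
coordinates `(u, v)` that diagonalize the linear part (hyperbolic eigenvalue
`λ`, center eigenvalue 0), the cubic ansatz

```
u = h(v, ε) = a1 v² + a2 vε + a3 ε² + a4 v³ + a5 v²ε + a6 vε² + a7 ε³
```

is substituted into the invariance condition `du/dt = (∂h/∂v)·dv/dt`.
Collecting monomials of total degree ≤ 3 gives a *triangular* linear system:
each monomial's equation contains exactly one new unknown, multiplied by
`λ`, so the solve proceeds degree by degree with a single division each —
no matrix inversion, no global `solve`. Terms `u^i·h^i` with `i ≥ 2` are
`O(degree 4)` and dropped by the truncated coefficient bookkeeping. The full
(untruncated) residual of the invariance equation is then recomputed and
verified to contain no monomial below total degree 4.

Substituting `h` back into the `v`-equation yields the reduced dynamics
`dv/dt = n1 v² + n2 vε + n3 ε² + n4 v³ + n5 v²ε + n6 vε² + n7 ε³`; its
fixed-point branches (trivial, plus the two roots of the quadratic factor)
with first-order perturbation series give the bifurcation diagram, and the
branches are mapped back to `(x, z)` space through the transform columns.

### Two transform modes, and which coefficients vanish

This is the one place the package's exact computation and the published
analysis genuinely differ, so both constructions are implemented:

- **`exact`**: the true eigenbasis `T = [[B, B], [−p_c, −A]]` of
  `L_c = [[A, B], [C, −p_c]]`. In this basis the suspended field has no pure-ε
  forcing, so `a3 = a7 = 0` and `n3 = n7 = 0` identically. But `n6 ≠ 0`: the
  left center eigenvector is *not* orthogonal to the ε-forcing direction
  `(1, −1)`, so a `v·ε²` term survives in the reduced dynamics.
- **`paper_approx`**: the small-rate asymptotic transform
  `T = [[−a·Xe, 1], [a·Xe, 1]]`, valid when `D1, k, p ≪ a·Xe` (the regime in
  which the eigenvalues tend to `{a·Xe, 0}`). This matrix does not
  diagonalize the full `L_c`, so for self-consistency the linear part is
  replaced by its limit `diag(a·Xe, 0)`. Its center-row projection
  `(1/2)(1, 1)` annihilates the forcing pair `(+ε·z, −ε·z)` exactly, which
  is precisely why `n2 = n3 = n6 = n7 = 0` in this mode — the full published
  vanishing set. Both statements are proven with every parameter a free
  positive symbol (`generic_suspended_system`), not just for the presets.

So the published claim "`n3 = n6 = n7 = 0` independent of parameter values"
is reproduced *within the published small-rate construction*; under the
exact eigenbasis the correct statement is `n3 = n7 = 0`, `n6 ≠ 0`. The two
modes agree on the leading bifurcation structure (`n1, n4` signs and the
branch topology), since `n6` only perturbs the branches at `O(ε²)`.

## Numerical integration

`solve_ivp` with DOP853, `rtol = 1e-9`, `atol = 1e-12`, and the step size
capped at `min(t_max/50, 10)` so the dense-output interpolant on the uniform
reporting grid stays at interpolation error ~1e-13 relative (uncapped LSODA
dense output plateaus near 2.5e-7 and would dominate the error budget).
The system is non-stiff (eigenvalues `O(0.3)` and smaller). Integration
stops early — flagged divergent — once `|x|` or `|z|` exceeds `10·M`, where
the model has left its physical domain. A fully damped solution underflows
to exactly zero, making the RK error-norm ratio 0/0; the resulting benign
FP warnings are suppressed around the call.

Regime classification compares the maximum `|x|` envelope over the last
third of the window against the first third: ratio < 0.5 attenuated,
> 2 (or early termination) divergent, otherwise sustained.

## Problem sizes and runtimes (1 CPU)

- Steady state, classification, bisection for `p_c`: < 10 ms.
- Numeric-exact center-manifold reduction (preset coefficients in
  `Q(√disc)`): ~2 s per mode.
- Fully symbolic generic reduction (all parameters free symbols): ~25 s.
- Nine-trajectory sweep over `t ∈ [0, 3300]`: < 1 s total.
- Full test suite: ~2 min.
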