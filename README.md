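# cmstab — center-manifold stability analysis of protein-assembly kinetics

`cmstab` analyses a minimal kinetic model of cooperative protein assembly in
which a monomer cycles through three pools: an activated, cofactor-bound form
**X** that diffuses to and joins a growing oligomer, an oligomer-bound form
**Y**, and a released, inactive form **Z** that is re-activated by cofactor
supply. The distinctive feature of the model is *diffusion feedback*: the
transport coefficients that move monomer between the pools depend linearly on
the local concentrations, so the macroscopic rate equations pick up quadratic
terms. Total monomer is conserved, `X + Y + Z = M`.

The scientific question is the stability of the steady state against small
fluctuations as the cofactor supply rate `p` is varied. The package

1. computes the steady state `(Xe, Ye, Ze)` in closed form,
2. linearizes the fluctuation dynamics and classifies the `(trace, det)`
   regime of the 2×2 Jacobian `L(p)`,
3. locates the **critical supply** `p_c` where `det L(p) = 0`, i.e. where a
   zero eigenvalue appears and the steady state loses stability through a
   transcritical-type bifurcation,
4. performs a **symbolic center-manifold reduction** at `p_c` in exact
   arithmetic (rationals and radicals, no floats), yielding the manifold graph
   `u = h(v, ε)` with `ε = p − p_c` and the reduced one-dimensional dynamics
   `dv/dt = n1 v² + n2 vε + … + n7 ε³`, whose fixed-point branches describe
   the bifurcation, and
5. integrates the full nonlinear fluctuation system numerically to show
   damped oscillations below `p_c` and divergence above it.

## Worked example

```python
from cmstab import (PRESETS, steady_state, find_critical_p,
                    center_manifold_reduction)

params = PRESETS["fig2_code"]          # canonical oscillation parameter set

# steady state just above criticality
ss = steady_state(params.replace(p=0.011))
print(f"Xe={ss.Xe:.6g}  Ye={ss.Ye:.6g}  Ze={ss.Ze:.6g}  total={ss.total:.6g}")

# critical cofactor supply (bisection on det L(p) with p-dependent steady states)
cp = find_critical_p(params, "paper_eq", bracket=(0.001, 0.05))
print(f"p_c={cp.p_c:.12g}  residual={cp.residual:.3g}  iterations={cp.iterations}")

# exact symbolic reduction at p_c, in the small-rate (published) transform
res = center_manifold_reduction(params, "paper_eq", "paper_approx")
print("n (approx mode):", [f"{v:.6g}" for v in res.n_floats])
res2 = center_manifold_reduction(params, "paper_eq", "exact")
print("n (exact mode): ", [f"{v:.6g}" for v in res2.n_floats])
```

Output (verbatim):

```
Xe=0.0019951  Ye=0.0463136  Ze=0.0516913  total=0.1
p_c=0.010796942112  residual=1e-11  iterations=29
n (approx mode): ['-2.9', '0', '0', '1569.96', '-506.438', '0', '0']
n (exact mode):  ['772.401', '-20.099', '0', '2.14803e+09', '-7.95358e+07', '654014', '0']
```

`p_c` rounds to 0.011; `Xe(0.011)` rounds to 0.002. Note that which of the
ε-coefficients vanish depends on the coordinate transform: the small-rate
asymptotic transform kills `n2, n3, n6, n7`, whereas the exact eigenbasis of
the critical Jacobian leaves `n6 ≠ 0` (only `n3 = n7 = 0` are structural).
See [docs/methods.md](docs/methods.md) for why.

## Command line

Every analysis stage is exposed as a subcommand of `cmstab`
(`steady-state`, `classify`, `critical-point`, `sweep`, `simulate`, `fig2`,
`cmt`, `run-all`); all numeric output is fixed at 12 significant digits so
repeated runs are byte-identical. For example:

```
$ cmstab critical-point
{
  "bracket": [1e-06, 0.1],
  "eigenvalues": [[0.000586949351257, 0.0], [-2.42700988809e-10, 0.0]],
  "iterations": 30,
  "p_c": 0.0107969420684,
  "residual": 1.42453187918e-13,
  "variant": "paper_eq"
}

$ cmstab simulate --p 0.008 --out traj.csv
{
  "diverged": false,
  "envelope_ratio": 7.59268456648e-21,
  "n_peaks": 17,
  "out": "traj.csv",
  "regime": "attenuated"
}
```

(JSON shown abridged to one line per list; values are verbatim.)

`cmstab run-all --out run/` writes the full reproduction bundle: steady-state
and critical-point JSON, the stability sweep CSV, nine trajectory CSVs over
the canonical supply values `0.000 … 0.011`, and the center-manifold report
in both transform modes.

## Model variants and presets

Two published versions of the same model disagree in small ways; both are
implemented and explicit everywhere:

- **variant** `paper_eq` vs `fig2_code`: the z-equation's linear coupling is
  `(k − c·Ye)x` in the printed equations but plain `k·x` in the simulation
  code, and the `x·z` coefficient is `c` vs an independent `d`.
- **preset** `fig2_code` (`b=156, c=0.1, D2=0.012061855670103093`) vs
  `text_2017` (`b=150, c=0, D2=0.012`): the running-text and the
  figure-caption parameter lists. Only `fig2_code` reproduces the published
  critical point; `text_2017`'s root lies elsewhere (> 0.015).

## Reproduction

```
pytest -q                                        # full test suite (~2 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the headline quantities at runtime
(`t1` critical supply → 0.011, `t2` critical `Xe` → 0.002, `t3` manifold
coefficient `a3` → 0, `t4` max(|n3|,|n6|,|n7|) in the small-rate transform,
fully symbolic → 0, `t5` conserved total at `p=0.01` → 0.1).

The test suite is oracle-driven: analytic Jacobians are checked against
central differences over 1000 random parameter sets, trajectories against
matrix-exponential solutions in the linear regime, symbolic vanishing
statements are proven with free positive symbols rather than sampled
numerically, and the invariance-equation residual is verified to contain no
monomials below total degree 4.
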