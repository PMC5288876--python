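"""Parameter containers, steady states, and the full three-species kinetics.

The model tracks three interconverting monomer pools of a self-assembling
protein (tubulin/actin-like): the active, ATP/GTP-bound monomer ``X``, the
oligomer-incorporated monomer ``Y`` sitting at the end of a constant oligomer
pool ``W``, and the released, ADP/GDP-bound monomer ``Z``.  The cycle is

    X + W -> W + Y      (rate m1 = k1*DX, diffusion-limited addition)
    Y     -> Z          (rate m2 = k2*DY, release)
    Z + P -> X + P'     (rate k0, cofactor exchange; p = k0*P)
    X     -> Z          (rate k3 = k, slow direct hydrolysis)

Total monomer is conserved: X + Y + Z = M.  The lumped parameter set
(D1, D2, a, b, c, d, k, p, M, W) is the primary interface; the microscopic
set (k0..k3, DX, DY, DW, alpha..delta, ...) maps onto it via
:func:`lump_parameters`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Union

__all__ = [
    "MicroParams",
    "ModelParams",
    "SteadyState",
    "ParameterError",
    "DegenerateModelError",
    "lump_parameters",
    "steady_state",
    "full_rhs",
    "load_params",
    "save_params",
    "PRESETS",
]


class ParameterError(ValueError):
    """A parameter value violates its validity constraints."""


class DegenerateModelError(ValueError):
    """All rates vanish; the steady state is undefined."""


def _check_nonnegative(obj, names):
    for name in names:
        value = getattr(obj, name)
        if value < 0:
            raise ParameterError(f"parameter {name!r} must be nonnegative, got {value}")


@dataclass(frozen=True)
class MicroParams:
    """Microscopic rate, diffusion and feedback constants.

    Attributes
    ----------
    k0 : cofactor-exchange rate constant (1/(conc*time)).
    k1, k2 : proportionality coefficients tying the addition/release rates to
        the monomer diffusion coefficients (m1 = k1*DX, m2 = k2*DY).
    k3 : direct X -> Z conversion rate (1/time).
    DX, DY, DW : diffusion coefficients of X, Y and the oligomer (area/time).
        The oligomer is assumed slow (DW << DX, DY); violated values trigger a
        warning, not an error.
    P : active-cofactor (ATP/GTP) concentration, held constant by supply.
    W : oligomer concentration, constant.
    M : total monomer concentration.
    alpha, beta : concentration feedback on DX (dDX = alpha*x - beta*z).
    gamma, delta : concentration feedback on DZ (dDZ = gamma*x - delta*z).
        delta is retained in the container but dropped from the lumped
        dynamics (negligible when Z has low assembly activity).
    """

    k0: float
    k1: float
    k2: float
    k3: float
    DX: float
    DY: float
    DW: float
    P: float
    W: float
    M: float
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    delta: float = 0.0

    def __post_init__(self):
        _check_nonnegative(self, [f.name for f in fields(self)])
        if self.M <= 0:
            raise ParameterError(f"parameter 'M' must be positive, got {self.M}")
        if self.W <= 0:
            raise ParameterError(f"parameter 'W' must be positive, got {self.W}")
        if self.DW > 0 and (self.DW >= self.DX or self.DW >= self.DY):
            warnings.warn(
                "oligomer diffusion DW is not small relative to DX/DY; the "
                "diffusion-limited approximations m1 ~ k1*DX, m2 ~ k2*DY assume "
                "DW << DX, DY",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ModelParams:
    """Lumped kinetic parameters of the fluctuation system.

    D1 = k1*DX*W and D2 = k2*DY are the effective addition/release rates;
    a, b are the diffusion-feedback coefficients on x and z in dx/dt
    (a = D1*alpha, b = D1*beta); c = k2*gamma feeds back in dz/dt; d is an
    independent coefficient of the x*z term in dz/dt; k = k3 and p = k0*P.
    """

    D1: float
    D2: float
    a: float
    b: float
    c: float
    k: float
    p: float
    M: float
    W: float
    d: float = 0.0

    def __post_init__(self):
        _check_nonnegative(self, [f.name for f in fields(self)])
        if self.M <= 0:
            raise ParameterError(f"parameter 'M' must be positive, got {self.M}")
        if self.W <= 0:
            raise ParameterError(f"parameter 'W' must be positive, got {self.W}")

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        values = asdict(self)
        unknown = set(kwargs) - set(values)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        values.update(kwargs)
        return ModelParams(**values)


@dataclass(frozen=True)
class SteadyState:
    """Equilibrium concentrations (Xe, Ye, Ze); they sum to M exactly."""

    Xe: float
    Ye: float
    Ze: float

    @property
    def total(self) -> float:
        return self.Xe + self.Ye + self.Ze

    def as_array(self):
        import numpy as np

        return np.array([self.Xe, self.Ye, self.Ze])


def lump_parameters(micro: MicroParams) -> ModelParams:
    """Collapse microscopic constants into the lumped parameter set.

    D1 = k1*DX*W, D2 = k2*DY, a = k1*DX*W*alpha, b = k1*DX*W*beta,
    c = k2*gamma, k = k3, p = k0*P; d defaults to 0 (it has no microscopic
    counterpart).  Note the lumping of the feedback coefficients follows the
    lumped-interface convention (a = D1*alpha); dimensional bookkeeping of the
    microscopic feedback terms is ambiguous and the lumped set is taken as
    authoritative.
    """
    D1 = micro.k1 * micro.DX * micro.W
    return ModelParams(
        D1=D1,
        D2=micro.k2 * micro.DY,
        a=D1 * micro.alpha,
        b=D1 * micro.beta,
        c=micro.k2 * micro.gamma,
        d=0.0,
        k=micro.k3,
        p=micro.k0 * micro.P,
        M=micro.M,
        W=micro.W,
    )


def _denominator(params: ModelParams, p=None):
    p = params.p if p is None else p
    return (
        params.D2 * params.k
        + params.D2 * p
        + params.D1 * params.D2 * params.W
        + params.D1 * p * params.W
    )


def steady_state(params: ModelParams, p: float | None = None) -> SteadyState:
    """Equilibrium concentrations from the common-denominator closed forms.

        Xe = D2*M*p / den,  Ye = D1*M*p*W / den,  Ze = D2*M*(k + D1*W) / den,
        den = D2*k + D2*p + D1*D2*W + D1*p*W.

    The three numerators sum to M*den, so conservation Xe+Ye+Ze = M is an
    algebraic identity.  ``p`` may override the value stored in ``params``
    (used when sweeping the cofactor supply).
    """
    p = params.p if p is None else p
    den = _denominator(params, p)
    if den <= 0:
        raise DegenerateModelError(
            "steady-state denominator is zero: all rates vanish "
            f"(D1={params.D1}, D2={params.D2}, k={params.k}, p={p})"
        )
    return SteadyState(
        Xe=params.D2 * params.M * p / den,
        Ye=params.D1 * params.M * p * params.W / den,
        Ze=params.D2 * params.M * (params.k + params.D1 * params.W) / den,
    )


def full_rhs(state, params: ModelParams):
    """Right-hand side of the full three-species kinetics.

    dX/dt = -D1*W*X + p*Z - k*X
    dY/dt =  D1*W*X - D2*Y
    dZ/dt =  D2*Y - p*Z + k*X

    The addition flux carries the oligomer concentration W (monomer joins an
    oligomer at a rate proportional to both).  The three components sum to
    zero identically (total monomer conservation).
    """
    X, Y, Z = state
    addition = params.D1 * params.W * X
    dX = -addition + params.p * Z - params.k * X
    dY = addition - params.D2 * Y
    dZ = params.D2 * Y - params.p * Z + params.k * X
    return (dX, dY, dZ)


# ---------------------------------------------------------------------------
# Presets and JSON round-tripping
# ---------------------------------------------------------------------------

#: Named parameter sets.  ``fig2_code`` is the canonical oscillation preset
#: (the one whose critical cofactor level is ~0.011); ``text_2017`` is the
#: variant quoted in running text, which places the bifurcation elsewhere.
PRESETS: dict[str, ModelParams] = {
    "fig2_code": ModelParams(
        M=0.1,
        W=1.0,
        D1=0.28,
        D2=0.012061855670103093,
        a=150.0,
        b=156.0,
        k=0.005,
        c=0.1,
        d=0.0,
        p=0.01,
    ),
    "text_2017": ModelParams(
        M=0.1,
        W=1.0,
        D1=0.28,
        D2=0.012,
        a=150.0,
        b=150.0,
        k=0.005,
        c=0.0,
        d=0.0,
        p=0.01,
    ),
}

_MODEL_KEYS = {f.name for f in fields(ModelParams)}
_MICRO_KEYS = {f.name for f in fields(MicroParams)}


def load_params(source: Union[str, Path, dict]) -> Union[ModelParams, MicroParams]:
    """Load a parameter set from a flat JSON document (path or dict).

    The key set decides the schema: lumped keys (D1, D2, a, b, c, d, k, p,
    M, W) give a :class:`ModelParams`; microscopic keys give a
    :class:`MicroParams`.  Unknown keys are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = dict(source)
    if not isinstance(doc, dict):
        raise ParameterError("parameter document must be a JSON object")
    keys = set(doc)
    if keys <= _MODEL_KEYS:
        return ModelParams(**doc)
    if keys <= _MICRO_KEYS:
        return MicroParams(**doc)
    unknown = sorted(keys - (_MODEL_KEYS | _MICRO_KEYS))
    if unknown:
        raise ParameterError(f"unknown parameter keys: {unknown}")
    raise ParameterError(
        "parameter document mixes lumped and microscopic schemas; "
        f"keys = {sorted(keys)}"
    )


def save_params(params: Union[ModelParams, MicroParams], path: Union[str, Path]) -> None:
    """Write a parameter set as a flat JSON document with symbol-name keys."""
    with open(path, "w") as fh:
        json.dump(asdict(params), fh, indent=2, sort_keys=True)
        fh.write("\n")
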