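"""Two-dimensional fluctuation dynamics around the assembly steady state.

Writing X = Xe + x, Y = Ye + y, Z = Ze + z, total-monomer conservation gives
x + y + z = 0, so the fluctuation kinetics close in (x, z).  The nonlinearity
comes from the concentration dependence of the monomer diffusion coefficients
(dDX = alpha*x - beta*z, dDZ = gamma*x - delta*z): a concentration excess of
active monomer slows its own diffusion, which feeds back quadratically on the
assembly rate.

Two published variants of the (x, z) right-hand side are supported:

``fig2_code`` (default)
    dx/dt = (-D1 + a*Xe - k)*x + a*x^2 + (p - b*Xe)*z - b*x*z
    dz/dt = k*x + c*x^2 + d*x*z - p*z

``paper_eq``
    dx/dt identical;
    dz/dt = (k - c*Ye)*x - p*z + c*x^2 + c*x*z

The two coincide when c = d = 0.  The linear x-coefficient is
-D1 + a*Xe - k in both (the variant of the sign of k that is consistent with
the published Jacobian and simulation code).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .params import ModelParams, SteadyState

__all__ = ["FluctuationState", "Variant", "fluct_rhs", "linearize"]


class Variant(str, Enum):
    """Which published form of the fluctuation right-hand side to use."""

    paper_eq = "paper_eq"
    fig2_code = "fig2_code"

    @classmethod
    def coerce(cls, value) -> "Variant":
        try:
            return cls(value)
        except ValueError:
            raise ValueError(
                f"unknown model variant {value!r}; expected one of "
                f"{[v.value for v in cls]}"
            ) from None


@dataclass(frozen=True)
class FluctuationState:
    """Fluctuations (x, z); y = -x - z follows from conservation."""

    x: float
    z: float

    @property
    def y(self) -> float:
        return -self.x - self.z


def _coerce_xz(state):
    if isinstance(state, FluctuationState):
        return state.x, state.z
    x, z = state
    return x, z


def fluct_rhs(state, params: ModelParams, steady: SteadyState,
              variant=Variant.fig2_code):
    """Right-hand side (dx/dt, dz/dt) of the fluctuation system.

    ``steady`` must be the steady state of ``params`` (the origin is then a
    fixed point for every p).  ``state`` is an (x, z) pair or a
    :class:`FluctuationState`.
    """
    variant = Variant.coerce(variant)
    x, z = _coerce_xz(state)
    Xe = steady.Xe
    dx = (-params.D1 + params.a * Xe - params.k) * x \
        + params.a * x * x \
        + (params.p - params.b * Xe) * z \
        - params.b * x * z
    if variant is Variant.fig2_code:
        dz = params.k * x + params.c * x * x + params.d * x * z - params.p * z
    else:
        dz = (params.k - params.c * steady.Ye) * x - params.p * z \
            + params.c * x * x + params.c * x * z
    return (dx, dz)


def linearize(params: ModelParams, steady: SteadyState,
              variant=Variant.fig2_code) -> np.ndarray:
    """Jacobian of :func:`fluct_rhs` at the origin.

        L = [[-D1 + a*Xe - k,  -b*Xe + p],
             [k - c*Ye,        -p       ]]   (paper_eq)

    For the ``fig2_code`` variant the (2,1) entry is plain ``k`` (its
    feedback enters through the independent x*z coefficient ``d``, which is
    quadratic and drops out of the linearization).
    """
    variant = Variant.coerce(variant)
    Xe, Ye = steady.Xe, steady.Ye
    a11 = -params.D1 + params.a * Xe - params.k
    a12 = -params.b * Xe + params.p
    a21 = params.k - params.c * Ye if variant is Variant.paper_eq else params.k
    a22 = -params.p
    return np.array([[a11, a12], [a21, a22]], dtype=float)
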