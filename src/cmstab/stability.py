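"""Eigenvalue classification and the critical cofactor concentration.

The fluctuation Jacobian L(p) depends on the cofactor-supply level p both
explicitly (the z-column) and through the steady state Xe(p), Ye(p).  The
critical supply p_c is the root of det L(p) = 0: below it the steady state is
linearly stable and concentration fluctuations are damped; above it the
fluctuations grow (the onset of assembly/disassembly oscillation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluctuation import Variant, linearize
from .params import ModelParams, steady_state

__all__ = [
    "StabilityReport",
    "CriticalPoint",
    "NoCriticalPointError",
    "classify",
    "find_critical_p",
    "sweep",
]

REGIMES = (
    "stable_node",
    "stable_spiral",
    "unstable_node",
    "unstable_spiral",
    "saddle",
    "center_degenerate",
)


class NoCriticalPointError(ValueError):
    """det L(p) does not change sign on the supplied bracket."""


@dataclass(frozen=True)
class StabilityReport:
    p: float
    jacobian: np.ndarray
    trace: float
    det: float
    discriminant: float
    eigenvalues: tuple[complex, complex]
    regime: str
    variant: str

    def as_row(self) -> dict:
        l1, l2 = self.eigenvalues
        return {
            "p": self.p,
            "trace": self.trace,
            "det": self.det,
            "discriminant": self.discriminant,
            "re_lambda1": l1.real,
            "im_lambda1": l1.imag,
            "re_lambda2": l2.real,
            "im_lambda2": l2.imag,
            "regime": self.regime,
        }


@dataclass(frozen=True)
class CriticalPoint:
    p_c: float
    bracket: tuple[float, float]
    residual: float
    eigenvalues: tuple[complex, complex]
    iterations: int
    variant: str


def _eigenvalues_2x2(trace: float, det: float):
    """Closed-form eigenvalues of a 2x2 matrix from its trace/determinant."""
    disc = trace * trace - 4.0 * det
    if disc >= 0.0:
        s = np.sqrt(disc)
        return ((trace + s) / 2.0 + 0.0j, (trace - s) / 2.0 + 0.0j)
    s = np.sqrt(-disc)
    return (complex(trace / 2.0, s / 2.0), complex(trace / 2.0, -s / 2.0))


def _label(trace: float, det: float, disc: float) -> str:
    if det == 0.0 or (det > 0.0 and trace == 0.0):
        return "center_degenerate"
    if det < 0.0:
        return "saddle"
    kind = "spiral" if disc < 0.0 else "node"
    side = "stable" if trace < 0.0 else "unstable"
    return f"{side}_{kind}"


def classify(params: ModelParams, variant=Variant.paper_eq,
             p: float | None = None) -> StabilityReport:
    """Stability report of the fluctuation Jacobian at the given p.

    The steady state is recomputed at ``p`` (default: the value stored in
    ``params``) before building the Jacobian, so sweeping p moves both the
    explicit entries and Xe(p), Ye(p).
    """
    variant = Variant.coerce(variant)
    p = params.p if p is None else float(p)
    at_p = params.replace(p=p)
    L = linearize(at_p, steady_state(at_p), variant)
    trace = float(L[0, 0] + L[1, 1])
    det = float(L[0, 0] * L[1, 1] - L[0, 1] * L[1, 0])
    disc = trace * trace - 4.0 * det
    return StabilityReport(
        p=p,
        jacobian=L,
        trace=trace,
        det=det,
        discriminant=disc,
        eigenvalues=_eigenvalues_2x2(trace, det),
        regime=_label(trace, det, disc),
        variant=variant.value,
    )


def det_at(params: ModelParams, p: float, variant=Variant.paper_eq) -> float:
    """det L(p) with the steady state recomputed at p."""
    at_p = params.replace(p=p)
    L = linearize(at_p, steady_state(at_p), variant)
    return float(L[0, 0] * L[1, 1] - L[0, 1] * L[1, 0])


def find_critical_p(params: ModelParams, variant=Variant.paper_eq,
                    bracket=(1e-6, 0.1), tol: float = 1e-10,
                    max_iter: int = 200) -> CriticalPoint:
    """Bisection root of det L(p) = 0 on ``bracket``.

    Bisection is guaranteed to converge under the sign-change precondition
    and is deterministic; ``tol`` bounds the final bracket width.  Raises
    :class:`NoCriticalPointError` (listing det at both ends) when the
    determinant does not change sign on the bracket.
    """
    variant = Variant.coerce(variant)
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError(f"invalid bracket {bracket}")
    f_lo = det_at(params, lo, variant)
    f_hi = det_at(params, hi, variant)
    if f_lo == 0.0:
        root, n_iter = lo, 0
    elif f_hi == 0.0:
        root, n_iter = hi, 0
    elif f_lo * f_hi > 0.0:
        raise NoCriticalPointError(
            f"no critical point in range [{lo}, {hi}]: det L has the same "
            f"sign at both ends (det({lo}) = {f_lo:.6g}, "
            f"det({hi}) = {f_hi:.6g})"
        )
    else:
        n_iter = 0
        while hi - lo > tol and n_iter < max_iter:
            mid = 0.5 * (lo + hi)
            f_mid = det_at(params, mid, variant)
            if f_mid == 0.0:
                lo = hi = mid
                break
            if f_lo * f_mid < 0.0:
                hi = mid
            else:
                lo, f_lo = mid, f_mid
            n_iter += 1
        root = 0.5 * (lo + hi)
    residual = abs(det_at(params, root, variant))
    report = classify(params, variant, p=root)
    return CriticalPoint(
        p_c=root,
        bracket=(float(bracket[0]), float(bracket[1])),
        residual=residual,
        eigenvalues=report.eigenvalues,
        iterations=n_iter,
        variant=variant.value,
    )


def sweep(params: ModelParams, p_values, variant=Variant.paper_eq) -> pd.DataFrame:
    """One stability report per p value, as a DataFrame sorted by p.

    Duplicated p values yield duplicated identical rows; an empty list yields
    an empty table with the standard columns.
    """
    rows = [classify(params, variant, p=p).as_row() for p in p_values]
    columns = ["p", "trace", "det", "discriminant",
               "re_lambda1", "im_lambda1", "re_lambda2", "im_lambda2", "regime"]
    frame = pd.DataFrame(rows, columns=columns)
    return frame.sort_values("p", kind="stable").reset_index(drop=True)
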