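"""Time integration of the fluctuation dynamics and regime diagnostics.

Trajectories start from a small seed perturbation (x0 = z0 = 1e-6 by
default) and are integrated with an adaptive stiff-capable solver.  Absolute
concentrations are reconstructed as X = Xe + x, Y = Ye - x - z, Z = Ze + z,
so total monomer X + Y + Z = M holds exactly by construction.  A trajectory
is classified by its amplitude envelope: damped below the critical cofactor
supply, growing (eventually beyond physical meaning) above it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .fluctuation import Variant, fluct_rhs
from .params import ModelParams, SteadyState, steady_state
from .stability import classify

__all__ = [
    "Trajectory",
    "RegimeDiagnosis",
    "InsufficientDataError",
    "integrate",
    "diagnose",
    "reproduce_fig2",
    "FIG2_P_VALUES",
]

#: the nine cofactor-supply levels of the published oscillation sweep
FIG2_P_VALUES = (0.0, 0.001, 0.002, 0.004, 0.008, 0.009, 0.01, 0.010705, 0.011)

#: fluctuations larger than this multiple of the total monomer pool have left
#: the model's domain of validity; integration stops and the run is flagged
DIVERGENCE_CEILING_FACTOR = 10.0


class InsufficientDataError(ValueError):
    """Trajectory too short to support a regime diagnosis."""


@dataclass(frozen=True)
class Trajectory:
    t: np.ndarray
    x: np.ndarray
    z: np.ndarray
    params: ModelParams
    steady: SteadyState
    variant: str
    diverged: bool
    failure_time: float | None
    rtol: float
    atol: float

    @property
    def y(self) -> np.ndarray:
        return -self.x - self.z

    @property
    def X(self) -> np.ndarray:
        return self.steady.Xe + self.x

    @property
    def Y(self) -> np.ndarray:
        return self.steady.Ye + self.y

    @property
    def Z(self) -> np.ndarray:
        return self.steady.Ze + self.z

    def param_hash(self) -> str:
        doc = json.dumps(
            {**{k: getattr(self.params, k)
                for k in ("D1", "D2", "a", "b", "c", "d", "k", "p", "M", "W")},
             "variant": self.variant}, sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "x": self.x, "z": self.z, "y": self.y,
            "X": self.X, "Y": self.Y, "Z": self.Z,
        })

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# params_hash={self.param_hash()} variant={self.variant} "
                     f"p={self.params.p:.12g}\n")
            self.to_frame().to_csv(fh, index=False,
                                   float_format="%.12g", lineterminator="\n")


@dataclass(frozen=True)
class RegimeDiagnosis:
    label: str  # attenuated | sustained | divergent
    envelope_ratio: float
    peak_times: np.ndarray
    divergence_time: float | None


def integrate(params: ModelParams, variant=Variant.fig2_code,
              x0: float = 1e-6, z0: float = 1e-6, t_max: float = 3300.0,
              rtol: float = 1e-9, atol: float = 1e-12,
              n_report: int = 2000, method: str = "DOP853",
              max_step: float | None = None) -> Trajectory:
    """Integrate the fluctuation system from (x0, z0) over [0, t_max].

    Uses an adaptive high-order solver (DOP853 by default; the eigenvalues
    here are all O(0.3) or smaller, so the system is not stiff — pass
    ``method="Radau"`` or ``"LSODA"`` for stiff parameter regimes) with dense
    output resampled on a uniform reporting grid.  The step size is capped so
    the dense-output interpolant stays accurate between steps.  Integration
    stops early, with the divergence flag set, if |x| or |z| exceeds
    ``DIVERGENCE_CEILING_FACTOR * M`` or the solver fails; the partial
    trajectory up to the failure time is returned.
    """
    variant = Variant.coerce(variant)
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    steady = steady_state(params)
    ceiling = DIVERGENCE_CEILING_FACTOR * params.M

    def rhs(t, state):
        return fluct_rhs(state, params, steady, variant)

    def blow_up(t, state):
        return max(abs(state[0]), abs(state[1])) - ceiling

    blow_up.terminal = True
    blow_up.direction = 1

    if max_step is None:
        max_step = min(t_max / 50.0, 10.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        # the error-norm ratio inside the RK controller is 0/0 once a fully
        # damped trajectory underflows to exactly zero; the step is still valid
        sol = solve_ivp(rhs, (0.0, t_max), [x0, z0], method=method,
                        rtol=rtol, atol=atol, dense_output=True,
                        events=blow_up, max_step=max_step)
    t_end = sol.t[-1]
    diverged = bool(sol.t_events[0].size) or (sol.status < 0)
    failure_time = t_end if (diverged or t_end < t_max) else None

    t_grid = np.linspace(0.0, t_end, n_report)
    xs, zs = sol.sol(t_grid)
    return Trajectory(t=t_grid, x=xs, z=zs, params=params, steady=steady,
                      variant=variant.value, diverged=diverged,
                      failure_time=failure_time, rtol=rtol, atol=atol)


def diagnose(traj: Trajectory, attenuation_threshold: float = 0.5,
             divergence_threshold: float = 2.0) -> RegimeDiagnosis:
    """Classify a trajectory by its amplitude envelope.

    The envelope ratio r compares max |x| over the last third of the window
    with max |x| over the first third; r < ``attenuation_threshold`` labels
    the run attenuated, r > ``divergence_threshold`` (or an early-terminated
    integration) divergent, anything in between sustained.
    """
    n = traj.t.size
    if n < 16:
        raise InsufficientDataError(
            f"insufficient data: only {n} samples; need at least 16")
    third = n // 3
    early = float(np.max(np.abs(traj.x[:third])))
    late = float(np.max(np.abs(traj.x[-third:])))
    if early == 0.0:
        raise InsufficientDataError(
            "insufficient data: zero fluctuation amplitude in the early window")
    ratio = late / early
    peaks, _ = find_peaks(traj.x)
    peak_times = traj.t[peaks]
    if traj.diverged:
        label = "divergent"
    elif ratio > divergence_threshold:
        label = "divergent"
    elif ratio < attenuation_threshold:
        label = "attenuated"
    else:
        label = "sustained"
    return RegimeDiagnosis(label=label, envelope_ratio=ratio,
                           peak_times=peak_times,
                           divergence_time=traj.failure_time
                           if traj.diverged else None)


def reproduce_fig2(params: ModelParams, p_values=FIG2_P_VALUES,
                   variant=Variant.fig2_code, out_dir=None,
                   plot: bool = False, t_max: float = 3300.0,
                   plot_window: float = 1000.0, **integrate_kwargs):
    """Sweep the cofactor supply over the published nine values.

    Returns (trajectories, summary DataFrame).  With ``out_dir`` set, writes
    one trajectory CSV per p plus a sweep summary CSV; with ``plot`` also a
    PNG of X, Y, Z over the reporting window for each p.
    """
    trajectories = []
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for p in p_values:
        at_p = params.replace(p=float(p))
        traj = integrate(at_p, variant=variant, t_max=t_max, **integrate_kwargs)
        diag = diagnose(traj)
        report = classify(at_p, variant)
        trajectories.append(traj)
        rows.append({
            "p": float(p),
            "regime": diag.label,
            "envelope_ratio": diag.envelope_ratio,
            "n_peaks": int(diag.peak_times.size),
            "eigen_regime": report.regime,
        })
        if out_dir is not None:
            traj.write_csv(out_dir / f"trajectory_p{p:.6f}.csv")
            if plot:
                _plot_concentrations(traj, plot_window,
                                     out_dir / f"fig2_p{p:.6f}.png")
    summary = pd.DataFrame(rows)
    if out_dir is not None:
        summary.to_csv(out_dir / "sweep_summary.csv", index=False,
                       float_format="%.12g", lineterminator="\n")
    return trajectories, summary


def _plot_concentrations(traj: Trajectory, window: float, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mask = traj.t <= window
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(traj.t[mask], traj.X[mask], color="black", lw=0.8, label="X")
    ax.plot(traj.t[mask], traj.Y[mask], color="red", lw=0.8, label="Y")
    ax.plot(traj.t[mask], traj.Z[mask], color="blue", lw=0.8, label="Z")
    ax.set_xlabel("time")
    ax.set_ylabel("concentration")
    ax.set_title(f"p = {traj.params.p:g}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
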