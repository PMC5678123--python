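"""Simulation engine: integration, observables, and timing readouts.

Produces :class:`Trajectory` objects on a dense (default 0.1 min) grid,
detects the switch-like aPKC activation/deactivation and the IRS1/Akt
rebound, and computes windowed AUC statistics of any state or observable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .integrate import integrate_fast, rhs_kernel
from .model import (
    ModelState,
    ModelVariant,
    ParameterSet,
    STATE_NAMES,
    pack_parameters,
)
from .profiles import InsulinProfile

__all__ = [
    "Trajectory",
    "SwitchEvents",
    "SolverFailure",
    "basal_state",
    "simulate",
    "detect_switch_events",
    "windowed_auc",
]

_STATE_INDEX = {n: i for i, n in enumerate(STATE_NAMES)}

#: observable name -> (state variable, scaling factor name); aPKC was never
#: measured in the underlying experiments, so it is reported unscaled
OBSERVABLE_MAP = {
    "IRS1": ("irs1", "s_IRS1"),
    "IRS2": ("irs2", "s_IRS2"),
    "Akt_feed": ("akt", "s_Akt_feed"),
    "Akt_inf": ("akt", "s_Akt_inf"),
    "aPKC": ("pkc", None),
}


class SolverFailure(RuntimeError):
    """Integration failed; carries the parameter set and failure time."""

    def __init__(self, message, params=None, t_fail=None):
        super().__init__(message)
        self.params = params
        self.t_fail = t_fail


@dataclass
class Trajectory:
    """Solver output: dense state grid plus scaled observables."""

    times: np.ndarray
    states: np.ndarray  # (n_times, 8), columns per STATE_NAMES
    observables: dict[str, np.ndarray]
    insulin: np.ndarray | None = None

    def state(self, name: str) -> np.ndarray:
        return self.states[:, _STATE_INDEX[name]]

    def series(self, name: str) -> np.ndarray:
        """A state variable or observable by name."""
        if name in _STATE_INDEX:
            return self.state(name)
        if name in self.observables:
            return self.observables[name]
        raise KeyError(f"unknown variable {name!r}")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def to_frame(self):
        """Tidy (time_min, variable, value) table of states and observables."""
        import pandas as pd

        frames = []
        for name in STATE_NAMES:
            frames.append(
                pd.DataFrame(
                    {"time_min": self.times, "variable": name, "value": self.state(name)}
                )
            )
        for name, vals in self.observables.items():
            frames.append(
                pd.DataFrame({"time_min": self.times, "variable": name, "value": vals})
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class SwitchEvents:
    """Timing readouts (minutes); absent events are ``None``."""

    pkc_on: float | None = None
    pkc_off: float | None = None
    irs1_rebound: float | None = None
    akt_rebound: float | None = None

    def to_json(self) -> dict:
        return {
            "pkc_on": self.pkc_on,
            "pkc_off": self.pkc_off,
            "irs1_rebound": self.irs1_rebound,
            "akt_rebound": self.akt_rebound,
        }


def basal_state(
    params: ParameterSet, variant: ModelVariant, relax_min: float = 0.0
) -> ModelState:
    """Zero-insulin steady state.

    With insulin identically zero the model has an exact fixed point for
    every variant: all activities vanish and the IRS2 pool sits at its
    synthesis/degradation balance k_s2/k_deg (Akt = 0 lifts the
    transcriptional brake).  ``relax_min`` > 0 additionally integrates the
    model at zero insulin from that point, as a polish for custom kinetics.
    """
    k = params.kinetic
    y = ModelState(irs2_tot=k["k_s2"] / k["k_deg"])
    if relax_min > 0:
        p = pack_parameters(params, variant)
        _, states = integrate_fast(
            y.to_array(), relax_min, lambda t: np.zeros_like(t), p, grid_dt=relax_min
        )
        y = ModelState.from_array(states[-1])
    return y


def simulate(
    variant: ModelVariant,
    params: ParameterSet,
    insulin: InsulinProfile,
    t_end: float | None = None,
    init: ModelState | str = "basal",
    solver: str = "lsoda",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    grid_dt: float = 0.1,
    rk4_dt: float = 0.01,
    input_scale: float = 1.0,
    apply_amplitude: bool = True,
) -> Trajectory:
    """Integrate the model under an insulin profile from t = 0 to ``t_end``.

    The profile template is multiplied by the variant's fitted input
    amplitude (``a_feed`` or ``a_inf``, chosen by the profile's family) and
    by ``input_scale`` (the dose perturbation used for mAICc).  ``solver``
    is ``"lsoda"`` (stiff-capable, dense output) or ``"rk4"`` (the fast
    fixed-step path used inside fitting).
    """
    p = pack_parameters(params, variant)
    if t_end is None:
        t_end = insulin.span[1]
    if t_end > insulin.span[1] + 1e-9:
        raise ValueError(
            f"t_end={t_end} outside insulin profile span {insulin.span}"
        )
    amp = params.kinetic[insulin.amplitude_param] if apply_amplitude else 1.0
    amp *= input_scale

    def drive(t):
        return amp * insulin.evaluate(t)

    y0 = basal_state(params, variant) if init == "basal" else init
    y0_arr = y0.to_array()

    if solver == "rk4":
        times, states = integrate_fast(y0_arr, t_end, drive, p, dt=rk4_dt, grid_dt=grid_dt)
    elif solver == "lsoda":
        t_eval = np.arange(0.0, t_end + grid_dt / 2, grid_dt)
        sol = solve_ivp(
            lambda t, y: rhs_kernel(y, drive(t), p),
            (0.0, float(t_end)),
            y0_arr,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            max_step=1.0,
        )
        if not sol.success:
            raise SolverFailure(
                f"LSODA failed at t={sol.t[-1] if sol.t.size else 0.0:.2f} min: "
                f"{sol.message}",
                params=params,
                t_fail=float(sol.t[-1]) if sol.t.size else 0.0,
            )
        times, states = sol.t, sol.y.T
    else:
        raise ValueError(f"unknown solver {solver!r}")

    if not np.all(np.isfinite(states)):
        bad = np.argmax(~np.isfinite(states).all(axis=1))
        raise SolverFailure(
            f"non-finite state at t={times[bad]:.2f} min",
            params=params,
            t_fail=float(times[bad]),
        )

    observables = {}
    for name, (state_name, scale_name) in OBSERVABLE_MAP.items():
        scale = params.scaling[scale_name] if scale_name else 1.0
        observables[name] = scale * states[:, _STATE_INDEX[state_name]]
    return Trajectory(times, states, observables, insulin=drive(times))


def _first_sustained(mask, times, min_len, start=0):
    """Index of the first contiguous True run sustained for ``min_len``
    minutes (a run reaching the final sample counts as sustained)."""
    i, n = start, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if times[j] - times[i] >= min_len or j == n - 1:
                return i
            i = j + 1
        else:
            i += 1
    return None


def _rebound_time(
    times: np.ndarray, x: np.ndarray, confirm_frac: float, smooth_min: float
) -> float | None:
    """Time of the global minimum between the first activity peak and the end,
    confirmed by a subsequent rise of at least ``confirm_frac`` of the range."""
    rng = float(x.max() - x.min())
    if rng <= 0:
        return None
    # light smoothing so 5-min input ripple does not spawn spurious peaks
    dt = times[1] - times[0]
    w = max(1, int(round(smooth_min / dt)))
    if w > 1:
        kernel = np.ones(w) / w
        # reflect-pad so the moving average has no edge droop
        xp = np.concatenate([x[w - 1 : 0 : -1], x, x[-2 : -w - 1 : -1]])
        xs = np.convolve(xp, kernel, mode="same")[w - 1 : w - 1 + len(x)]
    else:
        xs = x
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(xs, prominence=0.05 * rng)
    if len(peaks) == 0:
        return None
    i_peak = peaks[0]
    seg = xs[i_peak:]
    i_min = i_peak + int(np.argmin(seg))
    if i_min >= len(x) - 1:
        return None
    if xs[i_min:].max() - xs[i_min] < confirm_frac * rng:
        return None
    return float(times[i_min])


def detect_switch_events(
    traj: Trajectory,
    persistence: float = 5.0,
    threshold_frac: float = 0.5,
    rebound_confirm_frac: float = 0.05,
    rebound_smooth_min: float = 2.5,
) -> SwitchEvents:
    """Extract aPKC switch-on/off and IRS1/Akt rebound times.

    aPKC switch-on is the first upward crossing of ``threshold_frac`` of the
    trajectory's aPKC maximum sustained for at least ``persistence`` minutes;
    switch-off is the first subsequent sustained downward crossing.  A
    rebound of IRS1/Akt is the global minimum between the variable's first
    activity peak and the end of the trajectory, provided the variable
    subsequently rises by at least ``rebound_confirm_frac`` of its range.
    """
    if traj.span[1] - traj.span[0] < 30.0:
        raise ValueError("trajectory must cover at least 30 min")
    times = traj.times
    pkc = traj.state("pkc")
    events = SwitchEvents()

    pmax = float(pkc.max())
    if pmax > 0:
        thr = threshold_frac * pmax
        above = pkc >= thr
        i_on = _first_sustained(above, times, persistence)
        if i_on is not None:
            events.pkc_on = float(times[i_on])
            below = ~above
            i_off = _first_sustained(below, times, persistence, start=i_on + 1)
            if i_off is not None:
                events.pkc_off = float(times[i_off])

    events.irs1_rebound = _rebound_time(
        times, traj.state("irs1"), rebound_confirm_frac, rebound_smooth_min
    )
    events.akt_rebound = _rebound_time(
        times, traj.state("akt"), rebound_confirm_frac, rebound_smooth_min
    )
    return events


def windowed_auc(
    traj: Trajectory, variable: str, window: tuple[float, float]
) -> float:
    """Trapezoidal AUC of a state/observable over ``window`` (minutes)."""
    t_a, t_b = window
    lo, hi = traj.span
    if t_a < lo - 1e-9 or t_b > hi + 1e-9 or t_b <= t_a:
        raise ValueError(f"window {window} outside trajectory span {traj.span}")
    x = traj.series(variable)
    times = traj.times
    mask = (times >= t_a) & (times <= t_b)
    t_seg = times[mask]
    x_seg = x[mask]
    # interpolate exact endpoints so the window bounds are honoured
    if t_seg.size == 0 or t_seg[0] > t_a:
        t_seg = np.insert(t_seg, 0, t_a)
        x_seg = np.insert(x_seg, 0, np.interp(t_a, times, x))
    if t_seg[-1] < t_b:
        t_seg = np.append(t_seg, t_b)
        x_seg = np.append(x_seg, np.interp(t_b, times, x))
    return float(np.trapezoid(x_seg, t_seg))
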