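"""Pre-hepatic insulin input profiles.

All profiles are continuous, non-negative functions of time (minutes) in
dimensionless template units; the model's fitted input amplitudes (``a_feed``
for feeding-type inputs, ``a_inf`` for portal-vein infusion inputs) convert
them to the drive seen by the receptor.  Discretization is the solver's
concern.

The menu:

* ``feeding``: smooth unimodal postprandial curve on [0, 120] min peaking at
  30 min, decaying to an elevated plateau (~2x basal) at 120 min.
* ``pulsatile_high`` / ``constant_high`` / ``T2D_a``: portal-vein infusion
  templates — an offset sinusoid with 5-min period, the equal-dose constant
  level, and the same sinusoid at a reduced (default 1/3) amplitude mimicking
  impaired pulsatility in type-2 diabetes.
* ``normal_fp`` / ``impaired_slope`` / ``T2D_b``: first-phase secretion shapes
  on [0, 180] min (bump plus second-phase plateau) renormalized to identical
  area under the curve (AUC).
* ``composite_pulsatile``: a 5-min sinusoidal carrier superimposed on any base
  profile at a chosen relative pulse amplitude, renormalized to the base AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "InsulinProfile",
    "feeding_profile",
    "infusion_profile",
    "first_phase_profile",
    "composite_pulsatile",
    "by_label",
    "PULSE_PERIOD_MIN",
]

#: portal-vein insulin pulse period (minutes)
PULSE_PERIOD_MIN = 5.0

#: quadrature grid spacing for AUC bookkeeping (min)
_AUC_DT = 0.005

#: which fitted input amplitude applies to which profile family
_FEEDING_LABELS = {
    "feeding", "normal_fp", "impaired_slope", "T2D_b",
    "pulse_high_amp", "pulse_low_amp", "T2D_c", "custom",
}
_INFUSION_LABELS = {"pulsatile_high", "constant_high", "T2D_a"}


def _quad_grid(t0: float, t1: float) -> np.ndarray:
    n = max(2, int(round((t1 - t0) / _AUC_DT)) + 1)
    return np.linspace(t0, t1, n)


@dataclass(frozen=True)
class InsulinProfile:
    """A time-parameterized insulin input with AUC accounting."""

    label: str
    span: tuple[float, float]
    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, t):
        return self.evaluate(t)

    def evaluate(self, t):
        """Insulin level at time ``t`` (scalar or array, minutes)."""
        t_arr = np.asarray(t, dtype=float)
        out = np.asarray(self.fn(t_arr), dtype=float)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    @property
    def auc(self) -> float:
        """Area under the curve over the span (template units * min)."""
        grid = _quad_grid(*self.span)
        return float(np.trapezoid(self.fn(grid), grid))

    @property
    def amplitude_param(self) -> str:
        """Name of the fitted input amplitude this profile is scaled by."""
        return "a_inf" if self.label in _INFUSION_LABELS else "a_feed"

    def scaled(self, factor: float, label: str | None = None) -> "InsulinProfile":
        """Pointwise multiple of this profile (AUC scales by ``factor``)."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        base_fn = self.fn
        return InsulinProfile(
            label or self.label, self.span, lambda t: factor * base_fn(t)
        )

    def to_frame(self, dt: float = 0.1):
        """Two-column table (time_min, insulin) for export."""
        import pandas as pd

        t = np.arange(self.span[0], self.span[1] + dt / 2, dt)
        return pd.DataFrame({"time_min": t, "insulin": self.fn(t)})


def feeding_profile(scale: float = 1.0) -> InsulinProfile:
    """Postprandial pre-hepatic insulin template on [0, 120] min.

    A log-Gaussian rise-and-decay over a basal offset: basal 0.1, peak 1.0 at
    exactly t = 30 min, and an elevated tail (~2x basal at 120 min), emulating
    serum insulin that peaks 30 min after refeeding.  ``scale`` multiplies the
    whole curve (0.85 / 1.0 / 1.15 are the dose-response settings).
    """
    if not scale > 0:
        raise ValueError("scale must be > 0")
    basal, amp, t_peak, sigma = 0.1, 0.9, 30.0, 0.6614
    # sigma chosen so the curve sits at ~2x basal at 120 min

    def fn(t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            logr = np.where(t > 0, np.log(np.maximum(t, 1e-300) / t_peak), -np.inf)
        bump = np.exp(-(logr**2) / (2.0 * sigma**2))
        return scale * (basal + amp * bump)

    return InsulinProfile("feeding", (0.0, 120.0), fn)


def infusion_profile(
    mode: str,
    duration: float = 30.0,
    amplitude: float = 1.0,
    t2d_fraction: float = 1.0 / 3.0,
) -> InsulinProfile:
    """Portal-vein infusion templates.

    ``pulsatile_high``: A*(1 + sin(2*pi*t/T - pi/2))/2 with T = 5 min (starts
    at the trough, so infusion begins at zero).  ``constant_high``: the equal-
    AUC constant level A/2.  ``T2D_a``: the same sinusoid at the reduced
    amplitude fraction ``t2d_fraction`` (default 1/3), mimicking the damped
    insulin pulses of type-2 diabetes.
    """
    if duration < 30.0:
        raise ValueError("infusion duration must be >= 30 min")
    omega = 2.0 * np.pi / PULSE_PERIOD_MIN
    if mode == "pulsatile_high":
        fn = lambda t: amplitude * (1.0 + np.sin(omega * np.asarray(t) - np.pi / 2)) / 2.0
    elif mode == "constant_high":
        fn = lambda t: np.full_like(np.asarray(t, dtype=float), amplitude / 2.0)
    elif mode == "T2D_a":
        rho = t2d_fraction
        fn = lambda t: rho * amplitude * (1.0 + np.sin(omega * np.asarray(t) - np.pi / 2)) / 2.0
    else:
        raise ValueError(f"unknown infusion mode {mode!r}")
    return InsulinProfile(mode, (0.0, float(duration)), fn)


# -- first-phase secretion shapes -----------------------------------------

def _smoothstep(t, t_on, t_off):
    """C1 smooth 0 -> 1 ramp; exactly 0 before ``t_on`` and 1 after ``t_off``."""
    t = np.asarray(t, dtype=float)
    u = np.clip((t - t_on) / (t_off - t_on), 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _bump(t, peak, t_rise, tau_fall, convex):
    """Ramp to ``peak`` at ``t_rise`` followed by exponential decay.

    The healthy first phase rises along a smoothstep (steep mid-rise); the
    impaired shapes use a convex cubic ramp (slow start, late surge), which
    is what a blunted, delayed secretion burst looks like and keeps their
    early-window insulin below the healthy curve's.
    """
    t = np.asarray(t, dtype=float)
    u = np.clip(t / t_rise, 0.0, 1.0)
    rise = u**3 if convex else u * u * (3.0 - 2.0 * u)
    fall = np.exp(-np.maximum(t - t_rise, 0.0) / tau_fall)
    return peak * np.where(t <= t_rise, rise, fall)


_FIRST_PHASE_SHAPES = {
    # (bump peak, rise time min, fall time constant min, convex rise);
    # slower shapes fall faster so every bump fits the shared AUC budget
    "normal_fp": (1.0, 15.0, 22.0, False),
    "impaired_slope": (1.0, 35.0, 18.0, True),
    "T2D_b": (0.55, 35.0, 18.0, True),
}
_PLATEAU_ON, _PLATEAU_OFF = 45.0, 75.0
_FP_SPAN = (0.0, 180.0)
_NORMAL_PLATEAU = 0.29


def first_phase_profile(shape: str) -> InsulinProfile:
    """First-phase insulin shapes on [0, 180] min with matched AUC.

    ``normal_fp``: fast rise to an early high peak; ``impaired_slope``:
    reduced initial slope, same peak height; ``T2D_b``: reduced slope *and*
    reduced peak with a compensating elevated second phase.  The second-phase
    plateau (a smooth ramp between 60 and 100 min) is exactly zero at the
    bump's peak time, so peak heights compare exactly; its level is solved so
    every shape matches the AUC of ``normal_fp``.
    """
    if shape not in _FIRST_PHASE_SHAPES:
        raise ValueError(f"unknown first-phase shape {shape!r}")

    grid = _quad_grid(*_FP_SPAN)
    step_auc = float(np.trapezoid(_smoothstep(grid, _PLATEAU_ON, _PLATEAU_OFF), grid))

    def bump_auc_of(name):
        return float(np.trapezoid(_bump(grid, *_FIRST_PHASE_SHAPES[name]), grid))

    target_auc = bump_auc_of("normal_fp") + _NORMAL_PLATEAU * step_auc
    peak, t_rise, tau_fall, convex = _FIRST_PHASE_SHAPES[shape]
    plateau = (target_auc - bump_auc_of(shape)) / step_auc
    if plateau < 0:
        raise ValueError(f"shape {shape!r} cannot match the reference AUC")
    return InsulinProfile(
        shape,
        _FP_SPAN,
        lambda t: _bump(t, peak, t_rise, tau_fall, convex)
        + plateau * _smoothstep(t, _PLATEAU_ON, _PLATEAU_OFF),
    )


def composite_pulsatile(
    base: InsulinProfile, amplitude_factor: float, label: str | None = None
) -> InsulinProfile:
    """Superimpose 5-min pulses of relative amplitude ``amplitude_factor``.

    The carrier is (1 - cos(2*pi*t/T))/2, starting at its trough so the input
    begins without an artificial bolus.  The modulated curve is renormalized
    (multiplicatively) so its AUC equals the base profile's AUC exactly;
    ``amplitude_factor`` = 1 is "high" pulses, 0.25 is "low".
    """
    if not 0.0 < amplitude_factor <= 1.0:
        raise ValueError("amplitude_factor must be in (0, 1]")
    a = float(amplitude_factor)
    omega = 2.0 * np.pi / PULSE_PERIOD_MIN
    base_fn = base.fn

    def raw(t):
        t = np.asarray(t, dtype=float)
        carrier = (1.0 - np.cos(omega * t)) / 2.0
        return base_fn(t) * (1.0 - a + 2.0 * a * carrier)

    grid = _quad_grid(*base.span)
    raw_auc = float(np.trapezoid(raw(grid), grid))
    gamma = base.auc / raw_auc
    if label is None:
        label = "pulse_high_amp" if a >= 0.5 else "pulse_low_amp"
    return InsulinProfile(label, base.span, lambda t: gamma * raw(t))


def by_label(label: str, **kwargs) -> InsulinProfile:
    """Construct a profile from its label (the CLI/dataset vocabulary)."""
    if label == "feeding":
        return feeding_profile(kwargs.get("scale", 1.0))
    if label in _INFUSION_LABELS:
        return infusion_profile(label, **kwargs)
    if label in _FIRST_PHASE_SHAPES:
        return first_phase_profile(label)
    if label == "pulse_high_amp":
        return composite_pulsatile(first_phase_profile("normal_fp"), 1.0)
    if label == "pulse_low_amp":
        return composite_pulsatile(first_phase_profile("normal_fp"), 0.25)
    if label == "T2D_c":
        return composite_pulsatile(
            first_phase_profile("T2D_b"), kwargs.get("amplitude_factor", 0.25),
            label="T2D_c",
        )
    raise ValueError(f"unknown profile label {label!r}")
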