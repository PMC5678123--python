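"""Equilibrium and fold analysis of the aPKC subsystem.

The aPKC equation decouples from the rest of the network once active IRS2 is
treated as a control parameter (no other state enters it):

    dpkc/dt = f(pkc, irs2)
            = (k_aP * irs2 + v_auto * pkc^2 / (K_auto^2 + pkc^2)) * (1 - pkc)
              - k_dP * pkc

With sufficiently strong auto-activation the equilibrium curve folds twice,
producing a bistable window bounded by two saddle-node (limit) points: LP1
(the switch-on threshold, at the higher IRS2 value) and LP2 (the switch-off
threshold, at the lower value).  The gap between them is the hysteresis that
lets brief IRS2 troughs — e.g. under pulsatile insulin — shut aPKC off while
a constant input of the same dose keeps it on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import ParameterSet
from .simulate import Trajectory

__all__ = [
    "LimitPoint",
    "BifurcationDiagram",
    "pkc_rate",
    "equilibria_at",
    "find_limit_points",
    "compute_diagram",
    "classify_infusion_regime",
    "UndefinedRegimeError",
]


class UndefinedRegimeError(RuntimeError):
    """Regime classification was requested without a switch-off threshold."""


@dataclass(frozen=True)
class LimitPoint:
    irs2: float
    pkc: float


@dataclass
class BifurcationDiagram:
    """Equilibrium branches of aPKC vs active IRS2, with limit points."""

    branch_points: list[tuple[float, float, bool]]  # (irs2, pkc_eq, stable)
    lp1: LimitPoint | None  # switch-on threshold (higher irs2)
    lp2: LimitPoint | None  # switch-off threshold (lower irs2)

    @property
    def bistable(self) -> bool:
        return self.lp1 is not None and self.lp2 is not None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.branch_points, columns=["irs2", "pkc_eq", "stable"]
        )


def _coeffs(params: ParameterSet):
    k = params.kinetic
    return k["k_aP"], k["k_dP"], k.get("v_auto", 0.0), k.get("K_auto", 1.0)


def pkc_rate(pkc, irs2, params: ParameterSet):
    """f(pkc, irs2): the aPKC time derivative at frozen active IRS2."""
    k_aP, k_dP, v, K = _coeffs(params)
    auto = v * pkc**2 / (K**2 + pkc**2)
    return (k_aP * irs2 + auto) * (1.0 - pkc) - k_dP * pkc


def _df_dpkc(pkc, irs2, params: ParameterSet):
    k_aP, k_dP, v, K = _coeffs(params)
    K2 = K * K
    auto = v * pkc**2 / (K2 + pkc**2)
    d_auto = 2.0 * v * pkc * K2 / (K2 + pkc**2) ** 2
    return -(k_aP * irs2 + auto) + d_auto * (1.0 - pkc) - k_dP


def _d2f_dpkc2(pkc, irs2, params: ParameterSet):
    _, _, v, K = _coeffs(params)
    K2 = K * K
    den = (K2 + pkc**2)
    d_auto = 2.0 * v * pkc * K2 / den**2
    d2_auto = 2.0 * v * K2 * (K2 - 3.0 * pkc**2) / den**3
    return -2.0 * d_auto + d2_auto * (1.0 - pkc)


def equilibria_at(
    irs2: float, params: ParameterSet, grid: float = 1e-3
) -> list[tuple[float, bool]]:
    """All equilibria of the aPKC subsystem on [0, 1] at the given IRS2.

    Roots are bracketed by sign changes on a uniform grid and refined by
    Brent bisection; stability is the sign of df/dpkc at the root.
    """
    if irs2 < 0:
        raise ValueError("irs2 must be >= 0")
    n = int(round(1.0 / grid)) + 1
    xs = np.linspace(0.0, 1.0, n)
    fs = pkc_rate(xs, irs2, params)
    roots: list[float] = []
    for i in range(n - 1):
        a, b = fs[i], fs[i + 1]
        if a == 0.0:
            roots.append(float(xs[i]))
        elif a * b < 0:
            roots.append(
                float(
                    brentq(
                        lambda x: pkc_rate(x, irs2, params),
                        xs[i],
                        xs[i + 1],
                        xtol=1e-12,
                        rtol=8.9e-16,
                    )
                )
            )
    if fs[-1] == 0.0:
        roots.append(1.0)
    # dedupe near-coincident roots (tangency at grid nodes)
    out: list[tuple[float, bool]] = []
    for r in roots:
        if out and abs(r - out[-1][0]) < 1e-9:
            continue
        out.append((r, bool(_df_dpkc(r, irs2, params) < 0)))
    return out


def _fold_newton(params, pkc0, irs20, max_iter=60, tol=1e-12):
    """Solve {f = 0, df/dpkc = 0} for (pkc, irs2) by damped Newton."""
    k_aP = params.kinetic["k_aP"]
    x = np.array([pkc0, irs20], dtype=float)
    for _ in range(max_iter):
        p, s = x
        F = np.array([pkc_rate(p, s, params), _df_dpkc(p, s, params)])
        if np.all(np.abs(F) < tol):
            return float(p), float(s)
        J = np.array(
            [
                [_df_dpkc(p, s, params), k_aP * (1.0 - p)],
                [_d2f_dpkc2(p, s, params), -k_aP],
            ]
        )
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            return None
        # damping keeps the iterate in the physical box
        lam = 1.0
        for _ in range(30):
            xn = x - lam * step
            if 0.0 <= xn[0] <= 1.0 and xn[1] >= 0.0:
                break
            lam *= 0.5
        x = x - lam * step
        if not np.all(np.isfinite(x)):
            return None
    p, s = x
    F = np.array([pkc_rate(p, s, params), _df_dpkc(p, s, params)])
    if np.all(np.abs(F) < 1e-8):
        return float(p), float(s)
    return None


def _count_changes(params, irs2_grid):
    """(irs2_lo, irs2_hi, pkc_seed) brackets where the equilibrium count jumps."""
    counts = []
    eqs_list = []
    for s in irs2_grid:
        eqs = equilibria_at(s, params, grid=2e-3)
        counts.append(len(eqs))
        eqs_list.append(eqs)
    brackets = []
    for i in range(len(irs2_grid) - 1):
        if counts[i] != counts[i + 1]:
            # seed the fold near the pair of roots that is about to merge
            rich = eqs_list[i] if counts[i] > counts[i + 1] else eqs_list[i + 1]
            mid = rich[len(rich) // 2][0] if len(rich) >= 3 else rich[0][0]
            brackets.append((irs2_grid[i], irs2_grid[i + 1], mid))
    return brackets


def _fold_bisect(params, lo, hi, tol=1e-10):
    """Bisection on the equilibrium count; returns the fold irs2 value."""
    n_lo = len(equilibria_at(lo, params, grid=2e-3))
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if len(equilibria_at(mid, params, grid=2e-3)) == n_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_limit_points(
    params: ParameterSet,
    irs2_range: tuple[float, float] = (0.0, 2.0),
    scan_points: int = 400,
) -> tuple[LimitPoint | None, LimitPoint | None]:
    """Locate both folds of the aPKC equilibrium curve, if they exist.

    Returns ``(lp1, lp2)`` ordered so irs2(LP1) > irs2(LP2); monostable
    parameterizations return ``(None, None)``.  Fold candidates are seeded
    from equilibrium-count changes on a scan and polished by 2-D Newton on
    {f = 0, df/dpkc = 0}, with count-bisection as fallback.
    """
    grid = np.linspace(irs2_range[0], irs2_range[1], scan_points)
    brackets = _count_changes(params, grid)
    folds: list[LimitPoint] = []
    for lo, hi, pkc_seed in brackets:
        sol = _fold_newton(params, pkc_seed, 0.5 * (lo + hi))
        if sol is None or not (lo - 0.05 <= sol[1] <= hi + 0.05):
            s_fold = _fold_bisect(params, lo, hi)
            eqs = equilibria_at(s_fold, params, grid=1e-4)
            mid = eqs[len(eqs) // 2][0] if len(eqs) >= 3 else eqs[0][0]
            sol = (mid, s_fold)
        folds.append(LimitPoint(irs2=sol[1], pkc=sol[0]))
    if len(folds) < 2:
        return None, None
    folds.sort(key=lambda lp: lp.irs2)
    lp2, lp1 = folds[0], folds[-1]
    return lp1, lp2


def compute_diagram(
    params: ParameterSet,
    irs2_range: tuple[float, float] = (0.0, 2.0),
    n_points: int = 400,
) -> BifurcationDiagram:
    """Equilibrium branches on an IRS2 grid plus the limit points."""
    branch = []
    for s in np.linspace(irs2_range[0], irs2_range[1], n_points):
        for pkc_eq, stable in equilibria_at(s, params):
            branch.append((float(s), pkc_eq, stable))
    lp1, lp2 = find_limit_points(params, irs2_range)
    return BifurcationDiagram(branch, lp1, lp2)


def classify_infusion_regime(
    traj: Trajectory,
    diagram: BifurcationDiagram,
    transient_min: float = 10.0,
    crossing_min: float = 1.0,
) -> str:
    """``"stays_on"`` or ``"switches_off"`` for an infusion trajectory.

    aPKC switches off when active IRS2 stays below the switch-off threshold
    irs2(LP2) for at least ``crossing_min`` contiguous minutes; otherwise,
    if the post-transient minimum remains above the threshold (or dips are
    too brief to matter), the upper branch persists.
    """
    if diagram.lp2 is None:
        raise UndefinedRegimeError("diagram has no LP2; regime undefined")
    thr = diagram.lp2.irs2
    times = traj.times
    irs2 = traj.state("irs2")
    post = times >= transient_min
    below = (irs2 < thr) & post
    # longest contiguous below-threshold stretch
    longest = 0.0
    i, n = 0, len(times)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            longest = max(longest, times[j] - times[i])
            i = j + 1
        else:
            i += 1
    if longest >= crossing_min:
        return "switches_off"
    return "stays_on"
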