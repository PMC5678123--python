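"""Numerical kernels: jitted right-hand side and a fixed-step RK4 driver.

Two integration paths exist in the package:

* the accurate path (`simulate` with ``solver="lsoda"``): scipy ``solve_ivp``
  (LSODA, rtol 1e-8 / atol 1e-10) driving the jitted right-hand side through a
  thin Python wrapper;
* the fast path (``solver="rk4"``): a fixed-step classical Runge-Kutta driver
  compiled with numba, with the insulin input pre-sampled on the half-step
  grid.  This is what the differential-evolution objective uses; a test checks
  the two paths agree.

The step size (default 0.01 min) is far below the fastest time scale the
fitting bounds allow, so the fixed-step scheme is stable and accurate over
the whole search box.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# parameter indices follow hepinsulin.model.ALL_PARAMS; the kernel uses raw
# integer offsets so numba sees compile-time constants


@njit(cache=True)
def rhs_kernel(y, insulin, p):  # pragma: no cover - exercised via wrappers
    r_p = y[0]
    r_pe = y[1]
    r_e = y[2]
    irs1 = y[3]
    s2t = y[4]
    irs2 = y[5]
    akt = y[6]
    pkc = y[7]

    # non-negative clamps only where a fractional power could see a tiny
    # negative excursion from the integrator
    akt_c = akt if akt > 0.0 else 0.0
    pkc_c = pkc if pkc > 0.0 else 0.0
    irs2_c = irs2 if irs2 > 0.0 else 0.0

    free = 1.0 - r_p - r_pe - r_e

    # receptor cycle (optional feedbacks modulate internalization and
    # membrane dephosphorylation)
    k_int_eff = p[2] * (1.0 + p[25] * pkc_c / (p[26] + pkc_c))
    k_dp1_eff = p[1] / (1.0 + p[27] * akt_c / p[28])
    j_act = p[0] * insulin * free
    j_dp1 = k_dp1_eff * r_p
    j_int = k_int_eff * r_p
    j_dp2 = p[3] * r_pe
    j_rec = p[4] * r_e
    d_rp = j_act - j_dp1 - j_int
    d_rpe = j_int - j_dp2
    d_re = j_dp2 - j_rec

    # receptor signal seen by the IRS proteins
    S = r_p + p[5] * r_pe

    # IRS1: aPKC (Hill) and optionally Akt inhibit activation
    phi = 1.0 / (1.0 + (pkc_c / p[8]) ** p[9])
    phi = phi / (1.0 + p[31] * akt_c / p[32])
    d_irs1 = p[6] * S * (1.0 - irs1) * phi - p[7] * irs1

    # IRS2 pool: synthesis transcriptionally suppressed by Akt
    psi = 1.0 / (1.0 + (akt_c / p[12]) ** p[13])
    d_s2t = p[10] * psi - p[11] * s2t
    d_irs2 = p[14] * S * (s2t - irs2) - (p[15] + p[11]) * irs2

    # Akt: driven by IRS1 and (weighted) IRS2; optional auto-feedback and
    # optional inhibition by aPKC modulate activation
    chi = (1.0 + p[29] * akt_c / (p[30] + akt_c)) / (1.0 + p[33] * pkc_c / p[34])
    d_akt = p[16] * (irs1 + p[17] * irs2_c) * (1.0 - akt) * chi - p[18] * akt

    # aPKC: IRS2 drive plus Hill-2 auto-activation
    auto = p[21] * pkc_c * pkc_c / (p[22] * p[22] + pkc_c * pkc_c)
    d_pkc = (p[19] * irs2_c + auto) * (1.0 - pkc) - p[20] * pkc

    out = np.empty(8)
    out[0] = d_rp
    out[1] = d_rpe
    out[2] = d_re
    out[3] = d_irs1
    out[4] = d_s2t
    out[5] = d_irs2
    out[6] = d_akt
    out[7] = d_pkc
    return out


@njit(cache=True)
def rk4_integrate(y0, dt, n_steps, ins_half, p, record_every):
    """Classical RK4 over ``n_steps`` steps of size ``dt``.

    ``ins_half`` holds the insulin input sampled on the half-step grid
    (length ``2*n_steps + 1``), so no interpolation happens inside the loop.
    Every ``record_every``-th state (plus the initial one) is stored.
    """
    n_rec = n_steps // record_every + 1
    out = np.empty((n_rec, 8))
    y = y0.copy()
    for j in range(8):
        out[0, j] = y[j]
    rec = 1
    for i in range(n_steps):
        ia = ins_half[2 * i]
        im = ins_half[2 * i + 1]
        ib = ins_half[2 * i + 2]
        k1 = rhs_kernel(y, ia, p)
        k2 = rhs_kernel(y + 0.5 * dt * k1, im, p)
        k3 = rhs_kernel(y + 0.5 * dt * k2, im, p)
        k4 = rhs_kernel(y + dt * k3, ib, p)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if (i + 1) % record_every == 0:
            for j in range(8):
                out[rec, j] = y[j]
            rec += 1
    return out


def integrate_fast(
    y0: np.ndarray,
    t_end: float,
    insulin_fn,
    p: np.ndarray,
    dt: float = 0.01,
    grid_dt: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 integration from t=0 to ``t_end``.

    Returns ``(times, states)`` with states recorded every ``grid_dt``
    minutes.  ``insulin_fn`` is any vectorizable callable of time (an
    :class:`~hepinsulin.profiles.InsulinProfile` works).
    """
    record_every = max(1, round(grid_dt / dt))
    dt = grid_dt / record_every
    n_steps = max(1, round(t_end / dt))
    t_half = np.linspace(0.0, n_steps * dt, 2 * n_steps + 1)
    ins_half = np.asarray(insulin_fn(t_half), dtype=float)
    states = rk4_integrate(
        np.asarray(y0, dtype=float), dt, n_steps, ins_half, p, record_every
    )
    times = np.linspace(0.0, n_steps * dt, states.shape[0])
    return times, states
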