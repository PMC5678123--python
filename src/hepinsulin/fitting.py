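"""Parameter estimation by differential evolution and AICc/mAICc selection.

Datasets mirror the structure of the two in vivo studies the model family is
built around: a refeeding time course (phospho-IRS1, IRS2, phospho-Akt over
0-120 min with s.e.m.) and a portal-vein infusion study (Akt phosphorylation
at/after 10 min under pulsatile, constant and T2D-mimicking insulin).  The
root-mean-square (RMS) residual between scaled model observables and the
measured means is minimized by differential evolution in log10 parameter
space; variants are ranked by the small-sample-corrected Akaike criterion
(AICc) and its mean under insulin-dose perturbations (mAICc), which rewards
responses that are robust to errors in the unmeasured pre-hepatic insulin
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import differential_evolution

from .integrate import rk4_integrate
from .model import (
    ModelVariant,
    ParameterSet,
    SCALING_PARAMS,
    pack_parameters,
)
from .profiles import by_label
from .simulate import OBSERVABLE_MAP, _STATE_INDEX

__all__ = [
    "Condition",
    "ExperimentDataset",
    "DEConfig",
    "FitResult",
    "default_bounds",
    "rms_objective",
    "aicc",
    "maicc",
    "fit_variant",
    "rank_variants",
]

_PENALTY = 1e6


@dataclass
class Condition:
    """One experimental condition: a profile, an observable, sampled times."""

    profile_label: str
    observable: str  # IRS1 / IRS2 / Akt_feed / Akt_inf
    times: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    scaling_id: str | None = None  # defaults to the observable's scaling

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sems = np.asarray(self.sems, dtype=float)
        if self.scaling_id is None:
            self.scaling_id = OBSERVABLE_MAP[self.observable][1]


_FEEDING_MAX_MIN = 120.0   # refeeding data restricted to the first 2 h
_INFUSION_MIN_MIN = 10.0   # infusion data before 10 min are discarded


@dataclass
class ExperimentDataset:
    """A collection of conditions fitted simultaneously."""

    conditions: list[Condition]

    def __post_init__(self):
        for c in self.conditions:
            if not np.all(c.sems > 0):
                raise ValueError(f"s.e.m. must be > 0 ({c.profile_label}/{c.observable})")
            if c.observable not in OBSERVABLE_MAP:
                raise ValueError(f"unknown observable {c.observable!r}")
            prof = by_label(c.profile_label)
            if np.any(c.times < prof.span[0]) or np.any(c.times > prof.span[1]):
                raise ValueError(
                    f"time points outside profile span for {c.profile_label}"
                )
            if c.profile_label == "feeding" and np.any(c.times > _FEEDING_MAX_MIN):
                raise ValueError("feeding observables restricted to <= 120 min")
            if prof.amplitude_param == "a_inf" and np.any(c.times < _INFUSION_MIN_MIN):
                raise ValueError("infusion data points must be >= 10 min")

    @property
    def n_points(self) -> int:
        return sum(c.times.size for c in self.conditions)

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in self.conditions:
            for t, m, s in zip(c.times, c.means, c.sems):
                rows.append((c.profile_label, c.observable, t, m, s, c.scaling_id))
        return pd.DataFrame(
            rows, columns=["condition", "observable", "time_min", "mean", "sem", "scaling_id"]
        )

    @classmethod
    def from_frame(cls, df) -> "ExperimentDataset":
        conditions = []
        for (label, obs, sid), grp in df.groupby(
            ["condition", "observable", "scaling_id"], sort=False
        ):
            conditions.append(
                Condition(label, obs, grp["time_min"].values, grp["mean"].values,
                          grp["sem"].values, sid)
            )
        return cls(conditions)


@dataclass
class DEConfig:
    """Differential-evolution and objective settings.

    ``popsize`` is the population multiplier per free dimension (scipy
    convention), ``mutation`` the F factor, ``recombination`` the crossover
    rate CR; the search runs in log10 parameter space.  When
    ``profile_scalings`` is on, the four observable scaling factors are
    solved in closed form (least squares through the origin per scaling id)
    inside the objective instead of being searched; they still count toward
    the free-parameter number k.
    """

    popsize: int = 15
    mutation: float = 0.7
    recombination: float = 0.9
    generations: int = 300
    tol: float = 0.0
    polish: bool = False
    polish_topk: int = 0        # L-BFGS-B from the k best distinct members
    polish_min_dist: float = 0.8  # log10 distance defining "distinct"
    polish_maxfun: int = 6000
    profile_scalings: bool = True
    rk4_dt: float = 0.01
    grid_dt: float = 0.1
    init: str | np.ndarray = "latinhypercube"
    weighted: bool = False  # 1/sem weighting; plain RMS by default


@dataclass
class FitResult:
    params: ParameterSet
    rms: float
    rss: float
    n: int
    k: int
    aicc: float
    maicc: float
    seed: int | None
    converged: bool
    variant_name: str
    nfev: int = 0
    #: distinct polished local optima (rms, ParameterSet), best first; these
    #: sample the flat directions of the objective and feed the
    #: identifiability analysis at no extra cost
    alternates: list = None

    def to_json(self) -> dict:
        return {
            "variant": self.variant_name,
            "params": self.params.to_json(),
            "rms": self.rms,
            "rss": self.rss,
            "n": self.n,
            "k": self.k,
            "aicc": self.aicc,
            "maicc": self.maicc,
            "seed": self.seed,
            "converged": self.converged,
            "nfev": self.nfev,
        }


#: plausible physiological search ranges (min^-1 for rates, activity units
#: for half-saturations, dimensionless otherwise)
_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_ins": (0.1, 10.0), "k_dp1": (0.05, 5.0), "k_int": (0.05, 5.0),
    "k_dp2": (0.05, 5.0), "k_rec": (0.05, 5.0), "w_e": (0.05, 2.0),
    "k_a1": (0.02, 2.0), "k_d1": (0.02, 2.0), "K_P1": (0.02, 1.0), "h1": (1.0, 6.0),
    "k_s2": (0.002, 0.2), "k_deg": (0.005, 0.1), "K_A2": (0.02, 2.0),
    "h2": (1.0, 6.0), "k_a2": (0.1, 10.0), "k_d2": (0.05, 5.0),
    "k_aA": (0.02, 2.0), "w_2": (0.02, 2.0), "k_dA": (0.02, 2.0),
    "k_aP": (0.02, 2.0), "k_dP": (0.1, 10.0), "v_auto": (0.1, 10.0),
    "K_auto": (0.05, 1.0),
    "a_feed": (0.2, 5.0), "a_inf": (0.2, 5.0),
    "a_rint": (0.1, 10.0), "K_rint": (0.02, 2.0),
    "a_rdp": (0.1, 10.0), "K_rdp": (0.02, 2.0),
    "a_aauto": (0.1, 10.0), "K_aauto": (0.02, 2.0),
    "a_airs1": (0.1, 10.0), "K_airs1": (0.02, 2.0),
    "a_pakt": (0.1, 10.0), "K_pakt": (0.02, 2.0),
    "s_IRS1": (5.0, 500.0), "s_IRS2": (5.0, 500.0),
    "s_Akt_feed": (5.0, 500.0), "s_Akt_inf": (5.0, 500.0),
}


def default_bounds(variant: ModelVariant) -> dict[str, tuple[float, float]]:
    """Per-parameter positive search ranges for a variant (incl. scalings)."""
    names = list(variant.parameter_names()) + list(SCALING_PARAMS)
    return {n: _DEFAULT_BOUNDS[n] for n in names}


# ---------------------------------------------------------------------------
# compiled fitting problem: everything precomputed once per (variant, data)
# ---------------------------------------------------------------------------

class _Problem:
    def __init__(self, variant: ModelVariant, data: ExperimentDataset, cfg: DEConfig):
        self.variant = variant
        self.data = data
        self.cfg = cfg
        self.param_names = list(variant.parameter_names())
        self.scaling_index = {s: i for i, s in enumerate(SCALING_PARAMS)}

        # group conditions by profile label: one integration per group
        groups: dict[str, dict] = {}
        for c in data.conditions:
            g = groups.setdefault(c.profile_label, {"conds": []})
            g["conds"].append(c)
        for label, g in groups.items():
            prof = by_label(label)
            t_end = max(float(c.times.max()) for c in g["conds"])
            record_every = max(1, round(cfg.grid_dt / cfg.rk4_dt))
            dt = cfg.grid_dt / record_every
            n_steps = max(1, round(t_end / dt))
            t_half = np.linspace(0.0, n_steps * dt, 2 * n_steps + 1)
            g["template_half"] = np.asarray(prof.evaluate(t_half), dtype=float)
            g["amp_param"] = prof.amplitude_param
            g["dt"] = dt
            g["n_steps"] = n_steps
            g["record_every"] = record_every
            grid_times = np.linspace(0.0, n_steps * dt, n_steps // record_every + 1)
            for c in g["conds"]:
                idx = np.rint(c.times / cfg.grid_dt).astype(np.int64)
                if not np.allclose(grid_times[idx], c.times, atol=1e-6):
                    raise ValueError(
                        "data times must lie on the output grid "
                        f"(grid_dt={cfg.grid_dt} min)"
                    )
            g["state_idx"] = {
                c.observable: _STATE_INDEX[OBSERVABLE_MAP[c.observable][0]]
                for c in g["conds"]
            }
        self.groups = groups

        self.means = np.concatenate([c.means for g in groups.values() for c in g["conds"]])
        self.sems = np.concatenate([c.sems for g in groups.values() for c in g["conds"]])
        self.sids = np.array(
            [self.scaling_index[c.scaling_id]
             for g in groups.values() for c in g["conds"]
             for _ in range(c.times.size)]
        )
        self.n = self.means.size

    # -- raw (unscaled) model predictions at every datum -------------------
    def raw_predictions(self, kin: Mapping[str, float], input_scale: float = 1.0):
        ps = ParameterSet(dict(kin))
        p = pack_parameters(ps, self.variant)
        k_s2, k_deg = kin["k_s2"], kin["k_deg"]
        y0 = np.zeros(8)
        y0[4] = k_s2 / k_deg  # basal IRS2 pool
        out = []
        for label, g in self.groups.items():
            amp = kin[g["amp_param"]] * input_scale
            ins_half = amp * g["template_half"]
            states = rk4_integrate(
                y0, g["dt"], g["n_steps"], ins_half, p, g["record_every"]
            )
            if not np.isfinite(states[-1]).all():
                return None
            for c in g["conds"]:
                idx = np.rint(c.times / self.cfg.grid_dt).astype(np.int64)
                out.append(states[idx, g["state_idx"][c.observable]])
        return np.concatenate(out)

    def residual_rms(self, kin, scaling, input_scale=1.0, profile=False):
        """RMS and (optionally closed-form) scalings; None on solver failure."""
        with np.errstate(over="ignore", invalid="ignore"):
            return self._residual_rms(kin, scaling, input_scale, profile)

    def _residual_rms(self, kin, scaling, input_scale, profile):
        raw = self.raw_predictions(kin, input_scale)
        if raw is None or not np.all(np.isfinite(raw)):
            return None, scaling
        s_out = dict(scaling)
        if profile:
            for sid, j in self.scaling_index.items():
                mask = self.sids == j
                if not mask.any():
                    continue
                mm = float(raw[mask] @ raw[mask])
                md = float(raw[mask] @ self.means[mask])
                s_out[sid] = md / mm if mm > 0 and md > 0 else 1e-12
        s_vec = np.array([s_out[s] for s in SCALING_PARAMS])
        pred = raw * s_vec[self.sids]
        resid = pred - self.means
        if self.cfg.weighted:
            resid = resid / self.sems
        rms = float(np.sqrt(np.mean(resid**2)))
        if not np.isfinite(rms):
            return None, scaling
        return rms, s_out


def rms_objective(
    params: ParameterSet,
    variant: ModelVariant,
    data: ExperimentDataset,
    input_scale: float = 1.0,
    cfg: DEConfig | None = None,
) -> float:
    """Plain (unweighted) RMS between scaled model observables and the data.

    Solver failure returns the penalty value 1e6 rather than raising, so the
    optimizer can keep moving.
    """
    cfg = cfg or DEConfig()
    prob = _Problem(variant, data, cfg)
    rms, _ = prob.residual_rms(params.kinetic, params.scaling, input_scale)
    return _PENALTY if rms is None else rms


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected Akaike criterion n*ln(rss/n) + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def maicc(
    params: ParameterSet,
    variant: ModelVariant,
    data: ExperimentDataset,
    perturbations: Sequence[float] = (0.85, 1.0, 1.15),
    cfg: DEConfig | None = None,
) -> float:
    """Mean AICc over insulin-input rescalings, parameters held fixed.

    Robustness criterion: the insulin input of every condition is rescaled by
    each perturbation factor (default 0.85/1.0/1.15) without refitting, and
    the AICc values are averaged.
    """
    if len(perturbations) == 0:
        raise ValueError("perturbations must be non-empty")
    cfg = cfg or DEConfig()
    prob = _Problem(variant, data, cfg)
    k = len(variant.parameter_names()) + len(SCALING_PARAMS)
    vals = []
    for f in perturbations:
        rms, _ = prob.residual_rms(params.kinetic, params.scaling, input_scale=f)
        if rms is None:
            return _PENALTY
        vals.append(aicc(rms**2 * prob.n, prob.n, k))
    return float(np.mean(vals))


def fit_variant(
    variant: ModelVariant,
    data: ExperimentDataset,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    de_config: DEConfig | None = None,
    seed: int | None = 0,
) -> FitResult:
    """DE/rand/1/bin search in log10 space minimizing the RMS objective.

    Deterministic given ``seed``; non-convergence is flagged on the result,
    never raised.  ``bounds`` maps parameter names to positive (lo, hi)
    ranges and may clamp any subset (used by the identifiability pipeline's
    region-constrained fits).
    """
    cfg = de_config or DEConfig()
    prob = _Problem(variant, data, cfg)
    all_bounds = default_bounds(variant)
    if bounds:
        unknown = set(bounds) - set(all_bounds)
        if unknown:
            raise ValueError(f"bounds for unknown parameters: {sorted(unknown)}")
        all_bounds.update(bounds)

    free_names = list(prob.param_names)
    if not cfg.profile_scalings:
        free_names += list(SCALING_PARAMS)
    log_bounds = [
        (math.log10(all_bounds[n][0]), math.log10(all_bounds[n][1]))
        for n in free_names
    ]
    n_kin = len(prob.param_names)

    def unpack(x):
        vals = 10.0 ** np.asarray(x)
        kin = dict(zip(free_names[:n_kin], vals[:n_kin]))
        if cfg.profile_scalings:
            scal = {s: 1.0 for s in SCALING_PARAMS}
        else:
            scal = dict(zip(free_names[n_kin:], vals[n_kin:]))
        return kin, scal

    def objective(x):
        kin, scal = unpack(x)
        rms, _ = prob.residual_rms(kin, scal, profile=cfg.profile_scalings)
        return _PENALTY if rms is None or not np.isfinite(rms) else rms

    result = differential_evolution(
        objective,
        log_bounds,
        strategy="rand1bin",
        popsize=cfg.popsize,
        mutation=cfg.mutation,
        recombination=cfg.recombination,
        maxiter=cfg.generations,
        tol=cfg.tol,
        seed=seed,
        polish=cfg.polish and cfg.polish_topk == 0,
        init=cfg.init,
        updating="immediate",
        workers=1,
    )
    best_x, best_f, nfev = np.asarray(result.x), float(result.fun), int(result.nfev)
    alternates: list[tuple[float, np.ndarray]] = []

    if cfg.polish_topk > 0:
        # local refinement from the k best mutually-distinct population
        # members; DE roughs out the basin, L-BFGS-B finishes it
        from scipy.optimize import minimize

        order = np.argsort(result.population_energies)
        starts: list[np.ndarray] = []
        for i in order:
            x = result.population[i]
            if all(np.linalg.norm(x - s) > cfg.polish_min_dist for s in starts):
                starts.append(np.asarray(x))
            if len(starts) >= cfg.polish_topk:
                break
        for x0 in starts:
            loc = minimize(
                objective, x0, method="L-BFGS-B", bounds=log_bounds,
                options={"maxfun": cfg.polish_maxfun},
            )
            nfev += int(loc.nfev)
            alternates.append((float(loc.fun), np.asarray(loc.x)))
            if loc.fun < best_f:
                best_f, best_x = float(loc.fun), np.asarray(loc.x)

    kin, scal = unpack(best_x)
    rms, scal = prob.residual_rms(kin, scal, profile=cfg.profile_scalings)
    converged = rms is not None and np.isfinite(rms) and rms < _PENALTY
    if rms is None:
        rms = _PENALTY
    best = ParameterSet(kin, scal)
    alt_sets = []
    for f, x in sorted(alternates, key=lambda t: t[0]):
        a_kin, a_scal = unpack(x)
        a_rms, a_scal = prob.residual_rms(a_kin, a_scal,
                                          profile=cfg.profile_scalings)
        if a_rms is not None and np.isfinite(a_rms):
            alt_sets.append((float(a_rms), ParameterSet(a_kin, a_scal)))
    k = len(prob.param_names) + len(SCALING_PARAMS)
    rss = rms**2 * prob.n
    score = aicc(rss, prob.n, k) if converged else math.inf
    m_score = maicc(best, variant, data, cfg=cfg) if converged else math.inf
    return FitResult(
        params=best,
        rms=float(rms),
        rss=float(rss),
        n=prob.n,
        k=k,
        aicc=score,
        maicc=m_score,
        seed=seed,
        converged=bool(converged),
        variant_name=variant.name,
        nfev=nfev,
        alternates=alt_sets,
    )


def rank_variants(results: Mapping[str, FitResult]):
    """Rank fitted variants ascending by mAICc (ties: AICc, then RMS)."""
    if len(results) < 1:
        raise ValueError("need at least one fitted variant")
    import pandas as pd

    rows = [
        {
            "variant": name,
            "k": r.k,
            "rms": r.rms,
            "aicc": r.aicc,
            "maicc": r.maicc,
            "converged": r.converged,
        }
        for name, r in results.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["maicc", "aicc", "rms"], kind="mergesort"
    ).reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df
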