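"""Five-step identifiability and prediction-reliability pipeline.

When data pin down only a subset of parameters, a single best fit is not a
safe basis for predictions.  The pipeline (1) generates deliberately diverse
solutions by re-running the global fit with one parameter at a time confined
to different regions of its range, (2) discards solutions whose receptor
cycle is too slow to follow physiological 5-min insulin pulses, (3) enforces
a minimum distance between surviving solutions in log10 parameter space so
local-minimum duplicates collapse to one representative, (4) keeps only
solutions whose mAICc is within a cutoff of the best (robustness to insulin
dose errors), and (5) reports only those qualitative predictions that are
consistent across every surviving solution.  A confinement report classifies
each parameter as well confined if its across-solution spread is below a
decade threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .fitting import DEConfig, ExperimentDataset, FitResult, default_bounds, fit_variant
from .integrate import integrate_fast
from .model import ModelVariant, ParameterSet, SCALING_PARAMS, pack_parameters
from .profiles import PULSE_PERIOD_MIN

__all__ = [
    "SolutionSet",
    "region_constrained_fits",
    "receptor_recycling_filter",
    "min_distance_filter",
    "maicc_filter",
    "prediction_consistency",
    "confinement_report",
    "receptor_pulse_amplitude",
]


@dataclass
class SolutionSet:
    """Fit solutions plus provenance and a log of every filtering removal."""

    solutions: list[FitResult]
    provenance: list[dict] = field(default_factory=list)
    filter_log: list[dict] = field(default_factory=list)

    def _apply(self, keep_mask: Sequence[bool], step: str) -> "SolutionSet":
        kept, prov = [], []
        for i, (sol, keep) in enumerate(zip(self.solutions, keep_mask)):
            if keep:
                kept.append(sol)
                prov.append(self.provenance[i] if i < len(self.provenance) else {})
            else:
                self.filter_log.append(
                    {"step": step, "index": i,
                     "provenance": self.provenance[i] if i < len(self.provenance) else {}}
                )
        return SolutionSet(kept, prov, self.filter_log)

    def to_json(self) -> dict:
        return {
            "solutions": [s.to_json() for s in self.solutions],
            "provenance": self.provenance,
            "filter_log": self.filter_log,
        }


def expand_solutions(
    fits: Sequence[FitResult],
    variant: ModelVariant,
    data: "ExperimentDataset",
    cfg: DEConfig | None = None,
    max_rms_factor: float = 2.0,
) -> SolutionSet:
    """Pool fits with their polished local optima into one solution set.

    Each fit's ``alternates`` (distinct polished optima from the multi-start
    polish) sample the objective's flat directions at no extra cost;
    alternates worse than ``max_rms_factor`` times the best RMS are dropped.
    mAICc is evaluated for every member so downstream filters apply.
    """
    from .fitting import aicc as _aicc, maicc as _maicc

    best_rms = min(f.rms for f in fits)
    solutions, provenance = [], []
    seen: set[int] = set()
    for fit in fits:
        members = [(fit.rms, fit.params)] + list(fit.alternates or [])
        for i, (rms, params) in enumerate(members):
            if rms > max_rms_factor * best_rms:
                continue
            key = id(params)
            if key in seen:
                continue
            seen.add(key)
            rss = rms**2 * fit.n
            solutions.append(
                FitResult(
                    params=params, rms=rms, rss=rss, n=fit.n, k=fit.k,
                    aicc=_aicc(rss, fit.n, fit.k),
                    maicc=_maicc(params, variant, data, cfg=cfg),
                    seed=fit.seed, converged=True,
                    variant_name=fit.variant_name,
                )
            )
            provenance.append({"source_seed": fit.seed, "member": i})
    return SolutionSet(solutions, provenance)


def region_constrained_fits(
    variant: ModelVariant,
    data: ExperimentDataset,
    param_regions: Mapping[str, Sequence[tuple[float, float]]],
    de_config: DEConfig | None = None,
    seed: int = 0,
) -> SolutionSet:
    """One global fit per (parameter, region), the parameter clamped there.

    ``param_regions`` maps each poorly-informed parameter to a list of
    (lo, hi) sub-ranges partitioning its bounds.  Seeds are derived
    deterministically from ``seed`` so the whole sweep is reproducible.
    """
    solutions, provenance = [], []
    job = 0
    for pname in param_regions:
        for lo, hi in param_regions[pname]:
            sub_seed = (seed + 7919 * job) % (2**31 - 1)
            res = fit_variant(
                variant, data, bounds={pname: (lo, hi)},
                de_config=de_config, seed=sub_seed,
            )
            solutions.append(res)
            provenance.append(
                {"confined_parameter": pname, "region": (lo, hi), "seed": sub_seed}
            )
            job += 1
    return SolutionSet(solutions, provenance)


def receptor_pulse_amplitude(
    params: ParameterSet,
    variant: ModelVariant,
    amplitude: float | None = None,
    t_end: float = 60.0,
    transient_min: float = 30.0,
) -> float:
    """Steady-state relative oscillation of membrane R_p under 5-min pulses.

    Drives the model with the sinusoidal infusion template at the solution's
    own infusion amplitude (or ``amplitude``) and returns
    (peak - trough) / mean of R_p after the transient.
    """
    p = pack_parameters(params, variant)
    amp = params.kinetic["a_inf"] if amplitude is None else amplitude
    omega = 2.0 * math.pi / PULSE_PERIOD_MIN

    def drive(t):
        return amp * (1.0 + np.sin(omega * np.asarray(t) - np.pi / 2)) / 2.0

    y0 = np.zeros(8)
    y0[4] = params.kinetic["k_s2"] / params.kinetic["k_deg"]
    times, states = integrate_fast(y0, t_end, drive, p, dt=0.005, grid_dt=0.02)
    r_p = states[times >= transient_min, 0]
    # the mean is floored at 1% of receptor capacity so a degenerate cycle
    # that traps receptors internally (vanishing R_p) cannot pass on
    # relative terms
    mean = max(float(r_p.mean()), 0.01)
    return float((r_p.max() - r_p.min()) / mean)


def receptor_recycling_filter(
    solutions: SolutionSet,
    variant: ModelVariant,
    threshold: float = 0.2,
) -> SolutionSet:
    """Keep solutions whose receptor cycle follows 5-min insulin pulses.

    Operationalization of the qualitative requirement that receptor recycling
    can track physiological pulsatility: the relative steady-state R_p
    oscillation under the 5-min sinusoidal input must reach ``threshold``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    keep = [
        receptor_pulse_amplitude(s.params, variant) >= threshold
        for s in solutions.solutions
    ]
    return solutions._apply(keep, "receptor_recycling")


def _log10_vector(params: ParameterSet, names: Sequence[str]) -> np.ndarray:
    vals = []
    for n in names:
        v = params.kinetic.get(n, params.scaling.get(n))
        vals.append(math.log10(v))
    return np.array(vals)


def min_distance_filter(
    solutions: SolutionSet, epsilon: float = 0.5
) -> SolutionSet:
    """Greedy minimum-distance pruning in log10 parameter space.

    Solutions are visited in ascending-RMS order; one is kept iff its
    Euclidean log10 distance to every already-kept solution is at least
    ``epsilon``, so near-duplicates from the same local minimum collapse to
    their best representative.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    sols = solutions.solutions
    if not sols:
        return SolutionSet([], [], solutions.filter_log)
    names = sorted(sols[0].params.kinetic)
    order = sorted(range(len(sols)), key=lambda i: sols[i].rms)
    kept_vecs: list[np.ndarray] = []
    keep = [False] * len(sols)
    for i in order:
        v = _log10_vector(sols[i].params, names)
        if all(np.linalg.norm(v - w) >= epsilon for w in kept_vecs):
            keep[i] = True
            kept_vecs.append(v)
    return solutions._apply(keep, "min_distance")


def maicc_filter(solutions: SolutionSet, cutoff_delta: float = 2.0) -> SolutionSet:
    """Keep solutions with mAICc within ``cutoff_delta`` units of the best."""
    if not cutoff_delta > 0:
        raise ValueError("cutoff_delta must be > 0")
    sols = solutions.solutions
    if not sols:
        return solutions._apply([], "maicc")
    best = min(s.maicc for s in sols)
    keep = [s.maicc <= best + cutoff_delta for s in sols]
    return solutions._apply(keep, "maicc")


def prediction_consistency(
    solutions: SolutionSet,
    battery: Mapping[str, Callable[[FitResult], object]],
) -> dict:
    """Evaluate a battery of boolean/ordinal predictions on every solution.

    A prediction is *consistent* iff every solution yields the identical
    value; the report lists consistent predictions (with their shared value)
    and flags the inconsistent ones with the per-solution values.
    """
    report: dict = {"consistent": {}, "inconsistent": {}}
    for name, fn in battery.items():
        values = [fn(s) for s in solutions.solutions]
        if len(set(map(repr, values))) <= 1:
            report["consistent"][name] = values[0] if values else None
        else:
            report["inconsistent"][name] = values
    return report


def confinement_report(
    solutions: SolutionSet, decade_threshold: float = 1.0
) -> dict[str, dict]:
    """Per-parameter verdicts: well confined iff the across-solution log10
    range is below ``decade_threshold`` decades."""
    sols = solutions.solutions
    if len(sols) < 2:
        raise ValueError("confinement needs at least 2 solutions")
    names = sorted(sols[0].params.kinetic) + list(SCALING_PARAMS)
    out = {}
    for n in names:
        logs = np.array(
            [math.log10(s.params.kinetic.get(n, s.params.scaling.get(n))) for s in sols]
        )
        spread = float(logs.max() - logs.min())
        out[n] = {
            "log10_range": spread,
            "confined": bool(spread < decade_threshold),
            "median": float(10 ** np.median(logs)),
        }
    return out
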