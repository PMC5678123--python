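"""Synthetic datasets with the structure of the two in vivo studies.

The refeeding study (mouse) contributes phospho-IRS1, IRS2 and phospho-Akt
time courses over the first 2 h after feeding; the portal-vein infusion
study (rat) contributes Akt phosphorylation at/after 10 min under pulsatile
high-dose, constant high-dose and T2D-mimicking (reduced-amplitude pulsatile)
insulin.  ``synthesize`` simulates a ground-truth parameter set under those
four conditions, samples the scaled observables on realistic in vivo grids,
and applies mean-preserving multiplicative log-normal noise per replicate,
reporting replicate means and s.e.m. — everything parameter recovery and
model selection need, with no external downloads.

``default_truth`` ships a curated minimal-model (M4) parameter set whose
phenotype matches the published analysis: a bistable aPKC subsystem with
hysteresis, feeding-driven switch-on by ~15 min and switch-off between 60
and 120 min, IRS1/Akt drop-then-rebound, constant infusion that keeps aPKC
on while equal-dose pulsatile infusion shuts it off by ~30 min, and scaled
IRS2 infusion levels in the published arbitrary-unit range (~44 a.u. steady
state under constant infusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import Condition, ExperimentDataset
from .model import ModelVariant, ParameterSet, variant as named_variant
from .profiles import by_label
from .simulate import OBSERVABLE_MAP, simulate

__all__ = ["SynthesisDesign", "synthesize", "default_truth", "truth_self_test"]

#: observables measured in each condition of the emulated studies
_FEEDING_OBSERVABLES = ("IRS1", "IRS2", "Akt_feed")
_INFUSION_LABELS = ("pulsatile_high", "constant_high", "T2D_a")

#: s.e.m. floor (a.u.) protecting the noiseless limit
_SEM_FLOOR = 1e-9


@dataclass
class SynthesisDesign:
    """Sampling design for one synthetic two-study dataset."""

    # grids dense enough that n exceeds the largest variant's parameter
    # count + 1, so AICc is defined for every model in the family
    feeding_times: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.0, 5, 10, 15, 20, 30, 45, 60, 75, 90, 105, 120]
        )
    )
    infusion_times: np.ndarray = field(
        default_factory=lambda: np.array([10.0, 15.0, 20.0, 25.0, 30.0])
    )
    noise_cv: float = 0.05
    replicates: int = 5
    seed: int = 0
    solver: str = "lsoda"  # "rk4" gives exact agreement with the fit objective

    def __post_init__(self):
        self.feeding_times = np.asarray(self.feeding_times, dtype=float)
        self.infusion_times = np.asarray(self.infusion_times, dtype=float)
        if np.any(self.feeding_times > 120.0):
            raise ValueError("feeding sampling restricted to the first 2 h")
        if np.any(self.infusion_times < 10.0):
            raise ValueError("infusion sampling starts at 10 min")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def synthesize(
    truth: ParameterSet,
    variant: ModelVariant,
    design: SynthesisDesign | None = None,
) -> ExperimentDataset:
    """Generate a noisy two-study dataset from a ground-truth parameter set.

    Noise is multiplicative log-normal with coefficient of variation
    ``design.noise_cv`` (mean-preserving), independent across points and
    replicates; reported are replicate means and s.e.m.  Bit-reproducible
    given ``design.seed``.
    """
    design = design or SynthesisDesign()
    rng = np.random.default_rng(design.seed)
    sigma = np.sqrt(np.log1p(design.noise_cv**2))
    conditions = []

    def sample(label, observable, times):
        prof = by_label(label)
        traj = simulate(
            variant, truth, prof, t_end=float(times.max()), solver=design.solver
        )
        clean = np.interp(times, traj.times, traj.observables[observable])
        if design.noise_cv > 0:
            z = rng.standard_normal((design.replicates, times.size))
            reps = clean[None, :] * np.exp(sigma * z - sigma**2 / 2.0)
        else:
            reps = np.repeat(clean[None, :], design.replicates, axis=0)
        means = reps.mean(axis=0)
        if design.replicates > 1:
            sems = reps.std(axis=0, ddof=1) / np.sqrt(design.replicates)
        else:
            sems = np.zeros_like(means)
        sems = np.maximum(sems, _SEM_FLOOR)
        conditions.append(Condition(label, observable, times, means, sems))

    for obs in _FEEDING_OBSERVABLES:
        sample("feeding", obs, design.feeding_times)
    for label in _INFUSION_LABELS:
        sample(label, "Akt_inf", design.infusion_times)
    return ExperimentDataset(conditions)


#: curated minimal-model ground truth (see module docstring); calibrated once
#: against the published phenotype and frozen
_TRUTH_KINETIC = {
    # receptor cycle
    "k_ins": 2.0824, "k_dp1": 1.3032, "k_int": 0.8813, "k_dp2": 2.2021,
    "k_rec": 1.2, "w_e": 0.1757,
    # IRS1
    "k_a1": 0.10, "k_d1": 0.03, "K_P1": 0.10, "h1": 4.0,
    # IRS2
    "k_s2": 0.0186, "k_deg": 0.01073, "K_A2": 0.1774, "h2": 2.9727,
    "k_a2": 3.4298, "k_d2": 2.8778,
    # Akt
    "k_aA": 0.168, "w_2": 0.8866, "k_dA": 0.1509,
    # aPKC
    "k_aP": 0.1377, "k_dP": 1.0, "v_auto": 0.857, "K_auto": 0.35,
    # input amplitudes
    "a_feed": 1.8185, "a_inf": 1.1781,
}

_TRUTH_SCALING = {
    "s_IRS1": 100.0,
    "s_IRS2": 130.0,
    "s_Akt_feed": 100.0,
    "s_Akt_inf": 100.0,
}


def default_truth() -> tuple[ParameterSet, ModelVariant]:
    """The curated M4 ground truth used throughout tests and analyses."""
    return (
        ParameterSet(dict(_TRUTH_KINETIC), dict(_TRUTH_SCALING)),
        named_variant("M4"),
    )


def truth_self_test() -> dict:
    """Verify the shipped truth exhibits the expected phenotype.

    Returns a dict of booleans (all must be True): bistability with
    hysteresis, feeding switch-on by 15 min and switch-off in (60, 120) min,
    IRS1 rebound detected, constant infusion stays on while pulsatile
    switches off by ~30 min.
    """
    from .bifurcation import classify_infusion_regime, compute_diagram
    from .simulate import detect_switch_events

    truth, v = default_truth()
    checks = {}
    diagram = compute_diagram(truth)
    checks["bistable"] = diagram.bistable
    checks["hysteresis"] = (
        diagram.bistable and diagram.lp1.irs2 > diagram.lp2.irs2
    )

    feed = simulate(v, truth, by_label("feeding"), t_end=120.0)
    ev = detect_switch_events(feed)
    checks["feeding_switch_on_by_15"] = ev.pkc_on is not None and ev.pkc_on <= 15.0
    checks["feeding_switch_off_60_120"] = (
        ev.pkc_off is not None and 60.0 < ev.pkc_off < 120.0
    )
    checks["irs1_rebound_detected"] = ev.irs1_rebound is not None

    const = simulate(v, truth, by_label("constant_high"), t_end=30.0)
    puls = simulate(v, truth, by_label("pulsatile_high"), t_end=30.0)
    checks["constant_stays_on"] = (
        classify_infusion_regime(const, diagram) == "stays_on"
    )
    checks["pulsatile_switches_off"] = (
        classify_infusion_regime(puls, diagram) == "switches_off"
    )
    return checks
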