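"""Kinetic model family of proximal hepatic insulin signaling.

The model tracks the insulin receptor cycle (membrane phosphorylated R_p,
internalized phosphorylated R_p,en, internalized dephosphorylated R_en, with
the unphosphorylated membrane pool recovered by conservation), the two insulin
receptor substrates IRS1 (fixed total pool) and IRS2 (synthesized/degraded
total pool plus an active fraction), and the two metabolic effector kinases
Akt and atypical PKC (aPKC).  Phosphorylated receptors (membrane and, with a
weight, endosomal) activate both IRS proteins; both IRS proteins activate Akt;
only IRS2 activates aPKC; Akt transcriptionally suppresses IRS2 synthesis.

A menu of eight feedback/crosstalk mechanisms can be toggled per model
variant.  Three of them define the minimal model M4:

* aPKC inhibits IRS1 activation (Hill-type inhibition),
* aPKC auto-activation (Hill-2 positive feedback, the source of bistability),
* Akt suppresses IRS2 transcription.

Five further candidate feedbacks (aPKC on receptor internalization, Akt on
receptor dephosphorylation, Akt auto-feedback, Akt on IRS1, aPKC on Akt) are
optional; each enabled feedback contributes exactly two kinetic parameters.
Named variants M0..M6/M2a differ only in which feedbacks are enabled.

Time unit is minutes; all activities are fractions of a unit capacity except
the IRS2 pool, which carries its own synthesis/degradation balance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ConfigurationError",
    "Feedback",
    "ModelVariant",
    "ParameterSet",
    "ModelState",
    "STATE_NAMES",
    "BASE_PARAMS",
    "SCALING_PARAMS",
    "ALL_PARAMS",
    "FEEDBACK_PARAMS",
    "NAMED_VARIANTS",
    "NEUTRAL_VALUES",
    "variant",
    "count_free_parameters",
    "rhs",
    "rhs_array",
    "pack_parameters",
]


class ConfigurationError(ValueError):
    """A parameter set does not match the requested model variant."""


class Feedback(str, Enum):
    """The feedback/crosstalk menu."""

    PKC_IRS1 = "pkc_irs1"        # aPKC inhibits IRS1 activation
    PKC_AUTO = "pkc_auto"        # aPKC auto-activation (bistability source)
    AKT_IRS2TX = "akt_irs2tx"    # Akt suppresses IRS2 transcription
    PKC_RINT = "pkc_rint"        # aPKC promotes receptor internalization
    AKT_RDEPHOS = "akt_rdephos"  # Akt attenuates receptor dephosphorylation
    AKT_AUTO = "akt_auto"        # Akt positive auto-feedback
    AKT_IRS1 = "akt_irs1"        # Akt inhibits IRS1 activation
    PKC_AKT = "pkc_akt"          # aPKC inhibits Akt activation


#: state vector layout used throughout the package
STATE_NAMES = ("r_p", "r_pe", "r_e", "irs1", "irs2_tot", "irs2", "akt", "pkc")

#: kinetic parameters present in every variant (19)
BASE_PARAMS = (
    # receptor cycle
    "k_ins", "k_dp1", "k_int", "k_dp2", "k_rec", "w_e",
    # IRS1
    "k_a1", "k_d1",
    # IRS2
    "k_s2", "k_deg", "k_a2", "k_d2",
    # Akt
    "k_aA", "w_2", "k_dA",
    # aPKC
    "k_aP", "k_dP",
    # input amplitudes
    "a_feed", "a_inf",
)

#: two kinetic parameters per feedback
FEEDBACK_PARAMS: dict[Feedback, tuple[str, str]] = {
    Feedback.PKC_IRS1: ("K_P1", "h1"),
    Feedback.PKC_AUTO: ("v_auto", "K_auto"),
    Feedback.AKT_IRS2TX: ("K_A2", "h2"),
    Feedback.PKC_RINT: ("a_rint", "K_rint"),
    Feedback.AKT_RDEPHOS: ("a_rdp", "K_rdp"),
    Feedback.AKT_AUTO: ("a_aauto", "K_aauto"),
    Feedback.AKT_IRS1: ("a_airs1", "K_airs1"),
    Feedback.PKC_AKT: ("a_pakt", "K_pakt"),
}

SCALING_PARAMS = ("s_IRS1", "s_IRS2", "s_Akt_feed", "s_Akt_inf")

#: canonical packing order for the numeric kernel (all possible kinetic params)
ALL_PARAMS = (
    "k_ins", "k_dp1", "k_int", "k_dp2", "k_rec", "w_e",
    "k_a1", "k_d1", "K_P1", "h1",
    "k_s2", "k_deg", "K_A2", "h2", "k_a2", "k_d2",
    "k_aA", "w_2", "k_dA",
    "k_aP", "k_dP", "v_auto", "K_auto",
    "a_feed", "a_inf",
    "a_rint", "K_rint", "a_rdp", "K_rdp",
    "a_aauto", "K_aauto", "a_airs1", "K_airs1", "a_pakt", "K_pakt",
)
PARAM_INDEX = {name: i for i, name in enumerate(ALL_PARAMS)}

#: values at which a feedback term reduces exactly to 1 (or 0 for v_auto):
#: disabling a feedback and neutral-parameterizing it give identical dynamics
NEUTRAL_VALUES = {
    "K_P1": math.inf, "h1": 1.0,
    "K_A2": math.inf, "h2": 1.0,
    "v_auto": 0.0, "K_auto": 1.0,
    "a_rint": 0.0, "K_rint": 1.0,
    "a_rdp": 0.0, "K_rdp": 1.0,
    "a_aauto": 0.0, "K_aauto": 1.0,
    "a_airs1": 0.0, "K_airs1": 1.0,
    "a_pakt": 0.0, "K_pakt": 1.0,
}

_HILL_PARAMS = {"h1", "h2"}


@dataclass(frozen=True)
class ModelVariant:
    """A feedback-toggle configuration identifying one model of the family."""

    name: str
    feedbacks: frozenset[Feedback]

    def parameter_names(self) -> tuple[str, ...]:
        """Kinetic parameter names of this variant in canonical packing order."""
        enabled = {p for fb in self.feedbacks for p in FEEDBACK_PARAMS[fb]}
        allowed = set(BASE_PARAMS) | enabled
        return tuple(p for p in ALL_PARAMS if p in allowed)

    def n_kinetic(self) -> int:
        return len(BASE_PARAMS) + 2 * len(self.feedbacks)

    def has(self, fb: Feedback) -> bool:
        return fb in self.feedbacks

    def to_json(self) -> dict:
        return {"name": self.name, "feedbacks": sorted(f.value for f in self.feedbacks)}

    @classmethod
    def from_json(cls, doc: Mapping) -> "ModelVariant":
        return cls(doc["name"], frozenset(Feedback(f) for f in doc["feedbacks"]))


_MINIMAL = frozenset({Feedback.PKC_IRS1, Feedback.PKC_AUTO, Feedback.AKT_IRS2TX})
_FULL = frozenset(set(Feedback) - {Feedback.AKT_AUTO})

NAMED_VARIANTS: dict[str, ModelVariant] = {
    # full model: every feedback except the Akt auto-feedback
    "M0": ModelVariant("M0", _FULL),
    # M1: receptor-internalization feedback from aPKC removed
    "M1": ModelVariant("M1", _FULL - {Feedback.PKC_RINT}),
    # M2: additionally the negative feedback from Akt on IRS1 removed
    "M2": ModelVariant("M2", _FULL - {Feedback.PKC_RINT, Feedback.AKT_IRS1}),
    # M2a: like M2 but Akt auto-feedback replaces the Akt -> receptor feedback
    "M2a": ModelVariant(
        "M2a",
        (_FULL - {Feedback.PKC_RINT, Feedback.AKT_IRS1, Feedback.AKT_RDEPHOS})
        | {Feedback.AKT_AUTO},
    ),
    # M3: aPKC -> Akt crosstalk removed from M2
    "M3": ModelVariant(
        "M3", _FULL - {Feedback.PKC_RINT, Feedback.AKT_IRS1, Feedback.PKC_AKT}
    ),
    # M4: minimal model, only the three core feedbacks
    "M4": ModelVariant("M4", _MINIMAL),
    # M5: full model without aPKC -| IRS1 (fits poorly)
    "M5": ModelVariant("M5", _FULL - {Feedback.PKC_IRS1}),
    # M6: full model without aPKC auto-activation (no bistable switch)
    "M6": ModelVariant("M6", _FULL - {Feedback.PKC_AUTO}),
}


def variant(name: str) -> ModelVariant:
    """Look up a named variant (M0, M1, M2, M2a, M3, M4, M5, M6)."""
    try:
        return NAMED_VARIANTS[name]
    except KeyError:
        raise KeyError(
            f"unknown variant {name!r}; known: {sorted(NAMED_VARIANTS)}"
        ) from None


def count_free_parameters(v: ModelVariant | str) -> int:
    """Number of fitted parameters: kinetic parameters plus 4 scaling factors."""
    if isinstance(v, str):
        v = variant(v)
    return v.n_kinetic() + len(SCALING_PARAMS)


@dataclass
class ParameterSet:
    """Named kinetic parameters plus observable scaling factors.

    ``kinetic`` maps parameter names (rate constants in 1/min, half-saturation
    constants in activity units, Hill exponents dimensionless, input
    amplitudes dimensionless) to positive reals.  ``scaling`` maps the four
    observable scaling factors (s_IRS1, s_IRS2, s_Akt_feed, s_Akt_inf) to
    positive reals converting model activities to measured arbitrary units.
    """

    kinetic: dict[str, float]
    scaling: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in SCALING_PARAMS}
    )

    def validate(self, v: ModelVariant) -> None:
        """Raise :class:`ConfigurationError` if incompatible with variant ``v``."""
        needed = v.parameter_names()
        for name in needed:
            if name not in self.kinetic:
                fb = next(
                    (f for f, ps in FEEDBACK_PARAMS.items() if name in ps), None
                )
                where = f" (required by feedback {fb.value})" if fb else ""
                raise ConfigurationError(
                    f"missing parameter {name!r} for variant {v.name}{where}"
                )
        extra = set(self.kinetic) - set(needed)
        if extra:
            raise ConfigurationError(
                f"parameters {sorted(extra)} are not part of variant {v.name}"
            )
        for name, val in self.kinetic.items():
            # a feedback parameter may sit exactly at its neutral value
            # (equivalent to disabling the feedback); anything else must be
            # strictly positive
            if not val > 0 and val != NEUTRAL_VALUES.get(name):
                raise ConfigurationError(f"parameter {name}={val} must be > 0")
            if name in _HILL_PARAMS and val < 1.0:
                raise ConfigurationError(f"Hill exponent {name}={val} must be >= 1")
        for name in SCALING_PARAMS:
            if name not in self.scaling:
                raise ConfigurationError(f"missing scaling factor {name!r}")
            if not self.scaling[name] > 0:
                raise ConfigurationError(f"scaling {name} must be > 0")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> dict:
        return {"kinetic": dict(self.kinetic), "scaling": dict(self.scaling)}

    @classmethod
    def from_json(cls, doc: Mapping) -> "ParameterSet":
        return cls(dict(doc["kinetic"]), dict(doc["scaling"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json(), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSet":
        return cls.from_json(json.loads(Path(path).read_text()))

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.kinetic), dict(self.scaling))


def pack_parameters(params: ParameterSet, v: ModelVariant) -> np.ndarray:
    """Pack a validated ParameterSet into the fixed-layout kernel vector.

    Disabled feedbacks are filled with their neutral values, which makes the
    kernel identical for every variant: toggling a feedback off is exactly
    equivalent to neutral parameterization.
    """
    params.validate(v)
    vec = np.empty(len(ALL_PARAMS))
    for i, name in enumerate(ALL_PARAMS):
        if name in params.kinetic:
            vec[i] = params.kinetic[name]
        else:
            vec[i] = NEUTRAL_VALUES[name]
    return vec


@dataclass
class ModelState:
    """One point of the state space (see module docstring for meaning)."""

    r_p: float = 0.0
    r_pe: float = 0.0
    r_e: float = 0.0
    irs1: float = 0.0
    irs2_tot: float = 0.0
    irs2: float = 0.0
    akt: float = 0.0
    pkc: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES])

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "ModelState":
        return cls(*map(float, y))


def receptor_fluxes(y: np.ndarray, insulin: float, p: np.ndarray) -> tuple:
    """The five receptor-cycle fluxes (activation, dephos at membrane,
    internalization, endosomal dephos, recycling); used for conservation
    checks and in the right-hand side."""
    r_p, r_pe, r_e = y[0], y[1], y[2]
    akt = max(y[6], 0.0)
    pkc = max(y[7], 0.0)
    free = 1.0 - r_p - r_pe - r_e
    k_int_eff = p[PARAM_INDEX["k_int"]] * (
        1.0 + p[PARAM_INDEX["a_rint"]] * pkc / (p[PARAM_INDEX["K_rint"]] + pkc)
    )
    k_dp1_eff = p[PARAM_INDEX["k_dp1"]] / (
        1.0 + p[PARAM_INDEX["a_rdp"]] * akt / p[PARAM_INDEX["K_rdp"]]
    )
    j_act = p[PARAM_INDEX["k_ins"]] * insulin * free
    j_dp1 = k_dp1_eff * r_p
    j_int = k_int_eff * r_p
    j_dp2 = p[PARAM_INDEX["k_dp2"]] * r_pe
    j_rec = p[PARAM_INDEX["k_rec"]] * r_e
    return j_act, j_dp1, j_int, j_dp2, j_rec


def rhs_array(y: np.ndarray, insulin: float, p: np.ndarray) -> np.ndarray:
    """Reference (pure NumPy) right-hand side on the packed layout.

    The numerically hot path lives in :mod:`hepinsulin.integrate`; this
    version is the readable reference implementation and the two are held
    together by a test.
    """
    from .integrate import rhs_kernel  # jitted twin

    return rhs_kernel(np.asarray(y, dtype=float), float(insulin), p)


def rhs(
    state: ModelState,
    t: float,
    insulin,
    params: ParameterSet,
    v: ModelVariant,
) -> ModelState:
    """Time derivative of the model state at time ``t``.

    ``insulin`` may be a scalar level, a callable of time, or an
    :class:`hepinsulin.profiles.InsulinProfile` (evaluated at ``t``; the
    profile template is multiplied by the variant's fitted input amplitude
    elsewhere — here the value is used as given).
    """
    p = pack_parameters(params, v)
    lvl = insulin(t) if callable(insulin) else float(insulin)
    dy = rhs_array(state.to_array(), lvl, p)
    return ModelState.from_array(dy)
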