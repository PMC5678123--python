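import json
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hepinsulin.bifurcation import _df_dpkc
from hepinsulin.model import (
    ALL_PARAMS,
    BASE_PARAMS,
    ConfigurationError,
    FEEDBACK_PARAMS,
    Feedback,
    ModelState,
    ModelVariant,
    NAMED_VARIANTS,
    NEUTRAL_VALUES,
    ParameterSet,
    count_free_parameters,
    pack_parameters,
    receptor_fluxes,
    rhs,
    rhs_array,
    variant,
)
from hepinsulin.synth import default_truth


def random_state(rng):
    r = rng.uniform(0, 0.3, 3)
    return np.array([*r, rng.uniform(0, 1), rng.uniform(0.2, 2),
                     rng.uniform(0, 0.2), rng.uniform(0, 1), rng.uniform(0, 1)])


def test_count_formula_matches_feedback_algebra():
    for name, v in NAMED_VARIANTS.items():
        assert count_free_parameters(v) == len(BASE_PARAMS) + 2 * len(v.feedbacks) + 4
    custom = ModelVariant("custom", frozenset({Feedback.PKC_AUTO}))
    assert count_free_parameters(custom) == 19 + 2 + 4


def test_named_variant_structure():
    m4 = variant("M4")
    assert m4.feedbacks == frozenset(
        {Feedback.PKC_IRS1, Feedback.PKC_AUTO, Feedback.AKT_IRS2TX}
    )
    m0 = variant("M0")
    assert m0.feedbacks == frozenset(set(Feedback) - {Feedback.AKT_AUTO})
    m2a = variant("M2a")
    assert Feedback.AKT_AUTO in m2a.feedbacks
    assert Feedback.AKT_RDEPHOS not in m2a.feedbacks
    with pytest.raises(KeyError):
        variant("M7")


def test_receptor_pool_derivatives_sum_to_zero(truth_params, m4, rng):
    p = pack_parameters(truth_params, m4)
    for _ in range(20):
        y = random_state(rng)
        insulin = rng.uniform(0, 2)
        dy = rhs_array(y, insulin, p)
        j_act, j_dp1, j_int, j_dp2, j_rec = receptor_fluxes(y, insulin, p)
        d_free = j_dp1 + j_rec - j_act
        assert abs(dy[0] + dy[1] + dy[2] + d_free) < 1e-12


def test_invariant_box_at_corners(truth_params, m4):
    p = pack_parameters(truth_params, m4)
    zero = np.zeros(8)
    dy = rhs_array(zero, 0.0, p)
    # at rest with no insulin, only IRS2 synthesis is active
    assert dy[4] > 0
    assert np.all(dy[[0, 1, 2, 3, 5, 6, 7]] == 0.0)
    # every normalized activity at capacity decays
    full = np.array([1.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    dy_full = rhs_array(full, 0.0, p)
    assert np.all(dy_full[[3, 5, 6, 7]] <= 0.0)


def test_disabled_feedback_equals_neutral_parameterization(truth_params, rng):
    m4 = variant("M4")
    m6_like = ModelVariant(
        "M4_minus_auto", m4.feedbacks - {Feedback.PKC_AUTO}
    )
    without = ParameterSet(
        {k: v for k, v in truth_params.kinetic.items()
         if k not in FEEDBACK_PARAMS[Feedback.PKC_AUTO]},
        dict(truth_params.scaling),
    )
    with_neutral = without.copy()
    for name in FEEDBACK_PARAMS[Feedback.PKC_AUTO]:
        with_neutral.kinetic[name] = NEUTRAL_VALUES[name]
    p_a = pack_parameters(without, m6_like)
    p_b = pack_parameters(with_neutral, m4)
    for _ in range(10):
        y = random_state(rng)
        insulin = rng.uniform(0, 2)
        a = rhs_array(y, insulin, p_a)
        b = rhs_array(y, insulin, p_b)
        assert np.array_equal(a, b)


def test_missing_feedback_parameter_names_culprit(truth_params, m4):
    broken = truth_params.copy()
    del broken.kinetic["v_auto"]
    with pytest.raises(ConfigurationError, match="v_auto"):
        pack_parameters(broken, m4)


def test_hill_exponent_below_one_rejected(truth_params, m4):
    bad = truth_params.copy()
    bad.kinetic["h1"] = 0.5
    with pytest.raises(ConfigurationError, match="h1"):
        pack_parameters(bad, m4)


def test_apkc_derivative_matches_finite_differences(truth_params, m4):
    """The analytic d(dpkc/dt)/dpkc used by the fold solver agrees with a
    central finite-difference of the coded right-hand side."""
    p = pack_parameters(truth_params, m4)
    rng = np.random.default_rng(3)
    for _ in range(10):
        y = random_state(rng)
        h = 1e-6
        y_hi, y_lo = y.copy(), y.copy()
        y_hi[7] += h
        y_lo[7] -= h
        fd = (rhs_array(y_hi, 0.7, p)[7] - rhs_array(y_lo, 0.7, p)[7]) / (2 * h)
        analytic = _df_dpkc(y[7], y[5], truth_params)
        assert fd == pytest.approx(analytic, rel=1e-6, abs=1e-8)


def test_parameterset_json_roundtrip_is_identical(tmp_path, truth_params):
    path = tmp_path / "params.json"
    truth_params.save(path)
    loaded = ParameterSet.load(path)
    assert loaded.kinetic == truth_params.kinetic
    assert loaded.scaling == truth_params.scaling
    path2 = tmp_path / "params2.json"
    loaded.save(path2)
    assert path.read_bytes() == path2.read_bytes()


def test_variant_json_roundtrip():
    for v in NAMED_VARIANTS.values():
        assert ModelVariant.from_json(v.to_json()) == v


def test_rhs_wrapper_accepts_callable_insulin(truth_params, m4):
    state = ModelState(irs2_tot=1.0)
    d1 = rhs(state, 10.0, lambda t: 0.5, truth_params, m4)
    d2 = rhs(state, 10.0, 0.5, truth_params, m4)
    assert d1 == d2


@given(
    scale=st.floats(0.2, 5.0),
    insulin=st.floats(0.0, 3.0),
)
def test_rhs_finite_on_scaled_parameters(scale, insulin):
    truth_params, m4 = default_truth()
    scaled = ParameterSet(
        {k: (v * scale if not k.startswith("h") else v)
         for k, v in truth_params.kinetic.items()},
        dict(truth_params.scaling),
    )
    p = pack_parameters(scaled, m4)
    y = np.array([0.1, 0.1, 0.1, 0.5, 1.0, 0.3, 0.5, 0.5])
    dy = rhs_array(y, insulin, p)
    assert np.all(np.isfinite(dy))
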