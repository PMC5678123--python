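import math

import numpy as np
import pytest

from hepinsulin.fitting import (
    Condition,
    DEConfig,
    ExperimentDataset,
    FitResult,
    aicc,
    default_bounds,
    fit_variant,
    maicc,
    rank_variants,
    rms_objective,
)
from hepinsulin.model import SCALING_PARAMS, variant
from hepinsulin.profiles import by_label
from hepinsulin.simulate import simulate

TINY_DE = DEConfig(popsize=4, generations=4, rk4_dt=0.05, polish_topk=0)


# -- dataset validation ----------------------------------------------------

def test_dataset_rejects_out_of_window_points():
    # the feeding template spans exactly the first 2 h, so a later point
    # violates both the span and the 2-h restriction
    with pytest.raises(ValueError, match="span|120"):
        ExperimentDataset([
            Condition("feeding", "IRS1", [0.0, 130.0], [1.0, 1.0], [0.1, 0.1])
        ])
    with pytest.raises(ValueError, match="10"):
        ExperimentDataset([
            Condition("pulsatile_high", "Akt_inf", [5.0], [1.0], [0.1])
        ])
    with pytest.raises(ValueError, match="s.e.m."):
        ExperimentDataset([
            Condition("feeding", "IRS1", [0.0], [1.0], [0.0])
        ])


def test_dataset_csv_roundtrip(noisy_dataset):
    df = noisy_dataset.to_frame()
    back = ExperimentDataset.from_frame(df)
    assert back.n_points == noisy_dataset.n_points
    for a, b in zip(noisy_dataset.conditions, back.conditions):
        np.testing.assert_allclose(a.means, b.means)
        assert a.profile_label == b.profile_label


# -- RMS objective ---------------------------------------------------------

def test_rms_zero_on_self_generated_data(truth, clean_dataset):
    params, v = truth
    assert rms_objective(params, v, clean_dataset) < 1e-8


def test_rms_of_uniform_shift_is_the_shift(truth, clean_dataset):
    params, v = truth
    shifted = ExperimentDataset([
        Condition(c.profile_label, c.observable, c.times, c.means + 3.0,
                  c.sems, c.scaling_id)
        for c in clean_dataset.conditions
    ])
    assert rms_objective(params, v, shifted) == pytest.approx(3.0, abs=1e-8)


def test_rms_matches_independent_two_pass_accumulation(truth, noisy_dataset):
    params, v = truth
    total, count = 0.0, 0
    for c in noisy_dataset.conditions:
        traj = simulate(v, params, by_label(c.profile_label),
                        t_end=float(c.times.max()), solver="rk4")
        idx = np.rint(c.times / 0.1).astype(int)
        pred = traj.observables[c.observable][idx]
        for p_i, m_i in zip(pred, c.means):
            total += (p_i - m_i) ** 2
            count += 1
    expected = math.sqrt(total / count)
    assert rms_objective(params, v, noisy_dataset) == pytest.approx(
        expected, abs=1e-12
    )


# -- AICc / mAICc ----------------------------------------------------------

def test_aicc_closed_form_value():
    # n ln(rss/n) + 2k + 2k(k+1)/(n-k-1) at n=40, k=5, rss=10
    # 40*ln(1/4) + 10 + 60/34, evaluated by hand to 7 decimals
    assert aicc(10.0, 40, 5) == pytest.approx(-43.6870686, abs=1e-6)


def test_aicc_monotonicity_and_log_identity():
    assert aicc(10.0, 40, 5) < aicc(10.0, 40, 7)
    assert aicc(5.0, 40, 5) < aicc(10.0, 40, 5)
    assert aicc(10.0 * math.e, 40, 5) - aicc(10.0, 40, 5) == pytest.approx(40.0)
    with pytest.raises(ValueError):
        aicc(1.0, 6, 5)


def test_maicc_single_perturbation_equals_aicc(truth, noisy_dataset):
    params, v = truth
    rms = rms_objective(params, v, noisy_dataset)
    n = noisy_dataset.n_points
    k = len(v.parameter_names()) + len(SCALING_PARAMS)
    expected = aicc(rms**2 * n, n, k)
    got = maicc(params, v, noisy_dataset, perturbations=(1.0,))
    assert got == pytest.approx(expected, abs=1e-9)


def test_maicc_is_mean_of_componentwise_aicc(truth, noisy_dataset):
    params, v = truth
    n = noisy_dataset.n_points
    k = len(v.parameter_names()) + len(SCALING_PARAMS)
    comps = []
    for f in (0.85, 1.0, 1.15):
        rms = rms_objective(params, v, noisy_dataset, input_scale=f)
        comps.append(aicc(rms**2 * n, n, k))
    assert maicc(params, v, noisy_dataset) == pytest.approx(
        float(np.mean(comps)), abs=1e-12
    )
    with pytest.raises(ValueError):
        maicc(params, v, noisy_dataset, perturbations=())


# -- differential evolution ------------------------------------------------

def _init_population(v, include, n_members, seed):
    bounds = default_bounds(v)
    names = list(v.parameter_names())
    rng = np.random.default_rng(seed)
    lo = np.array([math.log10(bounds[n][0]) for n in names])
    hi = np.array([math.log10(bounds[n][1]) for n in names])
    pop = rng.uniform(lo, hi, size=(n_members, len(names)))
    pop[0] = [math.log10(include.kinetic[n]) for n in names]
    return pop


def test_fit_recovers_planted_truth_on_clean_data(truth, clean_dataset):
    """With the truth present in the initial population and no noise, no
    candidate can beat it, so DE returns it with (near) zero residual."""
    params, v = truth
    init = _init_population(v, params, 40, seed=5)
    cfg = DEConfig(popsize=4, generations=5, rk4_dt=0.01, init=init,
                   polish_topk=0)
    res = fit_variant(v, clean_dataset, de_config=cfg, seed=0)
    assert res.rms < 1e-6
    for name, val in params.kinetic.items():
        assert res.params.kinetic[name] == pytest.approx(val, rel=1e-9)


def test_fit_is_deterministic_given_seed(truth, noisy_dataset):
    _, v = truth
    r1 = fit_variant(v, noisy_dataset, de_config=TINY_DE, seed=11)
    r2 = fit_variant(v, noisy_dataset, de_config=TINY_DE, seed=11)
    assert r1.rms == r2.rms
    assert r1.params.kinetic == r2.params.kinetic
    r3 = fit_variant(v, noisy_dataset, de_config=TINY_DE, seed=12)
    assert r3.params.kinetic != r1.params.kinetic


def test_fit_result_is_finite_and_flagged(truth, noisy_dataset):
    _, v = truth
    res = fit_variant(v, noisy_dataset, de_config=TINY_DE, seed=1)
    assert res.converged
    assert math.isfinite(res.aicc) and math.isfinite(res.maicc)
    assert res.k == 29 and res.n == noisy_dataset.n_points


def test_bounds_clamp_is_respected(truth, noisy_dataset):
    _, v = truth
    res = fit_variant(
        v, noisy_dataset, bounds={"k_rec": (0.5, 0.6)}, de_config=TINY_DE, seed=3
    )
    assert 0.5 <= res.params.kinetic["k_rec"] <= 0.6
    with pytest.raises(ValueError):
        fit_variant(v, noisy_dataset, bounds={"nope": (1, 2)}, de_config=TINY_DE)


# -- ranking ---------------------------------------------------------------

def fake_result(name, k, rms, score, m_score):
    return FitResult(
        params=None, rms=rms, rss=rms**2 * 50, n=50, k=k, aicc=score,
        maicc=m_score, seed=0, converged=True, variant_name=name,
    )


def test_rank_orders_by_maicc_then_aicc_then_rms():
    table = rank_variants({
        "A": fake_result("A", 29, 1.0, -10.0, -9.0),
        "B": fake_result("B", 37, 1.0, -12.0, -9.0),
        "C": fake_result("C", 31, 2.0, -5.0, -20.0),
    })
    assert list(table["variant"]) == ["C", "B", "A"]


def test_rank_penalizes_extra_parameters_at_equal_fit():
    n, rss = 50, 4.0
    small = fake_result("small", 29, math.sqrt(rss / n), aicc(rss, n, 29), aicc(rss, n, 29))
    big = fake_result("big", 37, math.sqrt(rss / n), aicc(rss, n, 37), aicc(rss, n, 37))
    table = rank_variants({"small": small, "big": big})
    assert list(table["variant"])[0] == "small"
    single = rank_variants({"only": small})
    assert len(single) == 1
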