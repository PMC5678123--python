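import numpy as np
import pytest
from scipy.signal import find_peaks

from hepinsulin.fitting import DEConfig, FitResult
from hepinsulin.identifiability import (
    SolutionSet,
    confinement_report,
    maicc_filter,
    min_distance_filter,
    prediction_consistency,
    receptor_pulse_amplitude,
    receptor_recycling_filter,
    region_constrained_fits,
)
from hepinsulin.model import ParameterSet
from hepinsulin.profiles import PULSE_PERIOD_MIN, infusion_profile
from hepinsulin.simulate import simulate

TINY_DE = DEConfig(popsize=3, generations=2, rk4_dt=0.05, polish_topk=0)


def solution_from(params, rms=1.0, m=0.0):
    return FitResult(params=params, rms=rms, rss=rms**2, n=50, k=29, aicc=m,
                     maicc=m, seed=0, converged=True, variant_name="M4")


def shifted(params, name, factor):
    p = params.copy()
    p.kinetic[name] *= factor
    return p


# -- step 1: region-constrained fits ---------------------------------------

def test_region_fits_launch_one_job_per_region(truth, noisy_dataset):
    _, v = truth
    regions = {"k_rec": [(0.05, 0.5), (0.5, 5.0)], "w_e": [(0.05, 0.3), (0.3, 2.0)]}
    sols = region_constrained_fits(v, noisy_dataset, regions, de_config=TINY_DE, seed=4)
    assert len(sols.solutions) == 4
    for sol, prov in zip(sols.solutions, sols.provenance):
        lo, hi = prov["region"]
        assert lo <= sol.params.kinetic[prov["confined_parameter"]] <= hi
    rerun = region_constrained_fits(v, noisy_dataset, regions, de_config=TINY_DE, seed=4)
    for a, b in zip(sols.solutions, rerun.solutions):
        assert a.params.kinetic == b.params.kinetic


# -- step 2: receptor recycling filter -------------------------------------

def test_trapped_receptor_is_rejected(truth):
    params, v = truth
    assert receptor_pulse_amplitude(params, v) > 0.2
    trapped = params.copy()
    trapped.kinetic["k_rec"] = 1e-4
    trapped.kinetic["k_dp2"] = 1e-4
    assert receptor_pulse_amplitude(trapped, v) < 0.2

    sols = SolutionSet([solution_from(params), solution_from(trapped)],
                       provenance=[{}, {}])
    kept = receptor_recycling_filter(sols, v, threshold=0.2)
    assert len(kept.solutions) == 1
    assert kept.filter_log[0]["step"] == "receptor_recycling"


def test_recycling_metric_matches_peak_finding_oracle(truth):
    """The filter's (peak - trough)/mean agrees with direct long-horizon
    simulation plus peak detection."""
    params, v = truth
    prof = infusion_profile("pulsatile_high", duration=60.0)
    traj = simulate(v, params, prof, t_end=60.0)
    r_p = traj.state("r_p")[traj.times >= 30.0]
    t = traj.times[traj.times >= 30.0]
    peaks, _ = find_peaks(r_p)
    troughs, _ = find_peaks(-r_p)
    oracle = (r_p[peaks].mean() - r_p[troughs].mean()) / r_p.mean()
    got = receptor_pulse_amplitude(params, v)
    assert got == pytest.approx(oracle, rel=0.05)
    # sanity: pulses recur at the forcing period
    assert np.allclose(np.diff(t[peaks]), PULSE_PERIOD_MIN, atol=0.1)


# -- step 3: minimum distance ----------------------------------------------

def test_min_distance_keeps_best_of_duplicates(truth_params):
    best = solution_from(truth_params, rms=0.5)
    dup = solution_from(truth_params.copy(), rms=0.9)
    far = solution_from(shifted(truth_params, "k_rec", 100.0), rms=1.2)
    sols = SolutionSet([dup, best, far], provenance=[{}, {}, {}])
    kept = min_distance_filter(sols, epsilon=0.5)
    assert len(kept.solutions) == 2
    assert best in kept.solutions and far in kept.solutions


def test_min_distance_boundary_pair_both_kept(truth_params):
    eps = 0.5
    a = solution_from(truth_params, rms=0.5)
    b = solution_from(shifted(truth_params, "k_rec", 10 ** (eps + 1e-9)), rms=0.6)
    kept = min_distance_filter(SolutionSet([a, b], [{}, {}]), epsilon=eps)
    assert len(kept.solutions) == 2
    empty = min_distance_filter(SolutionSet([], []), epsilon=eps)
    assert empty.solutions == []


def test_min_distance_idempotent(truth_params):
    sols = SolutionSet(
        [solution_from(shifted(truth_params, "k_rec", f), rms=f)
         for f in (1.0, 1.01, 50.0)],
        [{}, {}, {}],
    )
    once = min_distance_filter(sols)
    twice = min_distance_filter(once)
    assert [s.rms for s in once.solutions] == [s.rms for s in twice.solutions]


# -- step 4: mAICc filter ---------------------------------------------------

def test_maicc_filter_rule(truth_params):
    scores = [0.0, 1.5, 10.0, 0.5]
    sols = SolutionSet(
        [solution_from(truth_params, m=m) for m in scores],
        [{} for _ in scores],
    )
    kept = maicc_filter(sols, cutoff_delta=2.0)
    kept_scores = [s.maicc for s in kept.solutions]
    assert kept_scores == [m for m in scores if m <= min(scores) + 2.0]
    all_equal = SolutionSet([solution_from(truth_params, m=3.0)] * 3, [{}] * 3)
    assert len(maicc_filter(all_equal).solutions) == 3


# -- step 5: prediction consistency ----------------------------------------

def test_single_solution_is_trivially_consistent(truth_params):
    sols = SolutionSet([solution_from(truth_params)], [{}])
    report = prediction_consistency(sols, {"bistable": lambda s: True})
    assert report["consistent"] == {"bistable": True}
    assert report["inconsistent"] == {}


def test_planted_outlier_is_flagged(truth_params):
    mono = shifted(truth_params, "v_auto", 1e-3)
    sols = SolutionSet(
        [solution_from(truth_params)] * 3 + [solution_from(mono)],
        [{}] * 4,
    )

    def bistable(sol):
        from hepinsulin.bifurcation import find_limit_points

        lp1, _ = find_limit_points(sol.params)
        return lp1 is not None

    report = prediction_consistency(sols, {"bistable": bistable})
    assert "bistable" in report["inconsistent"]


# -- confinement -----------------------------------------------------------

def test_confinement_verdicts_match_columnwise_ranges(truth_params):
    sols = SolutionSet(
        [solution_from(truth_params),
         solution_from(shifted(truth_params, "k_rec", 2000.0)),
         solution_from(shifted(truth_params, "w_e", 1.01))],
        [{}] * 3,
    )
    report = confinement_report(sols, decade_threshold=1.0)
    assert not report["k_rec"]["confined"]
    assert report["k_rec"]["log10_range"] == pytest.approx(np.log10(2000.0))
    assert report["w_e"]["confined"]
    assert report["k_ins"]["confined"]  # identical across solutions
    with pytest.raises(ValueError):
        confinement_report(SolutionSet([solution_from(truth_params)], [{}]))
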