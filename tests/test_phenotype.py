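"""Property tests of the timing phenotype under the shipped ground truth:
dose decoding by switch timing, pulse-amplitude effects, and the
IRS2/aPKC-vs-IRS1/Akt window dissociation."""

import numpy as np
import pytest

from hepinsulin.bifurcation import classify_infusion_regime
from hepinsulin.profiles import (
    by_label,
    composite_pulsatile,
    feeding_profile,
    first_phase_profile,
)
from hepinsulin.simulate import detect_switch_events, simulate, windowed_auc
from hepinsulin.synth import default_truth

DOSES = (0.85, 1.0, 1.15)
SHAPES = ("normal_fp", "impaired_slope", "T2D_b")


@pytest.fixture(scope="module")
def truth_pair():
    return default_truth()


@pytest.fixture(scope="module")
def dose_runs(truth_pair):
    params, v = truth_pair
    out = {}
    for sc in DOSES:
        traj = simulate(v, params, feeding_profile(sc), t_end=120.0, solver="rk4")
        out[sc] = (traj, detect_switch_events(traj))
    return out


@pytest.fixture(scope="module")
def shape_runs(truth_pair):
    params, v = truth_pair
    out = {}
    for shape in SHAPES:
        prof = first_phase_profile(shape)
        traj = simulate(v, params, prof, t_end=180.0, solver="rk4")
        out[shape] = (prof, traj, detect_switch_events(traj))
    return out


@pytest.fixture(scope="module")
def pulse_runs(truth_pair):
    params, v = truth_pair
    base = first_phase_profile("normal_fp")
    out = {}
    for name, prof in [
        ("non_pulsatile", base),
        ("high", composite_pulsatile(base, 1.0)),
        ("low", composite_pulsatile(base, 0.25)),
    ]:
        traj = simulate(v, params, prof, t_end=180.0, solver="rk4")
        out[name] = detect_switch_events(traj)
    return out


def test_dose_delays_switch_off_and_rebounds(dose_runs):
    offs = [dose_runs[sc][1].pkc_off for sc in DOSES]
    irs1_rebs = [dose_runs[sc][1].irs1_rebound for sc in DOSES]
    akt_rebs = [dose_runs[sc][1].akt_rebound for sc in DOSES]
    for seq in (offs, irs1_rebs, akt_rebs):
        assert all(x is not None for x in seq)
        assert seq[0] < seq[1] < seq[2]


def test_dose_leaves_plateau_levels_unchanged(dose_runs):
    pkc_plateaus, irs1_tails = [], []
    for sc in DOSES:
        traj, ev = dose_runs[sc]
        on_window = (traj.times > ev.pkc_on + 5) & (traj.times < ev.pkc_off - 5)
        pkc_plateaus.append(traj.state("pkc")[on_window].mean())
        irs1_tails.append(traj.state("irs1")[traj.times > 115].mean())
    for levels in (pkc_plateaus, irs1_tails):
        spread = (max(levels) - min(levels)) / np.mean(levels)
        assert spread < 0.10


def test_pulse_amplitude_orders_switch_off(pulse_runs):
    assert (
        pulse_runs["high"].pkc_off
        < pulse_runs["low"].pkc_off
        < pulse_runs["non_pulsatile"].pkc_off
    )


def test_pulsatile_switch_off_within_an_hour_of_onset(pulse_runs):
    for name in ("high", "low"):
        ev = pulse_runs[name]
        assert ev.pkc_off - ev.pkc_on <= 60.0


def test_infusion_regimes_split_by_lp2(truth_pair, diagram):
    params, v = truth_pair
    const = simulate(v, params, by_label("constant_high"), t_end=30.0, solver="rk4")
    puls = simulate(v, params, by_label("pulsatile_high"), t_end=30.0, solver="rk4")
    assert classify_infusion_regime(const, diagram) == "stays_on"
    assert classify_infusion_regime(puls, diagram) == "switches_off"
    # residual aPKC activity under constant infusion, deactivation under pulses
    assert const.state("pkc")[-1] > 0.2 * const.state("pkc").max()
    assert puls.state("pkc")[-1] < 0.5 * const.state("pkc")[-1]


def test_first_phase_switch_off_ordering(shape_runs):
    offs = [shape_runs[s][2].pkc_off for s in SHAPES]
    assert all(o is not None for o in offs)
    assert offs[0] < offs[1] < offs[2]


def test_first_hour_irs2_apkc_follow_insulin(shape_runs):
    ins, irs2, pkc = [], [], []
    for shape in SHAPES:
        prof, traj, _ = shape_runs[shape]
        grid = np.linspace(0, 60, 6001)
        ins.append(np.trapezoid(prof.evaluate(grid), grid))
        irs2.append(windowed_auc(traj, "irs2", (0, 60)))
        pkc.append(windowed_auc(traj, "pkc", (0, 60)))
    assert ins[0] > ins[1] > ins[2]
    assert irs2[0] > irs2[1] > irs2[2]
    assert pkc[0] > pkc[1] > pkc[2]


def test_second_hour_irs1_akt_reverse_insulin_trend(shape_runs):
    ins, irs1, akt = [], [], []
    for shape in SHAPES:
        prof, traj, _ = shape_runs[shape]
        grid = np.linspace(60, 120, 6001)
        ins.append(np.trapezoid(prof.evaluate(grid), grid))
        irs1.append(windowed_auc(traj, "irs1", (60, 120)))
        akt.append(windowed_auc(traj, "akt", (60, 120)))
    assert ins[0] < ins[1] < ins[2]
    assert irs1[0] > irs1[1] > irs1[2]
    assert akt[0] > akt[1] > akt[2]


def test_receptor_conservation_on_all_runs(dose_runs, shape_runs):
    for traj, _ in dose_runs.values():
        total = traj.states[:, :3].sum(axis=1)
        assert np.all(total < 1 + 1e-6) and np.all(total > -1e-9)
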