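"""Simulate refeeding at three insulin doses (85/100/115%) and extract the
timing readouts: the aPKC switch window shifts with dose while the
activation plateaus barely move — dose is decoded by timing, not level."""

import argparse
from pathlib import Path

import pandas as pd

from hepinsulin.profiles import feeding_profile
from hepinsulin.simulate import detect_switch_events, simulate
from hepinsulin.synth import default_truth


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/feeding"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    params, v = default_truth()
    rows = []
    for scale in (0.85, 1.0, 1.15):
        traj = simulate(v, params, feeding_profile(scale), t_end=120.0)
        traj.to_frame().to_csv(args.out / f"trajectory_scale{scale}.csv", index=False)
        ev = detect_switch_events(traj)
        on_win = (traj.times > ev.pkc_on + 5) & (traj.times < ev.pkc_off - 5)
        rows.append({
            "scale": scale,
            "pkc_on_min": ev.pkc_on,
            "pkc_off_min": ev.pkc_off,
            "irs1_rebound_min": ev.irs1_rebound,
            "akt_rebound_min": ev.akt_rebound,
            "pkc_plateau": traj.state("pkc")[on_win].mean(),
            "irs1_late": traj.state("irs1")[traj.times > 115].mean(),
        })
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "dose_timing.csv", index=False)
    print(table.to_string(index=False))
    print("\nswitch-off and rebounds are delayed by higher insulin dose;"
          " plateau levels change by "
          f"{100 * (table.pkc_plateau.max() / table.pkc_plateau.min() - 1):.1f}%"
          " (aPKC) across doses.")


if __name__ == "__main__":
    main()
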