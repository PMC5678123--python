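"""Scaled-down identifiability pipeline: generate diverse solutions by
region-constrained refits, filter them (receptor recycling, minimum
distance, mAICc), report which parameters are well confined, and check that
the headline predictions are consistent across all surviving solutions."""

import argparse
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from hepinsulin.bifurcation import find_limit_points
from hepinsulin.fitting import DEConfig, default_bounds
from hepinsulin.identifiability import (
    confinement_report,
    maicc_filter,
    min_distance_filter,
    prediction_consistency,
    receptor_recycling_filter,
    region_constrained_fits,
)
from hepinsulin.model import variant
from hepinsulin.synth import SynthesisDesign, default_truth, synthesize


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--generations", type=int, default=50)
    ap.add_argument("--confine", nargs="+", default=["k_rec", "w_e"],
                    help="poorly-informed parameters to confine region-wise")
    ap.add_argument("--regions", type=int, default=2)
    ap.add_argument("--out", type=Path, default=Path("results/identifiability"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    truth, v = default_truth()
    ds = synthesize(truth, v, SynthesisDesign(noise_cv=0.05, seed=args.seed))
    cfg = DEConfig(popsize=5, generations=args.generations, rk4_dt=0.02,
                   polish_topk=2)
    bounds = default_bounds(v)
    regions = {}
    for pname in args.confine:
        lo, hi = bounds[pname]
        edges = np.logspace(math.log10(lo), math.log10(hi), args.regions + 1)
        regions[pname] = list(zip(edges[:-1], edges[1:]))

    sols = region_constrained_fits(v, ds, regions, de_config=cfg, seed=args.seed)
    print(f"step 1: {len(sols.solutions)} region-constrained fits")
    sols = receptor_recycling_filter(sols, v)
    print(f"step 2: {len(sols.solutions)} pass the receptor-recycling filter")
    sols = min_distance_filter(sols)
    print(f"step 3: {len(sols.solutions)} after minimum-distance pruning")
    sols = maicc_filter(sols)
    print(f"step 4: {len(sols.solutions)} within the mAICc cutoff")
    (args.out / "solution_set.json").write_text(
        json.dumps(sols.to_json(), indent=2) + "\n"
    )

    if len(sols.solutions) >= 2:
        report = confinement_report(sols)
        pd.DataFrame(report).T.to_csv(args.out / "confinement.csv")
        confined = sorted(n for n, r in report.items() if r["confined"])
        print(f"\nwell-confined parameters ({len(confined)}): {confined}")

    battery = {
        "bistable": lambda s: find_limit_points(s.params)[0] is not None,
        "hysteresis": lambda s: (
            (lp := find_limit_points(s.params))[0] is not None
            and lp[0].irs2 > lp[1].irs2
        ),
    }
    consistency = prediction_consistency(sols, battery)
    (args.out / "consistency.json").write_text(
        json.dumps(consistency, indent=2, default=str) + "\n"
    )
    print("\nstep 5 consistency report:", consistency)


if __name__ == "__main__":
    main()
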