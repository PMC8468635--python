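#!/usr/bin/env python
"""Vessel morphometry over a simulated observation week.

Generates synthetic lumen masks for day 0-7 (with the same per-day cohort
sizes as the week-long device observations), measures diameter and density,
and runs the longitudinal stability ANOVA. Writes tidy CSVs under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import oxychip as oc
from oxychip import io as oio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--masks-per-day", type=int, default=3,
                    help="synthetic masks measured per day (desk scale)")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    mask_dir = args.out / "masks"
    mask_dir.mkdir(exist_ok=True)

    rows = []
    measurements = []
    seed = args.seed
    for day in range(8):
        for k in range(args.masks_per_day):
            mask, truth = oc.gen_lumen_mask(oc.LumenGenParams(seed=seed))
            mask.day = day
            seed += 1
            vm = oc.measure_diameter(mask)
            measurements.append(vm)
            if k == 0:
                oio.write_mask(mask, mask_dir / f"day{day}.tif")
            rows.append(
                {
                    "day": day,
                    "replicate": k,
                    "diameter_um": vm.mean * 1e6,
                    "diameter_sd_um": vm.sd * 1e6,
                    "true_width_um": truth["true_width_m"].mean() * 1e6,
                    "density": vm.density,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "morphometry.csv", index=False)

    summary, F, p = oc.longitudinal_stability(measurements)
    summary.to_csv(args.out / "morphometry_by_day.csv", index=False)
    grand = table["diameter_um"].mean()
    err = abs(grand - table["true_width_um"].mean()) / table["true_width_um"].mean()
    print(f"grand mean diameter {grand:.1f} um "
          f"(ground-truth recovery error {100 * err:.1f}%)")
    print(f"one-way ANOVA across days: F = {F:.2f}, p = {p:.3f} -> "
          f"{'stable (n.s.)' if p >= 0.05 else 'significant change'}")


if __name__ == "__main__":
    main()
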