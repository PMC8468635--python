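#!/usr/bin/env python
"""Derive the hypoxia read-outs from the simulated oxygen fields.

Reads the HDF5 fields written by 01_simulate_oxygen.py and emits tidy CSVs
(radial profiles, vascular difference, approach-to-steady-state curves)
plus overview figures under results/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import oxychip as oc
from oxychip import io as oio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fields", type=Path, default=Path("results"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    steady_with = oio.load_fields(args.fields / "steady_with.h5").final
    steady_without = oio.load_fields(args.fields / "steady_without.h5").final
    series = oio.load_fields(args.fields / "transient_with.h5")

    p_with = oc.radial_profile(steady_with, label="with_vasculature")
    p_without = oc.radial_profile(steady_without, label="without_vasculature")
    diff = oc.vascular_difference(p_with, p_without)
    profiles = pd.concat(
        [
            pd.DataFrame({"r_m": p.r, "C_mol_m3": p.C, "label": p.label})
            for p in (p_with, p_without, diff)
        ]
    )
    profiles.to_csv(args.out / "radial_profiles.csv", index=False)
    print(f"center oxygen (with vasculature): {p_with.C[0]:.3e} mol/m^3; "
          f"edge difference without-with: {diff.C[-1]:.3e} mol/m^3")

    curve = oc.approach_fraction(series, steady_with)
    tidy = pd.DataFrame(
        [
            {"t_s": t, "r_m": r, "fraction": curve.f[i, k]}
            for i, r in enumerate(curve.positions)
            for k, t in enumerate(curve.t)
        ]
    )
    tidy.to_csv(args.out / "approach_curves.csv", index=False)
    f30 = curve.f[:, -1].min()
    print(f"minimum transition completion at 30 min over tracked radii: "
          f"{100 * f30:.2f}%")

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for p in (p_with, p_without):
        axes[0].plot(p.r * 1e3, p.C, label=p.label)
    ax2 = axes[0].twinx()
    ax2.plot(diff.r * 1e3, diff.C, color="orange", label="difference")
    ax2.set_ylabel("difference, mol/m$^3$")
    axes[0].set_xlabel("r, mm")
    axes[0].set_ylabel("C, mol/m$^3$")
    axes[0].legend(loc="upper left")
    for i, r in enumerate(curve.positions):
        axes[1].plot(curve.t / 60, curve.f[i], label=f"r = {r * 1e3:.2f} mm")
    axes[1].axhline(0.9, ls="--", c="gray")
    axes[1].set_xlabel("t, min")
    axes[1].set_ylabel("completion fraction")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(args.out / "hypoxia_readouts.png", dpi=150)


if __name__ == "__main__":
    main()
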