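#!/usr/bin/env python
"""Force-clamp campaign: classify planted catch/slip bonds from trajectories.

Plants one bond of each of the five force-response modes (steady,
catch-slip, slip-catch, catch-slip-catch, slip-catch-slip), samples three
2000-frame replicates at each of 0/25/50/75/100 pN, and recovers:

* the per-pair occupancy thermograph with its mode classification,
* force-response profiles (mean ± SE over replicates) for interaction
  energy, N_HB, fD, loop mass-centre distance (DMC) and strand cross-angle,
* biphasic force thresholds of each profile,
* a Gaussian fit of the N_HB frequency histogram at every force.

The classification must return exactly the planted mode for every bond;
the catch-slip bond's occupancy peaks at 50 pN, so the fD profile of a
catch-slip-only interface would bottom out there.
"""

import argparse
import os
import sys

import mechbond as mb

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "tests"))
from helpers import five_mode_specs

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "clamp")


def main() -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--frames", type=int, default=2000)
    args = parser.parse_args()

    cfg = mb.GeneratorConfig(
        n_residues_per_chain=5, bond_specs=five_mode_specs(),
        n_frames=args.frames, seed=args.seed,
    )
    structure = mb.generate_complex(cfg)
    trajectories = {
        force: [
            mb.generate_trajectory(structure, cfg, force, replicate=r)
            for r in range(3)
        ]
        for force in cfg.force_grid
    }
    rc = mb.RunConfig(
        label="clamp", sasa_stride=500, sasa_points=240,
        loop1=("A", 1, 2), loop2=("B", 1, 2),
        strand_a=("A", 1, 5), strand_b=("B", 1, 5),
    )
    report = mb.run_force_clamp_analysis(trajectories, rc)
    paths = report.write(os.path.join(OUT, "clamp"))

    print("thermograph (mean occupancy per force, classified mode):")
    print(report.thermograph.round(3).to_string())
    planted = {s.label: s.mode for s in cfg.bond_specs}
    got = dict(zip(report.thermograph.index, report.thermograph["mode"]))
    ok = sum(
        got[f"GLY{i + 1}(A)-GLY{i + 1}(B)"] == spec.mode
        for i, spec in enumerate(cfg.bond_specs)
    )
    print(f"\nplanted modes recovered: {ok}/5")
    print("\nbiphasic thresholds of the mean profiles:")
    for metric, res in sorted(report.thresholds.items()):
        if res.monotone:
            desc = "monotone (no threshold)"
        elif res.biphasic:
            desc = f"{res.threshold[0]:g} pN ({res.threshold[1]})"
        else:
            desc = "non-biphasic: " + ", ".join(
                f"{f:g} pN ({k})" for f, k in res.thresholds
            )
        print(f"  {metric:8s} {desc}")
    print("\nGaussian fits of the N_HB frequency:")
    for force, fit in sorted(report.gaussian_fits.items()):
        if fit:
            print(f"  {force:5.0f} pN: mu={fit.mean:.2f} sigma={fit.sigma:.2f}")
    print(f"\nwrote {len(paths)} files under {OUT}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
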