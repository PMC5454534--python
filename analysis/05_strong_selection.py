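"""One-round strong selection of the generation-3 populations on three
antibiotic overlays: deleterious-fraction curves, weakly beneficial
fractions, and antibiotic-specific SNPs.

Usage: python analysis/05_strong_selection.py [--seed 1] [--out results]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mistransevo import evo_sim as sim
from mistransevo.amplicon_io import classify_snp_effect
from mistransevo.trajectories import (
    beneficial_fraction,
    condition_specific_snps,
    deleterious_fraction_curve,
    mean_curve,
)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

outdir = args.out / "strong_selection"
outdir.mkdir(parents=True, exist_ok=True)

base = sim.SimConfig(seed=args.seed)
landscape = sim.init_effect_table(base, np.random.default_rng([args.seed, 1000]))
conditions = ("piperacillin", "cefoxitin", "oxacillin_clavulanate")

curve_rows = []
for arm_name, cfg in {
    "wild_type": base.wild_type_arm(),
    "error_prone": base.error_prone_arm(),
}.items():
    pops, table, _ = sim.run_experiment(cfg, landscape)
    gen3 = pops[3]
    by_condition = {}
    for i, cond in enumerate(conditions):
        overlay = sim.condition_overlay(table, cond, seed=1)
        _, changes = sim.strong_selection_round(gen3, cfg, table, overlay,
                                                seed_offset=i)
        changes["effect"] = [
            classify_snp_effect(int(r["position"]), r["alt"], cfg.reference)[0]
            for _, r in changes.iterrows()
        ]
        by_condition[cond] = changes
        curve = deleterious_fraction_curve(changes)
        curve["host"] = arm_name
        curve["condition"] = cond
        curve_rows.append(curve)
        print(
            f"{arm_name} / {cond}: "
            f"{curve[curve.threshold == 0.01]['percentage'].iloc[0]:.1f}% of "
            f"non-synonymous SNPs decrease by >=1%; weakly beneficial "
            f"(increase >0.5%): {beneficial_fraction(changes):.1f}%"
        )
    specific = condition_specific_snps(by_condition)
    n_del = sum((df["delta_f"] <= -0.005).sum() for df in by_condition.values())
    print(
        f"{arm_name}: {len(specific)} condition-specific SNPs "
        f"out of {n_del} decreasing by >=0.5% anywhere"
    )
    specific.to_csv(outdir / f"condition_specific_{arm_name}.tsv",
                    sep="\t", index=False)

curves = pd.concat(curve_rows, ignore_index=True)
curves.to_csv(outdir / "deleterious_fraction_curves.tsv", sep="\t", index=False)
for arm_name in ("wild_type", "error_prone"):
    m = mean_curve(
        [g for _, g in curves[curves.host == arm_name].groupby("condition")]
    )
    m["host"] = arm_name
    m.to_csv(outdir / f"mean_curve_{arm_name}.tsv", sep="\t", index=False)
print(f"wrote curves to {outdir}")
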