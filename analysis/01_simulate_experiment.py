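"""Simulate one wild-type-host and one error-prone-host evolution experiment
(four rounds of mutagenesis + cefotaxime truncation selection) and write the
emitted FASTQ reads, ground-truth allele frequencies and MIC trajectories.

Usage: python analysis/01_simulate_experiment.py [--seed 1] [--out results]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from mistransevo import evo_sim as sim

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

outdir = args.out / "simulation"
outdir.mkdir(parents=True, exist_ok=True)

base = sim.SimConfig(seed=args.seed)
landscape = sim.init_effect_table(base, np.random.default_rng([args.seed, 1000]))
ref = base.reference
(outdir / "reference.fa").write_text(f">{ref.id}\n{ref.cds_sequence}\n")

manifest = {"seed": args.seed, "arms": {}}
meta_rows = []
for arm_name, cfg in {
    "wild_type": base.wild_type_arm(),
    "error_prone": base.error_prone_arm(),
}.items():
    pops, _, truth = sim.run_experiment(cfg, landscape)
    truth.to_csv(outdir / f"truth_{arm_name}.tsv", sep="\t", index=False)
    mics = [p.chosen_concentration for p in pops[1:]]
    manifest["arms"][arm_name] = {
        "mistranslation_rate": cfg.mistranslation_rate,
        "mic_trajectory": mics,
    }
    for pop in pops:
        rng = np.random.default_rng([cfg.seed, 9, pop.generation])
        records, _ = sim.emit_fastq(pop, cfg.depth, cfg.seq_error_rate, rng)
        name = f"{arm_name}_gen{pop.generation}.fastq"
        sim.write_fastq(records, outdir / name)
        meta_rows.append(
            f"{name}\t{arm_name}\t1\t{pop.generation}\tcefotaxime"
        )
    print(f"{arm_name}: MIC trajectory {mics}")

(outdir / "metadata.tsv").write_text(
    "file\thost\treplicate\tgeneration\tcondition\n" + "\n".join(meta_rows) + "\n"
)
(outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
print(f"wrote FASTQ + truth tables to {outdir}")
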