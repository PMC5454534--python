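"""Diversity analyses of the simulated populations: per-site and mean
positional-counting diversity, pairwise Hamming distributions, haplotype
spectra and a PCA projection of sampled haplotypes (sweep columns removed).

Usage: python analysis/03_diversity_analysis.py [--seed 1] [--out results]
(after 01/02)
"""

import argparse
from pathlib import Path

import pandas as pd

from mistransevo.amplicon_io import filter_reads, read_reference, reads_from_fastq, PopulationAlignment, snp_frequency_table
from mistransevo.diversity import (
    haplotype_spectrum,
    mean_diversity,
    pairwise_hamming,
    pca_project,
)
from mistransevo.trajectories import build_trajectories, detect_sweeps

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

simdir = args.out / "simulation"
outdir = args.out / "diversity"
outdir.mkdir(parents=True, exist_ok=True)

reference = read_reference(simdir / "reference.fa", require_start=False)
meta = pd.read_csv(simdir / "metadata.tsv", sep="\t")
L = len(reference)

pops, tables = [], []
for _, row in meta.iterrows():
    reads = reads_from_fastq(simdir / row["file"], reference)
    passed, _ = filter_reads(reads, reference, len_range=(L - 60, L + 60))
    pop = PopulationAlignment(
        passed, host=row["host"], replicate=int(row["replicate"]),
        generation=int(row["generation"]), condition=row["condition"],
    )
    pops.append(pop)
    tables.append(snp_frequency_table(pop, reference))

rows = []
for pop in pops:
    ham = pairwise_hamming(pop)
    spectrum = haplotype_spectrum(pop)
    rows.append(
        {
            "host": pop.host,
            "generation": pop.generation,
            "mean_diversity": mean_diversity(pop),
            "mean_hamming": ham["mean"],
            "sd_hamming": ham["sd"],
            "n_haplotypes": spectrum.n_distinct,
        }
    )
summary = pd.DataFrame(rows).sort_values(["host", "generation"])
summary.to_csv(outdir / "diversity_by_generation.tsv", sep="\t", index=False)
print(summary.to_string(index=False))

# PCA of final-generation populations, sweep columns pruned
traj = build_trajectories(tables)
sweep_positions = {c.position for c in detect_sweeps(traj)}
final = [p for p in pops if p.generation == max(q.generation for q in pops)]
n_sample = min(200, min(len(p) for p in final))
coords, explained = pca_project(
    final, n_sample=n_sample, sweep_positions=sweep_positions, seed=args.seed
)
coords.to_csv(outdir / "pca_coordinates.tsv", sep="\t", index=False)
print(
    f"PCA over {n_sample} sampled sequences per population "
    f"({len(sweep_positions)} swept columns removed): "
    f"PC1 {explained[0]:.1%}, PC2 {explained[1]:.1%} variance explained"
)
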