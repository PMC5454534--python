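"""End-to-end orchestration: real-data analysis runs and two-arm
simulation studies, with manifests for reproducibility.

The simulation study is the package's central experiment: two arms that
differ only in the mistranslation rate (wild-type-like epsilon = 5e-4 vs
error-prone epsilon = 5e-3 per codon) are evolved in replicate, the emitted
reads are pushed through the same filtering / SNP-calling / diversity /
trajectory code that real data would use, and the arms are compared on
(i) number of selective sweeps, (ii) final-generation mean diversity and
(iii) the fraction of non-synonymous SNPs decreasing by >= 1% in a
subsequent strong-selection round.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import amplicon_io as aio
from . import diversity as div
from . import evo_sim as sim
from . import trajectories as trj
from .stat_tests import two_sample_t

__all__ = [
    "RunManifest",
    "analyze_populations",
    "run_analysis",
    "pipeline_for_replicate",
    "run_simulation_study",
]


class RunManifest:
    """Config hash, seed and per-output checksums of one run."""

    def __init__(self, config: dict, seed: int | None):
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        self.data = {
            "config_hash": hashlib.sha256(blob).hexdigest(),
            "seed": seed,
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {},
        }

    def add_file(self, path: str | Path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.data["outputs"][path.name] = digest

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2) + "\n")


def _records_to_reads(
    records: list[tuple[str, str, np.ndarray]],
    reference: aio.Reference,
    barcode_length: int = 6,
) -> list[aio.AlignedRead]:
    """In-memory counterpart of reads_from_fastq for simulator output."""
    out = []
    for read_id, seq, quals in records:
        out.append(
            aio.AlignedRead(
                read_id,
                seq[barcode_length:],
                np.asarray(quals[barcode_length:], dtype=np.int16),
                seq[:barcode_length],
            )
        )
    return out


def _sequence_population(
    pop: sim.SimPopulation,
    config: sim.SimConfig,
    host: str,
    replicate: int,
    condition: str,
    rng: np.random.Generator,
    len_slack: int = 60,
) -> tuple[aio.PopulationAlignment, pd.DataFrame, aio.FilterReport]:
    """Emit reads for one population and run them through the read filters."""
    records, truth = sim.emit_fastq(
        pop, config.depth, config.seq_error_rate, rng
    )
    reads = _records_to_reads(records, config.reference)
    L = len(config.reference)
    passed, report = aio.filter_reads(
        reads, config.reference, len_range=(L - len_slack, L + len_slack)
    )
    aln = aio.PopulationAlignment(
        passed, host=host, replicate=replicate,
        generation=pop.generation, condition=condition, empty_ok=True,
    )
    return aln, truth, report


def pipeline_for_replicate(
    config: sim.SimConfig,
    host: str,
    replicate: int,
    condition: str = "cefotaxime",
    strong_conditions: tuple[str, ...] = (
        "piperacillin", "cefoxitin", "oxacillin_clavulanate",
    ),
    effect_table: sim.EffectTable | None = None,
) -> dict:
    """Evolve one replicate and run the full read-level analysis on it.

    Returns sweeps, final-generation diversity, and the post-strong-selection
    frequency-change tables (ground truth) per condition.
    """
    pops, table, truth = sim.run_experiment(config, effect_table)
    ref = config.reference

    snp_tables = []
    alignments = {}
    for pop in pops:
        rng_seq = np.random.default_rng([config.seed, 9, pop.generation])
        aln, _, _ = _sequence_population(
            pop, config, host, replicate, condition, rng_seq
        )
        alignments[pop.generation] = aln
        if len(aln):
            snp_tables.append(aio.snp_frequency_table(aln, ref))
    traj = trj.build_trajectories(snp_tables)
    sweeps = trj.detect_sweeps(traj)
    sweep_keys = {(c.position, c.alt) for c in sweeps}

    final_aln = alignments[config.generations]
    final_diversity = div.mean_diversity(final_aln)

    # strong one-round selection on the generation-3 populations
    gen3 = pops[3] if len(pops) > 3 else pops[-1]
    strong_changes: dict[str, pd.DataFrame] = {}
    for i, cond in enumerate(strong_conditions):
        overlay = sim.condition_overlay(table, cond, seed=1)
        _, changes = sim.strong_selection_round(
            gen3, config, table, overlay, seed_offset=i
        )
        changes = changes.copy()
        effects, labels = [], []
        for _, row in changes.iterrows():
            eff, lab = aio.classify_snp_effect(int(row["position"]), row["alt"], ref)
            effects.append(eff)
            labels.append(lab)
        changes["effect"] = effects
        changes["aa_change"] = labels
        strong_changes[cond] = changes

    return {
        "host": host,
        "replicate": replicate,
        "trajectory": traj,
        "sweeps": sweeps,
        "n_sweeps": len(sweeps),
        "final_diversity": final_diversity,
        "strong_changes": strong_changes,
        "mic_trajectory": [p.chosen_concentration for p in pops[1:]],
        "effect_table": table,
        "sweep_keys": sweep_keys,
        "populations": pops,
        "alignments": alignments,
    }


def _one_sided_p(x, y) -> tuple[float, float]:
    """Pooled t-test of H1: mean(x) > mean(y); returns (t, one-sided p).

    A completely degenerate comparison (zero variance in both groups) gives
    (0, 1): no evidence of a difference.
    """
    try:
        res = two_sample_t(x, y, equal_var=True)
    except ValueError:
        return 0.0, 1.0
    p = res.p_value / 2.0 if res.statistic > 0 else 1.0 - res.p_value / 2.0
    return res.statistic, p


def run_simulation_study(
    base_config: sim.SimConfig | None = None,
    n_replicates: int = 10,
    seed: int = 0,
    deleterious_threshold: float = 0.01,
    keep_details: bool = False,
) -> dict:
    """Two-arm replicate study of the effect of mistranslation on evolution.

    Both arms share every parameter except the per-codon mistranslation rate,
    and evolve on ONE shared fitness landscape (the distribution of fitness
    effects is a property of the protein, so it is drawn once per study and
    reused across arms and replicates, exactly as all real populations evolve
    the same enzyme).  Returns per-arm summaries and one-sided cross-arm
    tests of the three directional predictions (fewer sweeps, higher
    diversity, smaller deleterious-SNP fraction in the error-prone arm).
    """
    base = base_config or sim.SimConfig()
    landscape = sim.init_effect_table(base, np.random.default_rng([seed, 1000]))
    arms = {
        "wild_type": base.wild_type_arm(),
        "error_prone": base.error_prone_arm(),
    }
    per_arm: dict[str, dict] = {}
    n_extinct: dict[str, int] = {}
    for arm_idx, (arm, arm_cfg) in enumerate(arms.items()):
        sweeps, diversities, del_fracs, details = [], [], [], []
        extinct = 0
        for rep in range(1, n_replicates + 1):
            cfg = replace(arm_cfg, seed=int(
                np.random.SeedSequence([seed, arm_idx, rep]).generate_state(1)[0]
                % 2**31
            ))
            try:
                rep_out = pipeline_for_replicate(
                    cfg, arm, rep, effect_table=landscape
                )
            except sim.ExtinctionError:
                extinct += 1
                continue
            sweeps.append(rep_out["n_sweeps"])
            diversities.append(rep_out["final_diversity"])
            # per-replicate deleterious fraction: mean over the strong-
            # selection antibiotics, as the experiment assays several drugs
            fracs = []
            for changes in rep_out["strong_changes"].values():
                curve = trj.deleterious_fraction_curve(
                    changes,
                    thresholds=np.array([deleterious_threshold]),
                    exclude_sweeping=rep_out["sweep_keys"],
                )
                fracs.append(float(curve["percentage"].iloc[0]))
            del_fracs.append(float(np.mean(fracs)))
            if keep_details:
                details.append(rep_out)
        if extinct > n_replicates / 2:
            raise RuntimeError(
                f"arm {arm}: extinction in {extinct}/{n_replicates} replicates "
                "— parameter regime failure"
            )
        n_extinct[arm] = extinct
        per_arm[arm] = {
            "sweep_counts": sweeps,
            "final_diversity": diversities,
            "deleterious_fraction": del_fracs,
            "details": details,
        }
    wt, ep = per_arm["wild_type"], per_arm["error_prone"]
    t_sw, p_sw = _one_sided_p(wt["sweep_counts"], ep["sweep_counts"])
    t_dv, p_dv = _one_sided_p(ep["final_diversity"], wt["final_diversity"])
    t_df, p_df = _one_sided_p(
        wt["deleterious_fraction"], ep["deleterious_fraction"]
    )
    return {
        "arms": per_arm,
        "n_extinct": n_extinct,
        "tests": {
            "fewer_sweeps_in_error_prone": {"t": t_sw, "p_one_sided": p_sw},
            "higher_diversity_in_error_prone": {"t": t_dv, "p_one_sided": p_dv},
            "smaller_deleterious_fraction_in_error_prone": {
                "t": t_df, "p_one_sided": p_df,
            },
        },
        "summary": {
            "mean_sweeps_wild_type": float(np.mean(wt["sweep_counts"])),
            "mean_sweeps_error_prone": float(np.mean(ep["sweep_counts"])),
            "mean_diversity_wild_type": float(np.mean(wt["final_diversity"])),
            "mean_diversity_error_prone": float(np.mean(ep["final_diversity"])),
            "mean_deleterious_fraction_wild_type": float(
                np.mean(wt["deleterious_fraction"])
            ),
            "mean_deleterious_fraction_error_prone": float(
                np.mean(ep["deleterious_fraction"])
            ),
        },
    }


def analyze_populations(
    pops: list[aio.PopulationAlignment],
    reference: aio.Reference,
    outdir: str | Path,
    seed: int = 0,
    pca_sample: int | None = None,
) -> dict:
    """The full descriptive analysis bundle for a set of populations.

    Writes SNP tables (TSV + VCF), diversity profiles, Hamming summaries,
    haplotype spectra, sweep calls, frequency-change curves and (when every
    population is large enough) PCA coordinates, plus a manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest({"n_pops": len(pops), "reference": reference.id}, seed)

    tables = []
    for pop in pops:
        if not len(pop):
            continue
        table = aio.snp_frequency_table(pop, reference)
        tables.append(table)
        stem = outdir / f"snps_{pop.label}"
        aio.write_snp_tsv(table, stem.with_suffix(".tsv"))
        aio.write_snp_vcf(table, reference, stem.with_suffix(".vcf"))
        manifest.add_file(stem.with_suffix(".tsv"))
        manifest.add_file(stem.with_suffix(".vcf"))

    div_rows = []
    for pop in pops:
        if not len(pop):
            continue
        profile = div.diversity_profile(pop)
        profile.to_csv(outdir / f"diversity_{pop.label}.tsv", sep="\t", index=False)
        manifest.add_file(outdir / f"diversity_{pop.label}.tsv")
        ham = div.pairwise_hamming(pop) if len(pop) > 1 else None
        spectrum = div.haplotype_spectrum(pop)
        div_rows.append(
            {
                "population": pop.label,
                "mean_diversity": div.mean_diversity(pop),
                "mean_hamming": ham["mean"] if ham else float("nan"),
                "n_haplotypes": spectrum.n_distinct,
            }
        )
    summary = pd.DataFrame(div_rows)
    summary.to_csv(outdir / "diversity_summary.tsv", sep="\t", index=False)
    manifest.add_file(outdir / "diversity_summary.tsv")

    traj = trj.build_trajectories(tables)
    traj.to_tsv(outdir / "trajectories.tsv")
    manifest.add_file(outdir / "trajectories.tsv")
    sweeps = trj.detect_sweeps(traj)
    pd.DataFrame([vars(s) for s in sweeps]).to_csv(
        outdir / "sweeps.tsv", sep="\t", index=False
    )
    manifest.add_file(outdir / "sweeps.tsv")

    result = {
        "snp_tables": tables,
        "trajectory": traj,
        "sweeps": sweeps,
        "diversity_summary": summary,
    }

    if pca_sample and all(len(p) >= pca_sample for p in pops):
        sweep_positions = {s.position for s in sweeps}
        coords, explained = div.pca_project(
            pops, n_sample=pca_sample, sweep_positions=sweep_positions, seed=seed
        )
        coords.to_csv(outdir / "pca_coordinates.tsv", sep="\t", index=False)
        manifest.add_file(outdir / "pca_coordinates.tsv")
        result["pca"] = (coords, explained)

    manifest.write(outdir / "manifest.json")
    return result


def run_analysis(
    fastq_dir: str | Path,
    metadata: str | Path,
    reference_fasta: str | Path,
    outdir: str | Path,
    seed: int = 0,
    len_slack: int = 60,
) -> dict:
    """Real-data mode: load FASTQs listed in a metadata TSV, filter, and run
    the full analysis bundle.

    metadata columns: file, host, replicate, generation, condition.
    """
    fastq_dir = Path(fastq_dir)
    meta = pd.read_csv(metadata, sep="\t")
    required = {"file", "host", "replicate", "generation", "condition"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks columns {sorted(missing)}")
    reference = aio.read_reference(reference_fasta, require_start=False)
    L = len(reference)
    pops = []
    for _, row in meta.iterrows():
        reads = aio.reads_from_fastq(fastq_dir / row["file"], reference)
        passed, _ = aio.filter_reads(
            reads, reference, len_range=(L - len_slack, L + len_slack)
        )
        pops.append(
            aio.PopulationAlignment(
                passed,
                host=row["host"],
                replicate=int(row["replicate"]),
                generation=int(row["generation"]),
                condition=row["condition"],
                empty_ok=True,
            )
        )
    return analyze_populations(pops, reference, outdir, seed=seed)
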