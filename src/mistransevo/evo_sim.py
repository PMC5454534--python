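"""Forward simulation of serial mutagenesis and truncation selection on a
beta-lactamase-like coding sequence, with per-molecule mistranslation.

The model follows the serial evolution protocol of amplicon selection
experiments: each round (generation), every sequence receives a Poisson
number of point mutations (mean ~0.7, transition-biased towards A->G and
T->C); cells are then challenged on a twofold antibiotic dilution series and
the next generation is resampled from the survivors at the highest
concentration still supporting growth.

Fitness is an enzymatic activity.  Every (codon, alternative amino acid)
pair carries a selection effect s drawn once from a mixture distribution of
fitness effects (neutral / weakly deleterious / rarely beneficial); a
genotype's activity is the product of (1+s) over its amino-acid changes,
with premature stops giving activity 0.  Mistranslation enters per molecule:
each of the M protein molecules of a cell receives a Poisson number of
phenotypic amino-acid changes (rate epsilon per codon), whose effects come
from the SAME effect table, so a weakly deleterious genotypic change and a
phenotypic change at another residue compound multiplicatively.  Cell
activity is the mean over its M molecules; survival at concentration c
requires activity >= c.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .amplicon_io import AlignedRead, PopulationAlignment, Reference
from .genetics import BASES, CODON_AA, N_AA, STOP_AA, decode, encode, translate_codes

__all__ = [
    "SimConfig",
    "EffectTable",
    "SimPopulation",
    "ExtinctionError",
    "synthetic_reference",
    "init_effect_table",
    "mutagenize",
    "genotype_activities",
    "cell_activity",
    "population_activities",
    "select_on_gradient",
    "run_experiment",
    "condition_overlay",
    "strong_selection_round",
    "emit_fastq",
    "write_fastq",
    "population_alignment_from_genotypes",
]


class ExtinctionError(RuntimeError):
    """No concentration on the gradient supported the survival quorum."""


# default canonical large-benefit codons, by analogy with the three strongly
# sweeping resistance substitutions of TEM-1 (E104K, M182T, G238S)
CANONICAL_CODONS = (104, 182, 238)
# optional secondary large-effect resistance codons (e.g. the ESBL /
# secondary substitution positions 69, 164, 237, 240, 265, 275, 276 of
# class A beta-lactamases); the default repertoire is the trio alone, since
# adaptation to the selecting drug is dominated by the strongly sweeping
# canonical substitutions
SECONDARY_RESISTANCE_CODONS: tuple[int, ...] = ()


def synthetic_reference(n_codons: int = 287, seed: int = 20170301) -> Reference:
    """A fixed synthetic CDS: ATG start, random stop-free body, TAA stop.

    The default length (287 codons, 861 nt) matches a class-A beta-lactamase
    coding sequence so that read-length filters and codon numbering behave as
    they would on real amplicons.  The canonical resistance codons carry the
    real beta-lactamase codons (GAA at 104, ATG at 182, GGT at 238) so that
    the canonical routes are mutationally accessible exactly as in the real
    enzyme.  The default seed is a constant: the reference is a fixture of
    the model, not a random variable of a run.
    """
    if n_codons < 3:
        raise ValueError("need at least start, one body codon, and stop")
    rng = np.random.default_rng(seed)
    codes = [encode("ATG")]
    stops = {48, 50, 56}  # TAA, TAG, TGA codon indices (16*b0+4*b1+b2)
    body = rng.integers(0, 4, size=(n_codons - 2, 3))
    for codon in body:
        idx = 16 * codon[0] + 4 * codon[1] + codon[2]
        while idx in stops:
            codon = rng.integers(0, 4, size=3)
            idx = 16 * codon[0] + 4 * codon[1] + codon[2]
        codes.append(codon.astype(np.uint8))
    codes.append(encode("TAA"))
    seq = np.concatenate(codes)
    for codon_1based, real_codon in zip(CANONICAL_CODONS, ("GAA", "ATG", "GGT")):
        if codon_1based < n_codons:
            seq[3 * (codon_1based - 1) : 3 * codon_1based] = encode(real_codon)
    return Reference("synthetic_blaM", decode(seq))


def _default_bias() -> dict[str, float]:
    # transitions A->G and T->C jointly 60% of substitution mass,
    # the remaining ten substitution types uniform
    bias = {}
    for a in BASES:
        for b in BASES:
            if a != b:
                bias[f"{a}>{b}"] = 0.04
    bias["A>G"] = 0.30
    bias["T>C"] = 0.30
    return bias


@dataclass
class SimConfig:
    """All simulator parameters.

    Desk-scale defaults (B=1000, M=100, depth=500) run a full two-arm
    replicate study in minutes; the experiment-scale bottleneck of 1e5 cells
    is available by overriding bottleneck_size.
    """

    reference: Reference = field(default_factory=synthetic_reference)
    bottleneck_size: int = 1_000  # B
    generations: int = 4  # G
    mutation_rate: float = 0.7  # lambda, per sequence per round
    substitution_bias: dict[str, float] = field(default_factory=_default_bias)
    # distribution of fitness effects over (codon, alt amino acid) entries
    p_neutral: float = 0.30
    p_deleterious: float = 0.69
    p_beneficial: float = 0.01
    deleterious_shape: float = 0.3
    deleterious_scale: float = 0.8
    # the random beneficial class is weakly beneficial (activity multiplier
    # well below the twofold ladder spacing); large MIC-multiplying effects
    # are reserved for the fixed resistance repertoire (canonical trio and
    # any secondary resistance codons)
    beneficial_low: float = 0.05
    beneficial_high: float = 0.25
    canonical_effects: tuple[float, ...] = (7.0, 7.0, 7.0)
    canonical_codons: tuple[int, ...] = CANONICAL_CODONS
    secondary_resistance_codons: tuple[int, ...] = SECONDARY_RESISTANCE_CODONS
    # mistranslation
    mistranslation_rate: float = 5e-4  # epsilon, per codon per molecule
    molecules_per_cell: int = 100  # M
    # phenotypic changes share the genotypic effect table by default (the
    # compounding model); False draws an independent table for contrast runs
    shared_phenotypic_effects: bool = True
    # selection gradient
    base_concentration: float = 2.0**-6  # c0
    n_concentrations: int = 16
    dilution_factor: float = 2.0
    survival_quorum: int = 10  # K
    # None = hard threshold (activity >= c survives); a positive number
    # switches to logistic survival with that steepness on log-activity
    soft_threshold_steepness: float | None = None
    # sequencing
    depth: int = 500
    seq_error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        mix = self.p_neutral + self.p_deleterious + self.p_beneficial
        if abs(mix - 1.0) > 1e-9:
            raise ValueError(f"DFE mixture sums to {mix}, not 1")
        for name in ("p_neutral", "p_deleterious", "p_beneficial"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.mutation_rate < 0 or self.mistranslation_rate < 0:
            raise ValueError("rates must be non-negative")
        for name in ("bottleneck_size", "generations", "molecules_per_cell",
                     "survival_quorum", "depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def concentrations(self) -> np.ndarray:
        return self.base_concentration * self.dilution_factor ** np.arange(
            self.n_concentrations
        )

    def wild_type_arm(self) -> "SimConfig":
        return replace(self, mistranslation_rate=5e-4)

    def error_prone_arm(self) -> "SimConfig":
        return replace(self, mistranslation_rate=5e-3)

    def experiment_scale(self) -> "SimConfig":
        """Preset at the experimental bottleneck of ~1e5 cells."""
        return replace(self, bottleneck_size=100_000)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Build a config from a flat-key YAML file.

        Recognized keys are the dataclass fields (reference may be given as
        `reference_fasta`, a path to a FASTA file).
        """
        import yaml

        data = dict(yaml.safe_load(open(path)) or {})
        if "reference_fasta" in data:
            from .amplicon_io import read_reference

            data["reference"] = read_reference(
                data.pop("reference_fasta"), require_start=False
            )
        for key in ("canonical_codons", "canonical_effects",
                    "secondary_resistance_codons"):
            if key in data:
                data[key] = tuple(data[key])
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class EffectTable:
    """Selection effect of every (codon index, alternative amino acid) pair.

    effects has shape (n_codons, 21): column indices are amino-acid codes,
    with the stop column fixed at -1 (activity 0 for truncated molecules) and
    the reference amino acid of each codon fixed at 0 (synonymous changes are
    neutral).  Effects are shared between genotypic and phenotypic (i.e.
    mistranslation-induced) changes at the same residue.
    """

    def __init__(self, effects: np.ndarray, ref_aas: np.ndarray,
                 canonical: list[tuple[int, int, float]]):
        self.effects = effects
        self.ref_aas = ref_aas
        self.canonical = canonical

    @property
    def n_codons(self) -> int:
        return self.effects.shape[0]

    def with_overlay(self, overlay: dict[tuple[int, int], float]) -> "EffectTable":
        """A copy with per-(codon, aa) additive perturbations applied."""
        eff = self.effects.copy()
        for (codon, aa), delta in overlay.items():
            eff[codon, aa] = max(eff[codon, aa] + delta, -1.0)
        return EffectTable(eff, self.ref_aas, self.canonical)


def init_effect_table(config: SimConfig, rng: np.random.Generator) -> EffectTable:
    """Draw the distribution of fitness effects once for the whole run."""
    ref = config.reference
    n_codons = ref.n_codons
    ref_aas = ref.codon_aas.astype(np.int64)
    effects = np.zeros((n_codons, N_AA + 1), dtype=np.float64)
    effects[:, STOP_AA] = -1.0

    cls = rng.choice(
        3,
        size=(n_codons, N_AA),
        p=[config.p_neutral, config.p_deleterious, config.p_beneficial],
    )
    del_draw = -np.minimum(
        rng.gamma(config.deleterious_shape, config.deleterious_scale,
                  size=(n_codons, N_AA)),
        1.0,
    )
    # log-uniform activity multiplier in [1+low, 1+high]
    log_lo = np.log2(1.0 + config.beneficial_low)
    log_hi = np.log2(1.0 + config.beneficial_high)
    ben_draw = 2.0 ** rng.uniform(log_lo, log_hi, size=(n_codons, N_AA)) - 1.0
    body = np.where(cls == 1, del_draw, np.where(cls == 2, ben_draw, 0.0))
    effects[:, :N_AA] = body
    # the reference amino acid itself is "no change"
    rows = np.arange(n_codons)
    valid = ref_aas < N_AA  # skip the terminal stop codon row
    effects[rows[valid], ref_aas[valid]] = 0.0

    # fixed resistance repertoire: the canonical trio at +canonical_effect
    # and any secondary resistance codons at log-uniform 2-16x multipliers.
    # Each route is realized as the amino acid with the highest mutational
    # flux (one nucleotide substitution, weighted by the mutagenesis bias)
    # from the reference codon: resistance routes must be mutationally
    # accessible, as the real canonical substitutions are
    canonical: list[tuple[int, int, float]] = []
    bias_matrix = _bias_matrix(config.substitution_bias)

    def _accessible_alt_aa(codon_0based: int) -> int:
        start = 3 * codon_0based
        codon = ref.codes[start : start + 3].astype(np.int64)
        flux: dict[int, float] = {}
        for offset in range(3):
            for b in range(4):
                if b == codon[offset]:
                    continue
                mutant = codon.copy()
                mutant[offset] = b
                aa = int(CODON_AA[16 * mutant[0] + 4 * mutant[1] + mutant[2]])
                if aa != STOP_AA and aa != ref_aas[codon_0based]:
                    flux[aa] = flux.get(aa, 0.0) + float(
                        bias_matrix[codon[offset], b]
                    )
        if not flux:
            raise ValueError(
                f"no accessible non-stop amino acid at codon {codon_0based + 1}"
            )
        return max(sorted(flux), key=lambda a: flux[a])

    for codon_1based, s_can in zip(config.canonical_codons,
                                   config.canonical_effects):
        c = codon_1based - 1
        if not 0 <= c < n_codons - 1:
            raise ValueError(f"canonical codon {codon_1based} outside CDS body")
        aa = _accessible_alt_aa(c)
        effects[c, aa] = s_can
        canonical.append((c, aa, float(s_can)))
    for codon_1based in config.secondary_resistance_codons:
        c = codon_1based - 1
        if not 0 <= c < n_codons - 1:
            raise ValueError(
                f"resistance codon {codon_1based} outside CDS body"
            )
        aa = _accessible_alt_aa(c)
        s = 2.0 ** rng.uniform(1.0, 4.0) - 1.0
        effects[c, aa] = s
        canonical.append((c, aa, float(s)))
    return EffectTable(effects, ref_aas, canonical)


@dataclass
class SimPopulation:
    """One generation's genotypes plus its selection outcome."""

    generation: int
    genotypes: np.ndarray  # (B, L) uint8
    reference: Reference
    chosen_concentration: float | None = None
    n_survivors: int | None = None

    @property
    def size(self) -> int:
        return self.genotypes.shape[0]

    def allele_frequencies(self) -> pd.DataFrame:
        """True per-(position, alt) allele frequencies of the population."""
        return _allele_frequencies(self.genotypes, self.reference)


def _allele_frequencies(genotypes: np.ndarray, reference: Reference) -> pd.DataFrame:
    B = genotypes.shape[0]
    diff = genotypes != reference.codes[None, :]
    cols = np.nonzero(diff.any(axis=0))[0]
    rows = []
    for col in cols:
        bases = genotypes[diff[:, col], col]
        for code in np.unique(bases):
            rows.append(
                {
                    "position": int(col) + 1,
                    "alt": BASES[code],
                    "count": int((bases == code).sum()),
                    "frequency": float((bases == code).sum() / B),
                }
            )
    return pd.DataFrame(rows, columns=["position", "alt", "count", "frequency"])


def _bias_matrix(bias: dict[str, float]) -> np.ndarray:
    """Row-normalized 4x4 substitution matrix from global substitution weights.

    A base whose outgoing weights are all zero never mutates (its row stays
    zero and draws landing there are discarded).
    """
    m = np.zeros((4, 4))
    for key, w in bias.items():
        a, b = key.split(">")
        if a == b or w < 0:
            raise ValueError(f"invalid substitution weight {key}={w}")
        m[BASES.index(a), BASES.index(b)] = w
    if m.sum() == 0:
        raise ValueError("at least one substitution weight must be positive")
    sums = m.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, m / sums, 0.0)
    return out


def mutagenize(
    genotypes: np.ndarray,
    mutation_rate: float,
    bias: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """One round of mutagenic PCR: Poisson(lambda) substitutions per sequence,
    uniform positions, substitution type drawn from the (row-conditional)
    bias matrix at the current base."""
    if mutation_rate < 0:
        raise ValueError("mutation rate must be non-negative")
    out = genotypes.copy()
    if mutation_rate == 0:
        return out
    B, L = out.shape
    counts = rng.poisson(mutation_rate, size=B)
    total = int(counts.sum())
    if total == 0:
        return out
    seq_idx = np.repeat(np.arange(B), counts)
    pos = rng.integers(0, L, size=total)
    cur = out[seq_idx, pos]
    P = _bias_matrix(bias)
    cum = P.cumsum(axis=1)
    u = rng.random(total)
    new = (u[:, None] > cum[cur]).sum(axis=1).astype(np.uint8)
    # draws at bases with an all-zero row do not mutate
    new = np.where(P[cur].sum(axis=1) > 0, new, cur).astype(np.uint8)
    # later draws at the same (sequence, position) overwrite earlier ones
    out[seq_idx, pos] = new
    return out


def genotype_activities(
    genotypes: np.ndarray, reference: Reference, table: EffectTable
) -> np.ndarray:
    """Deterministic activity of each genotype: product of (1+s) over its
    amino-acid changes relative to the reference; premature stop -> 0."""
    B = genotypes.shape[0]
    n_codons = reference.n_codons
    diff_cols = np.nonzero((genotypes != reference.codes[None, :]).any(axis=0))[0]
    act = np.ones(B, dtype=np.float64)
    if diff_cols.size == 0:
        return act
    rows, cols = np.nonzero(genotypes[:, diff_cols] != reference.codes[diff_cols])
    cods = diff_cols[cols] // 3
    pair_codes = np.unique(rows.astype(np.int64) * n_codons + cods)
    r = pair_codes // n_codons
    c = pair_codes % n_codons
    tri = genotypes[r[:, None], (3 * c)[:, None] + np.arange(3)[None, :]].astype(np.int64)
    aa = CODON_AA[16 * tri[:, 0] + 4 * tri[:, 1] + tri[:, 2]].astype(np.int64)
    s = np.where(aa == table.ref_aas[c], 0.0, table.effects[c, aa])
    np.multiply.at(act, r, np.maximum(1.0 + s, 0.0))
    return act


def _phenotypic_molecule_factors(
    B: int,
    M: int,
    epsilon: float,
    table: EffectTable,
    rng: np.random.Generator,
) -> np.ndarray:
    """(B, M) multiplicative activity factors from mistranslation.

    Each molecule receives Poisson(epsilon * n_codons) phenotypic amino-acid
    changes at uniform codons; the alternative amino acid is uniform over the
    19 non-reference amino acids of that codon, with effects looked up in the
    shared table.
    """
    n_codons = table.n_codons
    k = rng.poisson(epsilon * n_codons, size=B * M)
    factors = np.ones(B * M, dtype=np.float64)
    total = int(k.sum())
    if total:
        mol = np.repeat(np.arange(B * M), k)
        cod = rng.integers(0, n_codons, size=total)
        draw = rng.integers(0, N_AA - 1, size=total)
        ref_aa = table.ref_aas[cod]
        # skip over the reference amino acid so alternatives stay uniform;
        # at the terminal stop codon (ref_aa == STOP_AA) all 20 aas miss it
        aa = draw + (draw >= np.minimum(ref_aa, N_AA - 1))
        s = np.where(aa == ref_aa, 0.0, table.effects[cod, aa])
        np.multiply.at(factors, mol, np.maximum(1.0 + s, 0.0))
    return factors.reshape(B, M)


def population_activities(
    genotypes: np.ndarray,
    reference: Reference,
    table: EffectTable,
    epsilon: float,
    M: int,
    rng: np.random.Generator,
    phenotypic_table: EffectTable | None = None,
) -> np.ndarray:
    """Cell activities: mean over M molecules of genotypic x phenotypic factors.

    phenotypic_table overrides the effect table used for mistranslation
    changes (the default shares the genotypic table — the compounding model).
    """
    if M < 1:
        raise ValueError("molecules per cell must be >= 1")
    geno = genotype_activities(genotypes, reference, table)
    if epsilon == 0:
        return geno
    pheno = _phenotypic_molecule_factors(
        genotypes.shape[0], M, epsilon, phenotypic_table or table, rng
    )
    return geno * pheno.mean(axis=1)


def cell_activity(
    genotype: np.ndarray,
    reference: Reference,
    table: EffectTable,
    epsilon: float,
    M: int,
    rng: np.random.Generator,
) -> float:
    """Activity of a single cell (convenience wrapper for one genotype)."""
    return float(
        population_activities(
            np.asarray(genotype, dtype=np.uint8)[None, :],
            reference, table, epsilon, M, rng,
        )[0]
    )


def select_on_gradient(
    genotypes: np.ndarray,
    activities: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, int]:
    """Truncation selection on the twofold dilution series.

    Survivors at concentration c are cells with activity >= c; the chosen
    concentration c* is the highest with at least the survival quorum K, and
    the next generation is B cells resampled with replacement from the
    survivors at c*.  Raises ExtinctionError when no concentration supports
    the quorum.
    """
    if genotypes.shape[0] == 0:
        raise ValueError("empty population")
    K = config.survival_quorum
    k_soft = config.soft_threshold_steepness
    if k_soft is None:
        def survivors_at(c: float) -> np.ndarray:
            return activities >= c
    else:
        # one uniform draw per cell keeps survival sets nested across the
        # ladder (a cell surviving at c also survives at any lower c)
        u = rng.random(activities.shape[0])

        def survivors_at(c: float) -> np.ndarray:
            # logistic in log-activity: p = 1 / (1 + (c/act)^k)
            with np.errstate(divide="ignore", over="ignore"):
                ratio = np.log(c) - np.log(np.maximum(activities, 1e-300))
                p = 1.0 / (1.0 + np.exp(np.minimum(k_soft * ratio, 700.0)))
            p[activities <= 0] = 0.0
            return p >= u

    chosen = None
    for c in config.concentrations[::-1]:  # highest first
        if int(survivors_at(float(c)).sum()) >= K:
            chosen = float(c)
            break
    if chosen is None:
        raise ExtinctionError(
            f"no concentration on the gradient retained >= {K} survivors"
        )
    surv_idx = np.nonzero(survivors_at(chosen))[0]
    resampled = rng.choice(surv_idx, size=config.bottleneck_size, replace=True)
    return genotypes[resampled], chosen, int(surv_idx.size)


def _spawn(seed: int, *path: int) -> np.random.Generator:
    """Deterministic substream keyed by (root seed, stage path).

    Seeding a Generator with the entropy list [seed, stage, ...] gives
    independent, individually reproducible streams per stage and generation.
    """
    return np.random.default_rng([seed, *path])


def run_experiment(
    config: SimConfig, effect_table: EffectTable | None = None
) -> tuple[list[SimPopulation], EffectTable, pd.DataFrame]:
    """Run G rounds of mutagenesis -> translation/selection -> bottleneck.

    Returns the per-generation populations (generation 0 is the unselected
    ancestral clone), the effect table used, and the ground-truth SNP
    frequency trajectory (long format).
    """
    ref = config.reference
    rng_table = _spawn(config.seed, 0)
    table = effect_table if effect_table is not None else init_effect_table(
        config, rng_table
    )
    pheno_table = (
        None
        if config.shared_phenotypic_effects
        else init_effect_table(config, _spawn(config.seed, 7))
    )
    B = config.bottleneck_size
    genotypes = np.tile(ref.codes, (B, 1))
    pops = [SimPopulation(0, genotypes, ref)]
    truth_rows = []
    for gen in range(1, config.generations + 1):
        rng_mut = _spawn(config.seed, 1, gen)
        rng_act = _spawn(config.seed, 2, gen)
        rng_sel = _spawn(config.seed, 3, gen)
        mutated = mutagenize(
            pops[-1].genotypes, config.mutation_rate, config.substitution_bias, rng_mut
        )
        acts = population_activities(
            mutated, ref, table, config.mistranslation_rate,
            config.molecules_per_cell, rng_act, phenotypic_table=pheno_table,
        )
        selected, c_star, n_surv = select_on_gradient(mutated, acts, config, rng_sel)
        pop = SimPopulation(gen, selected, ref, c_star, n_surv)
        pops.append(pop)
        freqs = pop.allele_frequencies()
        freqs["generation"] = gen
        truth_rows.append(freqs)
    truth = (
        pd.concat(truth_rows, ignore_index=True)
        if truth_rows
        else pd.DataFrame(columns=["position", "alt", "count", "frequency", "generation"])
    )
    return pops, table, truth


def condition_overlay(
    table: EffectTable,
    condition: str,
    fraction: float = 0.05,
    penalty: float = -0.5,
    seed: int = 0,
) -> dict[tuple[int, int], float]:
    """A per-condition perturbation of the effect table: a seeded random
    subset of (codon, amino acid) entries becomes additionally deleterious
    under this condition only.  The subset is a deterministic function of
    (seed, condition name)."""
    condition_key = zlib.crc32(condition.encode("utf-8"))
    rng = np.random.default_rng([seed, condition_key])
    n_entries = table.n_codons * N_AA
    n_pick = max(1, int(round(fraction * n_entries)))
    picks = rng.choice(n_entries, size=n_pick, replace=False)
    overlay = {}
    for p in picks:
        codon, aa = int(p) // N_AA, int(p) % N_AA
        if aa == table.ref_aas[codon]:
            continue  # never penalize the reference amino acid
        overlay[(codon, aa)] = penalty
    return overlay


def strong_selection_round(
    pop: SimPopulation,
    config: SimConfig,
    table: EffectTable,
    overlay: dict[tuple[int, int], float] | None = None,
    seed_offset: int = 0,
) -> tuple[SimPopulation, pd.DataFrame]:
    """One pure selection pass (no mutagenesis) under a condition overlay.

    Returns the post-selection population and the ground-truth frequency
    change of every SNP segregating before selection (delta_f = after-before).
    """
    eff = table.with_overlay(overlay) if overlay else table
    rng_act = _spawn(config.seed, 4, pop.generation, seed_offset)
    rng_sel = _spawn(config.seed, 5, pop.generation, seed_offset)
    acts = population_activities(
        pop.genotypes, pop.reference, eff, config.mistranslation_rate,
        config.molecules_per_cell, rng_act,
    )
    selected, c_star, n_surv = select_on_gradient(pop.genotypes, acts, config, rng_sel)
    after = SimPopulation(pop.generation + 1, selected, pop.reference, c_star, n_surv)
    before_f = pop.allele_frequencies().set_index(["position", "alt"])["frequency"]
    after_f = after.allele_frequencies().set_index(["position", "alt"])["frequency"]
    merged = pd.concat(
        {"before": before_f, "after": after_f}, axis=1, join="outer"
    ).fillna(0.0)
    merged = merged[merged["before"] > 0]  # segregating before selection
    merged["delta_f"] = merged["after"] - merged["before"]
    return after, merged.reset_index()


@dataclass
class QAssignment:
    """Phred assignment model for simulated reads.

    Correct bases get q_correct.  Error bases get q_error with probability
    1 - miscalibration (so quality gating removes most of them) and q_correct
    otherwise (miscalibrated errors that slip through the gate).
    """

    q_correct: int = 40
    q_error: int = 10
    miscalibration: float = 0.1


def emit_fastq(
    pop: SimPopulation,
    depth: int,
    seq_error_rate: float,
    rng: np.random.Generator,
    barcode: str = "ACGTAC",
    q_assignment: QAssignment | None = None,
) -> tuple[list[tuple[str, str, np.ndarray]], pd.DataFrame]:
    """Sample reads with replacement from the population and add sequencing
    errors.

    Returns (records, truth) where records are (read_id, sequence-with-
    barcode, per-base Phred array) and truth holds the allele frequencies of
    the sampled genotypes (the quantity an error-free pipeline should
    recover exactly).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    qa = q_assignment or QAssignment()
    idx = rng.integers(0, pop.size, size=depth)
    reads = pop.genotypes[idx].copy()
    L = reads.shape[1]
    quals = np.full((depth, L), qa.q_correct, dtype=np.int16)
    if seq_error_rate > 0:
        err = rng.random((depth, L)) < seq_error_rate
        n_err = int(err.sum())
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        reads[err] = (reads[err] + shift) % 4
        miscal = rng.random(n_err) < qa.miscalibration
        quals[err] = np.where(miscal, qa.q_correct, qa.q_error)
    truth = _allele_frequencies(pop.genotypes[idx], pop.reference)
    bc_quals = np.full(len(barcode), qa.q_correct, dtype=np.int16)
    records = []
    for i in range(depth):
        records.append(
            (
                f"sim_gen{pop.generation}_read{i}",
                barcode + decode(reads[i]),
                np.concatenate([bc_quals, quals[i]]),
            )
        )
    return records, truth


def write_fastq(records: list[tuple[str, str, np.ndarray]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, quals in records:
            qstr = "".join(chr(int(q) + 33) for q in quals)
            fh.write(f"@{read_id}\n{seq}\n+\n{qstr}\n")


def population_alignment_from_genotypes(
    pop: SimPopulation,
    host: str = "wild_type",
    replicate: int = 1,
    condition: str = "none",
    quality: int = 40,
) -> PopulationAlignment:
    """Wrap true genotypes as a perfectly sequenced population alignment."""
    reads = [
        AlignedRead(
            f"g{pop.generation}_truth{i}",
            decode(pop.genotypes[i]),
            np.full(pop.genotypes.shape[1], quality, dtype=np.int16),
        )
        for i in range(pop.size)
    ]
    return PopulationAlignment(
        reads, host=host, replicate=replicate,
        generation=pop.generation, condition=condition,
    )
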