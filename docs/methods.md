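# Methods

## Read model and filtering

All analyses operate on reads projected into reference coordinates over a
single coding sequence.  Insertions relative to the reference are dropped at
ingestion and deletions become `-`; indels are outside the analysis, which
considers point mutations only.  Coordinates are 1-based on the CDS.
Per-base Phred qualities stay co-indexed with the aligned sequence; gap
columns carry a sentinel quality of −1.

Filters are applied in a fixed order — length, mean quality, span, stop
codon — and a rejected read is charged to the first rule it fails, so filter
reports are deterministic and conserve read counts.  The defaults follow
the amplicon-consensus regime this pipeline targets: ungapped length within
850–1,200 nt (a window around the 861-nt CDS), mean Phred strictly above
20, non-gap coverage of every CDS position, and an in-frame translation
with exactly one terminal stop.  Demultiplexing accepts exact barcode
matches only; one-mismatch rescue is deliberately not attempted.

A mismatch is a SNP call only when its own Phred exceeds 20.  The same
per-base gate is applied to the depth denominator, so a site's frequency is
exactly `count / (quality-passing non-gap bases)`.  Whether the denominator
should also be gated is genuinely ambiguous in this kind of protocol; we
chose the symmetric convention and expose `min_base_q` everywhere.

## Diversity

Per-site diversity is the unordered-pair mismatch fraction computed from
base counts (see README for the formula); the population value D averages
over all computable CDS sites, monomorphic sites included (a
`polymorphic_only` flag exists for sensitivity analysis, and `min_depth`,
default 2, excludes sites without enough gated bases).  Pairwise Hamming
distances skip columns where either read is gapped or masked (a strict mode
counts them as mismatches).  PCA encodes each retained column as four
indicator channels (gaps all-zero), removes columns swept in any
population, centres, and decomposes by SVD; coordinates are deterministic
given the sampled set, up to component sign.

## Inferential statistics

Student-t and F tail areas are computed directly from the regularized
incomplete beta function; the two-sample test defaults to the
pooled-variance form (df = n₁+n₂−2) because the comparisons of interest
are balanced few-replicate designs, with Welch available by flag.  The
Mann–Whitney U statistic counts wins of the first sample with ½ for ties;
p-values are exact (full enumeration) when n₁·n₂ ≤ 200 and otherwise use a
normal approximation with midrank tie correction, continuity correction,
and an Edgeworth kurtosis term
γ₂ = −(6/5)(n₁²+n₂²+n₁n₂+n₁+n₂)/(n₁n₂(n+1)),
which brings exact-vs-approximate disagreement at n₁=n₂=8 from ~0.011 to
~0.0005.

## The simulator

One round = mutagenesis → translation/selection → bottleneck resampling.

**Mutagenesis.** Each sequence receives Poisson(λ=0.7) substitutions at
uniform positions.  Substitution type is drawn conditionally on the current
base from a weight table whose default puts 30 % of global mass on each of
A→G and T→C and 4 % on each remaining type — an operationalization of
transition-biased mutagenic PCR; the global bias value is a configuration
choice, not a measurement.

**Fitness.** Every (codon, alternative amino acid) pair carries a selection
effect s drawn once per study: 30 % neutral, 69 % deleterious with
s = −min(1, Gamma(shape 0.3, scale 0.8)) (mostly weak, a tail of lethals),
and 1 % weakly beneficial with s ~ U(0.05, 0.25).  Premature stops give
activity 0.  The landscape is drawn once and shared by both arms and all
replicates of a study, as every real population evolves the same enzyme.
A genotype's activity is Π(1+s) over its amino-acid changes (clamped at 0).

**Resistance repertoire.** Adaptation to the selecting drug runs through a
small fixed set of large-effect routes, by analogy with the canonical
strongly sweeping β-lactamase substitutions: the three canonical codons
(104, 182, 238 — whose reference codons are the real GAA/ATG/GGT) each get
an activity ×8 entry at the accessible alternative amino acid with the
highest single-nucleotide mutational flux under the transition bias.
Two design constraints matter on a twofold dilution ladder: an effect is
visible to truncation selection only if it multiplies activity by ≥ 2, so
the random beneficial class (≤ ×1.25) models weakly beneficial variation
that drifts rather than sweeps; and routes must be single-nucleotide
accessible, as the real canonical substitutions are.  A configurable
secondary-resistance list (e.g. codons 69, 164, 237, 240, 265, 275, 276)
is off by default: with the trio alone, the carrier supply at desk scale
matches the regime where wild-type hosts sweep regularly while error-prone
hosts rarely establish a sweep within four rounds.

**Mistranslation.** Each of a cell's M = 100 protein molecules receives
Poisson(ε·n_codons) phenotypic amino-acid changes (uniform codon, uniform
alternative amino acid), with effects looked up in the *same* table as
genotypic changes — the minimal formalization of genotypic and phenotypic
mutations compounding multiplicatively.  Cell activity is the mean over
molecules.  ε defaults: 5×10⁻⁴ (wild-type-like) and 5×10⁻³ (error-prone),
order-of-magnitude choices within the measured 10⁻⁵–10⁻³ per-codon range.
With ε = 0 the model reduces to a deterministic Wright–Fisher truncation
selection.

**Selection.** The dilution ladder is c₀·2^i with c₀ = 2⁻⁶ and 16 rungs, so
unit activity sits exactly on a rung.  Survival at concentration c requires
activity ≥ c (hard threshold; "growth visible" is operationalized as a
survivor quorum K = 10).  The chosen concentration c* is the highest rung
retaining ≥ K cells — the simulated MIC analogue — and the next generation
is B = 1,000 cells resampled with replacement from the survivors at c*.
If no rung retains K cells the population is extinct (an explicit error,
never silent).

**Sequencing.** Reads are genotypes sampled with replacement (depth 500),
with per-base error 10⁻³ to a uniform other base; error bases receive Phred
10 except for a 10 % miscalibrated remainder at Phred 40, so quality gating
removes most but not all errors.  A sample barcode is prepended.  The truth
table accompanying each emission records the allele frequencies of the
*sampled* genotypes, which an error-free pipeline must recover exactly.

**Randomness.** Every stream derives from one root seed through fixed
stage keys (effect table; per-generation mutagenesis / translation /
selection; sequencing; per-condition overlays), so any stage can be
re-run in isolation and full runs are bit-reproducible.

## The two-arm study

Ten replicates per arm differ only in ε.  Per replicate we record
(i) sweeping SNPs (read-level frequency > 0.9 in any generation),
(ii) final-generation mean diversity of the emitted reads, and (iii) after
one strong-selection round of the generation-3 population under three
antibiotic overlays (each overlay makes a seeded 5 % of effect entries
additionally deleterious by −0.5 under that drug only), the percentage of
segregating non-synonymous SNPs (sweeping SNPs excluded) whose true
frequency drops by ≥ 1 %, averaged over the three drugs.  Cross-arm
comparisons use one-sided pooled-variance t-tests across replicates.

Why the directions emerge: in the wild-type arm the cell-activity
distribution is nearly deterministic and sits just below a rung, so each
round keeps only a small upper tail — arriving resistance carriers amplify
by one to two orders of magnitude per round and sweep, crashing diversity;
weakly deleterious variants that survive do so untouched until a strong
round exposes them.  In the error-prone arm the phenotypic load shifts the
bulk to mid-band and adds activity noise: resistance carriers get no
enrichment until they reach the quorum by drift (rarely within four
rounds), diversity accumulates, and the repeated partial selection against
weakly-deleterious-plus-phenotypic combinations purges those variants
before the strong round measures them.

## Desk scale, and what passing does not show

The defaults (B = 1,000 cells, 500 reads/population, 10 replicates/arm) run
the full study in seconds; they are 100-fold below the experimental
bottleneck of ~10⁵ cells, so absolute sweep counts are smaller than the
four-to-eight per population seen at scale, and replicate-to-replicate
variance is dominated by whether a resistance carrier arrives in the first
round (probability ≈ 0.8 per replicate).  The generator also idealizes:
no codon-usage or tRNA-competition structure in mistranslation, no
misfolding toxicity, no host-specific baseline MIC differences, uniform
sequencing error, and a single shared effect table rather than a measured
fitness landscape.  Passing tests therefore demonstrate the internal
consistency of the analysis chain and the directional logic of
mistranslation-enhanced purging under this model — not a quantitative
reproduction of any laboratory measurement.

## Degenerate inputs and numerical conventions

Sites with fewer than two gated bases are excluded from D; populations
smaller than the PCA sample size, unknown generations, single-condition
specificity queries, thresholds outside (0,1), and zero-variance test
inputs all raise explicit errors.  Sweep calls use strict inequality
("exceeding" 90 %); deleterious thresholds are inclusive ("by at least"),
beneficial strict ("by more than"), matching the asymmetric definitions.
Frequencies are exact integer ratios; diversity oracles are checked to
1e−12 and the Hamming identity to 1e−9.
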