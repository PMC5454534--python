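"""Reading, filtering and SNP-calling of reference-aligned amplicon reads.

The unit of analysis is a population of full-length coding-sequence reads
aligned to a single reference CDS.  Alignment columns are reference-anchored:
insertions relative to the reference are dropped on ingestion and deletions
become ``-`` (indels are deliberately outside the analysis; only point
mutations are called).  Coordinates are 1-based on the reference CDS.

Filtering follows the study design for amplicon consensus reads: reads must
fall in a plausible insert-length window, have mean Phred quality strictly
above 20, span every reference position, and translate with exactly one
(terminal) stop codon.  A mismatch to the reference is a SNP call only when
its per-base Phred quality is strictly above the threshold (default 20).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetics import (
    GAP_CODE,
    N_CODE,
    STOP_AA,
    aa_letter,
    decode,
    encode,
    translate_codes,
)

logger = logging.getLogger(__name__)

GAP_QUALITY = -1  # sentinel quality carried by gap columns

__all__ = [
    "Reference",
    "AlignedRead",
    "PopulationAlignment",
    "SnpRecord",
    "SnpFrequencyTable",
    "FilterReport",
    "read_reference",
    "read_barcode_map",
    "read_numbering_map",
    "reads_from_fastq",
    "reads_from_sam",
    "demultiplex",
    "filter_reads",
    "call_snps",
    "snp_frequency_table",
    "classify_snp_effect",
    "write_snp_tsv",
    "write_snp_vcf",
]


@dataclass
class Reference:
    """A reference coding sequence and optional display numbering.

    numbering_map maps 1-based codon index to a display label (e.g. the
    historical Ambler numbering of class A beta-lactamases).  The default is
    sequential codon numbering from the start codon.
    """

    id: str
    cds_sequence: str
    numbering_map: dict[int, str] | None = None
    require_start: bool = True

    def __post_init__(self) -> None:
        self.cds_sequence = self.cds_sequence.upper()
        n = len(self.cds_sequence)
        if n < 3 or n % 3:
            raise ValueError("CDS length must be >= 3 and divisible by 3")
        if set(self.cds_sequence) - set("ACGT"):
            raise ValueError("reference CDS may contain only A/C/G/T")
        self.codes = encode(self.cds_sequence)
        aas = translate_codes(self.codes)
        if self.require_start and self.cds_sequence[:3] != "ATG":
            raise ValueError("reference CDS does not begin with ATG")
        if aas[-1] != STOP_AA:
            raise ValueError("reference CDS must end in a stop codon")
        if (aas[:-1] == STOP_AA).any():
            raise ValueError("reference CDS has an internal stop codon")
        self.codon_aas = aas

    def __len__(self) -> int:
        return len(self.cds_sequence)

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3

    def codon_label(self, codon_index: int) -> str:
        """Display label of a 1-based codon index."""
        if self.numbering_map:
            return self.numbering_map.get(codon_index, str(codon_index))
        return str(codon_index)


@dataclass
class AlignedRead:
    """One read in reference coordinates, with co-indexed Phred qualities.

    aligned_seq has exactly the reference length over {A,C,G,T,-,N}; gap
    columns carry the sentinel quality GAP_QUALITY so sequence and quality
    stay co-indexed.
    """

    read_id: str
    aligned_seq: str
    qualities: np.ndarray
    barcode: str | None = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.aligned_seq) != self.qualities.size:
            raise ValueError(
                f"read {self.read_id}: sequence and qualities differ in length"
            )
        self.codes = encode(self.aligned_seq)

    @property
    def mean_quality(self) -> float:
        mask = self.codes != GAP_CODE
        if not mask.any():
            return 0.0
        return float(self.qualities[mask].mean())

    @property
    def ungapped_length(self) -> int:
        return int((self.codes != GAP_CODE).sum())


@dataclass
class PopulationAlignment:
    """Filtered reads of one population sample, with its design labels."""

    reads: list[AlignedRead]
    host: str = "wild_type"
    replicate: int = 1
    generation: int = 0
    condition: str = "none"
    empty_ok: bool = False

    def __post_init__(self) -> None:
        lengths = {len(r.aligned_seq) for r in self.reads}
        if len(lengths) > 1:
            raise ValueError("reads have differing aligned lengths")
        if not self.reads and not self.empty_ok:
            raise ValueError("population is empty (set empty_ok to allow)")
        self._matrix: np.ndarray | None = None
        self._quals: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def matrix(self) -> np.ndarray:
        """(n_reads, L) uint8 base-code matrix."""
        if self._matrix is None:
            self._matrix = np.vstack([r.codes for r in self.reads])
        return self._matrix

    @property
    def quality_matrix(self) -> np.ndarray:
        if self._quals is None:
            self._quals = np.vstack([r.qualities for r in self.reads])
        return self._quals

    @property
    def label(self) -> str:
        return (
            f"{self.host}_rep{self.replicate}_gen{self.generation}_{self.condition}"
        )


@dataclass
class SnpRecord:
    """One (position, alternative base) observation in one population."""

    position: int  # 1-based on the reference CDS
    ref_base: str
    alt_base: str
    count: int
    depth: int
    effect: str  # synonymous | nonsynonymous | nonsense
    aa_change: str

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt base equals reference base")
        if not 0 <= self.count <= self.depth:
            raise ValueError("count must satisfy 0 <= count <= depth")

    @property
    def frequency(self) -> float:
        return self.count / self.depth


class SnpFrequencyTable:
    """All SNP records of one population plus the per-site call depth."""

    def __init__(
        self,
        records: list[SnpRecord],
        site_depth: np.ndarray,
        population: PopulationAlignment | None = None,
        meta: dict | None = None,
    ) -> None:
        self.records = records
        self.site_depth = np.asarray(site_depth, dtype=np.int64)
        self.population = population
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": r.position,
                "ref": r.ref_base,
                "alt": r.alt_base,
                "count": r.count,
                "depth": r.depth,
                "frequency": r.frequency,
                "effect": r.effect,
                "aa_change": r.aa_change,
            }
            for r in self.records
        ]
        df = pd.DataFrame(
            rows,
            columns=[
                "position",
                "ref",
                "alt",
                "count",
                "depth",
                "frequency",
                "effect",
                "aa_change",
            ],
        )
        for key, val in self.meta.items():
            df[key] = val
        return df


@dataclass
class FilterReport:
    """Per-rule removal accounting; each read counts against the first rule it fails."""

    n_input: int = 0
    n_passed: int = 0
    removed: Counter = field(default_factory=Counter)

    RULES = ("length", "quality", "span", "stop_codon")

    def check(self) -> None:
        if self.n_input != self.n_passed + sum(self.removed.values()):
            raise AssertionError("filter report does not conserve read count")


# ---------------------------------------------------------------------------
# ingestion


def read_reference(path: str | Path, numbering_map: dict[int, str] | None = None,
                   require_start: bool = True) -> Reference:
    """Load the reference CDS from a single-record FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one reference record in {path}")
    rec = records[0]
    return Reference(rec.id, str(rec.seq), numbering_map, require_start)


def read_numbering_map(path: str | Path) -> dict[int, str]:
    """Two-column TSV (codon index, display label) for historical numbering
    schemes such as the Ambler labels of class A beta-lactamases."""
    df = pd.read_csv(path, sep="\t", header=None, names=["codon", "label"],
                     dtype={"codon": int, "label": str}, comment="#")
    if df["codon"].duplicated().any():
        raise ValueError("duplicate codon indices in numbering map")
    return dict(zip(df["codon"], df["label"]))


def read_barcode_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (barcode, sample) -> dict, validating uniqueness."""
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "sample"],
                     dtype=str, comment="#")
    barcodes = df["barcode"].str.upper()
    if barcodes.duplicated().any():
        raise ValueError("duplicate barcodes in barcode map")
    return dict(zip(barcodes, df["sample"]))


def reads_from_fastq(
    path: str | Path, reference: Reference, barcode_length: int = 6
) -> list[AlignedRead]:
    """Load reads whose first barcode_length bases are the sample barcode and
    whose remainder is already in reference coordinates (uniform length).

    Reads whose post-barcode length differs from the reference length are
    rejected, because they cannot be interpreted as gapless alignments.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()
        quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16)
        barcode, body = seq[:barcode_length], seq[barcode_length:]
        if len(body) != len(reference):
            raise ValueError(
                f"read {rec.id}: aligned length {len(body)} != reference "
                f"length {len(reference)}"
            )
        out.append(AlignedRead(rec.id, body, quals[barcode_length:], barcode))
    return out


def reads_from_sam(path: str | Path, reference: Reference) -> list[AlignedRead]:
    """Project primary SAM alignments onto reference coordinates.

    Insertions and soft clips are dropped; deletions and unaligned reference
    positions become '-' with the sentinel quality.  Secondary and
    supplementary records are skipped (counted in the log).
    """
    import pysam

    L = len(reference)
    reads: list[AlignedRead] = []
    skipped = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                skipped += 1
                continue
            seq = aln.query_sequence
            quals = aln.query_qualities
            if seq is None:
                skipped += 1
                continue
            cols = np.full(L, "-", dtype="U1")
            qcols = np.full(L, GAP_QUALITY, dtype=np.int16)
            for qpos, rpos in aln.get_aligned_pairs(matches_only=False):
                if rpos is None or rpos >= L:
                    continue  # insertion relative to reference, or overhang
                if qpos is None:
                    continue  # deletion: stays '-'
                cols[rpos] = seq[qpos].upper()
                qcols[rpos] = quals[qpos] if quals is not None else 0
            barcode = (
                dict(aln.get_tags()).get("BC")
                if aln.has_tag("BC")
                else None
            )
            reads.append(AlignedRead(aln.query_name, "".join(cols), qcols, barcode))
    if skipped:
        logger.info("skipped %d secondary/supplementary/unmapped records", skipped)
    return reads


# ---------------------------------------------------------------------------
# demultiplexing and filtering


def demultiplex(
    reads: Iterable[AlignedRead], barcode_map: Mapping[str, str]
) -> tuple[dict[str, list[AlignedRead]], list[AlignedRead], Counter]:
    """Assign reads to samples by exact barcode match.

    Returns (sample -> reads, unassigned reads, counters).  One-mismatch
    rescue is deliberately not attempted: only perfect barcode matches are
    assigned.
    """
    barcodes = list(barcode_map)
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcode map")
    if len({len(b) for b in barcodes} | {0}) > 2:
        raise ValueError("barcodes must have equal length")
    assigned: dict[str, list[AlignedRead]] = {s: [] for s in barcode_map.values()}
    unassigned: list[AlignedRead] = []
    counts: Counter = Counter()
    for read in reads:
        counts["input"] += 1
        sample = barcode_map.get(read.barcode) if read.barcode else None
        if sample is None:
            unassigned.append(read)
            counts["unassigned"] += 1
        else:
            assigned[sample].append(read)
            counts["assigned"] += 1
    return assigned, unassigned, counts


def _read_passes_stop_rule(read: AlignedRead, reference: Reference) -> bool:
    codes = read.codes
    if ((codes == GAP_CODE) | (codes == N_CODE)).any():
        return False  # cannot translate; span rule normally catches this first
    aas = translate_codes(codes)
    return bool(aas[-1] == STOP_AA and not (aas[:-1] == STOP_AA).any())


def filter_reads(
    reads: Iterable[AlignedRead],
    reference: Reference,
    min_mean_q: float = 20.0,
    len_range: tuple[int, int] = (850, 1200),
    require_full_span: bool = True,
    stop_codon_rule: bool = True,
) -> tuple[list[AlignedRead], FilterReport]:
    """Apply the read-level filters in the fixed order length, quality, span,
    stop codon; each rejected read is attributed to the first failing rule."""
    if stop_codon_rule and reference.codon_aas[-1] != STOP_AA:
        raise ValueError("stop-codon rule requires a reference with terminal stop")
    report = FilterReport()
    passed: list[AlignedRead] = []
    lo, hi = len_range
    for read in reads:
        report.n_input += 1
        if not lo <= read.ungapped_length <= hi:
            report.removed["length"] += 1
            continue
        if not read.mean_quality > min_mean_q:
            report.removed["quality"] += 1
            continue
        if require_full_span and (read.codes == GAP_CODE).any():
            report.removed["span"] += 1
            continue
        if stop_codon_rule and not _read_passes_stop_rule(read, reference):
            report.removed["stop_codon"] += 1
            continue
        passed.append(read)
        report.n_passed += 1
    report.check()
    return passed, report


# ---------------------------------------------------------------------------
# SNP calling


def call_snps(
    read: AlignedRead, reference: Reference, min_base_q: float = 20.0
) -> list[tuple[int, str]]:
    """Positions (1-based) where the read differs from the reference with
    per-base Phred strictly above min_base_q.  Gaps and N are never calls."""
    codes = read.codes
    if codes.size != len(reference):
        raise ValueError("read is not in reference coordinates")
    callable_mask = (codes < GAP_CODE) & (read.qualities > min_base_q)
    mism = callable_mask & (codes != reference.codes)
    positions = np.nonzero(mism)[0]
    return [(int(p) + 1, read.aligned_seq[p]) for p in positions]


def classify_snp_effect(
    position: int, alt_base: str, reference: Reference
) -> tuple[str, str]:
    """Effect of a single substitution on the encoded protein.

    Returns (effect, aa_change) where effect is synonymous / nonsynonymous /
    nonsense and aa_change is e.g. "E104K" under the reference numbering.
    """
    if not 1 <= position <= len(reference):
        raise ValueError(f"position {position} outside reference CDS")
    if alt_base not in "ACGT":
        raise ValueError(f"invalid alternative base {alt_base!r}")
    i = position - 1
    codon_idx = i // 3
    codon = list(reference.cds_sequence[3 * codon_idx : 3 * codon_idx + 3])
    if codon[i % 3] == alt_base:
        raise ValueError("alternative base equals the reference base")
    codon[i % 3] = alt_base
    aa_ref = int(reference.codon_aas[codon_idx])
    aa_alt = int(translate_codes(encode("".join(codon)))[0])
    label = (
        f"{aa_letter(aa_ref)}{reference.codon_label(codon_idx + 1)}{aa_letter(aa_alt)}"
    )
    if aa_alt == aa_ref:
        return "synonymous", label
    if aa_alt == STOP_AA:
        return "nonsense", label
    return "nonsynonymous", label


def snp_frequency_table(
    pop: PopulationAlignment,
    reference: Reference,
    min_base_q: float = 20.0,
    meta: dict | None = None,
) -> SnpFrequencyTable:
    """Tabulate per-(position, alt) counts and frequencies over a population.

    depth at a site is the number of reads contributing a quality-passing,
    non-gap base there (the same per-base gate applies to numerator and
    denominator), so frequency is an exact integer ratio count/depth.
    """
    if len(pop) == 0:
        raise ValueError("population is empty")
    mat = pop.matrix
    quals = pop.quality_matrix
    callable_mask = (mat < GAP_CODE) & (quals > min_base_q)
    site_depth = callable_mask.sum(axis=0)
    records: list[SnpRecord] = []
    mism = callable_mask & (mat != reference.codes[None, :])
    cols = np.nonzero(mism.any(axis=0))[0]
    for col in cols:
        bases = mat[mism[:, col], col]
        for code in np.unique(bases):
            alt = "ACGT"[code]
            effect, aa_change = classify_snp_effect(int(col) + 1, alt, reference)
            records.append(
                SnpRecord(
                    position=int(col) + 1,
                    ref_base=reference.cds_sequence[col],
                    alt_base=alt,
                    count=int((bases == code).sum()),
                    depth=int(site_depth[col]),
                    effect=effect,
                    aa_change=aa_change,
                )
            )
    records.sort(key=lambda r: (r.position, r.alt_base))
    table_meta = {
        "host": pop.host,
        "replicate": pop.replicate,
        "generation": pop.generation,
        "condition": pop.condition,
    }
    table_meta.update(meta or {})
    return SnpFrequencyTable(records, site_depth, pop, table_meta)


# ---------------------------------------------------------------------------
# export


def write_snp_tsv(table: SnpFrequencyTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_snp_vcf(table: SnpFrequencyTable, reference: Reference,
                  path: str | Path) -> None:
    """Minimal single-sample VCF: POS/REF/ALT plus AF and DP in INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={reference.id},length={len(reference)}>",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Call depth at site">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for r in table.records:
        lines.append(
            f"{reference.id}\t{r.position}\t.\t{r.ref_base}\t{r.alt_base}\t.\t"
            f"PASS\tAF={r.frequency:.6g};DP={r.depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
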