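"""Population genetic diversity of aligned amplicon populations.

Per-site diversity follows pairwise positional nucleotide counting: at an
alignment column with base counts A_j, C_j, G_j, T_j summing to N_j, the
diversity is the fraction of unordered read pairs that differ at the site,

    d_j = 1 - [A_j(A_j-1) + C_j(C_j-1) + G_j(G_j-1) + T_j(T_j-1)]
              / (N_j (N_j - 1)),

and the population diversity D is the arithmetic mean of d_j over sites
(monomorphic sites included by default).  The module also provides
all-against-all pairwise Hamming distances, exact haplotype spectra, and a
PCA projection of one-hot-encoded sampled haplotypes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amplicon_io import PopulationAlignment
from .genetics import GAP_CODE

__all__ = [
    "SiteCounts",
    "site_counts",
    "site_diversity",
    "diversity_profile",
    "mean_diversity",
    "pairwise_hamming",
    "HaplotypeSpectrum",
    "haplotype_spectrum",
    "pca_project",
]


@dataclass
class SiteCounts:
    """Counts of A/C/G/T at one alignment column (gaps and N excluded)."""

    position: int  # 1-based
    a: int
    c: int
    g: int
    t: int

    @property
    def n(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.a, self.c, self.g, self.t], dtype=np.int64)


def _count_matrix(pop: PopulationAlignment, min_base_q: float | None) -> np.ndarray:
    """(L, 4) base-count matrix with optional per-base quality gating."""
    if len(pop) == 0:
        raise ValueError("population is empty")
    mat = pop.matrix
    ok = mat < GAP_CODE
    if min_base_q is not None:
        ok &= pop.quality_matrix > min_base_q
    counts = np.zeros((mat.shape[1], 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = (ok & (mat == b)).sum(axis=0)
    return counts


def site_counts(
    pop: PopulationAlignment, min_base_q: float | None = 20.0
) -> list[SiteCounts]:
    """Per-column A/C/G/T counts; bases failing the quality gate are excluded."""
    counts = _count_matrix(pop, min_base_q)
    return [
        SiteCounts(j + 1, int(row[0]), int(row[1]), int(row[2]), int(row[3]))
        for j, row in enumerate(counts)
    ]


def site_diversity(sc: SiteCounts | np.ndarray) -> float:
    """Fraction of unordered read pairs differing at the site; NaN if N_j < 2."""
    counts = sc.counts if isinstance(sc, SiteCounts) else np.asarray(sc, dtype=np.int64)
    n = int(counts.sum())
    if n < 2:
        return float("nan")
    same = (counts * (counts - 1)).sum()
    return 1.0 - same / (n * (n - 1))


def _profile_from_counts(counts: np.ndarray, min_depth: int) -> np.ndarray:
    n = counts.sum(axis=1)
    same = (counts * (counts - 1)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - same / (n * (n - 1))
    d[n < max(min_depth, 2)] = np.nan
    return d


def diversity_profile(
    pop: PopulationAlignment,
    min_base_q: float | None = 20.0,
    min_depth: int = 2,
) -> pd.DataFrame:
    """Per-site diversity d_j for every reference column (NaN = not computable)."""
    counts = _count_matrix(pop, min_base_q)
    d = _profile_from_counts(counts, min_depth)
    return pd.DataFrame(
        {"position": np.arange(1, counts.shape[0] + 1), "d": d, "depth": counts.sum(axis=1)}
    )


def mean_diversity(
    pop: PopulationAlignment,
    min_base_q: float | None = 20.0,
    min_depth: int = 2,
    polymorphic_only: bool = False,
) -> float:
    """Mean of d_j over computable CDS sites (monomorphic included by default)."""
    counts = _count_matrix(pop, min_base_q)
    d = _profile_from_counts(counts, min_depth)
    if polymorphic_only:
        d = d[np.nan_to_num(d) > 0]
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no computable sites (all below minimum depth)")
    return float(d.mean())


def pairwise_hamming(
    pop: PopulationAlignment,
    subsample_n: int | None = None,
    seed: int | None = None,
    strict_gaps: bool = False,
) -> dict:
    """All-against-all pairwise Hamming distances between reads.

    Columns where either read is gapped or N are skipped by default
    (strict_gaps=True counts them as mismatches).  Returns the full distance
    multiset plus summary statistics.
    """
    if len(pop) < 2:
        raise ValueError("need at least two reads")
    mat = pop.matrix
    if subsample_n is not None:
        if subsample_n > mat.shape[0]:
            raise ValueError("subsample larger than population")
        rng = np.random.default_rng(seed)
        idx = rng.choice(mat.shape[0], size=subsample_n, replace=False)
        mat = mat[np.sort(idx)]
    n = mat.shape[0]
    valid = mat < GAP_CODE
    dists = []
    for i in range(n - 1):
        diff = mat[i + 1 :] != mat[i][None, :]
        if strict_gaps:
            both = np.ones_like(diff, dtype=bool)
        else:
            both = valid[i + 1 :] & valid[i][None, :]
        dists.append((diff & both).sum(axis=1))
    distances = np.concatenate(dists)
    values, counts = np.unique(distances, return_counts=True)
    return {
        "distances": distances,
        "mean": float(distances.mean()),
        "sd": float(distances.std(ddof=1)) if distances.size > 1 else 0.0,
        "histogram": pd.DataFrame({"distance": values, "n_pairs": counts}),
        "n_pairs": int(distances.size),
    }


@dataclass
class HaplotypeSpectrum:
    """Exact-sequence haplotype counts of one population."""

    counts: dict[str, int]

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> np.ndarray:
        freq = np.array(sorted(self.counts.values(), reverse=True), dtype=float)
        return freq / freq.sum()


def haplotype_spectrum(pop: PopulationAlignment) -> HaplotypeSpectrum:
    if len(pop) == 0:
        raise ValueError("population is empty")
    return HaplotypeSpectrum(dict(Counter(r.aligned_seq for r in pop.reads)))


def _one_hot(mat: np.ndarray) -> np.ndarray:
    """(n, L) base codes -> (n, 4L) indicator channels; gaps/N are all-zero."""
    n, L = mat.shape
    out = np.zeros((n, 4 * L), dtype=np.float32)
    for b in range(4):
        out[:, b::4] = (mat == b).astype(np.float32)
    return out


def pca_project(
    pops: list[PopulationAlignment],
    n_sample: int = 200,
    sweep_positions: set[int] | frozenset[int] = frozenset(),
    n_components: int = 3,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project sampled haplotypes from several populations into PC space.

    From each population, n_sample sequences are drawn without replacement;
    alignment columns at positions (1-based) where a SNP swept in any
    population are removed; remaining columns are one-hot encoded (four
    indicator channels per column, gap -> all-zero), centred, and decomposed.

    Returns (coordinates DataFrame, explained variance fractions).
    """
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for pop in pops:
        if len(pop) < n_sample:
            raise ValueError(
                f"population {pop.label} has {len(pop)} reads < n_sample={n_sample}"
            )
        idx = np.sort(rng.choice(len(pop), size=n_sample, replace=False))
        blocks.append(pop.matrix[idx])
        labels.extend([pop.label] * n_sample)
    mat = np.vstack(blocks)
    keep = np.array(
        [j for j in range(mat.shape[1]) if (j + 1) not in sweep_positions],
        dtype=np.int64,
    )
    X = _one_hot(mat[:, keep])
    X -= X.mean(axis=0, keepdims=True)
    # economy SVD: deterministic up to component sign
    _, svals, vt = np.linalg.svd(X, full_matrices=False)
    coords = X @ vt[:n_components].T
    total_var = (X**2).sum()
    explained = (
        (svals[:n_components] ** 2) / total_var
        if total_var > 0
        else np.zeros(n_components)
    )
    df = pd.DataFrame(
        coords, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    df.insert(0, "population", labels)
    return df, explained
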