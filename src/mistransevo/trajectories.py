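"""SNP frequency trajectories across generations, sweeps, and
frequency-change classification of deleterious / beneficial / antibiotic-
specific variants.

A selective sweep is a SNP whose frequency strictly exceeds a threshold
(default 90%) in at least one generation.  Frequency-change classification
uses absolute frequency differences in percentage points: a SNP counts as
decreasing "by at least x" when df <= -x (inclusive), and as increasing
"by more than x" when df > +x (strict), mirroring the asymmetric wording of
the two rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amplicon_io import SnpFrequencyTable
from .stat_tests import StatResult, two_sample_t

__all__ = [
    "TrajectoryTable",
    "SweepCall",
    "build_trajectories",
    "detect_sweeps",
    "sweep_counts",
    "frequency_change",
    "deleterious_fraction_curve",
    "mean_curve",
    "beneficial_fraction",
    "condition_specific_snps",
    "sweep_count_comparison",
]

KEY = ["position", "alt"]
META = ["host", "replicate", "condition"]


class TrajectoryTable:
    """Long-format SNP frequencies per (position, alt, host, replicate,
    condition, generation).  Missing observations are NaN; a frequency of 0
    means the site had positive call depth but the allele was not seen."""

    def __init__(self, df: pd.DataFrame) -> None:
        required = KEY + META + ["generation", "frequency", "depth", "effect"]
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"trajectory frame lacks columns {sorted(missing)}")
        bad = df["frequency"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("frequencies outside [0, 1]")
        self.df = df.sort_values(KEY + META + ["generation"]).reset_index(drop=True)

    @property
    def generations(self) -> list[int]:
        return sorted(self.df["generation"].unique())

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class SweepCall:
    position: int
    alt: str
    host: str
    replicate: int
    condition: str
    max_frequency: float
    first_generation: int
    effect: str


def build_trajectories(tables: list[SnpFrequencyTable]) -> TrajectoryTable:
    """Merge per-population SNP tables into one trajectory table.

    The SNP key set is the union over all tables.  Where a SNP is absent from
    a table, the fill policy is: frequency 0 if the table has positive call
    depth at the site, otherwise missing (NaN) — absence of coverage is never
    turned into an observed zero.
    """
    if not tables:
        raise ValueError("no SNP tables supplied")
    metas = []
    for t in tables:
        m = t.meta
        metas.append((m["host"], m["replicate"], m["condition"], m["generation"]))
    if len(set(metas)) != len(metas):
        raise ValueError("duplicate (host, replicate, condition, generation) metadata")

    frames = [t.to_frame() for t in tables]
    all_keys = (
        pd.concat([f[KEY + ["effect"]] for f in frames if len(f)])
        .drop_duplicates(KEY)
        .reset_index(drop=True)
        if any(len(f) for f in frames)
        else pd.DataFrame(columns=KEY + ["effect"])
    )
    rows = []
    for table, frame in zip(tables, frames):
        merged = all_keys.merge(
            frame[KEY + ["frequency", "depth"]], on=KEY, how="left"
        )
        pos = merged["position"].to_numpy(dtype=np.int64, na_value=0)
        site_depth = table.site_depth[pos - 1]
        absent = merged["frequency"].isna()
        merged.loc[absent & (site_depth > 0), "frequency"] = 0.0
        merged.loc[absent, "depth"] = site_depth[absent.to_numpy()]
        m = table.meta
        for col in ("host", "replicate", "condition", "generation"):
            merged[col] = m[col]
        rows.append(merged)
    df = pd.concat(rows, ignore_index=True)
    return TrajectoryTable(df)


def detect_sweeps(traj: TrajectoryTable, threshold: float = 0.90) -> list[SweepCall]:
    """SNPs whose frequency strictly exceeds the threshold in >=1 generation."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("sweep threshold must lie strictly between 0 and 1")
    calls: list[SweepCall] = []
    grouped = traj.df.dropna(subset=["frequency"]).groupby(KEY + META, sort=True)
    for (pos, alt, host, rep, cond), grp in grouped:
        over = grp[grp["frequency"] > threshold]
        if len(over):
            calls.append(
                SweepCall(
                    position=int(pos),
                    alt=str(alt),
                    host=str(host),
                    replicate=int(rep),
                    condition=str(cond),
                    max_frequency=float(grp["frequency"].max()),
                    first_generation=int(over["generation"].min()),
                    effect=str(grp["effect"].iloc[0]),
                )
            )
    return calls


def sweep_counts(calls: list[SweepCall]) -> dict[tuple[str, int], int]:
    """Number of sweeping SNPs per (host, replicate)."""
    out: dict[tuple[str, int], int] = {}
    for c in calls:
        out[(c.host, c.replicate)] = out.get((c.host, c.replicate), 0) + 1
    return out


def frequency_change(
    traj: TrajectoryTable,
    gen_a: int,
    gen_b: int,
    host: str | None = None,
    replicate: int | None = None,
    condition: str | None = None,
) -> pd.DataFrame:
    """Per-SNP frequency difference f(gen_b) - f(gen_a).

    SNPs missing (NaN) in either generation are excluded from the comparison;
    SNPs absent from both are never present in the output.
    """
    df = traj.df
    for col, val in (("host", host), ("replicate", replicate), ("condition", condition)):
        if val is not None:
            df = df[df[col] == val]
    gens = set(df["generation"].unique())
    for g in (gen_a, gen_b):
        if g not in gens:
            raise ValueError(f"generation {g} not present in trajectory table")
    a = df[df["generation"] == gen_a].set_index(KEY + META)
    b = df[df["generation"] == gen_b].set_index(KEY + META)
    joined = a[["frequency", "effect"]].join(
        b[["frequency"]], lsuffix="_a", rsuffix="_b", how="inner"
    )
    joined = joined.dropna(subset=["frequency_a", "frequency_b"])
    out = joined.reset_index()
    out["delta_f"] = out["frequency_b"] - out["frequency_a"]
    return out[KEY + META + ["frequency_a", "frequency_b", "delta_f", "effect"]]


DEFAULT_THRESHOLDS = np.round(np.arange(0.005, 0.0501, 0.005), 4)


def _filter_changes(
    changes: pd.DataFrame,
    exclude_sweeping: set[tuple[int, str]] | None,
    effect_filter: str | None,
) -> pd.DataFrame:
    out = changes
    if effect_filter is not None:
        out = out[out["effect"] == effect_filter]
    if exclude_sweeping and len(out):
        mask = out.apply(
            lambda r: (int(r["position"]), str(r["alt"])) in exclude_sweeping, axis=1
        )
        out = out[~mask]
    return out


def deleterious_fraction_curve(
    changes: pd.DataFrame,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
    exclude_sweeping: set[tuple[int, str]] | None = None,
    effect_filter: str | None = "nonsynonymous",
) -> pd.DataFrame:
    """Percentage of SNPs decreasing in frequency by at least each threshold.

    Strongly sweeping SNPs (given as {(position, alt)}) are excluded, as is
    any effect class other than the one requested (default nonsynonymous).
    Percentages are on the 0-100 scale; the curve is non-increasing in the
    threshold by construction.
    """
    subset = _filter_changes(changes, exclude_sweeping, effect_filter)
    if len(subset) == 0:
        raise ValueError(
            "no SNPs remain after exclusions; cannot form a percentage"
        )
    delta = subset["delta_f"].to_numpy()
    rows = [
        {"threshold": float(x), "percentage": 100.0 * float((delta <= -x).mean())}
        for x in np.asarray(thresholds, dtype=float)
    ]
    return pd.DataFrame(rows)


def mean_curve(curves: list[pd.DataFrame]) -> pd.DataFrame:
    """Cross-replicate mean of percentage curves sharing a threshold grid."""
    merged = pd.concat(curves).groupby("threshold", as_index=False)["percentage"].mean()
    return merged


def beneficial_fraction(
    changes: pd.DataFrame,
    threshold: float = 0.005,
    exclude_sweeping: set[tuple[int, str]] | None = None,
    effect_filter: str | None = "nonsynonymous",
) -> float:
    """Percentage of SNPs increasing in frequency by strictly more than the
    threshold (default 0.5%)."""
    subset = _filter_changes(changes, exclude_sweeping, effect_filter)
    if len(subset) == 0:
        raise ValueError("no SNPs remain after exclusions")
    delta = subset["delta_f"].to_numpy()
    return 100.0 * float((delta > threshold).mean())


def condition_specific_snps(
    changes_by_condition: dict[str, pd.DataFrame],
    threshold: float = 0.005,
) -> pd.DataFrame:
    """SNPs that decrease by at least the threshold under exactly one condition.

    A SNP is specific to condition c iff delta_f <= -threshold under c and
    delta_f > -threshold under every OTHER condition where it is observed.
    SNPs unobserved under one or more other conditions are still reported but
    carry full_coverage=False, so downstream analyses can treat the vacuous
    comparisons explicitly.
    """
    if len(changes_by_condition) < 2:
        raise ValueError("need at least two conditions")
    tables = {
        cond: df.set_index(KEY)["delta_f"] for cond, df in changes_by_condition.items()
    }
    rows = []
    for cond, deltas in tables.items():
        others = [c for c in tables if c != cond]
        for key, df_val in deltas.items():
            if df_val > -threshold:
                continue
            observed_elsewhere = 0
            hit_elsewhere = False
            for other in others:
                if key in tables[other].index:
                    observed_elsewhere += 1
                    if tables[other].loc[key] <= -threshold:
                        hit_elsewhere = True
                        break
            if hit_elsewhere:
                continue
            rows.append(
                {
                    "condition": cond,
                    "position": key[0],
                    "alt": key[1],
                    "delta_f": float(df_val),
                    "full_coverage": observed_elsewhere == len(others),
                }
            )
    return pd.DataFrame(
        rows, columns=["condition", "position", "alt", "delta_f", "full_coverage"]
    )


def sweep_count_comparison(sweeps_by_host: dict[str, list[int]]) -> StatResult:
    """Pooled-variance two-tailed t-test on per-replicate sweep counts of the
    two hosts."""
    if len(sweeps_by_host) != 2:
        raise ValueError("expect exactly two hosts to compare")
    (h1, c1), (h2, c2) = sweeps_by_host.items()
    result = two_sample_t(c1, c2, equal_var=True)
    result.extras.update({"group_1": h1, "group_2": h2})
    return result
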