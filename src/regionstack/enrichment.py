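"""Per-bin locus-overlap enrichment (LOLA-style odds ratios).

For a binned region set, each relative bin position defines a *target*: the
collection of that bin's genomic intervals across all regions.  Against the
universe of all genome-wide bins of the matched size, and a candidate
feature region set as *query*, the 2×2 contingency table is

    a = target universe bins overlapping the query
    b = non-target universe bins overlapping the query
    c = target universe bins not overlapping the query
    d = non-target universe bins not overlapping the query

and the reported statistic is the odds ratio (a·d)/(b·c).  A universe bin
counts as target or query-overlapping when the overlap is at least 1 bp.
The Haldane–Anscombe correction (add 0.5 to every cell when any cell is
zero) is applied by default so that rankings stay finite.

Scanning every relative bin yields an enrichment *profile* per feature set:
where along the regions (center, flanks, …) a feature preferentially sits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import BinFrame, GenomeAssembly, RegionSet


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class BinUniverse:
    """All genome-wide bins of one size; tiling starts at 0 per chromosome,
    the last partial bin included."""

    assembly: GenomeAssembly
    binsize: int
    offsets: dict[str, int]
    n_bins: dict[str, int]
    total_bins: int


def make_universe(assembly: GenomeAssembly, binsize: int) -> BinUniverse:
    if binsize <= 0:
        raise EnrichmentError("binsize must be positive")
    offsets: dict[str, int] = {}
    n_bins: dict[str, int] = {}
    off = 0
    for chrom, length in assembly.chrom_sizes.items():
        offsets[chrom] = off
        n_bins[chrom] = math.ceil(length / binsize)
        off += n_bins[chrom]
    return BinUniverse(assembly=assembly, binsize=binsize, offsets=offsets,
                       n_bins=n_bins, total_bins=off)


def _interval_bins(universe: BinUniverse, chrom: str, start: float, end: float) -> range:
    """Global indices of universe bins overlapping [start, end) by >= 1 bp."""
    if chrom not in universe.offsets or end <= start:
        return range(0)
    nb = universe.n_bins[chrom]
    lo = max(int(math.floor(start / universe.binsize)), 0)
    hi = min(int(math.ceil(end / universe.binsize)), nb)
    if hi <= lo:
        return range(0)
    off = universe.offsets[chrom]
    return range(off + lo, off + hi)


def _mask_from_intervals(universe: BinUniverse,
                         intervals: list[tuple[str, float, float]]) -> np.ndarray:
    mask = np.zeros(universe.total_bins, dtype=bool)
    for chrom, start, end in intervals:
        r = _interval_bins(universe, chrom, start, end)
        if len(r):
            mask[r.start:r.stop] = True
    return mask


def query_mask(universe: BinUniverse, query: RegionSet) -> np.ndarray:
    """Boolean mask over universe bins overlapped (>=1 bp) by any query record."""
    return _mask_from_intervals(
        universe,
        [(row.chrom, row.start, row.end) for _, row in query.records.iterrows()],
    )


def bin_targets(frames: list[BinFrame], bin_index: int) -> tuple[list[tuple[str, float, float]], int]:
    """The ``bin_index``-th bin of every region, as genomic intervals.

    Out-of-bounds bins are dropped; the second return value counts them.
    """
    if not frames:
        return [], 0
    n_bins = frames[0].n_bins
    if not 0 <= bin_index < n_bins:
        raise EnrichmentError(f"bin_index {bin_index} outside [0, {n_bins})")
    targets, dropped = [], 0
    for f in frames:
        if f.out_of_bounds[bin_index]:
            dropped += 1
            continue
        targets.append((f.chrom, float(f.edges[bin_index]), float(f.edges[bin_index + 1])))
    return targets, dropped


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # target bins overlapping query
    b: int  # non-target bins overlapping query
    c: int  # target bins not overlapping query
    d: int  # non-target bins not overlapping query

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EnrichmentError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency(
    targets: list[tuple[str, float, float]],
    query: RegionSet | np.ndarray,
    universe: BinUniverse,
) -> ContingencyTable:
    """Count (target vs non-target) × (query-overlap vs not) universe bins.

    ``query`` may be a RegionSet or a precomputed boolean mask over universe
    bins (so a fixed query is not re-rasterized for every relative bin).
    """
    tmask = _mask_from_intervals(universe, targets)
    qmask = query if isinstance(query, np.ndarray) else query_mask(universe, query)
    a = int(np.sum(tmask & qmask))
    b = int(np.sum(~tmask & qmask))
    c = int(np.sum(tmask & ~qmask))
    d = int(np.sum(~tmask & ~qmask))
    return ContingencyTable(a=a, b=b, c=c, d=d)


def odds_ratio(t: ContingencyTable, correction: str = "haldane") -> float:
    """(a·d)/(b·c); Haldane–Anscombe adds 0.5 to every cell when any is 0."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if correction == "haldane":
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif correction != "none":
        raise EnrichmentError(f"unknown correction {correction!r}")
    denom = b * c
    if denom == 0:
        return math.nan
    return (a * d) / denom


@dataclass
class EnrichmentProfile:
    """Odds ratios per (feature set × relative bin), with raw counts."""

    odds_ratios: pd.DataFrame              # features × bins
    tables: dict[tuple[str, int], ContingencyTable]
    dropped_targets: pd.Series             # per bin, count of out-of-bounds targets

    def top_features(self) -> pd.Series:
        """Most enriched feature at each relative bin (NaN columns -> NA)."""
        return self.odds_ratios.idxmax(axis=0, skipna=True)

    def ranked(self, bin_index: int) -> pd.Series:
        """All features at one bin, sorted by odds ratio desc, ties by name."""
        col = self.odds_ratios.iloc[:, bin_index]
        order = sorted(col.index, key=lambda name: (-col[name] if np.isfinite(col[name])
                                                    else np.inf, name))
        return col.loc[order]


def per_bin_enrichment(
    frames: list[BinFrame],
    feature_sets: list[RegionSet],
    universe: BinUniverse,
    correction: str = "haldane",
) -> EnrichmentProfile:
    """Full (feature × relative-bin) odds-ratio matrix for a region set."""
    if not feature_sets:
        raise EnrichmentError("at least one feature set required")
    if not frames:
        raise EnrichmentError("no frames given")
    n_bins = frames[0].n_bins
    names = []
    for i, fs in enumerate(feature_sets):
        names.append(fs.name if fs.name not in names else f"{fs.name}_{i}")
    masks = {name: query_mask(universe, fs) for name, fs in zip(names, feature_sets)}
    ors = np.full((len(feature_sets), n_bins), np.nan)
    tables: dict[tuple[str, int], ContingencyTable] = {}
    dropped = np.zeros(n_bins, dtype=int)
    for j in range(n_bins):
        targets, dropped[j] = bin_targets(frames, j)
        for fi, name in enumerate(names):
            if not targets:
                continue  # no in-bounds target bins: odds ratio undefined -> NaN
            t = contingency(targets, masks[name], universe)
            tables[(name, j)] = t
            if t.a + t.b == 0:  # empty query
                ors[fi, j] = np.nan
            else:
                ors[fi, j] = odds_ratio(t, correction=correction)
    df = pd.DataFrame(ors, index=names, columns=range(n_bins))
    return EnrichmentProfile(odds_ratios=df, tables=tables,
                             dropped_targets=pd.Series(dropped, index=range(n_bins)))
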