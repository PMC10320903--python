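"""Genomic region sets and their binned coordinate frames.

All coordinates are 0-based half-open (BED-native) at every interface.

A region set is either *point*-kind — each record is reduced to an anchor
coordinate ``floor((start+end)/2)`` and analysed in a symmetric window —
or *interval*-kind, where each record keeps its own length and is analysed
over the interval plus proportional flanks (20% on either side by default),
with the bin width scaling with the interval length so that every region
yields the same number of bins regardless of its size.

Precomputing frames for several window/bin-size (or bin-fraction)
combinations gives a *resolution stack*: the same region set viewed at
multiple length scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

POINT = "point"
INTERVAL = "interval"

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class RegionError(ValueError):
    """Raised on malformed region input or invalid binning configuration."""


@dataclass(frozen=True)
class GenomeAssembly:
    """A named genome assembly: ordered chromosome name -> length (bp)."""

    name: str
    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        sizes = dict(self.chrom_sizes)
        if len(sizes) != len(self.chrom_sizes):
            raise RegionError("duplicate chromosome names in assembly")
        for chrom, length in sizes.items():
            if int(length) <= 0:
                raise RegionError(f"chromosome {chrom!r} has non-positive length {length}")
        object.__setattr__(self, "chrom_sizes", sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def length(self, chrom: str) -> int:
        return int(self.chrom_sizes[chrom])


def read_chrom_sizes(path: str | Path, name: str | None = None) -> GenomeAssembly:
    """Read a two-column ``chrom.sizes`` file (name, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise RegionError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise RegionError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from exc
    return GenomeAssembly(name=name or Path(path).stem, chrom_sizes=sizes)


@dataclass
class RegionSet:
    """Typed genomic intervals (point or interval kind) on a named assembly.

    ``records`` is a DataFrame with columns chrom, start, end, name, strand;
    its integer index is the stable region id used throughout the package.
    """

    kind: str
    records: pd.DataFrame
    assembly: GenomeAssembly
    name: str = "regions"

    def __post_init__(self) -> None:
        if self.kind not in (POINT, INTERVAL):
            raise RegionError(f"unknown region kind {self.kind!r}")
        df = self.records
        for col, default in (("name", "."), ("strand", ".")):
            if col not in df.columns:
                df = df.assign(**{col: default})
        self.records = df[["chrom", "start", "end", "name", "strand"]].copy()
        self._validate()

    def _validate(self) -> None:
        df = self.records
        for rid, row in df.iterrows():
            if row.chrom not in self.assembly:
                raise RegionError(f"record {rid}: chromosome {row.chrom!r} not in assembly")
            if not (0 <= row.start < row.end <= self.assembly.length(row.chrom)):
                raise RegionError(
                    f"record {rid}: invalid interval {row.chrom}:{row.start}-{row.end}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def anchors(self) -> np.ndarray:
        """Point anchors: floor midpoint of each record."""
        s = self.records["start"].to_numpy(dtype=np.int64)
        e = self.records["end"].to_numpy(dtype=np.int64)
        return (s + e) // 2

    def subset(self, region_ids: Sequence[int], name: str | None = None) -> "RegionSet":
        """New RegionSet with the given records, original order preserved."""
        ids = sorted(set(int(i) for i in region_ids))
        df = self.records.loc[ids].copy()
        return RegionSet(kind=self.kind, records=df, assembly=self.assembly,
                         name=name or f"{self.name}_subset")

    def to_bed(self, path: str | Path) -> None:
        write_bed(self, path)


def load_bed(
    path: str | Path,
    assembly: GenomeAssembly,
    kind: str = POINT,
    on_unknown_chrom: str = "warn",
    name: str | None = None,
) -> RegionSet:
    """Load a BED3/BED6 file into a RegionSet.

    Tab- (or whitespace-) separated, 0-based half-open; ``#``, ``track`` and
    ``browser`` lines are skipped.  Column 6, when present, is parsed as
    strand.  Records on chromosomes absent from the assembly are dropped with
    a warning by default (``on_unknown_chrom='warn'``) or raise with
    ``'error'``.
    """
    if on_unknown_chrom not in ("warn", "error"):
        raise ValueError("on_unknown_chrom must be 'warn' or 'error'")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise RegionError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise RegionError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise RegionError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if start < 0:
                raise RegionError(f"{path}:{lineno}: negative start {start}")
            if chrom not in assembly:
                if on_unknown_chrom == "error":
                    raise RegionError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                warnings.warn(f"{path}:{lineno}: skipping unknown chromosome {chrom!r}")
                continue
            if end > assembly.length(chrom):
                raise RegionError(
                    f"{path}:{lineno}: end {end} beyond {chrom} length {assembly.length(chrom)}"
                )
            rec_name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            rows.append((chrom, start, end, rec_name, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return RegionSet(kind=kind, records=df, assembly=assembly, name=name or Path(path).stem)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write BED6 (score column 0); round-trips exactly through load_bed."""
    with open(path, "w") as fh:
        for _, row in regions.records.iterrows():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row['name']}\t0\t{row.strand}\n")


@dataclass(frozen=True)
class PointConfig:
    """Point-region binning: symmetric window of half-width ``windowsize``
    around each anchor, cut into bins of ``binsize`` bp."""

    windowsize: int
    binsize: int

    kind: str = field(default=POINT, init=False)

    def __post_init__(self) -> None:
        if self.windowsize <= 0 or self.binsize <= 0:
            raise RegionError("windowsize and binsize must be positive")
        if (2 * self.windowsize) % self.binsize != 0:
            raise RegionError(
                f"binsize {self.binsize} does not divide window {2 * self.windowsize}"
            )

    @property
    def n_bins(self) -> int:
        return 2 * self.windowsize // self.binsize


@dataclass(frozen=True)
class IntervalConfig:
    """Interval-region binning: bin width is ``binsize_fraction`` of the
    interval length; ``flank_fraction`` of the length is added on each side."""

    binsize_fraction: float
    flank_fraction: float = 0.2

    kind: str = field(default=INTERVAL, init=False)

    def __post_init__(self) -> None:
        if self.flank_fraction < 0:
            raise RegionError("flank_fraction must be >= 0")
        if not (0 < self.binsize_fraction <= self.flank_fraction + 1):
            raise RegionError("binsize_fraction must be in (0, 1 + flank_fraction]")

    @property
    def n_bins(self) -> int:
        return int(round((1 + 2 * self.flank_fraction) / self.binsize_fraction))


ResolutionConfig = PointConfig | IntervalConfig


@dataclass
class BinFrame:
    """Binned coordinate window of one region.

    ``edges`` has ``n_bins + 1`` entries, contiguous left-to-right in genomic
    coordinates; edges may be real-valued (interval kind) and may extend below
    0 or beyond the chromosome end.  ``out_of_bounds[i]`` is True when bin i
    contains any basepair outside ``[0, chrom_length)``.
    """

    chrom: str
    edges: np.ndarray
    out_of_bounds: np.ndarray
    strand: str = "."
    region_id: int = -1

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def int_edges(self) -> np.ndarray:
        """Materialize integer-bp edges (round half up), width clamped >= 1."""
        e = np.floor(np.asarray(self.edges, dtype=float) + 0.5).astype(np.int64)
        if np.any(np.diff(e) < 1):
            for i in range(1, len(e)):  # clamp degenerate (sub-bp) bins
                if e[i] < e[i - 1] + 1:
                    e[i] = e[i - 1] + 1
        return e


def _oob_mask(edges: np.ndarray, chrom_len: int) -> np.ndarray:
    left = np.asarray(edges[:-1], dtype=float)
    right = np.asarray(edges[1:], dtype=float)
    return (left < 0) | (right > chrom_len)


def point_frames(regions: RegionSet, cfg: PointConfig) -> list[BinFrame]:
    """Frames ``[c - w, c + w)`` in ``2w/b`` bins around each anchor c."""
    if regions.kind != POINT:
        raise RegionError("point_frames requires a point-kind region set")
    if cfg.kind != POINT:
        raise RegionError("point_frames requires a PointConfig")
    frames = []
    anchors = regions.anchors
    for (rid, row), c in zip(regions.records.iterrows(), anchors):
        edges = np.arange(cfg.n_bins + 1, dtype=np.int64) * cfg.binsize + (c - cfg.windowsize)
        oob = _oob_mask(edges, regions.assembly.length(row.chrom))
        frames.append(BinFrame(chrom=row.chrom, edges=edges.astype(float), out_of_bounds=oob,
                               strand=row.strand, region_id=int(rid)))
    return frames


def interval_frames(regions: RegionSet, cfg: IntervalConfig) -> list[BinFrame]:
    """Frames spanning each interval plus proportional flanks.

    Every frame has the same bin count ``round((1 + 2*flank)/p)`` regardless
    of interval length (size normalization); edges stay real-valued until
    extraction.
    """
    if regions.kind != INTERVAL:
        raise RegionError("interval_frames requires an interval-kind region set")
    if cfg.kind != INTERVAL:
        raise RegionError("interval_frames requires an IntervalConfig")
    n = cfg.n_bins
    frames = []
    for rid, row in regions.records.iterrows():
        L = row.end - row.start
        if L * cfg.binsize_fraction < 1:
            warnings.warn(
                f"region {rid}: bin width {L * cfg.binsize_fraction:.2f} bp < 1; clamped"
            )
        lo = row.start - cfg.flank_fraction * L
        hi = row.end + cfg.flank_fraction * L
        edges = np.linspace(lo, hi, n + 1)
        oob = _oob_mask(edges, regions.assembly.length(row.chrom))
        frames.append(BinFrame(chrom=row.chrom, edges=edges, out_of_bounds=oob,
                               strand=row.strand, region_id=int(rid)))
    return frames


def frames_for(regions: RegionSet, cfg: ResolutionConfig) -> list[BinFrame]:
    return point_frames(regions, cfg) if regions.kind == POINT else interval_frames(regions, cfg)


DEFAULT_POINT_STACK = tuple(PointConfig(w, w // 25) for w in (50_000, 200_000, 1_000_000))
DEFAULT_INTERVAL_STACK = (IntervalConfig(0.05), IntervalConfig(0.1))


def resolution_stack(
    regions: RegionSet,
    configs: Iterable[ResolutionConfig] | None = None,
) -> dict[ResolutionConfig, list[BinFrame]]:
    """Compute frames for every config; the multi-scale view of a region set."""
    if configs is None:
        configs = DEFAULT_POINT_STACK if regions.kind == POINT else DEFAULT_INTERVAL_STACK
    configs = list(configs)
    if not configs:
        raise RegionError("resolution_stack requires at least one config")
    for cfg in configs:
        if cfg.kind != regions.kind:
            raise RegionError(
                f"config kind {cfg.kind!r} does not match region kind {regions.kind!r}"
            )
    return {cfg: frames_for(regions, cfg) for cfg in configs}
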