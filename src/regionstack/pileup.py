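"""Snippet extraction and reduction: average profiles, average maps,
stacked line-profile matrices, and sharable sort orders.

The central container is the :class:`SnippetStack`: one row of binned signal
(1D) or one square sub-matrix (2D) per region, aligned to the region ids of
the frames it was extracted from.  Missing data — out-of-bounds bins,
off-chromosome windows — is encoded NaN and every reduction ignores NaN
per cell, so a region falling off the chromosome end thins the average
locally instead of poisoning it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .featureio import ContactMatrix2D, SignalTrack1D
from .regions import BinFrame


class PileupError(ValueError):
    pass


@dataclass
class SnippetStack:
    """Region-by-bin (1D) or region-by-bin-by-bin (2D) value array."""

    values: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=np.int64)
        if self.values.shape[0] != len(self.region_ids):
            raise PileupError("first dimension must equal region count")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def ndim(self) -> int:
        return self.values.ndim - 1

    def valid_counts(self) -> np.ndarray:
        """Per-cell count of non-NaN contributions across regions."""
        return np.sum(~np.isnan(self.values), axis=0)


@dataclass
class SortOrder:
    """A permutation of region ids, sharable between stacks of one region
    set so several views can be sorted consistently (coupled sorting)."""

    region_ids: np.ndarray
    provenance: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids, dtype=np.int64)
        if len(np.unique(self.region_ids)) != len(self.region_ids):
            raise PileupError("sort order contains duplicate region ids")


def _check_homogeneous(frames: list[BinFrame]) -> int:
    if not frames:
        raise PileupError("no frames given")
    n_bins = {f.n_bins for f in frames}
    if len(n_bins) != 1:
        raise PileupError(f"frames have differing bin counts: {sorted(n_bins)}")
    return n_bins.pop()


def extract_1d(
    track: SignalTrack1D,
    frames: list[BinFrame],
    flip_minus_strand: bool = False,
) -> SnippetStack:
    """Extract one binned row per frame; out-of-bounds bins become NaN.

    With ``flip_minus_strand``, rows of '-'-strand records are reversed so
    that all rows read 5'→3' relative to the region.
    """
    n_bins = _check_homogeneous(frames)
    out = np.full((len(frames), n_bins), np.nan)
    for i, frame in enumerate(frames):
        row = track.binned_means(frame.chrom, frame.int_edges().astype(float))
        row = np.asarray(row, dtype=float).copy()
        row[frame.out_of_bounds] = np.nan
        if flip_minus_strand and frame.strand == "-":
            row = row[::-1]
        out[i] = row
    return SnippetStack(values=out, region_ids=np.array([f.region_id for f in frames]))


def aggregate_1d(stack: SnippetStack) -> np.ndarray:
    """Per-bin mean over regions, ignoring NaN; all-NaN bins stay NaN."""
    if stack.n_regions == 0:
        raise PileupError("cannot aggregate an empty stack")
    if stack.ndim != 1:
        raise PileupError("aggregate_1d requires a 1D stack")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stack.values, axis=0)


def extract_2d(
    contacts: ContactMatrix2D,
    frames: list[BinFrame],
    binsize: int | None = None,
) -> SnippetStack:
    """Extract one square contact snippet per frame.

    For frames whose bins sit on the store's native grid (point regions with
    bin width equal to a stored binsize) the native matrix is sliced
    directly.  Variable-width frames (interval regions) are served by
    querying the nearest finer native binsize and block-averaging native
    bins onto frame bins.  Off-chromosome rows and columns are NaN.
    """
    n_bins = _check_homogeneous(frames)
    widths = np.concatenate([np.diff(f.edges) for f in frames])
    min_width = float(np.min(widths))
    if binsize is None:
        finer = [b for b in contacts.binsizes if b <= min_width]
        if not finer:
            raise PileupError(
                f"no stored binsize <= minimum frame bin width {min_width:.1f} bp "
                f"(stored: {sorted(contacts.binsizes)})"
            )
        binsize = max(finer)
    elif binsize > min_width:
        raise PileupError(f"binsize {binsize} exceeds minimum frame bin width {min_width:.1f}")

    out = np.full((len(frames), n_bins, n_bins), np.nan)
    for i, frame in enumerate(frames):
        w = np.diff(frame.edges)
        if np.allclose(w, binsize):
            # native-width frame: direct slice, start snapped to nearest grid bin
            i0 = int(np.floor(frame.edges[0] / binsize + 0.5))
            snip = contacts.matrix(frame.chrom, i0 * binsize,
                                   (i0 + n_bins) * binsize, binsize)
        else:
            lo = int(np.floor(frame.edges[0] / binsize)) * binsize
            hi = int(np.ceil(frame.edges[-1] / binsize)) * binsize
            native = contacts.matrix(frame.chrom, lo, hi, binsize)
            mids = lo + (np.arange(native.shape[0]) + 0.5) * binsize
            assign = np.searchsorted(frame.edges, mids, side="right") - 1
            keep = (assign >= 0) & (assign < n_bins)
            snip = _block_mean(native[keep][:, keep], assign[keep], n_bins)
        snip = snip.copy()
        snip[frame.out_of_bounds, :] = np.nan
        snip[:, frame.out_of_bounds] = np.nan
        out[i] = snip
    return SnippetStack(values=out, region_ids=np.array([f.region_id for f in frames]))


def _block_mean(m: np.ndarray, assign: np.ndarray, n_bins: int) -> np.ndarray:
    """NaN-aware mean of matrix blocks grouped by ``assign`` on both axes."""
    out = np.full((n_bins, n_bins), np.nan)
    groups = [np.flatnonzero(assign == k) for k in range(n_bins)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, gj in enumerate(groups):
            if len(gj) == 0:
                continue
            rows = m[gj]
            for k, gk in enumerate(groups):
                if len(gk) == 0:
                    continue
                out[j, k] = np.nanmean(rows[:, gk])
    return out


def aggregate_2d(stack: SnippetStack) -> np.ndarray:
    """Pixel-wise NaN-ignoring mean over all snippets."""
    if stack.n_regions == 0:
        raise PileupError("cannot aggregate an empty stack")
    if stack.ndim != 2:
        raise PileupError("aggregate_2d requires a 2D stack")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stack.values, axis=0)


def sort_order_by_track(
    stack: SnippetStack,
    statistic: str = "row_mean",
    descending: bool = True,
) -> SortOrder:
    """Permutation of region ids by a per-row statistic.

    ``row_mean`` is the NaN-ignoring row mean; ``center_bin`` the value of
    the middle bin.  All-NaN rows sort last; ties keep region order (stable).
    """
    if stack.ndim != 1:
        raise PileupError("sort_order_by_track requires a 1D stack")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if statistic == "row_mean":
            keys = np.nanmean(stack.values, axis=1)
        elif statistic == "center_bin":
            keys = stack.values[:, stack.values.shape[1] // 2]
        else:
            raise PileupError(f"unknown statistic {statistic!r}")
    nan = np.isnan(keys)
    sortable = np.where(nan, 0.0, keys)
    if descending:
        sortable = -sortable
    perm = np.lexsort((np.arange(len(keys)), sortable, nan.astype(int)))
    return SortOrder(region_ids=stack.region_ids[perm],
                     provenance=(statistic, "desc" if descending else "asc"))


def apply_sort_order(stack: SnippetStack, order: SortOrder) -> SnippetStack:
    """Reorder (and possibly subset) a stack by a SortOrder of region ids."""
    pos = {rid: i for i, rid in enumerate(stack.region_ids)}
    missing = [rid for rid in order.region_ids if rid not in pos]
    if missing:
        raise PileupError(f"sort order references unknown region ids: {missing[:5]}")
    idx = np.array([pos[rid] for rid in order.region_ids], dtype=np.int64)
    return SnippetStack(values=stack.values[idx], region_ids=stack.region_ids[idx])


def stacked_profiles(
    stack: SnippetStack,
    max_rows: int = 1000,
    order: SortOrder | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, SortOrder]:
    """Stacked line-profile matrix: one row per (retained) region.

    When the stack exceeds ``max_rows`` regions, a uniform random subsample
    of exactly ``max_rows`` rows (without replacement, seeded) is taken
    before any ordering, keeping heatmap rendering bounded.  The returned
    SortOrder names the retained region ids in display order, so it can be
    applied to another stack of the same region set for coupled sorting.
    """
    if stack.ndim != 1:
        raise PileupError("stacked_profiles requires a 1D stack")
    sub = stack
    if stack.n_regions > max_rows:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(stack.n_regions, size=max_rows, replace=False))
        sub = SnippetStack(values=stack.values[keep], region_ids=stack.region_ids[keep])
    if order is not None:
        retained = set(sub.region_ids.tolist())
        ids = [rid for rid in order.region_ids if rid in retained]
        if len(ids) != sub.n_regions:
            unknown = set(order.region_ids.tolist()) - set(stack.region_ids.tolist())
            if unknown:
                raise PileupError(f"sort order references unknown region ids: "
                                  f"{sorted(unknown)[:5]}")
            raise PileupError("sort order does not cover all retained regions")
        sub = apply_sort_order(sub, SortOrder(region_ids=np.array(ids)))
        final = SortOrder(region_ids=sub.region_ids, provenance=order.provenance)
    else:
        final = SortOrder(region_ids=sub.region_ids, provenance=("input_order", ""))
    return sub.values, final


def insulation_contrast(avg_map: np.ndarray, q: int | None = None) -> float:
    """Distance-matched within-quadrant minus cross-quadrant mean.

    Splits the average map at its center boundary into an upstream and a
    downstream quadrant of ``q`` bins each (default: half the side).  Raw
    quadrant means are confounded by distance decay — cross-quadrant pixels
    lie farther from the diagonal — so pixel pairs are grouped by their
    diagonal distance ``|i - j|`` and within/cross means are compared at
    equal distance, then averaged over distances.  Positive values indicate
    insulation: contacts crossing the center are depleted relative to
    same-side contacts at the same genomic separation.
    """
    n = avg_map.shape[0]
    m = n // 2
    if q is None:
        q = m
    q = min(q, m)
    diffs = []
    for d in range(1, 2 * q):
        within, cross = [], []
        for i in range(m - q, m + q):
            j = i + d
            if j >= m + q:
                continue
            v = avg_map[i, j]
            if np.isnan(v):
                continue
            if (i < m) == (j < m):
                within.append(v)
            else:
                cross.append(v)
        if within and cross:
            diffs.append(np.mean(within) - np.mean(cross))
    if not diffs:
        raise PileupError("no distance class has both within- and cross-quadrant pixels")
    return float(np.mean(diffs))
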