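"""Readers for 1D coverage tracks and 2D contact matrices.

Two backends each:

* 1D — bigWig (via pyBigWig) and a plain-text bedGraph-like dialect
  (``chrom  start  end  value``, tab-separated, ``#`` comments allowed,
  intervals must not overlap).
* 2D — a plain-text contact dialect and, when the optional ``cooler``
  package is importable, ``.cool``/``.mcool`` files.  Text grammar::

      #binsize<TAB><bp>
      #chrom<TAB><name><TAB><length_bp>       (one line per chromosome)
      <bin_i><TAB><bin_j><TAB><value>         (global bin indices, upper or
                                               either triangle; symmetrized)

Bin-aggregation semantics for 1D queries: value of a bin is the mean over
its basepairs, where basepairs not covered by any interval count as 0
(coverage semantics) and basepairs outside the chromosome make the bin NaN.
Contact values are used as stored; no balancing is applied unless a stored
weight column is selected (cooler backend only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


class FeatureIOError(ValueError):
    pass


# --------------------------------------------------------------------------
# 1D tracks


class SignalTrack1D:
    """Query contract: values(chrom, start, end, n_bins) -> per-bin means."""

    name: str = "track"

    def binned_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Per-bin mean for arbitrary (real-valued) bin edges."""
        raise NotImplementedError

    def values(self, chrom: str, start: float, end: float, n_bins: int) -> np.ndarray:
        edges = np.linspace(float(start), float(end), int(n_bins) + 1)
        return self.binned_means(chrom, edges)


class TextTrack(SignalTrack1D):
    """bedGraph-like text track held in memory.

    Queries integrate the step function exactly: for each chromosome the
    cumulative integral F(x) of the track is piecewise linear, so the mean
    over [a, b) is (F(b) - F(a)) / (b - a) with uncovered basepairs
    contributing 0.
    """

    def __init__(self, path: str | Path):
        self.name = Path(path).stem
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 4:
                    raise FeatureIOError(f"{path}:{lineno}: expected 4 columns")
                try:
                    s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
                except ValueError as exc:
                    raise FeatureIOError(f"{path}:{lineno}: bad numeric field") from exc
                if s >= e:
                    raise FeatureIOError(f"{path}:{lineno}: start >= end")
                per_chrom.setdefault(parts[0], []).append((s, e, v))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        self.chrom_extent: dict[str, int] = {}
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            starts = np.array([i[0] for i in ivals], dtype=float)
            ends = np.array([i[1] for i in ivals], dtype=float)
            vals = np.array([i[2] for i in ivals], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise FeatureIOError(f"overlapping intervals on {chrom} in {path}")
            # cumulative integral of the step function at each interval start
            cum = np.concatenate([[0.0], np.cumsum((ends - starts) * vals)])
            self._chroms[chrom] = (starts, ends, vals, cum)
            self.chrom_extent[chrom] = int(ends[-1])

    def set_chrom_lengths(self, sizes: dict[str, int]) -> None:
        """Declare true chromosome lengths (else the last covered bp is used)."""
        self.chrom_extent.update({c: int(v) for c, v in sizes.items()})

    def _integral(self, chrom: str, x: np.ndarray) -> np.ndarray:
        starts, ends, vals, cum = self._chroms[chrom]
        x = np.asarray(x, dtype=float)
        i = np.searchsorted(starts, x, side="right") - 1
        out = np.where(i >= 0, cum[np.maximum(i, 0)], 0.0)
        inside = i >= 0
        ii = np.maximum(i, 0)
        # within interval ii: add value * overlap; past its end: whole interval
        overlap = np.clip(x - starts[ii], 0.0, ends[ii] - starts[ii])
        out = out + np.where(inside, vals[ii] * overlap, 0.0)
        return out

    def binned_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        edges = np.asarray(edges, dtype=float)
        n = len(edges) - 1
        if chrom not in self._chroms:
            return np.full(n, np.nan)
        length = self.chrom_extent[chrom]
        F = self._integral(chrom, np.clip(edges, 0, None))
        widths = np.diff(edges)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(widths > 0, np.diff(F) / np.maximum(widths, 1e-300), np.nan)
        oob = (edges[:-1] < 0) | (edges[1:] > length)
        means = means.astype(float)
        means[oob & ((edges[1:] <= 0) | (edges[:-1] >= length))] = np.nan  # fully outside
        # partially out-of-bounds bins: mean over in-bounds part only
        partial = oob & ~((edges[1:] <= 0) | (edges[:-1] >= length))
        if np.any(partial):
            lo = np.clip(edges[:-1], 0, length)
            hi = np.clip(edges[1:], 0, length)
            Fi = self._integral(chrom, lo)
            Fj = self._integral(chrom, hi)
            w = hi - lo
            means[partial] = ((Fj - Fi) / np.maximum(w, 1e-300))[partial]
        return means


class BigWigTrack(SignalTrack1D):
    """bigWig-backed track; uncovered basepairs count as 0 in bin means."""

    def __init__(self, path: str | Path):
        import pyBigWig

        self._bw = pyBigWig.open(str(path))
        if not self._bw.isBigWig():
            raise FeatureIOError(f"{path} is not a bigWig file")
        self.name = Path(path).stem
        self.chrom_extent = dict(self._bw.chroms())

    def binned_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        edges = np.asarray(edges, dtype=float)
        n = len(edges) - 1
        if chrom not in self.chrom_extent:
            return np.full(n, np.nan)
        length = self.chrom_extent[chrom]
        lo = int(np.floor(max(edges[0], 0)))
        hi = int(np.ceil(min(edges[-1], length)))
        out = np.full(n, np.nan)
        if hi <= lo:
            return out
        vals = np.asarray(self._bw.values(chrom, lo, hi, numpy=True), dtype=float)
        vals = np.nan_to_num(vals, nan=0.0)  # uncovered bp -> 0
        cum = np.concatenate([[0.0], np.cumsum(vals)])

        def integral(x: np.ndarray) -> np.ndarray:
            x = np.clip(x, lo, hi) - lo
            i = np.floor(x).astype(int)          # in [0, hi-lo]; cum is valid there
            frac = x - i
            iv = np.minimum(i, hi - lo - 1)      # frac is 0 whenever i is clamped
            return cum[i] + frac * vals[iv] if len(vals) else np.zeros_like(x)

        a = np.clip(edges[:-1], 0, length)
        b = np.clip(edges[1:], 0, length)
        w = b - a
        ok = w > 0
        out[ok] = (integral(b) - integral(a))[ok] / w[ok]
        return out


def open_track(path: str | Path) -> SignalTrack1D:
    """Open a bigWig or text-dialect 1D track, auto-detected by magic/extension."""
    p = Path(path)
    if not p.exists():
        raise FeatureIOError(f"no such track file: {path}")
    with open(p, "rb") as fh:
        magic = fh.read(4)
    if magic in (b"\x26\xfc\x8f\x88", b"\x88\x8f\xfc\x26") or p.suffix.lower() in (".bw", ".bigwig"):
        return BigWigTrack(p)
    return TextTrack(p)


# --------------------------------------------------------------------------
# 2D contact stores


class ContactMatrix2D:
    """Query contract: matrix(chrom, start, end, binsize) -> square array.

    The queried window is snapped onto the native bin grid: queried bin k
    covers native bin ``floor(start/binsize) + k``.  Bins outside the
    chromosome are NaN rows/columns.
    """

    binsizes: tuple[int, ...] = ()

    def matrix(self, chrom: str, start: int, end: int, binsize: int) -> np.ndarray:
        raise NotImplementedError

    def _check_binsize(self, binsize: int) -> None:
        if binsize not in self.binsizes:
            raise FeatureIOError(
                f"binsize {binsize} not available; stored binsizes: {sorted(self.binsizes)}"
            )


class TextContactStore(ContactMatrix2D):
    """Plain-text sparse contact store (single binsize), symmetrized on load."""

    def __init__(self, path: str | Path):
        from scipy import sparse

        self.name = Path(path).stem
        binsize = None
        chrom_sizes: dict[str, int] = {}
        rows, cols, vals = [], [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#binsize"):
                    binsize = int(line.split("\t")[1])
                    continue
                if line.startswith("#chrom"):
                    _, cname, clen = line.split("\t")
                    chrom_sizes[cname] = int(clen)
                    continue
                if line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise FeatureIOError(f"{path}:{lineno}: expected 3 columns")
                i, j = int(parts[0]), int(parts[1])
                rows.append(min(i, j))  # canonicalize to the upper triangle
                cols.append(max(i, j))
                vals.append(float(parts[2]))
        if binsize is None or not chrom_sizes:
            raise FeatureIOError(f"{path}: missing #binsize or #chrom header")
        self.binsizes = (binsize,)
        self.chrom_sizes = chrom_sizes
        self._nbins = {c: -(-l // binsize) for c, l in chrom_sizes.items()}
        offsets, off = {}, 0
        for c, nb in self._nbins.items():
            offsets[c] = off
            off += nb
        self._offsets = offsets
        total = off
        upper = sparse.coo_matrix((vals, (rows, cols)), shape=(total, total)).tocsr()
        self._m = (upper + upper.T - sparse.diags(upper.diagonal())).tocsr()

    def matrix(self, chrom: str, start: int, end: int, binsize: int) -> np.ndarray:
        self._check_binsize(binsize)
        if chrom not in self._offsets:
            n = max(int(round((end - start) / binsize)), 0)
            return np.full((n, n), np.nan)
        n = int(round((end - start) / binsize))
        i0 = int(np.floor(start / binsize))
        nb = self._nbins[chrom]
        out = np.full((n, n), np.nan)
        lo = max(i0, 0)
        hi = min(i0 + n, nb)
        if hi <= lo:
            return out
        off = self._offsets[chrom]
        block = self._m[off + lo:off + hi, off + lo:off + hi].toarray()
        out[lo - i0:hi - i0, lo - i0:hi - i0] = block
        return out


class CoolerContacts(ContactMatrix2D):
    """cooler-backed store (.cool single or .mcool multi-resolution).

    Requires the optional ``cooler`` dependency.
    """

    def __init__(self, path: str | Path, balance: bool = False):
        try:
            import cooler
        except ImportError as exc:
            raise FeatureIOError(
                "opening .cool/.mcool files requires the optional 'cooler' package"
            ) from exc
        p = str(path)
        self.name = Path(path).stem
        self._balance = balance
        if cooler.fileops.is_multires_file(p):
            uris = cooler.fileops.list_coolers(p)
            self._coolers = {cooler.Cooler(f"{p}::{u}").binsize: cooler.Cooler(f"{p}::{u}")
                             for u in uris}
        else:
            c = cooler.Cooler(p)
            self._coolers = {c.binsize: c}
        self.binsizes = tuple(sorted(self._coolers))

    def matrix(self, chrom: str, start: int, end: int, binsize: int) -> np.ndarray:
        self._check_binsize(binsize)
        c = self._coolers[binsize]
        if chrom not in c.chromnames:
            n = int(round((end - start) / binsize))
            return np.full((n, n), np.nan)
        clen = c.chromsizes[chrom]
        nb = -(-clen // binsize)
        n = int(round((end - start) / binsize))
        i0 = int(np.floor(start / binsize))
        out = np.full((n, n), np.nan)
        lo, hi = max(i0, 0), min(i0 + n, nb)
        if hi <= lo:
            return out
        block = c.matrix(balance=self._balance)[
            c.offset(chrom) + lo:c.offset(chrom) + hi,
            c.offset(chrom) + lo:c.offset(chrom) + hi,
        ]
        out[lo - i0:hi - i0, lo - i0:hi - i0] = np.asarray(block, dtype=float)
        return out


def open_contacts(path: str | Path, balance: bool = False) -> ContactMatrix2D:
    """Open a text-dialect or cooler contact store, detected by extension."""
    p = Path(path)
    if not p.exists():
        raise FeatureIOError(f"no such contact file: {path}")
    if p.suffix.lower() in (".cool", ".mcool"):
        return CoolerContacts(p, balance=balance)
    return TextContactStore(p)
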