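"""Seeded synthetic genomes, region sets, tracks and contact stores.

Everything downstream — pileups, embeddings, enrichment — is testable on
data generated here, with planted structure whose recovery is the test:

* coverage tracks carry Gaussian-shaped signal bumps at the anchors of
  "responsive" region subtypes over Gaussian background noise (clamped at
  zero), emulating ChIP-seq read density at bound sites;
* contact matrices follow a power-law distance decay ``C·(d+1)^(-α)`` with
  multiplicative stripe rows/columns emanating from responsive anchors and
  depletion of contacts crossing them (insulation), Poisson-sampled and
  symmetric — the signatures of loop-extrusion anchors and domain
  boundaries in Hi-C;
* feature region sets include the universe bins containing region anchors
  with probability ``p_center`` and every other universe bin with
  probability ``p_background``, planting a positional enrichment with
  closed-form expected odds ratio
  ``(p_center/(1-p_center)) / (p_background/(1-p_background))``.

Each region receives a hidden subtype label ("active"/"repressed" analogue)
drawn from the configured mixture; labels go to a sidecar TSV, never into
the BED name column, so recovery tests cannot leak them.  All generators
are pure functions of (config, seed): same seed, byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import BinUniverse
from .regions import INTERVAL, POINT, GenomeAssembly, RegionSet, write_bed


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generators."""

    seed: int = 0
    chrom_sizes: tuple[tuple[str, int], ...] = (("chr1", 1_000_000), ("chr2", 1_000_000))
    n_regions: int = 500
    min_spacing: int = 2_500  # equals contact_binsize: anchors sit on the bin grid
    # 1D track
    peak_amplitude: float = 6.0
    peak_width: int = 2_000          # Gaussian std of the planted bump, bp
    noise_scale: float = 1.0
    track_step: int = 200            # bp resolution of the emitted track
    # 2D contacts
    decay_exponent: float = 1.0
    contact_scale: float = 50.0      # expected counts at distance 0
    stripe_strength: float = 1.0     # multiplicative, 0 disables
    insulation_strength: float = 2.0  # multiplicative depletion, 0 disables
    stripe_extent: int = 100_000     # bp reach of a stripe from its anchor
    contact_binsize: int = 2_500
    # planted enrichment
    p_center: float = 0.8
    p_background: float = 0.05
    # region subtypes
    mixture_fractions: tuple[float, ...] = (0.5, 0.5)
    interval_length_range: tuple[int, int] = (5_000, 50_000)

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise SynthError("at least one chromosome required")
        for _, length in self.chrom_sizes:
            if length <= 0:
                raise SynthError("chromosome lengths must be positive")
        for p in (self.p_center, self.p_background, *self.mixture_fractions):
            if not 0 <= p <= 1:
                raise SynthError("probabilities must be in [0, 1]")
        if abs(sum(self.mixture_fractions) - 1) > 1e-9:
            raise SynthError("mixture fractions must sum to 1")
        if self.n_regions < 1:
            raise SynthError("n_regions must be >= 1")


def synth_genome(cfg: SynthConfig, out_dir: str | Path | None = None
                 ) -> tuple[GenomeAssembly, Path | None]:
    """Toy assembly (default two 1-Mb chromosomes) + optional chrom.sizes file."""
    assembly = GenomeAssembly(name="synth", chrom_sizes=dict(cfg.chrom_sizes))
    path = None
    if out_dir is not None:
        path = Path(out_dir) / "synth.chrom.sizes"
        with open(path, "w") as fh:
            for chrom, length in cfg.chrom_sizes:
                fh.write(f"{chrom}\t{length}\n")
    return assembly, path


def synth_regions(
    cfg: SynthConfig,
    assembly: GenomeAssembly,
    kind: str = POINT,
    out_dir: str | Path | None = None,
) -> tuple[RegionSet, np.ndarray]:
    """Region set with anchors at least ``min_spacing`` apart + hidden labels.

    Anchors are drawn without replacement from a spacing-grid per
    chromosome (count proportional to length), guaranteeing the minimum
    spacing exactly.  Returns (regions, subtype labels); when ``out_dir``
    is given, writes ``<kind>_regions.bed`` and a ``.labels.tsv`` sidecar.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = np.array([l for _, l in cfg.chrom_sizes], dtype=float)
    margin = max(cfg.min_spacing, cfg.interval_length_range[1] if kind == INTERVAL else 0)
    counts = np.floor(cfg.n_regions * lengths / lengths.sum()).astype(int)
    counts[: cfg.n_regions - counts.sum()] += 1
    rows = []
    for (chrom, length), n_c in zip(cfg.chrom_sizes, counts):
        grid = np.arange(margin, length - margin, cfg.min_spacing)
        if len(grid) < n_c:
            raise SynthError(f"{chrom}: genome too small for {n_c} regions "
                             f"with spacing {cfg.min_spacing}")
        anchors = np.sort(rng.choice(grid, size=n_c, replace=False))
        if kind == POINT:
            for a in anchors:
                rows.append((chrom, int(a) - 1, int(a) + 1))
        else:
            lo, hi = cfg.interval_length_range
            ln = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_c)).astype(int)
            for a, L in zip(anchors, ln):
                start = max(int(a) - L // 2, 0)
                end = min(start + int(L), length)
                rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"r{i}" for i in range(len(df))]
    df["strand"] = "."
    regions = RegionSet(kind=kind, records=df, assembly=assembly, name=f"synth_{kind}")
    labels = rng.choice(len(cfg.mixture_fractions), size=len(df),
                        p=np.asarray(cfg.mixture_fractions))
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_bed(regions, out_dir / f"{kind}_regions.bed")
        pd.DataFrame({"region_id": df.index, "subtype": labels}).to_csv(
            out_dir / f"{kind}_regions.labels.tsv", sep="\t", index=False)
    return regions, labels


def synth_track(
    cfg: SynthConfig,
    assembly: GenomeAssembly,
    regions: RegionSet,
    labels: np.ndarray,
    subtype_effects: tuple[float, ...] | None = None,
    out_path: str | Path | None = None,
    write_bigwig: bool = False,
) -> Path | None:
    """Coverage track: clamped Gaussian noise + planted bumps at anchors.

    ``subtype_effects[s]`` scales the bump amplitude for regions of subtype
    ``s`` (default: full amplitude for subtype 0, none for the others).
    Written as the text dialect at ``track_step`` resolution; optionally
    also as bigWig (same values) when pyBigWig is importable.
    """
    if subtype_effects is None:
        subtype_effects = tuple(1.0 if s == 0 else 0.0
                                for s in range(len(cfg.mixture_fractions)))
    rng = np.random.default_rng(cfg.seed + 1)
    step = cfg.track_step
    anchors = regions.anchors
    chroms = regions.records["chrom"].to_numpy()
    per_chrom_values: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chrom_sizes:
        n = -(-length // step)
        centers = (np.arange(n) + 0.5) * step
        vals = rng.normal(0.0, cfg.noise_scale, size=n)
        sel = chroms == chrom
        for a, lab in zip(anchors[sel], np.asarray(labels)[sel]):
            amp = cfg.peak_amplitude * subtype_effects[int(lab)]
            if amp == 0:
                continue
            near = np.abs(centers - a) < 5 * cfg.peak_width
            vals[near] += amp * np.exp(-((centers[near] - a) ** 2)
                                       / (2.0 * cfg.peak_width ** 2))
        per_chrom_values[chrom] = np.maximum(vals, 0.0)
    if out_path is None:
        return None
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for chrom, length in cfg.chrom_sizes:
            vals = per_chrom_values[chrom]
            for i, v in enumerate(vals):
                if v == 0.0:
                    continue
                s = i * step
                e = min(s + step, length)
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
    if write_bigwig:
        _write_bigwig(out_path.with_suffix(".bw"), cfg, per_chrom_values, step)
    return out_path


def _write_bigwig(path: Path, cfg: SynthConfig,
                  per_chrom_values: dict[str, np.ndarray], step: int) -> None:
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    bw.addHeader(list(cfg.chrom_sizes))
    for chrom, length in cfg.chrom_sizes:
        vals = per_chrom_values[chrom]
        starts = np.arange(len(vals)) * step
        ends = np.minimum(starts + step, length)
        keep = vals != 0.0
        if np.any(keep):
            bw.addEntries([chrom] * int(keep.sum()),
                          starts[keep].tolist(),
                          ends=ends[keep].tolist(),
                          values=[float(f"{v:.6g}") for v in vals[keep]])  # match text dialect
    bw.close()


def synth_contacts(
    cfg: SynthConfig,
    assembly: GenomeAssembly,
    regions: RegionSet,
    labels: np.ndarray,
    subtype_effects: tuple[float, ...] | None = None,
    out_path: str | Path | None = None,
) -> Path | None:
    """Contact store: distance decay × stripes × insulation, Poisson noise.

    Expected counts between bins i, j on one chromosome:

        E[i,j] = contact_scale · (|i−j| + 1)^(−α)    (bin distance)
                 · Π_anchors stripe(i,j) · insulation(i,j)

    where for each responsive anchor, stripe(i,j) multiplies by
    ``1 + stripe_strength`` when exactly one of i, j is the anchor bin and
    the other lies within ``stripe_extent``, and insulation(i,j) divides by
    ``1 + insulation_strength`` when i and j fall on opposite sides of the
    anchor within ``stripe_extent``.  The upper triangle is Poisson-sampled
    and mirrored, so the store is symmetric by construction.
    """
    if subtype_effects is None:
        subtype_effects = tuple(1.0 if s == 0 else 0.0
                                for s in range(len(cfg.mixture_fractions)))
    rng = np.random.default_rng(cfg.seed + 2)
    bs = cfg.contact_binsize
    anchors = regions.anchors
    chroms = regions.records["chrom"].to_numpy()
    if out_path is None:
        return None
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write(f"#binsize\t{bs}\n")
        for chrom, length in cfg.chrom_sizes:
            fh.write(f"#chrom\t{chrom}\t{length}\n")
        offset = 0
        for chrom, length in cfg.chrom_sizes:
            n = -(-length // bs)
            d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))  # bin distance
            expected = cfg.contact_scale * np.power(d + 1.0, -cfg.decay_exponent)
            sel = chroms == chrom
            reach = max(cfg.stripe_extent // bs, 1)
            for a, lab in zip(anchors[sel], np.asarray(labels)[sel]):
                eff = subtype_effects[int(lab)]
                if eff == 0:
                    continue
                ab = int(a // bs)
                lo, hi = max(ab - reach, 0), min(ab + reach + 1, n)
                if cfg.stripe_strength > 0:
                    boost = 1.0 + cfg.stripe_strength * eff
                    expected[ab, lo:hi] *= boost
                    expected[lo:hi, ab] *= boost
                    expected[ab, ab] /= boost  # diagonal boosted once, not twice
                if cfg.insulation_strength > 0:
                    damp = 1.0 + cfg.insulation_strength * eff
                    expected[lo:ab, ab + 1:hi] /= damp
                    expected[ab + 1:hi, lo:ab] /= damp
            iu = np.triu_indices(n)
            counts = rng.poisson(expected[iu])
            nz = counts > 0
            for i, j, v in zip(iu[0][nz], iu[1][nz], counts[nz]):
                fh.write(f"{offset + i}\t{offset + j}\t{v}\n")
            offset += n
    return out_path


def synth_feature_sets(
    cfg: SynthConfig,
    regions: RegionSet,
    universe: BinUniverse,
    n_sets: int = 1,
    out_dir: str | Path | None = None,
) -> list[RegionSet]:
    """Feature region sets with planted positional enrichment at anchors.

    Universe bins containing a region anchor are included with probability
    ``p_center``; every other universe bin with ``p_background``.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    bs = universe.binsize
    anchor_bins: set[tuple[str, int]] = set()
    for (_, row), a in zip(regions.records.iterrows(), regions.anchors):
        anchor_bins.add((row.chrom, int(a // bs)))
    out = []
    for si in range(n_sets):
        rows = []
        for chrom, length in universe.assembly.chrom_sizes.items():
            nb = universe.n_bins[chrom]
            p = np.where([(chrom, b) in anchor_bins for b in range(nb)],
                         cfg.p_center, cfg.p_background)
            include = rng.random(nb) < p
            for b in np.flatnonzero(include):
                rows.append((chrom, int(b * bs), int(min((b + 1) * bs, length))))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        fs = RegionSet(kind=POINT, records=df, assembly=universe.assembly,
                       name=f"feature_{si}")
        if out_dir is not None:
            write_bed(fs, Path(out_dir) / f"feature_{si}.bed")
        out.append(fs)
    return out
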