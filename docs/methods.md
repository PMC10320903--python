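# Methods

This note records the models, parameter choices and numerical conventions
behind `regionstack`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinate and binning model

All genomic coordinates are 0-based half-open, at every interface,
including the text dialects. The anchor of a point region is the floor
midpoint `⌊(start+end)/2⌋`; for a window of half-width `w` and bin width
`b` (with `b | 2w` validated), the anchor falls exactly on the boundary
between bins `n/2−1` and `n/2`, so "the center" of an even-length profile
is the shared edge of the two central bins, and a symmetric planted signal
peaks equally in both.

Interval regions are binned proportionally: window
`[s − fL, e + fL)` for flank fraction `f` (default 0.2) and bin width
`p·L`, giving `round((1+2f)/p)` bins for every region. Bin edges are kept
real-valued in the frame and materialized to integer basepairs only at
extraction time, by rounding half-up; this avoids cumulative drift across
bins (rounding each width independently would let errors accumulate over
long intervals). Where rounding would produce an empty bin (interval
shorter than `1/p` bp) the bin is clamped to 1 bp and a warning is issued.

A bin is out-of-bounds when any of its basepairs lies outside
`[0, chromosome length)`; such bins are flagged in the frame and their
extracted values are NaN. Frames are never dropped: the frame list always
has one entry per region, aligned by region id.

Default resolution stacks: point `w ∈ {50 kb, 200 kb, 1 Mb}` with
`b = w/25` (40 bins), interval `p ∈ {0.05, 0.1}` with `f = 0.2`. These are
package defaults for interactive use; every pipeline takes explicit
parameters.

## 1D signal semantics

The value of a bin is the mean over its basepairs, where basepairs not
covered by any interval count as 0 (coverage semantics: a read-density
track is zero where no reads fall, not missing) and basepairs outside the
chromosome make a fully-outside bin NaN. A partially out-of-bounds query
bin averages over its in-bounds part only; the stricter any-bp-outside NaN
rule is applied at the frame level during extraction. Both track backends
(text dialect, bigWig) integrate the step function exactly via cumulative
sums, so splitting a query range and length-weighted averaging reproduces
the single-query value to rounding error. Strand is carried through but
frames are never auto-flipped; `extract_1d(flip_minus_strand=True)` is the
explicit opt-in, reversing rows of minus-strand records.

## 2D extraction

The contact store answers `(chrom, start, end, binsize)` with a square
matrix on the native bin grid anchored at coordinate 0. Frames whose bin
width equals a stored binsize are served by a direct slice with the frame
start snapped to the nearest grid bin (a sub-half-bin shift at most — point
anchors are arbitrary coordinates, the grid is not). Variable-width frames
(interval regions) are served by querying the nearest finer native binsize
and block-averaging native bins onto frame bins by bin-midpoint
assignment. Contact values are used as stored; no matrix balancing is
performed (the cooler backend can read a stored weight column on request).
Off-chromosome rows and columns are NaN; the NaN block is always square
because row and column masks coincide.

The `.cool/.mcool` backend is optional (guarded import); the plain-text
dialect is the canonical, dependency-free store and is what the test suite
exercises.

## Aggregation and stacking

All reductions are NaN-ignoring means per bin (1D) or per pixel (2D); a
cell that is NaN in every region stays NaN, and a per-cell valid-count
matrix is available (`SnippetStack.valid_counts`) for transparency.
Aggregation is invariant to row order by construction.

Stacked line profiles subsample uniformly without replacement, with a
mandatory seed, down to `max_rows` (default 1000) *before* ordering, so
the retained set is independent of the sort key. The returned sort order
names region ids, not row positions, which is what makes coupled sorting
across widgets well-defined: applying the order to another stack of the
same region set reorders it identically. Sort keys: NaN-ignoring row mean
or the value of bin `n/2`; all-NaN rows sort last; ties are broken by
region id (stable).

## Embedding features

1D mode: entry `(i, j)` is the NaN-ignoring mean of track `j` over region
`i`'s full frame — one scalar per region per feature, matching
`extract_1d` followed by a row mean exactly (tested as a composition
oracle).

2D mode: each snippet of side `m` is smoothed with a Gaussian kernel and
down-sampled to `f × f` (default 10, hence 100 pixel features). The
smoothing geometry derives from the interpolation factor:

    I = ⌊m/f⌋,  K = ⌊(I+1)/2⌋,  σ = 4K + 1

Note `σ` is large relative to the K-tap truncation window, so the kernel
is close to a K-point moving average; the relation is implemented exactly
as written, with the reference test pinned to the same definition. The
kernel is a separable K-tap truncated Gaussian, normalized to unit sum
(constants are preserved exactly up to float rounding), applied with
reflect padding; for even K the window is centered as well as a discrete
even-length window can be. Down-sampling is a block mean over near-equal
blocks (`⌊linspace⌋` edges); snippets smaller than the target are
up-sampled by nearest-pixel mapping without smoothing. NaN cells are
imputed as 0 before smoothing; snippets more than 50 % NaN are excluded
and reported.

UMAP runs with library defaults apart from the seeded random state (which
forces single-threaded, reproducible layout). K-means (seeded, `n_init=10`)
runs on the original high-dimensional feature rows, not the 2D
coordinates: cluster membership should reflect full feature-space
similarity, with the embedding only a display device. Features are not
standardized by default; `standardize=True` is available but off, since
mean-signal features share units and pixel features share one intensity
scale. Cluster summaries are arithmetic means of member rows in the
original space; normalized intensities are per-feature min–max across
clusters, with constant features mapped to 0.5 by convention.

## Enrichment model

The universe is every genome-wide bin of the chosen size, tiled from
coordinate 0 per chromosome with the last partial bin included
(`Σ ceil(length/binsize)` bins). The overlap predicate is ≥ 1 bp, for both
"bin is a target" (after snapping target intervals onto universe bins) and
"bin overlaps the query" — the simplest reproducible choice and the common
default for locus-overlap analysis. Contingency cells are counted over the
whole universe, so they always sum to the universe size. The
Haldane–Anscombe correction (add 0.5 to every cell when any is zero) is on
by default so per-bin rankings stay finite; `correction="none"` gives the
raw ratio with NaN on zero denominators. Degenerate cases: an empty query
yields NaN; a relative bin with no in-bounds targets yields NaN and the
dropped-target count is reported. No p-values are computed: the statistic
of interest is the odds ratio, and rankings are by odds ratio with ties
broken by feature name.

## Synthetic data: what it emulates

The generators plant known structure so every downstream statistic has a
ground truth:

* **Tracks** — Gaussian-shaped bumps (amplitude 6, sd 2 kb by default)
  at the anchors of responsive subtypes over N(0, 1) background noise,
  clamped at 0, emitted as a 200 bp step function. This emulates ChIP-seq
  read density at bound sites.
* **Contacts** — expected counts `C·(d+1)^(−α)` in bin distance `d`
  (α = 1, C = 50 at 2.5 kb bins), modulated per responsive anchor by a
  multiplicative stripe along the anchor's row/column (reach 100 kb) and
  by depletion of contacts crossing the anchor (insulation), then
  Poisson-sampled on the upper triangle and mirrored. This emulates
  stripes emanating from loop-extrusion anchors and domain-boundary
  insulation.
* **Feature sets** — universe bins containing a region anchor included
  with probability `p_center`, all others with `p_background`, so the
  anchor-bin odds ratio has the closed form
  `(p_center/(1−p_center))/(p_background/(1−p_background))` (= 76 at the
  defaults 0.8/0.05).

Anchors are drawn without replacement from a spacing grid (default
2.5 kb, equal to the default contact binsize, so anchors sit on the bin
grid and planted enrichment lands on exactly one universe bin per region).
Subtype labels live in a sidecar TSV, not in the BED, so recovery tests
cannot leak them. All generators are pure functions of (config, seed).

**Experiment geometry.** Two recovery experiments use non-default
geometry, chosen from the planted-signal footprint rather than tuned:
subtype-recovery embedding uses 20 kb anchor spacing on a 2 × 6 Mb genome,
so a region's ±10 kb feature window cannot contain a neighbour's bump
(at the default 2.5 kb spacing, windows overlap many neighbours and
subtype profiles mix); the insulation experiment uses 100 anchors at 50 kb
spacing on 2 × 5 Mb with stripes disabled, so each ±50 kb snippet contains
a single planted boundary. The null enrichment experiment (equal
probabilities everywhere) is sized by a power calculation: for the per-bin
odds ratio to concentrate within ±25 % of 1, the Woolf variance
`1/a+1/b+1/c+1/d` must be ≲ (0.223/3)², which at a dense p = 0.5 design
requires ≈ 2000 target bins and a comparable number of background bins —
hence n = 2000 regions on a 2 × 5 Mb genome. The planted-enrichment
comparison to the closed form uses the Woolf standard error of the log
odds ratio at 3σ.

**What passing tests do not show.** The generators produce idealized data:
isolated Gaussian bumps (real peaks have mixed shapes and widths),
homogeneous power-law decay (real Hi-C has chromatin-compartment structure
and coverage biases — no balancing is emulated), independent per-bin
feature inclusion (real annotations cluster), and exactly two region
subtypes. Recovery of planted structure validates the arithmetic and the
pipelines, not biological discovery performance on real data.

## Insulation contrast

The planted-insulation check compares within-quadrant and cross-quadrant
pixels of the average map. Raw quadrant means are confounded by distance
decay — cross-quadrant pixel pairs are on average farther apart — so the
statistic (`pileup.insulation_contrast`) groups pixel pairs by diagonal
distance `|i−j|`, takes the within-minus-cross difference at each
distance, and averages over distances. Under no planted structure its
expectation is 0; planted boundary depletion makes it positive.

## Numerical choices and degenerate inputs

* NaN encodes both "off chromosome" and "missing data"; 0 encodes "no
  signal" in coverage tracks and "no observed contacts" in count matrices.
* Ties in sorting and ranking are always broken by a stable, documented
  key (region id, feature name) so outputs are deterministic.
* Empty stacks, empty config lists, empty cluster choices and k outside
  `[2, n−1]` raise typed errors; an empty cluster in a chosen subset
  warns instead of failing.
* Every stochastic step (subsampling, UMAP, k-means, all generators)
  takes an explicit seed; CLI manifests echo all parameters and seeds, and
  re-running a manifest reproduces outputs byte-identically.

## Problem sizes in the validation suite

The test and validation experiments use toy genomes of 2–12 Mb, 100–2000
regions, 100-trial oracle sweeps on ≤ 200-bin universes, and n = 500
regions with k = 10 for the embedding recovery — sizes at which brute-force
oracles (per-basepair averaging, exhaustive per-bin membership
enumeration) are exact and fast, and the whole suite completes in well
under a minute apart from the UMAP fits.
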