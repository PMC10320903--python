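# regionstack

Multi-resolution analysis of genomic region sets: signal pileups around
point and interval regions, stacked line-profile heatmaps, UMAP/k-means
embedding of regions by their feature content, and per-bin locus-overlap
(LOLA-style) odds-ratio enrichment — as a headless Python library plus a
thin command-line interface, fully testable on seeded synthetic data.

## Who this is for

Epigenomics and 3D-genome researchers who work with *region sets* — all
TSSs, all ChIP-seq peaks of a factor, all TAD boundaries — and want to ask,
without a genome browser session per locus:

* What does a 1D signal (ChIP-seq coverage, ATAC, GC) look like on average
  around these regions, at several length scales?
* What does the average Hi-C contact map look like around them (loops,
  stripes, insulation)?
* Do the regions fall into subgroups with distinct feature profiles?
* Which other region sets overlap mine, and *where* along my regions —
  center, flank, or a specific offset?

## The core computations

**Resolution stacks.** A *point region* is reduced to its anchor
`c = ⌊(start+end)/2⌋` and binned over `[c−w, c+w)` in `2w/b` bins of width
`b`. An *interval region* of length `L` keeps its own scale: the window is
the interval plus a 20 % flank on either side, `[s − 0.2L, e + 0.2L)`, cut
into `round((1 + 2·0.2)/p)` bins of width `p·L`, so every region yields the
same bin count regardless of length. Computing frames for a set of `(w, b)`
or `p` choices gives the multi-scale "resolution stack" of a region set.
All coordinates are 0-based half-open (BED-native).

**Pileups.** For each region the binned signal snippet (1D vector or 2D
contact sub-matrix) is extracted; out-of-bounds bins are NaN and every
reduction is a NaN-ignoring mean, per bin or per pixel. Stacked line
profiles render one row per region (subsampled to at most 1000 rows,
seeded), and sort orders are explicit values that can be shared between
stacks for coupled sorting.

**Embedding.** 1D mode summarizes each region by its mean signal per track
(an *n* × *m* matrix); 2D mode Gaussian-smooths each contact snippet and
down-samples it to 10 × 10 = 100 pixel features, with kernel size
`K = ⌊(I+1)/2⌋` and standard deviation `σ = 4K+1` derived from the
interpolation factor `I = ⌊m/10⌋`. UMAP (seeded, library defaults) gives 2D
display coordinates; k-means runs on the original high-dimensional rows.

**Enrichment.** For each relative bin of the region set, that bin across
all regions is the *target*, a candidate feature set is the *query*, and
all genome-wide bins of the same size are the *universe*. With

```
a = target bins overlapping the query      b = non-target bins overlapping
c = target bins not overlapping            d = non-target bins not overlapping
```

the reported statistic is the odds ratio `(a·d)/(b·c)` (Haldane–Anscombe
+0.5 correction when a cell is zero). Scanning bins yields a positional
enrichment profile per feature set.

## File formats

* Region sets: BED3/BED6 (tab-separated, 0-based half-open; `#`, `track`,
  `browser` lines ignored). Chromosome sizes: two-column text.
* 1D tracks: bigWig, or a bedGraph-like text dialect —
  `chrom<TAB>start<TAB>end<TAB>value`, non-overlapping intervals; absent
  intervals count as signal 0.
* 2D contacts: cooler (optional), or a text dialect —
  a `#binsize<TAB><bp>` header, one `#chrom<TAB>name<TAB>length` line per
  chromosome, then `bin_i<TAB>bin_j<TAB>value` triplets with global bin
  indices (each unordered pair once; symmetrized on load).

## Worked example

Generate a synthetic dataset with planted structure, then average a
coverage track around the regions:

```bash
regionstack synth --out-dir demo --seed 11 --n-regions 200
regionstack aggregate1d --regions demo/point_regions.bed \
    --chrom-sizes demo/synth.chrom.sizes --track demo/track.bedgraph.txt \
    --window 10000 --binsize 1000 --out-dir demo/agg
cat demo/agg/profile.tsv
```

```
0	1	2	...	8	9	10	11	...	19
1.6619947	1.6694946	1.7076983	...	3.540556	4.1390613	4.0992061	3.5987324	...	1.8247215
```

The profile is flat background (≈1.7) away from the regions and peaks at
the two central bins (≈4.1) — the planted coverage bump at the region
anchors, recovered by the pileup. Roughly half the regions carry the bump
(the generator plants two region subtypes), so the peak height is about
half the planted amplitude above background.

Per-bin enrichment of a planted feature set against the same regions:

```bash
regionstack lola --regions demo/point_regions.bed \
    --chrom-sizes demo/synth.chrom.sizes --features demo/feature_0.bed \
    --window 12500 --binsize 2500 --out-dir demo/lola
cat demo/lola/odds_ratios.tsv
```

```
	0	1	2	3	4	5	6	7	8	9
feature_0	1.3980567	0.71966957	0.93671679	0.96363554	0.64605946	68.727273	1.0275938	0.99092559	0.90222576	0.69076892
```

The feature set was generated to include the universe bin containing each
region anchor with probability 0.8 and any other bin with probability 0.05,
so the closed-form expected odds ratio at the anchor bin is
`(0.8/0.2)/(0.05/0.95) = 76`; the measured 68.7 at the central bin (with
all flank bins near 1) recovers it within counting noise.

Other subcommands: `aggregate2d` (average contact map), `stack` (stacked
line profiles), `embed1d`/`embed2d` (UMAP + k-means), each writing TSV
outputs plus a JSON run manifest; re-running any subcommand with the same
arguments and seed reproduces its outputs byte-identically.

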