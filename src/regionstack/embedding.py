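"""Per-region feature representations, UMAP embedding and k-means grouping.

Two feature modes mirror the two feature dimensionalities:

* 1D mode — each region is summarized by its mean signal per track, giving
  an n-regions × m-tracks matrix.
* 2D mode — each contact snippet is Gaussian-smoothed, down-sampled to an
  f × f image (f = 10 by default) and flattened, giving f² pixel features
  per region.  Smoothing parameters derive from the interpolation factor
  I = ⌊m/f⌋: kernel size K = ⌊(I+1)/2⌋, standard deviation σ = 4K + 1,
  applied as a K-tap truncated-Gaussian separable kernel with reflect
  padding.  Since σ ≫ K, the kernel is close to a K-point moving average;
  it is implemented literally as specified.

The feature matrix is embedded with UMAP (library defaults, seeded) for
display, while k-means runs on the original high-dimensional rows — cluster
membership reflects full feature-space similarity, not the 2D projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .featureio import SignalTrack1D
from .pileup import SnippetStack, aggregate_1d, extract_1d
from .regions import RegionSet, ResolutionConfig, frames_for


class EmbeddingError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """n-regions × m-features value matrix with labels and region ids."""

    values: np.ndarray
    region_ids: np.ndarray
    feature_labels: list[str]
    excluded_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.region_ids = np.asarray(self.region_ids, dtype=np.int64)
        if self.values.shape[0] != len(self.region_ids):
            raise EmbeddingError("row count must equal region count")
        if self.values.shape[1] != len(self.feature_labels):
            raise EmbeddingError("column count must equal number of feature labels")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SmoothingParams:
    """Gaussian-smoothing geometry for one snippet of side m."""

    m: int
    f: int
    interpolation_factor: int  # I = floor(m / f)
    kernel_size: int           # K = floor((I + 1) / 2)
    sigma: float               # 4K + 1

    @property
    def smooths(self) -> bool:
        return self.interpolation_factor >= 1 and self.kernel_size >= 1 and self.m > self.f


def smoothing_params(m: int, f: int = 10) -> SmoothingParams:
    """Derive (I, K, σ) from snippet side m and target side f."""
    if m < 1 or f < 1:
        raise EmbeddingError("m and f must be >= 1")
    I = m // f
    K = (I + 1) // 2
    return SmoothingParams(m=m, f=f, interpolation_factor=I, kernel_size=K,
                           sigma=float(4 * K + 1))


def _gauss_kernel(K: int, sigma: float) -> np.ndarray:
    x = np.arange(K, dtype=float) - (K - 1) / 2.0
    w = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return w / w.sum()


def _smooth2d(img: np.ndarray, K: int, sigma: float) -> np.ndarray:
    if K <= 1:
        return img
    k = _gauss_kernel(K, sigma)
    out = ndimage.correlate1d(img, k, axis=0, mode="reflect")
    return ndimage.correlate1d(out, k, axis=1, mode="reflect")


def _resample(img: np.ndarray, f: int) -> np.ndarray:
    """Resample a square image to f × f.

    Downsampling is a block mean over near-equal blocks; upsampling (m < f)
    maps each target pixel to its nearest source pixel.
    """
    m = img.shape[0]
    if m == f:
        return img
    if m < f:
        idx = np.floor((np.arange(f) + 0.5) * m / f).astype(int)
        return img[np.ix_(idx, idx)]
    edges = np.floor(np.linspace(0, m, f + 1)).astype(int)
    out = np.empty((f, f))
    for a in range(f):
        rows = img[edges[a]:edges[a + 1]]
        for b in range(f):
            out[a, b] = rows[:, edges[b]:edges[b + 1]].mean()
    return out


def pixel_features_2d(stack: SnippetStack, f: int = 10,
                      max_nan_fraction: float = 0.5) -> FeatureMatrix:
    """Smoothed, down-sampled, flattened pixel features for 2D snippets.

    NaN cells are imputed as 0 before smoothing; snippets with more than
    ``max_nan_fraction`` NaN cells are excluded and reported via
    ``excluded_ids``.  Constant snippets map to constant feature rows
    (the normalized kernel and block mean both preserve constants).
    """
    if stack.ndim != 2:
        raise EmbeddingError("pixel_features_2d requires a 2D stack")
    rows, ids, excluded = [], [], []
    for i in range(stack.n_regions):
        snip = stack.values[i]
        nan_frac = float(np.isnan(snip).mean())
        if nan_frac > max_nan_fraction:
            excluded.append(int(stack.region_ids[i]))
            continue
        img = np.nan_to_num(snip, nan=0.0)
        p = smoothing_params(img.shape[0], f)
        if p.smooths:
            img = _smooth2d(img, p.kernel_size, p.sigma)
        rows.append(_resample(img, f).ravel())
        ids.append(int(stack.region_ids[i]))
    labels = [f"px_{a}_{b}" for a in range(f) for b in range(f)]
    values = np.array(rows) if rows else np.empty((0, f * f))
    return FeatureMatrix(values=values, region_ids=np.array(ids, dtype=np.int64),
                         feature_labels=labels,
                         excluded_ids=np.array(excluded, dtype=np.int64))


def feature_matrix_1d(
    regions: RegionSet,
    tracks: list[SignalTrack1D],
    cfg: ResolutionConfig,
) -> FeatureMatrix:
    """Mean signal per (region, track): the 1D high-dimensional representation."""
    if not tracks:
        raise EmbeddingError("at least one track required")
    frames = frames_for(regions, cfg)
    cols = []
    for track in tracks:
        stack = extract_1d(track, frames)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col = np.nanmean(stack.values, axis=1)
        if np.all(np.isnan(col)):
            raise EmbeddingError(f"track {track.name!r} has no signal over any region")
        cols.append(col)
    return FeatureMatrix(values=np.column_stack(cols),
                         region_ids=np.asarray(regions.records.index, dtype=np.int64),
                         feature_labels=[t.name for t in tracks])


@dataclass
class EmbeddingResult:
    """2D coordinates, cluster labels and per-cluster summaries."""

    coords: np.ndarray
    labels: np.ndarray
    region_ids: np.ndarray
    cluster_summaries: np.ndarray          # k × m mean feature vector per cluster
    intensity_raw: pd.DataFrame            # clusters × features, mean values
    intensity_normalized: pd.DataFrame     # per-feature min-max across clusters
    seed: int
    excluded_ids: np.ndarray


def cluster_intensity(fm: FeatureMatrix, labels: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster mean feature table, raw and min-max normalized.

    Normalization is per feature across clusters; a feature constant across
    clusters maps to 0.5 by convention.
    """
    labels = np.asarray(labels)
    if len(labels) != fm.n:
        raise EmbeddingError("labels length must equal region count")
    df = pd.DataFrame(fm.values, columns=fm.feature_labels)
    raw = df.groupby(labels).mean()
    raw.index.name = "cluster"
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    span = hi - lo
    norm = (raw - lo) / span.replace(0, np.nan)
    norm = norm.fillna(0.5)
    return raw, norm


def embed_and_cluster(fm: FeatureMatrix, k: int = 10, seed: int = 0,
                      standardize: bool = False) -> EmbeddingResult:
    """UMAP-embed and k-means-cluster a feature matrix, fully seeded.

    Rows with non-finite values are dropped (and reported) first.  UMAP runs
    with library defaults apart from the random state; k-means runs on the
    original high-dimensional rows, not the 2D coordinates.
    """
    finite = np.all(np.isfinite(fm.values), axis=1)
    values = fm.values[finite]
    ids = fm.region_ids[finite]
    excluded = fm.region_ids[~finite]
    n = values.shape[0]
    if not 2 <= k <= n - 1:
        raise EmbeddingError(f"k must be in [2, n-1]; got k={k}, n={n}")

    X = values
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        X = (X - mu) / np.where(sd == 0, 1.0, sd)

    import umap
    from sklearn.cluster import KMeans

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, random_state=int(seed))
        coords = np.asarray(reducer.fit_transform(X), dtype=float)
    km = KMeans(n_clusters=k, random_state=int(seed), n_init=10)
    labels = km.fit_predict(X)

    summaries = np.vstack([values[labels == c].mean(axis=0) if np.any(labels == c)
                           else np.full(values.shape[1], np.nan)
                           for c in range(k)])
    sub = FeatureMatrix(values=values, region_ids=ids, feature_labels=fm.feature_labels)
    raw, norm = cluster_intensity(sub, labels)
    return EmbeddingResult(coords=coords, labels=labels, region_ids=ids,
                           cluster_summaries=summaries, intensity_raw=raw,
                           intensity_normalized=norm, seed=int(seed),
                           excluded_ids=excluded)


def subset_from_clusters(regions: RegionSet, labels: np.ndarray,
                         region_ids: np.ndarray, chosen: set[int],
                         name: str = "subset") -> RegionSet:
    """New RegionSet from the regions whose cluster label is in ``chosen``."""
    if not chosen:
        raise EmbeddingError("chosen cluster set is empty")
    labels = np.asarray(labels)
    region_ids = np.asarray(region_ids)
    present = set(np.unique(labels).tolist())
    for c in chosen:
        if c not in present:
            warnings.warn(f"cluster {c} has no members")
    keep = region_ids[np.isin(labels, list(chosen))]
    return regions.subset(keep, name=name)
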