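"""Distance-histogram clustering of latent means.

Clusters are extracted iteratively. A random point whose distance histogram
has a valley-to-peak ratio below 0.5 becomes a seed; all points closer than
bin_width x valley form a candidate cluster; a sample of the candidate
(10%, capped at 1000) is searched for the point with the smallest ratio,
and that anchor's valley radius defines the confident cluster, which is
removed from the active set. Low ratios mark points near the centre of a
dense cluster, so the valley radius adapts to each cluster's own extent
and clusters of vastly different sizes can be recovered.

Cosine distance d(a, b) = 1 - a.b / (|a||b|) is used throughout; the
histogram spans [0, 2] with bin width delta (default 0.005, i.e. 400 bins).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DELTA = 0.005
SEED_RATIO = 0.5
MIN_CLUSTER_SIZE = 5000
MAX_ITERATIONS = 1000
MAX_SEED_ATTEMPTS = 100
# Peak/valley detection runs on a moving-average-smoothed copy of the counts
# and requires the smoothed peak to average at least MIN_PEAK_MASS points per
# bin. Raw per-bin counts are Poisson; on datasets of a few thousand reads a
# single stray neighbour (counts [1, 0, ...]) would otherwise qualify any
# scatter point as a seed, and mid-cluster count wiggles would truncate
# extraction early. At the scale the method targets (1e5-1e7 reads per
# dataset) bin counts are large and smoothing leaves the detected extrema
# unchanged.
SMOOTH_WINDOW = 5
MIN_PEAK_MASS = 1.0


@dataclass
class DistanceHistogram:
    """Binned distances from one anchor to the other active points.

    ``counts`` holds the raw per-bin counts; ``peak``/``valley`` are detected
    on the smoothed counts (see :data:`SMOOTH_WINDOW`), on which ``ratio`` is
    also evaluated.
    """

    counts: np.ndarray
    anchor: int
    peak: Optional[int] = None
    valley: Optional[int] = None
    smoothed: Optional[np.ndarray] = None

    @property
    def ratio(self) -> Optional[float]:
        if self.peak is None or self.valley is None:
            return None
        ref = self.smoothed if self.smoothed is not None else self.counts
        return float(ref[self.valley]) / float(ref[self.peak])

    @property
    def defined(self) -> bool:
        return self.peak is not None and self.valley is not None


@dataclass
class ClusterResult:
    """Disjoint clusters plus the residual unclustered points."""

    clusters: list[np.ndarray]
    unclustered: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return sum(len(c) for c in self.clusters) + len(self.unclustered)


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cosine similarity; in [0, 2]. Errors on a zero vector."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - (a @ b) / (na * nb))


def _unit_rows(points: np.ndarray) -> np.ndarray:
    """Row-normalised copy; zero rows are nudged by 1e-12 in the first coordinate."""
    points = np.asarray(points, dtype=np.float64)
    norms = np.linalg.norm(points, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero latent vectors perturbed for cosine distance", int(zero.sum()))
        points = points.copy()
        points[zero, 0] = 1e-12
        norms = np.linalg.norm(points, axis=1)
    return points / norms[:, None]


def _n_bins(delta: float) -> int:
    return int(math.ceil(2.0 / delta))


def _bin_distances(d: np.ndarray, delta: float) -> np.ndarray:
    nb = _n_bins(delta)
    idx = np.clip(np.floor(d / delta).astype(np.int64), 0, nb - 1)
    return np.bincount(idx, minlength=nb)


def find_peak_valley(counts: np.ndarray) -> tuple[Optional[int], Optional[int]]:
    """First local maximal and the first local minimal after it.

    peak: smallest j with counts[j] > 0, counts[j] >= counts[j-1] (or j = 0)
    and counts[j] > counts[j+1] (past the end counts as 0). valley: smallest
    v > peak with counts[v] < counts[v-1] and counts[v] <= counts[v+1]
    (the array end counts as a minimal). Returns (None, None) when no such
    pair exists, e.g. for a monotone histogram.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty histogram")
    n = counts.size
    peak = None
    for j in range(n):
        if counts[j] <= 0:
            continue
        left_ok = j == 0 or counts[j] >= counts[j - 1]
        right = counts[j + 1] if j + 1 < n else 0
        if left_ok and counts[j] > right:
            peak = j
            break
    if peak is None:
        return None, None
    for v in range(peak + 1, n):
        if counts[v] < counts[v - 1] and (v + 1 >= n or counts[v] <= counts[v + 1]):
            return peak, v
    return None, None


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return counts.astype(np.float64)
    kernel = np.ones(window) / window
    return np.convolve(counts.astype(np.float64), kernel, mode="same")


def _detect_extrema(
    counts: np.ndarray, window: int = SMOOTH_WINDOW, min_peak_mass: float = MIN_PEAK_MASS
) -> tuple[Optional[int], Optional[int], np.ndarray]:
    """Peak/valley on the smoothed counts, requiring a minimally massive peak."""
    smoothed = _smooth(counts, window)
    peak, valley = find_peak_valley(smoothed)
    if peak is not None and smoothed[peak] < min_peak_mass:
        return None, None, smoothed
    return peak, valley, smoothed


def distance_histogram(
    anchor: int,
    points: np.ndarray,
    active: Sequence[int],
    delta: float = DELTA,
    unit: Optional[np.ndarray] = None,
    smooth_window: int = SMOOTH_WINDOW,
) -> DistanceHistogram:
    """Histogram of distances from ``anchor`` to every other active point."""
    active = np.asarray(active, dtype=np.int64)
    if len(active) < 2:
        raise ValueError("need at least 2 active points")
    if anchor not in active:
        raise ValueError("anchor must be in the active set")
    if unit is None:
        unit = _unit_rows(points)
    others = active[active != anchor]
    d = 1.0 - unit[others] @ unit[anchor]
    counts = _bin_distances(d, delta)
    peak, valley, smoothed = _detect_extrema(counts, smooth_window)
    return DistanceHistogram(counts=counts, anchor=int(anchor), peak=peak, valley=valley, smoothed=smoothed)


def select_seed(
    points: np.ndarray,
    active: np.ndarray,
    delta: float,
    rng: np.random.Generator,
    max_attempts: int = MAX_SEED_ATTEMPTS,
    seed_ratio: float = SEED_RATIO,
    unit: Optional[np.ndarray] = None,
) -> Optional[tuple[int, DistanceHistogram]]:
    """Draw random points until one qualifies as a seed (ratio < seed_ratio)."""
    if unit is None:
        unit = _unit_rows(points)
    for _ in range(max_attempts):
        cand = int(rng.choice(active))
        hist = distance_histogram(cand, points, active, delta, unit=unit)
        if hist.defined and hist.ratio < seed_ratio:
            return cand, hist
    return None


def candidate_cluster(
    seed_hist: DistanceHistogram,
    points: np.ndarray,
    active: np.ndarray,
    delta: float = DELTA,
    unit: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Active points within delta x valley of the seed, seed included."""
    if not seed_hist.defined:
        raise ValueError("seed histogram has no defined valley")
    if unit is None:
        unit = _unit_rows(points)
    radius = delta * seed_hist.valley
    d = 1.0 - unit[active] @ unit[seed_hist.anchor]
    members = active[d < radius]
    if seed_hist.anchor not in members:
        members = np.append(members, seed_hist.anchor)
    return np.sort(members)


def confident_cluster(
    candidate: np.ndarray,
    points: np.ndarray,
    active: np.ndarray,
    delta: float,
    rng: np.random.Generator,
    seed_index: Optional[int] = None,
    unit: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, int, Optional[int]]:
    """Refine a candidate cluster around its best-ratio sampled anchor.

    Samples min(max(1, ceil(0.1 * |candidate|)), 1000) candidate points
    (always including the seed when given), picks the one whose distance
    histogram has the minimum valley-to-peak ratio, and returns the active
    points within its valley radius together with the anchor index and the
    valley bin. Falls back to the candidate set itself if no sampled point
    has a defined peak/valley.
    """
    candidate = np.asarray(candidate, dtype=np.int64)
    if len(candidate) < 1:
        raise ValueError("empty candidate cluster")
    if unit is None:
        unit = _unit_rows(points)
    n_sample = min(max(1, math.ceil(0.10 * len(candidate))), 1000)
    sample = rng.choice(candidate, size=min(n_sample, len(candidate)), replace=False)
    if seed_index is not None and seed_index not in sample:
        sample = np.append(sample[:-1], seed_index) if len(sample) >= n_sample else np.append(sample, seed_index)

    best: Optional[DistanceHistogram] = None
    for p in sample:
        hist = distance_histogram(int(p), points, active, delta, unit=unit)
        if hist.defined and (best is None or hist.ratio < best.ratio):
            best = hist
    if best is None:
        logger.warning("no sampled point had a defined peak/valley; keeping candidate cluster as-is")
        return candidate, int(sample[0]), None
    radius = delta * best.valley
    d = 1.0 - unit[active] @ unit[best.anchor]
    cluster = active[d < radius]
    if best.anchor not in cluster:
        cluster = np.append(cluster, best.anchor)
    return np.sort(cluster), best.anchor, best.valley


def run_clustering(
    points: np.ndarray,
    delta: float = DELTA,
    seed_ratio: float = SEED_RATIO,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    max_iterations: int = MAX_ITERATIONS,
    rng_seed: int = 0,
    max_attempts: int = MAX_SEED_ATTEMPTS,
) -> ClusterResult:
    """Iteratively extract confident clusters from the latent means.

    Stops when fewer than ``min_cluster_size`` points remain active, after
    ``max_iterations`` extracted clusters, or when no seed point can be
    found. Clusters are disjoint and, with the unclustered residue,
    partition the input points.
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    if n < 1:
        raise ValueError("no points to cluster")
    unit = _unit_rows(points)
    rng = np.random.default_rng(rng_seed)
    active = np.arange(n, dtype=np.int64)
    clusters: list[np.ndarray] = []
    provenance: list[dict] = []

    while len(active) >= max(min_cluster_size, 2) and len(clusters) < max_iterations:
        found = select_seed(points, active, delta, rng, max_attempts=max_attempts, seed_ratio=seed_ratio, unit=unit)
        if found is None:
            break
        seed, seed_hist = found
        cand = candidate_cluster(seed_hist, points, active, delta, unit=unit)
        cluster, anchor, valley = confident_cluster(cand, points, active, delta, rng, seed_index=seed, unit=unit)
        clusters.append(cluster)
        provenance.append(
            {"seed": int(seed), "anchor": int(anchor), "valley": valley, "size": int(len(cluster))}
        )
        mask = np.isin(active, cluster, assume_unique=True, invert=True)
        active = active[mask]
        logger.debug("cluster %d: size %d (seed %d, anchor %d, valley %s)", len(clusters) - 1, len(cluster), seed, anchor, valley)

    logger.info("extracted %d clusters, %d points unclustered", len(clusters), len(active))
    return ClusterResult(clusters=clusters, unclustered=active, provenance=provenance)
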