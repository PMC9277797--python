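"""Maximum-likelihood assignment of unclustered reads to detected bins.

Each detected cluster gets a diagonal Gaussian profile (per-dimension mean
and standard deviation of its members' raw coverage and composition
vectors). An unclustered read goes to the bin maximising the product of the
coverage-block and composition-block likelihoods; all likelihoods are
evaluated in log space, since the literal 64-term density product
underflows for typical values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cluster import ClusterResult

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-4
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass
class ClusterProfile:
    """Per-bin diagonal Gaussian over the 32+32 raw feature dimensions."""

    mu_cov: np.ndarray
    sigma_cov: np.ndarray
    mu_com: np.ndarray
    sigma_com: np.ndarray


@dataclass
class BinAssignment:
    """Final read -> bin mapping plus the per-bin profiles."""

    mapping: dict[str, int]
    profiles: dict[int, ClusterProfile]
    source: dict[str, str] = field(default_factory=dict)  # "clustered" | "assigned"


def build_profiles(
    clusters: ClusterResult,
    coverage: np.ndarray,
    composition: np.ndarray,
    sigma_floor: float = SIGMA_FLOOR,
) -> dict[int, ClusterProfile]:
    """Per-cluster mean/std over members' raw feature vectors, stds floored."""
    profiles: dict[int, ClusterProfile] = {}
    for bin_id, members in enumerate(clusters.clusters):
        if len(members) == 0:
            raise ValueError(f"cluster {bin_id} is empty")
        cov = coverage[members]
        com = composition[members]
        sd_cov = np.maximum(cov.std(axis=0), sigma_floor)
        sd_com = np.maximum(com.std(axis=0), sigma_floor)
        if len(members) == 1:
            logger.warning("cluster %d has a single member; stds set to the floor", bin_id)
        profiles[bin_id] = ClusterProfile(
            mu_cov=cov.mean(axis=0), sigma_cov=sd_cov, mu_com=com.mean(axis=0), sigma_com=sd_com
        )
    return profiles


def log_pdf(v: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Log of the diagonal Gaussian density: sum_j [-ln(sqrt(2 pi) sigma_j) - (v_j - mu_j)^2 / (2 sigma_j^2)]."""
    v = np.asarray(v, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if not (np.isfinite(v).all() and np.isfinite(mu).all() and np.isfinite(sigma).all()):
        raise ValueError("non-finite input to log_pdf")
    return float(np.sum(-_LOG_SQRT_2PI - np.log(sigma) - (v - mu) ** 2 / (2.0 * sigma**2)))


def _log_likelihood_table(
    coverage: np.ndarray, composition: np.ndarray, profiles: Mapping[int, ClusterProfile]
) -> tuple[np.ndarray, list[int]]:
    """n_reads x n_bins table of summed log likelihoods, bins in sorted id order."""
    bin_ids = sorted(profiles)
    table = np.empty((len(coverage), len(bin_ids)))
    for j, b in enumerate(bin_ids):
        p = profiles[b]
        ll_cov = (
            -np.sum(_LOG_SQRT_2PI + np.log(p.sigma_cov))
            - ((coverage - p.mu_cov) ** 2 / (2.0 * p.sigma_cov**2)).sum(axis=1)
        )
        ll_com = (
            -np.sum(_LOG_SQRT_2PI + np.log(p.sigma_com))
            - ((composition - p.mu_com) ** 2 / (2.0 * p.sigma_com**2)).sum(axis=1)
        )
        table[:, j] = ll_cov + ll_com
    return table, bin_ids


def assign_read(cov: np.ndarray, com: np.ndarray, profiles: Mapping[int, ClusterProfile]) -> int:
    """Bin maximising the joint coverage x composition log likelihood.

    Ties break towards the smallest bin id.
    """
    if not profiles:
        raise ValueError("no profiles to assign against")
    table, bin_ids = _log_likelihood_table(np.atleast_2d(cov), np.atleast_2d(com), profiles)
    return bin_ids[int(np.argmax(table[0]))]  # argmax takes the first (= smallest id) on ties


def finalize_bins(
    clusters: ClusterResult,
    coverage: np.ndarray,
    composition: np.ndarray,
    read_ids: Sequence[str],
    sigma_floor: float = SIGMA_FLOOR,
) -> BinAssignment:
    """Keep clustered reads in their bins; assign every unclustered read by ML."""
    if not clusters.clusters:
        raise ValueError(
            "no clusters detected; consider lowering --min-cluster-size or --seed-ratio"
        )
    profiles = build_profiles(clusters, coverage, composition, sigma_floor=sigma_floor)
    mapping: dict[str, int] = {}
    source: dict[str, str] = {}
    for bin_id, members in enumerate(clusters.clusters):
        for i in members:
            mapping[read_ids[i]] = bin_id
            source[read_ids[i]] = "clustered"
    if len(clusters.unclustered):
        idx = clusters.unclustered
        table, bin_ids = _log_likelihood_table(coverage[idx], composition[idx], profiles)
        best = np.argmax(table, axis=1)
        for i, j in zip(idx, best):
            mapping[read_ids[i]] = bin_ids[int(j)]
            source[read_ids[i]] = "assigned"
    assert len(mapping) == clusters.n_points
    return BinAssignment(mapping=mapping, profiles=profiles, source=source)
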