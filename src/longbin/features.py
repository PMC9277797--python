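"""Per-read composition and coverage features.

Composition: canonical trimer frequencies (a trimer and its reverse
complement merged), 32 dimensions, normalised per read.

Coverage: each read's 15-mers are looked up in a dataset-wide canonical
k-mer count index; the counts are histogrammed (bin width 10, 32 bins,
overflow into the last bin) and normalised per read. Reads of abundant
species carry high-count k-mers, so the histogram is an alignment-free
abundance proxy.

Nucleotides are 2-bit encoded as A=00, C=01, T=10, G=11, under which the
complement of a base is its code XOR 2. K-mers spanning non-ACGT characters
are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import ReadRecord

logger = logging.getLogger(__name__)

TRIMER_DIM = 32
COVERAGE_BINS = 32
COVERAGE_BIN_WIDTH = 10
KMER_K = 15

# A=00, C=01, T=10, G=11; complement = code ^ 2
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _b, _c in zip(b"ACTG", range(4)):
    _BASE_CODE[_b] = _c
    _BASE_CODE[_b + 32] = _c  # lowercase
_CODE_BASE = "ACTG"


class UnscorableReadError(ValueError):
    """Raised when a read has no valid k-mer window at the requested k."""


def _encode(sequence: str) -> np.ndarray:
    """Map a nucleotide string to 2-bit codes; non-ACGT become -1."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def _kmer_codes(vals: np.ndarray, k: int, canonical: bool = True) -> np.ndarray:
    """2-bit codes of all valid k-mer windows (canonicalised by default).

    A window is valid when none of its k positions is a non-ACGT character.
    The canonical code is the smaller of the window's code and its reverse
    complement's code.
    """
    m = vals.size - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    invalid = (vals < 0).astype(np.int32)
    csum = np.concatenate(([0], np.cumsum(invalid)))
    ok = (csum[k:] - csum[:-k]) == 0
    v = np.where(vals >= 0, vals, 0).astype(np.uint64)
    code = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        code |= v[j : j + m] << np.uint64(2 * (k - 1 - j))
    if not canonical:
        return code[ok]
    comp = v ^ np.uint64(2)
    rc = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        rc |= comp[j : j + m] << np.uint64(2 * j)
    return np.minimum(code, rc)[ok]


def _build_trimer_table() -> tuple[np.ndarray, int]:
    """64-entry lookup from trimer 2-bit code to canonical index in [0, 32)."""
    codes = np.arange(64, dtype=np.uint64)
    b0, b1, b2 = codes >> np.uint64(4), (codes >> np.uint64(2)) & np.uint64(3), codes & np.uint64(3)
    rc = ((b2 ^ np.uint64(2)) << np.uint64(4)) | ((b1 ^ np.uint64(2)) << np.uint64(2)) | (b0 ^ np.uint64(2))
    canon = np.minimum(codes, rc)
    distinct = np.unique(canon)
    table = np.searchsorted(distinct, canon).astype(np.int64)
    return table, len(distinct)


_TRIMER_TABLE, _N_CANON_TRIMERS = _build_trimer_table()
assert _N_CANON_TRIMERS == TRIMER_DIM


def canonical_trimer_index(trimer: str) -> int:
    """Index in [0, 32) shared by a trimer and its reverse complement.

    Returns -1 for a trimer containing a non-ACGT character (the caller
    skips that window).
    """
    if len(trimer) != 3:
        raise ValueError("trimer must have length 3")
    vals = _encode(trimer)
    if (vals < 0).any():
        return -1
    code = (int(vals[0]) << 4) | (int(vals[1]) << 2) | int(vals[2])
    return int(_TRIMER_TABLE[code])


def compute_composition(read: ReadRecord) -> np.ndarray:
    """Normalised canonical trimer frequency vector (32 dims, sums to 1)."""
    vals = _encode(read.sequence)
    canon = _kmer_codes(vals, 3)
    if canon.size == 0:
        raise UnscorableReadError(f"read {read.read_id!r}: no valid trimer")
    idx = _TRIMER_TABLE[canon.astype(np.int64)]
    counts = np.bincount(idx, minlength=TRIMER_DIM).astype(np.float64)
    return counts / counts.sum()


@dataclass
class KmerIndex:
    """Dataset-wide canonical k-mer occurrence counts.

    Keys are sorted 2-bit-encoded canonical k-mers; ``counts[i]`` is the
    number of occurrences of ``keys[i]`` across all reads.
    """

    k: int
    keys: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    canonical: bool = True

    @property
    def total_occurrences(self) -> int:
        return int(self.counts.sum())

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Occurrence counts for an array of (canonical) k-mer codes; 0 if absent."""
        if len(self.keys) == 0:
            return np.zeros(len(codes), dtype=np.int64)
        pos = np.searchsorted(self.keys, codes)
        pos = np.clip(pos, 0, len(self.keys) - 1)
        hit = self.keys[pos] == codes
        return np.where(hit, self.counts[pos], 0).astype(np.int64)


def build_kmer_index(
    reads: Iterable[ReadRecord], k: int = KMER_K, canonical: bool = True, chunk_positions: int = 20_000_000
) -> KmerIndex:
    """Count every (canonical) k-mer across the whole dataset.

    Counting is chunked so memory stays proportional to the number of
    distinct k-mers rather than the number of positions scanned.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    keys = np.empty(0, dtype=np.uint64)
    counts = np.empty(0, dtype=np.int64)
    pending: list[np.ndarray] = []
    pending_size = 0

    def _flush() -> tuple[np.ndarray, np.ndarray]:
        nonlocal pending, pending_size
        if not pending:
            return keys, counts
        chunk = np.concatenate(pending)
        pending, pending_size = [], 0
        ck, cc = np.unique(chunk, return_counts=True)
        merged = np.concatenate([keys, ck])
        merged_counts = np.concatenate([counts, cc])
        order = np.argsort(merged, kind="stable")
        merged, merged_counts = merged[order], merged_counts[order]
        uk, start = np.unique(merged, return_index=True)
        uc = np.add.reduceat(merged_counts, start) if len(merged) else merged_counts
        return uk, uc.astype(np.int64)

    for read in reads:
        codes = _kmer_codes(_encode(read.sequence), k, canonical=canonical)
        if codes.size:
            pending.append(codes)
            pending_size += codes.size
        if pending_size >= chunk_positions:
            keys, counts = _flush()
    keys, counts = _flush()
    return KmerIndex(k=k, keys=keys, counts=counts, canonical=canonical)


def compute_coverage_histogram(
    read: ReadRecord,
    index: KmerIndex,
    bins: int = COVERAGE_BINS,
    bin_width: int = COVERAGE_BIN_WIDTH,
) -> np.ndarray:
    """Normalised histogram of the read's k-mer dataset counts.

    Count c lands in bin ``min(c // bin_width, bins - 1)``; counts past the
    histogram range accumulate in the last bin. Sums to 1.
    """
    codes = _kmer_codes(_encode(read.sequence), index.k, canonical=index.canonical)
    if codes.size == 0:
        raise UnscorableReadError(f"read {read.read_id!r}: no valid {index.k}-mer")
    c = index.lookup(codes)
    bin_idx = np.minimum(c // bin_width, bins - 1)
    hist = np.bincount(bin_idx, minlength=bins).astype(np.float64)
    return hist / hist.sum()


# Backwards-friendly aliases for the two feature blocks as plain arrays.
CompositionVector = np.ndarray
CoverageHistogram = np.ndarray


def assemble_features(
    reads: Sequence[ReadRecord],
    k: int = KMER_K,
    bins: int = COVERAGE_BINS,
    bin_width: int = COVERAGE_BIN_WIDTH,
    canonical_kmers: bool = True,
    index: Optional[KmerIndex] = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Build the n x 64 feature matrix (coverage block then composition block).

    Returns ``(features, kept_read_ids, dropped_read_ids)``; row i of the
    matrix corresponds to ``kept_read_ids[i]`` in input order. Reads with no
    valid k-mer are dropped and logged.
    """
    reads = list(reads)
    per_read_codes: list[np.ndarray] = []
    compositions: list[Optional[np.ndarray]] = []
    for read in reads:
        vals = _encode(read.sequence)
        per_read_codes.append(_kmer_codes(vals, k, canonical=canonical_kmers))
        tri = _kmer_codes(vals, 3)
        if tri.size:
            com = np.bincount(_TRIMER_TABLE[tri.astype(np.int64)], minlength=TRIMER_DIM).astype(np.float64)
            compositions.append(com / com.sum())
        else:
            compositions.append(None)

    lens = np.array([c.size for c in per_read_codes], dtype=np.int64)
    concat = np.concatenate(per_read_codes) if lens.sum() else np.empty(0, dtype=np.uint64)
    if index is None:
        # counting and lookup collapse into one unique() pass over the dataset
        _, inverse, uniq_counts = np.unique(concat, return_inverse=True, return_counts=True)
        per_pos = uniq_counts[inverse]
    else:
        per_pos = index.lookup(concat)
    bin_idx = np.minimum(per_pos // bin_width, bins - 1)
    row = np.repeat(np.arange(len(reads)), lens)
    hists = np.bincount(row * bins + bin_idx, minlength=len(reads) * bins).reshape(len(reads), bins)

    rows: list[np.ndarray] = []
    kept: list[str] = []
    dropped: list[str] = []
    for i, read in enumerate(reads):
        if lens[i] == 0 or compositions[i] is None:
            dropped.append(read.read_id)
            continue
        cov = hists[i].astype(np.float64) / lens[i]
        rows.append(np.concatenate([cov, compositions[i]]))
        kept.append(read.read_id)
    if dropped:
        logger.warning("dropped %d unscorable reads: %s%s", len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    if not rows:
        raise ValueError("all reads are unscorable; nothing to bin")
    return np.vstack(rows), kept, dropped
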