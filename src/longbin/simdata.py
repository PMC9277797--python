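"""Synthetic long-read communities with known ground truth.

Mock genomes are drawn from species-specific 3rd-order Markov nucleotide
models (one transition matrix per species, rows sampled from a Dirichlet
whose concentration is set by ``composition_divergence``), which gives each
species a distinct trimer profile without any reference download. Reads are
sampled proportional to abundance x genome length, from either strand, with
lengths from a truncated normal, and corrupted by per-base substitution,
insertion and deletion noise at configurable rates (defaults 0.01 / 0.11 /
0.04, the error regime of typical error-prone long reads).
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import ReadRecord

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class CommunitySpec:
    """Parameters of a synthetic community."""

    n_species: int = 4
    n_reads: int = 6000
    genome_length: int = 200_000
    abundances: Optional[Sequence[float]] = None  # relative; default equal
    read_length_mean: int = 5000
    read_length_sd: int = 1000
    substitution_rate: float = 0.01
    insertion_rate: float = 0.11
    deletion_rate: float = 0.04
    composition_divergence: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.abundances is None:
            self.abundances = [1.0] * self.n_species
        self.abundances = list(self.abundances)
        if len(self.abundances) != self.n_species:
            raise ValueError("one abundance per species required")
        if min(self.abundances) <= 0:
            raise ValueError("abundances must be positive")
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= r <= 0.3:
                raise ValueError("error rates must lie in [0, 0.3]")

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "n_reads": self.n_reads,
            "genome_length": self.genome_length,
            "abundances": self.abundances,
            "read_length_mean": self.read_length_mean,
            "read_length_sd": self.read_length_sd,
            "substitution_rate": self.substitution_rate,
            "insertion_rate": self.insertion_rate,
            "deletion_rate": self.deletion_rate,
            "composition_divergence": self.composition_divergence,
            "seed": self.seed,
        }


def _markov_genome(length: int, transitions: np.ndarray, rng: np.random.Generator) -> str:
    """Sample a genome from a 3rd-order Markov chain (64 contexts x 4 bases)."""
    cum = np.cumsum(transitions, axis=1)
    cum[:, -1] = 1.0
    cum_list = cum.tolist()
    u = rng.random(length)
    out = []
    ctx = int(rng.integers(64))
    for i in range(length):
        row = cum_list[ctx]
        b = bisect_right(row, u[i])
        if b > 3:
            b = 3
        out.append(b)
        ctx = ((ctx << 2) | b) & 63
    codes = np.array(out, dtype=np.int64)
    return "".join(_BASES[c] for c in codes)


def generate_genomes(spec: CommunitySpec) -> list[str]:
    """One mock genome per species, reproducible from the spec seed.

    Higher ``composition_divergence`` sharpens each species' Markov
    transition rows, making trimer profiles more distinct between species.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = 1.0 * spec.composition_divergence
    genomes = []
    for _ in range(spec.n_species):
        # sparse Dirichlet rows => species-specific oligonucleotide bias
        transitions = rng.dirichlet([1.0 / alpha if alpha > 0 else 1.0] * 4, size=64)
        genomes.append(_markov_genome(spec.genome_length, transitions, rng))
    return genomes


def _apply_errors(codes: np.ndarray, spec: CommunitySpec, rng: np.random.Generator) -> np.ndarray:
    """Per-base substitution / insertion / deletion noise on 0..3 codes."""
    n = codes.size
    keep = rng.random(n) >= spec.deletion_rate
    codes = codes[keep]
    m = codes.size
    if spec.substitution_rate > 0 and m:
        sub = rng.random(m) < spec.substitution_rate
        codes = codes.copy()
        codes[sub] = (codes[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    if spec.insertion_rate > 0 and m:
        ins = np.flatnonzero(rng.random(m) < spec.insertion_rate)
        if ins.size:
            codes = np.insert(codes, ins, rng.integers(0, 4, size=ins.size))
    return codes


def simulate_reads(
    genomes: Sequence[str],
    spec: CommunitySpec,
    fastq_path=None,
    truth_path=None,
) -> tuple[list[ReadRecord], dict[str, str]]:
    """Sample noisy reads from the genomes; optionally write FASTQ + truth TSV.

    Read counts per species follow a multinomial with probabilities
    proportional to abundance x genome length; start positions are uniform,
    lengths normal (mean/sd from the spec) truncated to [500, genome
    length], and each read comes from either strand with probability 1/2.
    Returns the reads (with ``origin_label`` set) and the truth mapping.
    """
    rng = np.random.default_rng(spec.seed + 1)
    weights = np.array([a * len(g) for a, g in zip(spec.abundances, genomes)], dtype=np.float64)
    probs = weights / weights.sum()
    counts = rng.multinomial(spec.n_reads, probs)
    for s, c in enumerate(counts):
        if c == 0:
            logger.warning("species_%d received 0 reads at the requested abundances", s)

    genome_codes = [np.frombuffer(g.encode(), dtype=np.uint8) for g in genomes]
    base_to_code = np.full(256, 0, dtype=np.int64)
    for i, b in enumerate(_BASES.encode()):
        base_to_code[b] = i

    reads: list[ReadRecord] = []
    truth: dict[str, str] = {}
    r = 0
    for s, c in enumerate(counts):
        species = f"species_{s}"
        gl = len(genomes[s])
        gcodes = base_to_code[genome_codes[s]]
        lengths = np.clip(np.rint(rng.normal(spec.read_length_mean, spec.read_length_sd, size=c)), 500, gl).astype(int)
        for length in lengths:
            start = int(rng.integers(0, gl - length + 1))
            fragment = gcodes[start : start + length]
            if rng.random() < 0.5:  # reverse-complement strand; complement is 3-code under ACGT=0123
                fragment = (3 - fragment)[::-1]
            noisy = _apply_errors(np.asarray(fragment), spec, rng)
            if noisy.size == 0:
                noisy = np.array([int(rng.integers(0, 4))])
            seq = "".join(_BASES[b] for b in noisy)
            read_id = f"R{r:06d}"
            reads.append(ReadRecord(read_id=read_id, sequence=seq, origin_label=species))
            truth[read_id] = species
            r += 1

    if fastq_path is not None:
        fastq_path = Path(fastq_path)
        with open(fastq_path, "w") as fh:
            for read in reads:
                fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            for read in reads:
                fh.write(f"{read.read_id}\t{read.origin_label}\n")
    return reads, truth


def write_manifest(spec: CommunitySpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2)
        fh.write("\n")
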