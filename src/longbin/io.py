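"""Reading and writing of on-disk formats.

FASTA/FASTQ input (plain or gzip), the two-column ``bins.tsv`` output,
per-bin FASTA files and ground-truth label tables.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)


@dataclass
class ReadRecord:
    """One long read: identifier, nucleotide sequence and optional truth label."""

    read_id: str
    sequence: str
    origin_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")


def _open_maybe_gzip(path: Path) -> IO[str]:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle: IO[str]) -> str:
    first = handle.read(1)
    handle.seek(0)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    if first == "":
        raise ValueError("empty input file")
    raise ValueError(f"cannot detect FASTA/FASTQ format (first byte {first!r})")


def read_sequences(path, min_length: int = 0) -> Iterator[ReadRecord]:
    """Stream reads from a FASTA/FASTQ file, dropping those shorter than ``min_length``.

    The format is auto-detected from the first byte (``>`` vs ``@``) after
    transparent gzip decompression. Quality strings are parsed but ignored.
    Kept/dropped counts are logged when the stream is exhausted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    handle = _open_maybe_gzip(path)
    fmt = _sniff_format(handle)
    kept = dropped = 0
    seen_ids: set[str] = set()
    try:
        for i, rec in enumerate(SeqIO.parse(handle, fmt)):
            seq = str(rec.seq).upper()
            if not rec.id or not seq:
                raise ValueError(f"malformed {fmt.upper()} record at index {i}")
            if rec.id in seen_ids:
                raise ValueError(f"duplicate read id {rec.id!r} at record index {i}")
            seen_ids.add(rec.id)
            if len(seq) < min_length:
                dropped += 1
                continue
            kept += 1
            yield ReadRecord(read_id=rec.id, sequence=seq)
    except ValueError:
        raise
    finally:
        handle.close()
    if kept == 0 and dropped == 0:
        raise ValueError(f"{path}: no records found")
    logger.info("%s: kept %d reads, dropped %d shorter than %d bp", path, kept, dropped, min_length)


def read_truth(path) -> dict[str, str]:
    """Load a two-column ``read_id TAB species`` ground-truth table."""
    truth: dict[str, str] = {}
    with _open_maybe_gzip(Path(path)) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
            truth[parts[0]] = parts[1]
    return truth


def write_bins(assignment, reads: Iterable[ReadRecord], out_dir, partial: bool = False) -> list[Path]:
    """Write ``bins.tsv`` plus one FASTA per bin.

    Every read in the stream must have a bin in ``assignment.mapping`` unless
    ``partial`` is set, in which case unassigned reads are written under
    bin_id -1 (table only, no FASTA).

    Returns the list of files written. The per-bin FASTA files partition the
    assigned input reads; within each bin, input order is preserved.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mapping = assignment.mapping if hasattr(assignment, "mapping") else dict(assignment)

    tsv_path = out_dir / "bins.tsv"
    handles: dict[int, IO[str]] = {}
    written: list[Path] = [tsv_path]
    try:
        with open(tsv_path, "w") as tsv:
            for read in reads:
                if read.read_id in mapping:
                    bin_id = mapping[read.read_id]
                elif partial:
                    bin_id = -1
                else:
                    raise ValueError(f"read {read.read_id!r} has no bin assignment")
                tsv.write(f"{read.read_id}\t{bin_id}\n")
                if bin_id == -1:
                    continue
                if bin_id not in handles:
                    fasta_path = out_dir / f"bin_{bin_id}.fasta"
                    handles[bin_id] = open(fasta_path, "w")
                    written.append(fasta_path)
                handles[bin_id].write(f">{read.read_id}\n{read.sequence}\n")
    finally:
        for fh in handles.values():
            fh.close()
    return written
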