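"""FASTQ streaming and read retention.

Reads are kept when they are at least ``min_length`` bases long and at
least ``min_pass_fraction`` of their bases reach the Phred
``quality_threshold``.  The defaults (30 bp, 20 %, Q30) follow the common
FASTX-toolkit quality-filter idiom for WGBS preprocessing; every knob is a
:class:`FilterPolicy` field.  N bases never count toward the
quality-passing numerator but do count toward read length.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqParseError

__all__ = [
    "SequenceRead",
    "FilterPolicy",
    "FilterCounts",
    "read_fastq",
    "write_fastq",
    "passes_filter",
    "filter_reads",
]

_VALID = frozenset("ACGTN")


@dataclass
class SequenceRead:
    """One sequencing read: identifier, bases (A/C/G/T/N) and Phred scores."""

    read_id: str
    bases: str
    quals: np.ndarray  # integer Phred scores, one per base

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != self.quals.size:
            raise FastqParseError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{self.quals.size} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class FilterPolicy:
    """Length/quality retention rule applied to raw reads."""

    min_length: int = 30
    min_pass_fraction: float = 0.20
    quality_threshold: int = 30
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_pass_fraction <= 1.0:
            raise ValueError("min_pass_fraction must be in [0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")


@dataclass(frozen=True)
class FilterCounts:
    kept: int
    dropped: int

    @property
    def total(self) -> int:
        return self.kept + self.dropped


def _open_text(path_or_stream, mode: str = "rt"):
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        return path_or_stream, False
    path = Path(path_or_stream)
    if path.suffix == ".gz":
        return gzip.open(path, mode), True
    return open(path, mode), True


def read_fastq(path_or_stream, phred_offset: int = 33) -> Iterator[SequenceRead]:
    """Stream FASTQ records (plain or gzip) as :class:`SequenceRead`.

    Bases are uppercased on ingest; qualities decoded at ``phred_offset``.
    Malformed records raise :class:`FastqParseError` naming the record
    index.
    """
    handle, owned = _open_text(path_or_stream)
    index = 0
    try:
        for title, seq, qual in FastqGeneralIterator(handle):
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"record {index}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            bases = seq.upper()
            bad = set(bases) - _VALID
            if bad:
                raise FastqParseError(
                    f"record {index}: invalid bases {sorted(bad)}"
                )
            quals = (
                np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
                - phred_offset
            )
            if quals.size and quals.min() < 0:
                raise FastqParseError(
                    f"record {index}: quality below Phred offset {phred_offset}"
                )
            yield SequenceRead(title.split()[0] if title else f"read{index}",
                               bases, quals)
            index += 1
    except ValueError as exc:  # Biopython structural errors
        raise FastqParseError(f"record {index}: {exc}") from exc
    finally:
        if owned:
            handle.close()


def write_fastq(reads: Iterable[SequenceRead], path_or_stream,
                phred_offset: int = 33) -> int:
    """Write reads as 4-line FASTQ; returns the number written."""
    handle, owned = _open_text(path_or_stream, "wt")
    n = 0
    try:
        for read in reads:
            qual = "".join(chr(int(q) + phred_offset) for q in read.quals)
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    finally:
        if owned:
            handle.close()
    return n


def passes_filter(read: SequenceRead, policy: FilterPolicy = FilterPolicy()) -> bool:
    """True iff the read meets the length and quality retention rule."""
    n = len(read)
    if n < policy.min_length:
        return False
    not_n = np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8) != ord("N")
    passing = int(((read.quals >= policy.quality_threshold) & not_n).sum())
    return passing / n >= policy.min_pass_fraction


def filter_reads(
    reads: Iterable[SequenceRead], policy: FilterPolicy = FilterPolicy()
) -> tuple[list[SequenceRead], FilterCounts]:
    """Order-preserving retention filter; returns (kept reads, counts)."""
    kept: list[SequenceRead] = []
    dropped = 0
    for read in reads:
        if passes_filter(read, policy):
            kept.append(read)
        else:
            dropped += 1
    return kept, FilterCounts(kept=len(kept), dropped=dropped)


def reads_from_string(text: str, phred_offset: int = 33) -> list[SequenceRead]:
    """Parse FASTQ from an in-memory string (convenience for tests/examples)."""
    return list(read_fastq(io.StringIO(text), phred_offset=phred_offset))
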