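"""Reference-free cytosine-context tallying.

Bisulfite treatment converts unmethylated cytosines to thymines, so in raw
WGBS reads an observed ``C`` at a context site is evidence of methylation
while an observed ``T`` at the analogous position is either a converted
unmethylated cytosine or a true thymine — the two are indistinguishable
without a reference.  This module counts, directly on reads:

* ``n_c_sites`` — windows matching a context pattern whose first base is C
  (observed methylated sites),
* ``n_t_sites`` — the same windows with first base T (converted or true T),
* ``n_g`` and ``n_bases`` — G and non-N base totals, from which genomic GC
  content is later estimated (G is untouched by bisulfite conversion).

Context patterns use H = {A, C, T}.  H is evaluated on observed bases; this
is safe because conversion maps C to T *within* H, so a window's context
class is stable under bisulfite conversion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "Context",
    "ContextTally",
    "PLANT_CONTEXTS",
    "MAMMAL_CONTEXTS",
    "ALL_CONTEXTS",
    "contexts_for_mode",
    "as_context",
    "reverse_complement",
    "tally_read",
    "tally_reads",
    "tallies_to_frame",
    "write_tallies",
    "read_tallies",
]


class Context(str, enum.Enum):
    """A cytosine sequence context (H = A, C or T)."""

    CPG = "CPG"  # C followed by G
    CHG = "CHG"  # C, H, G (plant)
    CHH = "CHH"  # C, H, H (plant)
    CH = "CH"    # C followed by H (mammal non-CpG)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


PLANT_CONTEXTS = (Context.CPG, Context.CHG, Context.CHH)
MAMMAL_CONTEXTS = (Context.CPG, Context.CH)
ALL_CONTEXTS = tuple(Context)

PATTERN_LENGTH: Mapping[Context, int] = {
    Context.CPG: 2,
    Context.CHG: 3,
    Context.CHH: 3,
    Context.CH: 2,
}


def contexts_for_mode(mode: str) -> tuple[Context, ...]:
    """Contexts tallied for a species mode: plant, mammal or all."""
    try:
        return {
            "plant": PLANT_CONTEXTS,
            "mammal": MAMMAL_CONTEXTS,
            "all": ALL_CONTEXTS,
        }[mode]
    except KeyError:
        raise ConfigurationError(
            f"unknown context mode {mode!r}; expected plant, mammal or all"
        ) from None


def as_context(name: "Context | str") -> Context:
    """Coerce a name like ``"CpG"`` to a :class:`Context`."""
    if isinstance(name, Context):
        return name
    s = str(name).upper()
    if s == "CG":  # common alias
        s = "CPG"
    try:
        return Context(s)
    except ValueError:
        raise ConfigurationError(f"unknown context {name!r}") from None


@dataclass
class ContextTally:
    """Window and base counts for one context over a set of reads.

    Tallies form a commutative monoid under ``+`` (field-wise sum with the
    zero tally as identity), so chunked or parallel tallies merge exactly.
    """

    context: Context
    n_c_sites: int = 0
    n_t_sites: int = 0
    n_g: int = 0
    n_bases: int = 0
    n_reads: int = 0

    def __post_init__(self) -> None:
        self.context = as_context(self.context)

    @property
    def n_sites(self) -> int:
        """Total context sites observed (denominator of the estimator)."""
        return self.n_c_sites + self.n_t_sites

    def __add__(self, other: "ContextTally") -> "ContextTally":
        if not isinstance(other, ContextTally):
            return NotImplemented
        if other.context != self.context:
            raise ConfigurationError(
                f"cannot merge tallies for {self.context} and {other.context}"
            )
        return ContextTally(
            self.context,
            self.n_c_sites + other.n_c_sites,
            self.n_t_sites + other.n_t_sites,
            self.n_g + other.n_g,
            self.n_bases + other.n_bases,
            self.n_reads + other.n_reads,
        )


_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(bases: str) -> str:
    """Reverse complement of an A/C/G/T/N string (N maps to N)."""
    return bases.translate(_RC_TABLE)[::-1]


def _window_counts(arr: np.ndarray, context: Context) -> tuple[int, int]:
    """(C-start, T-start) window counts for one context on a byte array.

    N fails every base class, so windows containing N are skipped; a
    sentinel N between concatenated reads therefore also prevents windows
    from spanning reads.
    """
    if arr.size < PATTERN_LENGTH[context]:
        return 0, 0
    is_c = arr == _C
    is_t = arr == _T
    if context is Context.CPG:
        tail = arr[1:] == _G
        return int((is_c[:-1] & tail).sum()), int((is_t[:-1] & tail).sum())
    is_h = is_c | is_t | (arr == _A)
    if context is Context.CH:
        tail = is_h[1:]
        return int((is_c[:-1] & tail).sum()), int((is_t[:-1] & tail).sum())
    mid = is_h[1:-1]
    if context is Context.CHG:
        tail = mid & (arr[2:] == _G)
    elif context is Context.CHH:
        tail = mid & is_h[2:]
    else:  # pragma: no cover - enum is closed
        raise ConfigurationError(f"unknown context {context!r}")
    return int((is_c[:-2] & tail).sum()), int((is_t[:-2] & tail).sum())


def _bases_of(read) -> str:
    return read if isinstance(read, str) else read.bases


def tally_read(
    read,
    context: "Context | str",
    tally: "ContextTally | None" = None,
) -> ContextTally:
    """Add one read's windows and base counts to a tally.

    ``read`` may be a :class:`~rawmeth.seqio.SequenceRead` or a plain base
    string.  Windows are scanned at every offset (overlapping windows count
    independently: each cytosine is its own potential methylation site).
    """
    context = as_context(context)
    if tally is None:
        tally = ContextTally(context)
    arr = np.frombuffer(_bases_of(read).encode("ascii"), dtype=np.uint8)
    n_c, n_t = _window_counts(arr, context)
    return ContextTally(
        context,
        tally.n_c_sites + n_c,
        tally.n_t_sites + n_t,
        tally.n_g + int((arr == _G).sum()),
        tally.n_bases + int((arr != _N).sum()),
        tally.n_reads + 1,
    )


def tally_reads(
    reads: Iterable,
    contexts: Iterable["Context | str"] = ALL_CONTEXTS,
    read2_mode: bool = False,
    chunk_size: int = 50_000,
) -> dict[Context, ContextTally]:
    """Tally a read set for several contexts in one pass.

    With ``read2_mode`` each read is reverse-complemented before counting
    (read 2 of a directional library observes the complement of the
    converted strand).  Reads are concatenated in chunks with an ``N``
    sentinel between them; since N-containing windows never match, no
    window spans two reads, and sentinels contribute nothing to the G or
    base totals.
    """
    ctxs = tuple(as_context(c) for c in contexts)
    totals = {c: ContextTally(c) for c in ctxs}
    pending: list[str] = []
    n_pending = 0

    def flush() -> None:
        nonlocal pending, n_pending
        if not pending:
            return
        blob = "N".join(pending)
        arr = np.frombuffer(blob.encode("ascii"), dtype=np.uint8)
        n_g = int((arr == _G).sum())
        n_bases = int((arr != _N).sum())
        for c in ctxs:
            n_c, n_t = _window_counts(arr, c)
            t = totals[c]
            totals[c] = ContextTally(
                c, t.n_c_sites + n_c, t.n_t_sites + n_t,
                t.n_g + n_g, t.n_bases + n_bases, t.n_reads + len(pending),
            )
        pending = []
        n_pending = 0

    for read in reads:
        bases = _bases_of(read)
        if read2_mode:
            bases = reverse_complement(bases)
        pending.append(bases)
        n_pending += len(bases)
        if n_pending >= chunk_size:
            flush()
    flush()
    return totals


def tallies_to_frame(tallies: Mapping[Context, ContextTally]) -> pd.DataFrame:
    """Flat table of tallies (one row per context)."""
    rows = [
        {
            "context": t.context.value,
            "n_c_sites": t.n_c_sites,
            "n_t_sites": t.n_t_sites,
            "n_g": t.n_g,
            "n_bases": t.n_bases,
            "n_reads": t.n_reads,
        }
        for t in tallies.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["context", "n_c_sites", "n_t_sites", "n_g", "n_bases", "n_reads"],
    )


def write_tallies(tallies: Mapping[Context, ContextTally], path) -> None:
    tallies_to_frame(tallies).to_csv(path, sep="\t", index=False)


def read_tallies(path) -> dict[Context, ContextTally]:
    """Load tallies written by :func:`write_tallies`."""
    df = pd.read_csv(path, sep="\t")
    out: dict[Context, ContextTally] = {}
    for _, row in df.iterrows():
        c = as_context(row["context"])
        out[c] = ContextTally(
            c,
            int(row["n_c_sites"]),
            int(row["n_t_sites"]),
            int(row["n_g"]),
            int(row["n_bases"]),
            int(row["n_reads"]),
        )
    return out
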