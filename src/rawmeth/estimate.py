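"""Genome-wide methylation estimation without a reference.

Core quantities, per cytosine context:

* ``f_hat`` — the fraction of context-matching windows in raw bisulfite
  reads whose first base is an observed C.  Under the model assumptions
  (all context cytosines methylated at rate m; thymines at the analogous
  T-start windows are converted cytosines or true thymines; bases randomly
  distributed) its expectation is ``m * p`` where ``p`` is genomic GC
  content — the estimator confounds methylation level with GC content.
* ``p_hat`` — GC content estimated as twice the G-base frequency of the
  reads; G is unaffected by bisulfite treatment and under strand symmetry
  the G fraction of either strand is ``p / 2``.
* ``m_hat = f_hat / p_hat`` — the GC-corrected methylation estimate.

When additional non-converted genomic reads are available (>= 500,000 bp),
``direct_mode_m`` instead divides the frequency of intact context sites in
the bisulfite reads (sites that were methylated and escaped C-to-T
conversion) by the context-site frequency measured from the genomic reads.

Reference-based target levels are computed from per-cytosine (allC) tables
as the weighted level: sum of methylated read counts over sum of total
read counts across sites in the context.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .contexts import Context, ContextTally, as_context
from .errors import AllcParseError, ConfigurationError, EstimationError

__all__ = [
    "MethylationEstimate",
    "AllcRecord",
    "compute_f_hat",
    "estimate_gc",
    "estimate_m",
    "direct_mode_m",
    "read_allc",
    "allc_context_mask",
    "target_m_from_allc",
    "adjust_for_nonconversion",
    "estimates_to_frame",
    "DEFAULT_SITE_FLOOR",
    "DIRECT_MODE_BASE_FLOOR",
]

#: below this many observed context sites a low-evidence warning is attached
DEFAULT_SITE_FLOOR = 1_000

#: minimum genomic bases recommended for direct mode
DIRECT_MODE_BASE_FLOOR = 500_000


@dataclass
class MethylationEstimate:
    """One context's estimate with its diagnostics."""

    context: Context
    f_hat: float
    p_hat: float
    m_hat: float
    n_sites: int
    n_reads: int
    n_bases: int
    mode: str = "gc_corrected"  # or "direct"
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class AllcRecord:
    """One row of a per-cytosine methylation table."""

    seq_name: str
    position: int  # 1-based
    strand: str  # "+" or "-"
    context: str  # 3-letter genomic context, e.g. "CGA", "CTT"
    mc_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise AllcParseError(f"position must be >= 1, got {self.position}")
        if not 0 <= self.mc_reads <= self.total_reads:
            raise AllcParseError(
                f"need 0 <= mc_reads <= total_reads, got "
                f"{self.mc_reads}/{self.total_reads} at "
                f"{self.seq_name}:{self.position}"
            )


def compute_f_hat(tally: ContextTally) -> float:
    """Observed-C fraction of context sites, n_c / (n_c + n_t)."""
    denom = tally.n_c_sites + tally.n_t_sites
    if denom <= 0:
        raise EstimationError(
            f"no {tally.context.value} target sites observed"
        )
    return tally.n_c_sites / denom


def estimate_gc(tally: ContextTally) -> float:
    """GC content as twice the G-base frequency, clamped to 1."""
    if tally.n_bases <= 0:
        raise EstimationError("no bases tallied; cannot estimate GC content")
    return min(1.0, 2.0 * tally.n_g / tally.n_bases)


def estimate_m(
    tally: ContextTally,
    p_hat: "float | None" = None,
    site_floor: int = DEFAULT_SITE_FLOOR,
) -> MethylationEstimate:
    """GC-corrected methylation estimate m_hat = f_hat / p_hat.

    If ``p_hat`` is not given it is estimated from the same tally.  Values
    of m_hat above 1 are reported with a warning, never clamped (silent
    clamping would bias downstream calibration fits).
    """
    warnings: list[str] = []
    f_hat = compute_f_hat(tally)
    if p_hat is None:
        raw = 2.0 * tally.n_g / tally.n_bases if tally.n_bases else 0.0
        if raw > 1.0:
            warnings.append(f"raw GC estimate {raw:.4f} > 1 clamped to 1")
        p_hat = estimate_gc(tally)
    if p_hat <= 0:
        raise EstimationError("GC estimate is zero; m_hat undefined")
    m_hat = f_hat / p_hat
    if m_hat > 1.0:
        warnings.append(f"m_hat {m_hat:.4f} exceeds 1 (not clamped)")
    if tally.n_sites < site_floor:
        warnings.append(
            f"only {tally.n_sites} {tally.context.value} sites observed "
            f"(< {site_floor}); estimate may be unstable"
        )
    return MethylationEstimate(
        context=tally.context,
        f_hat=f_hat,
        p_hat=p_hat,
        m_hat=m_hat,
        n_sites=tally.n_sites,
        n_reads=tally.n_reads,
        n_bases=tally.n_bases,
        mode="gc_corrected",
        warnings=warnings,
    )


def direct_mode_m(
    bisulfite_tally: ContextTally,
    genomic_tally: ContextTally,
    base_floor: int = DIRECT_MODE_BASE_FLOOR,
    strict: bool = False,
) -> MethylationEstimate:
    """Direct-measurement estimate from paired genomic + bisulfite reads.

    m_hat = (intact-site frequency in bisulfite reads) /
            (context-site frequency in genomic reads),
    where each frequency is ``n_c_sites / n_bases`` of its tally.  Intact
    sites in bisulfite reads are those that were methylated and escaped
    conversion.
    """
    if bisulfite_tally.context != genomic_tally.context:
        raise ConfigurationError(
            "bisulfite and genomic tallies are for different contexts"
        )
    warnings: list[str] = []
    if genomic_tally.n_bases < base_floor:
        msg = (
            f"genomic reads total {genomic_tally.n_bases} bases "
            f"(< {base_floor}); direct mode may be unreliable"
        )
        if strict:
            raise EstimationError(msg)
        warnings.append(msg)
    if genomic_tally.n_bases <= 0 or bisulfite_tally.n_bases <= 0:
        raise EstimationError("empty tally in direct mode")
    genomic_freq = genomic_tally.n_c_sites / genomic_tally.n_bases
    if genomic_freq <= 0:
        raise EstimationError(
            f"no {genomic_tally.context.value} sites in genomic reads; "
            "direct-mode denominator is zero"
        )
    intact_freq = bisulfite_tally.n_c_sites / bisulfite_tally.n_bases
    m_hat = intact_freq / genomic_freq
    if m_hat > 1.0:
        warnings.append(f"m_hat {m_hat:.4f} exceeds 1 (not clamped)")
    return MethylationEstimate(
        context=bisulfite_tally.context,
        f_hat=intact_freq,
        p_hat=genomic_freq,
        m_hat=m_hat,
        n_sites=bisulfite_tally.n_sites,
        n_reads=bisulfite_tally.n_reads,
        n_bases=bisulfite_tally.n_bases,
        mode="direct",
        warnings=warnings,
    )


_ALLC_COLUMNS = [
    "seq_name", "position", "strand", "context", "mc_reads", "total_reads",
]
_H = set("ACT")


def read_allc(path_or_stream) -> pd.DataFrame:
    """Read an allC-style per-cytosine TSV.

    Expected columns: chrom, 1-based position, strand, 3-letter context,
    methylated read count, total read count, and optionally a binary call
    column (ignored).  A header line is detected and skipped.
    """
    try:
        df = pd.read_csv(
            path_or_stream, sep="\t", header=None, comment="#", dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise AllcParseError("empty allC table") from None
    except pd.errors.ParserError as exc:
        raise AllcParseError(f"malformed allC table: {exc}") from exc
    if df.shape[1] < 6:
        raise AllcParseError(
            f"allC table needs >= 6 columns, found {df.shape[1]}"
        )
    # optional header: second column of first row not an integer
    first = str(df.iloc[0, 1])
    if not re.fullmatch(r"\d+", first):
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise AllcParseError("allC table has a header but no rows")
    df = df.iloc[:, :6].copy()
    df.columns = _ALLC_COLUMNS
    for col, kind in (("position", "position"), ("mc_reads", "mc_reads"),
                      ("total_reads", "total_reads")):
        try:
            df[col] = df[col].astype(np.int64)
        except (TypeError, ValueError) as exc:
            bad = df[~df[col].str.fullmatch(r"\d+", na=False)].index
            line = int(bad[0]) + 1 if len(bad) else "?"
            raise AllcParseError(
                f"line {line}: non-integer {kind} value"
            ) from exc
    if (df["mc_reads"] > df["total_reads"]).any():
        line = int((df["mc_reads"] > df["total_reads"]).idxmax()) + 1
        raise AllcParseError(f"line {line}: mc_reads exceeds total_reads")
    df["context"] = df["context"].str.upper()
    return df


def allc_context_mask(contexts: pd.Series, context: "Context | str",
                      mammal_mode: "bool | None" = None) -> np.ndarray:
    """Boolean mask of 3-letter allC contexts matching a context class.

    CG* -> CPG; C[ACT]G -> CHG; C[ACT][ACT] -> CHH; C[ACT]* -> CH.
    """
    context = as_context(context)
    s = contexts.astype(str).str.upper()
    second = s.str[1]
    third = s.str[2]
    if context is Context.CPG:
        return (second == "G").to_numpy()
    in_h2 = second.isin(_H)
    if context is Context.CH:
        return in_h2.to_numpy()
    if context is Context.CHG:
        return (in_h2 & (third == "G")).to_numpy()
    return (in_h2 & third.isin(_H)).to_numpy()  # CHH


def target_m_from_allc(
    records: "pd.DataFrame | Iterable[AllcRecord]",
    context: "Context | str",
    per_site_binary: bool = False,
    binary_threshold: float = 0.5,
) -> float:
    """Reference-based target methylation level for one context.

    Default is the weighted level sum(mc) / sum(total) over covered sites
    matching the context.  With ``per_site_binary`` each covered site
    instead contributes 0/1 by whether mc/total >= ``binary_threshold``.
    """
    context = as_context(context)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        recs = list(records)
        df = pd.DataFrame(
            [(r.seq_name, r.position, r.strand, r.context, r.mc_reads,
              r.total_reads) for r in recs],
            columns=_ALLC_COLUMNS,
        )
    if df.empty:
        raise EstimationError("no allC records supplied")
    mask = allc_context_mask(df["context"], context)
    sub = df.loc[mask & (df["total_reads"].to_numpy() > 0)]
    if sub.empty:
        raise EstimationError(
            f"no covered {context.value} sites in the allC table"
        )
    if per_site_binary:
        calls = (sub["mc_reads"] / sub["total_reads"]) >= binary_threshold
        return float(calls.mean())
    return float(sub["mc_reads"].sum() / sub["total_reads"].sum())


def adjust_for_nonconversion(m_hat: float, nonconversion_rate: float) -> float:
    """Remove bisulfite nonconversion inflation from an estimate.

    Unconverted unmethylated cytosines inflate the raw estimate as
    E[m_hat] = m + (1 - m) * r; this inverts that law and floors at 0.
    The rate r is estimated in practice from spiked-in unmethylated
    Lambda DNA.
    """
    if not 0.0 <= nonconversion_rate < 1.0:
        raise ConfigurationError(
            f"nonconversion rate must be in [0, 1), got {nonconversion_rate}"
        )
    if m_hat < 0:
        raise ConfigurationError(f"m_hat must be >= 0, got {m_hat}")
    return max(0.0, (m_hat - nonconversion_rate) / (1.0 - nonconversion_rate))


def estimates_to_frame(estimates: Iterable[MethylationEstimate]) -> pd.DataFrame:
    """Flat export table (one row per context estimate)."""
    rows = [
        {
            "context": e.context.value,
            "mode": e.mode,
            "f_hat": e.f_hat,
            "p_hat": e.p_hat,
            "m_hat": e.m_hat,
            "n_sites": e.n_sites,
            "n_reads": e.n_reads,
            "n_bases": e.n_bases,
            "warnings": ";".join(e.warnings),
        }
        for e in estimates
    ]
    return pd.DataFrame(
        rows,
        columns=["context", "mode", "f_hat", "p_hat", "m_hat",
                 "n_sites", "n_reads", "n_bases", "warnings"],
    )
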