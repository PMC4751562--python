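"""Read subsampling and replicate variability.

A genome-wide level is stable from surprisingly few raw reads; the
workflow therefore estimates from a random subsample (default 10,000
reads) and, optionally, from several independent replicates whose spread
(standard error of m_hat) quantifies sampling stability.

Replicates are independent draws from the full pool, not a partition:
each replicate samples without replacement internally but replicates may
overlap each other.  Child randomness for replicate ``i`` comes from
``SeedSequence([master_seed, i])``, so any replicate is replayable in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contexts import ALL_CONTEXTS, Context, as_context, tally_reads
from .errors import SamplingError
from .estimate import DEFAULT_SITE_FLOOR, MethylationEstimate, estimate_m

__all__ = [
    "SubsampleSpec",
    "replicate_rng",
    "sample_without_replacement",
    "reservoir_sample",
    "replicate_estimates",
]


@dataclass(frozen=True)
class SubsampleSpec:
    n_reads: int = 10_000
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    """Deterministic child generator for one replicate."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(replicate_index)])
    )


def sample_without_replacement(
    reads: Sequence, spec: SubsampleSpec, replicate_index: int = 0
) -> list:
    """Uniform sample of ``spec.n_reads`` distinct reads.

    Deterministic given (seed, replicate_index, input order).
    """
    total = len(reads)
    if spec.n_reads > total:
        raise SamplingError(
            f"requested {spec.n_reads} reads but only {total} available"
        )
    rng = replicate_rng(spec.seed, replicate_index)
    idx = rng.choice(total, size=spec.n_reads, replace=False, shuffle=False)
    return [reads[i] for i in idx]


def reservoir_sample(reads: Iterable, n: int,
                     rng: np.random.Generator) -> list:
    """Single-pass uniform sample without replacement (for streams whose
    size is unknown up front).  Raises if the stream has fewer than n items."""
    reservoir: list = []
    for i, read in enumerate(reads):
        if i < n:
            reservoir.append(read)
        else:
            j = int(rng.integers(0, i + 1))
            if j < n:
                reservoir[j] = read
    if len(reservoir) < n:
        raise SamplingError(
            f"requested {n} reads but only {len(reservoir)} available"
        )
    return reservoir


def replicate_estimates(
    reads: Sequence,
    spec: SubsampleSpec,
    contexts: Iterable = ALL_CONTEXTS,
    read2_mode: bool = False,
    site_floor: int = DEFAULT_SITE_FLOOR,
) -> tuple[list[dict[Context, MethylationEstimate]], pd.DataFrame]:
    """GC-corrected estimates over independent subsample replicates.

    Returns per-replicate estimates and a per-context summary with the
    mean and standard error of m_hat (se = sample sd / sqrt(replicates);
    absent when replicates == 1).
    """
    ctxs = tuple(as_context(c) for c in contexts)
    per_replicate: list[dict[Context, MethylationEstimate]] = []
    for r in range(spec.replicates):
        subset = sample_without_replacement(reads, spec, replicate_index=r)
        tallies = tally_reads(subset, ctxs, read2_mode=read2_mode)
        per_replicate.append(
            {c: estimate_m(tallies[c], site_floor=site_floor) for c in ctxs}
        )
    rows = []
    for c in ctxs:
        values = np.array([rep[c].m_hat for rep in per_replicate])
        if spec.replicates > 1:
            sd = float(values.std(ddof=1))
            se = sd / np.sqrt(spec.replicates)
        else:
            sd = np.nan
            se = np.nan
        rows.append({
            "context": c.value,
            "replicates": spec.replicates,
            "n_reads": spec.n_reads,
            "mean_m_hat": float(values.mean()),
            "sd_m_hat": sd,
            "se_m_hat": se,
        })
    summary = pd.DataFrame(
        rows, columns=["context", "replicates", "n_reads",
                       "mean_m_hat", "sd_m_hat", "se_m_hat"]
    )
    return per_replicate, summary
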