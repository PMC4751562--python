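"""Bisulfite sequencing simulator.

Generates, from a parameter set and a seed, everything the estimator needs
for end-to-end testing without external data:

* a random double-stranded genome of chosen GC content (bases i.i.d. with
  P(G) = P(C) = p/2, optionally with a first-order CpG-depletion pass to
  mimic the mammalian depletion of CpG dinucleotides outside islands),
* per-cytosine context labels and Bernoulli methylation states per
  context-specific level,
* bisulfite-converted reads: uniform strand and start, unmethylated C
  written as T unless it escapes conversion (nonconversion rate r),
  methylated C retained unless hit by the methylated-conversion failure
  rate, then independent substitution sequencing errors; constant Q40
  qualities,
* fully unmethylated contaminant reads from an independent genome, mixed
  in at an expected fraction (the unmethylated-organelle contamination
  scenario),
* a matching per-cytosine truth table in allC layout, whose weighted
  level equals the realized simulated methylation exactly under the
  noiseless coverage model.

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .contexts import Context
from .errors import ConfigurationError
from .seqio import SequenceRead, write_fastq

__all__ = [
    "BsSimConfig",
    "SimulatedGenome",
    "simulate_genome",
    "assign_methylation",
    "emit_reads",
    "truth_allc_frame",
    "write_truth_allc",
    "simulate_dataset",
]

# base codes: A=0 C=1 G=2 T=3
_A, _C, _G, _T = 0, 1, 2, 3
_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
# context codes on the cytosine's own strand, 5'->3'
CTX_CG, CTX_CHG, CTX_CHH, CTX_NA = 0, 1, 2, -1


@dataclass(frozen=True)
class BsSimConfig:
    """Full truth specification for one simulated dataset."""

    genome_length: int = 500_000
    gc_content: float = 0.40
    methylation: Mapping[str, float] = field(
        default_factory=lambda: {"CPG": 0.24, "CHG": 0.10, "CHH": 0.05}
    )
    nonconversion_rate: float = 0.0   # unmethylated C retained as C
    methylated_conversion_rate: float = 0.0  # methylated C read as T
    sequencing_error: float = 0.0     # per-base substitution probability
    read_length: int = 50
    n_reads: int = 10_000
    contamination_fraction: float = 0.0
    contaminant_gc: "float | None" = None  # defaults to genome GC
    cpg_depletion: float = 0.0  # 0 = i.i.d.; 1 = no CG on forward strand
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "gc_content": self.gc_content,
            "nonconversion_rate": self.nonconversion_rate,
            "methylated_conversion_rate": self.methylated_conversion_rate,
            "sequencing_error": self.sequencing_error,
            "contamination_fraction": self.contamination_fraction,
            "cpg_depletion": self.cpg_depletion,
            **{f"m[{k}]": v for k, v in self.methylation.items()},
        }
        if self.contaminant_gc is not None:
            rates["contaminant_gc"] = self.contaminant_gc
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.read_length > self.genome_length:
            raise ConfigurationError("read_length exceeds genome_length")
        if self.read_length < 1 or self.n_reads < 0 or self.genome_length < 1:
            raise ConfigurationError("sizes must be positive")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["methylation"] = dict(self.methylation)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class StrandTruth:
    """Cytosine positions and states on one strand (its own 5'->3' frame)."""

    c_pos: np.ndarray   # indices of C in the strand sequence
    ctx3: np.ndarray    # CTX_CG / CTX_CHG / CTX_CHH / CTX_NA
    is_ch: np.ndarray   # di-context: next base defined and != G
    meth: "np.ndarray | None" = None  # bool per cytosine once assigned


@dataclass
class SimulatedGenome:
    """A genome, its per-cytosine truth, and the config that produced it."""

    config: BsSimConfig
    forward: np.ndarray          # uint8 codes
    fwd: StrandTruth
    rev: StrandTruth

    @property
    def reverse(self) -> np.ndarray:
        """Reverse-complement strand, 5'->3' (code complement is 3 - code)."""
        return (3 - self.forward[::-1]).astype(np.uint8)

    @property
    def length(self) -> int:
        return int(self.forward.size)

    def forward_string(self) -> str:
        return _ASCII[self.forward].tobytes().decode("ascii")

    def realized_levels(self) -> dict[Context, float]:
        """True per-context methylated fractions actually realized.

        CH pools all non-CpG cytosines (it is the mammal-mode complement
        of CpG), so with distinct CHG/CHH inputs its realized level is
        their site-weighted mixture.
        """
        if self.fwd.meth is None:
            raise ConfigurationError("methylation states not assigned yet")
        out: dict[Context, float] = {}
        for context, picker in (
            (Context.CPG, lambda s: s.ctx3 == CTX_CG),
            (Context.CHG, lambda s: s.ctx3 == CTX_CHG),
            (Context.CHH, lambda s: s.ctx3 == CTX_CHH),
            (Context.CH, lambda s: s.is_ch),
        ):
            num = 0
            den = 0
            for strand in (self.fwd, self.rev):
                mask = picker(strand)
                num += int(strand.meth[mask].sum())
                den += int(mask.sum())
            out[context] = num / den if den else float("nan")
        return out

    def realized_gc(self) -> float:
        return float(np.isin(self.forward, (_C, _G)).mean())


def _iid_genome(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs).astype(np.uint8)


def _deplete_cpg(seq: np.ndarray, gc: float, depletion: float,
                 rng: np.random.Generator) -> np.ndarray:
    """First-order pass: after each C, the next base is redrawn with P(G)
    scaled by (1 - depletion) and the remainder renormalized."""
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    after_c = base_p.copy()
    after_c[_G] *= 1.0 - depletion
    after_c /= after_c.sum()
    cum = np.cumsum(after_c)
    u = rng.random(seq.size)
    out = seq.copy()
    for i in range(1, seq.size):  # sequential: state is "previous base is C"
        if out[i - 1] == _C:
            out[i] = np.searchsorted(cum, u[i], side="right")
    return out


def _label_strand(seq: np.ndarray) -> StrandTruth:
    length = seq.size
    c_pos = np.flatnonzero(seq == _C)
    n = c_pos.size
    ctx3 = np.full(n, CTX_NA, dtype=np.int8)
    nxt = np.full(n, -1, dtype=np.int8)
    nxt2 = np.full(n, -1, dtype=np.int8)
    has1 = c_pos <= length - 2
    has2 = c_pos <= length - 3
    nxt[has1] = seq[c_pos[has1] + 1]
    nxt2[has2] = seq[c_pos[has2] + 2]
    is_cg = has1 & (nxt == _G)
    is_ch = has1 & (nxt != _G)
    ctx3[is_cg] = CTX_CG
    ctx3[is_ch & has2 & (nxt2 == _G)] = CTX_CHG
    ctx3[is_ch & has2 & (nxt2 != _G)] = CTX_CHH
    return StrandTruth(c_pos=c_pos, ctx3=ctx3, is_ch=is_ch)


def simulate_genome(config: BsSimConfig,
                    rng: "np.random.Generator | None" = None) -> SimulatedGenome:
    """Draw a random genome and label every cytosine's context on both strands."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    seq = _iid_genome(config.genome_length, config.gc_content, rng)
    if config.cpg_depletion > 0:
        seq = _deplete_cpg(seq, config.gc_content, config.cpg_depletion, rng)
    genome = SimulatedGenome(
        config=config,
        forward=seq,
        fwd=_label_strand(seq),
        rev=_label_strand((3 - seq[::-1]).astype(np.uint8)),
    )
    return genome


def _context_probs(config: BsSimConfig) -> tuple[float, float, float, float]:
    m = {str(k).upper(): float(v) for k, v in config.methylation.items()}
    if "CG" in m and "CPG" not in m:
        m["CPG"] = m["CG"]
    m_cg = m.get("CPG", 0.0)
    m_chg = m.get("CHG", m.get("CH", 0.0))
    m_chh = m.get("CHH", m.get("CH", 0.0))
    # non-CpG cytosine too close to the strand end to resolve CHG vs CHH
    m_ch_edge = m.get("CH", m_chh)
    return m_cg, m_chg, m_chh, m_ch_edge


def assign_methylation(genome: SimulatedGenome,
                       rng: "np.random.Generator | None" = None) -> SimulatedGenome:
    """Independently methylate each cytosine at its context's level (in place)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([genome.config.seed, 1]))
    m_cg, m_chg, m_chh, m_ch_edge = _context_probs(genome.config)
    for strand in (genome.fwd, genome.rev):
        # strand-edge cytosines (truncated context) fall back to the CH level
        prob = np.full(strand.c_pos.size, m_ch_edge)
        prob[strand.ctx3 == CTX_CG] = m_cg
        prob[strand.ctx3 == CTX_CHG] = m_chg
        prob[strand.ctx3 == CTX_CHH] = m_chh
        strand.meth = rng.random(strand.c_pos.size) < prob
    return genome


def _meth_mask(length: int, truth: StrandTruth) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    if truth.meth is not None:
        mask[truth.c_pos[truth.meth]] = True
    return mask


def _emit_windows(seq: np.ndarray, meth_mask: np.ndarray, starts: np.ndarray,
                  read_length: int, config: BsSimConfig,
                  rng: np.random.Generator, bisulfite: bool) -> np.ndarray:
    idx = starts[:, None] + np.arange(read_length)
    bases = seq[idx].copy()
    if bisulfite:
        is_c = bases == _C
        meth = meth_mask[idx]
        u = rng.random(bases.shape)
        to_t = (is_c & ~meth & (u >= config.nonconversion_rate)) | (
            is_c & meth & (u < config.methylated_conversion_rate)
        )
        bases[to_t] = _T
    if config.sequencing_error > 0:
        hit = rng.random(bases.shape) < config.sequencing_error
        shift = rng.integers(1, 4, size=int(hit.sum()))
        bases[hit] = (bases[hit] + shift) % 4
    return bases


def emit_reads(
    genome: SimulatedGenome,
    rng: "np.random.Generator | None" = None,
    n_reads: "int | None" = None,
    bisulfite: bool = True,
) -> tuple[list[SequenceRead], pd.DataFrame]:
    """Emit reads (and a provenance table) from a methylated genome.

    Each read picks a strand uniformly and a uniform start, copies bases
    5'->3' from that strand, then applies bisulfite conversion and
    sequencing error.  With ``bisulfite=False`` the genome is read
    untreated (the "additional genomic short read data" of direct mode);
    contamination only applies to bisulfite samples.  Read names encode
    origin, strand and start for truth tracking.
    """
    config = genome.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_reads if n_reads is None else int(n_reads)
    rl = config.read_length
    if bisulfite and (genome.fwd.meth is None):
        raise ConfigurationError("assign_methylation must run before emit_reads")

    frac = config.contamination_fraction if bisulfite else 0.0
    is_cont = rng.random(n) < frac
    strands = rng.integers(0, 2, size=n)  # 0 = forward, 1 = reverse

    length = genome.length
    fwd = genome.forward
    rev = genome.reverse
    meth_fwd = _meth_mask(length, genome.fwd)
    meth_rev = _meth_mask(length, genome.rev)

    if is_cont.any():
        cont_gc = (config.contaminant_gc if config.contaminant_gc is not None
                   else config.gc_content)
        cont = _iid_genome(length, cont_gc, rng)
        cont_rev = (3 - cont[::-1]).astype(np.uint8)
        no_meth = np.zeros(length, dtype=bool)
    starts = rng.integers(0, length - rl + 1, size=n)

    out = np.empty((n, rl), dtype=np.uint8)
    groups = [
        (~is_cont & (strands == 0), fwd, meth_fwd),
        (~is_cont & (strands == 1), rev, meth_rev),
    ]
    if is_cont.any():
        groups += [
            (is_cont & (strands == 0), cont, no_meth),
            (is_cont & (strands == 1), cont_rev, no_meth),
        ]
    for sel, seq, mask in groups:
        if sel.any():
            out[sel] = _emit_windows(seq, mask, starts[sel], rl, config, rng,
                                     bisulfite)

    ascii_rows = _ASCII[out].tobytes().decode("ascii")
    quals = np.full(rl, 40, dtype=np.int16)
    tag = "bs" if bisulfite else "gen"
    reads: list[SequenceRead] = []
    origin = np.where(is_cont, "contaminant", "sample")
    strand_sym = np.where(strands == 0, "+", "-")
    for i in range(n):
        name = f"{tag}{i:06d}|{origin[i]}|{strand_sym[i]}|{starts[i]}"
        reads.append(SequenceRead(name, ascii_rows[i * rl:(i + 1) * rl], quals))
    provenance = pd.DataFrame(
        {"read_id": [r.read_id for r in reads], "origin": origin,
         "strand": strand_sym, "start": starts}
    )
    return reads, provenance


def _context_strings(seq: np.ndarray, c_pos: np.ndarray) -> np.ndarray:
    # 3-letter context of each cytosine, padded with N at the strand end
    lut = np.array(list("ACGTN"))
    padded = np.concatenate([seq, np.full(2, 4, dtype=np.uint8)])
    l1 = lut[padded[c_pos]]
    l2 = lut[padded[c_pos + 1]]
    l3 = lut[padded[c_pos + 2]]
    return np.char.add(np.char.add(l1, l2), l3)


def truth_allc_frame(
    genome: SimulatedGenome,
    coverage: int = 10,
    noisy: bool = False,
    noise_error: float = 0.01,
    rng: "np.random.Generator | None" = None,
) -> pd.DataFrame:
    """Per-cytosine truth in allC layout (both strands, 1-based forward
    coordinates, context read 5'->3' on the cytosine's own strand).

    Noiseless (default): every site gets ``total = coverage`` and
    ``mc = coverage * state``, so the weighted level over any context
    equals the realized methylated fraction exactly.  With ``noisy`` the
    methylated read count is Binomial(coverage, state +- noise_error).
    """
    if genome.fwd.meth is None:
        raise ConfigurationError("assign_methylation must run first")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([genome.config.seed, 3]))
    length = genome.length
    parts = {"pos": [], "strand": [], "context": [], "state": []}
    for strand_code, seq, truth in (
        (0, genome.forward, genome.fwd),
        (1, genome.reverse, genome.rev),
    ):
        if strand_code == 0:
            pos = truth.c_pos + 1
        else:  # reverse index j sits at forward coordinate length - j
            pos = length - truth.c_pos
        parts["pos"].append(pos.astype(np.int64))
        parts["strand"].append(np.full(pos.size, strand_code, dtype=np.int8))
        parts["context"].append(_context_strings(seq, truth.c_pos))
        parts["state"].append(truth.meth.astype(np.int64))
    pos = np.concatenate(parts["pos"])
    strand = np.concatenate(parts["strand"])
    context = np.concatenate(parts["context"])
    state = np.concatenate(parts["state"])
    order = np.lexsort((strand, pos))
    pos, strand, context, state = (
        pos[order], strand[order], context[order], state[order]
    )
    total = np.full(state.size, coverage, dtype=np.int64)
    if noisy:
        p = np.where(state == 1, 1.0 - noise_error, noise_error)
        mc = rng.binomial(total, p)
    else:
        mc = coverage * state
    return pd.DataFrame({
        "seq_name": "chr1",
        "position": pos,
        "strand": np.where(strand == 0, "+", "-"),
        "context": context,
        "mc_reads": mc,
        "total_reads": total,
        "binary": state,
    })


def write_truth_allc(genome: SimulatedGenome, path, **kwargs) -> pd.DataFrame:
    """Write the truth table as a headerless allC TSV; returns the frame."""
    df = truth_allc_frame(genome, **kwargs)
    df.to_csv(path, sep="\t", index=False, header=False)
    return df


def simulate_dataset(
    config: BsSimConfig,
    out_prefix: "str | Path | None" = None,
) -> dict:
    """Full pipeline: genome -> methylation -> reads (+ genomic reads) -> truth.

    Returns a dict with the genome, reads, provenance, truth frame and
    realized levels; if ``out_prefix`` is given, also writes
    ``<prefix>.fastq``, ``<prefix>.allc.tsv`` and ``<prefix>.config.json``.
    """
    genome = assign_methylation(simulate_genome(config))
    reads, provenance = emit_reads(genome)
    truth = truth_allc_frame(genome)
    result = {
        "genome": genome,
        "reads": reads,
        "provenance": provenance,
        "truth": truth,
        "realized_levels": genome.realized_levels(),
        "realized_gc": genome.realized_gc(),
    }
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_fastq(reads, Path(f"{prefix}.fastq"))
        truth.to_csv(f"{prefix}.allc.tsv", sep="\t", index=False, header=False)
        Path(f"{prefix}.config.json").write_text(config.to_json() + "\n")
    return result
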