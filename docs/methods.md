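# Methods

## Model

Let *m* be the genome-wide fraction of cytosines in a given sequence
context (CpG, CHG, CHH with H ∈ {A,C,T}, or the mammalian non-CpG pool
CH) that are methylated, and *p* the genomic GC content. In bisulfite
reads every unmethylated C reads as T, so the reference-based definition

  m = ΣCm / Σ(Cm + Cu)

cannot be evaluated directly: T-start windows conflate converted
cytosines with true thymines. The reference-free estimator counts, over
every window of every read,

  F̂ = ΣsCm / Σs(Cm + C?)

where the numerator is C-start windows matching the context pattern and
C? pools converted cytosines and true thymines (T-start windows with the
same pattern tail). Under three assumptions — (i) context cytosines are
methylated independently at rate m, (ii) T-start context windows are
either converted cytosines or true thymines, (iii) bases are i.i.d. with
P(G) = P(C) = p/2 — the expected window frequencies give E[F̂] ≈ m·p for
every context (the context-tail factors cancel between numerator and
denominator because H = {A,C,T} is closed under C→T conversion). G bases
are untouched by conversion, so p is estimated as p̂ = 2 × (G frequency),
and m̂ = F̂/p̂ estimates m.

Two further estimators share the surface:

* **Direct mode** replaces assumption (iii) by measurement: with
  non-converted genomic reads (recommended ≥ 500,000 bp; below that a
  warning, or an error in strict mode), m̂ = (intact-context-site
  frequency in bisulfite reads) / (context-site frequency in genomic
  reads). Intact sites are those that were methylated and escaped
  conversion.
* **Reference-based target** levels are computed from per-cytosine
  ("allC") tables as the read-weighted level Σmc/Σtotal over covered
  sites in the context; a per-site binary variant (fraction of sites
  with mc/total ≥ 0.5) is available behind a flag, since both readings
  of "proportion of methylated cytosines" occur in practice.

Bisulfite nonconversion at rate r inflates the estimate as
E[m̂] = m + (1−m)·r; `adjust_for_nonconversion` inverts this law
(flooring at 0). The adjustment is off by default — r must come from an
external control such as spiked-in unmethylated Lambda DNA — and the
plain estimate is reported unless the user supplies r.

## Window-tallying conventions

* Windows are scanned at every offset; overlapping windows count
  independently ("CCG" contributes one CHG site and one CpG site), since
  each cytosine is its own potential methylation site.
* Context classes are evaluated on observed bases. This is
  conversion-stable: conversion maps C→T within H and never creates or
  destroys a G, so a window's class is the same before and after
  treatment.
* N matches no base class; a window containing N is skipped entirely,
  while N-free bases still count toward the G and base totals. Positions
  too close to the read end to head a window still count toward those
  totals (the denominator n of the GC estimate is total sequenced
  bases).
* Read 2 of a directional library observes the complement of the
  converted strand; `read2_mode` reverse-complements reads before
  tallying. Non-directional (PBAT-style) libraries are not modeled.
* C-start windows are included in the estimator denominator by
  construction (F̂'s denominator is all context sites, observed C or T).

## Filtering and subsampling

Reads are retained when at least 30 bp long with ≥ 20 % of bases at or
above the quality threshold. The threshold unit is genuinely ambiguous in
the tooling tradition this rule comes from ("quality ≥ 75 %"); we read it
as 75 % of the Phred-40 ceiling, i.e. Q30, and expose it as a
configurable `FilterPolicy` field alongside the Phred offset (33 default,
64 optional). N bases never count toward the passing numerator but do
count toward length — a conservative, deterministic choice.

Subsampling is exact uniform sampling without replacement
(`numpy.Generator.choice`), deterministic given (seed, replicate index,
input order); a reservoir variant serves unsized streams. Replicates are
independent draws, not a partition, matching the "k replicates of n
reads" design; replicate i uses the child generator
`SeedSequence([seed, i])`, so any replicate is replayable alone. The
replicate summary reports the mean and standard error
(sd/√replicates) of m̂ per context.

## Calibration

Ordinary least squares of target on estimate (via
`scipy.stats.linregress`) per context and species class, scored by MAPE
over the fitted values; pairs with a zero target are excluded from MAPE
(near-zero methylomes would dominate the average) and counted in a
warning. The shipped default model is the identity for every
context/class: on random genomes the GC-corrected estimate already sits
near the 1:1 line, and shipping fabricated species coefficients would be
worse than shipping none. Model files are plain-text key-value blocks
with a versioned header — diffable and language-neutral. Model selection
is exact on (context, class), falls back to (context, general) with a
warning, and never crosses contexts. We standardize on regressing the
target on the GC-corrected estimate; confidence bands are display-level
and out of the core contract.

## Simulator

`bssim` generates the study conditions end to end:

* **Genome**: bases i.i.d. with P(G) = P(C) = p/2 on a single linear
  chromosome (default 500 kb, GC 0.40). An optional CpG-depletion knob
  re-draws the base after each C with P(G) scaled by (1 − depletion),
  emulating mammalian CpG depletion; at 1.0 the forward strand has no
  CpG.
* **Methylation truth**: every cytosine on both strands is labeled with
  its context read 5'→3' on its own strand and methylated independently
  at its context's level. Defaults (CpG 0.24, CHG 0.10, CHH 0.05 at GC
  0.40) are typical flowering-plant genome-wide levels, the best-studied
  case for context-specific methylation. Strand-edge cytosines with
  truncated context fall back to the CH level; they are excluded from
  realized-level bookkeeping and carry N-padded context strings in the
  truth table, so no context class claims them.
* **Reads**: uniform strand and start, 50 bp, constant Q40 qualities;
  unmethylated C → T except with probability r (nonconversion);
  methylated C retained except for an optional failure rate; then
  independent substitution errors. Contaminant reads come from an
  independent, fully unmethylated i.i.d. genome at their own GC content
  and are mixed in at an expected fraction f — the scenario of
  unmethylated organelle reads contaminating a sample. Read names encode
  origin, strand and start.
* **Truth tables**: allC layout (chrom, 1-based position, strand,
  3-letter context, mc, total, binary), default constant coverage 10;
  noiselessly, the weighted level over any context equals the realized
  methylated fraction exactly, which pins the target-side computations.
  A noisy option draws mc ~ Binomial(coverage, state ± ε).
* Identical config + seed ⇒ byte-identical FASTQ and truth outputs;
  genome, methylation, reads and truth each use fixed child seeds of the
  config seed.

What the simulator does **not** emulate: fragment-size and PCR-duplicate
structure, position-dependent quality and error profiles, bisulfite
degradation, real organelle sequence composition, CpG-island spatial
clustering (beyond the depletion knob), and paired-end mechanics (read-2
fixtures are made by reverse-complementing emitted reads). Passing tests
therefore establish correctness of the estimator under its own model
assumptions and robustness laws — not performance on any particular real
library.

## Numerical and testing choices

* f̂ with an empty site denominator, p̂ with zero bases, direct mode with
  zero genomic site frequency: hard errors. m̂ > 1 and raw p̂ > 1 are
  warned (the former never clamped — silent clamping would bias
  calibration fits; the latter clamped to 1 with a warning). Fewer than
  1,000 observed sites attaches a low-evidence warning, not an error:
  degraded inputs still return diagnostics.
* Test problem sizes: estimator-recovery checks run 500 kb genomes with
  10,000 × 50 bp reads over GC ∈ {0.30, 0.40, 0.50} and m ∈ {0, 0.05,
  0.30, 0.70, 1.0}; replicate-stability checks use a 100,000-read pool.
  Sampling checks compare the streaming tally against a brute-force
  window-enumeration oracle, and read-level expectations against a
  deterministic full-genome conversion oracle (the population window
  ratio, which is the read-sampling expectation of F̂ for a fixed
  genome), with binomial 3-standard-error bounds.
* Known limitations: 5-methylcytosine and 5-hydroxymethylcytosine are
  indistinguishable by bisulfite conversion, so levels represent their
  sum; genomes violating the random-base assumption (strong CpG
  depletion, extreme isochore structure) bias the GC-corrected route —
  use direct mode or a class-specific calibration model; the estimator
  targets genome-wide levels only, never per-locus calls.
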