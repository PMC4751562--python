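# rawmeth

Reference-free estimation of genome-wide, context-specific DNA methylation
levels from raw whole-genome bisulfite sequencing (WGBS) reads.

Most WGBS analysis requires aligning reads to a reference genome so that a
T observed at a cytosine reference position can be called an unmethylated
(converted) cytosine. For the majority of species no assembly exists, and
for large genomes deep sequencing purely to measure a *genome-wide* level
is wasteful. `rawmeth` estimates that level per cytosine context — CpG,
CHG, CHH (plants) and CH (mammals), with H ∈ {A, C, T} — directly from a
few thousand raw reads, no reference needed. It is aimed at comparative
epigenomics across species without assemblies, and at cheap screening of
time-course, developmental or mutant panels.

## The estimator

Bisulfite treatment converts unmethylated C to T and leaves methylated C
(and all other bases) untouched. For a context such as CpG, scan every
read position and count windows:

```
F̂ = Σs Cm / Σs (Cm + C?)
```

where `Σs Cm` counts windows whose first base reads **C** (a methylated,
protected cytosine) and `Σs C?` counts the analogous **T**-start windows —
converted cytosines and true thymines, indistinguishable without a
reference. Under the model assumptions (context cytosines methylated at
rate *m*, T-start windows are conversions or true thymines, bases randomly
distributed), the expectation of F̂ is *m·p*, with *p* the genomic GC
content: the estimator confounds methylation with base composition. Since
G is untouched by conversion and strand-symmetric, *p* is estimated as
twice the G frequency of the reads, and

```
m̂ = F̂ / p̂
```

recovers the level. With ≥ 500,000 bp of ordinary genomic reads available,
a *direct mode* instead divides the intact-context-site frequency of the
bisulfite reads by the measured genomic site frequency, dropping the
random-genome assumption. Linear calibration models (`calibrate` module)
map m̂ onto reference-based target levels per context and species class
(general / plant / mammal — mammalian CpG depletion violates the
random-base assumption and benefits from its own model), scored by mean
absolute percentage error (MAPE). A bisulfite read simulator (`bssim`)
with per-cytosine truth tables makes every claim testable end to end.

## Worked example

`examples/estimate_from_raw_reads.py` simulates a 200 kb genome (GC 0.40)
with plant-like methylation, emits 10,000 × 50 bp bisulfite reads, and
estimates the levels back:

```
simulated genome: 200,000 bp, GC 0.400, 10,000 reads
context       F^      p^      m^  true m
CPG       0.2814  0.4013  0.7012  0.6979
CHG       0.1185  0.4013  0.2954  0.2973
CHH       0.0194  0.4013  0.0483  0.0489
CH        0.0393  0.4013  0.0980  0.0993
```

Per context: `F^` is the raw observed-C fraction of context windows
(≈ m·p: 0.70 × 0.40 ≈ 0.28 for CpG), `p^` the GC content recovered from
the reads' G frequency, and `m^ = F^/p^` the corrected level, matching the
simulation truth to a few thousandths. The other example scripts cover
direct mode, fitting calibration models, and robustness to contamination
and nonconversion.

The same pipeline is available from the shell:

```bash
rawmeth simulate --genome-length 200000 --m-cpg 0.7 --seed 42 --out-prefix sim
rawmeth estimate sim.fastq --n-reads 10000 --seed 1 --out estimates.tsv
rawmeth target sim.allc.tsv          # reference-based levels from the truth table
```

`rawmeth estimate` filters reads (≥ 30 bp with ≥ 20 % of bases at Q30, all
configurable), subsamples without replacement, tallies contexts and writes
a TSV of estimates with a reproducibility header.

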