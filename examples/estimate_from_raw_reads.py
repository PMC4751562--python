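"""Estimate genome-wide methylation levels from raw bisulfite reads.

Simulates a 200 kb genome (GC 0.40) with plant-like methylation
(CpG 0.70, CHG 0.30, CHH 0.05), emits 10,000 x 50 bp bisulfite reads,
and estimates the levels back without ever aligning to the genome.
"""

from rawmeth import BsSimConfig, estimate_m, tally_reads
from rawmeth.bssim import assign_methylation, emit_reads, simulate_genome

config = BsSimConfig(
    genome_length=200_000,
    gc_content=0.40,
    methylation={"CPG": 0.70, "CHG": 0.30, "CHH": 0.05},
    n_reads=10_000,
    read_length=50,
    seed=42,
)
genome = assign_methylation(simulate_genome(config))
reads, _ = emit_reads(genome)
realized = genome.realized_levels()

print(f"simulated genome: {config.genome_length:,} bp, "
      f"GC {genome.realized_gc():.3f}, {len(reads):,} reads")
print(f"{'context':8} {'F^':>7} {'p^':>7} {'m^':>7} {'true m':>7}")
tallies = tally_reads(reads)
for context, tally in tallies.items():
    est = estimate_m(tally)
    print(f"{context.value:8} {est.f_hat:7.4f} {est.p_hat:7.4f} "
          f"{est.m_hat:7.4f} {realized[context]:7.4f}")
print()
print("F^ is the observed-C fraction of context sites in the reads; its")
print("expectation is m x p, so dividing by the GC estimate p^ (twice the")
print("G frequency) recovers the true methylation level m per context.")
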