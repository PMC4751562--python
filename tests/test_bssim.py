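import io

import numpy as np
import pytest

from rawmeth.bssim import (
    BsSimConfig,
    assign_methylation,
    emit_reads,
    simulate_dataset,
    simulate_genome,
    truth_allc_frame,
    write_truth_allc,
)
from rawmeth.contexts import ALL_CONTEXTS, Context, tally_reads
from rawmeth.errors import ConfigurationError
from rawmeth.estimate import read_allc, target_m_from_allc
from rawmeth.seqio import write_fastq


class TestConfig:
    def test_rates_validated(self):
        with pytest.raises(ConfigurationError):
            BsSimConfig(gc_content=1.5)
        with pytest.raises(ConfigurationError):
            BsSimConfig(methylation={"CPG": -0.1})
        with pytest.raises(ConfigurationError):
            BsSimConfig(genome_length=10, read_length=20)

    def test_json_echo_round_trips(self):
        import json

        config = BsSimConfig(seed=9, methylation={"CPG": 0.3})
        data = json.loads(config.to_json())
        assert data["seed"] == 9 and data["methylation"] == {"CPG": 0.3}


class TestGenome:
    def test_all_gc_boundary(self):
        g = simulate_genome(BsSimConfig(genome_length=500, gc_content=1.0,
                                        read_length=50))
        assert set(g.forward_string()) <= {"C", "G"}
        assert g.realized_gc() == 1.0

    def test_realized_gc_within_binomial_bound(self):
        L, p = 200_000, 0.4
        g = simulate_genome(BsSimConfig(genome_length=L, gc_content=p, seed=2))
        assert abs(g.realized_gc() - p) <= 3 * np.sqrt(p * (1 - p) / L)

    def test_depletion_knob_at_maximum_removes_cg(self):
        g = simulate_genome(
            BsSimConfig(genome_length=20_000, gc_content=0.5, cpg_depletion=1.0,
                        seed=3)
        )
        assert "CG" not in g.forward_string()

    def test_strand_labels_agree_with_string_scan(self):
        g = simulate_genome(BsSimConfig(genome_length=3_000, seed=4))
        s = g.forward_string()
        cg = [i for i in range(len(s) - 1) if s[i : i + 2] == "CG"]
        fwd_cg = g.fwd.c_pos[g.fwd.ctx3 == 0]
        assert list(fwd_cg) == cg

    def test_reverse_strand_is_reverse_complement(self):
        from rawmeth.contexts import reverse_complement

        g = simulate_genome(BsSimConfig(genome_length=300, seed=5))
        from rawmeth.bssim import _ASCII

        rev = _ASCII[g.reverse].tobytes().decode()
        assert rev == reverse_complement(g.forward_string())


class TestMethylationAssignment:
    @pytest.mark.parametrize("level", [0.0, 1.0])
    def test_all_or_nothing(self, level):
        config = BsSimConfig(
            genome_length=5_000,
            methylation={"CPG": level, "CHG": level, "CHH": level, "CH": level},
            seed=6,
        )
        g = assign_methylation(simulate_genome(config))
        for strand in (g.fwd, g.rev):
            # the final C of a strand has no context and stays unmethylated
            scorable = strand.ctx3 >= 0
            assert strand.meth[scorable].all() == bool(level)
        for v in g.realized_levels().values():
            assert v == level

    def test_realized_fraction_within_binomial_bound(self):
        config = BsSimConfig(genome_length=400_000, methylation={"CPG": 0.7},
                             seed=7)
        g = assign_methylation(simulate_genome(config))
        n_cpg = int((g.fwd.ctx3 == 0).sum() + (g.rev.ctx3 == 0).sum())
        assert n_cpg > 10_000
        se = np.sqrt(0.7 * 0.3 / n_cpg)
        assert abs(g.realized_levels()[Context.CPG] - 0.7) <= 3 * se

    def test_ch_level_is_site_weighted_mixture(self):
        config = BsSimConfig(genome_length=200_000,
                             methylation={"CPG": 0.9, "CHG": 0.4, "CHH": 0.1},
                             seed=8)
        g = assign_methylation(simulate_genome(config))
        levels = g.realized_levels()
        assert min(0.1, 0.4) <= levels[Context.CH] <= max(0.1, 0.4)


class TestEmitReads:
    def test_complete_conversion_leaves_no_c(self):
        config = BsSimConfig(genome_length=10_000, methylation={}, n_reads=300,
                             seed=9)
        g = assign_methylation(simulate_genome(config))
        reads, _ = emit_reads(g)
        assert all("C" not in r.bases for r in reads)

    def test_no_conversion_yields_verbatim_substrings(self):
        config = BsSimConfig(
            genome_length=10_000,
            methylation={"CPG": 1.0, "CHG": 1.0, "CHH": 1.0},
            n_reads=100, seed=10,
        )
        g = assign_methylation(simulate_genome(config))
        reads, prov = emit_reads(g)
        fwd = g.forward_string()
        from rawmeth.contexts import reverse_complement

        rev = reverse_complement(fwd)
        for read, strand, start in zip(reads, prov["strand"], prov["start"]):
            source = fwd if strand == "+" else rev
            assert read.bases == source[start : start + 50]

    def test_genomic_reads_are_untreated(self):
        config = BsSimConfig(genome_length=10_000, methylation={}, n_reads=100,
                             seed=11)
        g = assign_methylation(simulate_genome(config))
        reads, prov = emit_reads(g, bisulfite=False)
        fwd = g.forward_string()
        from rawmeth.contexts import reverse_complement

        rev = reverse_complement(fwd)
        for read, strand, start in zip(reads, prov["strand"], prov["start"]):
            source = fwd if strand == "+" else rev
            assert read.bases == source[start : start + 50]

    def test_contaminant_fraction_and_provenance(self):
        config = BsSimConfig(genome_length=20_000, n_reads=4_000,
                             contamination_fraction=0.3, seed=12)
        g = assign_methylation(simulate_genome(config))
        reads, prov = emit_reads(g)
        frac = (prov["origin"] == "contaminant").mean()
        assert frac == pytest.approx(0.3, abs=3 * np.sqrt(0.21 / 4000))
        # origin is recoverable from the read name
        assert all(
            ("contaminant" in r.read_id) == (o == "contaminant")
            for r, o in zip(reads, prov["origin"])
        )

    def test_sequencing_error_perturbs_bases(self):
        base_cfg = dict(genome_length=10_000,
                        methylation={"CPG": 1.0, "CHG": 1.0, "CHH": 1.0},
                        n_reads=200, seed=13)
        clean = assign_methylation(simulate_genome(BsSimConfig(**base_cfg)))
        noisy_cfg = BsSimConfig(sequencing_error=0.05, **base_cfg)
        noisy = assign_methylation(simulate_genome(noisy_cfg))
        reads_clean, _ = emit_reads(clean)
        reads_noisy, _ = emit_reads(noisy)
        diffs = sum(
            sum(a != b for a, b in zip(x.bases, y.bases))
            for x, y in zip(reads_clean, reads_noisy)
        )
        total = 200 * 50
        assert diffs / total == pytest.approx(0.05, abs=0.01)

    def test_requires_assignment_first(self):
        g = simulate_genome(BsSimConfig(genome_length=1_000, seed=1))
        with pytest.raises(ConfigurationError):
            emit_reads(g)

    def test_byte_identical_under_same_seed(self, tmp_path):
        config = BsSimConfig(genome_length=5_000, n_reads=500,
                             contamination_fraction=0.1, sequencing_error=0.01,
                             nonconversion_rate=0.01, seed=14)
        blobs = []
        for _ in range(2):
            g = assign_methylation(simulate_genome(config))
            reads, _ = emit_reads(g)
            buf = io.StringIO()
            write_fastq(reads, buf)
            blobs.append(buf.getvalue())
        assert blobs[0] == blobs[1]


class TestTruthTable:
    def test_small_hand_case(self):
        # find a genome with CpGs, set half methylated via level 0.5 and
        # check the weighted level equals the realized fraction exactly
        config = BsSimConfig(genome_length=2_000, methylation={"CPG": 0.5},
                             seed=15)
        g = assign_methylation(simulate_genome(config))
        truth = truth_allc_frame(g, coverage=10)
        realized = g.realized_levels()
        assert target_m_from_allc(truth, Context.CPG) == pytest.approx(
            realized[Context.CPG], abs=1e-12
        )

    def test_exact_for_every_context(self, small_dataset):
        truth = truth_allc_frame(small_dataset["genome"])
        for context in ALL_CONTEXTS:
            assert target_m_from_allc(truth, context) == pytest.approx(
                small_dataset["realized"][context], abs=1e-12
            )

    def test_written_table_parses_back(self, tmp_path, small_dataset):
        path = tmp_path / "truth.allc.tsv"
        write_truth_allc(small_dataset["genome"], path)
        df = read_allc(path)
        assert target_m_from_allc(df, Context.CPG) == pytest.approx(
            small_dataset["realized"][Context.CPG], abs=1e-12
        )

    def test_positions_are_one_based_and_stranded(self):
        config = BsSimConfig(genome_length=500, seed=16)
        g = assign_methylation(simulate_genome(config))
        truth = truth_allc_frame(g)
        s = g.forward_string()
        for _, row in truth.head(50).iterrows():
            i = row["position"] - 1
            assert s[i] == ("C" if row["strand"] == "+" else "G")

    def test_noisy_coverage_still_near_truth(self):
        config = BsSimConfig(genome_length=100_000, methylation={"CPG": 0.6},
                             seed=17)
        g = assign_methylation(simulate_genome(config))
        truth = truth_allc_frame(g, coverage=20, noisy=True, noise_error=0.01)
        level = target_m_from_allc(truth, Context.CPG)
        assert level == pytest.approx(g.realized_levels()[Context.CPG], abs=0.02)


class TestDatasetPipeline:
    def test_writes_all_artifacts(self, tmp_path):
        config = BsSimConfig(genome_length=4_000, n_reads=200, seed=18)
        prefix = tmp_path / "sim"
        result = simulate_dataset(config, out_prefix=prefix)
        assert (tmp_path / "sim.fastq").exists()
        assert (tmp_path / "sim.allc.tsv").exists()
        assert (tmp_path / "sim.config.json").exists()
        assert len(result["reads"]) == 200
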