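import math

import pytest

from cloneseq import (MixtureSpec, build_isoform_sequence, isoform_label,
                      isoform_segments, simulate_clones, simulate_reads,
                      toy_locus)
from cloneseq.simulate import revcomp


def _spec(isoforms, n, seed=1, **kw):
    return MixtureSpec(isoforms=tuple(isoforms), n_read_pairs=n, seed=seed,
                       **kw)


class TestIsoformSequences:
    def test_structure_lengths(self, toy_model, toy_genome):
        assert len(build_isoform_sequence(toy_model, "FL", toy_genome)) == 300
        assert len(build_isoform_sequence(toy_model, "skip:E2",
                                          toy_genome)) == 200
        assert len(build_isoform_sequence(toy_model, "retain_intron:1",
                                          toy_genome)) == 400

    def test_fl_sequence_is_spliced_exon_concatenation(self, toy_model,
                                                       toy_genome):
        expected = "".join(toy_genome[e.genomic_start - 1: e.genomic_end]
                           for e in toy_model.exons)
        assert build_isoform_sequence(toy_model, "FL", toy_genome) == expected

    def test_minus_strand_is_reverse_complement(self, toy_minus):
        model, genome = toy_minus
        fl = build_isoform_sequence(model, "FL", genome)
        plus_concat = "".join(
            genome[e.genomic_start - 1: e.genomic_end]
            for e in sorted(model.exons, key=lambda e: e.genomic_start))
        assert fl == revcomp(plus_concat)

    def test_segment_descriptors(self, toy_model):
        assert isoform_segments(toy_model, "skip:E2") == [
            (1001, 1100), (1401, 1500)]
        assert isoform_segments(toy_model, "retain_intron:1") == [
            (1001, 1100), (1101, 1200), (1201, 1300), (1401, 1500)]
        assert isoform_segments(toy_model, "alt_donor:E2:30") == [
            (1001, 1100), (1201, 1270), (1401, 1500)]
        assert isoform_segments(toy_model, "cryptic:2:29:60") == [
            (1001, 1100), (1201, 1300), (1330, 1389), (1401, 1500)]

    def test_unknown_label_is_config_error(self, toy_model):
        from cloneseq.gene_models import AnnotationError
        with pytest.raises(AnnotationError):
            isoform_segments(toy_model, "skip:E9")

    def test_labels(self):
        assert isoform_label("FL") == "FL"
        assert isoform_label("skip:E2") == "ΔE2"
        assert isoform_label("skip:E2,E3") == "ΔE2+E3"
        assert isoform_label("retain_intron:1") == "IR1"


class TestReadSimulation:
    def test_same_seed_gives_byte_identical_outputs(self, toy, tmp_path):
        model, genome = toy
        spec = _spec([("FL", 0.7), ("skip:E2", 0.3)], 200, seed=9)
        a = tmp_path / "a"
        b = tmp_path / "b"
        simulate_reads(model, genome, spec, out_dir=a)
        simulate_reads(model, genome, spec, out_dir=b)
        for name in ("sim_R1.fastq", "sim_R2.fastq", "sim.truth.sam"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_error_free_reads_substring_match_their_isoform(self, toy):
        model, genome = toy
        spec = _spec([("FL", 0.5), ("skip:E2", 0.5)], 150,
                     substitution_rate=0.0)
        res = simulate_reads(model, genome, spec)
        seqs = {isoform_label(s): build_isoform_sequence(model, s, genome)
                for s, _ in spec.isoforms}
        # reconstruct each read's sequence by splicing its genomic blocks;
        # without errors it must appear verbatim in its source isoform
        for rec in res.records:
            iso = rec.read_id.split(":")[1]
            read = "".join(genome[s - 1: e] for s, e in rec.blocks)
            assert read in seqs[iso]

    def test_mixture_fraction_within_binomial_noise(self, toy):
        model, genome = toy
        spec = _spec([("FL", 0.7), ("skip:E2", 0.3)], 5000, seed=21)
        res = simulate_reads(model, genome, spec)
        frac = res.truth.per_isoform_pairs["ΔE2"] / 5000
        sd = math.sqrt(0.3 * 0.7 / 5000)
        assert abs(frac - 0.3) <= 3 * sd

    def test_read_counts_sum_to_twice_pairs(self, toy):
        model, genome = toy
        spec = _spec([("FL", 0.6), ("skip:E2", 0.4)], 321, seed=3)
        res = simulate_reads(model, genome, spec)
        assert sum(res.truth.per_isoform_reads.values()) == 642
        assert len(res.records) == 642

    def test_zero_pairs_yield_empty_but_valid_outputs(self, toy, tmp_path):
        model, genome = toy
        spec = _spec([("FL", 1.0)], 0)
        res = simulate_reads(model, genome, spec, out_dir=tmp_path)
        assert res.records == []
        assert res.fastq1.read_text() == ""
        assert res.sam.read_text().startswith("@HD")

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MixtureSpec(isoforms=(("FL", 0.5), ("skip:E2", 0.4)),
                        n_read_pairs=10)

    def test_substitutions_appear_at_requested_rate(self, toy):
        model, genome = toy
        spec = _spec([("FL", 1.0)], 1, seed=8, substitution_rate=0.01)
        clean = build_isoform_sequence(model, "FL", genome)
        recs, _ = simulate_clones(model, genome, spec, n_clones=300)
        mism = sum(a != b for _, seq in recs for a, b in zip(seq, clean))
        total = 300 * len(clean)
        rate = mism / total
        sd = math.sqrt(0.01 * 0.99 / total)
        assert abs(rate - 0.01) <= 4 * sd


class TestCloneSimulation:
    def test_replicate_and_clone_counts(self, toy, tmp_path):
        model, genome = toy
        spec = _spec([("FL", 0.5), ("skip:E2", 0.5)], 1, seed=2)
        fasta = tmp_path / "clones.fa"
        recs, truth = simulate_clones(model, genome, spec, n_clones=56,
                                      n_replicates=3, out_fasta=fasta)
        assert len(recs) == 168
        assert len([ln for ln in fasta.read_text().splitlines()
                    if ln.startswith(">")]) == 168

    def test_degenerate_mixture_all_full_length(self, toy):
        model, genome = toy
        spec = _spec([("FL", 1.0), ("skip:E2", 0.0)], 1, seed=2)
        _, truth = simulate_clones(model, genome, spec, n_clones=30)
        assert {lab for _, lab in truth} == {"FL"}

    def test_large_draw_matches_proportions(self, toy):
        model, genome = toy
        spec = _spec([("FL", 0.5), ("skip:E2", 0.5)], 1, seed=6,
                     substitution_rate=0.0)
        _, truth = simulate_clones(model, genome, spec, n_clones=10000)
        frac = sum(1 for _, lab in truth if lab == "ΔE2") / 10000
        assert abs(frac - 0.5) <= 3 * math.sqrt(0.25 / 10000)
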