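"""Synthetic world generator: divergence structure, samples, evaluation."""

import numpy as np
import pytest

import kmertyper as kt
from kmertyper.fixtures import FixtureSpec, evaluate_calls, generate_database, generate_sample
from kmertyper.sequtils import revcomp


def _identity(a, b):
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestGenerateDatabase:
    def test_deterministic_for_fixed_seed(self):
        spec = FixtureSpec(n_genes=2, alleles_per_gene=5, gene_length=300, seed=11)
        w1, w2 = generate_database(spec), generate_database(spec)
        assert [(str(r.name), r.sequence, r.status) for r in w1.records] == [
            (str(r.name), r.sequence, r.status) for r in w2.records
        ]

    def test_nested_divergence_ordering(self):
        spec = FixtureSpec(n_genes=3, alleles_per_gene=10, gene_length=800, partial_fraction=0.0, seed=13)
        world = generate_database(spec)
        seqs = {str(r.name): r.sequence for r in world.records}
        same_protein = _identity(seqs["GF1*01:01:01"], seqs["GF1*01:01:02"])
        cross_protein = _identity(seqs["GF1*01:01:01"], seqs["GF1*01:02:01"])
        cross_group = _identity(seqs["GF1*01:01:01"], seqs["GF1*02:01:01"])
        cross_gene = _identity(seqs["GF1*01:01:01"], seqs["GF2*01:01:01"])
        assert same_protein > cross_protein > cross_gene
        assert cross_group > cross_gene

    def test_partial_fraction_counts(self):
        spec = FixtureSpec(n_genes=5, alleles_per_gene=10, gene_length=300, partial_fraction=0.2, seed=3)
        world = generate_database(spec)
        partials = [r for r in world.records if r.status == "partial"]
        assert len(partials) == 10  # 0.2 x 50
        for rec in partials:
            full = world.truth_sequences[str(rec.name)]
            assert rec.sequence in full and len(rec.sequence) < len(full)
            assert rec.missing_exons == (1, 4, 5, 6)

    def test_novel_alleles_held_out_but_kept_in_truth(self):
        spec = FixtureSpec(n_genes=2, alleles_per_gene=10, gene_length=300, novel_fraction=0.1, seed=3)
        world = generate_database(spec)
        emitted = {str(r.name) for r in world.records}
        assert len(world.novel_names) == 2
        for name in world.novel_names:
            assert str(name) not in emitted
            assert str(name) in world.truth_sequences

    def test_unordered_divergences_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            FixtureSpec(group_divergence=0.5)


@pytest.fixture(scope="module")
def world():
    return generate_database(FixtureSpec(n_genes=2, alleles_per_gene=4, gene_length=400, partial_fraction=0.0, seed=21))


class TestGenerateSample:

    def test_zero_depth_gene_gets_no_reads(self, world, rng):
        genotypes = {g: (world.names_for_gene(g)[0],) * 2 for g in world.genes()}
        reads = generate_sample(world, genotypes, 0, rng=rng)
        assert reads == []

    def test_homozygous_genotype_reads_all_from_one_sequence(self, world, rng):
        gene = world.genes()[0]
        allele = world.names_for_gene(gene)[0]
        params = kt.SimulationParams(num_reads=0, error_rate=0.0)
        reads = generate_sample(world, {gene: (allele, allele)}, 100, params, rng, family_read_fraction=1.0)
        seq = world.truth_sequences[allele]
        assert len(reads) == 100
        assert all(p.seq2 in seq and revcomp(p.seq1) in seq for p in reads)

    def test_haplotype_split_within_binomial_bounds(self, world, rng):
        gene = world.genes()[0]
        a1, a2 = world.names_for_gene(gene)[:2]
        n = 2000
        reads = generate_sample(world, {gene: (a1, a2)}, n, rng=rng, family_read_fraction=1.0)
        tag = a1.replace("*", "_").replace(":", "-")
        n1 = sum(1 for p in reads if tag in p.name)
        # 99% binomial bounds around n/2 (z = 2.576)
        half_width = 2.576 * np.sqrt(n * 0.25)
        assert abs(n1 - n / 2) <= half_width

    def test_background_reads_fill_requested_fraction(self, world, rng):
        gene = world.genes()[0]
        allele = world.names_for_gene(gene)[0]
        reads = generate_sample(world, {gene: (allele, allele)}, 800, rng=rng, family_read_fraction=0.8)
        n_bg = sum(1 for p in reads if "_TX" in p.name)
        assert n_bg == 200  # 800 family reads -> 20% background

    def test_unknown_allele_rejected(self, world, rng):
        with pytest.raises(ValueError, match="unknown allele"):
            generate_sample(world, {world.genes()[0]: ("GF1*99:99", "GF1*99:99")}, 10, rng=rng)


class TestEvaluateCalls:
    def test_perfect_calls_are_perfect_at_every_precision(self):
        truth = {("S1", "A"): ("A*01:01:01", "A*02:01:01")}
        calls = {("S1", "A"): [["A*01:01:01"], ["A*02:01:01"]]}
        for prec in (1, 2, "exact"):
            assert evaluate_calls(calls, truth, prec).overall_accuracy == 1.0

    def test_third_field_mismatch_correct_at_two_fields_only(self):
        truth = {("S1", "A"): ("A*01:01:02", "A*01:01:02")}
        calls = {("S1", "A"): [["A*01:01:01"], ["A*01:01:01"]]}
        assert evaluate_calls(calls, truth, 2).overall_accuracy == 1.0
        assert evaluate_calls(calls, truth, "exact").overall_accuracy == 0.0

    def test_missing_allele_counts_as_incorrect(self):
        # ten graded alleles, one of which the caller left blank -> 90%
        truth = {("S1", g): (f"{g}*01:01", f"{g}*01:01") for g in ("A", "B", "C", "D", "E")}
        calls = {("S1", g): [[f"{g}*01:01"], [f"{g}*01:01"]] for g in ("A", "B", "C", "D")}
        calls[("S1", "E")] = [[f"E*01:01"], []]
        result = evaluate_calls(calls, truth, 2)
        assert result.overall_accuracy == pytest.approx(0.9)

    def test_fully_uncalled_gene_counts_both_alleles_incorrect(self):
        truth = {("S1", "A"): ("A*01:01", "A*01:01"), ("S1", "B"): ("B*01:01", "B*01:01")}
        calls = {("S1", "A"): [["A*01:01"], ["A*01:01"]], ("S1", "B"): None}
        assert evaluate_calls(calls, truth, 2).overall_accuracy == pytest.approx(0.5)

    def test_merged_names_accepted(self):
        truth = {("S1", "A"): ("A*01:02", "A*01:02")}
        calls = {("S1", "A"): [["A*01:01", "A*01:02"], ["A*01:01", "A*01:02"]]}
        assert evaluate_calls(calls, truth, "exact").overall_accuracy == 1.0

    def test_ambiguity_map_collapses_before_comparison(self):
        truth = {("S1", "A"): ("A*01:01", "A*01:01")}
        calls = {("S1", "A"): [["A*01:09"], ["A*01:09"]]}
        amap = {"A*01:09": "A*01:01"}
        assert evaluate_calls(calls, truth, "exact", amap).overall_accuracy == 1.0
        assert evaluate_calls(calls, truth, "exact").overall_accuracy == 0.0

    def test_accuracy_monotone_as_precision_tightens(self, rng):
        genes = ["A", "B"]
        truth, calls = {}, {}
        for s in range(6):
            for g in genes:
                t = (f"{g}*0{rng.integers(1,3)}:0{rng.integers(1,3)}:01", f"{g}*01:01:0{rng.integers(1,3)}")
                c = [[f"{g}*0{rng.integers(1,3)}:0{rng.integers(1,3)}:01"], [f"{g}*01:01:01"]]
                truth[(f"S{s}", g)] = t
                calls[(f"S{s}", g)] = c
        a1 = evaluate_calls(calls, truth, 1).overall_accuracy
        a2 = evaluate_calls(calls, truth, 2).overall_accuracy
        ax = evaluate_calls(calls, truth, "exact").overall_accuracy
        assert a1 >= a2 >= ax

    def test_invalid_precision_rejected(self):
        with pytest.raises(ValueError):
            evaluate_calls({}, {}, 3)
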