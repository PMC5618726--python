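"""One-mismatch remapping, substitution calling, and refined-call classes."""

import numpy as np
import pytest

from kmertyper.nomenclature import AlleleRecord, parse_allele_name
from kmertyper.refine import (
    PositionSupport,
    call_substitutions,
    classify_refined,
    recalculate_refined,
    remap_with_one_mismatch,
)
from kmertyper.sequtils import ReadPair, revcomp


def _random_seq(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


def _tiling_pairs(seq, read_len=50, step=7, name="t"):
    """Error-free pairs whose mates tile the sequence."""
    pairs = []
    positions = list(range(0, len(seq) - read_len + 1, step))
    for i, p in enumerate(positions):
        j = positions[(i + len(positions) // 2) % len(positions)]
        m2 = seq[p : p + read_len]
        m1 = revcomp(seq[j : j + read_len])
        pairs.append(ReadPair(f"{name}{i}", m1, "I" * read_len, m2, "I" * read_len))
    return pairs


class TestRemap:
    def test_error_free_reads_support_reference_everywhere_covered(self, rng):
        seq = _random_seq(300, rng)
        support = remap_with_one_mismatch(_tiling_pairs(seq), {"a": seq})["a"]
        covered = support.coverage > 0
        assert covered.any()
        ref_idx = np.array(["ACGT".index(b) for b in seq])
        top = support.base_support.argmax(axis=0)
        assert (top[covered] == ref_idx[covered]).all()

    def test_systematic_mismatch_collects_full_alt_support(self, rng):
        seq = _random_seq(300, rng)
        pos = 150
        alt = "A" if seq[pos] != "A" else "G"
        observed = seq[:pos] + alt + seq[pos + 1 :]
        support = remap_with_one_mismatch(_tiling_pairs(observed), {"a": seq})["a"]
        assert support.coverage[pos] > 0
        frac = support.base_support["ACGT".index(alt), pos] / support.coverage[pos]
        assert frac == pytest.approx(1.0)

    def test_read_with_two_mismatches_contributes_nothing(self, rng):
        seq = _random_seq(200, rng)
        mate = seq[50:100]
        mutated = list(mate)
        for p in (5, 25):
            mutated[p] = "A" if mate[p] != "A" else "C"
        bad = ReadPair("r", revcomp("".join(mutated)), "I" * 50, "".join(mutated), "I" * 50)
        support = remap_with_one_mismatch([bad], {"a": seq})["a"]
        assert support.coverage.sum() == 0

    def test_tied_read_splits_weight_across_alleles(self, rng):
        seq = _random_seq(200, rng)
        mate = seq[20:70]
        pair = ReadPair("r", revcomp(mate), "I" * 50, mate, "I" * 50)
        support = remap_with_one_mismatch([pair], {"a": seq, "b": seq})
        # identical alleles tie; each receives half weight per mate
        assert support["a"].coverage[30] == pytest.approx(1.0)  # two mates x 0.5
        assert support["b"].coverage[30] == pytest.approx(1.0)
        total = support["a"].coverage.sum() + support["b"].coverage.sum()
        assert total == pytest.approx(2 * 50)


class TestCallSubstitutions:
    def _support(self, seq, pos, alt, alt_n, ref_n):
        sup = PositionSupport(len(seq))
        ref_idx = "ACGT".index(seq[pos])
        sup.coverage[pos] = alt_n + ref_n
        sup.base_support["ACGT".index(alt), pos] = alt_n
        sup.base_support[ref_idx, pos] += ref_n
        return sup

    def test_eighty_percent_alt_support_is_substituted(self):
        seq = "GGGGGGGGGG"
        sup = self._support(seq, 4, "A", 8, 2)
        refined, subs = call_substitutions(sup, seq)
        assert refined[4] == "A"
        assert subs == [(4, "G", "A", pytest.approx(0.8))]

    def test_seventy_percent_alt_support_is_not_substituted(self):
        seq = "GGGGGGGGGG"
        sup = self._support(seq, 4, "A", 7, 3)
        refined, subs = call_substitutions(sup, seq)
        assert refined == seq and subs == []

    def test_uniform_reference_agreement_gives_no_substitutions(self, rng):
        seq = _random_seq(120, rng)
        support = remap_with_one_mismatch(_tiling_pairs(seq), {"a": seq})["a"]
        refined, subs = call_substitutions(support, seq)
        assert refined == seq and subs == []

    def test_zero_coverage_positions_untouched(self):
        seq = "ACGTACGT"
        refined, subs = call_substitutions(PositionSupport(len(seq)), seq)
        assert refined == seq and subs == []


class TestClassifyRefined:
    def _records(self):
        full = "ACGTACGTACGTACGTACGTGGGGCCCCTTTT"
        partial = full[8:24]
        return [
            AlleleRecord(parse_allele_name("B*27:05:02"), "X1", full),
            AlleleRecord(parse_allele_name("B*27:05:03"), "X2", partial, status="partial", missing_exons=(1, 4, 5, 6)),
        ]

    def test_no_substitutions_is_unchanged(self):
        rc = classify_refined("ACGT", parse_allele_name("B*27:05:02"), [], self._records())
        assert rc.classification == "unchanged" and rc.suffix == ""

    def test_partial_substring_match_updates_with_u_suffix(self):
        records = self._records()
        refined = records[0].sequence[:8] + records[1].sequence + records[0].sequence[24:]
        rc = classify_refined(refined, parse_allele_name("B*27:05:02"), [(10, "G", "A", 0.9)], records)
        assert rc.classification == "updated_partial"
        assert str(rc.refined_name) == "B*27:05:03U"
        assert parse_allele_name("B*27:05:03") in rc.matched_partials

    def test_no_partial_superstring_is_novel_with_n_suffix(self):
        rc = classify_refined("TTTTTTTTTTTTTTTT", parse_allele_name("B*27:05:02"), [(2, "G", "T", 0.9)], self._records())
        assert rc.classification == "novel"
        assert str(rc.refined_name) == "B*27:05:02N"

    def test_longest_partial_match_wins_and_all_reported(self):
        records = self._records()
        longer = AlleleRecord(
            parse_allele_name("B*27:06"), "X3", records[0].sequence[4:28], status="partial", missing_exons=(1, 6)
        )
        refined = records[0].sequence
        rc = classify_refined(refined, parse_allele_name("B*27:05:02"), [(1, "A", "C", 0.9)], records + [longer])
        assert str(rc.refined_name) == "B*27:06U"
        assert len(rc.matched_partials) == 2


class TestRecalculate:
    def test_mode_off_returns_original(self):
        from kmertyper.refine import RefinedCall

        rc = RefinedCall(parse_allele_name("A*01:01"), "ACGT", "novel", "N")
        out, score = recalculate_refined(rc, None, None, None, mode="off")
        assert out is rc and score is None

    def test_invalid_mode_rejected(self):
        from kmertyper.refine import RefinedCall

        rc = RefinedCall(parse_allele_name("A*01:01"), "ACGT", "novel", "N")
        with pytest.raises(ValueError):
            recalculate_refined(rc, None, None, None, mode="sometimes")

    def test_refined_truth_sequence_lowers_error(self, micro_world, micro_db, rng):
        """Recalculating with the true (held-out) sequence must not score
        worse than the original mismatching call."""
        import kmertyper as kt
        from kmertyper.fixtures import _mutate
        from kmertyper.profiles import build_sample_profile
        from kmertyper.candidates import combine_pair_profile, score_pair

        gene = micro_world.genes()[0]
        base = micro_world.names_for_gene(gene)[0]
        truth_seq = _mutate(micro_world.truth_sequences[base], 0.0, rng, min_muts=3)
        micro_world.truth_sequences["__novel__"] = truth_seq
        reads = kt.generate_sample(
            micro_world, {gene: ("__novel__", "__novel__")}, 1200,
            kt.SimulationParams(num_reads=0, error_rate=0.0), rng,
        )
        binning = kt.bin_reads(reads, micro_db.classifier)
        sample_profile = build_sample_profile(binning.gene_bins()[gene], 50)
        base_prof = micro_db.profiles[gene][base]
        original = score_pair(combine_pair_profile(base_prof, base_prof), sample_profile, base, base)

        from kmertyper.refine import RefinedCall

        rc = RefinedCall(parse_allele_name(base), truth_seq, "novel", "N", [(0, "A", "C", 1.0)])

        def builder(name, sequence):
            from kmertyper.profiles import count_read_kmers

            sim = kt.simulate_read_pairs(sequence, micro_db.sim_params, rng=np.random.default_rng(1))
            return count_read_kmers(sim, 50, owner=name)

        _, updated = recalculate_refined(rc, base_prof, sample_profile, builder, mode="recalculate")
        assert updated.error <= original.error
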