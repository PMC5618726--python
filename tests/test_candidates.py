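"""Semifinalist ranking, pair-profile combination, and the Error score."""

import math

import numpy as np
import pytest

from kmertyper.candidates import (
    combine_pair_profile,
    score_all_pairs,
    score_pair,
    select_finalists,
    select_semifinalists,
)
from kmertyper.profiles import KmerProfile


def _prof(owner, counts, k=4):
    return KmerProfile(owner, k, dict(counts))


class TestSelectSemifinalists:
    def test_fewer_alleles_than_n_returns_all(self):
        alleles = {f"A*0{i}": _prof(f"A*0{i}", {"AAAA": 1}) for i in range(1, 4)}
        sample = _prof("s", {"AAAA": 5})
        assert len(select_semifinalists(alleles, sample, 100)) == 3

    def test_boundary_tie_grows_n(self):
        # observed fractions 1.0, 0.9, 0.9, 0.5 with n=2: the rank-2/3 tie
        # extends the cut to 3 semifinalists
        alleles = {
            "a1": _prof("a1", {"AAAA": 10}),
            "a2": _prof("a2", {"AAAA": 9, "CCCC": 1}),
            "a3": _prof("a3", {"AAAA": 9, "GGGG": 1}),
            "a4": _prof("a4", {"AAAA": 5, "TTTT": 5}),
        }
        sample = _prof("s", {"AAAA": 5})
        assert select_semifinalists(alleles, sample, 2) == ["a1", "a2", "a3"]

    def test_distinct_scores_cut_exactly_at_n(self):
        alleles = {
            "a1": _prof("a1", {"AAAA": 10}),
            "a2": _prof("a2", {"AAAA": 8, "CCCC": 2}),
            "a3": _prof("a3", {"AAAA": 5, "TTTT": 5}),
        }
        sample = _prof("s", {"AAAA": 5})
        assert select_semifinalists(alleles, sample, 2) == ["a1", "a2"]

    def test_empty_sample_profile_gives_empty_list(self):
        alleles = {"a1": _prof("a1", {"AAAA": 1})}
        assert select_semifinalists(alleles, _prof("s", {}), 5) == []


class TestCombinePairProfile:
    def test_disjoint_union(self):
        combined = combine_pair_profile(_prof("p", {"AAAA": 2}), _prof("q", {"CCCC": 3}))
        assert combined.counts == {"AAAA": 2, "CCCC": 3}

    def test_homozygous_pair_doubles_counts(self):
        p = _prof("p", {"AAAA": 2})
        assert combine_pair_profile(p, p).counts == {"AAAA": 4}

    def test_keywise_sum(self):
        combined = combine_pair_profile(_prof("p", {"AAAA": 1, "CCCC": 2}), _prof("q", {"AAAA": 3}))
        assert combined.counts == {"AAAA": 4, "CCCC": 2}

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_pair_profile(_prof("p", {"AAAA": 1}, k=4), _prof("q", {"AAAAA": 1}, k=5))


class TestScorePair:
    def test_identical_profiles_score_zero_error(self):
        counts = {"AAAA": 4, "CCCC": 2, "GGGG": 8}  # non-constant so Cor is defined
        score = score_pair(_prof("p", counts), _prof("s", dict(counts)))
        assert score.prop_reads == 1.0 and score.prop_prof == 1.0
        assert score.cor == pytest.approx(1.0)
        assert score.error == pytest.approx(0.0)

    def test_disjoint_profiles_score_error_three(self):
        score = score_pair(_prof("p", {"AAAA": 1, "CCCC": 1}), _prof("s", {"GGGG": 2, "TTTT": 2}))
        assert (score.prop_reads, score.prop_prof, score.cor) == (0.0, 0.0, 0.0)
        assert score.error == pytest.approx(3.0)

    def test_hand_computed_components_zero_variance_cor(self):
        # PropProf = (4+4)/10, PropReads = (4+4)/10, shared log-counts are
        # constant so Cor falls back to the neutral 0
        score = score_pair(_prof("p", {"AAAA": 4, "CCCC": 4, "GGGG": 2}), _prof("s", {"AAAA": 4, "CCCC": 4, "TTTT": 2}))
        assert score.prop_prof == pytest.approx(0.8)
        assert score.prop_reads == pytest.approx(0.8)
        assert score.cor == 0.0
        assert score.error == pytest.approx(0.2 + 0.2 + 1.0)

    def test_hand_computed_components_perfect_log_correlation(self):
        # shared k-mers have pair counts (2, 8) and sample counts (4, 16):
        # two points are perfectly log-correlated
        score = score_pair(_prof("p", {"AAAA": 2, "CCCC": 8, "GGGG": 5}), _prof("s", {"AAAA": 4, "CCCC": 16, "TTTT": 3}))
        assert score.cor == pytest.approx(1.0)
        assert score.prop_prof == pytest.approx(10 / 15)
        assert score.prop_reads == pytest.approx(20 / 23)
        assert score.error == pytest.approx((1 - 10 / 15) + (1 - 20 / 23) + 0.0)

    def test_error_is_exactly_the_defining_equation(self):
        # e.g. components (0.9, 0.8, 0.95) must give 0.35; checked on the
        # components the scorer itself reports
        s = score_pair(_prof("p", {"AAAA": 2, "CCCC": 8, "GGGG": 5}), _prof("s", {"AAAA": 4, "CCCC": 16, "TTTT": 3}))
        assert s.error == pytest.approx((1 - s.prop_prof) + (1 - s.prop_reads) + (1 - s.cor))
        assert (1 - 0.9) + (1 - 0.8) + (1 - 0.95) == pytest.approx(0.35)

    def test_error_symmetric_under_allele_swap(self):
        p1, p2 = _prof("x", {"AAAA": 3, "CCCC": 1}), _prof("y", {"GGGG": 2, "AAAA": 1})
        sample = _prof("s", {"AAAA": 6, "GGGG": 2, "TTTT": 4})
        e12 = score_pair(combine_pair_profile(p1, p2), sample).error
        e21 = score_pair(combine_pair_profile(p2, p1), sample).error
        assert e12 == pytest.approx(e21)

    def test_error_bounded_between_zero_and_four(self, rng):
        kmers = ["AAAA", "CCCC", "GGGG", "TTTT", "ACGT", "TGCA"]
        for _ in range(50):
            pick = lambda: {k: int(c) for k, c in zip(kmers, rng.integers(0, 9, len(kmers))) if c}
            p, s = pick(), pick()
            if not p or not s:
                continue
            err = score_pair(_prof("p", p), _prof("s", s)).error
            assert 0.0 <= err <= 4.0


class TestSelectFinalists:
    def _scores(self, errors_and_names):
        from kmertyper.candidates import PairScore

        return [PairScore(a, b, 0.5, 0.5, 0.5, e) for e, (a, b) in errors_and_names]

    def test_fewer_pairs_than_m_returns_all_sorted(self):
        scores = self._scores([(0.3, ("a", "b")), (0.1, ("c", "d"))])
        out = select_finalists(scores, 20)
        assert [s.error for s in out] == [0.1, 0.3]

    def test_tie_broken_by_pair_name(self):
        scores = self._scores([(0.2, ("z", "z")), (0.1, ("a", "a")), (0.2, ("b", "c")), (0.9, ("d", "d"))])
        out = select_finalists(scores, 2)
        assert [(s.allele1, s.allele2) for s in out] == [("a", "a"), ("b", "c")]

    def test_m_one_returns_minimum(self):
        scores = self._scores([(0.5, ("a", "b")), (0.05, ("c", "c"))])
        assert [s.pair for s in select_finalists(scores, 1)] == [("c", "c")]


def test_diploid_parameter_recovery_error_free(micro_world, micro_db, rng):
    """For an error-free diploid sample, the truth pair minimizes Error over
    an exhaustive all-pairs scan of its gene."""
    from kmertyper.profiles import build_sample_profile
    from kmertyper.simulate import SimulationParams

    import kmertyper as kt

    genotypes = kt.random_genotypes(micro_world, rng)
    params = SimulationParams(num_reads=0, error_rate=0.0)
    reads = kt.generate_sample(micro_world, genotypes, 1200, params, rng)
    binning = kt.bin_reads(reads, micro_db.classifier)
    for gene, bin_reads_list in binning.gene_bins().items():
        sample_profile = build_sample_profile(bin_reads_list, 50)
        all_alleles = list(micro_db.profiles[gene])
        scores = score_all_pairs(all_alleles, micro_db.profiles[gene], sample_profile)
        best = min(scores, key=lambda s: (s.error, s.label))
        assert set(best.pair) == set(genotypes[gene])
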