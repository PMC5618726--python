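"""Candidate allele-pair selection by k-mer profile comparison.

Alleles are first ranked by the fraction of their reference profile
observed in the sample (top n semifinalists, default 100, with ties at the
boundary extending n). Every unordered semifinalist pair — homozygous pairs
included — is then scored with

    Error = (1 - PropProf) + (1 - PropReads) + (1 - Cor)

where PropReads is the proportion of observed k-mer mass accounted for by
the combined pair profile, PropProf the proportion of the pair profile's
mass accounted for by the observed k-mers, and Cor the Pearson correlation
of log counts over the shared k-mers. The m lowest-Error pairs (default 20)
become finalists for competitive alignment. Sample k-mers with count <= 1
are excluded throughout (the sample profile arrives pre-filtered).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .profiles import KmerProfile, fraction_profile_observed

__all__ = [
    "PairScore",
    "select_semifinalists",
    "combine_pair_profile",
    "score_pair",
    "score_all_pairs",
    "select_finalists",
]


@dataclass(frozen=True)
class PairScore:
    """Profile-comparison score of one unordered candidate allele pair."""

    allele1: str
    allele2: str
    prop_reads: float
    prop_prof: float
    cor: float
    error: float

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.allele1, self.allele2)

    @property
    def label(self) -> str:
        return f"{self.allele1}/{self.allele2}"


def select_semifinalists(
    allele_profiles: Mapping[str, KmerProfile],
    sample_profile: KmerProfile,
    n: int = 100,
) -> List[str]:
    """Rank alleles by fraction of profile observed; keep the top n.

    When the allele at rank n+1 ties rank n, n grows until the next score
    is strictly smaller, so a tie never silently truncates the candidate
    set. An empty sample profile returns an empty list (gene uncallable).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not sample_profile:
        return []
    scored = sorted(
        ((fraction_profile_observed(prof, sample_profile), name) for name, prof in allele_profiles.items()),
        key=lambda t: (-t[0], t[1]),
    )
    cut = min(n, len(scored))
    while cut < len(scored) and scored[cut][0] == scored[cut - 1][0]:
        cut += 1
    return [name for _score, name in scored[:cut]]


def combine_pair_profile(p1: KmerProfile, p2: KmerProfile) -> KmerProfile:
    """Key-wise sum of two allele profiles; a homozygous pair doubles counts."""
    if p1.k != p2.k:
        raise ValueError(f"profile k mismatch: {p1.k} vs {p2.k}")
    counts = dict(p1.counts)
    for kmer, c in p2.counts.items():
        counts[kmer] = counts.get(kmer, 0) + c
    return KmerProfile(f"{p1.owner}/{p2.owner}", p1.k, counts)


def _log_correlation(pair_counts: Dict[str, int], sample_counts: Dict[str, int]) -> float:
    """Pearson correlation of (ln pair count, ln sample count) on the shared
    k-mer set. Fewer than two shared k-mers, or a zero-variance vector,
    yields the neutral value 0."""
    shared = [k for k in pair_counts if k in sample_counts]
    if len(shared) < 2:
        return 0.0
    x = np.log(np.array([pair_counts[k] for k in shared], dtype=float))
    y = np.log(np.array([sample_counts[k] for k in shared], dtype=float))
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def score_pair(pair_profile: KmerProfile, sample_profile: KmerProfile, allele1: str = "", allele2: str = "") -> PairScore:
    """Compute PropReads, PropProf, Cor and Error for one candidate pair."""
    if not pair_profile or not sample_profile:
        raise ValueError("pair and sample profiles must be non-empty")
    pc, sc = pair_profile.counts, sample_profile.counts
    pair_total, sample_total = pair_profile.total, sample_profile.total
    prop_prof = sum(c for kmer, c in pc.items() if kmer in sc) / pair_total
    prop_reads = sum(c for kmer, c in sc.items() if kmer in pc) / sample_total
    cor = _log_correlation(pc, sc)
    error = (1.0 - prop_prof) + (1.0 - prop_reads) + (1.0 - cor)
    return PairScore(allele1 or pair_profile.owner, allele2, prop_reads, prop_prof, cor, error)


def score_all_pairs(
    semifinalists: Sequence[str],
    allele_profiles: Mapping[str, KmerProfile],
    sample_profile: KmerProfile,
) -> List[PairScore]:
    """Score every unordered pair of semifinalists (homozygous included)."""
    scores = []
    for a1, a2 in itertools.combinations_with_replacement(sorted(semifinalists), 2):
        pair_prof = combine_pair_profile(allele_profiles[a1], allele_profiles[a2])
        scores.append(score_pair(pair_prof, sample_profile, a1, a2))
    return scores


def select_finalists(pair_scores: Sequence[PairScore], m: int = 20) -> List[PairScore]:
    """The m lowest-Error pairs, ascending, ties broken by pair name."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return sorted(pair_scores, key=lambda s: (s.error, s.label))[:m]
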