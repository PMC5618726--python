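"""Competitive exact-match alignment of read pairs against finalist pairs.

For every ordered pair of finalists (i, j), the alignment score matrix
(ASM) accumulates a quality weight S for each read pair that matches
candidate pair i but not j ("matches" = each mate is an exact substring of
at least one of the pair's two allele sequences, read 1 reverse
complemented). The matrix is then noise-adjusted by adding
total_matching_reads / 10,000 to every off-diagonal cell, and each finalist
is scored

    Score(i) = (row_sum(i) / col_sum(i))^P * 1 / Error(i)

with off-diagonal sums and default power P = 0.25. The top score is the
predicted pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .sequtils import ReadPair, revcomp

__all__ = [
    "quality_weight",
    "read_pair_matches_pair",
    "AlignmentScoreMatrix",
    "build_asm",
    "adjust_asm",
    "CallScore",
    "score_candidates",
]

NOISE_DIVISOR = 10_000.0
_ERROR_FLOOR = 1e-6  # perfect profile matches rank first instead of dividing by zero


def quality_weight(q: float, q_min: float = 20.0) -> float:
    """Piecewise quality weight S of a read pair's lowest base quality.

    0 at or below ``q_min``, 1 at or above phred 35, linear in between.
    """
    if q_min >= 35:
        raise ValueError("q_min must be below 35")
    if q <= q_min:
        return 0.0
    if q >= 35:
        return 1.0
    return (q - q_min) / (35.0 - q_min)


def _mate_matches(mate_forward: str, alleles: Tuple[str, str], sequences: Mapping[str, str], unstranded: bool) -> bool:
    for allele in alleles:
        seq = sequences[allele]
        if mate_forward in seq:
            return True
        if unstranded and revcomp(mate_forward) in seq:
            return True
    return False


def read_pair_matches_pair(
    pair: ReadPair,
    alleles: Tuple[str, str],
    sequences: Mapping[str, str],
    unstranded: bool = False,
) -> bool:
    """True iff each mate is an exact substring of at least one allele."""
    return _mate_matches(revcomp(pair.seq1), alleles, sequences, unstranded) and _mate_matches(
        pair.seq2, alleles, sequences, unstranded
    )


@dataclass
class AlignmentScoreMatrix:
    pairs: List[Tuple[str, str]]
    matrix: np.ndarray  # m x m, diagonal unused
    total_matching_reads: int = 0

    def row_sum(self, i: int) -> float:
        return float(self.matrix[i].sum() - self.matrix[i, i])

    def col_sum(self, i: int) -> float:
        return float(self.matrix[:, i].sum() - self.matrix[i, i])


def build_asm(
    read_pairs: Iterable[ReadPair],
    finalist_pairs: Sequence[Tuple[str, str]],
    sequences: Mapping[str, str],
    q_min: float = 20.0,
    unstranded: bool = False,
) -> AlignmentScoreMatrix:
    """Accumulate the m x m quality-weighted unique-match matrix.

    Reads are tested against the distinct alleles once each; pair-level
    matches and the (i, j) increments are then derived from bitmasks, so a
    read matching every finalist (or none) costs no matrix work.
    """
    m = len(finalist_pairs)
    if m < 1:
        raise ValueError("at least one finalist pair required")
    alleles = sorted({a for p in finalist_pairs for a in p})
    allele_idx = {a: i for i, a in enumerate(alleles)}
    seqs = [sequences[a] for a in alleles]
    pair_bits = [(allele_idx[a], allele_idx[b]) for a, b in finalist_pairs]

    mask_weight: Dict[int, float] = {}
    total_matching = 0
    for rp in read_pairs:
        m1 = revcomp(rp.seq1)
        m2 = rp.seq2
        if unstranded:
            m1r, m2r = rp.seq1, revcomp(rp.seq2)
            hits1 = [(m1 in s) or (m1r in s) for s in seqs]
            hits2 = [(m2 in s) or (m2r in s) for s in seqs]
        else:
            hits1 = [m1 in s for s in seqs]
            hits2 = [m2 in s for s in seqs]
        mask = 0
        for i, (a, b) in enumerate(pair_bits):
            if (hits1[a] or hits1[b]) and (hits2[a] or hits2[b]):
                mask |= 1 << i
        if mask == 0:
            continue
        total_matching += 1
        full = (1 << m) - 1
        if mask == full:
            continue  # matches every finalist: no unique evidence
        s = quality_weight(rp.min_quality(), q_min)
        if s > 0.0:
            mask_weight[mask] = mask_weight.get(mask, 0.0) + s

    matrix = np.zeros((m, m))
    for mask, weight in mask_weight.items():
        matched = [i for i in range(m) if mask >> i & 1]
        unmatched = [j for j in range(m) if not mask >> j & 1]
        matrix[np.ix_(matched, unmatched)] += weight
    return AlignmentScoreMatrix(list(finalist_pairs), matrix, total_matching)


def adjust_asm(asm: AlignmentScoreMatrix) -> AlignmentScoreMatrix:
    """Noise adjustment: add total_matching_reads/10,000 off-diagonal.

    The same mass lands in every row and column, so sign relationships
    between row sums are preserved while small-count ratios shrink toward 1
    — pairs backed by more unique reads keep the larger ratio.
    """
    increment = asm.total_matching_reads / NOISE_DIVISOR
    matrix = asm.matrix + increment
    np.fill_diagonal(matrix, np.diag(asm.matrix))
    return replace(asm, matrix=matrix)


@dataclass(frozen=True)
class CallScore:
    pair: Tuple[str, str]
    row_sum: float
    col_sum: float
    power: float
    error: float
    score: float

    @property
    def label(self) -> str:
        return f"{self.pair[0]}/{self.pair[1]}"


def score_candidates(
    asm: AlignmentScoreMatrix,
    pair_errors: Mapping[Tuple[str, str], float],
    power: float = 0.25,
) -> List[CallScore]:
    """Rank finalists by (row/col)^P / Error over the adjusted matrix.

    Zero row and column sums give a neutral ratio of 1; Error is floored at
    1e-6. Descending score, ties broken by pair name; the first entry is
    the predicted allele pair.
    """
    scores = []
    for i, pair in enumerate(asm.pairs):
        row, col = asm.row_sum(i), asm.col_sum(i)
        if row == 0.0 and col == 0.0:
            ratio = 1.0
        elif col == 0.0:
            ratio = np.inf
        else:
            ratio = row / col
        error = max(pair_errors[pair], _ERROR_FLOOR)
        score = float(ratio**power / error)
        scores.append(CallScore(pair, row, col, power, pair_errors[pair], score))
    return sorted(scores, key=lambda s: (-s.score, s.label))
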