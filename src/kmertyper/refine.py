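"""Allele refinement: detect systematic mismatches and emit corrected calls.

After the competitive alignment picks an allele pair, the gene's reads are
remapped to the two called sequences allowing a single mismatch, and
per-position nucleotide support is accumulated. Positions where a
non-reference base exceeds 75% of coverage (and beats the reference count)
are substituted into a putative corrected sequence. If a same-gene
reference allele with partial status is an exact substring of that
sequence, the call becomes the partial allele with a "U" (updated) suffix;
otherwise the called allele keeps its name with an "N" (novel) suffix.
Substitutions only — the procedure records support against the fixed
reference coordinate system, so indels are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .candidates import PairScore, combine_pair_profile, score_pair
from .nomenclature import AlleleName, AlleleRecord
from .profiles import KmerProfile
from .sequtils import ReadPair, revcomp

__all__ = [
    "PositionSupport",
    "RefinedCall",
    "remap_with_one_mismatch",
    "call_substitutions",
    "classify_refined",
    "recalculate_refined",
]

_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T byte codes
_BASES = "ACGT"


def _encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    enc = np.full(raw.shape, 4, dtype=np.int8)
    for byte, idx in _BASE_INDEX.items():
        enc[raw == byte] = idx
    return enc


@dataclass
class PositionSupport:
    """Per-position coverage and A/C/G/T support for one called allele.

    Weights are fractional because a read tying between the two called
    alleles contributes half weight to each, so base counts always sum to
    the coverage at every position.
    """

    length: int
    coverage: np.ndarray = field(default=None)
    base_support: np.ndarray = field(default=None)  # 4 x length

    def __post_init__(self):
        if self.coverage is None:
            self.coverage = np.zeros(self.length)
        if self.base_support is None:
            self.base_support = np.zeros((4, self.length))

    def add_read(self, enc_read: np.ndarray, position: int, weight: float) -> None:
        span = np.arange(position, position + enc_read.size)
        valid = enc_read >= 0
        valid &= enc_read < 4
        self.coverage[span[valid]] += weight
        self.base_support[enc_read[valid], span[valid]] += weight


class _AlleleIndex:
    """Sliding-window view of an allele sequence for mismatch counting."""

    def __init__(self, name: str, sequence: str, read_length_hint: int):
        self.name = name
        self.sequence = sequence
        self.enc = _encode(sequence)
        self._windows: Dict[int, np.ndarray] = {}

    def best_placement(self, enc_read: np.ndarray) -> Tuple[Optional[int], int]:
        """(leftmost best position, mismatch count); (None, big) if read
        longer than the sequence."""
        L = enc_read.size
        if L > self.enc.size:
            return None, L + 1
        win = self._windows.get(L)
        if win is None:
            win = np.lib.stride_tricks.sliding_window_view(self.enc, L)
            self._windows[L] = win
        mism = (win != enc_read).sum(axis=1)
        pos = int(np.argmin(mism))  # argmin is leftmost on ties
        return pos, int(mism[pos])


def remap_with_one_mismatch(
    read_pairs: Iterable[ReadPair],
    called_sequences: Mapping[str, str],
    max_mismatches: int = 1,
) -> Dict[str, PositionSupport]:
    """Pile up read support on the called pair, allowing one mismatch.

    Each mate (read 1 reverse complemented) is placed at its best-scoring
    substring position on each called allele; it is assigned to the allele
    it matches better, with ties contributing half weight to both. Mates
    with no placement within ``max_mismatches`` on either allele are
    skipped. Support is accumulated per called allele separately so
    homozygous/heterozygous differences stay visible.
    """
    indexes = {name: _AlleleIndex(name, seq, 50) for name, seq in called_sequences.items()}
    support = {name: PositionSupport(len(seq)) for name, seq in called_sequences.items()}
    names = list(indexes)
    for rp in read_pairs:
        for mate in (revcomp(rp.seq1), rp.seq2):
            enc = _encode(mate)
            placements = []
            for name in names:
                pos, mism = indexes[name].best_placement(enc)
                if pos is not None and mism <= max_mismatches:
                    placements.append((mism, name, pos))
            if not placements:
                continue
            best = min(p[0] for p in placements)
            winners = [p for p in placements if p[0] == best]
            weight = 1.0 / len(winners)
            for _mism, name, pos in winners:
                support[name].add_read(enc, pos, weight)
    return support


def call_substitutions(
    support: PositionSupport,
    reference: str,
    frac_threshold: float = 0.75,
) -> Tuple[str, List[Tuple[int, str, str, float]]]:
    """Substitute positions where a non-reference base dominates.

    A position is substituted iff the top non-reference base both exceeds
    ``frac_threshold`` of the coverage and beats the reference support
    (conjunctive). Zero-coverage positions are left untouched. Returns the
    refined sequence and a list of (position, ref, alt, support fraction).
    """
    ref_enc = _encode(reference)
    refined = list(reference)
    subs: List[Tuple[int, str, str, float]] = []
    coverage = support.coverage
    bases = support.base_support
    covered = np.nonzero(coverage > 0)[0]
    for pos in covered:
        ref_idx = int(ref_enc[pos])
        counts = bases[:, pos]
        alt_idx = int(np.argmax(counts)) if ref_idx >= 4 else int(
            np.argmax(np.where(np.arange(4) == ref_idx, -1.0, counts))
        )
        alt_count = float(counts[alt_idx])
        ref_count = float(counts[ref_idx]) if ref_idx < 4 else 0.0
        frac = alt_count / float(coverage[pos])
        if frac > frac_threshold and alt_count > ref_count:
            refined[pos] = _BASES[alt_idx]
            subs.append((int(pos), reference[pos], _BASES[alt_idx], frac))
    return "".join(refined), subs


@dataclass
class RefinedCall:
    """Outcome of refining one called allele against the observed reads."""

    base_allele: AlleleName
    refined_sequence: str
    classification: str  # "unchanged" | "updated_partial" | "novel"
    suffix: str  # "" | "U" | "N"
    substitutions: List[Tuple[int, str, str, float]] = field(default_factory=list)
    refined_name: Optional[AlleleName] = None
    matched_partials: List[AlleleName] = field(default_factory=list)
    updated_error: Optional[float] = None

    def __post_init__(self):
        if self.refined_name is None:
            self.refined_name = self.base_allele


def classify_refined(
    refined_sequence: str,
    base_allele: AlleleName,
    substitutions: Sequence[Tuple[int, str, str, float]],
    gene_records: Sequence[AlleleRecord],
) -> RefinedCall:
    """Decide whether a refined sequence updates a partial allele or is novel.

    With no substitutions the call is unchanged. Otherwise every same-gene
    reference allele with partial status is tested as an exact substring of
    the refined sequence; the longest match wins (all matches reported) and
    renames the call with a "U" suffix. With no qualifying partial, the
    base allele keeps its name with an "N" suffix.
    """
    if not substitutions:
        return RefinedCall(base_allele, refined_sequence, "unchanged", "")
    matches = [
        rec
        for rec in gene_records
        if rec.status == "partial"
        and rec.name.gene == base_allele.gene
        and rec.sequence in refined_sequence
    ]
    if matches:
        matches.sort(key=lambda r: (-len(r.sequence), str(r.name)))
        best = matches[0]
        return RefinedCall(
            base_allele,
            refined_sequence,
            "updated_partial",
            "U",
            list(substitutions),
            refined_name=best.name.with_suffix("U"),
            matched_partials=[m.name for m in matches],
        )
    return RefinedCall(
        base_allele,
        refined_sequence,
        "novel",
        "N",
        list(substitutions),
        refined_name=base_allele.with_suffix("N"),
    )


def recalculate_refined(
    refined: RefinedCall,
    partner_profile: KmerProfile,
    sample_profile: KmerProfile,
    profile_for_sequence: Callable[[str, str], KmerProfile],
    mode: str = "recalculate",
) -> Tuple[RefinedCall, Optional[PairScore]]:
    """Recompute the profile Error with the refined allele substituted in.

    ``profile_for_sequence(name, sequence)`` must build a reference-style
    profile for the refined sequence (simulation + k-mer counting). With
    mode "off", or an unchanged call, the original score stands.
    """
    if mode not in ("off", "recalculate", "all"):
        raise ValueError(f"invalid refinement mode {mode!r}")
    if mode == "off" or refined.classification == "unchanged":
        return refined, None
    refined_profile = profile_for_sequence(str(refined.refined_name), refined.refined_sequence)
    pair_prof = combine_pair_profile(refined_profile, partner_profile)
    score = score_pair(pair_prof, sample_profile, str(refined.refined_name), partner_profile.owner)
    refined.updated_error = score.error
    return refined, score


def write_refined_fasta(refined_calls: Sequence[RefinedCall], path, accession_prefix: str = "REFINED") -> None:
    """Write refined sequences as FASTA, suffixed headers per the call."""
    with open(str(path), "w") as fh:
        for i, rc in enumerate(refined_calls):
            if rc.classification == "unchanged":
                continue
            fh.write(f">{accession_prefix}{i}{rc.suffix} {rc.refined_name} refined\n")
            seq = rc.refined_sequence
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")
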