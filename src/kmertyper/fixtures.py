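"""Self-contained synthetic test worlds: allele databases with nested
divergence, partial and held-out (novel) alleles, distractome transcripts,
diploid samples, and typing-accuracy evaluation.

The generator emulates the structure of a polymorphic gene family: gene
ancestors diverge from a common root, allele groups (field 1) from each
gene, distinct proteins (field 2) within groups, and synonymous variants
(field 3) within proteins, with strictly decreasing divergence at each
level. Partial alleles ship only pseudo-exons 2-3 of six equal slices
(mirroring the historical submission of the peptide-binding exons) while
the full sequence is retained as truth; novel alleles are held out of the
emitted database entirely. Everything is deterministic given a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .nomenclature import AlleleName, AlleleRecord, truncate_precision
from .sequtils import ReadPair
from .simulate import SimulationParams, simulate_read_pairs

__all__ = [
    "FixtureSpec",
    "FixtureWorld",
    "generate_database",
    "random_genotypes",
    "generate_sample",
    "evaluate_calls",
    "EvalResult",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
N_PSEUDO_EXONS = 6
PARTIAL_KEPT_EXONS = (2, 3)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic gene-family world.

    Divergences are per-base substitution fractions between a node and its
    parent in the gene/group/protein/synonymous hierarchy and must be
    strictly ordered ``inter_gene > group > protein > synonymous > 0``.
    """

    n_genes: int = 5
    alleles_per_gene: int = 20
    gene_length: int = 1000
    inter_gene_divergence: float = 0.08
    group_divergence: float = 0.02
    protein_divergence: float = 0.008
    synonymous_divergence: float = 0.002
    partial_fraction: float = 0.1
    novel_fraction: float = 0.0
    n_distractome: int = 20
    distractome_length: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.gene_length <= 0 or self.n_genes < 1 or self.alleles_per_gene < 1:
            raise ValueError("degenerate fixture spec")
        divs = (
            self.inter_gene_divergence,
            self.group_divergence,
            self.protein_divergence,
            self.synonymous_divergence,
        )
        if not (divs[0] > divs[1] > divs[2] > divs[3] > 0):
            raise ValueError(f"divergences must be strictly ordered, got {divs}")
        for frac in (self.partial_fraction, self.novel_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class FixtureWorld:
    """A generated database plus the truth needed to evaluate against it."""

    spec: FixtureSpec
    records: List[AlleleRecord]  # emitted database (partial alleles truncated)
    truth_sequences: Dict[str, str]  # full sequence for every allele, by name
    allele_status: Dict[str, str]  # name -> complete | partial | novel
    novel_names: List[AlleleName]
    distractome: List[Tuple[str, str]]
    class_map: Dict[str, str]

    def complete_names(self) -> List[str]:
        return [n for n, s in self.allele_status.items() if s == "complete"]

    def genes(self) -> List[str]:
        return sorted({r.name.gene for r in self.records})

    def names_for_gene(self, gene: str, statuses=("complete",)) -> List[str]:
        return sorted(
            n for n, s in self.allele_status.items() if s in statuses and n.split("*")[0] == gene
        )


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(sequence: str, rate: float, rng: np.random.Generator, min_muts: int = 1) -> str:
    """Substitute a Binomial(L, rate) number of positions (at least
    ``min_muts`` so every child is distinct from its parent)."""
    L = len(sequence)
    n = max(min_muts, int(rng.binomial(L, rate)))
    n = min(n, L)
    positions = rng.choice(L, size=n, replace=False)
    arr = bytearray(sequence, "ascii")
    for pos in positions:
        current = arr[pos]
        options = [b for b in _ALPHABET if b != current]
        arr[pos] = int(options[rng.integers(0, 3)])
    return arr.decode("ascii")


def _partial_slice(sequence: str) -> Tuple[str, Tuple[int, ...]]:
    """Pseudo-exons 2-3 of six equal slices; the rest is reported missing."""
    L = len(sequence)
    bounds = [round(i * L / N_PSEUDO_EXONS) for i in range(N_PSEUDO_EXONS + 1)]
    kept = sequence[bounds[PARTIAL_KEPT_EXONS[0] - 1] : bounds[PARTIAL_KEPT_EXONS[-1]]]
    missing = tuple(e for e in range(1, N_PSEUDO_EXONS + 1) if e not in PARTIAL_KEPT_EXONS)
    return kept, missing


def generate_database(spec: FixtureSpec) -> FixtureWorld:
    """Generate the reference world for a fixture spec (seeded)."""
    rng = np.random.default_rng(spec.seed)
    root = _random_sequence(spec.gene_length, rng)
    records: List[AlleleRecord] = []
    truth: Dict[str, str] = {}
    class_map: Dict[str, str] = {}

    for g in range(spec.n_genes):
        gene = f"GF{g + 1}"
        class_map[gene] = "classI" if g % 2 == 0 else "classII"
        gene_seq = _mutate(root, spec.inter_gene_divergence, rng)
        group_seqs: Dict[int, str] = {}
        protein_seqs: Dict[Tuple[int, int], str] = {}
        for i in range(spec.alleles_per_gene):
            group = i // 5 + 1
            within = i % 5
            protein = within // 2 + 1
            syn = within % 2 + 1
            if group not in group_seqs:
                group_seqs[group] = _mutate(gene_seq, spec.group_divergence, rng)
            if (group, protein) not in protein_seqs:
                protein_seqs[(group, protein)] = _mutate(group_seqs[group], spec.protein_divergence, rng)
            base = protein_seqs[(group, protein)]
            seq = base if syn == 1 else _mutate(base, spec.synonymous_divergence, rng)
            name = AlleleName(gene, (f"{group:02d}", f"{protein:02d}", f"{syn:02d}"))
            truth[str(name)] = seq
            records.append(AlleleRecord(name, f"SYN{g:02d}{i:03d}", seq))

    n_alleles = len(records)
    n_partial = round(spec.partial_fraction * n_alleles)
    n_novel = round(spec.novel_fraction * n_alleles)
    special = rng.choice(n_alleles, size=min(n_alleles, n_partial + n_novel), replace=False)
    partial_idx = set(int(i) for i in special[:n_partial])
    novel_idx = set(int(i) for i in special[n_partial : n_partial + n_novel])

    status: Dict[str, str] = {}
    emitted: List[AlleleRecord] = []
    novel_names: List[AlleleName] = []
    for i, rec in enumerate(records):
        name = str(rec.name)
        if i in novel_idx:
            status[name] = "novel"
            novel_names.append(rec.name)
            continue  # held out of the database, kept in truth
        if i in partial_idx:
            kept, missing = _partial_slice(rec.sequence)
            emitted.append(replace(rec, sequence=kept, status="partial", missing_exons=missing))
            status[name] = "partial"
        else:
            emitted.append(rec)
            status[name] = "complete"

    distractome = [
        (f"TX{j + 1:04d}", _random_sequence(spec.distractome_length, rng))
        for j in range(spec.n_distractome)
    ]
    return FixtureWorld(spec, emitted, truth, status, novel_names, distractome, class_map)


def random_genotypes(
    world: FixtureWorld,
    rng: np.random.Generator,
    statuses: Tuple[str, ...] = ("complete",),
) -> Dict[str, Tuple[str, str]]:
    """Draw one diploid genotype per gene (with replacement, so homozygous
    genotypes occur). Defaults to complete-status alleles only, matching
    how evaluation datasets are assembled from fully known sequences."""
    genotypes = {}
    for gene in world.genes():
        eligible = world.names_for_gene(gene, statuses)
        picks = rng.choice(len(eligible), size=2, replace=True)
        genotypes[gene] = (eligible[int(picks[0])], eligible[int(picks[1])])
    return genotypes


def generate_sample(
    world: FixtureWorld,
    genotypes: Mapping[str, Tuple[str, str]],
    depth_pairs_per_gene: int,
    params: Optional[SimulationParams] = None,
    rng: Optional[np.random.Generator] = None,
    family_read_fraction: float = 0.8,
    sample_name: str = "S1",
) -> List[ReadPair]:
    """Simulate one diploid sample: family reads at the requested per-gene
    depth, split 50/50 between haplotypes by per-read Bernoulli draws, plus
    distractome background reads filling up to ``family_read_fraction``.

    Reads for each allele come from its full truth sequence, so partial and
    novel truth alleles are sequenced in full even though the database only
    knows their partial sequence or nothing at all (this stands in for the
    over-representation device that keeps family reads abundant in real
    transcriptome mixes).
    """
    if params is None:
        params = SimulationParams(num_reads=0, error_rate=0.001, base_quality=30)
    if rng is None:
        rng = np.random.default_rng(world.spec.seed + 1)
    if not 0 < family_read_fraction <= 1:
        raise ValueError("family_read_fraction must be in (0, 1]")
    reads: List[ReadPair] = []
    total_family = 0
    for gene in sorted(genotypes):
        a1, a2 = genotypes[gene]
        for allele in (a1, a2):
            if allele not in world.truth_sequences:
                raise ValueError(f"unknown allele {allele!r} in genotype for {gene}")
        if depth_pairs_per_gene == 0:
            continue
        n1 = int(rng.binomial(depth_pairs_per_gene, 0.5))
        for allele, n in ((a1, n1), (a2, depth_pairs_per_gene - n1)):
            if n == 0:
                continue
            p = replace(params, num_reads=n)
            prefix = f"{sample_name}_{gene}_{allele.replace('*', '_').replace(':', '-')}"
            reads.extend(simulate_read_pairs(world.truth_sequences[allele], p, rng=rng, name_prefix=prefix))
            total_family += n
    if world.distractome and family_read_fraction < 1 and total_family:
        n_background = int(round(total_family * (1 - family_read_fraction) / family_read_fraction))
        picks = rng.integers(0, len(world.distractome), size=n_background)
        counts = np.bincount(picks, minlength=len(world.distractome))
        for j, n in enumerate(counts):
            if n == 0:
                continue
            tid, seq = world.distractome[j]
            p = replace(params, num_reads=int(n))
            reads.extend(simulate_read_pairs(seq, p, rng=rng, name_prefix=f"{sample_name}_{tid}"))
    return reads


# ---------------------------------------------------------------------------
# Accuracy evaluation


@dataclass
class EvalResult:
    precision: object  # 1, 2 or "exact"
    per_gene: Dict[str, Tuple[int, int]]  # gene -> (correct alleles, total alleles)
    overall_correct: int
    overall_total: int

    @property
    def overall_accuracy(self) -> float:
        return self.overall_correct / self.overall_total if self.overall_total else float("nan")

    def gene_accuracy(self, gene: str) -> float:
        c, t = self.per_gene[gene]
        return c / t if t else float("nan")


def _reduce_name(name: str, precision, ambiguity_map: Optional[Mapping[str, str]]) -> str:
    from .nomenclature import parse_allele_name

    if ambiguity_map and name in ambiguity_map:
        name = ambiguity_map[name]
    parsed = parse_allele_name(name)
    if precision == "exact":
        return str(parsed.with_suffix(""))
    return str(truncate_precision(parsed, precision))


def _pair_correct(
    called: Optional[Sequence[Sequence[str]]],
    truth_pair: Tuple[str, str],
    precision,
    ambiguity_map,
) -> int:
    """Correct-allele count (0-2) for one gene call under the best
    assignment of called entries to truth alleles. ``called`` holds, per
    called allele, the set of acceptable names (merged identical sequences
    expanded); a missing call counts both truth alleles incorrect."""
    truth_red = [_reduce_name(t, precision, ambiguity_map) for t in truth_pair]
    if not called:
        return 0
    reduced: List[set] = [
        {_reduce_name(n, precision, ambiguity_map) for n in entry} for entry in called
    ]
    while len(reduced) < 2:
        reduced.append(set())
    best = 0
    for perm in itertools.permutations(range(2)):
        score = sum(1 for t_idx, c_idx in enumerate(perm) if truth_red[t_idx] in reduced[c_idx])
        best = max(best, score)
    return best


def evaluate_calls(
    calls: Mapping[Tuple[str, str], Optional[Sequence[Sequence[str]]]],
    truth: Mapping[Tuple[str, str], Tuple[str, str]],
    precision,
    ambiguity_map: Optional[Mapping[str, str]] = None,
) -> EvalResult:
    """Per-gene and overall typing accuracy at a precision level.

    ``calls`` and ``truth`` are keyed by (sample, gene); every truth entry
    is graded, and an absent or None call counts its alleles incorrect.
    ``precision`` is 1 (allele group), 2 (protein) or "exact". The optional
    ambiguity map collapses names before comparison.
    """
    if precision not in (1, 2, "exact"):
        raise ValueError(f"precision must be 1, 2 or 'exact', got {precision!r}")
    per_gene: Dict[str, List[int]] = {}
    for (sample, gene), truth_pair in truth.items():
        correct = _pair_correct(calls.get((sample, gene)), truth_pair, precision, ambiguity_map)
        acc = per_gene.setdefault(gene, [0, 0])
        acc[0] += correct
        acc[1] += 2
    total_c = sum(v[0] for v in per_gene.values())
    total_n = sum(v[1] for v in per_gene.values())
    return EvalResult(precision, {g: (v[0], v[1]) for g, v in per_gene.items()}, total_c, total_n)
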