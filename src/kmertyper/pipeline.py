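"""End-to-end typing pipeline: build a reference database, call samples.

``build_database`` merges identical alleles, builds the taxonomy and the
31-mer classifier, simulates reads per allele and aggregates them into
50-mer reference profiles. ``call_sample`` bins a sample's read pairs by
gene, builds the filtered sample profile, selects candidate pairs by the
profile Error, runs the competitive alignment, and optionally refines the
called pair against the observed reads.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .alignment import CallScore, adjust_asm, build_asm, score_candidates
from .candidates import PairScore, score_all_pairs, select_finalists, select_semifinalists
from .classifier import KmerClassifierDB, ReadBinning, bin_reads
from .nomenclature import (
    AlleleRecord,
    merge_identical_sequences,
    read_reference_fasta,
    write_reference_fasta,
)
from .profiles import (
    KmerProfile,
    build_sample_profile,
    count_read_kmers,
    load_profiles,
    save_profiles,
)
from .refine import RefinedCall, call_substitutions, classify_refined, recalculate_refined, remap_with_one_mismatch
from .sequtils import ReadPair
from .simulate import SimulationParams, simulate_read_pairs
from .taxonomy import TaxonomyTree, build_taxonomy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReferenceDatabase", "build_database", "build_reference_profiles", "GeneCall", "call_sample", "write_call_report"]

REPORT_SCHEMA = "kmertyper-call-report v1"


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters; defaults follow the published method."""

    k_filter: int = 31
    k_profile: int = 50
    n_semifinalists: int = 100
    m_finalists: int = 20
    q_min: float = 20.0
    power: float = 0.25
    refinement: str = "off"  # off | on | recalculate | all
    min_count_threshold: int = 1
    depth_alpha: float = 0.0
    min_gene_reads: int = 1000
    unstranded: bool = False
    seed: int = 0
    threads: int = 1  # accepted for interface compatibility; execution is serial
    reference_read_pairs: int = 500_000
    read_length: int = 50

    def __post_init__(self):
        if self.refinement not in ("off", "on", "recalculate", "all"):
            raise ValueError(f"invalid refinement mode {self.refinement!r}")


@dataclass
class ReferenceDatabase:
    """Everything needed to type samples: taxonomy, classifier, profiles."""

    config: RunConfig
    records: List[AlleleRecord]  # merged
    distractome: List[Tuple[str, str]]
    class_map: Dict[str, str]
    taxonomy: TaxonomyTree
    classifier: KmerClassifierDB
    profiles: Dict[str, Dict[str, KmerProfile]]  # gene -> allele -> profile
    sim_params: SimulationParams

    def record_by_name(self, name: str) -> AlleleRecord:
        return self._by_name[name]

    def gene_records(self, gene: str) -> List[AlleleRecord]:
        return [r for r in self.records if r.name.gene == gene]

    def sequence_of(self, name: str) -> str:
        return self._by_name[name].sequence

    def merged_names(self, name: str) -> List[str]:
        return sorted(str(n) for n in self._by_name[name].merged_names)

    def __post_init__(self):
        self._by_name = {str(r.name): r for r in self.records}

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        directory = str(directory)
        os.makedirs(directory, exist_ok=True)
        write_reference_fasta(self.records, os.path.join(directory, "reference.fasta"))
        with open(os.path.join(directory, "merged_names.tsv"), "w") as fh:
            for rec in self.records:
                fh.write(f"{rec.name}\t{';'.join(sorted(map(str, rec.merged_names)))}\n")
        with open(os.path.join(directory, "distractome.fasta"), "w") as fh:
            for tid, seq in self.distractome:
                fh.write(f">{tid}\n{seq}\n")
        self.taxonomy.export_dmp(os.path.join(directory, "taxonomy"))
        save_profiles(
            os.path.join(directory, "profiles"),
            self.profiles,
            {str(r.name): sorted(map(str, r.merged_names)) for r in self.records},
        )
        manifest = {
            "schema": "kmertyper-db v1",
            "config": asdict(self.config),
            "sim_params": asdict(self.sim_params),
            "class_map": self.class_map,
            "n_alleles": len(self.records),
            "n_distractome": len(self.distractome),
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, directory) -> "ReferenceDatabase":
        """Reload a persisted database. The 31-mer map is rebuilt from the
        stored sequences (deterministic and fast at the scales this package
        targets, so it is not serialized)."""
        directory = str(directory)
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        config = RunConfig(**manifest["config"])
        sim_params = SimulationParams(**manifest["sim_params"])
        records = read_reference_fasta(os.path.join(directory, "reference.fasta"))
        merged: Dict[str, List[str]] = {}
        with open(os.path.join(directory, "merged_names.tsv")) as fh:
            for line in fh:
                name, names = line.rstrip("\n").split("\t")
                merged[name] = names.split(";")
        from .nomenclature import parse_allele_name

        records = [
            replace(r, merged_names=frozenset(parse_allele_name(n) for n in merged[str(r.name)]))
            for r in records
        ]
        from .nomenclature import read_transcript_fasta

        distractome = read_transcript_fasta(os.path.join(directory, "distractome.fasta"))
        taxonomy = build_taxonomy(records, distractome, manifest["class_map"])
        classifier = _build_classifier(taxonomy, records, distractome, config.k_filter)
        profiles = load_profiles(os.path.join(directory, "profiles"))
        return cls(config, records, distractome, dict(manifest["class_map"]), taxonomy, classifier, profiles, sim_params)


def _build_classifier(
    taxonomy: TaxonomyTree,
    records: Sequence[AlleleRecord],
    distractome: Sequence[Tuple[str, str]],
    k: int,
) -> KmerClassifierDB:
    sequences: Dict[int, str] = {}
    for rec in records:
        sequences[taxonomy.leaf_map[str(rec.name)]] = rec.sequence
    for tid, seq in distractome:
        sequences[taxonomy.distractome_map[tid]] = seq
    return KmerClassifierDB.build(taxonomy, sequences, k)


def build_reference_profiles(
    records: Sequence[AlleleRecord],
    classifier: KmerClassifierDB,
    sim_params: SimulationParams,
    k_profile: int,
    base_seed: int = 0,
    unstranded: bool = False,
) -> Dict[str, Dict[str, KmerProfile]]:
    """Simulate reads per merged allele, bin them, and count 50-mers.

    Only reads the classifier bins to the allele's own gene contribute to
    its profile, exactly as sample reads will be filtered at call time.
    Deterministic given ``base_seed`` (one spawned stream per allele).
    """
    gene_nodes = classifier.taxonomy.gene_nodes()
    profiles: Dict[str, Dict[str, KmerProfile]] = {}
    seeds = np.random.SeedSequence(base_seed).spawn(len(records))
    for rec, seed in zip(records, seeds):
        rng = np.random.default_rng(seed)
        gene = rec.name.gene
        reads = simulate_read_pairs(rec.sequence, sim_params, rng=rng, name_prefix="ref")
        binning = bin_reads(reads, classifier, unstranded=unstranded)
        own_bin = binning.bins.get(gene_nodes[gene], [])
        profile = count_read_kmers(own_bin, k_profile, owner=str(rec.name))
        if not profile:
            logger.warning("allele %s: no reads binned to its own gene; empty profile", rec.name)
        profiles.setdefault(gene, {})[str(rec.name)] = profile
    return profiles


def build_database(
    records: Sequence[AlleleRecord],
    distractome: Sequence[Tuple[str, str]] = (),
    class_map: Optional[Mapping[str, str]] = None,
    config: RunConfig = RunConfig(),
    sim_params: Optional[SimulationParams] = None,
) -> ReferenceDatabase:
    """Merge records, build taxonomy + classifier + reference profiles."""
    if not distractome:
        logger.warning("no distractome provided; homologous non-family reads may misbin")
    merged = merge_identical_sequences(records)
    taxonomy = build_taxonomy(merged, distractome, class_map)
    classifier = _build_classifier(taxonomy, merged, distractome, config.k_filter)
    if sim_params is None:
        sim_params = SimulationParams(
            num_reads=config.reference_read_pairs, read_length=config.read_length, error_rate=0.0
        )
    profiles = build_reference_profiles(
        merged, classifier, sim_params, config.k_profile, base_seed=config.seed, unstranded=config.unstranded
    )
    return ReferenceDatabase(
        config, merged, list(distractome), dict(class_map or {}), taxonomy, classifier, profiles, sim_params
    )


# ---------------------------------------------------------------------------
# Calling


@dataclass
class GeneCall:
    """Typing result for one gene of one sample."""

    gene: str
    status: str  # "called" | "uncallable"
    allele1: Optional[str] = None
    allele2: Optional[str] = None
    merged1: List[str] = field(default_factory=list)
    merged2: List[str] = field(default_factory=list)
    pair_score: Optional[PairScore] = None
    call_score: Optional[CallScore] = None
    n_filtered_reads: int = 0
    refinements: List[RefinedCall] = field(default_factory=list)
    note: str = ""

    def called_names(self) -> Optional[List[List[str]]]:
        """Acceptable names per called allele (merged groups expanded, a
        refined rename appended), as consumed by evaluate_calls."""
        if self.status != "called":
            return None
        out = []
        for base, merged, idx in ((self.allele1, self.merged1, 0), (self.allele2, self.merged2, 1)):
            names = list(merged or [base])
            if idx < len(self.refinements):
                rc = self.refinements[idx]
                if rc.classification != "unchanged":
                    names.append(str(rc.refined_name))
            out.append(names)
        return out


def _profile_builder(db: ReferenceDatabase, rng: np.random.Generator):
    """Reference-style profile for an ad-hoc (refined) sequence: simulate
    reads with the database's parameters and count k-mers directly."""

    def build(name: str, sequence: str) -> KmerProfile:
        reads = simulate_read_pairs(sequence, db.sim_params, rng=rng, name_prefix="refine")
        return count_read_kmers(reads, db.config.k_profile, owner=name)

    return build


def call_sample(
    db: ReferenceDatabase,
    pairs: Iterable[ReadPair],
    config: Optional[RunConfig] = None,
    sample_name: str = "sample",
) -> List[GeneCall]:
    """Type every gene of the database from one sample's read pairs."""
    config = config or db.config
    if config.k_profile > config.read_length:
        raise ValueError(
            f"profile k-mer size {config.k_profile} exceeds read length {config.read_length}; "
            "profiles would be empty"
        )
    binning = bin_reads(pairs, db.classifier, unstranded=config.unstranded)
    gene_bins = binning.gene_bins()
    calls: List[GeneCall] = []
    for gene in sorted(db.profiles):
        reads = gene_bins.get(gene, [])
        call = GeneCall(gene=gene, status="uncallable", n_filtered_reads=len(reads))
        if len(reads) < config.min_gene_reads:
            call.note = f"only {len(reads)} filtered reads (< {config.min_gene_reads})"
            calls.append(call)
            continue
        sample_profile = build_sample_profile(
            reads, config.k_profile, config.min_count_threshold, config.depth_alpha, owner=f"{sample_name}:{gene}"
        )
        allele_profiles = {n: p for n, p in db.profiles[gene].items() if p}
        semis = select_semifinalists(allele_profiles, sample_profile, config.n_semifinalists)
        if not semis:
            call.note = "empty sample profile after filtering"
            calls.append(call)
            continue
        pair_scores = score_all_pairs(semis, allele_profiles, sample_profile)
        finalists = select_finalists(pair_scores, config.m_finalists)
        asm = build_asm(
            reads,
            [s.pair for s in finalists],
            {n: db.sequence_of(n) for n in {a for s in finalists for a in s.pair}},
            q_min=config.q_min,
            unstranded=config.unstranded,
        )
        adjusted = adjust_asm(asm)
        errors = {s.pair: s.error for s in finalists}
        ranked = score_candidates(adjusted, errors, config.power)
        top = ranked[0]
        a1, a2 = top.pair
        call.status = "called"
        call.allele1, call.allele2 = a1, a2
        call.merged1, call.merged2 = db.merged_names(a1), db.merged_names(a2)
        call.pair_score = next(s for s in finalists if s.pair == top.pair)
        call.call_score = top
        if config.refinement != "off":
            call.refinements = _refine_call(db, config, reads, (a1, a2), call.pair_score, sample_profile)
        calls.append(call)
    return calls


def _refine_call(
    db: ReferenceDatabase,
    config: RunConfig,
    reads: List[ReadPair],
    called_pair: Tuple[str, str],
    pair_score: PairScore,
    sample_profile,
) -> List[RefinedCall]:
    a1, a2 = called_pair
    sequences = {a1: db.sequence_of(a1)}
    sequences.setdefault(a2, db.sequence_of(a2))
    support = remap_with_one_mismatch(reads, sequences)
    refined: Dict[str, RefinedCall] = {}
    for name, sup in support.items():
        seq, subs = call_substitutions(sup, sequences[name])
        rec = db.record_by_name(name)
        refined[name] = classify_refined(seq, rec.name, subs, db.gene_records(rec.name.gene))
    mode = config.refinement
    if mode in ("recalculate", "all"):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        builder = _profile_builder(db, rng)
        gene = db.record_by_name(a1).name.gene
        for name, rc in refined.items():
            partner = a2 if name == a1 else a1
            recalculate_refined(rc, db.profiles[gene][partner], sample_profile, builder, mode)
    return [refined[a1], refined.get(a2, refined[a1])]


def write_call_report(calls_by_sample: Mapping[str, Sequence[GeneCall]], path) -> None:
    """Versioned TSV call report, one row per sample x gene."""
    cols = [
        "sample", "gene", "status", "allele1", "allele2", "merged1", "merged2",
        "prop_reads", "prop_prof", "cor", "error", "row_sum", "col_sum", "score",
        "n_filtered_reads", "refined1", "refined2", "substitutions", "note",
    ]
    with open(str(path), "w") as fh:
        fh.write(f"# {REPORT_SCHEMA}\n")
        fh.write("\t".join(cols) + "\n")
        for sample in sorted(calls_by_sample):
            for call in calls_by_sample[sample]:
                ps, cs = call.pair_score, call.call_score
                refined = ["", ""]
                subs = []
                for i, rc in enumerate(call.refinements[:2]):
                    refined[i] = f"{rc.refined_name}:{rc.classification}"
                    subs.extend(f"{p}{r}>{a}@{f:.2f}" for p, r, a, f in rc.substitutions)
                row = [
                    sample, call.gene, call.status,
                    call.allele1 or "", call.allele2 or "",
                    ";".join(call.merged1), ";".join(call.merged2),
                    f"{ps.prop_reads:.6f}" if ps else "", f"{ps.prop_prof:.6f}" if ps else "",
                    f"{ps.cor:.6f}" if ps else "", f"{ps.error:.6f}" if ps else "",
                    f"{cs.row_sum:.4f}" if cs else "", f"{cs.col_sum:.4f}" if cs else "",
                    f"{cs.score:.6f}" if cs else "",
                    str(call.n_filtered_reads),
                    refined[0], refined[1], ";".join(subs), call.note,
                ]
                fh.write("\t".join(row) + "\n")
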