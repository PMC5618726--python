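"""Taxonomic k-mer classification of read pairs (Kraken-style, in memory).

Every 31-mer of every leaf sequence (both strands, no canonicalization) maps
to the lowest common ancestor of the leaves containing it. A read pair is
classified by counting database hits over the k-mers of both mates (read 1
reverse complemented first), scoring every root-to-leaf path by the summed
hit counts of its nodes, and assigning the pair to the LCA of all leaves
attaining the maximal path score. Reads classified below gene rank are
lifted to their gene for binning; distractome and unclassified pairs are
excluded from the family bins.
"""

from __future__ import annotations

import logging
import os
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

from .sequtils import ReadPair, iter_kmers, revcomp
from .taxonomy import DISTRACTOME_LABEL, TaxonomyTree

logger = logging.getLogger(__name__)

__all__ = ["KmerClassifierDB", "ReadBinning", "bin_reads"]


class KmerClassifierDB:
    """Map from 31-mers to taxonomy nodes via lowest common ancestors."""

    def __init__(self, taxonomy: TaxonomyTree, k: int, kmer_map: Dict[str, int]):
        self.taxonomy = taxonomy
        self.k = k
        self.kmer_map = kmer_map
        self._precompute()

    def _precompute(self) -> None:
        tax = self.taxonomy
        self._ancestors: Dict[int, FrozenSet[int]] = {
            nid: frozenset(tax.ancestors(nid)) for nid in tax.nodes
        }
        self._depth: Dict[int, int] = {nid: len(tax.ancestors(nid)) for nid in tax.nodes}
        # leaf_lca[n] = LCA of all leaves in n's subtree: n itself when the
        # subtree branches, the single descendant leaf when it is a chain.
        self._leaf_lca: Dict[int, int] = {}
        order = sorted(tax.nodes, key=lambda n: -self._depth[n])
        for nid in order:
            kids = tax.children(nid)
            if not kids:
                self._leaf_lca[nid] = nid
            elif len(kids) == 1:
                self._leaf_lca[nid] = self._leaf_lca[kids[0]]
            else:
                self._leaf_lca[nid] = nid

    # -- construction --------------------------------------------------------

    @classmethod
    def build(
        cls, taxonomy: TaxonomyTree, sequences: Mapping[int, str], k: int = 31
    ) -> "KmerClassifierDB":
        """Build the database from leaf-node sequences.

        ``sequences`` maps leaf node ids (family alleles and distractome
        transcripts) to nucleotide strings. Both strands of every sequence
        are indexed; a k-mer seen under several leaves maps to their LCA.
        """
        if k < 4:
            raise ValueError(f"k must be >= 4, got {k}")
        kmer_map: Dict[str, int] = {}
        tax = taxonomy
        for leaf, seq in sequences.items():
            if leaf not in tax.nodes:
                raise ValueError(f"unknown taxonomy node {leaf}")
            for strand in (seq, revcomp(seq)):
                for kmer in iter_kmers(strand, k):
                    cur = kmer_map.get(kmer)
                    if cur is None:
                        kmer_map[kmer] = leaf
                    elif cur != leaf:
                        kmer_map[kmer] = tax.lca(cur, leaf)
        return cls(taxonomy, k, kmer_map)

    # -- classification ------------------------------------------------------

    def _hit_counts(self, pair: ReadPair, unstranded: bool) -> Counter:
        k = self.k
        get = self.kmer_map.get
        if unstranded:
            queries = (pair.seq1, revcomp(pair.seq1), pair.seq2, revcomp(pair.seq2))
        else:
            queries = (revcomp(pair.seq1), pair.seq2)
        counts: Counter = Counter()
        for seq in queries:
            if len(seq) < k:
                continue  # short mate contributes no k-mers
            for kmer in iter_kmers(seq, k):
                node = get(kmer)
                if node is not None:
                    counts[node] += 1
        return counts

    def classify_with_hits(
        self, pair: ReadPair, unstranded: bool = False
    ) -> Tuple[Optional[int], int]:
        """Classify one pair; returns (node id or None, total db hits)."""
        counts = self._hit_counts(pair, unstranded)
        if not counts:
            return None, 0
        total = sum(counts.values())
        # Path score of a leaf equals the chain score of its deepest hit
        # ancestor, so only hit nodes need scoring. A hit node's chain score
        # is the hit mass on its ancestor-or-self set; maximal chain-score
        # nodes are never ancestors of one another (a hit descendant always
        # scores strictly higher).
        best_score = -1
        best_nodes: List[int] = []
        items = list(counts.items())
        for node, _ in items:
            anc = self._ancestors[node]
            score = sum(c for n, c in items if n in anc)
            if score > best_score:
                best_score, best_nodes = score, [node]
            elif score == best_score:
                best_nodes.append(node)
        result = self._leaf_lca[best_nodes[0]]
        for node in best_nodes[1:]:
            result = self.taxonomy.lca(result, self._leaf_lca[node])
        return result, total

    def classify_read_pair(self, pair: ReadPair, unstranded: bool = False) -> Optional[int]:
        return self.classify_with_hits(pair, unstranded)[0]


@dataclass
class ReadBinning:
    """Read pairs grouped by gene-rank-or-higher taxonomy nodes."""

    taxonomy: TaxonomyTree
    bins: Dict[int, List[ReadPair]] = field(default_factory=dict)
    unclassified: int = 0
    assignments: Optional[List[Tuple[str, int, int]]] = None  # (read, node, hits)

    @property
    def total_binned(self) -> int:
        return sum(len(v) for v in self.bins.values())

    def gene_bins(self) -> Dict[str, List[ReadPair]]:
        """Family gene-rank bins only (label -> pairs); these feed profiles."""
        out = {}
        for node, pairs in self.bins.items():
            tn = self.taxonomy.nodes[node]
            if tn.rank == "gene" and not self.taxonomy.is_under(node, DISTRACTOME_LABEL):
                out[tn.label] = pairs
        return out

    def diagnostic_counts(self) -> Dict[str, int]:
        counts = {self.taxonomy.label(node): len(pairs) for node, pairs in self.bins.items()}
        counts["unclassified"] = self.unclassified
        return counts

    def write_fastq(self, directory) -> None:
        from .sequtils import write_fastq_pairs

        os.makedirs(str(directory), exist_ok=True)
        for node, pairs in self.bins.items():
            label = re.sub(r"[^A-Za-z0-9._-]", "_", self.taxonomy.label(node))
            write_fastq_pairs(
                pairs,
                os.path.join(str(directory), f"{label}.R1.fastq"),
                os.path.join(str(directory), f"{label}.R2.fastq"),
            )

    def write_classification_tsv(self, path) -> None:
        if self.assignments is None:
            raise ValueError("binning was run without keep_assignments=True")
        with open(str(path), "w") as fh:
            fh.write("read\tnode_id\tnode_label\thits\n")
            for name, node, hits in self.assignments:
                label = self.taxonomy.label(node) if node else "unclassified"
                fh.write(f"{name}\t{node or 0}\t{label}\t{hits}\n")


def bin_reads(
    pairs: Iterable[ReadPair],
    db: KmerClassifierDB,
    unstranded: bool = False,
    keep_assignments: bool = False,
) -> ReadBinning:
    """Classify a stream of pairs and group them by gene-or-higher node.

    Every input pair lands in exactly one bin or the unclassified counter,
    so bin sizes plus unclassified always sum to the input count.
    """
    binning = ReadBinning(db.taxonomy, assignments=[] if keep_assignments else None)
    tax = db.taxonomy
    lift_cache: Dict[int, int] = {}
    for pair in pairs:
        node, hits = db.classify_with_hits(pair, unstranded)
        if node is None:
            binning.unclassified += 1
            if keep_assignments:
                binning.assignments.append((pair.name, 0, 0))
            continue
        target = lift_cache.get(node)
        if target is None:
            target = tax.gene_or_higher(node)
            lift_cache[node] = target
        binning.bins.setdefault(target, []).append(pair)
        if keep_assignments:
            binning.assignments.append((pair.name, target, hits))
    return binning
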