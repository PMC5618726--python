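"""Custom classification taxonomy for k-mer read binning.

The tree mirrors the allele nomenclature: a single root with two branches —
the target gene family and the "distractome" of all other transcripts
(absorbing homologous reads). The family branch splits into class branches
(class I / class II / other), then gene nodes, then one field node per
precision level present in the data, down to allele leaves. Distractome
transcripts attach as leaves directly under the distractome branch.

The node and name tables export to (and re-import from) the tab-pipe NCBI
``names.dmp`` / ``nodes.dmp`` dump dialect.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .nomenclature import AlleleName, AlleleRecord, truncate_precision

__all__ = ["TaxNode", "TaxonomyTree", "build_taxonomy", "FAMILY_LABEL", "DISTRACTOME_LABEL"]

FAMILY_LABEL = "family"
DISTRACTOME_LABEL = "distractome"

RANKS = ("root", "branch", "class", "gene", "field", "allele")
_GENE_OR_HIGHER = frozenset({"gene", "class", "branch", "root"})


@dataclass(frozen=True)
class TaxNode:
    node_id: int
    label: str
    parent: int
    rank: str


@dataclass
class TaxonomyTree:
    nodes: Dict[int, TaxNode] = field(default_factory=dict)
    root_id: int = 1
    # leaf ids for family alleles keyed by rendered representative name
    leaf_map: Dict[str, int] = field(default_factory=dict)
    # leaf ids for distractome transcripts keyed by transcript id
    distractome_map: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self._children: Dict[int, List[int]] = {}

    # -- construction -------------------------------------------------------

    def _add(self, label: str, parent: Optional[int], rank: str) -> int:
        node_id = len(self.nodes) + 1
        if parent is None:
            parent = node_id  # NCBI convention: the root is its own parent
        node = TaxNode(node_id, label, parent, rank)
        self.nodes[node_id] = node
        if parent != node_id:
            self._children.setdefault(parent, []).append(node_id)
        return node_id

    # -- queries -------------------------------------------------------------

    def children(self, node_id: int) -> List[int]:
        return self._children.get(node_id, [])

    def parent(self, node_id: int) -> int:
        return self.nodes[node_id].parent

    def rank(self, node_id: int) -> str:
        return self.nodes[node_id].rank

    def label(self, node_id: int) -> str:
        return self.nodes[node_id].label

    def ancestors(self, node_id: int) -> List[int]:
        """Path from ``node_id`` up to and including the root (self first)."""
        path = [node_id]
        while self.nodes[path[-1]].parent != path[-1]:
            path.append(self.nodes[path[-1]].parent)
        return path

    def lca(self, a: int, b: int) -> int:
        anc_a = set(self.ancestors(a))
        for n in self.ancestors(b):
            if n in anc_a:
                return n
        raise ValueError("disconnected nodes")  # pragma: no cover

    def gene_or_higher(self, node_id: int) -> int:
        """Lift a classification to the nearest gene-rank-or-higher node."""
        n = node_id
        while self.nodes[n].rank not in _GENE_OR_HIGHER:
            n = self.nodes[n].parent
        return n

    def is_under(self, node_id: int, ancestor_label: str) -> bool:
        return any(self.nodes[n].label == ancestor_label for n in self.ancestors(node_id))

    def gene_nodes(self) -> Dict[str, int]:
        return {n.label: n.node_id for n in self.nodes.values() if n.rank == "gene"}

    def leaf_ids(self) -> List[int]:
        return [nid for nid in self.nodes if not self._children.get(nid)]

    # -- NCBI dump export/import --------------------------------------------

    def export_dmp(self, directory) -> None:
        os.makedirs(str(directory), exist_ok=True)
        with open(os.path.join(str(directory), "names.dmp"), "w") as fh:
            for nid in sorted(self.nodes):
                n = self.nodes[nid]
                fh.write(f"{nid}\t|\t{n.label}\t|\t\t|\tscientific name\t|\n")
        with open(os.path.join(str(directory), "nodes.dmp"), "w") as fh:
            for nid in sorted(self.nodes):
                n = self.nodes[nid]
                fh.write(f"{nid}\t|\t{n.parent}\t|\t{n.rank}\t|\n")

    @classmethod
    def import_dmp(cls, directory) -> "TaxonomyTree":
        names: Dict[int, str] = {}
        with open(os.path.join(str(directory), "names.dmp")) as fh:
            for line in fh:
                parts = [p.strip() for p in line.split("|")]
                nid = int(parts[0].rstrip("\t"))
                names[nid] = parts[1]
        tree = cls()
        with open(os.path.join(str(directory), "nodes.dmp")) as fh:
            for line in fh:
                parts = [p.strip() for p in line.split("|")]
                nid, parent, rank = int(parts[0]), int(parts[1]), parts[2]
                node = TaxNode(nid, names[nid], parent, rank)
                tree.nodes[nid] = node
                if parent != nid:
                    tree._children.setdefault(parent, []).append(nid)
                else:
                    tree.root_id = nid
        # leaves cannot be reattached to records from a dump alone; rebuild
        # the label maps from leaf labels.
        for nid in tree.leaf_ids():
            node = tree.nodes[nid]
            if tree.is_under(nid, DISTRACTOME_LABEL):
                tree.distractome_map[node.label] = nid
            elif node.rank == "allele":
                tree.leaf_map[node.label] = nid
        return tree

    def same_topology(self, other: "TaxonomyTree") -> bool:
        return {(n.node_id, n.label, n.parent, n.rank) for n in self.nodes.values()} == {
            (n.node_id, n.label, n.parent, n.rank) for n in other.nodes.values()
        }


def build_taxonomy(
    records: Sequence[AlleleRecord],
    distractome: Iterable[Tuple[str, str]] = (),
    class_map: Optional[Mapping[str, str]] = None,
) -> TaxonomyTree:
    """Build the classification tree from merged allele records.

    ``class_map`` assigns genes to branches ``classI`` / ``classII`` /
    ``other``; unlisted genes fall in ``other``. Field nodes are created only
    for the precision prefixes that actually occur. A duplicate leaf name
    (two records rendering the same name) is an error — records must have
    been merged first.
    """
    class_map = dict(class_map or {})
    tree = TaxonomyTree()
    root = tree._add("root", None, "root")
    family = tree._add(FAMILY_LABEL, root, "branch")
    distract = tree._add(DISTRACTOME_LABEL, root, "branch")

    class_nodes: Dict[str, int] = {}

    def class_node(cls_label: str) -> int:
        if cls_label not in class_nodes:
            class_nodes[cls_label] = tree._add(cls_label, family, "class")
        return class_nodes[cls_label]

    gene_nodes: Dict[str, int] = {}
    field_nodes: Dict[str, int] = {}

    for rec in records:
        name = rec.name
        gene = name.gene
        if gene not in gene_nodes:
            cls = class_map.get(gene, "other")
            if cls not in ("classI", "classII", "other"):
                raise ValueError(f"invalid class {cls!r} for gene {gene}")
            gene_nodes[gene] = tree._add(gene, class_node(cls), "gene")
        parent = gene_nodes[gene]
        # one field node per strict precision prefix present in this name
        for depth in range(1, name.n_fields):
            prefix = str(truncate_precision(name, depth))
            key = f"field:{prefix}"
            if key not in field_nodes:
                field_nodes[key] = tree._add(prefix, parent, "field")
            parent = field_nodes[key]
        leaf_label = str(name)
        if leaf_label in tree.leaf_map:
            raise ValueError(f"duplicate leaf {leaf_label!r}; merge records first")
        tree.leaf_map[leaf_label] = tree._add(leaf_label, parent, "allele")

    for tid, _seq in distractome:
        if tid in tree.distractome_map:
            raise ValueError(f"duplicate distractome transcript {tid!r}")
        tree.distractome_map[tid] = tree._add(tid, distract, "allele")

    return tree
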