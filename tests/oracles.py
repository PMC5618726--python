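"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the classification
oracle enumerates every root-to-leaf path and computes the LCA by common
path prefix rather than reusing the classifier's chain-score shortcut.
"""

from collections import Counter

from kmertyper.sequtils import iter_kmers, revcomp


def path_to_root(tree, node):
    path = [node]
    while tree.nodes[path[-1]].parent != path[-1]:
        path.append(tree.nodes[path[-1]].parent)
    return path


def lca_by_prefix(tree, nodes):
    """LCA of a node set via the common prefix of root-down paths."""
    paths = [list(reversed(path_to_root(tree, n))) for n in nodes]
    lca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        level = {p[depth] for p in paths}
        if len(level) != 1:
            break
        lca = level.pop()
    return lca


def oracle_classify(db, pair):
    """Exhaustive path-scoring classification of one read pair.

    Hits are recounted from the k-mer map, every leaf's path score is the
    sum of hit counts over its ancestor chain, and the result is the LCA of
    all maximal-score leaves (None if there are no hits at all).
    """
    counts = Counter()
    for seq in (revcomp(pair.seq1), pair.seq2):
        for kmer in iter_kmers(seq, db.k):
            node = db.kmer_map.get(kmer)
            if node is not None:
                counts[node] += 1
    if not counts:
        return None
    tree = db.taxonomy
    leaves = [n for n in tree.nodes if not tree.children(n)]
    scores = {leaf: sum(counts.get(a, 0) for a in path_to_root(tree, leaf)) for leaf in leaves}
    best = max(scores.values())
    winners = [leaf for leaf, s in scores.items() if s == best]
    return lca_by_prefix(tree, winners)


def oracle_kmer_node(db, kmer):
    """Expected database node for a k-mer: scan every leaf sequence (both
    strands) for containment and take the LCA of the containing leaves."""
    tree = db.taxonomy
    hits = []
    for label, leaf in list(tree.leaf_map.items()) + list(tree.distractome_map.items()):
        seq = db._oracle_sequences[leaf]  # attached by the test
        if kmer in seq or kmer in revcomp(seq):
            hits.append(leaf)
    if not hits:
        return None
    return lca_by_prefix(tree, hits)
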