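"""k-mer count profiles (default k = 50) for alleles and gene-binned samples.

A profile is a multiset of fixed-length k-mers with counts. Reference
profiles are built per allele from simulated, classifier-binned reads;
sample profiles come from the gene-binned reads of the sample, with
infrequent k-mers (count <= 1 by default) dropped to suppress sequencing
error. The fraction of an allele profile observed in a sample is the first
filtering statistic of candidate selection.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

from .sequtils import ReadPair, iter_kmers, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "KmerProfile",
    "count_read_kmers",
    "build_sample_profile",
    "fraction_profile_observed",
    "save_profiles",
    "load_profiles",
]


@dataclass
class KmerProfile:
    """Multiset of k-mers with counts, owned by an allele or a gene bin."""

    owner: str
    k: int
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)


def count_read_kmers(pairs: Iterable[ReadPair], k: int, owner: str = "") -> KmerProfile:
    """Count forward-strand k-mers across a stream of read pairs.

    Read 1 is reverse complemented first; a read of length L contributes
    max(0, L-k+1) k-mers, and windows containing non-ACGT characters are
    skipped.
    """
    counts: Dict[str, int] = {}
    for pair in pairs:
        for seq in (revcomp(pair.seq1), pair.seq2):
            for kmer in iter_kmers(seq, k):
                counts[kmer] = counts.get(kmer, 0) + 1
    return KmerProfile(owner, k, counts)


def build_sample_profile(
    pairs: Iterable[ReadPair],
    k: int,
    min_count_threshold: int = 1,
    depth_alpha: float = 0.0,
    owner: str = "sample",
) -> KmerProfile:
    """Observed-profile builder: count k-mers, then drop infrequent ones.

    K-mers with count <= ``min_count_threshold`` (default 1: singletons,
    mostly sequencing error) are removed. ``depth_alpha`` optionally scales
    the threshold with the mean per-k-mer depth:
    threshold = max(min_count_threshold, ceil(alpha * mean depth)).
    An empty bin yields an empty profile.
    """
    profile = count_read_kmers(pairs, k, owner=owner)
    if not profile.counts:
        return profile
    threshold = min_count_threshold
    if depth_alpha > 0:
        mean_depth = profile.total / len(profile.counts)
        threshold = max(threshold, int(np.ceil(depth_alpha * mean_depth)))
    profile.counts = {kmer: c for kmer, c in profile.counts.items() if c > threshold}
    return profile


def fraction_profile_observed(allele_profile: KmerProfile, sample_profile: KmerProfile) -> float:
    """Fraction of the allele profile's k-mer mass present in the sample.

    Counts of allele-profile k-mers that appear in the (already filtered)
    sample profile, divided by the allele profile's total count.
    """
    if not allele_profile.counts:
        raise ValueError(f"empty allele profile for {allele_profile.owner!r}")
    sample = sample_profile.counts
    observed = sum(c for kmer, c in allele_profile.counts.items() if kmer in sample)
    return observed / allele_profile.total


# ---------------------------------------------------------------------------
# Profile store: <gene>/<allele>.profile.gz of sorted "kmer<TAB>count" lines
# plus a manifest TSV. Sorted output makes rebuilt stores byte-comparable.


def _safe(label: str) -> str:
    return label.replace("*", "_").replace(":", "-")


def save_profiles(
    directory,
    profiles: Mapping[str, Mapping[str, KmerProfile]],
    merged_names: Optional[Mapping[str, Iterable[str]]] = None,
) -> None:
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    manifest: List[Tuple[str, str, str, int, int]] = []
    for gene in sorted(profiles):
        gene_dir = os.path.join(directory, _safe(gene))
        os.makedirs(gene_dir, exist_ok=True)
        for allele in sorted(profiles[gene]):
            prof = profiles[gene][allele]
            path = os.path.join(gene_dir, f"{_safe(allele)}.profile.gz")
            with gzip.open(path, "wt") as fh:
                for kmer in sorted(prof.counts):
                    fh.write(f"{kmer}\t{prof.counts[kmer]}\n")
            merged = ";".join(sorted(map(str, (merged_names or {}).get(allele, [allele]))))
            manifest.append((gene, allele, merged, prof.k, prof.total))
    with open(os.path.join(directory, "manifest.tsv"), "w") as fh:
        fh.write("gene\tallele\tmerged_names\tk\ttotal\n")
        for row in manifest:
            fh.write("\t".join(str(x) for x in row) + "\n")


def load_profiles(directory) -> Dict[str, Dict[str, KmerProfile]]:
    directory = str(directory)
    profiles: Dict[str, Dict[str, KmerProfile]] = {}
    with open(os.path.join(directory, "manifest.tsv")) as fh:
        header = fh.readline()
        for line in fh:
            gene, allele, _merged, k, _total = line.rstrip("\n").split("\t")
            path = os.path.join(directory, _safe(gene), f"{_safe(allele)}.profile.gz")
            counts: Dict[str, int] = {}
            with gzip.open(path, "rt") as pf:
                for row in pf:
                    kmer, count = row.split("\t")
                    counts[kmer] = int(count)
            profiles.setdefault(gene, {})[allele] = KmerProfile(allele, int(k), counts)
    return profiles
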