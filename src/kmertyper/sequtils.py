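"""Shared sequence primitives: reverse complement, k-mer iteration, FASTQ pairs.

All downstream modules treat read 1 of a pair as reverse-strand (stranded
dUTP-style library): it is reverse complemented before any k-mer extraction
or substring matching, so every comparison happens in forward-strand space.
"""

from __future__ import annotations

import gzip
import re
from typing import IO, Iterable, Iterator, NamedTuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_NON_ACGT = re.compile(r"[^ACGT]")

PHRED_OFFSET = 33


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iter_kmers(seq: str, k: int) -> Iterator[str]:
    """Yield all k-mers of ``seq`` over {A,C,G,T}.

    Windows spanning any other character (N, IUPAC codes, ...) are skipped
    rather than raising; sequences with ambiguity codes are legal input.
    """
    n = len(seq)
    if n < k:
        return
    bad = [m.start() for m in _NON_ACGT.finditer(seq)]
    if not bad:
        for i in range(n - k + 1):
            yield seq[i : i + k]
        return
    prev = -1
    for b in bad:
        for i in range(prev + 1, b - k + 1):
            yield seq[i : i + k]
        prev = b
    for i in range(prev + 1, n - k + 1):
        yield seq[i : i + k]


class ReadPair(NamedTuple):
    """A paired-end read. ``seq1`` is stored as sequenced (reverse strand)."""

    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def min_quality(self) -> int:
        """Lowest phred quality over all bases of both mates."""
        return ord(min(self.qual1 + self.qual2)) - PHRED_OFFSET


def _open_text(path, mode: str) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path) -> int:
    """Write pairs to two 4-line FASTQ files (gzipped iff path ends in .gz).

    Read names get ``/1`` and ``/2`` mate suffixes. Returns the pair count.
    """
    n = 0
    with _open_text(r1_path, "w") as f1, _open_text(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream pairs from two FASTQ files (gzip transparent).

    Mates are matched positionally; trailing ``/1``/``/2`` suffixes are
    stripped from the names.
    """
    with _open_text(r1_path, "r") as f1, _open_text(r2_path, "r") as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2):
            name = t1.split()[0]
            if name.endswith("/1") or name.endswith("/2"):
                name = name[:-2]
            yield ReadPair(name, s1.upper(), q1, s2.upper(), q2)
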