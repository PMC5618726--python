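"""Allele nomenclature for highly polymorphic gene families.

Alleles are named ``GENE*f1:f2:f3:f4`` (IPD-IMGT/HLA style): field 1 is the
allele group, field 2 the distinct protein, fields 3-4 synonymous and
non-coding variants. A trailing ``N`` marks a novel sequence emitted by
allele refinement and ``U`` an updated partial allele. Zero-padding of the
numeric fields is preserved so names round-trip losslessly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

from Bio import SeqIO

__all__ = [
    "AlleleName",
    "AlleleRecord",
    "AlleleNameError",
    "parse_allele_name",
    "truncate_precision",
    "merge_identical_sequences",
    "read_reference_fasta",
    "write_reference_fasta",
    "read_transcript_fasta",
]

_GENE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.\-]*$")
_FIELDS_RE = re.compile(r"^(?P<fields>\d+(?::\d+)*)(?P<suffix>[NU])?$")


class AlleleNameError(ValueError):
    """Raised for a malformed allele name; the message names the bad token."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """Parsed allele name: gene, up to four precision fields, optional suffix."""

    gene: str
    fields: Tuple[str, ...] = ()
    suffix: str = ""  # "", "N" (novel) or "U" (updated partial)

    def __post_init__(self):
        if not self.gene:
            raise AlleleNameError("empty gene name")
        if len(self.fields) > 4:
            raise AlleleNameError(f"more than 4 fields in {self.gene!r}: {self.fields}")
        if self.suffix not in ("", "N", "U"):
            raise AlleleNameError(f"invalid suffix {self.suffix!r}")

    def __str__(self) -> str:
        if not self.fields:
            return self.gene + self.suffix
        return f"{self.gene}*{':'.join(self.fields)}{self.suffix}"

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    def with_suffix(self, suffix: str) -> "AlleleName":
        return replace(self, suffix=suffix)


def parse_allele_name(raw: str) -> AlleleName:
    """Parse ``GENE[*f1[:f2[:f3[:f4]]]][N|U]`` into an :class:`AlleleName`.

    >>> parse_allele_name("A*02:02:01:01")
    AlleleName(gene='A', fields=('02', '02', '01', '01'), suffix='')
    """
    raw = raw.strip()
    if not raw:
        raise AlleleNameError("empty allele name")
    if "*" in raw:
        gene, _, rest = raw.partition("*")
        if not _GENE_RE.match(gene):
            raise AlleleNameError(f"malformed gene token {gene!r} in {raw!r}")
        m = _FIELDS_RE.match(rest)
        if not m:
            raise AlleleNameError(f"malformed field token {rest!r} in {raw!r}")
        fields = tuple(m.group("fields").split(":"))
        if len(fields) > 4:
            raise AlleleNameError(f"more than 4 fields in {raw!r}")
        return AlleleName(gene, fields, m.group("suffix") or "")
    if not _GENE_RE.match(raw):
        raise AlleleNameError(f"malformed gene token {raw!r}")
    return AlleleName(raw)


def truncate_precision(name: AlleleName, n_fields: int) -> AlleleName:
    """Keep the first ``n_fields`` precision fields; the suffix is dropped.

    Names with fewer fields than requested are returned unchanged (minus
    suffix): A*01:01 truncated to 4 fields is still A*01:01.
    """
    if not 1 <= n_fields <= 4:
        raise ValueError(f"n_fields must be in 1..4, got {n_fields}")
    return AlleleName(name.gene, name.fields[: n_fields], "")


@dataclass
class AlleleRecord:
    """A named allele sequence with completeness status.

    ``merged_names`` holds every name sharing this exact sequence (including
    ``name`` itself); typing output expands the set whenever the record is
    part of a predicted genotype.
    """

    name: AlleleName
    accession: str
    sequence: str
    status: str = "complete"  # "complete" | "partial"
    missing_exons: Tuple[int, ...] = ()
    merged_names: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.name}")
        if self.status not in ("complete", "partial"):
            raise ValueError(f"invalid status {self.status!r} for {self.name}")
        if not self.merged_names:
            self.merged_names = frozenset({self.name})
        elif self.name not in self.merged_names:
            self.merged_names = self.merged_names | {self.name}


def merge_identical_sequences(records: Sequence[AlleleRecord]) -> List[AlleleRecord]:
    """Collapse records sharing an identical sequence into one record.

    The representative is the lexicographically smallest rendered name;
    ``merged_names`` is the union over the group so every merge is
    reportable downstream. Idempotent and order-invariant.
    """
    groups: Dict[str, List[AlleleRecord]] = {}
    for rec in records:
        groups.setdefault(rec.sequence, []).append(rec)
    merged: List[AlleleRecord] = []
    for seq, group in groups.items():
        rep = min(group, key=lambda r: str(r.name))
        names = frozenset().union(*(r.merged_names for r in group))
        merged.append(replace(rep, merged_names=names))
    merged.sort(key=lambda r: str(r.name))
    return merged


# ---------------------------------------------------------------------------
# FASTA I/O
#
# Header dialect: ">ACCESSION NAME [len] [status[:e1,e2,...]]", e.g.
#   >ACC0042 B*27:05:03 1089 partial:1,4,5,6
# with a fallback of ">NAME" for bare references.


def _parse_header(description: str, lineno: int | None = None) -> Tuple[str, AlleleName, str, Tuple[int, ...]]:
    where = f" (record {lineno})" if lineno is not None else ""
    tokens = description.split()
    if not tokens:
        raise AlleleNameError(f"empty FASTA header{where}")
    if len(tokens) == 1:
        name = parse_allele_name(tokens[0])
        return tokens[0], name, "complete", ()
    accession = tokens[0]
    name = parse_allele_name(tokens[1])
    status, missing = "complete", ()
    for tok in tokens[2:]:
        if tok.isdigit():
            continue  # optional length annotation; informational only
        base, _, exons = tok.partition(":")
        if base not in ("complete", "partial"):
            raise AlleleNameError(f"unrecognized status token {tok!r}{where}")
        status = base
        if exons:
            missing = tuple(int(e) for e in exons.split(","))
    return accession, name, status, missing


def read_reference_fasta(path) -> List[AlleleRecord]:
    """Read an allele reference multi-FASTA using the header dialect above."""
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        accession, name, status, missing = _parse_header(rec.description, i)
        records.append(
            AlleleRecord(
                name=name,
                accession=accession,
                sequence=str(rec.seq).upper(),
                status=status,
                missing_exons=missing,
            )
        )
    return records


def write_reference_fasta(records: Iterable[AlleleRecord], path) -> None:
    with open(str(path), "w") as fh:
        for rec in records:
            status = rec.status
            if rec.status == "partial" and rec.missing_exons:
                status += ":" + ",".join(str(e) for e in rec.missing_exons)
            fh.write(f">{rec.accession} {rec.name} {len(rec.sequence)} {status}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_transcript_fasta(path) -> List[Tuple[str, str]]:
    """Read a plain (id, sequence) multi-FASTA, e.g. the distractome."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
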