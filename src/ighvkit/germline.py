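"""Germline IGHV allele data model and I/O.

A germline V allele is the reference unit for repertoire annotation: a named
V-REGION (optionally in the IMGT-gapped representation, gap character ``.``)
together with the optional upstream segments that precede it in the mRNA —
the 5'UTR, L-PART1 and L-PART2.  L-PART2 abuts the V-REGION start, so the
full upstream sequence is ``utr5 + l_part1 + l_part2`` read 5'→3'.

Coordinates on the V-REGION are 1-based over the gapped string: gap positions
consume coordinates.  This matches the IMGT unique numbering used in
substitution labels such as ``G207T``; ungapped references are treated as
already aligned to coordinate 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "."
BASES = "ACGT"
_SEQ_ALPHABET = frozenset("ACGTN.")
_UPSTREAM_ALPHABET = frozenset("ACGTN")


class DuplicateAlleleError(ValueError):
    """Two records in one database share an allele label."""


class HeaderParseError(ValueError):
    """A FASTA header could not be parsed into a gene*allele label."""


class ReferenceBaseMismatchError(ValueError):
    """The stated reference base disagrees with the reference sequence.

    Raised by :func:`name_novel` to guard against coordinate-convention bugs
    (off-by-one, gapped vs ungapped).
    """


def parse_label(label: str) -> tuple[str, str]:
    """Split ``"IGHV3-64D*06"`` into ``("IGHV3-64D", "*06")``."""
    gene, star, allele_id = label.partition("*")
    if not star or not gene or not allele_id:
        raise HeaderParseError(f"cannot parse allele label {label!r} (expected gene*allele)")
    return gene, "*" + allele_id


@dataclass(frozen=True)
class GermlineAllele:
    """A named germline V allele with optional upstream segments."""

    gene: str
    allele_id: str  # includes the leading "*", e.g. "*06"
    v_region: str
    utr5: str | None = None
    l_part1: str | None = None
    l_part2: str | None = None
    functional: bool = True

    def __post_init__(self) -> None:
        if not self.allele_id.startswith("*"):
            raise ValueError(f"allele_id must start with '*', got {self.allele_id!r}")
        if not self.v_region:
            raise ValueError(f"{self.label}: V-REGION must be non-empty")
        bad = set(self.v_region) - _SEQ_ALPHABET
        if bad:
            raise ValueError(f"{self.label}: invalid V-REGION characters {sorted(bad)}")
        for name in ("utr5", "l_part1", "l_part2"):
            seg = getattr(self, name)
            if seg is None:
                continue
            bad = set(seg) - _UPSTREAM_ALPHABET
            if bad:
                raise ValueError(f"{self.label}: {name} contains invalid characters {sorted(bad)} (gaps not allowed upstream)")

    @property
    def label(self) -> str:
        return self.gene + self.allele_id

    @property
    def upstream(self) -> str | None:
        """Full upstream sequence 5'→3' (5'UTR + L-PART1 + L-PART2), or None."""
        segs = [s for s in (self.utr5, self.l_part1, self.l_part2) if s is not None]
        if not segs:
            return None
        return "".join(segs)

    @property
    def v_region_ungapped(self) -> str:
        return self.v_region.replace(GAP, "")

    def with_substitution(self, position: int, to_base: str) -> "GermlineAllele":
        """Derived allele carrying one point substitution (gapped coordinate)."""
        ref = self.v_region[position - 1]
        if ref == GAP:
            raise ValueError(f"{self.label}: position {position} is a gap")
        name = name_novel(self, position, ref, to_base)
        _, allele_id = parse_label(name)
        v = self.v_region[: position - 1] + to_base + self.v_region[position:]
        return replace(self, allele_id=allele_id, v_region=v)


class AlleleDatabase:
    """An ordered collection of germline alleles with unique labels."""

    def __init__(self, alleles: Iterator[GermlineAllele] | list[GermlineAllele] = (),
                 version_tag: str = "unversioned") -> None:
        self.version_tag = version_tag
        self._by_label: dict[str, GermlineAllele] = {}
        for allele in alleles:
            self.add(allele)

    def add(self, allele: GermlineAllele) -> None:
        if allele.label in self._by_label:
            raise DuplicateAlleleError(f"duplicate allele label {allele.label!r} in database {self.version_tag!r}")
        self._by_label[allele.label] = allele

    def __getitem__(self, label: str) -> GermlineAllele:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"allele {label!r} not found in database {self.version_tag!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __iter__(self) -> Iterator[GermlineAllele]:
        return iter(self._by_label.values())

    def __len__(self) -> int:
        return len(self._by_label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleDatabase):
            return NotImplemented
        return list(self) == list(other)

    def labels(self) -> list[str]:
        return list(self._by_label)

    def by_gene(self) -> dict[str, list[GermlineAllele]]:
        out: dict[str, list[GermlineAllele]] = {}
        for allele in self:
            out.setdefault(allele.gene, []).append(allele)
        return out


# ---------------------------------------------------------------------------
# FASTA / TSV I/O

def _label_from_header(header_id: str, description: str, dialect: str, index: int) -> tuple[str, bool]:
    if dialect == "plain":
        return header_id, True
    if dialect == "imgt-header":
        fields = description.split("|")
        if len(fields) < 2 or not fields[1].strip():
            raise HeaderParseError(f"record {index}: IMGT-style header lacks an allele field: {description!r}")
        functional = True
        if len(fields) > 3 and fields[3].strip():
            functional = fields[3].strip().strip("()[]") == "F"
        return fields[1].strip(), functional
    raise ValueError(f"unknown FASTA dialect {dialect!r}")


def read_germline_fasta(path: str | Path, dialect: str = "plain",
                        version_tag: str | None = None) -> AlleleDatabase:
    """Read a germline V-allele FASTA into an :class:`AlleleDatabase`.

    ``dialect="plain"`` takes the first whitespace-delimited header token as
    the ``gene*allele`` label; ``dialect="imgt-header"`` parses pipe-delimited
    IMGT-style headers, taking field 2 as the label and field 4 as the
    functionality flag.  Gapped records are preserved verbatim and record
    order is kept.
    """
    db = AlleleDatabase(version_tag=version_tag or Path(path).stem)
    for index, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        label, functional = _label_from_header(rec.id, rec.description, dialect, index)
        try:
            gene, allele_id = parse_label(label)
        except HeaderParseError as exc:
            raise HeaderParseError(f"record {index}: {exc}") from None
        db.add(GermlineAllele(gene=gene, allele_id=allele_id,
                              v_region=str(rec.seq).upper(), functional=functional))
    return db


def write_germline_fasta(db: AlleleDatabase, path: str | Path, dialect: str = "plain") -> None:
    records = []
    for allele in db:
        if dialect == "plain":
            rec = SeqRecord(Seq(allele.v_region), id=allele.label, description="")
        elif dialect == "imgt-header":
            func = "F" if allele.functional else "P"
            header = f"{db.version_tag}|{allele.label}|Homo sapiens|{func}|V-REGION"
            rec = SeqRecord(Seq(allele.v_region), id=header, description="")
        else:
            raise ValueError(f"unknown FASTA dialect {dialect!r}")
        records.append(rec)
    SeqIO.write(records, str(path), "fasta")


_TSV_COLUMNS = ["gene", "allele", "v_region", "utr5", "l_part1", "l_part2", "functional"]


def write_germline_tsv(db: AlleleDatabase, path: str | Path) -> None:
    """Serialize a database, including upstream segments, as TSV."""
    rows = [
        {
            "gene": a.gene,
            "allele": a.allele_id,
            "v_region": a.v_region,
            "utr5": a.utr5 or "",
            "l_part1": a.l_part1 or "",
            "l_part2": a.l_part2 or "",
            "functional": a.functional,
        }
        for a in db
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_germline_tsv(path: str | Path, version_tag: str | None = None) -> AlleleDatabase:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise ValueError(f"germline TSV missing columns: {missing}")
    db = AlleleDatabase(version_tag=version_tag or Path(path).stem)
    for _, row in frame.iterrows():
        db.add(GermlineAllele(
            gene=row["gene"],
            allele_id=row["allele"],
            v_region=row["v_region"],
            utr5=row.get("utr5") or None,
            l_part1=row.get("l_part1") or None,
            l_part2=row.get("l_part2") or None,
            functional=str(row.get("functional", "True")).lower() != "false",
        ))
    return db


# ---------------------------------------------------------------------------
# Naming and comparison

def name_novel(closest: GermlineAllele, position: int, from_base: str, to_base: str) -> str:
    """Label a novel allele after its closest reference allele.

    Returns ``"<gene><allele_id>_<from><position><to>"``, e.g.
    ``"IGHV1-2*02_G207T"``.  ``position`` is a 1-based coordinate over the
    (gapped) reference V-REGION; the base found there must equal
    ``from_base``, otherwise :class:`ReferenceBaseMismatchError` is raised.
    """
    if not 1 <= position <= len(closest.v_region):
        raise ReferenceBaseMismatchError(
            f"position {position} outside V-REGION of {closest.label} (length {len(closest.v_region)})")
    ref = closest.v_region[position - 1]
    if ref != from_base:
        raise ReferenceBaseMismatchError(
            f"{closest.label} position {position} is {ref!r}, not {from_base!r}")
    return f"{closest.label}_{from_base}{position}{to_base}"


def diff_positions(a: str, b: str, anchor: str = "left") -> list[tuple[int, str, str]]:
    """Mismatching positions between two sequences over their overlap.

    With ``anchor="left"`` the sequences are compared from their first base
    and coordinates are positive and 1-based.  With ``anchor="right"`` they
    are aligned at their last base and coordinates are negative (−1 = last
    position), the convention used for upstream sequences where −1 is the
    base immediately 5' of the V-REGION.  ``N`` and gap positions are
    skipped.  An empty overlap yields an empty list.
    """
    if anchor not in ("left", "right"):
        raise ValueError(f"anchor must be 'left' or 'right', got {anchor!r}")
    out: list[tuple[int, str, str]] = []
    window = min(len(a), len(b))
    if anchor == "left":
        for i in range(window):
            ca, cb = a[i], b[i]
            if ca in "N." or cb in "N.":
                continue
            if ca != cb:
                out.append((i + 1, ca, cb))
    else:
        for k in range(1, window + 1):
            ca, cb = a[-k], b[-k]
            if ca in "N." or cb in "N.":
                continue
            if ca != cb:
                out.append((-k, ca, cb))
        out.sort()
    return out


def mismatch_count(a: str, b: str) -> int:
    """Hamming distance over the left-anchored overlap, skipping N and gaps."""
    return sum(
        1
        for ca, cb in zip(a, b)
        if ca not in "N." and cb not in "N." and ca != cb
    )


def closest_alleles(v_seq: str, db: AlleleDatabase) -> tuple[int, list[str]]:
    """Closest database alleles to an ungapped V sequence by Hamming distance.

    Returns ``(distance, labels)`` with all equally-close labels sorted
    lexicographically — ties occur for duplicated genes with identical
    reference sequences.
    """
    best = None
    labels: list[str] = []
    for allele in db:
        d = mismatch_count(v_seq, allele.v_region_ungapped)
        if best is None or d < best:
            best, labels = d, [allele.label]
        elif d == best:
            labels.append(allele.label)
    if best is None:
        raise ValueError("empty allele database")
    return best, sorted(labels)
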