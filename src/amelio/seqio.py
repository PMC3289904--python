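"""Sequence, annotation and table I/O with explicit coordinate semantics.

All coordinates inside the package are 0-based half-open; GenBank's 1-based
inclusive convention is converted at the parsing boundary and never leaks
further in.  Nucleotide records allow the ambiguity code ``N``; protein
records allow ``X``.  Everything is stored upper-case.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

STOP_CODONS = ("TAA", "TAG", "TGA")
#: canonical start plus the alternative starts common in Actinobacteria
STRICT_START_CODONS = ("ATG",)
EXTENDED_START_CODONS = ("ATG", "GTG", "TTG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqFormatError(ValueError):
    """Raised for malformed sequence input."""


class InternalStopError(ValueError):
    """Raised when a CDS translates with a premature stop codon."""

    def __init__(self, codon_index: int):
        self.codon_index = codon_index
        super().__init__(f"internal stop codon at codon {codon_index}")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header up to the first whitespace).
    residues : str
        The sequence; validated against the declared alphabet and stored
        upper-case.
    moltype : {"nucleotide", "protein"}
    description : str
        Free-text remainder of the header.
    """

    id: str
    residues: str
    moltype: str = "nucleotide"
    description: str = ""

    def __post_init__(self) -> None:
        if self.moltype not in ("nucleotide", "protein"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        res = self.residues.upper()
        object.__setattr__(self, "residues", res)
        if not res:
            raise SeqFormatError(f"record {self.id!r}: empty sequence")
        alphabet = (
            NUCLEOTIDE_ALPHABET if self.moltype == "nucleotide" else PROTEIN_ALPHABET
        )
        for pos, ch in enumerate(res, start=1):
            if ch not in alphabet:
                raise SeqFormatError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def reverse_complement(self) -> "SequenceRecord":
        if self.moltype != "nucleotide":
            raise ValueError("reverse complement of a protein record")
        return replace(self, residues=self.residues.translate(_COMPLEMENT)[::-1])


def reverse_complement(seq: str) -> str:
    """Reverse-complement a plain nucleotide string (A/C/G/T/N)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A strand-aware coding-gene interval on a contig.

    ``start``/``end`` are 0-based half-open on the forward strand.  A
    multi-exon (GenBank ``join``) feature carries its sub-intervals in
    ``parts``; ``start``/``end`` then span the whole footprint.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    product: str = ""
    parts: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.locus_tag}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")
        if self.parts is not None:
            for a, b in self.parts:
                if not (self.start <= a < b <= self.end):
                    raise ValueError(f"{self.locus_tag}: part ({a}, {b}) outside span")

    @property
    def length(self) -> int:
        if self.parts is None:
            return self.end - self.start
        return sum(b - a for a, b in self.parts)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, moltype: str = "nucleotide") -> list[SequenceRecord]:
    """Read a multi-record FASTA file, preserving record order."""
    records = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), moltype=moltype,
                           description=desc)
        )
    if not records:
        raise SeqFormatError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def read_genbank(path: str | Path) -> tuple[SequenceRecord, list[GeneFeature]]:
    """Read an annotated GenBank flat file.

    CDS features are converted from GenBank 1-based inclusive coordinates to
    0-based half-open; ``complement()`` maps to strand ``-`` and ``join()``
    parts are retained in ascending coordinate order.
    """
    rec = _BioSeqIO.read(str(path), "genbank")
    seq = str(rec.seq)
    if not seq:
        raise SeqFormatError(f"{path}: missing ORIGIN sequence")
    record = SequenceRecord(id=rec.id or rec.name, residues=seq,
                            moltype="nucleotide",
                            description=rec.description or "")
    features: list[GeneFeature] = []
    n_unnamed = 0
    for f in rec.features:
        if f.type != "CDS":
            continue
        parts = sorted((int(p.start), int(p.end)) for p in f.location.parts)
        start, end = parts[0][0], parts[-1][1]
        if end > len(seq) or start < 0:
            raise SeqFormatError(
                f"{path}: CDS {start + 1}..{end} extends beyond the "
                f"{len(seq)} bp sequence"
            )
        strand = "-" if f.location.strand == -1 else "+"
        quals = f.qualifiers
        tag = (quals.get("locus_tag") or quals.get("gene")
               or quals.get("protein_id") or [None])[0]
        if tag is None:
            n_unnamed += 1
            tag = f"cds_{n_unnamed:04d}"
        product = (quals.get("product") or [""])[0]
        features.append(
            GeneFeature(contig_id=record.id, start=start, end=end, strand=strand,
                        locus_tag=tag, product=product,
                        parts=tuple(parts) if len(parts) > 1 else None)
        )
    return record, features


# ---------------------------------------------------------------------------
# CDS extraction and translation
# ---------------------------------------------------------------------------

def extract_cds(record: SequenceRecord, feature: GeneFeature) -> SequenceRecord:
    """Extract the strand-aware coding sequence of ``feature`` from ``record``.

    For strand ``-`` the reverse complement is returned so the result always
    reads 5'→3' in the coding direction.
    """
    if feature.end > len(record):
        raise ValueError(
            f"{feature.locus_tag}: feature end {feature.end} beyond record "
            f"length {len(record)}"
        )
    intervals = feature.parts or ((feature.start, feature.end),)
    seq = "".join(record.residues[a:b] for a, b in intervals)
    if feature.strand == "-":
        seq = reverse_complement(seq)
    return SequenceRecord(id=feature.locus_tag, residues=seq,
                          moltype="nucleotide", description=feature.product)


def has_canonical_start(cds: str | SequenceRecord,
                        starts: Sequence[str] = EXTENDED_START_CODONS) -> bool:
    return str(cds)[:3] in starts


def has_canonical_stop(cds: str | SequenceRecord) -> bool:
    s = str(cds)
    return len(s) % 3 == 0 and s[-3:] in STOP_CODONS


def translate(cds: str | SequenceRecord, *,
              actinobacterial_starts: bool = False,
              record_id: str | None = None) -> SequenceRecord:
    """Translate a CDS with the standard genetic code.

    The terminal stop codon is dropped.  An internal stop raises
    :class:`InternalStopError` carrying the 1-based codon index.  With
    ``actinobacterial_starts`` an initial GTG/TTG is read as methionine
    (bacterial/archaeal table start-codon behaviour).
    """
    seq = str(cds)
    rid = record_id or (cds.id if isinstance(cds, SequenceRecord) else "cds")
    if len(seq) % 3 != 0:
        raise ValueError(f"{rid}: CDS length {len(seq)} not a multiple of 3")
    aa = str(Seq(seq).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise InternalStopError(aa.index("*") + 1)
    if not aa:
        raise ValueError(f"{rid}: CDS is a bare stop codon")
    if actinobacterial_starts and seq[:3] in ("GTG", "TTG"):
        aa = "M" + aa[1:]
    return SequenceRecord(id=rid, residues=aa, moltype="protein")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_tsv(table: pd.DataFrame, path: str | Path,
              comments: Sequence[str] = ()) -> None:
    """Write a DataFrame as TSV with optional ``#`` provenance header lines."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


_FEATURE_COLUMNS = ["contig_id", "locus_tag", "start", "end", "strand", "product"]


def write_features_tsv(features: Iterable[GeneFeature], path: str | Path,
                       comments: Sequence[str] = ()) -> None:
    rows = [
        {"contig_id": f.contig_id, "locus_tag": f.locus_tag, "start": f.start,
         "end": f.end, "strand": f.strand, "product": f.product}
        for f in features
    ]
    write_tsv(pd.DataFrame(rows, columns=_FEATURE_COLUMNS), path, comments)


def read_features_tsv(path: str | Path) -> list[GeneFeature]:
    df = read_tsv(path)
    return [
        GeneFeature(contig_id=str(r.contig_id), start=int(r.start), end=int(r.end),
                    strand=str(r.strand), locus_tag=str(r.locus_tag),
                    product="" if pd.isna(r.product) else str(r.product))
        for r in df.itertuples()
    ]


# Newick I/O lives with the tree structure; re-exported here as the package's
# file-format surface.
from .tree import read_newick, write_newick  # noqa: E402,F401
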