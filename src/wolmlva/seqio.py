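"""Sequence and annotation I/O plus shared coordinate conventions.

All internal coordinates are 0-based half-open. GFF3 is emitted 1-based
inclusive, BED 0-based half-open, per each format's convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO as _BioSeqIO

DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC ambiguity codes -> the set of bases they match (used by mlva primers)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class SeqRecord:
    """A named sequence, DNA or protein."""

    id: str
    residues: str
    moltype: str = "dna"  # {"dna", "protein"}

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords (uppercased, order preserved).

    Raises FormatError on an empty file or duplicate record ids.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace(" ", "")
        moltype = "dna" if set(residues) <= DNA_ALPHABET else "protein"
        records.append(SeqRecord(id=rec.id, residues=residues, moltype=moltype))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def revcomp(dna: str) -> str:
    """Reverse complement of a DNA string (involution)."""
    if not set(dna.upper()) <= DNA_ALPHABET:
        raise ValueError("revcomp: non-DNA characters in input")
    return dna.translate(_COMPLEMENT)[::-1]


def _fmt_attr(value) -> str:
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def write_gff3(
    features: Iterable[tuple[Interval, Mapping[str, object]]],
    path,
    source: str = "wolmlva",
    feature_type: str = "tandem_repeat",
) -> None:
    """Write (Interval, attributes) pairs as GFF3 (1-based inclusive coords).

    `score` in the attributes mapping is placed in column 6; remaining
    attributes go into column 9 as key=value pairs.
    """
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for iv, attrs in features:
        attrs = dict(attrs)
        score = attrs.pop("score", ".")
        ftype = attrs.pop("type", feature_type)
        col9 = ";".join(f"{k}={_fmt_attr(v)}" for k, v in attrs.items()) or "."
        buf.write(
            "\t".join(
                [
                    iv.seq_id,
                    source,
                    str(ftype),
                    str(iv.start + 1),
                    str(iv.end),
                    _fmt_attr(score),
                    iv.strand,
                    ".",
                    col9,
                ]
            )
            + "\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_gff3(path) -> list[tuple[Interval, dict[str, str]]]:
    """Re-parse GFF3 written by this package back to half-open intervals."""
    out: list[tuple[Interval, dict[str, str]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"bad GFF3 line: {line!r}")
            attrs: dict[str, str] = {}
            if cols[8] != ".":
                for pair in cols[8].split(";"):
                    k, _, v = pair.partition("=")
                    attrs[k] = v
            if cols[5] != ".":
                attrs["score"] = cols[5]
            attrs["type"] = cols[2]
            iv = Interval(cols[0], int(cols[3]) - 1, int(cols[4]), cols[6] if cols[6] in "+-" else "+")
            out.append((iv, attrs))
    return out


def write_bed(features: Iterable[tuple[Interval, str]], path) -> None:
    """Write (Interval, name) pairs as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv, name in features:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t.\t{iv.strand}\n")


def n_fraction(seq: str) -> float:
    """Fraction of N bases; windows above 10% N are skipped by the finder."""
    return seq.count("N") / len(seq) if seq else 0.0
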