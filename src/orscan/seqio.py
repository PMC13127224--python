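"""Sequence and annotation I/O.

FASTA parsing, six-frame translation and annotation output in the three
dialects the pipeline speaks:

* internal / TSV coordinates are 0-based half-open,
* GFF3 output is 1-based inclusive,
* BED output is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class SequenceRecord:
    """A named sequence (chromosome, scaffold or protein)."""

    id: str
    seq: str
    meta: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AnnotationRecord:
    """A genomic feature in internal (0-based half-open) coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    feature_type: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def parse_fasta(path: str | Path, molecule: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Multi-line sequences are concatenated and case-normalized to upper.
    Raises ``ValueError`` on an empty file, a duplicate id, or a character
    outside the alphabet of the declared molecule type.
    """
    if molecule == "nucleotide":
        alphabet = NUCLEOTIDE_ALPHABET
    elif molecule == "protein":
        alphabet = PROTEIN_ALPHABET
    else:
        raise ValueError(f"unknown molecule type {molecule!r}")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        bad = next((i for i, c in enumerate(seq) if c not in alphabet), None)
        if bad is not None:
            raise ValueError(
                f"illegal {molecule} character {seq[bad]!r} in record "
                f"{rec.id!r} at position {bad}"
            )
        records.append(SequenceRecord(rec.id, seq, rec.description))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a nucleotide string (standard code).

    Trailing partial codons are dropped; codons containing N become 'X'
    (never a stop), stops render as '*'.
    """
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def six_frame_translate(seq: str) -> dict[int, str]:
    """Translate all six reading frames.

    Frames +1/+2/+3 start at offsets 0/1/2 of the forward strand; -1/-2/-3
    are the same offsets of the reverse complement.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    rc = revcomp(seq)
    out: dict[int, str] = {}
    for f in (1, 2, 3):
        out[f] = translate(seq[f - 1 :])
        out[-f] = translate(rc[f - 1 :])
    return out


# --- annotation output dialects -------------------------------------------

_FORMATS = ("GFF3", "BED", "TSV")


def _fmt_attributes(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attributes(text: str) -> dict:
    if text in (".", ""):
        return {}
    out = {}
    for item in text.split(";"):
        if item:
            k, _, v = item.partition("=")
            out[k] = v
    return out


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path, format: str = "GFF3") -> None:
    """Write annotations in GFF3 (1-based inclusive), BED or TSV (0-based)."""
    fmt = format.upper()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown annotation format {format!r}")
    with open(path, "w") as fh:
        if fmt == "GFF3":
            fh.write("##gff-version 3\n")
            for r in records:
                fh.write(
                    "\t".join(
                        [
                            r.seq_id,
                            "orscan",
                            r.feature_type,
                            str(r.start + 1),
                            str(r.end),
                            ".",
                            r.strand,
                            ".",
                            _fmt_attributes(r.attributes),
                        ]
                    )
                    + "\n"
                )
        elif fmt == "BED":
            for r in records:
                name = r.attributes.get("ID", ".")
                fh.write(
                    "\t".join(
                        [r.seq_id, str(r.start), str(r.end), name, ".", r.strand]
                    )
                    + "\n"
                )
        else:  # TSV mirrors the internal model
            fh.write("seq_id\tstart\tend\tstrand\tfeature_type\tattributes\n")
            for r in records:
                fh.write(
                    "\t".join(
                        [
                            r.seq_id,
                            str(r.start),
                            str(r.end),
                            r.strand,
                            r.feature_type,
                            _fmt_attributes(r.attributes),
                        ]
                    )
                    + "\n"
                )


def parse_annotations(path: str | Path, format: str = "GFF3") -> list[AnnotationRecord]:
    """Inverse of :func:`write_annotations`; BED is lossy by design."""
    fmt = format.upper()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown annotation format {format!r}")
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if fmt == "GFF3":
                records.append(
                    AnnotationRecord(
                        seq_id=parts[0],
                        start=int(parts[3]) - 1,
                        end=int(parts[4]),
                        strand=parts[6],
                        feature_type=parts[2],
                        attributes=_parse_attributes(parts[8]),
                    )
                )
            elif fmt == "BED":
                attrs = {} if parts[3] == "." else {"ID": parts[3]}
                records.append(
                    AnnotationRecord(
                        seq_id=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        strand=parts[5],
                        feature_type="region",
                        attributes=attrs,
                    )
                )
            else:
                if parts[0] == "seq_id":
                    continue
                records.append(
                    AnnotationRecord(
                        seq_id=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        strand=parts[3],
                        feature_type=parts[4],
                        attributes=_parse_attributes(parts[5]),
                    )
                )
    return records
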