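"""FASTA input, six-frame translation primitives and GFF3 output.

Coordinates are 0-based half-open internally; every emitted file uses 1-based
inclusive coordinates (GFF3 convention). Minus-strand features are reported on
forward-strand coordinates with strand ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard nuclear genetic code (NCBI table 1); stops rendered as '*'.
_TABLE1 = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE1.forward_table)
for _stop in _TABLE1.stop_codons:
    CODON_TO_AA[_stop] = "*"


@dataclass(frozen=True)
class Frame:
    """One of the six reading frames: strand '+'/'-' and offset 0..2."""

    strand: Literal["+", "-"]
    offset: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.offset not in (0, 1, 2):
            raise ValueError(f"frame offset must be 0, 1 or 2, got {self.offset!r}")


SIX_FRAMES: tuple[Frame, ...] = tuple(
    Frame(strand, offset) for strand in "+-" for offset in (0, 1, 2)
)


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence (upper-case residues)."""

    id: str
    seq: str
    description: str = ""
    alphabet: Literal["dna", "protein"] = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.seq = self.seq.upper()
        _check_alphabet(self.seq, self.alphabet, self.id)

    def __len__(self) -> int:
        return len(self.seq)


def _check_alphabet(seq: str, alphabet: str, name: str) -> None:
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    bad = sorted(set(seq) - allowed)
    if bad:
        raise ValueError(
            f"sequence {name!r} contains characters outside the {alphabet} "
            f"alphabet: {', '.join(bad)}"
        )


def read_fasta(path: str | Path, alphabet: Literal["dna", "protein"]) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Record order is preserved; sequences are upper-cased. Duplicate ids, an
    empty file, or residues outside the declared alphabet raise ``ValueError``.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), description=desc,
                                      alphabet=alphabet))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def reverse_complement(dna: str) -> str:
    """Reverse complement; N maps to N."""
    _check_alphabet(dna, "dna", "<reverse_complement input>")
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str, frame: Frame = Frame("+", 0)) -> str:
    """Translate one reading frame under the standard nuclear code.

    Trailing partial codons are dropped, stop codons render as ``*`` and any
    codon containing ``N`` renders as ``X``.
    """
    _check_alphabet(dna, "dna", "<translate input>")
    s = dna if frame.strand == "+" else reverse_complement(dna)
    s = s[frame.offset:]
    aas = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i:i + 3]
        aas.append("X" if "N" in codon else CODON_TO_AA[codon])
    return "".join(aas)


@dataclass
class GffFeature:
    """A located feature destined for GFF3 output (0-based half-open span)."""

    contig: str
    start: int
    end: int
    strand: Literal["+", "-"]
    type: str
    feature_id: str
    attributes: dict[str, str] = field(default_factory=dict)


def write_gff3(features: Sequence[GffFeature], path: str | Path,
               contig_lengths: dict[str, int] | None = None,
               source: str = "pheroscan") -> None:
    """Write features as GFF3, 1-based inclusive, sorted by (contig, start).

    ``contig_lengths``, when given, is used to reject spans that exceed the
    contig and to emit ``##sequence-region`` pragmas.
    """
    if contig_lengths is not None:
        for f in features:
            length = contig_lengths.get(f.contig)
            if length is not None and f.end > length:
                raise ValueError(
                    f"feature {f.feature_id!r} span [{f.start},{f.end}) exceeds "
                    f"contig {f.contig!r} length {length}"
                )
    ordered = sorted(features, key=lambda f: (f.contig, f.start, f.end, f.feature_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for contig in sorted(contig_lengths):
                fh.write(f"##sequence-region {contig} 1 {contig_lengths[contig]}\n")
        for f in ordered:
            attrs = {"ID": f.feature_id, **f.attributes}
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write("\t".join([
                f.contig, source, f.type, str(f.start + 1), str(f.end), ".",
                f.strand, ".", attr_str,
            ]) + "\n")


def read_gff3_spans(path: str | Path) -> list[GffFeature]:
    """Re-parse a GFF3 file back to 0-based half-open features (round-trip aid)."""
    feats: list[GffFeature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            feats.append(GffFeature(
                contig=cols[0], start=int(cols[3]) - 1, end=int(cols[4]),
                strand=cols[6], type=cols[2],
                feature_id=attrs.pop("ID", ""), attributes=attrs,
            ))
    return feats
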