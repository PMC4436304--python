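"""Sequence records, gapped alignments, and FASTA input/output.

The pipeline tracks every sequence's provenance: cotton bHLH proteins come
from six annotation sources (two *G. raimondii* genome projects, the
*G. arboreum* genome, *G. hirsutum* unigenes, Gossypium EST contigs and
mRNAs), and downstream ortholog grouping and representative selection key on
that provenance. All coordinates in this package are 0-based half-open;
1-based values appear only in rendered reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Source",
    "SequenceRecord",
    "Alignment",
    "read_fasta",
    "write_fasta",
    "read_alignment_fasta",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")


class Source(str, enum.Enum):
    """Annotation source of a sequence record."""

    GrJGI = "GrJGI"
    GrCGP = "GrCGP"
    GaCGP = "GaCGP"
    GhUni = "GhUni"
    GoCon = "GoCon"
    mRNA = "mRNA"
    user = "user"


#: Source priority used when picking a reference representative: the JGI
#: D-genome assembly first, then the other genome projects, then
#: transcript-derived evidence.
SOURCE_PRIORITY = (
    Source.GrJGI,
    Source.GrCGP,
    Source.GaCGP,
    Source.GhUni,
    Source.GoCon,
    Source.mRNA,
    Source.user,
)


@dataclass
class SequenceRecord:
    """A protein or nucleotide sequence with provenance.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header token before the first whitespace).
    residues : str
        Upper-case residues; protein records allow the 20 amino acids plus
        ``X``, dna records allow ``ACGTN``.
    moltype : {"protein", "dna"}
    source : Source
    description : str
        Free text; never participates in identity.
    """

    id: str
    residues: str
    moltype: str = "protein"
    source: Source = Source.user
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.moltype not in ("protein", "dna"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        self.residues = self.residues.upper()
        alphabet = PROTEIN_ALPHABET if self.moltype == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in alphabet:
                raise ValueError(
                    f"illegal {self.moltype} residue {ch!r} at position {pos} "
                    f"in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A gapped multiple alignment: ordered (id, gapped string) rows.

    All rows share one length; ungapping a row reproduces the source
    residues. Gaps are ``-`` internally ('.' is normalised on input).
    """

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(g) for _, g in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, rid: str) -> str:
        for i, g in self.rows:
            if i == rid:
                return g
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")

    def column(self, c: int) -> list[str]:
        return [g[c] for _, g in self.rows]


def _parse_fasta_text(text: str) -> list[tuple[str, str, str]]:
    entries: list[tuple[str, str, str]] = []
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                entries.append((header, desc, "".join(chunks)))
            tokens = line[1:].split(None, 1)
            if not tokens:
                raise ValueError("FASTA header with empty id")
            header = tokens[0]
            desc = tokens[1] if len(tokens) > 1 else ""
            chunks = []
        else:
            if header is None:
                raise ValueError("sequence data before first FASTA header")
            chunks.append(line.replace(" ", ""))
    if header is not None:
        entries.append((header, desc, "".join(chunks)))
    return entries


def read_fasta(
    path: str | Path,
    moltype: str = "protein",
    source: Source = Source.user,
) -> list[SequenceRecord]:
    """Read a FASTA file into validated records, preserving file order.

    Duplicate ids, empty sequences and illegal residues raise ``ValueError``
    naming the offending record.
    """
    text = Path(path).read_text()
    seen: set[str] = set()
    records: list[SequenceRecord] = []
    for rid, desc, seq in _parse_fasta_text(text):
        if rid in seen:
            raise ValueError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        records.append(
            SequenceRecord(
                id=rid, residues=seq, moltype=moltype, source=source, description=desc
            )
        )
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as wrapped FASTA (default 60 columns)."""
    if width <= 0:
        raise ValueError(f"line width must be positive, got {width}")
    lines: list[str] = []
    for rec in records:
        header = f">{rec.id}"
        if rec.description:
            header += f" {rec.description}"
        lines.append(header)
        for i in range(0, len(rec.residues), width):
            lines.append(rec.residues[i : i + width])
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_alignment_fasta(path: str | Path) -> Alignment:
    """Read a gapped FASTA alignment; '.' and '-' both accepted as gaps."""
    text = Path(path).read_text()
    rows = []
    for rid, _desc, seq in _parse_fasta_text(text):
        rows.append((rid, seq.upper().replace(".", "-")))
    return Alignment(rows=rows)


def write_alignment_fasta(aln: Alignment, path: str | Path, width: int = 60) -> None:
    if width <= 0:
        raise ValueError(f"line width must be positive, got {width}")
    lines: list[str] = []
    for rid, gapped in aln.rows:
        lines.append(f">{rid}")
        for i in range(0, len(gapped), width):
            lines.append(gapped[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n")
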