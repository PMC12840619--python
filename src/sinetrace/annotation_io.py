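"""Readers/writers for repeat-annotation tables, FASTA genomes and BED export.

All internal coordinates are 1-based inclusive (the RepeatMasker ``.out``
convention).  Conversion to 0-based half-open happens only at the BED
boundary, so a single convention flows through every downstream module.
Strand is stored verbatim as ``+`` or ``C`` (RepeatMasker's symbol for the
reverse strand) to keep ``.out`` round-trips bit-exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, TextIO

from Bio import SeqIO

__all__ = [
    "RepeatAnnotation",
    "GenomeAssembly",
    "ConsensusLibrary",
    "MalformedAnnotationError",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_genome_fasta",
    "read_consensus_fasta",
    "write_fasta",
    "annotations_to_bed",
    "bed_to_intervals",
]

_OUT_HEADER = (
    "   SW  perc perc perc  query     position in query    matching"
    "       repeat            position in repeat\n"
    "score  div. del. ins.  sequence  begin end   (left)   repeat"
    "          class/family    begin  end  (left)   ID\n"
    "\n"
)


class MalformedAnnotationError(ValueError):
    """Raised when a ``.out`` row cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat-annotation row.

    ``cons_begin``/``cons_end`` are orientation-normalized: they always
    satisfy ``cons_begin <= cons_end`` and refer to positions on the repeat
    consensus regardless of strand.  ``run_id`` groups fragments of one
    interrupted element (nested-insertion detection relies on it).
    """

    sw_score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    query_name: str
    query_begin: int
    query_end: int
    strand: str  # "+" or "C"
    repeat_name: str
    repeat_class: str
    cons_begin: int
    cons_end: int
    cons_left: int
    run_id: int

    def __post_init__(self) -> None:
        if self.query_begin > self.query_end:
            raise ValueError(
                f"inverted query interval [{self.query_begin},{self.query_end}] "
                f"on {self.query_name}"
            )
        if self.query_begin < 1:
            raise ValueError(f"query_begin {self.query_begin} < 1")
        if not 0.0 <= self.pct_div <= 100.0:
            raise ValueError(f"pct_div {self.pct_div} outside [0,100]")
        if self.cons_begin < 1:
            raise ValueError(f"cons_begin {self.cons_begin} < 1")
        if self.run_id < 0:
            raise ValueError(f"run_id {self.run_id} < 0")
        if self.strand not in ("+", "C"):
            raise ValueError(f"strand must be '+' or 'C', got {self.strand!r}")

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_begin + 1


@dataclass
class GenomeAssembly:
    """A genome held in memory: species label, clade/family label, contigs."""

    species: str
    contigs: dict[str, str]
    family: str = ""

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")


@dataclass
class ConsensusLibrary:
    """Ordered repeat-consensus library; order is stable and used for tie-breaks."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)  # (name, class, seq)

    def __post_init__(self) -> None:
        names = [n for n, _, _ in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate consensus names in library")

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.entries]

    def sequence(self, name: str) -> str:
        for n, _, s in self.entries:
            if n == name:
                return s
        raise KeyError(name)

    def repeat_class(self, name: str) -> str:
        for n, c, _ in self.entries:
            if n == name:
                return c
        raise KeyError(name)

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, _, s in self.entries}


def _strip_parens(tok: str) -> str:
    return tok[1:-1] if tok.startswith("(") and tok.endswith(")") else tok


def _looks_like_header(line: str) -> bool:
    s = line.strip()
    if not s:
        return True
    first = s.split()[0]
    return first in ("SW", "score", "bit")


def read_repeatmasker_out(stream: TextIO | str) -> list[RepeatAnnotation]:
    """Parse a whitespace-delimited ``.out`` table (with or without header).

    The consensus coordinates of ``C``-strand rows appear as
    ``(left) end begin`` and are normalized so ``cons_begin <= cons_end``.
    A trailing asterisk overlap flag, if present, is ignored.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[RepeatAnnotation] = []
    for lineno, line in enumerate(stream, start=1):
        if _looks_like_header(line):
            continue
        toks = line.split()
        if toks and toks[-1] == "*":
            toks = toks[:-1]
        if len(toks) != 15:
            raise MalformedAnnotationError(
                f"line {lineno}: expected 15 fields, got {len(toks)}: {line.rstrip()!r}"
            )
        try:
            sw = int(toks[0])
            pct_div, pct_del, pct_ins = (float(t) for t in toks[1:4])
            qname = toks[4]
            qbeg, qend = int(toks[5]), int(toks[6])
            # toks[7] is (left) on the query; derivable, not stored
            strand = toks[8]
            rname, rclass = toks[9], toks[10]
            if strand == "C":
                # C strand: columns are (left) end begin
                cons_left = int(_strip_parens(toks[11]))
                cons_end = int(toks[12])
                cons_begin = int(toks[13])
            else:
                cons_begin = int(toks[11])
                cons_end = int(toks[12])
                cons_left = int(_strip_parens(toks[13]))
            run_id = int(toks[14])
            rec = RepeatAnnotation(
                sw_score=sw, pct_div=pct_div, pct_del=pct_del, pct_ins=pct_ins,
                query_name=qname, query_begin=qbeg, query_end=qend, strand=strand,
                repeat_name=rname, repeat_class=rclass,
                cons_begin=cons_begin, cons_end=cons_end, cons_left=cons_left,
                run_id=run_id,
            )
        except MalformedAnnotationError:
            raise
        except ValueError as exc:
            raise MalformedAnnotationError(f"line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_repeatmasker_out(
    annotations: Iterable[RepeatAnnotation],
    contig_lengths: dict[str, int] | None = None,
    header: bool = True,
) -> str:
    """Render annotations back to ``.out`` text.

    ``contig_lengths`` fills the query ``(left)`` column; absent contigs get
    ``(0)``.  ``C``-strand consensus columns are emitted as ``(left) end
    begin`` so that ``read_repeatmasker_out`` round-trips exactly.
    """
    lines: list[str] = []
    if header:
        lines.append(_OUT_HEADER.rstrip("\n"))
    for a in annotations:
        qleft = 0
        if contig_lengths and a.query_name in contig_lengths:
            qleft = contig_lengths[a.query_name] - a.query_end
        if a.strand == "C":
            cons_cols = f"({a.cons_left}) {a.cons_end} {a.cons_begin}"
        else:
            cons_cols = f"{a.cons_begin} {a.cons_end} ({a.cons_left})"
        lines.append(
            f"{a.sw_score} {a.pct_div:.1f} {a.pct_del:.1f} {a.pct_ins:.1f} "
            f"{a.query_name} {a.query_begin} {a.query_end} ({qleft}) "
            f"{a.strand} {a.repeat_name} {a.repeat_class} {cons_cols} {a.run_id}"
        )
    return "\n".join(lines) + "\n"


def _read_fasta_pairs(stream: TextIO | str) -> list[tuple[str, str]]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        seen.add(rec.id)
        pairs.append((rec.id, seq))
    return pairs


def read_genome_fasta(stream: TextIO | str, species: str = "", family: str = "") -> GenomeAssembly:
    """Read a multi-FASTA genome; ids are header tokens before whitespace,
    sequences uppercased."""
    pairs = _read_fasta_pairs(stream)
    return GenomeAssembly(species=species, family=family, contigs=dict(pairs))


def read_consensus_fasta(stream: TextIO | str, default_class: str = "Unknown") -> ConsensusLibrary:
    """Read a consensus library; the repeat class may be given as a second
    header token (``>name SINE/Platy``), else ``default_class`` applies."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    classes: dict[str, str] = {}
    for line in text.splitlines():
        if line.startswith(">"):
            toks = line[1:].split()
            if len(toks) >= 2 and "/" in toks[1]:
                classes[toks[0]] = toks[1]
    pairs = _read_fasta_pairs(io.StringIO(text))
    return ConsensusLibrary(
        entries=[(n, classes.get(n, default_class), s) for n, s in pairs]
    )


def write_fasta(records: Iterable[tuple[str, str]], width: int = 60) -> str:
    out: list[str] = []
    for name, seq in records:
        out.append(f">{name}")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width])
    return "\n".join(out) + "\n"


def annotations_to_bed(annotations: Iterable[RepeatAnnotation]) -> str:
    """BED6 export: 1-based inclusive -> 0-based half-open; strand C -> '-';
    score clamped to [0, 1000]."""
    lines = []
    for a in annotations:
        score = min(max(a.sw_score, 0), 1000)
        strand = "-" if a.strand == "C" else "+"
        lines.append(
            f"{a.query_name}\t{a.query_begin - 1}\t{a.query_end}\t"
            f"{a.repeat_name}\t{score}\t{strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def bed_to_intervals(bed_text: str) -> list[tuple[str, int, int]]:
    """Inverse of the BED coordinate conversion: back to 1-based inclusive."""
    out = []
    for line in bed_text.splitlines():
        if not line.strip():
            continue
        toks = line.split("\t")
        out.append((toks[0], int(toks[1]) + 1, int(toks[2])))
    return out


def _replace(a: RepeatAnnotation, **kw) -> RepeatAnnotation:
    return replace(a, **kw)
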