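"""Full-length element ascertainment and flanked locus construction.

A copy counts as full length when its alignment to the subfamily consensus
starts within 4 bp of the consensus 5' end (0-based offsets 0-4, i.e.
``cons_begin <= 5`` in 1-based coordinates) and reaches consensus position
>= 103.  Each retained copy is packaged with up to 500 bp of flanking
sequence on either side; those flanks anchor the orthologous site when the
locus is genotyped against other genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation_io import GenomeAssembly, RepeatAnnotation, write_fasta

__all__ = ["LocusRecord", "filter_full_length", "extract_locus",
           "loci_to_fasta", "loci_to_table"]

SHORT_FLANK = 50  # below this, a flank cannot reliably anchor an alignment


@dataclass(frozen=True)
class LocusRecord:
    """A full-length element plus its flanking sequence.

    ``sequence`` is left flank + element + right flank; ``element_offset``
    (== ``flank_left``) locates the element within it.  Flanks shorter than
    requested (contig edge) keep their actual lengths; loci with a flank
    below ``SHORT_FLANK`` bp are flagged and tend to genotype ``?``
    downstream rather than being dropped here.
    """

    locus_id: str
    species: str
    contig: str
    element_begin: int  # 1-based inclusive on the contig
    element_end: int
    subfamily: str
    strand: str
    flank_left: int
    flank_right: int
    sequence: str

    def __post_init__(self) -> None:
        elen = self.element_end - self.element_begin + 1
        if len(self.sequence) != self.flank_left + elen + self.flank_right:
            raise ValueError(
                f"{self.locus_id}: sequence length {len(self.sequence)} does "
                f"not match flanks {self.flank_left}+{elen}+{self.flank_right}"
            )

    @property
    def element_offset(self) -> int:
        return self.flank_left

    @property
    def element_length(self) -> int:
        return self.element_end - self.element_begin + 1

    @property
    def element_sequence(self) -> str:
        return self.sequence[self.flank_left : self.flank_left + self.element_length]

    @property
    def short_flank(self) -> bool:
        return self.flank_left < SHORT_FLANK or self.flank_right < SHORT_FLANK


def filter_full_length(
    annotations: list[RepeatAnnotation],
    consensus_lengths: dict[str, int],
    max_start_offset: int = 4,
    min_end: int | dict[str, int] = 103,
) -> list[RepeatAnnotation]:
    """Keep rows whose consensus alignment starts within ``max_start_offset``
    of the 5' end and ends at or beyond ``min_end``.

    ``min_end`` may be a per-subfamily mapping.  The caller restricts
    ``annotations`` to the focal family; every repeat name must be present in
    ``consensus_lengths``.
    """
    missing = sorted(
        {a.repeat_name for a in annotations} - set(consensus_lengths)
    )
    if missing:
        raise KeyError(
            f"consensus length unknown for: {', '.join(missing)}"
        )
    kept = []
    for a in annotations:
        end_req = min_end[a.repeat_name] if isinstance(min_end, dict) else min_end
        if a.cons_begin - 1 <= max_start_offset and a.cons_end >= end_req:
            kept.append(a)
    return kept


def extract_locus(
    genome: GenomeAssembly,
    annotation: RepeatAnnotation,
    flank: int = 500,
    locus_id: str | None = None,
) -> LocusRecord:
    """Cut the element plus up to ``flank`` bp on each side out of the genome.

    Pure: the genome is not modified, and re-extraction yields an identical
    record.  Flanks are truncated at contig ends with actual lengths kept.
    """
    if annotation.query_name not in genome.contigs:
        raise KeyError(
            f"contig {annotation.query_name!r} not in genome {genome.species!r}"
        )
    contig_seq = genome.contigs[annotation.query_name]
    if annotation.query_end > len(contig_seq):
        raise ValueError(
            f"interval [{annotation.query_begin},{annotation.query_end}] is off "
            f"the end of contig {annotation.query_name!r} "
            f"(length {len(contig_seq)})"
        )
    b, e = annotation.query_begin, annotation.query_end
    left = min(flank, b - 1)
    right = min(flank, len(contig_seq) - e)
    seq = contig_seq[b - 1 - left : e + right]
    return LocusRecord(
        locus_id=locus_id or f"{genome.species}:{annotation.query_name}:{b}-{e}",
        species=genome.species,
        contig=annotation.query_name,
        element_begin=b,
        element_end=e,
        subfamily=annotation.repeat_name,
        strand=annotation.strand,
        flank_left=left,
        flank_right=right,
        sequence=seq,
    )


def loci_to_fasta(loci: list[LocusRecord]) -> str:
    return write_fasta((l.locus_id, l.sequence) for l in loci)


def loci_to_table(loci: list[LocusRecord]) -> str:
    """Locus table TSV: one row per locus with provenance and flank lengths."""
    header = (
        "locus_id\tspecies\tcontig\telement_begin\telement_end\t"
        "subfamily\tstrand\tflank_left\tflank_right\tshort_flank"
    )
    rows = [header]
    for l in loci:
        rows.append(
            f"{l.locus_id}\t{l.species}\t{l.contig}\t{l.element_begin}\t"
            f"{l.element_end}\t{l.subfamily}\t{l.strand}\t{l.flank_left}\t"
            f"{l.flank_right}\t{int(l.short_flank)}"
        )
    return "\n".join(rows) + "\n"
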