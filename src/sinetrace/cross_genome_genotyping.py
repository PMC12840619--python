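"""Cross-genome presence/absence genotyping of flanked SINE loci.

Each locus (element + up to 500 bp flanks) is located in a target genome by
exact k-mer seeding from both flanks, then aligned locally under affine gap
scoring.  Presence (code 1) requires both flanks and the element span to
align; absence (code 0) requires both flanks to align around a single
query-only gap whose length matches the missing element — the observable
signature of a clean pre-integration site (for a ~100 bp element plus tail
and one TSD copy this is the classic "~85 bp and upward" gap).  Anything
else is a missing value (code ?) with a machine-readable reason instead of
silent manual resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio import Align

from . import _seq
from .annotation_io import GenomeAssembly
from .ascertainment import LocusRecord

__all__ = [
    "GenotypeThresholds",
    "CandidateWindow",
    "LocusAlignment",
    "GenotypeCall",
    "GenotypeMatrix",
    "GenomeKmerIndex",
    "find_candidate_windows",
    "align_locus",
    "call_genotype",
    "genotype_locus",
    "build_genotype_matrix",
]


@dataclass(frozen=True)
class GenotypeThresholds:
    """Tunable cut-offs for the genotype caller.

    The accepted absence-gap window scales with element length L:
    ``[gap_low_frac * L, gap_high_frac * (L + max_a_tail)]`` — the gap left
    by a missing element varies with its A-tail, so a hard constant would
    misclassify long-tailed loci.
    """

    k: int = 14
    min_seeds: int = 2
    window_pad: int = 1000
    max_windows: int = 3
    max_kmer_hits: int = 50
    cluster_gap: int = 800  # spans the diagonal shift of mid-sized deletions
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -0.5
    min_flank_identity: float = 0.85
    min_flank_coverage: float = 0.80
    min_element_match: float = 0.80
    max_element_match_for_absence: float = 0.20
    gap_low_frac: float = 0.6
    gap_high_frac: float = 1.3
    max_a_tail: int = 100
    unique_margin: float = 1.1


@dataclass
class CandidateWindow:
    contig: str
    start0: int  # 0-based half-open on the contig
    end0: int
    seeds: int


@dataclass
class LocusAlignment:
    window: CandidateWindow
    score: float
    target_begin: int  # 1-based inclusive, contig coordinates
    target_end: int
    identity_left: float
    identity_right: float
    coverage_left: float
    coverage_right: float
    element_match_frac: float
    element_gap_length: int  # largest net query-only gap over the element span
    element_gap_in_target_at: Optional[int]  # 1-based contig pos of the gap


@dataclass
class GenotypeCall:
    locus_id: str
    target_species: str
    code: str  # "1" | "0" | "?"
    contig: Optional[str] = None
    target_begin: Optional[int] = None
    target_end: Optional[int] = None
    identity_left: float = 0.0
    identity_right: float = 0.0
    gap_length: Optional[int] = None
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.code == "0" and self.gap_length is None:
            raise ValueError("absence call requires a recorded gap length")
        if self.code == "?" and not self.reason:
            raise ValueError("missing-value call requires a reason")


class GenomeKmerIndex:
    """Sorted k-mer index of one genome, shared across loci."""

    def __init__(self, genome: GenomeAssembly, k: int = 14):
        self.genome = genome
        self.k = k
        self._contigs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, seq in genome.contigs.items():
            arr = _seq.encode(seq)
            keys, valid = _seq.kmer_codes(arr, k)
            pos = np.nonzero(valid)[0]
            keys = keys[pos]
            order = np.argsort(keys, kind="stable")
            self._contigs[name] = (keys[order], pos[order])

    def lookup(self, query_keys: np.ndarray, max_hits: int
               ) -> dict[str, list[tuple[int, int]]]:
        """Map query k-mer keys to genome positions.

        Returns, per contig, (genome_pos0, query_index) pairs; keys hitting
        more than ``max_hits`` genome positions are skipped as repetitive.
        """
        out: dict[str, list[tuple[int, int]]] = {}
        for contig, (skeys, spos) in self._contigs.items():
            lo = np.searchsorted(skeys, query_keys, side="left")
            hi = np.searchsorted(skeys, query_keys, side="right")
            pairs: list[tuple[int, int]] = []
            for qi in range(len(query_keys)):
                n = hi[qi] - lo[qi]
                if 0 < n <= max_hits:
                    for p in spos[lo[qi] : hi[qi]]:
                        pairs.append((int(p), qi))
            if pairs:
                out[contig] = pairs
        return out


def _flank_query_kmers(locus: LocusRecord, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(keys, query_offsets) for all N-free k-mers in both flanks."""
    arr = _seq.encode(locus.sequence)
    keys, valid = _seq.kmer_codes(arr, k)
    offs = np.arange(len(keys))
    left_ok = offs + k <= locus.flank_left
    right_ok = offs >= locus.flank_left + locus.element_length
    sel = valid & (left_ok | right_ok)
    return keys[sel], offs[sel]


def find_candidate_windows(
    locus: LocusRecord,
    index: GenomeKmerIndex,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
) -> list[CandidateWindow]:
    """Cluster exact flank k-mer hits into padded candidate windows.

    Hits are projected to an implied locus start (genome position minus
    query offset) and clustered with a gap tolerance large enough to absorb
    the diagonal shift an absent element introduces between the two flanks.
    Windows are sorted by seed count, descending.
    """
    t = thresholds
    if len(locus.sequence) < t.k:
        return []
    keys, offs = _flank_query_kmers(locus, t.k)
    if len(keys) == 0:
        return []
    hits = index.lookup(keys, t.max_kmer_hits)
    windows: list[CandidateWindow] = []
    for contig, pairs in hits.items():
        clen = len(index.genome.contigs[contig])
        starts = np.array([p - offs[qi] for p, qi in pairs])
        ends = np.array([p + t.k for p, qi in pairs])
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        i = 0
        while i < len(starts):
            j = i + 1
            while j < len(starts) and starts[j] - starts[j - 1] <= t.cluster_gap:
                j += 1
            if j - i >= t.min_seeds:
                w0 = max(0, int(starts[i]) - t.window_pad)
                w1 = min(clen, int(ends[i:j].max()) + t.window_pad)
                windows.append(CandidateWindow(contig, w0, w1, seeds=j - i))
            i = j
    windows.sort(key=lambda w: (-w.seeds, w.contig, w.start0))
    return windows


def _make_aligner(t: GenotypeThresholds) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = t.match_score
    al.mismatch_score = t.mismatch_score
    al.open_gap_score = t.gap_open
    al.extend_gap_score = t.gap_extend
    return al


def align_locus(
    locus: LocusRecord,
    window: CandidateWindow,
    genome: GenomeAssembly,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    aligner: Align.PairwiseAligner | None = None,
) -> LocusAlignment:
    """Best local alignment of the locus against one candidate window,
    with per-flank identity/coverage and the largest element-span gap."""
    t = thresholds
    if window.end0 - window.start0 < 2 * t.k:
        raise ValueError("candidate window shorter than 2k")
    if aligner is None:
        aligner = _make_aligner(t)
    q = locus.sequence
    target = genome.contigs[window.contig][window.start0 : window.end0]
    aln = aligner.align(q, target)[0]
    qblocks, tblocks = aln.aligned
    qarr = _seq.encode(q)
    tarr = _seq.encode(target)

    fl = locus.flank_left
    el = locus.element_length
    espan = (fl, fl + el)  # 0-based half-open in query coords
    rspan = (fl + el, len(q))

    def span_stats(lo: int, hi: int) -> tuple[int, int]:
        """(aligned query positions, matches) within query span [lo,hi)."""
        aligned = matches = 0
        for (qs, qe), (ts, te) in zip(qblocks, tblocks):
            s, e = max(qs, lo), min(qe, hi)
            if s >= e:
                continue
            aligned += e - s
            off = ts + (s - qs)
            qa, ta = qarr[s:e], tarr[off : off + (e - s)]
            ok = (qa < 4) & (ta < 4)
            matches += int(((qa == ta) & ok).sum())
        return aligned, matches

    la, lm = span_stats(0, fl)
    ra, rm = span_stats(*rspan)
    ea, _ = span_stats(*espan)
    # the A-tail and 3' TSD copy sit at the start of the right flank and are
    # legitimately missing from a pre-integration site, so they are exempt
    # from the right-flank coverage requirement
    tail_allow = min(t.max_a_tail + 25, max(0, locus.flank_right - 100))
    ra_cov, _ = span_stats(rspan[0] + tail_allow, rspan[1])
    r_denominator = locus.flank_right - tail_allow

    # net query-only gap over the element span; short spurious matches inside
    # a long deletion fragment it, so overlapping net gaps are summed
    gap_len = 0
    gap_at: Optional[int] = None
    for idx in range(1, len(qblocks)):
        dq = int(qblocks[idx][0] - qblocks[idx - 1][1])
        dt = int(tblocks[idx][0] - tblocks[idx - 1][1])
        net = dq - dt
        if net <= 0:
            continue
        g_lo, g_hi = int(qblocks[idx - 1][1]), int(qblocks[idx][0])
        if g_lo < espan[1] + tail_allow and g_hi > espan[0]:
            gap_len += net
            if gap_at is None:
                gap_at = window.start0 + int(tblocks[idx - 1][1]) + 1
    return LocusAlignment(
        window=window,
        score=float(aln.score),
        target_begin=window.start0 + int(tblocks[0][0]) + 1,
        target_end=window.start0 + int(tblocks[-1][1]),
        identity_left=lm / la if la else 0.0,
        identity_right=rm / ra if ra else 0.0,
        coverage_left=la / fl if fl else 1.0,
        coverage_right=ra_cov / r_denominator if r_denominator > 0 else 1.0,
        element_match_frac=ea / el if el else 0.0,
        element_gap_length=gap_len,
        element_gap_in_target_at=gap_at,
    )


def call_genotype(
    locus: LocusRecord,
    alignments: list[LocusAlignment],
    target_species: str,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
) -> GenotypeCall:
    """Combine window alignments into a {1,0,?} call with evidence."""
    t = thresholds
    if locus.short_flank:
        return GenotypeCall(locus.locus_id, target_species, "?",
                            reason="short_flank")
    if not alignments:
        return GenotypeCall(locus.locus_id, target_species, "?",
                            reason="no_hit")
    ranked = sorted(alignments, key=lambda a: -a.score)
    best = ranked[0]
    if len(ranked) > 1 and ranked[1].score > 0 \
            and best.score < t.unique_margin * ranked[1].score:
        return GenotypeCall(locus.locus_id, target_species, "?",
                            reason="ambiguous_multi_hit")
    flanks_ok = (
        best.coverage_left >= t.min_flank_coverage
        and best.coverage_right >= t.min_flank_coverage
        and best.identity_left >= t.min_flank_identity
        and best.identity_right >= t.min_flank_identity
    )
    common = dict(
        contig=best.window.contig,
        target_begin=best.target_begin, target_end=best.target_end,
        identity_left=best.identity_left, identity_right=best.identity_right,
    )
    if not flanks_ok:
        reason = "one_flank_only" if (
            best.coverage_left >= t.min_flank_coverage
        ) != (best.coverage_right >= t.min_flank_coverage) else "flank_quality"
        return GenotypeCall(locus.locus_id, target_species, "?",
                            reason=reason, **common)
    if best.element_match_frac >= t.min_element_match:
        return GenotypeCall(locus.locus_id, target_species, "1", **common)
    L = locus.element_length
    gap_lo = t.gap_low_frac * L
    gap_hi = t.gap_high_frac * (L + t.max_a_tail)
    if (
        best.element_match_frac <= t.max_element_match_for_absence
        and best.element_gap_length > 0
    ):
        if gap_lo <= best.element_gap_length <= gap_hi:
            return GenotypeCall(locus.locus_id, target_species, "0",
                                gap_length=best.element_gap_length, **common)
        return GenotypeCall(locus.locus_id, target_species, "?",
                            reason="gap_outside_window",
                            gap_length=best.element_gap_length, **common)
    return GenotypeCall(locus.locus_id, target_species, "?",
                        reason="partial_element", **common)


def _split_flank_rescue(
    locus: LocusRecord,
    window: CandidateWindow,
    genome: GenomeAssembly,
    t: GenotypeThresholds,
    aligner: Align.PairwiseAligner,
    call: GenotypeCall,
) -> GenotypeCall:
    """Refine an ambiguous call when a deletion too large to bridge in one
    affine alignment separates the two flank anchors.

    Each flank is aligned independently inside the (expanded) window; when
    both anchor in order and the net query-only span between them exceeds
    the accepted absence gap, the locus sits on a target-side deletion that
    removed more than the element — reported as ``gap_outside_window``, the
    machine-readable stand-in for a deletion-involved anomaly.
    """
    contig = genome.contigs[window.contig]
    lo = max(0, window.start0 - 1000)
    hi = min(len(contig), window.end0 + 1000)
    target = contig[lo:hi]
    fl, el = locus.flank_left, locus.element_length
    left_q = locus.sequence[:fl]
    right_q = locus.sequence[fl + el :]
    if not left_q or not right_q:
        return call
    tarr = _seq.encode(target)
    res = []
    for qseq in (left_q, right_q):
        alns = aligner.align(qseq, target)
        if len(alns) == 0:
            return call
        aln = alns[0]
        qb, tb = aln.aligned
        qarr = _seq.encode(qseq)
        aligned = matches = 0
        for (qs, qe), (ts, te) in zip(qb, tb):
            a, b = qarr[qs:qe], tarr[ts:te]
            ok = (a < 4) & (b < 4)
            aligned += int(ok.sum())
            matches += int(((a == b) & ok).sum())
        # a deletion may leave only a remnant of the flank; a >= 60 bp
        # high-identity anchor is still effectively unique
        if aligned < 60 or matches < t.min_flank_identity * aligned:
            return call
        res.append((int(qb[0][0]), int(qb[-1][1]), int(tb[0][0]), int(tb[-1][1])))
    (lqs, lqe, lts, lte), (rqs, rqe, rts, rte) = res
    if rts < lte - 100:  # anchors grossly out of order: not a simple deletion
        return call
    net = ((rqs + fl + el) - lqe) - max(0, rts - lte)
    gap_hi = t.gap_high_frac * (el + t.max_a_tail)
    if net > gap_hi:
        return GenotypeCall(
            locus.locus_id, call.target_species, "?",
            reason="gap_outside_window", gap_length=int(net),
            contig=window.contig,
            target_begin=lo + lts + 1, target_end=lo + rte,
            identity_left=call.identity_left,
            identity_right=call.identity_right,
        )
    return call


def genotype_locus(
    locus: LocusRecord,
    index: GenomeKmerIndex,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    aligner: Align.PairwiseAligner | None = None,
) -> GenotypeCall:
    """Seed, align (top windows) and call one locus against one genome."""
    t = thresholds
    if aligner is None:
        aligner = _make_aligner(t)
    windows = find_candidate_windows(locus, index, t)
    if not windows:
        return GenotypeCall(locus.locus_id, index.genome.species, "?",
                            reason="no_hit")
    top = windows[0].seeds
    use = [w for w in windows[: t.max_windows] if w.seeds >= 0.25 * top]
    alignments = [
        align_locus(locus, w, index.genome, t, aligner) for w in use
    ]
    call = call_genotype(locus, alignments, index.genome.species, t)
    if call.code == "?" and call.reason in (
        "flank_quality", "one_flank_only", "partial_element"
    ):
        call = _split_flank_rescue(
            locus, use[0], index.genome, t, aligner, call
        )
    return call


@dataclass
class GenotypeMatrix:
    """Merged loci x species codes with per-cell evidence."""

    codes: pd.DataFrame  # values in {"1","0","?"}
    calls: dict[tuple[str, str], GenotypeCall] = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)
    source_species: dict[str, str] = field(default_factory=dict)

    def to_tsv(self) -> str:
        df = self.codes.copy()
        df.insert(0, "locus_id", df.index)
        return df.to_csv(sep="\t", index=False)

    def to_nexus(self) -> str:
        taxa = list(self.codes.columns)
        lines = [
            "#NEXUS", "BEGIN DATA;",
            f"DIMENSIONS NTAX={len(taxa)} NCHAR={len(self.codes)};",
            'FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
            "MATRIX",
        ]
        for sp in taxa:
            lines.append(f"{sp}\t{''.join(self.codes[sp].tolist())}")
        lines += [";", "END;"]
        return "\n".join(lines) + "\n"

    def calls_jsonl(self) -> str:
        import json

        rows = []
        for (lid, sp), c in sorted(self.calls.items()):
            rows.append(json.dumps({
                "locus_id": lid, "species": sp, "code": c.code,
                "contig": c.contig, "target_begin": c.target_begin,
                "target_end": c.target_end, "gap_length": c.gap_length,
                "reason": c.reason,
            }))
        return "\n".join(rows) + ("\n" if rows else "")


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # smaller id wins so merging is order-independent
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def build_genotype_matrix(
    loci: list[LocusRecord],
    genomes: dict[str, GenomeAssembly],
    thresholds: GenotypeThresholds = GenotypeThresholds(),
) -> GenotypeMatrix:
    """Genotype every locus against every genome and merge reciprocal
    duplicates (one insertion ascertained from two carrier species) into a
    single matrix row.  The source species of a locus always codes 1."""
    species = sorted(genomes)
    if not loci:
        return GenotypeMatrix(codes=pd.DataFrame(columns=species))
    ids = [l.locus_id for l in loci]
    if len(ids) != len(set(ids)):
        raise ValueError("locus ids must be globally unique")
    aligner = _make_aligner(thresholds)
    raw: dict[tuple[str, str], GenotypeCall] = {}
    for sp in species:
        index = GenomeKmerIndex(genomes[sp], thresholds.k)
        for locus in loci:
            if locus.species == sp:
                raw[(locus.locus_id, sp)] = GenotypeCall(
                    locus.locus_id, sp, "1",
                    contig=locus.contig,
                    target_begin=locus.element_begin,
                    target_end=locus.element_end,
                    identity_left=1.0, identity_right=1.0,
                )
            else:
                raw[(locus.locus_id, sp)] = genotype_locus(
                    locus, index, thresholds, aligner
                )

    by_id = {l.locus_id: l for l in loci}
    uf = _UnionFind(ids)
    by_species: dict[str, list[LocusRecord]] = {}
    for l in loci:
        by_species.setdefault(l.species, []).append(l)
    for la in loci:
        for sp, targets in by_species.items():
            if sp == la.species:
                continue
            ca = raw[(la.locus_id, sp)]
            if ca.code != "1" or ca.target_begin is None:
                continue
            for lb in targets:
                if lb.contig != ca.contig:
                    continue
                if not _overlap(
                    (ca.target_begin, ca.target_end),
                    (lb.element_begin, lb.element_end),
                ):
                    continue
                cb = raw[(lb.locus_id, la.species)]
                if (
                    cb.code == "1"
                    and cb.contig == la.contig
                    and cb.target_begin is not None
                    and _overlap(
                        (cb.target_begin, cb.target_end),
                        (la.element_begin, la.element_end),
                    )
                ):
                    uf.union(la.locus_id, lb.locus_id)

    groups: dict[str, list[str]] = {}
    for lid in ids:
        groups.setdefault(uf.find(lid), []).append(lid)

    rows = {}
    calls: dict[tuple[str, str], GenotypeCall] = {}
    members: dict[str, list[str]] = {}
    sources: dict[str, str] = {}
    for rep in sorted(groups):
        member_ids = sorted(groups[rep])
        members[rep] = member_ids
        sources[rep] = by_id[rep].species
        row = {}
        for sp in species:
            cands = [raw[(m, sp)] for m in member_ids]
            chosen = None
            for want in ("1", "0"):
                for c in cands:
                    if c.code == want:
                        chosen = c
                        break
                if chosen:
                    break
            if chosen is None:
                chosen = cands[0]
            row[sp] = chosen.code
            calls[(rep, sp)] = chosen
        rows[rep] = row
    codes = pd.DataFrame.from_dict(rows, orient="index")[species]
    codes = codes.loc[sorted(rows)]
    return GenotypeMatrix(codes=codes, calls=calls, members=members,
                          source_species=sources)
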