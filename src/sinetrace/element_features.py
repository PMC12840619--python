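"""TPRT hallmark detection on flanked loci.

Target-primed reverse transcription leaves a signature around each
integrated copy: a 3' poly-A tail, a short direct repeat (target-site
duplication, TSD) flanking element+tail, an endonuclease cleavage motif
(canonically 5'-TTTT/AA-3') at the 5' TSD boundary, and sometimes a TTTT
termination signal downstream of the 3' TSD.  These detectors make each
hallmark measurable with explicit, configurable rules; a copy with a
precise TSD (both copies identical) is the strongest evidence of genuine
TPRT integration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .ascertainment import LocusRecord

__all__ = [
    "FeatureReport",
    "detect_a_tail",
    "detect_tsd",
    "detect_cleavage",
    "find_termination",
    "characterize_locus",
    "reports_to_tsv",
]


@dataclass
class FeatureReport:
    locus_id: str
    a_tail_length: int
    tsd_sequence: str
    tsd_length: int
    tsd_precise: bool
    cleavage_match: str  # "canonical" | "near" | "none"
    termination_distance: Optional[int]

    def __post_init__(self) -> None:
        if self.a_tail_length < 0:
            raise ValueError("a_tail_length must be >= 0")
        if self.tsd_length != len(self.tsd_sequence):
            raise ValueError("tsd_length inconsistent with tsd_sequence")


def detect_a_tail(
    locus: LocusRecord,
    min_window_a_fraction: float = 0.9,
    window: int = 10,
    max_non_a_run: int = 2,
) -> int:
    """Length of the poly-A tract starting at the element 3' end.

    Extends rightward while the A-fraction over the trailing ``window``
    stays at or above ``min_window_a_fraction`` and no run of more than
    ``max_non_a_run`` consecutive non-A bases occurs; trailing non-A bases
    are then trimmed, so the tail always ends on an A.
    """
    seq = locus.sequence[locus.flank_left + locus.element_length :]
    taken = 0
    non_a_run = 0
    for i, base in enumerate(seq):
        is_a = base == "A"
        non_a_run = 0 if is_a else non_a_run + 1
        if non_a_run > max_non_a_run:
            break
        w = seq[max(0, i - window + 1) : i + 1]
        if w.count("A") / len(w) < min_window_a_fraction:
            break
        taken = i + 1
    while taken > 0 and seq[taken - 1] != "A":
        taken -= 1
    return taken


def detect_tsd(
    locus: LocusRecord,
    a_tail_length: int,
    min_len: int = 6,
    max_len: int = 25,
    max_mismatch: int = 1,
) -> tuple[str, bool]:
    """Longest direct repeat between the 5' flank suffix and the sequence
    immediately after the A-tail.

    Both copies are anchored — the left copy ends at the element 5'
    boundary, the right copy starts right after the tail — so only the
    repeat length varies.  An exact (precise) duplication is preferred at
    any length over a longer mismatched one.  Returns ("", False) when no
    duplication of at least ``min_len`` qualifies.
    """
    left = locus.sequence[: locus.flank_left]
    right_start = locus.flank_left + locus.element_length + a_tail_length
    right = locus.sequence[right_start:]
    limit = min(max_len, len(left), len(right))
    best_exact = ""
    best_loose = ""
    for l in range(limit, min_len - 1, -1):
        a, b = left[-l:], right[:l]
        mm = sum(1 for x, y in zip(a, b) if x != y)
        if mm == 0 and not best_exact:
            best_exact = a
        if mm <= max_mismatch and not best_loose:
            best_loose = a
    if best_exact:
        return best_exact, True
    if best_loose:
        return best_loose, False
    return "", False


def detect_cleavage(locus: LocusRecord, tsd: str) -> str:
    """Grade the endonuclease cleavage motif at the 5' TSD boundary.

    Examines the 6 bp straddling the TSD start — 4 bp of upstream flank plus
    the first 2 TSD bases — against the canonical 5'-TTTT/AA-3' site:
    "canonical" on identity, "near" at one mismatch, else "none".  Loci are
    oriented with the element in sense (A-tail 3') before calling this.
    """
    if len(tsd) < 2:
        return "none"
    upstream = locus.sequence[: locus.flank_left - len(tsd)]
    if len(upstream) < 4:
        return "none"
    motif = upstream[-4:] + tsd[:2]
    mm = sum(1 for x, y in zip(motif, "TTTTAA") if x != y)
    if mm == 0:
        return "canonical"
    if mm <= 1:
        return "near"
    return "none"


def find_termination(
    locus: LocusRecord,
    a_tail_length: int,
    tsd_length: int,
    scan_limit: int = 200,
) -> Optional[int]:
    """Distance from the base after the 3' TSD to the nearest exact TTTT
    start within ``scan_limit`` bp; None when absent."""
    start = (
        locus.flank_left + locus.element_length + a_tail_length + tsd_length
    )
    seg = locus.sequence[start : start + scan_limit + 4]
    for i in range(0, min(len(seg) - 3, scan_limit + 1)):
        if seg[i : i + 4] == "TTTT":
            return i
    return None


def characterize_locus(locus: LocusRecord, **tsd_kwargs) -> FeatureReport:
    """Run all hallmark detectors on one locus."""
    tail = detect_a_tail(locus)
    tsd, precise = detect_tsd(locus, tail, **tsd_kwargs)
    cleavage = detect_cleavage(locus, tsd) if tsd else "none"
    term = (
        find_termination(locus, tail, len(tsd)) if tsd else None
    )
    return FeatureReport(
        locus_id=locus.locus_id,
        a_tail_length=tail,
        tsd_sequence=tsd,
        tsd_length=len(tsd),
        tsd_precise=precise,
        cleavage_match=cleavage,
        termination_distance=term,
    )


def reports_to_tsv(reports: list[FeatureReport]) -> str:
    header = (
        "locus_id\ta_tail_length\ttsd_sequence\ttsd_length\ttsd_precise\t"
        "cleavage_match\ttermination_distance"
    )
    rows = [header]
    for r in reports:
        term = "" if r.termination_distance is None else str(r.termination_distance)
        rows.append(
            f"{r.locus_id}\t{r.a_tail_length}\t{r.tsd_sequence}\t"
            f"{r.tsd_length}\t{int(r.tsd_precise)}\t{r.cleavage_match}\t{term}"
        )
    return "\n".join(rows) + "\n"
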