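"""Repeat-landscape statistics around focal SINE insertions.

Covers four summaries of the annotation table: how often a focal element
sits within D bp of another repeat class (nearest-neighbor proximity),
what fraction of the genome each repeat class masks, how masked bp
distribute over percent-divergence bins (the classic repeat-landscape
histogram), and which focal elements are nested inside a pre-existing
Alu/L1 copy — detected primarily from fragment run IDs (two host fragments
sharing an ID whose consensus coordinates continue across the focal
element) with interval containment as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .annotation_io import RepeatAnnotation

__all__ = [
    "ProximityReport",
    "NestedCall",
    "interval_distance",
    "proximity_within",
    "genome_repeat_content",
    "divergence_histogram",
    "detect_nested",
    "nested_by_age",
]


def interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Bases strictly between two 1-based inclusive intervals; 0 on overlap
    or adjacency."""
    if a[0] > b[1]:
        return a[0] - b[1] - 1
    if b[0] > a[1]:
        return b[0] - a[1] - 1
    return 0


@dataclass
class ProximityReport:
    distance: int
    n_focal: int
    counts: dict[str, int]  # repeat class -> focal elements with a neighbor within D

    @property
    def percentages(self) -> dict[str, float]:
        if self.n_focal == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.n_focal for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "repeat_class": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [pct[k] for k in self.counts],
            }
        )


def proximity_within(
    focal: list[RepeatAnnotation],
    annotations: list[RepeatAnnotation],
    distance: int = 50,
) -> ProximityReport:
    """Count focal elements with a same-contig neighbor of each repeat class
    within ``distance`` bp (inclusive; overlap counts as distance 0).  The
    focal element itself is excluded as its own neighbor, but other focal
    elements of the same class do count."""
    classes = sorted({a.repeat_class for a in annotations})
    by_contig: dict[str, list[RepeatAnnotation]] = {}
    for a in annotations:
        by_contig.setdefault(a.query_name, []).append(a)
    for rows in by_contig.values():
        rows.sort(key=lambda r: r.query_begin)
    counts = {c: 0 for c in classes}
    for f in focal:
        rows = by_contig.get(f.query_name, [])
        near: set[str] = set()
        fi = (f.query_begin, f.query_end)
        for r in rows:
            if r is f:
                continue
            if r.query_begin - f.query_end - 1 > distance:
                break
            if interval_distance(fi, (r.query_begin, r.query_end)) <= distance:
                near.add(r.repeat_class)
        for c in near:
            counts[c] += 1
    return ProximityReport(distance=distance, n_focal=len(focal), counts=counts)


def genome_repeat_content(
    annotations: list[RepeatAnnotation],
    genome_sizes: dict[str, int],
) -> dict[str, float]:
    """Percent of total genome bp masked per repeat class.

    Overlapping intervals of the same class are merged before counting;
    cross-class overlaps count toward each class independently, mirroring
    per-class masking percentages."""
    total = sum(genome_sizes.values())
    if total <= 0:
        raise ValueError("total genome size must be positive")
    per_class: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for a in annotations:
        per_class.setdefault(a.repeat_class, {}).setdefault(
            a.query_name, []
        ).append((a.query_begin, a.query_end))
    out: dict[str, float] = {}
    for cls, contigs in per_class.items():
        covered = 0
        for ivs in contigs.values():
            ivs.sort()
            cur_lo, cur_hi = ivs[0]
            for lo, hi in ivs[1:]:
                if lo <= cur_hi + 1:
                    cur_hi = max(cur_hi, hi)
                else:
                    covered += cur_hi - cur_lo + 1
                    cur_lo, cur_hi = lo, hi
            covered += cur_hi - cur_lo + 1
        out[cls] = 100.0 * covered / total
    return out


def divergence_histogram(
    annotations: list[RepeatAnnotation],
    bin_width: float = 1.0,
    weight: str = "bp",
) -> pd.DataFrame:
    """Histogram of masked bp (or element count) per percent-divergence bin,
    per repeat class.  An element falls in bin floor(pct_div / bin_width);
    bins are labelled by their left edge."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if weight not in ("bp", "count"):
        raise ValueError("weight must be 'bp' or 'count'")
    rows = []
    for a in annotations:
        w = a.query_length if weight == "bp" else 1
        rows.append(
            {
                "repeat_class": a.repeat_class,
                "bin": int(a.pct_div // bin_width) * bin_width,
                "weight": w,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["repeat_class", "bin", "weight"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["repeat_class", "bin"], as_index=False)["weight"]
        .sum()
        .sort_values(["repeat_class", "bin"])
        .reset_index(drop=True)
    )


@dataclass
class NestedCall:
    inner: RepeatAnnotation
    host_class: str
    host_name: str
    evidence: str  # "run_id_adjacency" | "containment"
    host_fragments: tuple[Optional[RepeatAnnotation], Optional[RepeatAnnotation]]
    host_cons_position: Optional[int]  # inner position on the host consensus


def detect_nested(
    annotations: list[RepeatAnnotation],
    focal_class: str = "SINE/Platy",
    cons_tolerance: int = 20,
) -> list[NestedCall]:
    """Find focal elements nested inside another repeat.

    Primary rule: the rows immediately before and after the focal element on
    the contig share one run ID and repeat name, and the downstream
    fragment's consensus start continues from the upstream fragment's
    consensus end within ``cons_tolerance`` bp.  Fallback: the focal
    interval lies strictly inside a single host row."""
    by_contig: dict[str, list[RepeatAnnotation]] = {}
    for a in annotations:
        by_contig.setdefault(a.query_name, []).append(a)
    calls: list[NestedCall] = []
    for contig, rows in by_contig.items():
        rows.sort(key=lambda r: (r.query_begin, r.query_end))
        for i, a in enumerate(rows):
            if a.repeat_class != focal_class:
                continue
            up = rows[i - 1] if i > 0 else None
            down = rows[i + 1] if i + 1 < len(rows) else None
            if (
                up is not None
                and down is not None
                and up.run_id == down.run_id
                and up.repeat_name == down.repeat_name
                and up.repeat_class != focal_class
                and abs(down.cons_begin - (up.cons_end + 1)) <= cons_tolerance
            ):
                calls.append(
                    NestedCall(
                        inner=a,
                        host_class=up.repeat_class,
                        host_name=up.repeat_name,
                        evidence="run_id_adjacency",
                        host_fragments=(up, down),
                        host_cons_position=up.cons_end,
                    )
                )
                continue
            host = next(
                (
                    r for r in rows
                    if r is not a
                    and r.repeat_class != focal_class
                    and r.query_begin < a.query_begin
                    and a.query_end < r.query_end
                ),
                None,
            )
            if host is not None:
                pos = host.cons_begin + (a.query_begin - host.query_begin) - 1
                calls.append(
                    NestedCall(
                        inner=a,
                        host_class=host.repeat_class,
                        host_name=host.repeat_name,
                        evidence="containment",
                        host_fragments=(host, None),
                        host_cons_position=pos,
                    )
                )
    return calls


def nested_by_age(
    nested: dict[str, NestedCall],
    categories: dict[str, str],
) -> tuple[pd.DataFrame, float]:
    """Crosstab host class x specificity category over a common locus set.

    ``nested`` maps locus id -> NestedCall (loci absent from the mapping are
    unnested); ``categories`` maps locus id -> category label.  Returns the
    counts table and the overall nested fraction."""
    all_loci = list(categories)
    if not all_loci:
        return pd.DataFrame(), 0.0
    rows = []
    for lid, call in nested.items():
        if lid not in categories:
            raise KeyError(f"nested locus {lid!r} missing a category")
        rows.append({"host": call.host_class, "category": categories[lid]})
    frac = len(nested) / len(all_loci)
    if not rows:
        return pd.DataFrame(), 0.0
    df = pd.DataFrame(rows)
    tab = pd.crosstab(df["host"], df["category"])
    return tab, frac
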