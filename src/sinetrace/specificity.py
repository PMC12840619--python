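"""Specificity taxonomy for presence/absence rows.

Categories: FP (fixed present — every non-missing species carries the
insertion), LS (lineage-specific — exactly one carrier), MV (missing values
in a majority of species) and Poly (anything variable), with named-clade
sub-categories for Poly rows.  A Poly presence set matching no named clade
becomes "Other"; it is flagged as incomplete lineage sorting (ILS) when the
set is not a clade of the master species tree, and as deletion-involved
when any contributing call failed on an oversized gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional

import dendropy
import pandas as pd

from .cross_genome_genotyping import GenotypeCall, GenotypeMatrix

__all__ = ["CladeMap", "SpecificityCall", "classify_locus", "classify_matrix",
           "summarize"]

CATEGORIES = ("FP", "LS", "MV", "Poly")


@dataclass
class CladeMap:
    """Species universe, named clades and the master tree for ILS checks.

    ``mv_threshold`` defaults to a simple majority ceil((N+1)/2) — with 13
    species that is 7 ("seven or more of the thirteen").
    """

    species: list[str]
    families: dict[str, str] = field(default_factory=dict)
    clades: dict[str, frozenset[str]] = field(default_factory=dict)
    tree: Optional[str] = None  # Newick
    mv_threshold: Optional[int] = None

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species")
        universe = set(self.species)
        for name, members in self.clades.items():
            extra = set(members) - universe
            if extra:
                raise ValueError(
                    f"clade {name!r} names unknown species: {sorted(extra)}"
                )
            self.clades[name] = frozenset(members)
        if self.mv_threshold is None:
            self.mv_threshold = ceil((len(self.species) + 1) / 2)
        self._tree_clades: Optional[set[frozenset[str]]] = None
        if self.tree:
            t = dendropy.Tree.get(data=self.tree, schema="newick",
                                  suppress_internal_node_taxa=True)
            self._tree_clades = set()
            for node in t.preorder_node_iter():
                self._tree_clades.add(
                    frozenset(lf.taxon.label for lf in node.leaf_iter())
                )
            for sp in self.species:
                self._tree_clades.add(frozenset({sp}))

    def is_tree_clade(self, members: frozenset[str]) -> bool:
        if self._tree_clades is None:
            return True  # no tree: cannot call incompatibility
        return members in self._tree_clades


@dataclass
class SpecificityCall:
    locus_id: str
    category: str  # FP | LS | MV | Poly
    subcategory: Optional[str] = None  # clade name | "Other" | None
    ils: bool = False
    deletion: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.subcategory is not None and self.category != "Poly":
            raise ValueError("subcategory only applies to Poly calls")


def classify_locus(
    locus_id: str,
    row: dict[str, str],
    clade_map: CladeMap,
    evidence: Optional[dict[str, GenotypeCall]] = None,
) -> SpecificityCall:
    """Classify one presence/absence row.

    Precedence: MV (missing count at threshold) > FP (all non-missing 1) >
    LS (single carrier, others 0) > Poly.  Poly sub-category is the named
    clade equal to the carrier set once missing species are excluded from
    the comparison; otherwise "Other" with diagnostic flags.
    """
    if set(row) != set(clade_map.species):
        raise ValueError(
            "row species do not match the clade map: "
            f"{sorted(set(row) ^ set(clade_map.species))}"
        )
    missing = {sp for sp, c in row.items() if c == "?"}
    present = frozenset(sp for sp, c in row.items() if c == "1")
    absent = {sp for sp, c in row.items() if c == "0"}
    if len(missing) >= clade_map.mv_threshold:
        return SpecificityCall(locus_id, "MV")
    if not absent and present:
        return SpecificityCall(locus_id, "FP")
    if len(present) == 1:
        return SpecificityCall(locus_id, "LS")
    for name, members in clade_map.clades.items():
        if members - missing == present:
            return SpecificityCall(locus_id, "Poly", subcategory=name)
    ils = not clade_map.is_tree_clade(present)
    deletion = False
    if evidence:
        deletion = any(
            c.reason == "gap_outside_window" for c in evidence.values()
        )
    return SpecificityCall(locus_id, "Poly", subcategory="Other",
                           ils=ils, deletion=deletion)


def classify_matrix(
    matrix: GenotypeMatrix, clade_map: CladeMap
) -> dict[str, SpecificityCall]:
    out = {}
    for lid in matrix.codes.index:
        row = matrix.codes.loc[lid].to_dict()
        evidence = {
            sp: matrix.calls[(lid, sp)]
            for sp in matrix.codes.columns
            if (lid, sp) in matrix.calls
        }
        out[lid] = classify_locus(lid, row, clade_map, evidence)
    return out


def summarize(
    matrix: GenotypeMatrix,
    clade_map: CladeMap,
    calls: Optional[dict[str, SpecificityCall]] = None,
) -> pd.DataFrame:
    """Per-species tally of categories and Poly sub-categories, over the loci
    ascertained FROM each species.  Category counts partition each species'
    locus total; Poly sub-categories partition its Poly total."""
    if calls is None:
        calls = classify_matrix(matrix, clade_map)
    sub_names = list(clade_map.clades) + ["Other"]
    rows = []
    for sp in clade_map.species:
        lids = [
            lid for lid in matrix.codes.index
            if matrix.source_species.get(lid) == sp
        ]
        tally = {c: 0 for c in CATEGORIES}
        subs = {s: 0 for s in sub_names}
        for lid in lids:
            call = calls[lid]
            tally[call.category] += 1
            if call.category == "Poly" and call.subcategory:
                subs[call.subcategory] += 1
        row = {"species": sp, **tally,
               "total": sum(tally.values()), **subs}
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")
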