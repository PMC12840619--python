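"""Clade simulator: genomes descending along a species tree with SINE
insertions planted on branches.

The simulator produces the statistical structure the downstream analysis
assumes: presence/absence of an insertion follows descent from the branch it
arose on, every insertion carries a target-site duplication (TSD) and a 3'
poly-A tail, elements diverge from their subfamily consensus in proportion
to their age (Jukes-Cantor substitutions), and a configurable fraction of
insertions land inside pre-existing Alu/L1 copies, splitting the host into
two co-identified fragments.

Ground truth (branch of origin, presence set, per-carrier coordinates, TSD,
A-tail, nesting host, termination signal) is recorded for every planted
locus so each pipeline stage can be scored against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from . import _seq
from .annotation_io import (
    ConsensusLibrary,
    GenomeAssembly,
    RepeatAnnotation,
    write_repeatmasker_out,
)

__all__ = [
    "SimulationConfig",
    "PlantedInsertion",
    "PlantedTruth",
    "SimulatedClade",
    "default_library",
    "simulate_clade",
    "emit_truth_out",
    "simulate_subfamily_cohort",
]

DEFAULT_TREE = "((A:1.0,B:1.0):1.0,(C:1.0,(D:1.0,E:1.0):0.5):0.5);"

# Fixed internal seed for the synthetic consensus library: the library plays
# the role of a fixed external reference and must not vary with the
# simulation seed.
_LIBRARY_SEED = 20240917


def default_library() -> ConsensusLibrary:
    """Synthetic stand-in consensus library: three ~104 bp Platy-1-style SINE
    subfamilies, one 300 bp Alu-style SINE and one 3 kb L1-style LINE.

    All sequences are synthetic (generated from a fixed seed), not copies of
    any published consensus.  SINE consensuses end in non-A bases so that the
    genomic A-tail of a planted copy is measurable as an extension beyond the
    annotated element, and start with a non-A base so TSD anchors stay
    unambiguous.
    """
    rng = np.random.default_rng(_LIBRARY_SEED)

    def draw(length: int) -> np.ndarray:
        arr = rng.integers(0, 4, length).astype(np.uint8)
        arr[0] = _seq.G
        arr[-2:] = [_seq.G, _seq.C]
        return arr

    parent = draw(104)
    def variant(base: np.ndarray, n_subs: int) -> np.ndarray:
        out = base.copy()
        pos = rng.choice(np.arange(2, len(base) - 2), size=n_subs, replace=False)
        for p in pos:
            out[p] = (out[p] + rng.integers(1, 4)) % 4
        return out

    entries = [
        ("Platy-syn-4a", "SINE/Platy", _seq.decode(parent)),
        ("Platy-syn-2a", "SINE/Platy", _seq.decode(variant(parent, 8))),
        ("Platy-syn-5", "SINE/Platy", _seq.decode(variant(parent, 8))),
        ("Alu-syn", "SINE/Alu", _seq.decode(draw(300))),
        ("L1-syn", "LINE/L1", _seq.decode(draw(3000))),
    ]
    return ConsensusLibrary(entries=entries)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated clade.

    Rates are per unit branch length of the Newick tree.  ``insertion_rate``
    is the expected number of new SINE insertions per unit branch length;
    ``substitution_rate`` is the Jukes-Cantor substitution rate per site per
    unit time, applied to the whole genome along every branch and to each
    new element for the residual portion of the branch after its insertion
    time.
    """

    tree: str = DEFAULT_TREE
    ancestral_genome_length: int = 5_000_000
    n_contigs: int = 1
    insertion_rate: float = 12.0
    substitution_rate: float = 0.025
    stem_length: float = 1.0
    tsd_length_range: tuple[int, int] = (6, 20)
    a_tail_mean: float = 15.0
    a_tail_long_prob: float = 0.02
    a_tail_long_range: tuple[int, int] = (60, 120)
    nested_fraction: float = 0.10
    background_repeat_density: float = 0.12
    at_site_bias: float = 0.8
    termination_probability: float = 0.25
    termination_offset_range: tuple[int, int] = (5, 60)
    decoy_rate: float = 0.0
    ils_count: int = 0
    deletion_count: int = 0
    subfamily_schedule: Optional[dict[str, list[str]]] = None
    min_site_separation: int = 1300
    genome_size_cap: int = 50_000_000
    library: Optional[ConsensusLibrary] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insertion_rate < 0 or self.substitution_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.tsd_length_range[0] < 0:
            raise ValueError("tsd min must be >= 0")
        if not 0.0 <= self.nested_fraction <= 1.0:
            raise ValueError("nested_fraction must lie in [0,1]")


@dataclass
class _Feature:
    """A repeat interval tracked through a lineage (1-based inclusive)."""

    contig: str
    start: int
    end: int
    repeat_name: str
    repeat_class: str
    cons_begin: int
    cons_end: int
    run_id: int
    locus_id: Optional[str] = None
    is_decoy: bool = False
    tail_len: int = 0
    tsd_len: int = 0
    presence_set: Optional[frozenset[str]] = None  # ILS loci only

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PlantedInsertion:
    """Ground truth for one planted SINE locus."""

    locus_id: str
    branch: str
    subfamily: str
    presence: frozenset[str]
    tsd: str
    tsd_len: int
    a_tail_len: int
    nested_host: Optional[str]  # host repeat_class or None
    host_run_id: Optional[int]
    termination_offset: Optional[int]
    is_ils: bool = False
    deletion_species: Optional[str] = None
    coords: dict[str, tuple[str, int, int]] = field(default_factory=dict)


@dataclass
class PlantedTruth:
    insertions: list[PlantedInsertion]

    def by_id(self) -> dict[str, PlantedInsertion]:
        return {p.locus_id: p for p in self.insertions}

    def to_json(self) -> str:
        out = []
        for p in self.insertions:
            out.append(
                {
                    "locus_id": p.locus_id,
                    "branch": p.branch,
                    "subfamily": p.subfamily,
                    "presence": sorted(p.presence),
                    "tsd": p.tsd,
                    "tsd_len": p.tsd_len,
                    "a_tail_len": p.a_tail_len,
                    "nested_host": p.nested_host,
                    "host_run_id": p.host_run_id,
                    "termination_offset": p.termination_offset,
                    "is_ils": p.is_ils,
                    "deletion_species": p.deletion_species,
                    "coords": {k: list(v) for k, v in p.coords.items()},
                }
            )
        return json.dumps(out, indent=1)


@dataclass
class SimulatedClade:
    genomes: dict[str, GenomeAssembly]
    annotations: dict[str, list[RepeatAnnotation]]
    truth_matrix: pd.DataFrame  # loci x species, values {0,1}
    truth: PlantedTruth
    library: ConsensusLibrary


@dataclass
class _Lineage:
    contigs: dict[str, np.ndarray]
    features: list[_Feature]
    # ancestral coordinate of every base (-1 for lineage-inserted bases);
    # used to keep insertion sites apart across the whole clade so that
    # independent insertions never share a flanking neighborhood
    anc: dict[str, np.ndarray]

    def copy(self) -> "_Lineage":
        return _Lineage(
            contigs={k: v.copy() for k, v in self.contigs.items()},
            features=[dataclasses_replace_feature(f) for f in self.features],
            anc={k: v.copy() for k, v in self.anc.items()},
        )


def dataclasses_replace_feature(f: _Feature) -> _Feature:
    return _Feature(**{k: getattr(f, k) for k in f.__dataclass_fields__})


class _Simulator:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.library = config.library or default_library()
        self.platy_names = [
            n for n, c, _ in self.library.entries if c.startswith("SINE/Platy")
        ]
        self.host_names = [
            (n, c) for n, c, _ in self.library.entries
            if c in ("SINE/Alu", "LINE/L1")
        ]
        self.cons = {n: _seq.encode(s) for n, _, s in self.library.entries}
        self.next_run_id = 1
        self.next_locus = 1
        self.insertions: list[PlantedInsertion] = []
        # ancestral coordinates of every insertion site, per contig
        self.used_sites: dict[str, list[int]] = {}
        try:
            self.tree = dendropy.Tree.get(
                data=config.tree, schema="newick",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises various parse errors
            raise ValueError(f"unparsable Newick tree: {exc}") from exc
        self.leaves = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(self.leaves) < 2:
            raise ValueError("tree must have at least 2 leaves")

    # -- identifiers ------------------------------------------------------
    def _new_run_id(self) -> int:
        rid = self.next_run_id
        self.next_run_id += 1
        return rid

    def _new_locus_id(self) -> str:
        lid = f"L{self.next_locus:04d}"
        self.next_locus += 1
        return lid

    @staticmethod
    def _branch_label(node) -> str:
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        return "+".join(leaves)

    def _eligible_subfamilies(self, branch: str) -> list[str]:
        sched = self.cfg.subfamily_schedule
        if sched and branch in sched:
            return sched[branch]
        return self.platy_names

    # -- ancestral genome -------------------------------------------------
    def _build_root(self) -> _Lineage:
        cfg = self.cfg
        per = cfg.ancestral_genome_length // cfg.n_contigs
        contigs = {
            f"chr{i + 1}": self.rng.integers(0, 4, per).astype(np.uint8)
            for i in range(cfg.n_contigs)
        }
        anc = {c: np.arange(len(a), dtype=np.int64) for c, a in contigs.items()}
        lin = _Lineage(contigs=contigs, features=[], anc=anc)
        self._seed_background(lin)
        return lin

    def _seed_background(self, lin: _Lineage) -> None:
        """Overwrite non-overlapping intervals with Alu/L1 consensus copies
        (L1s 5'-truncated at random, mirroring their genomic norm) until the
        target density is reached."""
        cfg = self.cfg
        if cfg.background_repeat_density <= 0 or not self.host_names:
            return
        total = sum(len(a) for a in lin.contigs.values())
        target = int(cfg.background_repeat_density * total)
        covered = 0
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in lin.contigs}
        names = [c for c in lin.contigs]
        weights = np.array([len(lin.contigs[c]) for c in names], dtype=float)
        weights /= weights.sum()
        tries = 0
        while covered < target and tries < 100_000:
            tries += 1
            name, rclass = self.host_names[
                self.rng.integers(0, len(self.host_names))
            ]
            cons = self.cons[name]
            if rclass == "LINE/L1":
                cb = int(self.rng.integers(1, len(cons) - 400))  # 5' truncation
            else:
                cb = 1
            frag = cons[cb - 1 :]
            contig = names[self.rng.choice(len(names), p=weights)]
            arr = lin.contigs[contig]
            if len(arr) < len(frag) + 1400:
                continue
            s0 = int(self.rng.integers(700, len(arr) - len(frag) - 700))
            iv = (s0, s0 + len(frag))
            if any(not (iv[1] + 10 <= a or b + 10 <= iv[0]) for a, b in occupied[contig]):
                continue
            occupied[contig].append(iv)
            mutated = _seq.mutate(frag, 0.05, self.rng)  # aged copies
            arr[iv[0] : iv[1]] = mutated
            lin.features.append(
                _Feature(
                    contig=contig, start=s0 + 1, end=s0 + len(frag),
                    repeat_name=name, repeat_class=rclass,
                    cons_begin=cb, cons_end=len(cons),
                    run_id=self._new_run_id(),
                )
            )
            covered += len(frag)

    # -- site selection ---------------------------------------------------
    def _platy_blocked(self, lin: _Lineage, contig: str) -> list[tuple[int, int]]:
        pad = 650
        return [
            (f.start - pad, f.end + pad)
            for f in lin.features
            if f.contig == contig and f.repeat_class.startswith("SINE/Platy")
        ]

    def _check_site(self, lin: _Lineage, contig: str, cut: int, l: int,
                    blocked: list[tuple[int, int]]) -> bool:
        arr = lin.contigs[contig]
        if cut - l - 2 < 700 or cut + 700 > len(arr):
            return False
        if arr[cut - l] == _seq.A or arr[cut - l + 1] == _seq.A:
            return False  # TSD must not begin with A (keeps tail boundary crisp)
        if arr[cut - l - 1] == arr[cut]:
            return False  # TSD must be maximal (unambiguous length)
        pos1 = cut  # 1-based position of base before junction
        if any(a <= pos1 <= b for a, b in blocked):
            return False
        a_pos = int(lin.anc[contig][cut])
        if a_pos < 0:
            return False  # inside lineage-inserted sequence
        sep = self.cfg.min_site_separation
        if any(abs(a_pos - u) < sep for u in self.used_sites.get(contig, ())):
            return False  # would share a flanking neighborhood with another site
        return True

    def _choose_site(self, lin: _Lineage, l: int, nested: bool,
                     ) -> Optional[tuple[str, int, Optional[_Feature]]]:
        """Pick an insertion junction.  Returns (contig, cut, host) where
        ``cut`` is the 0-based junction index (insert between cut and cut+1)
        and ``host`` is the feature being split for a nested event."""
        names = list(lin.contigs)
        weights = np.array([len(lin.contigs[c]) for c in names], dtype=float)
        weights /= weights.sum()
        if nested:
            hosts = [
                f for f in lin.features
                if f.repeat_class in ("SINE/Alu", "LINE/L1") and f.length >= 80
            ]
            if not hosts:
                nested = False
            else:
                for _ in range(400):
                    host = hosts[int(self.rng.integers(0, len(hosts)))]
                    lo, hi = host.start + 25, host.end - 25
                    if hi <= lo:
                        continue
                    cut = int(self.rng.integers(lo, hi))
                    blocked = self._platy_blocked(lin, host.contig)
                    if self._check_site(lin, host.contig, cut, l, blocked):
                        return host.contig, cut, host
                return None
        biased = self.rng.random() < self.cfg.at_site_bias
        for _ in range(600):
            contig = names[self.rng.choice(len(names), p=weights)]
            arr = lin.contigs[contig]
            cut = int(self.rng.integers(710, len(arr) - 710))
            if biased and not (
                arr[cut - l - 2] == _seq.T and arr[cut - l - 1] == _seq.T
            ):
                continue
            blocked = self._platy_blocked(lin, contig)
            if not self._check_site(lin, contig, cut, l, blocked):
                continue
            host = next(
                (
                    f for f in lin.features
                    if f.contig == contig and f.start <= cut < f.end
                ),
                None,
            )
            if host is not None:
                # nesting is governed solely by nested_fraction, so the
                # uniform path never lands inside an existing repeat
                continue
            return contig, cut, host
        return None

    # -- insertion mechanics ----------------------------------------------
    def _draw_tail(self) -> int:
        cfg = self.cfg
        if self.rng.random() < cfg.a_tail_long_prob:
            lo, hi = cfg.a_tail_long_range
            return int(self.rng.integers(lo, hi + 1))
        # geometric with mean a_tail_mean, floor 4 so a tail always exists
        t = int(self.rng.geometric(1.0 / max(cfg.a_tail_mean, 1.0)))
        return max(4, t)

    def _splice(self, lin: _Lineage, contig: str, cut: int,
                ins: np.ndarray) -> None:
        arr = lin.contigs[contig]
        n = len(ins)
        lin.contigs[contig] = np.concatenate([arr[:cut], ins, arr[cut:]])
        anc = lin.anc[contig]
        lin.anc[contig] = np.concatenate(
            [anc[:cut], np.full(n, -1, dtype=np.int64), anc[cut:]]
        )
        pos1 = cut  # 1-based position of the base before the junction
        new_feats: list[_Feature] = []
        for f in lin.features:
            if f.contig != contig or f.end <= pos1:
                continue
            if f.start > pos1:
                f.start += n
                f.end += n
            else:  # f.start <= pos1 < f.end: the junction splits f
                left_len = pos1 - f.start + 1
                right = dataclasses_replace_feature(f)
                right.start = pos1 + 1 + n
                right.end = f.end + n
                right.cons_begin = f.cons_begin + left_len
                f.end = pos1
                f.cons_end = f.cons_begin + left_len - 1
                new_feats.append(right)
        lin.features.extend(new_feats)

    def _insert_element(self, lin: _Lineage, branch: str, residual_time: float,
                        *, decoy: bool = False,
                        presence: Optional[frozenset[str]] = None,
                        carriers: Optional[frozenset[str]] = None) -> Optional[_Feature]:
        """Plant one SINE copy.  ``residual_time`` is the remaining branch
        time over which the fresh copy accumulates substitutions."""
        cfg = self.cfg
        mu = cfg.substitution_rate
        l = int(self.rng.integers(cfg.tsd_length_range[0], cfg.tsd_length_range[1] + 1))
        # ILS loci are excised later in non-carriers; a nested ILS locus
        # could not be cleanly excised, so parallel insertions stay unnested.
        nested = (not decoy) and presence is None \
            and self.rng.random() < cfg.nested_fraction
        site = self._choose_site(lin, l, nested)
        if site is None:
            return None
        contig, cut, host = site
        arr = lin.contigs[contig]
        self.used_sites.setdefault(contig, []).append(
            int(lin.anc[contig][cut])
        )
        subfam = self._eligible_subfamilies(branch)[
            int(self.rng.integers(0, len(self._eligible_subfamilies(branch))))
        ]
        cons = self.cons[subfam]
        cb = 1
        if decoy:
            cb = int(self.rng.integers(7, max(8, len(cons) // 2)))
        elem = cons[cb - 1 :].copy()
        p_res = _seq.jc_substitution_probability(mu * residual_time)
        elem = _seq.mutate(elem, p_res, self.rng)
        tail_len = self._draw_tail()
        tail = np.full(tail_len, _seq.A, dtype=np.uint8)
        tail = _seq.mutate(tail, p_res, self.rng)
        tsd = arr[cut - l : cut].copy()
        tsd_copy = _seq.mutate(tsd, p_res, self.rng)
        ins = np.concatenate([elem, tail, tsd_copy])
        self._splice(lin, contig, cut, ins)
        locus_id = None if decoy else self._new_locus_id()
        feat = _Feature(
            contig=contig, start=cut + 1, end=cut + len(elem),
            repeat_name=subfam, repeat_class="SINE/Platy",
            cons_begin=cb, cons_end=len(cons),
            run_id=self._new_run_id(), locus_id=locus_id, is_decoy=decoy,
            tail_len=tail_len, tsd_len=l, presence_set=presence,
        )
        lin.features.append(feat)
        if decoy:
            return feat
        term_off = self._plant_termination(lin, contig, feat)
        self.insertions.append(
            PlantedInsertion(
                locus_id=locus_id, branch=branch, subfamily=subfam,
                presence=carriers if carriers is not None else frozenset(),
                tsd=_seq.decode(tsd), tsd_len=l, a_tail_len=tail_len,
                nested_host=host.repeat_class if host else None,
                host_run_id=host.run_id if host else None,
                termination_offset=term_off,
                is_ils=presence is not None,
            )
        )
        return feat

    def _plant_termination(self, lin: _Lineage, contig: str,
                           feat: _Feature) -> Optional[int]:
        """With configured probability, write a TTTT termination signal at a
        known offset downstream of the 3' TSD and scrub any closer natural
        TTTT so the planted offset is the true nearest."""
        cfg = self.cfg
        arr = lin.contigs[contig]
        dstart = feat.end + feat.tail_len + feat.tsd_len  # 0-based index after 3' TSD
        if self.rng.random() >= cfg.termination_probability:
            return self._nearest_tttt(arr, dstart)
        lo, hi = cfg.termination_offset_range
        off = int(self.rng.integers(lo, hi + 1))
        if dstart + off + 4 > len(arr):
            return self._nearest_tttt(arr, dstart)
        span_lo, span_hi = dstart + 1, dstart + off + 4  # 1-based touched span
        for f in lin.features:
            if f.contig == contig and not (f.end < span_lo or f.start > span_hi):
                return self._nearest_tttt(arr, dstart)
        arr[dstart + off : dstart + off + 4] = _seq.T
        # scrub any TTTT starting before the planted offset
        for _ in range(64):
            first = self._nearest_tttt(arr, dstart)
            if first is None or first >= off:
                break
            arr[dstart + first] = _seq.C
        return off

    @staticmethod
    def _nearest_tttt(arr: np.ndarray, dstart: int, limit: int = 200) -> Optional[int]:
        seg = arr[dstart : dstart + limit + 4]
        for i in range(min(len(seg) - 3, limit + 1)):
            if (seg[i : i + 4] == _seq.T).all():
                return i
        return None

    # -- branch evolution --------------------------------------------------
    def _evolve_branch(self, lin: _Lineage, branch: str, length: float,
                       carriers: frozenset[str]) -> None:
        cfg = self.cfg
        p = _seq.jc_substitution_probability(cfg.substitution_rate * length)
        for c in lin.contigs:
            lin.contigs[c] = _seq.mutate(lin.contigs[c], p, self.rng)
        n_ins = int(self.rng.poisson(cfg.insertion_rate * length))
        times = np.sort(self.rng.uniform(0.0, length, n_ins))
        for t in times:
            self._insert_element(lin, branch, length - t, carriers=carriers)
        n_dec = int(self.rng.poisson(cfg.decoy_rate * length))
        for _ in range(n_dec):
            self._insert_element(lin, branch, 0.0, decoy=True)
        total = sum(len(a) for a in lin.contigs.values())
        if total > cfg.genome_size_cap:
            raise RuntimeError(
                f"genome grew to {total} bp, beyond the configured cap "
                f"{cfg.genome_size_cap}; lower insertion_rate or raise the cap"
            )

    # -- ILS / deletion injectors ------------------------------------------
    def _non_clade_sets(self) -> list[frozenset[str]]:
        clades = set()
        for node in self.tree.preorder_node_iter():
            clades.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
        out = []
        leaves = self.leaves
        for i in range(len(leaves)):
            for j in range(i + 1, len(leaves)):
                s = frozenset({leaves[i], leaves[j]})
                if s not in clades:
                    out.append(s)
        return sorted(out, key=lambda s: tuple(sorted(s)))

    def _excise_locus(self, lin: _Lineage, feat: _Feature, pad: int = 0) -> bool:
        """Remove element + tail + 3' TSD copy (plus ``pad`` bp each side),
        restoring the pre-integration site when pad == 0."""
        contig = feat.contig
        arr = lin.contigs[contig]
        lo0 = feat.start - 1 - pad
        hi0 = feat.end + feat.tail_len + feat.tsd_len + pad  # exclusive 0-based
        if lo0 < 0 or hi0 > len(arr):
            return False
        span_lo, span_hi = lo0 + 1, hi0  # 1-based inclusive
        for f in lin.features:
            if f is feat or f.contig != contig:
                continue
            if not (f.end < span_lo or f.start > span_hi):
                return False  # refuse to clip another feature
        n = hi0 - lo0
        lin.contigs[contig] = np.concatenate([arr[:lo0], arr[hi0:]])
        anc = lin.anc[contig]
        lin.anc[contig] = np.concatenate([anc[:lo0], anc[hi0:]])
        lin.features.remove(feat)
        for f in lin.features:
            if f.contig == contig and f.start > span_hi:
                f.start -= n
                f.end -= n
        return True

    # -- main -------------------------------------------------------------
    def run(self) -> SimulatedClade:
        cfg = self.cfg
        root_lin = self._build_root()
        all_leaves = frozenset(self.leaves)

        # ILS loci: planted pre-radiation with a non-clade presence set; the
        # clean pre-integration site is restored in every non-carrier leaf.
        ncs = self._non_clade_sets()
        for _ in range(cfg.ils_count):
            if not ncs:
                break
            target = ncs[int(self.rng.integers(0, len(ncs)))]
            self._insert_element(root_lin, "stem", 0.0, presence=target,
                                 carriers=target)

        # stem: shared history above the root split (fixed-present loci)
        if cfg.stem_length > 0:
            self._evolve_branch(root_lin, "stem", cfg.stem_length, all_leaves)

        leaf_lineages: dict[str, _Lineage] = {}

        def walk(node, lin: _Lineage) -> None:
            children = node.child_nodes()
            if not children:
                leaf_lineages[node.taxon.label] = lin
                return
            for child in children:
                sub = lin.copy()
                carriers = frozenset(
                    lf.taxon.label for lf in child.leaf_iter()
                )
                self._evolve_branch(
                    sub, self._branch_label(child),
                    child.edge.length or 0.0, carriers,
                )
                walk(child, sub)

        walk(self.tree.seed_node, root_lin)

        # ILS excisions
        by_id = {p.locus_id: p for p in self.insertions}
        for sp, lin in leaf_lineages.items():
            for feat in [f for f in lin.features if f.presence_set is not None]:
                if sp not in feat.presence_set:
                    self._excise_locus(lin, feat)

        # deletion injector: remove an FP locus plus extra flank in one leaf
        fp_loci = [
            p for p in self.insertions
            if p.presence == all_leaves and not p.is_ils
        ]
        done = 0
        for p in fp_loci:
            if done >= cfg.deletion_count:
                break
            sp = self.leaves[int(self.rng.integers(0, len(self.leaves)))]
            lin = leaf_lineages[sp]
            feat = next(
                (f for f in lin.features if f.locus_id == p.locus_id), None
            )
            if feat is not None and self._excise_locus(lin, feat, pad=300):
                p.deletion_species = sp
                p.presence = p.presence - {sp}
                done += 1

        genomes: dict[str, GenomeAssembly] = {}
        annotations: dict[str, list[RepeatAnnotation]] = {}
        for sp in self.leaves:
            lin = leaf_lineages[sp]
            genomes[sp] = GenomeAssembly(
                species=sp,
                contigs={c: _seq.decode(a) for c, a in lin.contigs.items()},
            )
            annotations[sp] = self._emit_annotations(lin)
            for f in lin.features:
                if f.locus_id and f.locus_id in by_id:
                    by_id[f.locus_id].coords[sp] = (f.contig, f.start, f.end)

        loci = [p.locus_id for p in self.insertions]
        mat = pd.DataFrame(0, index=loci, columns=self.leaves, dtype=int)
        for p in self.insertions:
            for sp in p.presence:
                mat.loc[p.locus_id, sp] = 1
        return SimulatedClade(
            genomes=genomes, annotations=annotations,
            truth_matrix=mat, truth=PlantedTruth(self.insertions),
            library=self.library,
        )

    def _emit_annotations(self, lin: _Lineage) -> list[RepeatAnnotation]:
        recs = []
        for f in sorted(lin.features, key=lambda f: (f.contig, f.start)):
            arr = lin.contigs[f.contig][f.start - 1 : f.end]
            cons = self.cons[f.repeat_name][f.cons_begin - 1 : f.cons_end]
            div = 100.0 * _seq.p_distance(arr, cons)
            sw = int(10 * max(0, f.length - 2 * round(div / 100.0 * f.length)))
            recs.append(
                RepeatAnnotation(
                    sw_score=sw, pct_div=round(div, 1), pct_del=0.0, pct_ins=0.0,
                    query_name=f.contig, query_begin=f.start, query_end=f.end,
                    strand="+", repeat_name=f.repeat_name,
                    repeat_class=f.repeat_class,
                    cons_begin=f.cons_begin, cons_end=f.cons_end,
                    cons_left=len(self.cons[f.repeat_name]) - f.cons_end,
                    run_id=f.run_id,
                )
            )
        return recs


def simulate_clade(config: SimulationConfig) -> SimulatedClade:
    """Simulate genomes along ``config.tree`` with planted SINE insertions.

    Deterministic given ``config.seed``: the same config yields byte-identical
    genomes, annotations and truth tables.
    """
    return _Simulator(config).run()


def emit_truth_out(annotations: dict[str, list[RepeatAnnotation]]) -> dict[str, str]:
    """Render per-species truth annotations as RepeatMasker-style .out text."""
    return {sp: write_repeatmasker_out(recs) for sp, recs in annotations.items()}


def simulate_subfamily_cohort(
    parent_consensus: str,
    daughters: list[tuple[str, int, list[tuple[int, str]]]],
    n_parent_like: int = 20,
    n_exact: int = 0,
    background_divergence: float = 0.03,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Generate a cohort of element copies for subfamily-discovery tests.

    ``daughters`` is a list of (name, n_members, diagnostics) where each
    diagnostic is (1-based consensus position, derived base).  Members carry
    every diagnostic of their subfamily plus background substitutions at
    non-diagnostic positions; parent-like copies carry background noise only.
    Returns (sequences by element id, truth subfamily by element id; parent
    copies labelled "parent", exact copies "exact").
    """
    rng = np.random.default_rng(seed)
    cons = _seq.encode(parent_consensus)
    seqs: dict[str, str] = {}
    truth: dict[str, str] = {}
    counter = 0

    def background(arr: np.ndarray, frozen: set[int]) -> np.ndarray:
        out = arr.copy()
        for i in range(len(out)):
            if i in frozen:
                continue
            if rng.random() < background_divergence:
                out[i] = (out[i] + rng.integers(1, 4)) % 4
        return out

    for name, n_members, diags in daughters:
        base = cons.copy()
        frozen = set()
        for pos, b in diags:
            code = _seq.encode(b)[0]
            if base[pos - 1] == code:
                raise ValueError(
                    f"diagnostic at {pos} equals the parent base {b!r}"
                )
            base[pos - 1] = code
            frozen.add(pos - 1)
        for _ in range(n_members):
            counter += 1
            eid = f"e{counter:04d}"
            seqs[eid] = _seq.decode(background(base, frozen))
            truth[eid] = name
    for _ in range(n_parent_like):
        counter += 1
        eid = f"e{counter:04d}"
        seqs[eid] = _seq.decode(background(cons, set()))
        truth[eid] = "parent"
    for _ in range(n_exact):
        counter += 1
        eid = f"e{counter:04d}"
        seqs[eid] = parent_consensus
        truth[eid] = "exact"
    return seqs, truth
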