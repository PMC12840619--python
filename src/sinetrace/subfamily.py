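"""Subfamily assignment, discovery of young subfamilies from
lineage-specific copies, and neighbor-joining trees with bootstrap.

A SINE subfamily is a cluster of copies sharing diagnostic substitutions
relative to a parent consensus.  Discovery follows the co-segregation
logic of subfamily reconstruction tools: align every copy to the parent
consensus, drop exact matches, collect candidate diagnostics (position,
derived base) carried by enough copies, and greedily grow a set of
diagnostics whose joint carrier set is large and co-occurs beyond the
independence expectation.  Members define a new consensus by column
majority; discovered subfamilies are named sf0, sf1, ... by descending
size, mirroring the conventional numbering of such tools.

Alignment scores use a simple affine scheme (match +1, mismatch -1, open
-4, extend -0.5) scaled x10 to integers; only score differences and
rankings are meaningful, never score identity with other tools whose
matrices differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from . import _seq
from .annotation_io import ConsensusLibrary

__all__ = [
    "AssignmentResult",
    "SubfamilyModel",
    "assign_subfamily",
    "reassignment_delta",
    "discover_subfamilies",
    "neighbor_joining",
    "build_nj_tree",
    "newick_string",
    "tree_bipartitions",
]

_GAP = 255  # column not covered by the element's alignment


def _aligner(match=1.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-0.5,
             mode="local") -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


@dataclass(frozen=True)
class AssignmentResult:
    element_id: str
    subfamily: str
    sw_score: int  # affine score x10
    pct_div: float  # p-distance x100 over aligned non-gap columns
    alignment_length: int


def _score_against(aligner, elem: str, cons: str) -> tuple[float, float, int]:
    """(score, pct_div, aligned_columns) of elem vs one consensus."""
    aln = aligner.align(elem, cons)[0]
    qb, tb = aln.aligned
    qarr, tarr = _seq.encode(elem), _seq.encode(cons)
    aligned = matches = 0
    for (qs, qe), (ts, te) in zip(qb, tb):
        a = qarr[qs:qe]
        b = tarr[ts : ts + (qe - qs)]
        ok = (a < 4) & (b < 4)
        aligned += int(ok.sum())
        matches += int(((a == b) & ok).sum())
    div = 100.0 * (aligned - matches) / aligned if aligned else 100.0
    return float(aln.score), div, aligned


def assign_subfamily(
    element_id: str,
    sequence: str,
    library: ConsensusLibrary,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> AssignmentResult:
    """Best-scoring library consensus wins; ties break by lower divergence,
    then library order.  Deterministic given library order."""
    if not library.entries:
        raise ValueError("empty consensus library")
    if not sequence:
        raise ValueError("empty element sequence")
    if aligner is None:
        aligner = _aligner()
    best = None
    for order, (name, _, cons) in enumerate(library.entries):
        score, div, ncols = _score_against(aligner, sequence, cons)
        key = (-score, div, order)
        if best is None or key < best[0]:
            best = (key, name, score, div, ncols)
    _, name, score, div, ncols = best
    return AssignmentResult(
        element_id=element_id,
        subfamily=name,
        sw_score=int(round(score * 10)),
        pct_div=div,
        alignment_length=ncols,
    )


def reassignment_delta(
    elements: dict[str, str],
    old_library: ConsensusLibrary,
    new_library: ConsensusLibrary,
) -> tuple[dict[str, tuple[float, float]], tuple[float, float], tuple[float, float]]:
    """Score each element under both libraries.

    Returns (per-element {id: (dSW, d_pct_div)}, (mean_dSW, sd_dSW),
    (mean_ddiv, sd_ddiv)).  dSW = new - old; d_pct_div = old - new, so
    positive values mean the new library describes the element better.
    Standard deviations are sample (ddof=1) where n > 1.
    """
    al = _aligner()
    deltas: dict[str, tuple[float, float]] = {}
    for eid, seq in elements.items():
        old = assign_subfamily(eid, seq, old_library, al)
        new = assign_subfamily(eid, seq, new_library, al)
        deltas[eid] = (new.sw_score - old.sw_score, old.pct_div - new.pct_div)
    dsw = np.array([d[0] for d in deltas.values()], dtype=float)
    ddv = np.array([d[1] for d in deltas.values()], dtype=float)
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return deltas, (float(dsw.mean()), sd(dsw)), (float(ddv.mean()), sd(ddv))


@dataclass
class SubfamilyModel:
    name: str
    consensus: str
    diagnostics: list[tuple[int, str, str]]  # (1-based pos, ancestral, derived)
    member_ids: list[str]
    parent: str

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _project_onto_consensus(
    elements: dict[str, str], consensus: str
) -> dict[str, np.ndarray]:
    """Anchor-align each element to the consensus; per element, an array of
    element bases over consensus columns (gap where uncovered)."""
    al = _aligner()
    cons_len = len(consensus)
    out = {}
    for eid, seq in elements.items():
        aln = al.align(consensus, seq)[0]  # query = consensus
        cb, eb = aln.aligned
        col = np.full(cons_len, _GAP, dtype=np.uint8)
        earr = _seq.encode(seq)
        for (cs, ce), (es, ee) in zip(cb, eb):
            col[cs:ce] = earr[es : es + (ce - cs)]
        out[eid] = col
    return out


def discover_subfamilies(
    elements: dict[str, str],
    parent_consensus: str,
    parent_name: str = "parent",
    min_count: int = 10,
    min_diag: int = 2,
    cooccurrence_floor: float = 0.8,
) -> list[SubfamilyModel]:
    """Greedy co-segregating-diagnostic search for young subfamilies.

    Rounds continue until no diagnostic set with >= ``min_diag`` positions
    and >= ``min_count`` joint carriers remains; members are carriers of
    every selected diagnostic.  ``cooccurrence_floor`` keeps an added
    diagnostic from shrinking the carrier set below that fraction of the
    current one, so only genuinely co-segregating sites join a set.
    """
    if len(elements) < min_count:
        return []
    cons_arr = _seq.encode(parent_consensus)
    cols = _project_onto_consensus(elements, parent_consensus)
    # exact consensus matches carry no information about new subfamilies
    pool = {
        eid: col
        for eid, col in cols.items()
        if not (
            ((col == cons_arr) | (col == _GAP)).all() and (col != _GAP).any()
        )
    }
    models: list[SubfamilyModel] = []
    while len(pool) >= min_count:
        ids = sorted(pool)
        mat = np.stack([pool[e] for e in ids])  # elements x cons columns
        n = len(ids)
        carriers: dict[tuple[int, int], np.ndarray] = {}
        for pos in range(mat.shape[1]):
            colv = mat[:, pos]
            for b in range(4):
                if b == cons_arr[pos]:
                    continue
                mask = colv == b
                if int(mask.sum()) >= min_count:
                    carriers[(pos, b)] = mask
        cands = sorted(carriers)
        best_pair = None
        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                a, b = cands[i], cands[j]
                if a[0] == b[0]:
                    continue  # one diagnostic per column
                joint = carriers[a] & carriers[b]
                nj_ = int(joint.sum())
                if nj_ < min_count:
                    continue
                na, nb = int(carriers[a].sum()), int(carriers[b].sum())
                exp = na * nb / n
                # beyond the independence expectation, or perfectly
                # co-segregating (one carrier set contains the other)
                if nj_ <= exp and nj_ < min(na, nb):
                    continue
                key = (-nj_, a, b)
                if best_pair is None or key < best_pair[0]:
                    best_pair = (key, a, b, joint)
        if best_pair is None:
            break
        _, da, db, joint = best_pair
        selected = [da, db]
        current = joint
        improved = True
        while improved:
            improved = False
            best_ext = None
            for c in cands:
                if c in selected or any(c[0] == s[0] for s in selected):
                    continue
                inter = current & carriers[c]
                ni = int(inter.sum())
                if ni < min_count or ni < cooccurrence_floor * int(current.sum()):
                    continue
                key = (-ni, c)
                if best_ext is None or key < best_ext[0]:
                    best_ext = (key, c, inter)
            if best_ext is not None:
                _, c, inter = best_ext
                selected.append(c)
                current = inter
                improved = True
        member_ids = [ids[k] for k in np.nonzero(current)[0]]
        member_mat = mat[current]
        consensus = cons_arr.copy()
        for pos in range(mat.shape[1]):
            colv = member_mat[:, pos]
            colv = colv[colv != _GAP]
            if len(colv) == 0:
                continue
            counts = np.bincount(colv, minlength=4)
            top = int(counts.max())
            winners = [b for b in range(4) if counts[b] == top]
            if cons_arr[pos] in winners:
                consensus[pos] = cons_arr[pos]  # ties keep the parent base
            else:
                consensus[pos] = winners[0]
        diags = sorted(
            (pos + 1, _seq.decode(cons_arr[pos : pos + 1]),
             _seq.decode(np.array([b], dtype=np.uint8)))
            for pos, b in selected
        )
        models.append(
            SubfamilyModel(
                name="", consensus=_seq.decode(consensus),
                diagnostics=diags, member_ids=sorted(member_ids),
                parent=parent_name,
            )
        )
        for eid in member_ids:
            pool.pop(eid)
    models.sort(key=lambda m: (-m.size, m.member_ids[0] if m.member_ids else ""))
    for k, m in enumerate(models):
        m.name = f"sf{k}"
    return models


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    label: Optional[str] = None
    children: list[tuple["_Node", float]] = field(default_factory=list)
    support: Optional[float] = None

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset({self.label})
        out: set[str] = set()
        for c, _ in self.children:
            out |= c.leaves()
        return frozenset(out)


def neighbor_joining(dist: np.ndarray, labels: Sequence[str]) -> _Node:
    """Classic agglomerative NJ; negative branch lengths clamped to 0.

    Returns an unrooted tree represented with a trifurcating root.  On an
    additive distance matrix the generating topology is recovered exactly.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.asarray(dist, dtype=float).copy()
    nodes: list[_Node] = [_Node(label=l) for l in labels]
    active = list(range(n))
    edges: dict[int, float] = {}
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        i_, j_ = divmod(flat, m)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(0.0, li), max(0.0, lj)
        new = _Node(children=[(nodes[ai], li), (nodes[aj], lj)])
        nodes.append(new)
        D = np.pad(D, ((0, 1), (0, 1)))
        u = len(nodes) - 1
        for k_, ak in enumerate(active):
            if ak in (ai, aj):
                continue
            duk = 0.5 * (sub[i_, k_] + sub[j_, k_] - dij)
            D[u, ak] = D[ak, u] = duk
        active = [a for a in active if a not in (ai, aj)] + [u]
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = _Node(children=[
        (nodes[a], max(0.0, la)),
        (nodes[b], max(0.0, lb)),
        (nodes[c], max(0.0, lc)),
    ])
    return root


def tree_bipartitions(root: _Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each as the smaller-or-lexicographic side."""
    all_leaves = root.leaves()
    out: set[frozenset[str]] = set()

    def canon(s: frozenset[str]) -> frozenset[str]:
        other = all_leaves - s
        if len(s) < len(other):
            return s
        if len(other) < len(s):
            return other
        return min(s, other, key=lambda x: tuple(sorted(x)))

    def walk(node: _Node) -> None:
        for child, _ in node.children:
            lv = child.leaves()
            if 1 < len(lv) < len(all_leaves) - 1:
                out.add(canon(lv))
            walk(child)

    walk(root)
    return out


def newick_string(root: _Node, with_support: bool = False) -> str:
    def fmt(node: _Node) -> str:
        if not node.children:
            return node.label
        inner = ",".join(
            f"{fmt(c)}:{max(0.0, ln):.6g}" for c, ln in node.children
        )
        sup = ""
        if with_support and node.support is not None:
            sup = f"{node.support:g}"
        return f"({inner}){sup}"

    return fmt(root) + ";"


def _pairwise_pdist(cols: np.ndarray) -> np.ndarray:
    """p-distance matrix from an alignment matrix (taxa x columns, _GAP for
    missing); distances use columns where both taxa have a base."""
    n = cols.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cols[i], cols[j]
            ok = (a != _GAP) & (b != _GAP)
            if ok.any():
                D[i, j] = D[j, i] = float((a[ok] != b[ok]).mean())
    return D


def build_nj_tree(
    sequences: dict[str, str],
    bootstrap_n: int = 100,
    seed: int = 0,
) -> tuple[str, _Node]:
    """Anchor-aligned NJ tree with bootstrap supports.

    The longest input anchors a star alignment (each sequence pairwise
    aligned to it, columns projected onto anchor positions); distances are
    p-distances over shared columns.  Supports are the percentage of
    ``bootstrap_n`` column-resampled replicates containing each internal
    bipartition.  Deterministic given ``seed``.  Returns (newick, tree).
    """
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences")
    labels = sorted(sequences)
    anchor_label = max(labels, key=lambda l: (len(sequences[l]), l))
    anchor = sequences[anchor_label]
    proj = _project_onto_consensus(sequences, anchor)
    cols = np.stack([proj[l] for l in labels])
    D = _pairwise_pdist(cols)
    tree = neighbor_joining(D, labels)
    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset[str], int] = {}
        ncol = cols.shape[1]
        for _ in range(bootstrap_n):
            pick = rng.integers(0, ncol, ncol)
            bd = _pairwise_pdist(cols[:, pick])
            for bp in tree_bipartitions(neighbor_joining(bd, labels)):
                counts[bp] = counts.get(bp, 0) + 1
        all_leaves = tree.leaves()

        def annotate(node: _Node) -> None:
            for child, _ in node.children:
                lv = child.leaves()
                if 1 < len(lv) < len(all_leaves) - 1:
                    other = all_leaves - lv
                    key = lv if len(lv) < len(other) else (
                        other if len(other) < len(lv)
                        else min(lv, other, key=lambda x: tuple(sorted(x)))
                    )
                    child.support = 100.0 * counts.get(key, 0) / bootstrap_n
                annotate(child)

        annotate(tree)
    return newick_string(tree, with_support=True), tree
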