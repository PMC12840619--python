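"""Subfamily assignment and discovery, and neighbor-joining correctness.

NJ is checked two ways: against exhaustively generated additive matrices
from random trees (topology recovery is guaranteed on additive input) and
against scikit-bio's independent implementation on random noisy matrices.
"""

import numpy as np
import pytest

import dendropy

from sinetrace.annotation_io import ConsensusLibrary
from sinetrace.subfamily import (
    assign_subfamily,
    build_nj_tree,
    discover_subfamilies,
    neighbor_joining,
    newick_string,
    reassignment_delta,
    tree_bipartitions,
)
from sinetrace.synthetic_data import default_library, simulate_subfamily_cohort


@pytest.fixture(scope="module")
def library():
    return default_library()


@pytest.fixture(scope="module")
def parent(library):
    return library.sequence("Platy-syn-4a")


def _derived(parent, pos):
    """A base differing from the parent at 1-based pos."""
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[parent[pos - 1]]


# -- assignment ------------------------------------------------------------

def test_consensus_assigns_to_itself_with_zero_divergence(library):
    for name, _, seq in library.entries:
        r = assign_subfamily("e", seq, library)
        assert r.subfamily == name
        assert r.pct_div == 0.0


def test_five_substitutions_in_hundred_columns_is_five_percent():
    cons = "ACGT" * 25  # 100 bp
    mutated = list(cons)
    for i in (3, 23, 43, 63, 83):
        mutated[i] = _derived(cons, i + 1)
    lib = ConsensusLibrary(entries=[("c", "SINE/Platy", cons)])
    r = assign_subfamily("e", "".join(mutated), lib)
    assert r.pct_div == pytest.approx(5.0)
    assert r.alignment_length == 100


def test_assignment_is_order_stable_up_to_documented_tie_breaks(library):
    seq = library.sequence("Platy-syn-2a")
    reversed_lib = ConsensusLibrary(entries=list(reversed(library.entries)))
    a = assign_subfamily("e", seq, library)
    b = assign_subfamily("e", seq, reversed_lib)
    assert a.subfamily == b.subfamily == "Platy-syn-2a"
    assert (a.sw_score, a.pct_div) == (b.sw_score, b.pct_div)


def test_simulated_cohort_assigns_to_true_subfamily(library):
    rng = np.random.default_rng(5)
    ok = total = 0
    for name in ("Platy-syn-4a", "Platy-syn-2a", "Platy-syn-5"):
        cons = library.sequence(name)
        for _ in range(40):
            copy = list(cons)
            for i in range(len(copy)):
                if rng.random() < 0.04:  # <= 5% divergence
                    copy[i] = _derived("".join(copy), i + 1)
            r = assign_subfamily("e", "".join(copy), library)
            total += 1
            ok += r.subfamily == name
    assert ok / total >= 0.95


def test_empty_inputs_error(library):
    with pytest.raises(ValueError):
        assign_subfamily("e", "", library)
    with pytest.raises(ValueError):
        assign_subfamily("e", "ACGT", ConsensusLibrary(entries=[]))


# -- reassignment deltas ---------------------------------------------------

def test_identical_libraries_give_zero_deltas(library):
    elements = {"a": library.sequence("Platy-syn-4a")[5:],
                "b": library.sequence("Platy-syn-5")}
    deltas, (msw, _), (mdv, _) = reassignment_delta(elements, library, library)
    assert all(d == (0, 0.0) for d in deltas.values())
    assert msw == 0 and mdv == 0


def test_daughter_cohort_improves_under_augmented_library(library, parent):
    diags = [(20, _derived(parent, 20)), (61, _derived(parent, 61))]
    seqs, _truth = simulate_subfamily_cohort(
        parent, [("d0", 25, diags)], n_parent_like=0,
        background_divergence=0.03, seed=3,
    )
    models = discover_subfamilies(seqs, parent, parent_name="Platy-syn-4a")
    assert models
    new_lib = ConsensusLibrary(
        entries=list(library.entries)
        + [(m.name, "SINE/Platy", m.consensus) for m in models]
    )
    deltas, (msw, _), (mdv, _) = reassignment_delta(seqs, library, new_lib)
    assert mdv > 0  # divergence improves under the right consensus
    assert msw >= 0


# -- discovery -------------------------------------------------------------

def test_two_planted_daughters_recovered_and_named_by_size(parent):
    d0 = [(20, _derived(parent, 20)), (61, _derived(parent, 61))]
    d1 = [(33, _derived(parent, 33)), (80, _derived(parent, 80)),
          (90, _derived(parent, 90))]
    seqs, truth = simulate_subfamily_cohort(
        parent, [("big", 30, d0), ("small", 15, d1)],
        n_parent_like=20, background_divergence=0.03, seed=11,
    )
    models = discover_subfamilies(seqs, parent, parent_name="p")
    assert [m.name for m in models] == ["sf0", "sf1"]
    assert models[0].size >= models[1].size
    for m, truth_name in zip(models, ("big", "small")):
        want = {e for e, v in truth.items() if v == truth_name}
        got = set(m.member_ids)
        tp = len(got & want)
        assert tp / len(got) >= 0.9   # precision
        assert tp / len(want) >= 0.9  # recall
    assert {(p, d) for p, _a, d in models[0].diagnostics} == set(d0)
    # members' diagnostics are present in the new consensus
    for m in models:
        for pos, _anc, der in m.diagnostics:
            assert m.consensus[pos - 1] == der


def test_exact_parent_matches_yield_nothing(parent):
    seqs = {f"e{i}": parent for i in range(40)}
    assert discover_subfamilies(seqs, parent) == []


def test_too_few_elements_is_empty_not_error(parent):
    seqs = {"e1": parent[3:], "e2": parent[5:]}
    assert discover_subfamilies(seqs, parent, min_count=10) == []


# -- neighbor joining ------------------------------------------------------

def test_three_taxa_closed_form():
    D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
    root = neighbor_joining(D, ["a", "b", "c"])
    lengths = {c.label: ln for c, ln in root.children}
    assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
    assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
    assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)


def _random_additive(rng, n):
    taxa = [f"t{i}" for i in range(n)]

    def rand(labels):
        if len(labels) == 1:
            return labels[0]
        k = int(rng.integers(1, len(labels)))
        ls = list(labels)
        rng.shuffle(ls)
        return (
            f"({rand(ls[:k])}:{rng.uniform(0.1, 2):.4f},"
            f"{rand(ls[k:])}:{rng.uniform(0.1, 2):.4f})"
        )

    newick = rand(taxa) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    D = np.array([[pdm.distance(tx[a], tx[b]) for b in taxa] for a in taxa])
    leafset = frozenset(taxa)
    want = set()
    for node in tree.preorder_node_iter():
        lv = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(lv) < n - 1:
            other = leafset - lv
            key = lv if len(lv) < len(other) else (
                other if len(other) < len(lv)
                else min(lv, other, key=lambda s: tuple(sorted(s)))
            )
            want.add(key)
    return D, taxa, want


def test_nj_recovers_topology_from_additive_matrices():
    rng = np.random.default_rng(0)
    for _ in range(40):
        n = int(rng.integers(4, 9))
        D, taxa, want = _random_additive(rng, n)
        got = tree_bipartitions(neighbor_joining(D, taxa))
        assert got == want


def test_nj_agrees_with_scikit_bio_on_noisy_matrices():
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(1)
    for _ in range(10):
        n = int(rng.integers(4, 8))
        D, taxa, _ = _random_additive(rng, n)
        noise = rng.uniform(0, 0.05, D.shape)
        D = D + noise + noise.T
        D = (D + D.T) / 2.0  # exact float symmetry
        np.fill_diagonal(D, 0.0)
        ours = tree_bipartitions(neighbor_joining(D, taxa))
        sk_tree = skbio_nj(DistanceMatrix(D, ids=taxa))
        leafset = frozenset(taxa)
        theirs = set()
        for node in sk_tree.non_tips(include_self=False):
            lv = frozenset(t.name for t in node.tips())
            if 1 < len(lv) < n - 1:
                other = leafset - lv
                key = lv if len(lv) < len(other) else (
                    other if len(other) < len(lv)
                    else min(lv, other, key=lambda s: tuple(sorted(s)))
                )
                theirs.add(key)
        assert ours == theirs


def _perfect_phylogeny_sequences(newick, per_branch=25, base_len=1500, seed=0):
    """Sequences whose substitutions map 1:1 onto tree branches: distances
    are exactly additive and every branch owns many alignment columns.

    The shared backbone keeps overall divergence low (a few percent) so the
    anchor alignment is trivially correct and bootstrap resampling acts on
    clean columns."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)
    taxa = [l.taxon.label for l in tree.leaf_node_iter()]
    rng = np.random.default_rng(seed)
    branches = [
        frozenset(l.taxon.label for l in node.leaf_iter())
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    ]
    length = base_len + per_branch * len(branches)
    base = rng.integers(0, 4, length)
    seqs = {t: base.copy() for t in taxa}
    # scatter signal columns uniformly so no region is mismatch-dense and
    # the anchor alignment covers every column
    signal_cols = rng.permutation(length)[: per_branch * len(branches)]
    k = 0
    for members in branches:
        for _ in range(per_branch):
            col = signal_cols[k]
            k += 1
            for t in members:
                seqs[t][col] = (seqs[t][col] + 1) % 4
    return {t: "".join("ACGT"[b] for b in s) for t, s in seqs.items()}


def test_bootstrap_supports_are_full_on_noise_free_signal():
    newick = "((a:1,b:1):1,((c:1,d:1):1,e:1):1);"
    seqs = _perfect_phylogeny_sequences(newick)
    out_newick, tree = build_nj_tree(seqs, bootstrap_n=100, seed=4)
    bps = tree_bipartitions(tree)
    assert frozenset({"a", "b"}) in bps
    assert frozenset({"c", "d"}) in bps

    def supports(node, acc):
        for child, _ in node.children:
            if child.support is not None:
                acc.append(child.support)
            supports(child, acc)
        return acc

    assert all(s == 100.0 for s in supports(tree, []))
    assert out_newick.endswith(";") and "100" in out_newick


def test_build_nj_tree_is_deterministic_and_needs_three():
    seqs = _perfect_phylogeny_sequences("((a:1,b:1):1,(c:1,d:1):1);", seed=2)
    n1, _ = build_nj_tree(seqs, bootstrap_n=25, seed=9)
    n2, _ = build_nj_tree(seqs, bootstrap_n=25, seed=9)
    assert n1 == n2
    with pytest.raises(ValueError):
        build_nj_tree({"a": "ACGT", "b": "ACGT"})


def test_newick_round_trips_through_dendropy():
    seqs = _perfect_phylogeny_sequences("((a:1,b:1):1,(c:1,d:1):1);", seed=3)
    newick, _ = build_nj_tree(seqs, bootstrap_n=10, seed=1)
    t = dendropy.Tree.get(data=newick, schema="newick")
    assert {l.taxon.label for l in t.leaf_node_iter()} == set("abcd")
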