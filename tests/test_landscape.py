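"""Landscape statistics against brute-force oracles, plus histogram
conservation and nested-call structure.

The oracles are deliberately naive (all-pairs distances, per-base coverage
painting, exhaustive containment) and were written before the efficient
implementations; they remain the reference the implementations must match.
"""

import numpy as np
import pytest

from sinetrace.annotation_io import RepeatAnnotation
from sinetrace.landscape import (
    detect_nested,
    divergence_histogram,
    genome_repeat_content,
    interval_distance,
    nested_by_age,
    proximity_within,
)

from conftest import truth_by_coords

CLASSES = ["SINE/Platy", "SINE/Alu", "LINE/L1", "LTR/ERV", "DNA/hAT"]


def _ann(qb, qe, rclass="SINE/Alu", contig="chr1", run_id=None, name=None,
         cb=1, ce=100, div=5.0):
    return RepeatAnnotation(
        sw_score=100, pct_div=div, pct_del=0.0, pct_ins=0.0,
        query_name=contig, query_begin=qb, query_end=qe, strand="+",
        repeat_name=name or rclass.split("/")[1], repeat_class=rclass,
        cons_begin=cb, cons_end=ce, cons_left=0,
        run_id=run_id if run_id is not None else qb,
    )


def _random_instance(rng, n=60, contig_len=50_000):
    anns = []
    for _ in range(n):
        b = int(rng.integers(1, contig_len - 400))
        e = b + int(rng.integers(50, 400))
        anns.append(_ann(b, e, rclass=CLASSES[rng.integers(0, len(CLASSES))],
                         div=float(rng.integers(0, 300)) / 10))
    return anns


# -- oracles ---------------------------------------------------------------

def oracle_proximity(focal, anns, D):
    counts = {c: 0 for c in sorted({a.repeat_class for a in anns})}
    for f in focal:
        near = set()
        for a in anns:
            if a is f or a.query_name != f.query_name:
                continue
            d = max(0, max(a.query_begin - f.query_end,
                           f.query_begin - a.query_end) - 1)
            if d <= D:
                near.add(a.repeat_class)
        for c in near:
            counts[c] += 1
    return counts


def oracle_content(anns, sizes):
    out = {}
    for cls in {a.repeat_class for a in anns}:
        covered = 0
        for contig, n in sizes.items():
            mask = np.zeros(n + 1, dtype=bool)
            for a in anns:
                if a.repeat_class == cls and a.query_name == contig:
                    mask[a.query_begin : a.query_end + 1] = True
            covered += int(mask.sum())
        out[cls] = 100.0 * covered / sum(sizes.values())
    return out


def oracle_nested_containment(anns, focal_class="SINE/Platy"):
    inner = []
    for a in anns:
        if a.repeat_class != focal_class:
            continue
        for h in anns:
            if (
                h is not a
                and h.repeat_class != focal_class
                and h.query_name == a.query_name
                and h.query_begin < a.query_begin
                and a.query_end < h.query_end
            ):
                inner.append(a)
                break
    return inner


# -- proximity -------------------------------------------------------------

def test_interval_distance_convention():
    assert interval_distance((1000, 1100), (1140, 1440)) == 39
    assert interval_distance((1140, 1440), (1000, 1100)) == 39
    assert interval_distance((1000, 1100), (1151, 1400)) == 50
    assert interval_distance((1000, 1100), (1152, 1400)) == 51
    assert interval_distance((1000, 1100), (1050, 1200)) == 0  # overlap
    assert interval_distance((1000, 1100), (1101, 1200)) == 0  # adjacency


def test_proximity_boundary_counting():
    f = _ann(1000, 1100, rclass="SINE/Platy")
    at_50 = _ann(1151, 1400)
    at_51 = _ann(1152, 1400)
    r50 = proximity_within([f], [f, at_50], 50)
    r51 = proximity_within([f], [f, at_51], 50)
    assert r50.counts["SINE/Alu"] == 1
    assert r51.counts["SINE/Alu"] == 0


def test_single_element_has_no_neighbors():
    f = _ann(1000, 1100, rclass="SINE/Platy")
    rep = proximity_within([f], [f], 50)
    assert all(v == 0 for v in rep.counts.values())
    assert all(v == 0.0 for v in rep.percentages.values())


@pytest.mark.parametrize("seed", range(6))
def test_proximity_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    anns = _random_instance(rng)
    focal = [a for a in anns if a.repeat_class == "SINE/Platy"]
    got = proximity_within(focal, anns, 50)
    assert got.counts == oracle_proximity(focal, anns, 50)


# -- content ---------------------------------------------------------------

def test_content_merges_same_class_overlaps():
    sizes = {"chr1": 1_000_000}
    anns = [_ann(1, 250_000), _ann(1, 250_000)]  # identical: counted once
    got = genome_repeat_content(anns, sizes)
    assert got["SINE/Alu"] == pytest.approx(25.0)
    assert genome_repeat_content([], sizes) == {}


@pytest.mark.parametrize("seed", range(6))
def test_content_matches_base_counting_oracle(seed):
    rng = np.random.default_rng(seed + 100)
    anns = _random_instance(rng)
    sizes = {"chr1": 50_000}
    got = genome_repeat_content(anns, sizes)
    want = oracle_content(anns, sizes)
    assert got.keys() == want.keys()
    for k in got:
        assert got[k] == pytest.approx(want[k], abs=1e-9)


# -- divergence histogram --------------------------------------------------

def test_histogram_bins_and_conservation():
    anns = [_ann(1, 100, div=0.0), _ann(200, 399, div=1.0),
            _ann(500, 599, div=0.9)]
    h = divergence_histogram(anns, bin_width=1.0)
    bins = dict(zip(h["bin"], h["weight"]))
    assert bins[0.0] == 100 + 100  # div 0.0 and 0.9 share the [0,1) bin
    assert bins[1.0] == 200
    assert h["weight"].sum() == sum(a.query_length for a in anns)
    counts = divergence_histogram(anns, weight="count")
    assert counts["weight"].sum() == len(anns)


def test_histogram_mode_tracks_cohort_age():
    """A cohort of copies all of age t peaks within one bin of the
    Jukes-Cantor expected divergence for mu*t."""
    from sinetrace._seq import (
        encode,
        jc_substitution_probability,
        mutate,
        p_distance,
    )

    rng = np.random.default_rng(42)
    cons = encode("".join("ACGT"[i] for i in rng.integers(0, 4, 300)))
    mu_t = 0.06
    p = jc_substitution_probability(mu_t)
    anns = []
    for k in range(400):
        copy = mutate(cons, p, rng)
        div = round(100.0 * p_distance(copy, cons), 1)
        anns.append(_ann(1 + 400 * k, 300 + 400 * k, rclass="SINE/Platy",
                         div=div))
    h = divergence_histogram(anns, bin_width=1.0)
    mode_bin = h.loc[h["weight"].idxmax(), "bin"]
    assert abs(mode_bin - 100 * p // 1.0) <= 1.0


# -- nested ----------------------------------------------------------------

def test_run_id_adjacency_detects_planted_nesting(clade_mu0):
    tbc = truth_by_coords(clade_mu0)
    checked = 0
    for sp in clade_mu0.genomes:
        calls = {
            (c.inner.query_begin, c.inner.query_end): c
            for c in detect_nested(clade_mu0.annotations[sp])
        }
        for (s, contig, b, e), p in tbc.items():
            if s != sp or not p.nested_host:
                continue
            assert (b, e) in calls
            c = calls[(b, e)]
            assert c.host_class == p.nested_host
            assert c.evidence == "run_id_adjacency"
            up, down = c.host_fragments
            assert c.host_cons_position == up.cons_end
            checked += 1
    assert checked >= 3


def test_unrelated_neighbors_are_not_nesting():
    focal = _ann(1200, 1300, rclass="SINE/Platy")
    left = _ann(1000, 1199, run_id=1)
    right = _ann(1301, 1500, run_id=2)  # different run: no nesting
    assert detect_nested([left, focal, right]) == []


def test_containment_fallback():
    focal = _ann(1200, 1300, rclass="SINE/Platy")
    host = _ann(1000, 1500, rclass="LINE/L1", cb=501, ce=1100)
    (call,) = detect_nested([host, focal])
    assert call.evidence == "containment"
    assert call.host_class == "LINE/L1"
    assert call.host_cons_position == 501 + (1200 - 1000) - 1


@pytest.mark.parametrize("seed", range(4))
def test_nested_containment_matches_oracle(seed):
    """On host-split-free instances the detector equals exhaustive
    containment."""
    rng = np.random.default_rng(seed + 500)
    anns = []
    pos = 1000
    for _ in range(30):
        hb, he = pos, pos + int(rng.integers(300, 900))
        anns.append(_ann(hb, he, rclass="LINE/L1", cb=1, ce=he - hb + 1))
        if rng.random() < 0.5:  # drop a focal element inside
            fb = hb + int(rng.integers(50, (he - hb) // 2))
            anns.append(_ann(fb, fb + 100, rclass="SINE/Platy"))
        if rng.random() < 0.3:  # and some outside
            anns.append(_ann(he + 20, he + 120, rclass="SINE/Platy"))
        pos = he + int(rng.integers(200, 600))
    got = {(c.inner.query_begin, c.inner.query_end)
           for c in detect_nested(anns)}
    want = {(a.query_begin, a.query_end)
            for a in oracle_nested_containment(anns)}
    assert got == want


# -- crosstab --------------------------------------------------------------

def test_nested_by_age_crosstab_sums():
    from sinetrace.landscape import NestedCall

    cats = {"l1": "FP", "l2": "FP", "l3": "LS", "l4": "Poly"}
    inner = _ann(10, 100, rclass="SINE/Platy")
    nested = {
        "l1": NestedCall(inner, "SINE/Alu", "Alu", "containment", (None, None), 1),
        "l3": NestedCall(inner, "LINE/L1", "L1", "containment", (None, None), 1),
    }
    tab, frac = nested_by_age(nested, cats)
    assert frac == pytest.approx(0.5)
    assert tab.loc["SINE/Alu", "FP"] == 1
    assert tab.loc["LINE/L1", "LS"] == 1
    assert tab.values.sum() == len(nested)
    empty_tab, empty_frac = nested_by_age({}, cats)
    assert empty_frac == 0.0 and empty_tab.empty
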