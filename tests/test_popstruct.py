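"""Coincidence matching, sharing, distances, UPGMA, bootstrap, rate."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from svlineage.popstruct import (
    ClusterTree,
    PresenceMatrix,
    approximately_unbiased,
    bootstrap_support,
    cluster,
    estimate_rate,
    match_svs,
    presence_from_truth,
    sharing_stats,
    sv_distance,
)
from svlineage.simulate import LineTree, simulate_truth_table
from svlineage.svcall import SVRecord

from oracles import match_partition_oracle


def _sv(line, chrom, start, end, sv_type="deletion", size=None):
    size = size if size is not None else max(end - start, 100)
    return SVRecord(line, chrom, start, end, size, sv_type)


# ---------------------------------------------------------------------------
# match_svs
# ---------------------------------------------------------------------------


def _library_partition(svs_by_line, tol):
    """Recover match_svs's partition over flat record indices via provenance
    object identity."""
    flat = []
    for line in sorted(svs_by_line):
        for r in svs_by_line[line]:
            flat.append((line, r))
    index_of = {id(r): i for i, (_, r) in enumerate(flat)}
    matrix = match_svs(svs_by_line, tol=tol)
    return {
        frozenset(index_of[id(r)] for rs in prov.values() for r in rs)
        for prov in matrix.provenance
    }, flat


def _random_records(rng, n, lines=("A", "B", "C"), chroms=("chr1", "chr2"),
                    types=("insertion", "deletion", "tandem_expansion")):
    by_line = {l: [] for l in lines}
    for _ in range(n):
        line = lines[rng.integers(len(lines))]
        sv_type = types[rng.integers(len(types))]
        start = int(rng.integers(0, 3000))
        if sv_type == "insertion":
            end = start
        else:
            end = start + int(rng.integers(50, 200))
        by_line[line].append(
            SVRecord(line, chroms[rng.integers(len(chroms))], start, end,
                     max(end - start, 60), sv_type)
        )
    return by_line


def test_match_svs_equals_pairwise_oracle():
    rng = np.random.default_rng(21)
    for trial in range(5):
        by_line = _random_records(rng, 200)
        got, flat = _library_partition(by_line, tol=3)
        want = match_partition_oracle(flat, tol=3)
        assert got == want


def test_match_svs_tolerance_three_merges_four_splits():
    a = {"A": [_sv("A", "chr1", 1000, 1500)], "B": [_sv("B", "chr1", 1003, 1503)]}
    m = match_svs(a, tol=3)
    assert m.n_loci == 1 and m.cells.tolist() == [[1, 1]]
    b = {"A": [_sv("A", "chr1", 1000, 1500)], "B": [_sv("B", "chr1", 1004, 1504)]}
    m2 = match_svs(b, tol=3)
    assert m2.n_loci == 2


def test_match_svs_requires_same_type_and_chrom():
    a = {
        "A": [_sv("A", "chr1", 1000, 1500, "deletion")],
        "B": [_sv("B", "chr1", 1000, 1500, "tandem_contraction"),
              _sv("B", "chr2", 1000, 1500, "deletion")],
    }
    m = match_svs(a, tol=3)
    assert m.n_loci == 3


def test_match_svs_single_linkage_chain():
    # A@1000, B@1003, C@1006: A-B and B-C coincide, A-C alone would not
    a = {
        "A": [_sv("A", "chr1", 1000, 1500)],
        "B": [_sv("B", "chr1", 1003, 1503)],
        "C": [_sv("C", "chr1", 1006, 1506)],
    }
    m = match_svs(a, tol=3)
    assert m.n_loci == 1
    assert m.loci[0] == ("chr1", 1000, 1506, "deletion")


def test_match_svs_locus_key_min_start_max_end():
    a = {"A": [_sv("A", "chr1", 1002, 1498)], "B": [_sv("B", "chr1", 1000, 1500)]}
    m = match_svs(a, tol=3)
    assert m.loci[0] == ("chr1", 1000, 1500, "deletion")


def test_presence_matrix_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(22)
    m = match_svs(_random_records(rng, 80), tol=3)
    p = tmp_path / "m.tsv"
    m.to_tsv(p)
    back = PresenceMatrix.from_tsv(p)
    assert back.lines == m.lines
    assert back.loci == m.loci
    assert np.array_equal(back.cells, m.cells)


# ---------------------------------------------------------------------------
# sharing stats
# ---------------------------------------------------------------------------


def test_sharing_stats_counts():
    cells = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 1, 1]], dtype=np.int8)
    loci = [("chr1", i, i + 100, "deletion") for i in range(4)]
    m = PresenceMatrix(loci=loci, lines=["A", "B", "C"], cells=cells)
    s = sharing_stats(m)
    assert s.shared_in_all == 1
    assert s.per_line_counts == {"A": 3, "B": 3, "C": 2}
    # A shares 2 of its 3 loci with B
    assert s.pairwise_percent.loc["A", "B"] == pytest.approx(100 * 2 / 3)
    assert s.pairwise_percent.loc["C", "A"] == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def test_jaccard_identical_and_disjoint_closed_form():
    cells = np.array([[1, 1, 0], [0, 0, 1], [1, 1, 0]], dtype=np.int8)
    m = PresenceMatrix(loci=[("c", i, i + 1, "deletion") for i in range(3)],
                       lines=["A", "B", "C"], cells=cells)
    d = sv_distance(m)
    assert d.loc["A", "B"] == pytest.approx(0.0)   # identical columns
    assert d.loc["A", "C"] == pytest.approx(1.0)   # disjoint columns
    assert (np.diag(d.to_numpy()) == 0).all()


@given(st.integers(0, 10_000))
def test_jaccard_metric_properties(seed):
    rng = np.random.default_rng(seed)
    cells = rng.integers(0, 2, (12, 4)).astype(np.int8)
    cells[cells.sum(axis=1) == 0, 0] = 1  # every locus in >= 1 line
    m = PresenceMatrix(loci=[("c", i, i + 1, "deletion") for i in range(12)],
                       lines=list("ABCD"), cells=cells)
    D = sv_distance(m).to_numpy()
    assert np.allclose(D, D.T)
    assert (D >= 0).all() and (D <= 1).all()
    assert (np.diag(D) == 0).all()


# ---------------------------------------------------------------------------
# UPGMA (cross-checked against scipy average linkage)
# ---------------------------------------------------------------------------


def _scipy_clades(D, names):
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    Z = average(squareform(D, checks=False))
    n = len(names)
    members = {i: frozenset([names[i]]) for i in range(n)}
    clades = []
    for k, (a, b, *_rest) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        clades.append(merged)
    return set(clades)


def test_upgma_matches_scipy_on_random_matrices():
    rng = np.random.default_rng(23)
    names = list("ABCDEF")
    for _ in range(20):
        # continuous iid entries: ties (also between linkage *averages*,
        # which evenly spaced values can produce) have probability zero
        vals = 0.1 + 0.9 * rng.random(15)
        D = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        D[iu] = vals
        D += D.T
        tree = cluster(pd.DataFrame(D, index=names, columns=names))
        assert set(tree.clades()) == {
            frozenset(c) for c in _scipy_clades(D, names)
        }


def test_upgma_ultrametric_heights_exact():
    # perfect ultrametric: cophenetic distances reproduce the input
    names = ["A", "B", "C", "D"]
    D = pd.DataFrame(
        [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]],
        index=names, columns=names, dtype=float,
    )
    tree = cluster(D)
    heights = {frozenset(a | b): h for a, b, h in tree.merges}
    assert heights[frozenset({"A", "B"})] == pytest.approx(1.0)
    assert heights[frozenset({"C", "D"})] == pytest.approx(2.0)
    assert heights[frozenset(names)] == pytest.approx(4.0)


def test_upgma_deterministic_tie_break():
    names = ["A", "B", "C"]
    D = pd.DataFrame(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
                     index=names, columns=names)
    t1 = cluster(D)
    t2 = cluster(D)
    assert t1.to_newick() == t2.to_newick()
    # lexicographically smallest pair merged first
    assert t1.merges[0][0] | t1.merges[0][1] == frozenset({"A", "B"})


def test_cluster_rejects_asymmetric():
    D = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["A", "B"], columns=["A", "B"])
    with pytest.raises(ValueError):
        cluster(D)


def test_newick_contains_all_leaves_and_supports():
    names = ["A", "B", "C"]
    D = pd.DataFrame(np.array([[0, 0.2, 0.8], [0.2, 0, 0.8], [0.8, 0.8, 0]]),
                     index=names, columns=names)
    tree = cluster(D)
    tree.supports = {frozenset({"A", "B"}): (97.0, 99.0),
                     frozenset(names): (100.0, 100.0)}
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    for n in names:
        assert n in nwk
    assert "[99.0/97.0]" in nwk  # AU/BP order


# ---------------------------------------------------------------------------
# bootstrap + AU
# ---------------------------------------------------------------------------


def test_bootstrap_clean_signal_full_support():
    truth = simulate_truth_table(LineTree.default(), rate_per_branch=40.0, seed=3)
    matrix = presence_from_truth(truth)
    tree = bootstrap_support(matrix, B=200, seed=0)
    planted = {
        frozenset({"B10", "I03"}),
        frozenset({"N15", "T29"}),
        frozenset({"N15", "T29", "ZH26"}),
    }
    assert planted <= set(tree.clades())
    for clade in planted:
        bp, au = tree.supports[clade]
        assert bp >= 95.0
        assert au >= 95.0


def test_bootstrap_rejects_small_B():
    truth = simulate_truth_table(LineTree.default(), rate_per_branch=10.0, seed=1)
    with pytest.raises(ValueError):
        bootstrap_support(presence_from_truth(truth), B=50)


def test_bootstrap_requires_scale_one():
    truth = simulate_truth_table(LineTree.default(), rate_per_branch=10.0, seed=1)
    with pytest.raises(ValueError):
        bootstrap_support(presence_from_truth(truth), B=100, scales=[0.5, 0.7])


def test_au_closed_form_half():
    scales = np.array([round(0.5 + 0.1 * t, 1) for t in range(10)])
    assert approximately_unbiased(scales, np.full(10, 0.5), 1000) == pytest.approx(50.0)


def test_au_saturated_profile_falls_back_to_bp():
    scales = np.array([round(0.5 + 0.1 * t, 1) for t in range(10)])
    bp = np.array([0.97, 0.99] + [1.0] * 8)
    assert approximately_unbiased(scales, bp, 1000) == pytest.approx(100.0)
    assert approximately_unbiased(scales, np.zeros(10), 1000) == pytest.approx(0.0)


def test_au_monotone_profile_direction():
    scales = np.array([round(0.5 + 0.1 * t, 1) for t in range(10)])
    rising = np.linspace(0.62, 0.89, 10)   # BP grows with scale: true clade
    falling = rising[::-1].copy()
    assert approximately_unbiased(scales, rising, 1000) > 90
    assert approximately_unbiased(scales, falling, 1000) < 10


# ---------------------------------------------------------------------------
# rate + truth presence
# ---------------------------------------------------------------------------


def test_estimate_rate_closed_form():
    assert estimate_rate(100, 1, 1).rate == pytest.approx(50.0)
    assert estimate_rate(2928, 1.0, 120.0).rate == pytest.approx(12.2)


def test_estimate_rate_rejects_nonpositive():
    with pytest.raises(ValueError):
        estimate_rate(0, 1, 1)
    with pytest.raises(ValueError):
        estimate_rate(10, 0, 1)


def test_presence_from_truth_carriers():
    tree = LineTree.default()
    truth = simulate_truth_table(tree, rate_per_branch=10.0, seed=9)
    m = presence_from_truth(truth)
    assert m.lines == tree.leaves()
    assert m.n_loci == len(truth.records)
    by_key = {}
    for r in truth.records:
        by_key[(r.chrom, r.ref_start, r.ref_end, r.sv_type)] = r.carrier_lines
    for locus, row in zip(m.loci, m.cells):
        carriers = {m.lines[i] for i in np.flatnonzero(row)}
        assert carriers == by_key[locus]
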