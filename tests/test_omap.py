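"""Optical maps: digestion, both aligners, SV detection, cross-validation, I/O."""
from __future__ import annotations

import numpy as np
import pytest

from svlineage.omap import (
    LabelMap,
    MapAlignment,
    align_map,
    align_map_sv,
    cross_validate,
    detect_map_svs,
    digest_reference,
    digest_sequence,
    read_cmap,
    read_label_maps,
    suppress_reflection_artifacts,
    write_label_maps,
)
from svlineage.simulate import Genome, random_sequence, revcomp
from svlineage.svcall import SVRecord

from oracles import align_map_oracle, score_pairs


def _map(labels, length=None, map_id="m", chrom="chr1"):
    labels = np.asarray(labels, dtype=np.int64)
    if length is None:
        length = int(labels[-1]) + 1000 if len(labels) else 1000
    return LabelMap(map_id=map_id, length_bp=length, labels=labels, chrom=chrom,
                    line_id="L")


def _random_labels(rng, n, lo=1200, hi=2800):
    """Aperiodic label positions (uniform spacing would let SVs that are a
    multiple of the spacing phase-realign invisibly)."""
    return np.cumsum(rng.integers(lo, hi, n)).astype(np.int64)


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------


def _digest_oracle(seq, motif):
    rc = revcomp(motif)
    hits = set()
    for i in range(len(seq) - len(motif) + 1):
        w = seq[i : i + len(motif)]
        if w == motif or w == rc:
            hits.add(i)
    return sorted(hits)


def test_digest_matches_naive_scan():
    rng = np.random.default_rng(0)
    seq = random_sequence(50_000, rng)
    got = digest_sequence(seq, "CACGAG")
    assert list(got) == _digest_oracle(seq, "CACGAG")


def test_digest_both_strands_and_overlaps():
    seq = "AAACACGAGAAACTCGTGAAA"  # CACGAG at 3, its revcomp CTCGTG at 12
    assert list(digest_sequence(seq, "CACGAG")) == [3, 12]
    # overlapping occurrences are all reported (ATATAT is its own revcomp)
    assert list(digest_sequence("ATATATAT", "ATATAT")) == [0, 2]


def test_digest_reference_per_chromosome():
    rng = np.random.default_rng(1)
    g = Genome(id="r", sequences={"chr1": random_sequence(30_000, rng),
                                  "chr2": random_sequence(30_000, rng)})
    maps = digest_reference(g, "CACGAG")
    assert set(maps) == {"chr1", "chr2"}
    for chrom, m in maps.items():
        assert m.length_bp == 30_000
        assert list(m.labels) == _digest_oracle(g.sequences[chrom], "CACGAG")


def test_label_map_validation():
    with pytest.raises(ValueError):
        LabelMap("m", 1000, np.array([10, 10]))
    with pytest.raises(ValueError):
        LabelMap("m", 1000, np.array([10, 2000]))


# ---------------------------------------------------------------------------
# align_map (spec objective) against the exhaustive-DP oracle
# ---------------------------------------------------------------------------


def test_align_map_identical_maps_score_zero():
    rng = np.random.default_rng(2)
    labels = _random_labels(rng, 10)
    a = align_map(_map(labels), _map(labels))
    assert a.score == pytest.approx(0.0)
    assert a.pairs == [(i, i) for i in range(10)]


def test_align_map_matches_oracle_on_small_maps():
    rng = np.random.default_rng(3)
    for _ in range(60):
        nr = int(rng.integers(2, 13))
        nq = int(rng.integers(2, 13))
        r = _random_labels(rng, nr)
        q = _random_labels(rng, nq)
        want = align_map_oracle(q, r)
        if want == float("-inf"):
            with pytest.raises(ValueError):
                align_map(_map(q), _map(r))
            continue
        got = align_map(_map(q), _map(r))
        assert got.score == pytest.approx(want, abs=1e-9)
        assert score_pairs(got.pairs, q, r) == pytest.approx(got.score, abs=1e-9)


def test_align_map_requires_two_labels():
    with pytest.raises(ValueError):
        align_map(_map([100]), _map([100, 2000]))


# ---------------------------------------------------------------------------
# align_map_sv behavior
# ---------------------------------------------------------------------------


def test_sv_aligner_identical_maps_all_matched():
    rng = np.random.default_rng(4)
    labels = _random_labels(rng, 40)
    a = align_map_sv(_map(labels), _map(labels))
    assert a.pairs == [(i, i) for i in range(40)]


def _delete(labels, s, size):
    """Apply a deletion of [s, s+size) on the coordinate axis."""
    keep = labels[(labels < s) | (labels >= s + size)]
    return np.where(keep >= s + size, keep - size, keep)


def test_sv_aligner_single_deletion_one_jump():
    rng = np.random.default_rng(5)
    ref = _random_labels(rng, 60)
    q = _delete(ref, int(ref[25]) + 500, 5000)
    aln = align_map_sv(_map(q), _map(ref))
    calls = detect_map_svs(aln, _map(q), _map(ref), "L")
    assert len(calls) == 1
    c = calls[0]
    assert c.sv_type == "deletion" and c.size_bp == 5000


def test_sv_aligner_single_insertion():
    rng = np.random.default_rng(6)
    ref = _random_labels(rng, 60)
    pos = int(ref[30]) + 700
    q = np.where(ref >= pos, ref + 4200, ref)
    aln = align_map_sv(_map(q), _map(ref))
    calls = detect_map_svs(aln, _map(q), _map(ref), "L")
    assert len(calls) == 1
    assert calls[0].sv_type == "insertion" and calls[0].size_bp == 4200


def test_sv_aligner_reports_opposite_sign_pair_separately():
    """An insertion and a nearby deletion must not collapse into their net."""
    rng = np.random.default_rng(7)
    ref = _random_labels(rng, 80)
    ins_at = int(ref[30]) + 500   # insertion point
    del_at = int(ref[36]) + 500   # deletion ~6 labels downstream
    q = ref[(ref < del_at) | (ref >= del_at + 8000)]
    q = np.where(q >= del_at + 8000, q - 8000, q)
    q = np.where(q >= ins_at, q + 8700, q)
    aln = align_map_sv(_map(q), _map(ref))
    calls = detect_map_svs(aln, _map(q), _map(ref), "L")
    types = sorted((c.sv_type, c.size_bp) for c in calls)
    assert ("insertion", 8700) in types
    assert ("deletion", 8000) in types
    assert len(calls) == 2


def test_sv_aligner_skips_false_and_missed_labels():
    rng = np.random.default_rng(8)
    ref = _random_labels(rng, 50)
    q = ref.copy()
    q = np.delete(q, 20)                      # missed label
    q = np.sort(np.append(q, int(ref[35]) + 611))  # false label
    aln = align_map_sv(_map(q), _map(ref))
    calls = detect_map_svs(aln, _map(q), _map(ref), "L")
    assert calls == []
    matched_ref = {i for i, _ in aln.pairs}
    assert len(matched_ref) >= 48


def test_inversion_is_size_neutral_after_suppression():
    """A mirrored label pattern preserves pairwise distances, so the aligner
    can mis-pair across it and emit compensating +/- calls; the reflection
    filter must remove them."""
    rng = np.random.default_rng(9)
    ref = _random_labels(rng, 70)
    s, e = int(ref[30]) - 300, int(ref[42]) + 300
    inside = ref[(ref >= s) & (ref < e)]
    mirrored = (s + e - inside)[::-1]
    q = np.sort(np.concatenate([ref[ref < s], mirrored, ref[ref >= e]]))
    aln = align_map_sv(_map(q), _map(ref))
    calls = detect_map_svs(aln, _map(q), _map(ref), "L")
    kept = suppress_reflection_artifacts(calls, aln, _map(q), _map(ref))
    assert kept == []


def test_suppression_preserves_real_opposite_sign_pair():
    """A real insertion + equal-size deletion is net-zero but its interior is
    a translation, not a mirror; the filter must keep both calls."""
    rng = np.random.default_rng(21)
    ref = _random_labels(rng, 80)
    ins_at = int(ref[30]) + 500
    del_at = int(ref[38]) + 500
    q = ref[(ref < del_at) | (ref >= del_at + 6000)]
    q = np.where(q >= del_at + 6000, q - 6000, q)
    q = np.where(q >= ins_at, q + 6000, q)
    aln = align_map_sv(_map(q), _map(ref))
    calls = detect_map_svs(aln, _map(q), _map(ref), "L")
    kept = suppress_reflection_artifacts(calls, aln, _map(q), _map(ref))
    assert sorted((c.sv_type, c.size_bp) for c in kept) == [
        ("deletion", 6000), ("insertion", 6000)]


def test_suppression_keeps_isolated_calls():
    """Single-sided calls have nonzero net and must pass through unchanged."""
    rng = np.random.default_rng(22)
    ref = _random_labels(rng, 60)
    q = _delete(ref, int(ref[25]) + 500, 5000)
    aln = align_map_sv(_map(q), _map(ref))
    calls = detect_map_svs(aln, _map(q), _map(ref), "L")
    kept = suppress_reflection_artifacts(calls, aln, _map(q), _map(ref))
    assert kept == calls


def test_suppression_rejects_mismatched_calls():
    rng = np.random.default_rng(23)
    ref = _random_labels(rng, 60)
    q = _delete(ref, int(ref[25]) + 500, 5000)
    aln = align_map_sv(_map(q), _map(ref))
    calls = detect_map_svs(aln, _map(q), _map(ref), "L")
    with pytest.raises(ValueError):
        suppress_reflection_artifacts(calls + calls, aln, _map(q), _map(ref))


def test_suppression_empty_input():
    assert suppress_reflection_artifacts(
        [], MapAlignment(pairs=[(0, 0), (1, 1)], score=0.0),
        _map([100, 2000]), _map([100, 2000])) == []


def test_sv_aligner_tolerates_sizing_noise():
    rng = np.random.default_rng(10)
    ref = _random_labels(rng, 60)
    gaps = np.diff(np.concatenate([[0], ref])).astype(float)
    q = np.cumsum(gaps * rng.normal(1.0, 0.005, len(gaps))).astype(np.int64)
    aln = align_map_sv(_map(q), _map(ref))
    assert detect_map_svs(aln, _map(q), _map(ref), "L") == []


def test_sv_aligner_band_validation():
    m = _map([100, 2000])
    with pytest.raises(ValueError):
        align_map_sv(m, m, band=0)


def test_map_alignment_requires_monotone_pairs():
    with pytest.raises(ValueError):
        MapAlignment(pairs=[(0, 0), (1, 1), (1, 2)], score=0.0)
    with pytest.raises(ValueError):
        MapAlignment(pairs=[(0, 1), (1, 0)], score=0.0)


# ---------------------------------------------------------------------------
# detect_map_svs threshold
# ---------------------------------------------------------------------------


def test_detect_map_svs_floor_1000():
    ref = _map([0, 2000, 4000, 6000])
    # first interval stretched by 999, second by 1000
    q = _map([0, 2999, 5999, 7999])
    aln = MapAlignment(pairs=[(0, 0), (1, 1), (2, 2), (3, 3)], score=0.0)
    calls = detect_map_svs(aln, q, ref, "L")
    assert [(c.sv_type, c.size_bp, c.start, c.end) for c in calls] == [
        ("insertion", 1000, 2000, 4000)
    ]


def test_detect_map_svs_deletion_sign():
    ref = _map([0, 2000, 8000])
    q = _map([0, 2000, 5000])
    aln = MapAlignment(pairs=[(0, 0), (1, 1), (2, 2)], score=0.0)
    calls = detect_map_svs(aln, q, ref, "L")
    assert [(c.sv_type, c.size_bp) for c in calls] == [("deletion", 3000)]
    assert calls[0].method == "optical"


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def test_cross_validate_sign_matching():
    seq = [
        SVRecord("L", "chr1", 10_000, 10_000, 2000, "insertion"),
        SVRecord("L", "chr1", 50_000, 52_000, 2000, "deletion"),
        SVRecord("L", "chr1", 90_000, 105_000, 15_000, "inversion"),
    ]
    opt = [
        SVRecord("L", "chr1", 9000, 11_000, 2100, "insertion", method="optical"),
        SVRecord("L", "chr1", 49_500, 52_500, 1900, "deletion", method="optical"),
        SVRecord("L", "chr1", 90_000, 105_000, 1500, "insertion", method="optical"),
    ]
    out = cross_validate(seq, opt)
    assert [(r.sv_type, r.validated) for r in out] == [
        ("insertion", True), ("deletion", True)
    ]


def test_cross_validate_wrong_sign_rejected():
    seq = [SVRecord("L", "chr1", 10_000, 12_000, 2000, "deletion")]
    opt = [SVRecord("L", "chr1", 10_000, 12_000, 2000, "insertion", method="optical")]
    assert cross_validate(seq, opt) == []


def test_cross_validate_label_padding():
    labels = np.array([0, 5000, 10_000, 15_000, 20_000, 25_000])
    ref_maps = {"chr1": _map(labels, length=30_000)}
    seq = [SVRecord("L", "chr1", 12_000, 12_000, 1500, "insertion")]
    # optical call two label intervals away: overlaps only via the padding
    opt = [SVRecord("L", "chr1", 5000, 10_000, 1500, "insertion", method="optical")]
    assert cross_validate(seq, opt, ref_maps=ref_maps)
    far = [SVRecord("L", "chr1", 0, 4000, 1500, "insertion", method="optical")]
    assert not cross_validate(seq, far, ref_maps=ref_maps)


def test_cross_validate_rejects_sequence_method_input():
    seq = [SVRecord("L", "chr1", 0, 2000, 2000, "deletion")]
    with pytest.raises(ValueError):
        cross_validate(seq, seq)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_label_map_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(11)
    maps = [
        _map(_random_labels(rng, 15), map_id="L:chr1"),
        _map(_random_labels(rng, 8), map_id="L:chr2"),
    ]
    p = tmp_path / "maps.tsv"
    write_label_maps(maps, p)
    back = read_label_maps(p)
    assert [m.map_id for m in back] == ["L:chr1", "L:chr2"]
    for a, b in zip(maps, back):
        assert a.length_bp == b.length_bp
        assert np.array_equal(a.labels, b.labels)


def test_read_label_maps_rejects_orphan_label(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("#map_id\tlength_bp\n123\n")
    with pytest.raises(ValueError):
        read_label_maps(p)


CMAP_TEXT = """\
# CMAP File Version: 0.1
#h CMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition
#f int\tfloat\tint\tint\tint\tfloat
1\t20000.0\t3\t1\t1\t1500.0
1\t20000.0\t3\t2\t1\t7800.0
1\t20000.0\t3\t3\t1\t14020.0
1\t20000.0\t3\t4\t0\t20000.0
2\t9000.0\t1\t1\t1\t4400.0
2\t9000.0\t1\t2\t0\t9000.0
"""


def test_read_cmap(tmp_path):
    p = tmp_path / "x.cmap"
    p.write_text(CMAP_TEXT)
    maps = {m.map_id: m for m in read_cmap(p)}
    assert set(maps) == {"1", "2"}
    assert maps["1"].length_bp == 20_000
    assert list(maps["1"].labels) == [1500, 7800, 14_020]
    assert list(maps["2"].labels) == [4400]


def test_read_cmap_requires_header(tmp_path):
    p = tmp_path / "x.cmap"
    p.write_text("1\t100.0\t1\t1\t1\t50.0\n")
    with pytest.raises(ValueError):
        read_cmap(p)
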