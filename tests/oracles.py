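"""Independent reference implementations ("oracles") used by the tests.

Each oracle is written for clarity, not speed, and deliberately shares no
code with the library: plain loops, no numpy vectorization, no shared
helpers.  Tests freeze behavior by comparing library output to these.
"""
from __future__ import annotations

from functools import lru_cache


# ---------------------------------------------------------------------------
# align_map: exhaustive banded DP over monotone label matchings
# ---------------------------------------------------------------------------


def align_map_oracle(q_labels, r_labels, miss_penalty=3.0, false_penalty=3.0,
                     sizing_weight=1.0, band=5):
    """Optimal score of a monotone matching between reference labels
    ``r_labels`` and query labels ``q_labels`` under the align_map objective,
    by plain recursive DP over every cell (no vectorization, no pruning
    beyond the band).  Returns -inf when no matching is feasible."""
    r = [float(x) for x in r_labels]
    q = [float(x) for x in q_labels]
    nr, nq = len(r), len(q)

    @lru_cache(maxsize=None)
    def best_end(i, j):
        """Best score of a matching whose last matched pair is (i, j)."""
        best = float("-inf")
        if i <= band and j <= band:  # (i, j) as the first matched pair
            best = -miss_penalty * i - false_penalty * j
        for a in range(1, min(band + 1, i) + 1):
            dr = r[i] - r[i - a]
            for b in range(1, min(band + 1, j) + 1):
                dq = q[j] - q[j - b]
                step = (
                    -miss_penalty * (a - 1)
                    - false_penalty * (b - 1)
                    - sizing_weight * abs(dq - dr) / max(dr, 1000.0)
                )
                cand = best_end(i - a, j - b) + step
                if cand > best:
                    best = cand
        return best

    best = float("-inf")
    for i in range(nr):
        if nr - 1 - i > band:
            continue
        for j in range(nq):
            if nq - 1 - j > band:
                continue
            cand = best_end(i, j) - miss_penalty * (nr - 1 - i) - false_penalty * (
                nq - 1 - j
            )
            if cand > best:
                best = cand
    return best


def score_pairs(pairs, q_labels, r_labels, miss_penalty=3.0, false_penalty=3.0,
                sizing_weight=1.0):
    """Score an explicit matching under the align_map objective (for checking
    that the returned pairs actually achieve the returned score)."""
    nr, nq = len(r_labels), len(q_labels)
    i0, j0 = pairs[0]
    score = -miss_penalty * i0 - false_penalty * j0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        dr = float(r_labels[i2] - r_labels[i1])
        dq = float(q_labels[j2] - q_labels[j1])
        score += (
            -miss_penalty * (i2 - i1 - 1)
            - false_penalty * (j2 - j1 - 1)
            - sizing_weight * abs(dq - dr) / max(dr, 1000.0)
        )
    iL, jL = pairs[-1]
    score += -miss_penalty * (nr - 1 - iL) - false_penalty * (nq - 1 - jL)
    return score


# ---------------------------------------------------------------------------
# match_svs: exhaustive pairwise coincidence + union-find
# ---------------------------------------------------------------------------


def match_partition_oracle(records, tol):
    """Partition record indices into coincidence loci by checking every pair
    (O(n^2)) and joining with union-find.  ``records`` is a flat list of
    (line_id, SVRecord).  Returns a set of frozensets of indices."""
    n = len(records)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(n):
        _, ri = records[i]
        for j in range(i + 1, n):
            _, rj = records[j]
            if (
                ri.chrom == rj.chrom
                and ri.sv_type == rj.sv_type
                and abs(ri.start - rj.start) <= tol
                and abs(ri.end - rj.end) <= tol
            ):
                union(i, j)

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return {frozenset(g) for g in groups.values()}


# ---------------------------------------------------------------------------
# exon intersection: brute force double loop
# ---------------------------------------------------------------------------


def intersect_oracle(svs, exons):
    """Every (sv, exon) overlap by brute force, with the same insertion-point
    semantics as svlineage.impact: a zero-length SV overlaps iff its point is
    strictly inside the exon (0 bp); otherwise positive interval overlap."""
    out = set()
    for si, sv in enumerate(svs):
        for ei, ex in enumerate(exons):
            if sv.chrom != ex.chrom:
                continue
            if sv.start == sv.end:
                if ex.start < sv.start < ex.end:
                    out.add((si, ei, 0))
                continue
            ovl = min(sv.end, ex.end) - max(sv.start, ex.start)
            if ovl > 0:
                out.add((si, ei, ovl))
    return out
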