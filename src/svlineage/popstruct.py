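"""Cross-line SV coincidence and relationship analysis.

SVs called independently in each line are collapsed into shared loci when
they have the same class and breakpoints agreeing within a small tolerance
(3 bp, matching the published matching rule).  The resulting loci-by-lines
presence/absence matrix drives pairwise sharing statistics, a Jaccard
distance, an average-linkage (UPGMA) relationship tree, and clade supports
via ordinary (BP) and multiscale approximately-unbiased (AU) bootstrap.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .svcall import SVRecord

__all__ = [
    "PresenceMatrix",
    "ClusterTree",
    "RateEstimate",
    "SharingStats",
    "match_svs",
    "sharing_stats",
    "sv_distance",
    "cluster",
    "bootstrap_support",
    "approximately_unbiased",
    "estimate_rate",
    "presence_from_truth",
    "COINCIDENCE_TOL",
]

logger = logging.getLogger(__name__)

#: breakpoint tolerance (bp) for treating two lines' SVs as the same locus
COINCIDENCE_TOL = 3


@dataclass
class PresenceMatrix:
    """SV loci x lines binary matrix with per-cell provenance."""

    loci: list[tuple[str, int, int, str]]  # (chrom, start, end, sv_type)
    lines: list[str]
    cells: np.ndarray  # (n_loci, n_lines) int8
    provenance: list[dict[str, list[SVRecord]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.loci), len(self.lines)):
            raise ValueError("cells shape mismatch")
        if len(self.loci) and (self.cells.sum(axis=1) < 1).any():
            raise ValueError("every locus must be present in at least one line")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.DataFrame(self.loci, columns=["chrom", "start", "end", "sv_type"])
        return pd.concat(
            [idx, pd.DataFrame(self.cells, columns=self.lines)], axis=1
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t")
        key_cols = ["chrom", "start", "end", "sv_type"]
        lines = [c for c in df.columns if c not in key_cols]
        loci = [tuple(r) for r in df[key_cols].itertuples(index=False)]
        return cls(loci=loci, lines=lines, cells=df[lines].to_numpy(dtype=np.int8))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def match_svs(
    svs_by_line: dict[str, list[SVRecord]],
    tol: int = COINCIDENCE_TOL,
) -> PresenceMatrix:
    """Collapse per-line SVs into coincidence loci.

    Two records coincide iff same chromosome, same class, and both start and
    end positions differ by at most ``tol`` bp.  Loci are the connected
    components of the coincidence graph (single linkage), keyed by the
    component-wise minimum start / maximum end.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    lines = sorted(svs_by_line)
    flat: list[tuple[str, SVRecord]] = []
    for line in lines:
        for r in svs_by_line[line]:
            flat.append((line, r))
    n = len(flat)
    uf = _UnionFind(n)

    order = sorted(range(n), key=lambda t: (flat[t][1].chrom, flat[t][1].sv_type, flat[t][1].start))
    for a in range(n):
        i = order[a]
        ri = flat[i][1]
        for b in range(a + 1, n):
            j = order[b]
            rj = flat[j][1]
            if (rj.chrom, rj.sv_type) != (ri.chrom, ri.sv_type) or rj.start - ri.start > tol:
                break
            if abs(rj.end - ri.end) <= tol:
                uf.union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)

    entries = []
    for members in comps.values():
        recs = [flat[i] for i in members]
        chrom = recs[0][1].chrom
        sv_type = recs[0][1].sv_type
        start = min(r.start for _, r in recs)
        end = max(r.end for _, r in recs)
        prov: dict[str, list[SVRecord]] = {}
        for line, r in recs:
            prov.setdefault(line, []).append(r)
        for line, rs in prov.items():
            if len(rs) > 1:
                logger.info(
                    "locus %s:%d-%d %s merges %d records from line %s",
                    chrom, start, end, sv_type, len(rs), line,
                )
        entries.append(((chrom, start, end, sv_type), prov))

    entries.sort(key=lambda e: e[0])
    cells = np.zeros((len(entries), len(lines)), dtype=np.int8)
    provenance = []
    loci = []
    for k, (key, prov) in enumerate(entries):
        loci.append(key)
        provenance.append(prov)
        for line in prov:
            cells[k, lines.index(line)] = 1
    return PresenceMatrix(loci=loci, lines=lines, cells=cells, provenance=provenance)


@dataclass
class SharingStats:
    pairwise_percent: pd.DataFrame  # row i: % of line i's loci also in line j
    shared_in_all: int
    per_line_counts: dict[str, int]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# shared_in_all\t{self.shared_in_all}\n")
            for line, c in self.per_line_counts.items():
                fh.write(f"# loci\t{line}\t{c}\n")
        self.pairwise_percent.to_csv(path, sep="\t", mode="a")


def sharing_stats(matrix: PresenceMatrix) -> SharingStats:
    """Row-normalized pairwise sharing percentages, loci shared by every
    line, and per-line locus counts."""
    if matrix.n_loci == 0:
        raise ValueError("empty presence matrix")
    C = matrix.cells.astype(np.int64)
    counts = C.sum(axis=0)
    inter = C.T @ C
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * inter / counts[:, None]
    pct[counts == 0, :] = np.nan
    df = pd.DataFrame(pct, index=matrix.lines, columns=matrix.lines)
    shared_in_all = int((C.sum(axis=1) == len(matrix.lines)).sum())
    per_line = {line: int(c) for line, c in zip(matrix.lines, counts)}
    return SharingStats(pairwise_percent=df, shared_in_all=shared_in_all,
                        per_line_counts=per_line)


def _jaccard(C: np.ndarray) -> np.ndarray:
    C = C.astype(np.float64)
    inter = C.T @ C
    counts = np.diag(inter).copy()
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0  # two all-zero columns are indistinguishable
    np.fill_diagonal(d, 0.0)
    return d


def sv_distance(matrix: PresenceMatrix, method: str = "jaccard") -> pd.DataFrame:
    """Pairwise line distance from the presence matrix (1 - Jaccard index)."""
    if method != "jaccard":
        raise ValueError(f"unknown distance method {method!r}")
    if len(matrix.lines) < 2:
        raise ValueError("need at least 2 lines")
    return pd.DataFrame(_jaccard(matrix.cells), index=matrix.lines, columns=matrix.lines)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterTree:
    """Agglomerative tree: ordered merges of leaf sets plus optional clade
    supports (BP and AU, in percent)."""

    leaf_ids: list[str]
    merges: list[tuple[frozenset, frozenset, float]]
    supports: dict[frozenset, tuple[float, float]] | None = None  # clade -> (bp, au)

    def __post_init__(self) -> None:
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def clades(self) -> list[frozenset]:
        """All internal clades (size >= 2), root included."""
        return [a | b for a, b, _ in self.merges]

    def topology(self) -> frozenset:
        """Unordered set of non-trivial clades; equal iff same tree shape."""
        return frozenset(self.clades())

    def to_newick(self) -> str:
        height_of: dict[frozenset, float] = {frozenset([l]): 0.0 for l in self.leaf_ids}
        name_of: dict[frozenset, str] = {frozenset([l]): l for l in self.leaf_ids}
        for a, b, h in self.merges:
            parts = []
            for child in sorted((a, b), key=lambda s: sorted(s)):
                bl = h - height_of[child]
                parts.append(f"{name_of[child]}:{bl:.6g}")
            clade = a | b
            label = ""
            if self.supports and clade in self.supports:
                bp, au = self.supports[clade]
                label = f"[{au:.1f}/{bp:.1f}]"
            name_of[clade] = f"({','.join(parts)}){label}"
            height_of[clade] = h
        root = frozenset(self.leaf_ids)
        return name_of[root] + ";"


def _upgma_merges(D: np.ndarray, names: list[str]) -> list[tuple[frozenset, frozenset, float]]:
    """Average-linkage agglomeration with deterministic tie-breaking by the
    lexicographically smallest leaf names of the merged pair."""
    active = {i: frozenset([names[i]]) for i in range(len(names))}
    sizes = {i: 1 for i in range(len(names))}
    dist = {(i, j): float(D[i, j]) for i in range(len(names)) for j in range(i + 1, len(names))}
    merges = []
    nxt = len(names)
    while len(active) > 1:
        best = None
        for (i, j), d in dist.items():
            if i not in active or j not in active:
                continue
            tie_key = tuple(sorted((min(sorted(active[i])), min(sorted(active[j])))))
            cand = (d, tie_key)
            if best is None or cand < best[0:2]:
                best = (d, tie_key, i, j)
        d, _, i, j = best
        a, b = active.pop(i), active.pop(j)
        merges.append((a, b, d / 2.0))
        new = a | b
        for k in list(active):
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(nxt, k), max(nxt, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        dist.pop((i, j), None)
        active[nxt] = new
        sizes[nxt] = sizes[i] + sizes[j]
        nxt += 1
    return merges


def cluster(dist: pd.DataFrame, linkage: str = "average") -> ClusterTree:
    """Average-linkage (UPGMA) tree from a distance matrix.  Merge heights
    are half the merge distance, so an ultrametric input is reproduced
    exactly by the cophenetic distances."""
    if linkage != "average":
        raise ValueError(f"unsupported linkage {linkage!r}")
    D = dist.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T) or (np.diag(D) != 0).any():
        raise ValueError("invalid distance matrix")
    names = [str(c) for c in dist.columns]
    return ClusterTree(leaf_ids=names, merges=_upgma_merges(D, names))


def _upgma_clades_fast(D: np.ndarray) -> list[frozenset]:
    """Clades (index sets) of a UPGMA tree; minimal bookkeeping for the
    bootstrap inner loop (ties broken by smallest member index)."""
    n = D.shape[0]
    D = D.copy()
    members = [frozenset([i]) for i in range(n)]
    sizes = np.ones(n)
    alive = np.ones(n, dtype=bool)
    clades = []
    big = np.inf
    np.fill_diagonal(D, big)
    for _ in range(n - 1):
        sub = np.where(alive)[0]
        block = D[np.ix_(sub, sub)]
        flat = int(np.argmin(block))
        ai, aj = divmod(flat, len(sub))
        i, j = int(sub[min(ai, aj)]), int(sub[max(ai, aj)])
        new = members[i] | members[j]
        clades.append(new)
        # average-linkage update into slot i
        w = (sizes[i] * D[i] + sizes[j] * D[j]) / (sizes[i] + sizes[j])
        D[i], D[:, i] = w, w
        D[i, i] = big
        alive[j] = False
        D[j], D[:, j] = big, big
        members[i] = new
        sizes[i] += sizes[j]
    return clades


def approximately_unbiased(scales: np.ndarray, bp_r: np.ndarray, B: int) -> float:
    """AU p-value (percent) from per-scale bootstrap proportions.

    Multiscale model: z(r) = Phi^-1(1 - BP_r) is fitted as
    z = v*sqrt(r) + c/sqrt(r) by weighted least squares (binomial weights),
    and AU = 100 * (1 - Phi(v - c)).  Scales with BP_r in {0, 1} carry no
    usable z value; when fewer than half the scales are informative the
    profile is saturated and the fit would extrapolate from its tail, so
    the function falls back to 100 * BP at scale 1.
    """
    scales = np.asarray(scales, dtype=float)
    bp_r = np.asarray(bp_r, dtype=float)
    informative = (bp_r > 0) & (bp_r < 1)
    bp1 = float(bp_r[np.argmin(np.abs(scales - 1.0))])
    if informative.sum() < max(2, len(scales) // 2):
        return 100.0 * bp1
    r = scales[informative]
    bp = bp_r[informative]
    z = norm.ppf(1.0 - bp)
    w = B * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
    v, c = beta
    return float(100.0 * (1.0 - norm.cdf(v - c)))


def bootstrap_support(
    matrix: PresenceMatrix,
    B: int = 1000,
    scales: list[float] | None = None,
    seed: int = 0,
) -> ClusterTree:
    """Cluster with BP and AU clade supports by multiscale bootstrap.

    For each scale r, B resamples of ceil(r * n_loci) loci (rows, with
    replacement) are re-clustered and each original clade's recovery
    frequency BP_r recorded; BP is the frequency at r = 1 and AU comes from
    the multiscale fit (see :func:`approximately_unbiased`).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if scales is None:
        scales = [round(0.5 + 0.1 * t, 1) for t in range(10)]
    scales = sorted(float(s) for s in scales)
    if not any(abs(s - 1.0) < 1e-9 for s in scales):
        raise ValueError("scales must include 1.0")

    base_dist = sv_distance(matrix)
    base = cluster(base_dist)
    names = base.leaf_ids
    name_idx = {n: i for i, n in enumerate(names)}
    base_clades = [frozenset(name_idx[n] for n in c) for c in base.clades()]
    n = matrix.n_loci
    C = matrix.cells.astype(np.float64)
    rng = np.random.default_rng(seed)

    bp_per_scale = np.zeros((len(scales), len(base_clades)))
    for si, r in enumerate(scales):
        m = max(1, math.ceil(r * n))
        hits = np.zeros(len(base_clades))
        for _ in range(B):
            idx = rng.integers(0, n, m)
            sub = C[idx]
            clades = set(_upgma_clades_fast(_jaccard(sub)))
            for ci, clade in enumerate(base_clades):
                if clade in clades:
                    hits[ci] += 1
        bp_per_scale[si] = hits / B

    scale_arr = np.array(scales)
    s1 = int(np.argmin(np.abs(scale_arr - 1.0)))
    supports: dict[frozenset, tuple[float, float]] = {}
    for ci, clade in enumerate(base.clades()):
        bp = 100.0 * bp_per_scale[s1, ci]
        au = approximately_unbiased(scale_arr, bp_per_scale[:, ci], B)
        supports[clade] = (bp, au)
    return ClusterTree(leaf_ids=base.leaf_ids, merges=base.merges, supports=supports)


# ---------------------------------------------------------------------------
# Rate
# ---------------------------------------------------------------------------


@dataclass
class RateEstimate:
    """SV accumulation rate in SVs per million years per megabase.  The
    factor 2 in the denominator counts both lineages separating a line from
    the reference since their common ancestor."""

    sv_count: int
    divergence_my: float
    genome_mb: float
    rate: float

    def __post_init__(self) -> None:
        if min(self.sv_count, self.divergence_my, self.genome_mb) <= 0:
            raise ValueError("all rate inputs must be > 0")


def estimate_rate(sv_count: int, divergence_my: float, genome_mb: float) -> RateEstimate:
    if sv_count <= 0 or divergence_my <= 0 or genome_mb <= 0:
        raise ValueError("all rate inputs must be > 0")
    rate = sv_count / (2.0 * divergence_my * genome_mb)
    return RateEstimate(sv_count=sv_count, divergence_my=divergence_my,
                        genome_mb=genome_mb, rate=rate)


def presence_from_truth(truth, lines: list[str] | None = None) -> PresenceMatrix:
    """Presence matrix straight from a simulator truth table (each planted
    event is one locus, present in its carrier lines)."""
    if lines is None:
        lines = sorted({l for r in truth.records for l in r.carrier_lines})
    loci, rows = [], []
    recs = sorted(truth.records, key=lambda r: (r.chrom, r.ref_start, r.ref_end, r.sv_type))
    for r in recs:
        loci.append((r.chrom, r.ref_start, r.ref_end, r.sv_type))
        rows.append([1 if l in r.carrier_lines else 0 for l in lines])
    return PresenceMatrix(loci=loci, lines=list(lines),
                          cells=np.array(rows, dtype=np.int8).reshape(len(loci), len(lines)),
                          provenance=[{} for _ in loci])
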