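"""Whole-genome collinear alignment blocks.

Two routes produce :class:`AlignmentBlock` lists: an internal unique-anchor
chainer (maximal exact matches seeded at k-mers unique in both genomes,
suited to genomes that differ structurally but not by substitutions) and a
PAF reader for blocks produced by an external aligner such as minimap2.

Match-length filtering follows the published thresholds: a single match must
be at least 500 bp, while matches of 100 bp or more survive inside a cluster
(chain) of at least two matches.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .simulate import Genome, revcomp

__all__ = [
    "AlignmentBlock",
    "Chain",
    "find_unique_anchors",
    "chain_anchors",
    "filter_alignments",
    "read_paf",
    "write_paf",
    "MIN_SINGLE_MATCH",
    "MIN_CLUSTER_MATCH",
]

#: minimum length for a match standing alone
MIN_SINGLE_MATCH = 500
#: minimum length for a match inside a cluster (chain of >= 2)
MIN_CLUSTER_MATCH = 100


@dataclass
class AlignmentBlock:
    """One collinear ref<->query segment.  Coordinates are 0-based half-open;
    query coordinates are always on the forward query strand (PAF convention),
    with ``strand`` recording orientation."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    strand: str
    block_len: int = 0
    cigar: str | None = None

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start or self.query_end <= self.query_start:
            raise ValueError("blocks must have positive extent on both genomes")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.block_len == 0:
            self.block_len = self.ref_end - self.ref_start

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_len(self) -> int:
        return self.query_end - self.query_start


@dataclass
class Chain:
    """Ordered collinear blocks on one (ref_chrom, query_chrom, strand)."""

    blocks: list[AlignmentBlock]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("empty chain")
        b0 = self.blocks[0]
        for b in self.blocks:
            if (b.ref_chrom, b.query_chrom, b.strand) != (
                b0.ref_chrom,
                b0.query_chrom,
                b0.strand,
            ):
                raise ValueError("chain mixes chromosome pairs or strands")
        starts = [b.ref_start for b in self.blocks]
        if starts != sorted(starts):
            raise ValueError("chain blocks not sorted by ref_start")

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def ref_chrom(self) -> str:
        return self.blocks[0].ref_chrom

    @property
    def query_chrom(self) -> str:
        return self.blocks[0].query_chrom

    def __len__(self) -> int:
        return len(self.blocks)


# ---------------------------------------------------------------------------
# k-mer machinery
# ---------------------------------------------------------------------------

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _encode(seq: str) -> np.ndarray:
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer codes (k <= 32) for every position."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | arr[j : j + n].astype(np.uint64)
    return codes


class _KmerIndex:
    """Positions of k-mers occurring exactly once across a genome's strand."""

    def __init__(self, sequences: dict[str, str], k: int) -> None:
        self.k = k
        self.chroms = list(sequences)
        codes_parts, pos_parts, chrom_parts = [], [], []
        for ci, (name, seq) in enumerate(sequences.items()):
            c = _kmer_codes(_encode(seq), k)
            codes_parts.append(c)
            pos_parts.append(np.arange(len(c), dtype=np.int64))
            chrom_parts.append(np.full(len(c), ci, dtype=np.int32))
        codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.uint64)
        pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        chrom = np.concatenate(chrom_parts) if chrom_parts else np.empty(0, np.int32)
        order = np.argsort(codes, kind="stable")
        codes, pos, chrom = codes[order], pos[order], chrom[order]
        uniq, start, counts = np.unique(codes, return_index=True, return_counts=True)
        once = counts == 1
        self.codes = uniq[once]
        self.pos = pos[start[once]]
        self.chrom = chrom[start[once]]


def _extend_match(r: str, q: str, rs: int, re_: int, qs: int, qe: int) -> tuple[int, int, int, int]:
    """Extend an exact match [rs,re_) ~ [qs,qe) maximally in both directions
    using chunked slice comparison (C-speed for long identical stretches)."""
    # rightward (chunk doubles after a hit, halves after a miss: amortized O(n))
    step = 4096
    while step >= 1:
        a = r[re_ : re_ + step]
        if len(a) == step and a == q[qe : qe + step]:
            re_ += step
            qe += step
            step = min(step * 2, 1 << 16)
        else:
            step //= 2
    # leftward
    step = 4096
    while step >= 1:
        if rs >= step and qs >= step and r[rs - step : rs] == q[qs - step : qs]:
            rs -= step
            qs -= step
            step = min(step * 2, 1 << 16)
        else:
            step //= 2
    return rs, re_, qs, qe


def find_unique_anchors(
    reference: Genome,
    query: Genome,
    k: int = 21,
    _ref_index: "_KmerIndex | None" = None,
) -> list[AlignmentBlock]:
    """Maximal exact matches seeded at k-mers unique in both genomes, on both
    orientations, sorted by (ref_chrom, ref_start).

    Seeds inside repeats are never unique, so anchors naturally break at
    structural differences and pass straight through shared repeat copies.
    """
    if not (15 <= k <= 64):
        raise ValueError("k must be in [15, 64]")
    if k > 32:
        raise ValueError("k > 32 not supported by the packed-k-mer index")

    ref_idx = _ref_index if _ref_index is not None and _ref_index.k == k else _KmerIndex(
        reference.sequences, k
    )
    q_fwd = _KmerIndex(query.sequences, k)
    rc_sequences = {c: revcomp(s) for c, s in query.sequences.items()}
    q_rc = _KmerIndex(rc_sequences, k)

    anchors: list[AlignmentBlock] = []
    seen: set[tuple] = set()

    for strand, qidx, qseqs in (("+", q_fwd, query.sequences), ("-", q_rc, rc_sequences)):
        _, ri, qi = np.intersect1d(
            ref_idx.codes, qidx.codes, assume_unique=True, return_indices=True
        )
        if len(ri) == 0:
            continue
        r_chrom, r_pos = ref_idx.chrom[ri], ref_idx.pos[ri]
        s_chrom, s_pos = qidx.chrom[qi], qidx.pos[qi]
        # prune runs of seeds on the same diagonal: keep the first of each
        # contiguous run; extension plus the per-diagonal skip below covers
        # the rest.
        diag = r_pos - s_pos
        order = np.lexsort((r_pos, diag, s_chrom, r_chrom))
        r_chrom, r_pos = r_chrom[order], r_pos[order]
        s_chrom, s_pos = s_chrom[order], s_pos[order]
        diag = diag[order]
        same = np.zeros(len(diag), dtype=bool)
        if len(diag) > 1:
            same[1:] = (
                (np.diff(r_pos) == 1)
                & (np.diff(diag) == 0)
                & (r_chrom[1:] == r_chrom[:-1])
                & (s_chrom[1:] == s_chrom[:-1])
            )
        keep = ~same
        r_chrom, r_pos = r_chrom[keep], r_pos[keep]
        s_chrom, s_pos, diag = s_chrom[keep], s_pos[keep], diag[keep]

        covered: dict[tuple, int] = {}  # (rc, qc, diag) -> ref end of last anchor
        order2 = np.lexsort((r_pos, s_chrom, r_chrom))
        for t in order2:
            rc, qc = int(r_chrom[t]), int(s_chrom[t])
            key = (rc, qc, int(diag[t]))
            rp, sp = int(r_pos[t]), int(s_pos[t])
            if covered.get(key, -1) >= rp + k:
                continue
            rname = ref_idx.chroms[rc]
            qname = qidx.chroms[qc]
            rs, re_, qs, qe = _extend_match(
                reference.sequences[rname], qseqs[qname], rp, rp + k, sp, sp + k
            )
            covered[key] = re_
            if strand == "+":
                block = (rname, rs, re_, qname, qs, qe, "+")
            else:
                Lq = len(query.sequences[qname])
                block = (rname, rs, re_, qname, Lq - qe, Lq - qs, "-")
            if block not in seen:
                seen.add(block)
                anchors.append(AlignmentBlock(*block))

    anchors.sort(key=lambda b: (b.ref_chrom, b.ref_start, b.query_chrom, b.query_start))
    return anchors


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------


def _compatible(j: AlignmentBlock, i: AlignmentBlock, max_gap: int) -> bool:
    """May block ``i`` follow ``j`` in one collinear chain?"""
    if i.ref_end <= j.ref_end:
        return False
    ref_gap = i.ref_start - j.ref_end
    if ref_gap > max_gap:
        return False
    ref_ovl = max(0, j.ref_end - i.ref_start)
    if ref_ovl > min(i.ref_len, j.ref_len) / 2:
        return False
    if i.strand == "+":
        if i.query_end <= j.query_end or i.query_start < j.query_start:
            return False
        q_gap = i.query_start - j.query_end
        q_ovl = max(0, j.query_end - i.query_start)
    else:
        if i.query_start >= j.query_start or i.query_end > j.query_end:
            return False
        q_gap = j.query_start - i.query_end
        q_ovl = max(0, i.query_end - j.query_start)
    if q_gap > max_gap:
        return False
    if q_ovl > min(i.query_len, j.query_len) / 2:
        return False
    return True


def chain_anchors(anchors: list[AlignmentBlock], max_gap: int = 50_000) -> list[Chain]:
    """Assemble collinear chains of same-strand anchors with ref and query
    gaps each <= ``max_gap``.

    Optimal (maximum total anchor length) chains are peeled off one at a time
    by dynamic programming, so chain membership matches the exhaustive
    co-linear chaining optimum; each anchor joins at most one chain, and an
    unchained anchor overlapping a chained block by more than half its length
    is dropped.
    """
    chains: list[Chain] = []
    groups: dict[tuple, list[AlignmentBlock]] = {}
    for a in anchors:
        groups.setdefault((a.ref_chrom, a.query_chrom, a.strand), []).append(a)

    for key in sorted(groups):
        blocks = sorted(groups[key], key=lambda b: (b.ref_start, b.ref_end, b.query_start))
        remaining = list(range(len(blocks)))
        group_chains: list[list[AlignmentBlock]] = []
        while remaining:
            idx = remaining
            n = len(idx)
            score = [blocks[t].block_len for t in idx]
            back = [-1] * n
            for bi in range(n):
                i = blocks[idx[bi]]
                for bj in range(bi):
                    j = blocks[idx[bj]]
                    if _compatible(j, i, max_gap):
                        cand = score[bj] + i.block_len
                        if cand > score[bi]:
                            score[bi] = cand
                            back[bi] = bj
            best = max(range(n), key=lambda t: (score[t], -t))
            path = []
            t = best
            while t != -1:
                path.append(idx[t])
                t = back[t]
            path.reverse()
            group_chains.append([blocks[t] for t in path])
            used = set(path)
            remaining = [t for t in remaining if t not in used]
        # drop leftover singletons mostly covered by an earlier, bigger chain
        final: list[list[AlignmentBlock]] = []
        for ch in group_chains:
            if len(ch) == 1 and final:
                b = ch[0]
                ovl = 0
                for prev in final:
                    for pb in prev:
                        ovl = max(ovl, min(b.ref_end, pb.ref_end) - max(b.ref_start, pb.ref_start))
                        if key[2] == "+":
                            ovl = max(
                                ovl,
                                min(b.query_end, pb.query_end) - max(b.query_start, pb.query_start),
                            )
                if ovl > b.block_len / 2:
                    continue
            final.append(ch)
        chains.extend(Chain(blocks=ch) for ch in final)
    return chains


def filter_alignments(chains: list[Chain]) -> list[Chain]:
    """Apply the published match-length filters: blocks >= 500 bp always
    survive; blocks in [100, 500) survive only inside a cluster (chain) of at
    least two such matches; blocks < 100 bp are removed."""
    out: list[Chain] = []
    for chain in chains:
        kept = [b for b in chain.blocks if b.block_len >= MIN_CLUSTER_MATCH]
        if len(kept) < 2:
            kept = [b for b in kept if b.block_len >= MIN_SINGLE_MATCH]
        if kept:
            out.append(Chain(blocks=kept))
    return out


# ---------------------------------------------------------------------------
# PAF I/O
# ---------------------------------------------------------------------------


def read_paf(path) -> list[AlignmentBlock]:
    """Read PAF records into alignment blocks.  PAF already stores 0-based
    half-open coordinates with minus-strand query intervals on the forward
    strand, so coordinates carry over unchanged; a ``cg:Z`` CIGAR tag is kept
    when present."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: malformed PAF at line {ln}: expected >= 12 columns")
            try:
                qs, qe = int(f[2]), int(f[3])
                ts, te = int(f[7]), int(f[8])
                blen = int(f[10])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed PAF at line {ln}: {exc}") from None
            strand = f[4]
            if strand not in "+-":
                raise ValueError(f"{path}: malformed PAF at line {ln}: bad strand {strand!r}")
            cigar = None
            for tag in f[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = tag[5:]
            blocks.append(
                AlignmentBlock(
                    ref_chrom=f[5], ref_start=ts, ref_end=te,
                    query_chrom=f[0], query_start=qs, query_end=qe,
                    strand=strand, block_len=blen, cigar=cigar,
                )
            )
    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start, b.query_chrom, b.query_start))
    return blocks


def write_paf(
    blocks: list[AlignmentBlock],
    path,
    ref_lengths: dict[str, int],
    query_lengths: dict[str, int],
) -> None:
    """Write blocks as minimal PAF (matches = block length, mapq 60)."""
    with open(path, "w") as fh:
        for b in blocks:
            fields = [
                b.query_chrom, str(query_lengths[b.query_chrom]),
                str(b.query_start), str(b.query_end), b.strand,
                b.ref_chrom, str(ref_lengths[b.ref_chrom]),
                str(b.ref_start), str(b.ref_end),
                str(b.block_len), str(max(b.ref_len, b.query_len)), "60",
            ]
            if b.cigar:
                fields.append(f"cg:Z:{b.cigar}")
            fh.write("\t".join(fields) + "\n")
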