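"""Optical (label) map alignment and large-SV detection.

An optical map reduces a chromosome to the ordered positions of a nicking
enzyme's recognition hexamer (here BssSI-like labels).  Aligning a line's
consensus map against the reference's in-silico digest matches labels
monotonically; a structural variant shows up as a discrepancy between a
query inter-label distance and its reference counterpart.  Label maps only
resolve large events (>= 1 kb by default), but they are fully independent of
the sequence assembly, so they serve to cross-validate sequence SV calls.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import Genome, revcomp
from .svcall import SVRecord, GAIN_TYPES, LOSS_TYPES

__all__ = [
    "LabelMap",
    "MapAlignment",
    "digest_sequence",
    "digest_reference",
    "align_map",
    "align_map_sv",
    "detect_map_svs",
    "suppress_reflection_artifacts",
    "cross_validate",
    "write_label_maps",
    "read_label_maps",
    "read_cmap",
    "MIN_OPTICAL_SV_SIZE",
]

#: resolution floor of optical-map SV detection
MIN_OPTICAL_SV_SIZE = 1000


@dataclass
class LabelMap:
    """Ordered nick-label positions along one sequence."""

    map_id: str
    length_bp: int
    labels: np.ndarray
    chrom: str | None = None
    line_id: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels):
            if (np.diff(self.labels) <= 0).any():
                raise ValueError("labels must be strictly increasing")
            if self.labels[0] < 0 or self.labels[-1] > self.length_bp:
                raise ValueError("labels must lie within [0, length_bp]")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class MapAlignment:
    """Monotone matching between reference and query label indices."""

    pairs: list[tuple[int, int]]
    score: float

    def __post_init__(self) -> None:
        ri = [p[0] for p in self.pairs]
        qi = [p[1] for p in self.pairs]
        if any(b <= a for a, b in zip(ri, ri[1:])) or any(b <= a for a, b in zip(qi, qi[1:])):
            raise ValueError("alignment indices must be strictly increasing")


def digest_sequence(seq: str, motif: str) -> np.ndarray:
    """Sorted, deduplicated start positions of ``motif`` on both strands
    (occurrences of the motif and of its reverse complement on the forward
    strand), overlapping occurrences included."""
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over ACGT")
    positions: set[int] = set()
    for pat in {motif, revcomp(motif)}:
        i = seq.find(pat)
        while i != -1:
            positions.add(i)
            i = seq.find(pat, i + 1)
    return np.array(sorted(positions), dtype=np.int64)


def digest_reference(genome: Genome, motif: str) -> dict[str, LabelMap]:
    """In-silico digest: one reference label map per chromosome."""
    if len(motif) != 6:
        raise ValueError("motif must be a 6-mer")
    out = {}
    for chrom, seq in genome.sequences.items():
        out[chrom] = LabelMap(
            map_id=f"{genome.id}:{chrom}", length_bp=len(seq),
            labels=digest_sequence(seq, motif), chrom=chrom, line_id=genome.id,
        )
    return out


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def align_map(
    query: LabelMap,
    reference: LabelMap,
    miss_penalty: float = 3.0,
    false_penalty: float = 3.0,
    sizing_weight: float = 1.0,
    band: int = 5,
) -> MapAlignment:
    """Optimal monotone label matching by dynamic programming.

    The score of a matching is
    ``-sum sizing_weight * |dq - dr| / max(dr, 1000)
      - miss_penalty * (skipped reference labels)
      - false_penalty * (skipped query labels)``
    where ``dr``/``dq`` are the distances between consecutive matched labels.
    At most ``band`` consecutive labels may be skipped per step on each map
    (and at either end), which bounds the transition fan-out to
    ``(band + 1)^2`` per cell.
    """
    nr, nq = len(reference), len(query)
    if nr < 2 or nq < 2:
        raise ValueError("both maps need at least 2 labels")
    r = reference.labels.astype(np.float64)
    q = query.labels.astype(np.float64)
    NEG = -np.inf

    S = np.full((nr, nq), NEG)
    P = np.full((nr, nq), -1, dtype=np.int32)  # (a-1)*(band+1)+(b-1), -1 = start
    lead_r = min(band, nr - 1)
    lead_q = min(band, nq - 1)
    for i in range(lead_r + 1):
        for j in range(lead_q + 1):
            S[i, j] = -miss_penalty * i - false_penalty * j

    # Δq per skip width b, precomputed: dq[b-1][j] = q[j] - q[j-b] for j >= b
    dq = [q[b:] - q[:-b] for b in range(1, band + 2)]

    for i in range(1, nr):
        row = S[i]
        prow = P[i]
        for a in range(1, min(band + 1, i) + 1):
            prev = S[i - a]
            dr = r[i] - r[i - a]
            denom = max(dr, 1000.0)
            base = -miss_penalty * (a - 1)
            for b in range(1, min(band + 1, nq - 1) + 1):
                cand = (
                    prev[:-b]
                    + base
                    - false_penalty * (b - 1)
                    - sizing_weight * np.abs(dq[b - 1] - dr) / denom
                )
                seg = row[b:]
                better = cand > seg
                if better.any():
                    seg[better] = cand[better]
                    prow[b:][better] = (a - 1) * (band + 1) + (b - 1)

    ii, jj = np.meshgrid(np.arange(nr), np.arange(nq), indexing="ij")
    total = S - miss_penalty * (nr - 1 - ii) - false_penalty * (nq - 1 - jj)
    total[nr - 1 - ii > band] = NEG
    total[nq - 1 - jj > band] = NEG
    flat = int(np.argmax(total))
    i, j = divmod(flat, nq)
    if not np.isfinite(total[i, j]):
        raise ValueError("no feasible alignment within the skip band")
    best = float(total[i, j])

    pairs: list[tuple[int, int]] = []
    while True:
        pairs.append((int(i), int(j)))
        code = int(P[i, j])
        if code < 0:
            break
        a = code // (band + 1) + 1
        b = code % (band + 1) + 1
        i, j = i - a, j - b
    pairs.reverse()
    return MapAlignment(pairs=pairs, score=best)


def align_map_sv(
    query: LabelMap,
    reference: LabelMap,
    match_reward: float = 1.0,
    skip_penalty: float = 0.25,
    jump_penalty: float = 1.5,
    sizing_tol_bp: int = 100,
    sizing_tol_rel: float = 0.02,
    band: int = 10,
) -> MapAlignment:
    """SV-aware label matching: like :func:`align_map` but with an explicit
    structural-variant transition.

    ``align_map`` maximises agreement of inter-label distances, which charges
    the aligner in proportion to every real discrepancy it reports; two
    nearby opposite-sign SVs can then be scored away by bridging them with
    mis-paired labels.  Here the score is structural instead of metric:

    * each matched pair earns ``match_reward``;
    * a skipped label on either map costs ``skip_penalty`` (missed or false
      labels);
    * a step whose distance discrepancy is within the sizing tolerance
      ``max(sizing_tol_bp, sizing_tol_rel * ref_distance)`` is free;
    * any larger discrepancy must be taken as an SV jump with a flat cost
      ``jump_penalty``, independent of its size and of how many labels it
      spans (the labels consumed by the event itself are not billed).

    A real SV therefore costs one jump, while explaining it away costs one
    jump per out-of-tolerance interval of the bridge, so truthful paths win.
    Returns the optimal monotone matching under this score.

    Default calibration (in units of ``match_reward``): ``jump_penalty`` must
    exceed ``match_reward + skip_penalty`` so that mis-pairing a label inside
    a real event (earning a reward, paying a jump) never beats skipping it,
    and must stay below ``2 * match_reward`` so that two real events with at
    least two matchable labels between them are reported separately rather
    than as one net jump.
    """
    nr, nq = len(reference), len(query)
    if nr < 2 or nq < 2:
        raise ValueError("both maps need at least 2 labels")
    if band < 1:
        raise ValueError("band must be >= 1")
    r = reference.labels.astype(np.float64)
    q = query.labels.astype(np.float64)
    NEG = -np.inf
    JUMP = -2  # pointer code for an SV jump (origin in jump_from)

    S = np.full((nr, nq), NEG)
    P = np.full((nr, nq), -1, dtype=np.int32)  # -1 start, JUMP, or (a-1)*(band+1)+(b-1)
    jump_from = np.full((nr, nq), -1, dtype=np.int64)  # packed i*nq+j of jump origin

    # best score over all cells (i', j') with i' < current row, j' <= column,
    # plus a virtual start cell of score 0 (leading labels crossed by a jump
    # are free; plain leading skips are charged below).
    colmax = np.zeros(nq)  # running prefix max including the virtual start
    colarg = np.full(nq, -1, dtype=np.int64)

    dq = [q[b:] - q[:-b] for b in range(1, band + 2)]

    for i in range(nr):
        row = S[i]
        prow = P[i]
        # start as first matched pair, paying plain leading skips
        np.maximum(row, match_reward - skip_penalty * (i + np.arange(nq)), out=row)
        # SV jump from any earlier cell (or the start) strictly up-left
        if i > 0:
            cand = colmax[:-1] + match_reward - jump_penalty
            better = cand > row[1:]
            if better.any():
                row[1:][better] = cand[better]
                prow[1:][better] = JUMP
                jump_from[i, 1:][better] = colarg[:-1][better]
        # banded within-tolerance steps
        for a in range(1, min(band + 1, i) + 1):
            prev = S[i - a]
            dr = r[i] - r[i - a]
            tol = max(float(sizing_tol_bp), sizing_tol_rel * dr)
            base = match_reward - skip_penalty * (a - 1)
            for b in range(1, min(band + 1, nq - 1) + 1):
                cand = prev[:-b] + base - skip_penalty * (b - 1)
                cand[np.abs(dq[b - 1] - dr) > tol] = NEG
                seg = row[b:]
                better = cand > seg
                if better.any():
                    seg[better] = cand[better]
                    prow[b:][better] = (a - 1) * (band + 1) + (b - 1)
        rowbest = np.maximum.accumulate(row)
        upd = rowbest > colmax
        colmax[upd] = rowbest[upd]
        # argmax of the running prefix max within this row
        rowarg = np.maximum.accumulate(
            np.where(row == rowbest, i * nq + np.arange(nq), -1)
        )
        colarg[upd] = rowarg[upd]

    ii, jj = np.meshgrid(np.arange(nr), np.arange(nq), indexing="ij")
    trail = np.minimum(skip_penalty * ((nr - 1 - ii) + (nq - 1 - jj)), jump_penalty)
    total = S - trail
    flat = int(np.argmax(total))
    i, j = divmod(flat, nq)
    if not np.isfinite(total[i, j]):
        raise ValueError("no feasible alignment")
    best = float(total[i, j])

    pairs: list[tuple[int, int]] = []
    while True:
        pairs.append((int(i), int(j)))
        code = int(P[i, j])
        if code == -1:
            break
        if code == JUMP:
            origin = int(jump_from[i, j])
            if origin < 0:  # jumped in from the start
                break
            i, j = divmod(origin, nq)
        else:
            a = code // (band + 1) + 1
            b = code % (band + 1) + 1
            i, j = i - a, j - b
    pairs.reverse()
    return MapAlignment(pairs=pairs, score=best)


def detect_map_svs(
    alignment: MapAlignment,
    query: LabelMap,
    reference: LabelMap,
    line_id: str,
    min_size_map: int = MIN_OPTICAL_SV_SIZE,
) -> list[SVRecord]:
    """Insertions/deletions from inter-label distance discrepancies.

    For consecutive matched pairs, ``d = dq - dr``; ``d >= min_size_map`` is
    an optical insertion and ``d <= -min_size_map`` an optical deletion, both
    reported over the reference inter-label interval.
    """
    out: list[SVRecord] = []
    chrom = reference.chrom or reference.map_id
    r, q = reference.labels, query.labels
    for (i1, j1), (i2, j2) in zip(alignment.pairs, alignment.pairs[1:]):
        d = int(q[j2] - q[j1]) - int(r[i2] - r[i1])
        if abs(d) < min_size_map:
            continue
        out.append(
            SVRecord(line_id=line_id, chrom=chrom, start=int(r[i1]), end=int(r[i2]),
                     size_bp=abs(d), sv_type="insertion" if d > 0 else "deletion",
                     method="optical")
        )
    return out


def suppress_reflection_artifacts(
    calls: list[SVRecord],
    alignment: MapAlignment,
    query: LabelMap,
    reference: LabelMap,
    min_size_map: int = MIN_OPTICAL_SV_SIZE,
    max_span: int = 60_000,
    net_rel: float = 0.01,
    net_min: int = 500,
    reflect_tol: int = 150,
    min_match_frac: float = 0.75,
) -> list[SVRecord]:
    """Drop compensating insertion/deletion calls produced by an inversion.

    An inverted segment carries the mirror image of the reference label
    pattern.  Mirroring preserves pairwise label distances, so the aligner
    can profitably mis-pair labels across the segment and emit ladders of
    compensating +/- calls instead of crossing it in one size-neutral jump.
    Such ladders have two signatures no pair of real size-changing SVs
    shares: (1) the net size change over the window telescopes to ~0, and
    (2) the query labels inside the window are a reflection of the reference
    labels (a real insertion + deletion pair of equal size is net-zero but
    its interior labels match the reference directly, not mirrored).

    ``calls`` must be the output of :func:`detect_map_svs` for the same
    ``alignment``.  Consecutive calls whose enclosing window (bounded by the
    matched pairs just outside them) spans at most ``max_span`` on the
    reference, nets to within ``max(net_min, net_rel * span)``, and whose
    >= 3 interior labels reflect-match at fraction >= ``min_match_frac`` are
    removed; everything else is returned unchanged.
    """
    if not calls:
        return []
    r, q = reference.labels, query.labels
    # recover each call's generating step (same traversal as detect_map_svs)
    steps: list[int] = []
    for t, ((i1, j1), (i2, j2)) in enumerate(zip(alignment.pairs, alignment.pairs[1:])):
        d = int(q[j2] - q[j1]) - int(r[i2] - r[i1])
        if abs(d) >= min_size_map:
            steps.append(t)
    if len(steps) != len(calls):
        raise ValueError("calls do not correspond to this alignment")

    def _lis(seq: np.ndarray) -> int:
        """Length of the longest strictly increasing subsequence."""
        tails: list[int] = []
        for x in seq:
            pos = int(np.searchsorted(np.array(tails), x))
            if pos == len(tails):
                tails.append(int(x))
            else:
                tails[pos] = int(x)
        return len(tails)

    def _best_explained(u: np.ndarray, v: np.ndarray, images: np.ndarray,
                        candidates: np.ndarray, increasing: bool) -> int:
        """Max #query labels placed on reference labels (within reflect_tol)
        by one transform, order-consistently.  ``images`` is u mapped through
        the transform family at parameter 0; ``candidates`` the parameters."""
        best = 0
        for c in candidates:
            img = images + c
            k = np.clip(np.searchsorted(v, img), 1, len(v) - 1)
            pick = np.where(np.abs(v[k] - img) < np.abs(v[k - 1] - img), k, k - 1)
            matched = np.abs(v[pick] - img) <= reflect_tol
            if matched.sum() <= best:
                continue
            seq = pick[matched]
            best = max(best, _lis(seq if increasing else -seq))
        return best

    def reflects(i_lo: int, i_hi: int, j_lo: int, j_hi: int) -> bool:
        # >= 3 interior query labels make the mirror test non-vacuous (any
        # 2-label sets mirror-match trivially once the center is free)
        u = q[j_lo + 1 : j_hi].astype(np.int64)
        if len(u) < 3:
            return False
        # candidate mirror partners: reference labels in the window plus a
        # two-label margin, because the window ends may themselves be
        # mis-paired and the mirrored region need not coincide with them
        v = r[max(i_lo - 1, 0) : min(i_hi + 2, len(r))].astype(np.int64)
        if len(v) < 3:
            return False
        need = max(3, int(np.ceil(min_match_frac * len(u))))
        # Hough search for the mirror center: a reflection maps each query
        # label u to a reference label at C - u for one shared center C, so
        # every true (u, v) partner pair is a candidate C = u + v.  The
        # center C/2 must sit inside the window (a local inversion cannot
        # reflect about a far-away point).  Matches must reverse label order.
        centers = np.unique(u[:, None] + v[None, :])
        centers = centers[(centers >= 2 * r[i_lo]) & (centers <= 2 * r[i_hi])]
        mirror = _best_explained(u, v, -u, centers, increasing=False)
        if mirror < need:
            return False
        # a translated interior (the order-preserving bridge flanking a real
        # insertion+deletion pair) can by chance admit a decent mirror match;
        # suppress only when the mirror explains the window strictly better
        # than the best single translation does
        offsets = np.unique(u[:, None] - v[None, :])
        translation = _best_explained(u, v, u, -offsets, increasing=True)
        return mirror > translation

    drop = [False] * len(calls)
    k = 0
    while k < len(calls):
        if drop[k]:
            k += 1
            continue
        found = False
        i_lo, j_lo = alignment.pairs[steps[k]]
        for l in range(k, len(calls)):
            i_hi, j_hi = alignment.pairs[steps[l] + 1]
            span = int(r[i_hi] - r[i_lo])
            if span > max_span:
                break
            net = int(q[j_hi] - q[j_lo]) - span
            if abs(net) <= max(net_min, net_rel * span) and reflects(
                i_lo, i_hi, j_lo, j_hi
            ):
                for t in range(k, l + 1):
                    drop[t] = True
                k = l + 1
                found = True
                break
        if not found:
            k += 1
    return [c for c, dr in zip(calls, drop) if not dr]


def _padded_interval(sv: SVRecord, labels: np.ndarray | None, default_pad: int) -> tuple[int, int]:
    """SV interval padded by one flanking reference label interval per side
    (optical breakpoint uncertainty is bounded by label spacing)."""
    if labels is None or len(labels) < 2:
        return sv.start - default_pad, sv.end + default_pad
    i = int(np.searchsorted(labels, sv.start, side="right")) - 1
    lo = int(labels[max(i - 1, 0)]) if i >= 0 else 0
    j = int(np.searchsorted(labels, sv.end, side="left"))
    hi = int(labels[min(j + 1, len(labels) - 1)]) if j < len(labels) else int(labels[-1])
    return min(lo, sv.start), max(hi, sv.end)


def cross_validate(
    seq_svs: list[SVRecord],
    map_svs: list[SVRecord],
    ref_maps: dict[str, LabelMap] | None = None,
    default_pad: int = 2000,
) -> list[SVRecord]:
    """Mark sequence SVs independently supported by an optical SV.

    A sequence SV validates iff some optical SV of the same sign (gain
    classes vs optical insertion, loss classes vs optical deletion) has a
    reference interval overlapping the sequence SV's padded interval.  One
    optical SV may validate several sequence SVs.  Inversions have no optical
    size signal and are never validated.  Returns the validated records
    (copies with ``validated=True``).
    """
    optical_by_chrom: dict[str, list[SVRecord]] = {}
    for m in map_svs:
        if m.method != "optical":
            raise ValueError("map_svs must be optical calls")
        optical_by_chrom.setdefault(m.chrom, []).append(m)

    out: list[SVRecord] = []
    for sv in seq_svs:
        if sv.sv_type in GAIN_TYPES:
            want = "insertion"
        elif sv.sv_type in LOSS_TYPES:
            want = "deletion"
        else:
            continue
        labels = None
        if ref_maps is not None and sv.chrom in ref_maps:
            labels = ref_maps[sv.chrom].labels
        lo, hi = _padded_interval(sv, labels, default_pad)
        for m in optical_by_chrom.get(sv.chrom, ()):
            if m.sv_type == want and m.start < hi and lo < m.end:
                out.append(
                    SVRecord(sv.line_id, sv.chrom, sv.start, sv.end, sv.size_bp,
                             sv.sv_type, sv.method, validated=True)
                )
                break
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_label_maps(maps: list[LabelMap], path) -> None:
    """Plain-text label maps: a ``#<map_id>\\t<length_bp>`` header per map,
    then one label position per row."""
    with open(path, "w") as fh:
        fh.write("#map_id\tlength_bp\n")
        for m in maps:
            fh.write(f"#{m.map_id}\t{m.length_bp}\n")
            for p in m.labels:
                fh.write(f"{int(p)}\n")


def read_label_maps(path) -> list[LabelMap]:
    maps: list[LabelMap] = []
    cur_id, cur_len, cur_labels = None, None, []

    def flush():
        if cur_id is not None:
            maps.append(LabelMap(map_id=cur_id, length_bp=cur_len,
                                 labels=np.array(cur_labels, dtype=np.int64)))

    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:]
                if body.startswith("map_id"):
                    continue
                flush()
                parts = body.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{ln}: bad map header")
                cur_id, cur_len, cur_labels = parts[0], int(parts[1]), []
            else:
                if cur_id is None:
                    raise ValueError(f"{path}:{ln}: label before any map header")
                cur_labels.append(int(line))
    flush()
    return maps


def read_cmap(path) -> list[LabelMap]:
    """Reader for the documented CMAP text layout (column subset CMapId,
    ContigLength, Position); label-channel end markers (LabelChannel 0) are
    skipped when that column is present."""
    with open(path) as fh:
        lines = fh.readlines()
    header_cols: list[str] | None = None
    rows: list[list[str]] = []
    for line in lines:
        line = line.rstrip("\n")
        if line.startswith("#h"):
            header_cols = line[2:].strip().lstrip("\t ").replace("\t", " ").split()
        elif line.startswith("#") or not line.strip():
            continue
        else:
            rows.append(line.split())
    if header_cols is None:
        raise ValueError(f"{path}: no #h column header line")
    try:
        c_id = header_cols.index("CMapId")
        c_len = header_cols.index("ContigLength")
        c_pos = header_cols.index("Position")
    except ValueError as exc:
        raise ValueError(f"{path}: required CMAP column missing: {exc}") from None
    c_chan = header_cols.index("LabelChannel") if "LabelChannel" in header_cols else None

    grouped: dict[str, tuple[int, list[int]]] = {}
    for row in rows:
        mid = row[c_id]
        length = int(float(row[c_len]))
        if c_chan is not None and row[c_chan] == "0":
            grouped.setdefault(mid, (length, []))
            continue
        pos = int(round(float(row[c_pos])))
        grouped.setdefault(mid, (length, []))[1].append(pos)
    return [
        LabelMap(map_id=mid, length_bp=length, labels=np.array(sorted(set(pos)), dtype=np.int64))
        for mid, (length, pos) in grouped.items()
    ]
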