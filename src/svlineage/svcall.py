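"""Sequence-based structural-variant calling from alignment blocks.

The caller inspects the gap between consecutive collinear blocks on the
reference and on the query.  The signed discrepancy between the two gaps is
the SV size, and the sign pattern of the two gaps assigns one of six classes
(the scheme popularized by gap-based assembly comparison tools):

===================  =========  ===========
class                ref gap    query gap
===================  =========  ===========
insertion            >= 0       >= 0
tandem_expansion     < 0        >= 0
repeat_expansion     < 0        < 0
deletion             >= 0       >= 0  (size < 0)
tandem_contraction   >= 0       < 0
repeat_contraction   < 0        < 0
===================  =========  ===========

A negative gap means the blocks overlap on that genome, i.e. the breakpoint
falls in self-similar (tandem or repeated) sequence.  Variants smaller than
50 bp are not structural variants and are never reported; a configurable
ceiling (default 50 kb) removes chain artifacts.  Inversions are detected
separately as strand-flipped block runs flanked by forward blocks.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .align import AlignmentBlock, Chain

__all__ = [
    "SVRecord",
    "classify_gap",
    "call_between_alignments",
    "call_within_alignment",
    "detect_inversions",
    "write_svs",
    "read_svs",
    "write_assemblytics_tsv",
    "GAIN_TYPES",
    "LOSS_TYPES",
    "MIN_SV_SIZE",
    "MAX_SV_SIZE",
]

MIN_SV_SIZE = 50
MAX_SV_SIZE = 50_000

GAIN_TYPES = frozenset({"insertion", "tandem_expansion", "repeat_expansion"})
LOSS_TYPES = frozenset({"deletion", "tandem_contraction", "repeat_contraction"})


@dataclass
class SVRecord:
    """One structural variant anchored on reference coordinates."""

    line_id: str
    chrom: str
    start: int
    end: int
    size_bp: int
    sv_type: str
    method: str = "sequence"
    validated: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if self.start < 0:
            raise ValueError("negative coordinate")
        if self.size_bp <= 0:
            raise ValueError("size_bp must be positive")
        if self.method not in ("sequence", "optical"):
            raise ValueError(f"bad method {self.method!r}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.sv_type)


def classify_gap(
    ref_gap: int,
    query_gap: int,
    min_size: int = MIN_SV_SIZE,
    max_size: int = MAX_SV_SIZE,
) -> tuple[str, int] | None:
    """Classify the discrepancy between a reference gap and a query gap.

    Returns ``(sv_type, size_bp)`` or ``None`` when the size falls outside
    [min_size, max_size] (ties with size 0 are never calls).
    """
    size = query_gap - ref_gap
    if abs(size) < min_size or abs(size) > max_size:
        return None
    if size > 0:
        if ref_gap >= 0:
            sv_type = "insertion"
        elif query_gap >= 0:
            sv_type = "tandem_expansion"
        else:
            sv_type = "repeat_expansion"
    else:
        if query_gap >= 0:
            sv_type = "deletion"
        elif ref_gap >= 0:
            sv_type = "tandem_contraction"
        else:
            sv_type = "repeat_contraction"
    return sv_type, abs(size)


def call_between_alignments(
    chain: Chain,
    line_id: str,
    min_size: int = MIN_SV_SIZE,
    max_size: int = MAX_SV_SIZE,
) -> list[SVRecord]:
    """Call SVs between consecutive blocks of one chain.

    The reference interval of a ref-consuming call spans
    ``[min(ref_end1, ref_start2), max(ref_end1, ref_start2))`` (the gap, or
    the overlap when blocks overlap); insertions get a zero-length anchor
    point at the junction.
    """
    out: list[SVRecord] = []
    blocks = chain.blocks
    for b1, b2 in zip(blocks, blocks[1:]):
        ref_gap = b2.ref_start - b1.ref_end
        if chain.strand == "+":
            query_gap = b2.query_start - b1.query_end
        else:
            query_gap = b1.query_start - b2.query_end
        hit = classify_gap(ref_gap, query_gap, min_size, max_size)
        if hit is None:
            continue
        sv_type, size = hit
        if sv_type == "insertion":
            start = end = b1.ref_end
        else:
            start = min(b1.ref_end, b2.ref_start)
            end = max(b1.ref_end, b2.ref_start)
        out.append(
            SVRecord(line_id=line_id, chrom=chain.ref_chrom, start=start, end=end,
                     size_bp=size, sv_type=sv_type, method="sequence")
        )
    return out


_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def call_within_alignment(
    block: AlignmentBlock,
    line_id: str,
    min_size: int = MIN_SV_SIZE,
    max_size: int = MAX_SV_SIZE,
) -> list[SVRecord]:
    """Indels inside a single aligned block, read off its CIGAR (external PAF
    input; the internal exact anchors are gap-free by construction)."""
    if not block.cigar:
        raise ValueError("block has no CIGAR")
    ops = _CIG_RE.findall(block.cigar)
    if "".join(f"{n}{o}" for n, o in ops) != block.cigar:
        raise ValueError(f"unparseable CIGAR {block.cigar!r}")
    ref_len = sum(int(n) for n, o in ops if o in "MDN=X")
    q_len = sum(int(n) for n, o in ops if o in "MI=X")
    if ref_len != block.ref_len or q_len != block.query_len:
        raise ValueError(
            f"CIGAR walks ref {ref_len} bp / query {q_len} bp but block spans "
            f"{block.ref_len} / {block.query_len}"
        )
    out: list[SVRecord] = []
    rpos = block.ref_start
    for n, op in ops:
        n = int(n)
        if op in "M=X":
            rpos += n
        elif op in "DN":
            if min_size <= n <= max_size:
                out.append(SVRecord(line_id, block.ref_chrom, rpos, rpos + n, n,
                                    "deletion", "sequence"))
            rpos += n
        elif op == "I":
            if min_size <= n <= max_size:
                out.append(SVRecord(line_id, block.ref_chrom, rpos, rpos, n,
                                    "insertion", "sequence"))
    return out


def detect_inversions(
    chains: list[Chain],
    line_id: str,
    min_size: int = 10_000,
    max_flank_gap: int = 50_000,
) -> list[SVRecord]:
    """Report maximal runs of minus-strand blocks flanked on both sides by
    plus-strand blocks of the same query chromosome as inversions.

    The query interval of the run must sit between the flanking blocks'
    query intervals (the signature of a reversed segment); a pure
    reverse-complement chromosome has no forward flank and is not called.
    """
    by_pair: dict[tuple, list[AlignmentBlock]] = {}
    for chain in chains:
        for b in chain.blocks:
            by_pair.setdefault((b.ref_chrom, b.query_chrom), []).append(b)

    out: list[SVRecord] = []
    for (ref_chrom, _), blocks in sorted(by_pair.items()):
        blocks = sorted(blocks, key=lambda b: (b.ref_start, b.ref_end))
        i = 0
        while i < len(blocks):
            if blocks[i].strand != "-":
                i += 1
                continue
            j = i
            while j + 1 < len(blocks) and blocks[j + 1].strand == "-":
                j += 1
            left = blocks[i - 1] if i > 0 else None
            right = blocks[j + 1] if j + 1 < len(blocks) else None
            run = blocks[i : j + 1]
            if left is not None and right is not None and left.strand == "+" and right.strand == "+":
                q_lo = min(b.query_start for b in run)
                q_hi = max(b.query_end for b in run)
                consistent = (
                    q_lo >= left.query_end - max_flank_gap
                    and q_hi <= right.query_start + max_flank_gap
                )
                span_start = run[0].ref_start
                span_end = run[-1].ref_end
                if consistent and span_end - span_start >= min_size:
                    out.append(
                        SVRecord(line_id, ref_chrom, span_start, span_end,
                                 span_end - span_start, "inversion", "sequence")
                    )
            i = j + 1
    return out


# ---------------------------------------------------------------------------
# BED6+3 I/O
# ---------------------------------------------------------------------------


def write_svs(records: list[SVRecord], path) -> None:
    """BED6+3: chrom, start, end, name=line:type, score=size, strand='.',
    then sv_type, method, validated."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.line_id}:{r.sv_type}\t{r.size_bp}"
                f"\t.\t{r.sv_type}\t{r.method}\t{int(r.validated)}\n"
            )


def read_svs(path) -> list[SVRecord]:
    out: list[SVRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: row {ln}: expected 9 columns, got {len(f)}")
            try:
                start, end, size = int(f[1]), int(f[2]), int(f[4])
                validated = bool(int(f[8]))
            except ValueError as exc:
                raise ValueError(f"{path}: row {ln}: {exc}") from None
            if start < 0:
                raise ValueError(f"{path}: row {ln}: negative coordinate")
            line_id = f[3].rsplit(":", 1)[0]
            out.append(
                SVRecord(line_id=line_id, chrom=f[0], start=start, end=end,
                         size_bp=size, sv_type=f[6], method=f[7], validated=validated)
            )
    return out


def write_assemblytics_tsv(records: list[SVRecord], path) -> None:
    """Interoperability export using the column names of the Assemblytics
    between-alignment variant table."""
    header = (
        "reference\tref_start\tref_stop\tID\tsize\tstrand\ttype\t"
        "ref_gap_size\tquery_gap_size\tquery_coordinates\tmethod\n"
    )
    names = {
        "insertion": "Insertion",
        "deletion": "Deletion",
        "tandem_expansion": "Tandem_expansion",
        "tandem_contraction": "Tandem_contraction",
        "repeat_expansion": "Repeat_expansion",
        "repeat_contraction": "Repeat_contraction",
        "inversion": "Inversion",
    }
    with open(path, "w") as fh:
        fh.write(header)
        for i, r in enumerate(records, start=1):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tsv_{i}\t{r.size_bp}\t+\t"
                f"{names[r.sv_type]}\t.\t.\t{r.line_id}\t{r.method}\n"
            )
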