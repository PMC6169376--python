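"""Exonic impact of structural variants.

Intersects SV reference intervals with exon annotations and summarizes how
many exons, SVs and base pairs each variant class touches.  The module is
policy-free: the pipeline decides which SVs to feed it (by default only
those cross-validated by the optical maps).

Conventions: intervals are 0-based half-open.  A zero-length insertion
overlaps an exon iff its insertion point falls strictly inside the exon; its
base-pair contribution is the full inserted length (an inserted sequence at
an exonic point disrupts that exon along its whole length, and insertions
have no reference span to measure instead).
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass

from .svcall import SVRecord

__all__ = [
    "ExonRecord",
    "OverlapRecord",
    "intersect_exons",
    "exon_impact_summary",
    "write_exons_bed",
    "read_exons_bed",
    "write_exons_gff3",
    "read_exons_gff3",
    "write_overlaps_tsv",
]


@dataclass
class ExonRecord:
    chrom: str
    start: int
    end: int
    gene_id: str
    exon_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("exon must have positive length")
        if self.start < 0:
            raise ValueError("negative exon coordinate")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class OverlapRecord:
    sv: SVRecord
    exon: ExonRecord
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.overlap_bp < 0:
            raise ValueError("negative overlap")


def _sv_overlaps_exon(sv: SVRecord, exon: ExonRecord) -> int | None:
    """Overlap in bp, or None when disjoint.  Insertions overlap (with 0 bp)
    iff the insertion point is strictly inside the exon."""
    if sv.chrom != exon.chrom:
        return None
    if sv.start == sv.end:  # insertion point
        return 0 if exon.start < sv.start < exon.end else None
    ovl = min(sv.end, exon.end) - max(sv.start, exon.start)
    return ovl if ovl > 0 else None


def intersect_exons(svs: list[SVRecord], exons: list[ExonRecord]) -> list[OverlapRecord]:
    """All (SV, exon) pairs with positive interval overlap, plus insertion
    points inside exons, by a sorted sweep in O((n+m) log(n+m)) plus output.
    """
    out: list[OverlapRecord] = []
    by_chrom_sv: dict[str, list[SVRecord]] = {}
    by_chrom_ex: dict[str, list[ExonRecord]] = {}
    for sv in svs:
        by_chrom_sv.setdefault(sv.chrom, []).append(sv)
    for ex in exons:
        by_chrom_ex.setdefault(ex.chrom, []).append(ex)

    for chrom in sorted(set(by_chrom_sv) & set(by_chrom_ex)):
        svl = sorted(by_chrom_sv[chrom], key=lambda s: (s.start, s.end))
        exl = sorted(by_chrom_ex[chrom], key=lambda e: (e.start, e.end))
        active: list[tuple[int, int]] = []  # (exon_end, index into exl)
        ei = 0
        for sv in svl:
            while ei < len(exl) and exl[ei].start <= sv.start:
                heapq.heappush(active, (exl[ei].end, ei))
                ei += 1
            while active and active[0][0] <= sv.start:
                heapq.heappop(active)
            # exons already started (start <= sv.start) and still open
            for _, k in active:
                ovl = _sv_overlaps_exon(sv, exl[k])
                if ovl is not None:
                    out.append(OverlapRecord(sv=sv, exon=exl[k], overlap_bp=ovl))
            # exons starting inside the SV span
            ej = ei
            while ej < len(exl) and exl[ej].start < sv.end:
                ovl = _sv_overlaps_exon(sv, exl[ej])
                if ovl is not None:
                    out.append(OverlapRecord(sv=sv, exon=exl[ej], overlap_bp=ovl))
                ej += 1
    return out


def exon_impact_summary(
    overlaps: list[OverlapRecord],
    svs: list[SVRecord],
    lines: list[str],
) -> tuple[dict[str, int], dict[str, int], dict[str, int]]:
    """Per-line distinct affected exons, per-class SV counts (distinct SVs
    with >= 1 exon overlap), and per-class affected base pairs.

    Reference-consuming classes contribute the summed overlap; insertions
    contribute their full inserted length when the insertion point is exonic.
    """
    per_line_exons: dict[str, set] = {l: set() for l in lines}
    per_class_svs: dict[str, set] = {}
    per_class_bp: dict[str, int] = {}
    for ov in overlaps:
        sv = ov.sv
        if sv.line_id in per_line_exons:
            per_line_exons[sv.line_id].add(ov.exon.exon_id)
        per_class_svs.setdefault(sv.sv_type, set()).add(
            (sv.line_id, sv.chrom, sv.start, sv.end)
        )
        bp = sv.size_bp if sv.start == sv.end else ov.overlap_bp
        per_class_bp[sv.sv_type] = per_class_bp.get(sv.sv_type, 0) + bp
    per_line_count = {l: len(s) for l, s in per_line_exons.items()}
    per_class_count = {t: len(s) for t, s in per_class_svs.items()}
    return per_line_count, per_class_count, per_class_bp


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------


def write_exons_bed(exons: list[ExonRecord], path) -> None:
    """BED6 with name = gene_id|exon_id."""
    with open(path, "w") as fh:
        for e in exons:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.gene_id}|{e.exon_id}\t0\t+\n")


def read_exons_bed(path) -> list[ExonRecord]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{ln}: BED needs >= 4 columns")
            gene_id, _, exon_id = f[3].partition("|")
            out.append(ExonRecord(chrom=f[0], start=int(f[1]), end=int(f[2]),
                                  gene_id=gene_id, exon_id=exon_id or f[3]))
    return out


def write_exons_gff3(exons: list[ExonRecord], path, source: str = "svlineage") -> None:
    """GFF3 exon features (1-based closed coordinates on write)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in exons:
            fh.write(
                f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t+\t.\t"
                f"ID={e.exon_id};Parent={e.gene_id}\n"
            )


def read_exons_gff3(path) -> list[ExonRecord]:
    """Read features of type 'exon' only, converting to 0-based half-open."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out = []
    for f in db.features_of_type("exon"):
        exon_id = (f.attributes.get("ID") or [f.id])[0]
        gene_id = (f.attributes.get("Parent") or [""])[0]
        out.append(ExonRecord(chrom=f.seqid, start=f.start - 1, end=f.end,
                              gene_id=gene_id, exon_id=exon_id))
    out.sort(key=lambda e: (e.chrom, e.start, e.end))
    return out


def write_overlaps_tsv(overlaps: list[OverlapRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("line\tchrom\tsv_start\tsv_end\tsv_type\texon_id\tgene_id\toverlap_bp\n")
        for ov in overlaps:
            s = ov.sv
            fh.write(
                f"{s.line_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.sv_type}\t"
                f"{ov.exon.exon_id}\t{ov.exon.gene_id}\t{ov.overlap_bp}\n"
            )
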