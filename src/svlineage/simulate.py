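"""Synthetic genome cohorts with planted structural variants.

Generates a random ancestral ("reference") genome seeded with tandem arrays
and dispersed repeats, then derives line genomes by planting structural
variants (SVs) of six size-changing classes plus inversions along the
branches of a known line tree.  Every planted event is recorded in a
:class:`TruthTable`, which downstream modules use to score recovery.

Coordinates are 0-based half-open throughout and always refer to the
ancestral (reference) genome; an insertion is a zero-length reference
interval at the insertion point.
"""
from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Genome",
    "LineTree",
    "TruthRecord",
    "TruthTable",
    "RepeatConfig",
    "AncestorFeatures",
    "TandemArray",
    "simulate_ancestor",
    "plant_svs",
    "simulate_truth_table",
    "simulate_annotation",
    "simulate_label_map",
    "random_sequence",
    "revcomp",
    "SV_TYPES",
    "DEFAULT_TYPE_WEIGHTS",
    "log_uniform_sizes",
]

SV_TYPES = (
    "insertion",
    "deletion",
    "tandem_expansion",
    "tandem_contraction",
    "repeat_expansion",
    "repeat_contraction",
    "inversion",
)

#: Default mixture of event classes drawn per branch.  Indels dominate (as in
#: real long-read call sets), copy-number changes on repeats are less common
#: and large inversions are rare.
DEFAULT_TYPE_WEIGHTS = {
    "insertion": 0.30,
    "deletion": 0.30,
    "tandem_expansion": 0.085,
    "tandem_contraction": 0.085,
    "repeat_expansion": 0.085,
    "repeat_contraction": 0.085,
    "inversion": 0.06,
}

_COMP = str.maketrans("ACGT", "TGCA")
_BYTE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMP)[::-1]


def random_sequence(n: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT string of length ``n``."""
    if n < 0:
        raise ValueError("sequence length must be non-negative")
    return _BYTE_LUT[rng.integers(0, 4, n)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """A haploid genome: ordered chromosomes of ACGT sequence."""

    id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def validate_alphabet(self) -> None:
        for name, seq in self.sequences.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name!r} contains non-ACGT characters")

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        records = [
            SeqRecord(Seq(seq), id=name, description=f"line={self.id}")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, genome_id: str | None = None) -> "Genome":
        from Bio import SeqIO

        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls(id=genome_id or str(path), sequences=seqs)


@dataclass
class LineTree:
    """Rooted line tree: branches are (parent, child, length) in abstract time
    units.  Leaves are the sequenced lines; a stem branch above the common
    ancestor models divergence of the whole cohort from the reference lineage
    (events there are carried by every line)."""

    root: str
    branches: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        parents = {p for p, _, _ in self.branches}
        children = {c for c, _ in self._child_map().items()}
        nodes = parents | {c for _, c, _ in self.branches} | {self.root}
        # connectivity + acyclicity: every node except root has exactly one parent
        seen_child: set[str] = set()
        for _, c, L in self.branches:
            if c in seen_child:
                raise ValueError(f"node {c!r} has two parents")
            if L < 0:
                raise ValueError("branch lengths must be >= 0")
            seen_child.add(c)
        if self.root in seen_child:
            raise ValueError("root cannot have a parent")
        for leaf in self.leaves():
            if leaf not in self.reachable_from_root():
                raise ValueError(f"leaf {leaf!r} unreachable from root")
        del children, nodes

    def _child_map(self) -> dict[str, list[str]]:
        m: dict[str, list[str]] = {}
        for p, c, _ in self.branches:
            m.setdefault(p, []).append(c)
        return m

    def reachable_from_root(self) -> set[str]:
        m = self._child_map()
        out, stack = set(), [self.root]
        while stack:
            n = stack.pop()
            if n in out:
                raise ValueError("tree contains a cycle")
            out.add(n)
            stack.extend(m.get(n, ()))
        return out

    def leaves(self) -> list[str]:
        m = self._child_map()
        return sorted(n for n in self.reachable_from_root() if n not in m)

    def leaves_under(self, node: str) -> frozenset[str]:
        m = self._child_map()
        out, stack = set(), [node]
        while stack:
            n = stack.pop()
            kids = m.get(n)
            if kids:
                stack.extend(kids)
            else:
                out.add(n)
        return frozenset(out)

    @classmethod
    def default(cls) -> "LineTree":
        """Five-line cohort (one line per continent of origin, named after the
        study design) below a stem branch that represents divergence from the
        reference lineage."""
        return cls(
            root="REF",
            branches=[
                ("REF", "anc", 1.0),
                ("anc", "p1", 1.0),
                ("anc", "p2", 1.0),
                ("p1", "B10", 1.0),
                ("p1", "I03", 1.0),
                ("p2", "ZH26", 2.0),
                ("p2", "p3", 1.0),
                ("p3", "N15", 1.0),
                ("p3", "T29", 1.0),
            ],
        )


_SIGN = {
    "insertion": 1,
    "tandem_expansion": 1,
    "repeat_expansion": 1,
    "deletion": -1,
    "tandem_contraction": -1,
    "repeat_contraction": -1,
    "inversion": 0,
}


@dataclass
class TruthRecord:
    """One planted SV event, on reference coordinates."""

    branch_id: str
    sv_type: str
    chrom: str
    ref_start: int
    ref_end: int
    size_bp: int
    carrier_lines: frozenset[str]

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.size_bp < 50:
            raise ValueError("planted SVs must be >= 50 bp")
        if self.ref_end < self.ref_start:
            raise ValueError("ref_end < ref_start")

    @property
    def signed_size(self) -> int:
        """Length change of a carrier genome relative to the reference."""
        return _SIGN[self.sv_type] * self.size_bp


@dataclass
class TruthTable:
    records: list[TruthRecord]
    params: dict = field(default_factory=dict)

    def for_line(self, line_id: str) -> list[TruthRecord]:
        return [r for r in self.records if line_id in r.carrier_lines]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("branch_id\ttype\tchrom\tref_start\tref_end\tsize\tcarriers\n")
            for r in self.records:
                fh.write(
                    f"{r.branch_id}\t{r.sv_type}\t{r.chrom}\t{r.ref_start}\t"
                    f"{r.ref_end}\t{r.size_bp}\t{','.join(sorted(r.carrier_lines))}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        records = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("branch_id"):
                raise ValueError(f"{path}: missing truth-table header")
            for ln, line in enumerate(fh, start=2):
                f = line.rstrip("\n").split("\t")
                if len(f) != 7:
                    raise ValueError(f"{path}:{ln}: expected 7 columns")
                records.append(
                    TruthRecord(
                        branch_id=f[0],
                        sv_type=f[1],
                        chrom=f[2],
                        ref_start=int(f[3]),
                        ref_end=int(f[4]),
                        size_bp=int(f[5]),
                        carrier_lines=frozenset(f[6].split(",")) if f[6] else frozenset(),
                    )
                )
        return cls(records=records)


# ---------------------------------------------------------------------------
# Ancestor simulation
# ---------------------------------------------------------------------------


@dataclass
class RepeatConfig:
    """Repeat content of the ancestral genome.

    Tandem arrays host planted copy-number events, so the array count should
    comfortably exceed the expected number of tandem/repeat events.  Copy
    counts start at 10 so that every class of copy-number change (including a
    sub-half-array contraction of >= 50 bp) is feasible on any array.
    """

    tandem_array_count: int = 260
    tandem_unit_range: tuple[int, int] = (15, 40)
    tandem_copy_range: tuple[int, int] = (10, 25)
    dispersed_repeat_length: int = 500
    dispersed_repeat_count: int = 20


@dataclass
class TandemArray:
    chrom: str
    start: int
    end: int
    unit: str
    copies: int

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class AncestorFeatures:
    tandem_arrays: list[TandemArray]
    dispersed_repeats: list[tuple[str, int, int]]

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        out = [(a.start, a.end) for a in self.tandem_arrays if a.chrom == chrom]
        out += [(s, e) for c, s, e in self.dispersed_repeats if c == chrom]
        return sorted(out)


def simulate_ancestor(
    length_bp: int,
    n_chroms: int = 2,
    repeat_config: RepeatConfig | None = None,
    seed: int = 0,
) -> tuple[Genome, AncestorFeatures]:
    """Random ancestral genome of ``length_bp`` background sequence plus
    inserted repeat features (final length exceeds ``length_bp`` by the total
    feature footprint).  Feature coordinates are returned for SV planting.
    """
    cfg = repeat_config or RepeatConfig()
    if length_bp <= 0 or n_chroms <= 0:
        raise ValueError("length_bp and n_chroms must be positive")
    if cfg.tandem_array_count < 0 or cfg.dispersed_repeat_count < 0:
        raise ValueError("feature counts must be non-negative")
    if cfg.dispersed_repeat_count > 0 and length_bp < 10 * cfg.dispersed_repeat_length:
        raise ValueError("genome too short for requested dispersed repeats")

    rng = np.random.default_rng(seed)
    base_len = [length_bp // n_chroms] * n_chroms
    base_len[0] += length_bp - sum(base_len)

    # one repeat family shared by all dispersed copies
    dispersed_seq = random_sequence(cfg.dispersed_repeat_length, rng)

    # allocate features to chromosomes proportionally to length
    n_feat = cfg.tandem_array_count + cfg.dispersed_repeat_count
    chrom_of = rng.choice(n_chroms, size=n_feat, p=np.array(base_len) / length_bp)
    feat_kind = np.array([0] * cfg.tandem_array_count + [1] * cfg.dispersed_repeat_count)

    sequences: dict[str, str] = {}
    arrays: list[TandemArray] = []
    dispersed: list[tuple[str, int, int]] = []
    for ci in range(n_chroms):
        cname = f"chr{ci + 1}"
        L = base_len[ci]
        base = random_sequence(L, rng)
        kinds = feat_kind[chrom_of == ci]
        # insertion points in base coordinates, >= 2 kb apart, away from ends
        points: list[int] = []
        for _ in range(len(kinds)):
            for _attempt in range(500):
                p = int(rng.integers(10_000, max(10_001, L - 10_000)))
                i = bisect_left(points, p)
                ok = (i == 0 or p - points[i - 1] >= 2000) and (
                    i == len(points) or points[i] - p >= 2000
                )
                if ok:
                    insort(points, p)
                    break
            else:
                raise ValueError("could not place repeat features >= 2 kb apart")
        rng.shuffle(kinds)
        pieces: list[str] = []
        cur = 0
        offset = 0
        for p, kind in zip(points, kinds):
            pieces.append(base[cur:p])
            if kind == 0:
                u = int(rng.integers(cfg.tandem_unit_range[0], cfg.tandem_unit_range[1] + 1))
                c = int(rng.integers(cfg.tandem_copy_range[0], cfg.tandem_copy_range[1] + 1))
                unit = random_sequence(u, rng)
                feat = unit * c
                arrays.append(
                    TandemArray(cname, p + offset, p + offset + len(feat), unit, c)
                )
            else:
                feat = dispersed_seq
                dispersed.append((cname, p + offset, p + offset + len(feat)))
            pieces.append(feat)
            offset += len(feat)
            cur = p
        pieces.append(base[cur:])
        sequences[cname] = "".join(pieces)

    genome = Genome(id="ancestor", sequences=sequences)
    return genome, AncestorFeatures(tandem_arrays=arrays, dispersed_repeats=dispersed)


# ---------------------------------------------------------------------------
# SV planting
# ---------------------------------------------------------------------------


def log_uniform_sizes(lo: int = 50, hi: int = 10_000) -> Callable[[np.random.Generator], int]:
    """Log-uniform integer size sampler on [lo, hi] (default 50 bp – 10 kb)."""
    if not (0 < lo <= hi):
        raise ValueError("invalid size range")
    lg_lo, lg_hi = math.log(lo), math.log(hi)

    def sample(rng: np.random.Generator) -> int:
        return int(round(math.exp(rng.uniform(lg_lo, lg_hi))))

    return sample


class _Occupancy:
    """Sorted non-overlapping intervals per chromosome with a minimum-gap rule."""

    def __init__(self, min_gap: int) -> None:
        self.min_gap = min_gap
        self._iv: dict[str, list[tuple[int, int]]] = {}

    def fits(self, chrom: str, start: int, end: int) -> bool:
        iv = self._iv.get(chrom, [])
        i = bisect_left(iv, (start, end))
        if i > 0 and start - iv[i - 1][1] < self.min_gap:
            return False
        if i < len(iv) and iv[i][0] - end < self.min_gap:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self._iv.setdefault(chrom, []), (start, end))


def _near_feature(points: Sequence[int], intervals: list[tuple[int, int]], margin: int) -> bool:
    """True if any breakpoint in ``points`` lies within ``margin`` of a feature
    interval (features may still be fully contained between breakpoints)."""
    for p in points:
        for s, e in intervals:  # intervals per chrom are few hundred at most
            if s - margin < p < e + margin:
                return True
    return False


def _pick_copy_change(sv_type: str, array: TandemArray, rng: np.random.Generator) -> int | None:
    """Number of unit copies gained/lost so the planted event carries the gap
    signature of its class: with exact-match flanking alignment a gain G on an
    array of span A shows ref overlap A and query gap G-A, hence the class
    boundary sits at G = A for expansions and G = A/2 for contractions.  A
    one-unit margin keeps events away from those boundaries."""
    u, c = array.unit_len, array.copies
    k_floor = math.ceil(50 / u)  # SV definition: >= 50 bp
    if sv_type == "tandem_expansion":
        lo = max(c + 1, k_floor)
        hi = lo + c
    elif sv_type == "repeat_expansion":
        lo, hi = k_floor, c - 1
    elif sv_type == "tandem_contraction":
        lo = max(math.ceil(c / 2) + 1, k_floor)
        hi = c - 2
    elif sv_type == "repeat_contraction":
        lo, hi = k_floor, c // 2 - 1
    else:  # pragma: no cover
        raise ValueError(sv_type)
    if lo > hi:
        return None
    return int(rng.integers(lo, hi + 1))


def plant_svs(
    ancestor: Genome,
    features: AncestorFeatures,
    tree: LineTree,
    rate_per_branch: float = 40.0,
    size_sampler: Callable[[np.random.Generator], int] | None = None,
    type_weights: dict[str, float] | None = None,
    inversion_size_range: tuple[int, int] = (12_000, 30_000),
    min_locus_gap: int = 2000,
    max_attempts: int = 300,
    seed: int = 0,
) -> tuple[dict[str, Genome], TruthTable]:
    """Plant Poisson(rate x branch length) SV events per branch and build the
    leaf genomes.  Loci are pairwise non-overlapping on the reference and kept
    ``min_locus_gap`` apart, so every event has its own flanking anchors."""
    weights = dict(type_weights or DEFAULT_TYPE_WEIGHTS)
    if any(w < 0 for w in weights.values()) or not any(w > 0 for w in weights.values()):
        raise ValueError("type weights must be non-negative and not all zero")
    if rate_per_branch < 0:
        raise ValueError("rate_per_branch must be >= 0")
    for t in weights:
        if t not in SV_TYPES:
            raise ValueError(f"unknown sv_type {t!r} in weights")
    sampler = size_sampler or log_uniform_sizes()
    rng = np.random.default_rng(seed)

    types = sorted(weights)
    p = np.array([weights[t] for t in types], dtype=float)
    p /= p.sum()

    chroms = ancestor.chrom_names
    clen = ancestor.lengths
    occupied = _Occupancy(min_locus_gap)
    feat_iv = {c: features.intervals(c) for c in chroms}
    free_arrays = list(features.tandem_arrays)

    edits: dict[str, list[tuple[str, int, int, str]]] = {}  # branch child -> edits
    records: list[TruthRecord] = []

    def pick_chrom() -> str:
        w = np.array([clen[c] for c in chroms], dtype=float)
        return chroms[rng.choice(len(chroms), p=w / w.sum())]

    def place_interval(size: int, margin_feats: bool) -> tuple[str, int] | None:
        for _ in range(max_attempts):
            chrom = pick_chrom()
            if clen[chrom] <= size + 20_000:
                continue
            s = int(rng.integers(10_000, clen[chrom] - size - 10_000))
            if not occupied.fits(chrom, s, s + size):
                continue
            if margin_feats and _near_feature((s, s + size), feat_iv[chrom], 200):
                continue
            return chrom, s
        return None

    for parent, child, blen in sorted(tree.branches, key=lambda b: (b[0], b[1])):
        carriers = tree.leaves_under(child)
        if not carriers:
            continue
        n_events = rng.poisson(rate_per_branch * blen)
        for _ in range(n_events):
            sv_type = types[rng.choice(len(types), p=p)]
            seq = ancestor.sequences
            if sv_type == "insertion":
                size = sampler(rng)
                loc = place_interval(0, margin_feats=True)
                if loc is None:
                    raise RuntimeError("could not place insertion locus")
                chrom, pos = loc
                ins = list(random_sequence(size, rng))
                # force breakpoint-distinct flanks so anchors end exactly at pos
                ins[0] = rng.choice([b for b in "ACGT" if b != seq[chrom][pos]])
                ins[-1] = rng.choice([b for b in "ACGT" if b != seq[chrom][pos - 1]])
                edits.setdefault(child, []).append((chrom, pos, pos, "".join(ins)))
                records.append(TruthRecord(child, sv_type, chrom, pos, pos, size, carriers))
                occupied.add(chrom, pos, pos + 1)
            elif sv_type == "deletion":
                size = sampler(rng)
                placed = False
                for _ in range(max_attempts):
                    loc = place_interval(size, margin_feats=True)
                    if loc is None:
                        break
                    chrom, s = loc
                    e = s + size
                    sq = seq[chrom]
                    if sq[s] != sq[e] and sq[s - 1] != sq[e - 1]:
                        placed = True
                        break
                if not placed:
                    raise RuntimeError("could not place deletion locus")
                edits.setdefault(child, []).append((chrom, s, e, ""))
                records.append(TruthRecord(child, sv_type, chrom, s, e, size, carriers))
                occupied.add(chrom, s, e)
            elif sv_type == "inversion":
                size = int(rng.integers(inversion_size_range[0], inversion_size_range[1] + 1))
                placed = False
                for _ in range(max_attempts):
                    loc = place_interval(size, margin_feats=False)
                    if loc is None:
                        break
                    chrom, s = loc
                    e = s + size
                    if not _near_feature((s, e), feat_iv[chrom], 200):
                        placed = True
                        break
                if not placed:
                    raise RuntimeError("could not place inversion locus")
                edits.setdefault(child, []).append((chrom, s, e, revcomp(seq[chrom][s:e])))
                records.append(TruthRecord(child, sv_type, chrom, s, e, size, carriers))
                occupied.add(chrom, s, e)
            else:  # copy-number change on a tandem array
                rng.shuffle(free_arrays)
                chosen = None
                for ai, arr in enumerate(free_arrays):
                    if not occupied.fits(arr.chrom, arr.start, arr.end):
                        continue
                    k = _pick_copy_change(sv_type, arr, rng)
                    if k is not None:
                        chosen = (ai, arr, k)
                        break
                if chosen is None:
                    raise RuntimeError(f"no feasible tandem array left for {sv_type}")
                ai, arr, k = chosen
                free_arrays.pop(ai)
                G = k * arr.unit_len
                if sv_type.endswith("expansion"):
                    edits.setdefault(child, []).append((arr.chrom, arr.end, arr.end, arr.unit * k))
                else:
                    edits.setdefault(child, []).append(
                        (arr.chrom, arr.start, arr.start + G, "")
                    )
                records.append(
                    TruthRecord(child, sv_type, arr.chrom, arr.start, arr.end, G, carriers)
                )
                occupied.add(arr.chrom, arr.start, arr.end)

    # build leaf genomes by applying each leaf's inherited edits
    leaf_genomes: dict[str, Genome] = {}
    branch_of: dict[str, list[str]] = {}
    parent_of = {c: p for p, c, _ in tree.branches}
    for leaf in tree.leaves():
        path = []
        node = leaf
        while node in parent_of:
            path.append(node)
            node = parent_of[node]
        leaf_edits: list[tuple[str, int, int, str]] = []
        for node in path:
            leaf_edits.extend(edits.get(node, ()))
        sequences = {}
        for chrom in chroms:
            ch_edits = sorted(e for e in leaf_edits if e[0] == chrom)
            pieces, cur = [], 0
            for _, s, e, rep in ch_edits:
                pieces.append(ancestor.sequences[chrom][cur:s])
                pieces.append(rep)
                cur = e
            pieces.append(ancestor.sequences[chrom][cur:])
            sequences[chrom] = "".join(pieces)
        leaf_genomes[leaf] = Genome(id=leaf, sequences=sequences)
    del branch_of

    params = {
        "rate_per_branch": rate_per_branch,
        "type_weights": weights,
        "min_locus_gap": min_locus_gap,
        "inversion_size_range": list(inversion_size_range),
        "seed": seed,
    }
    return leaf_genomes, TruthTable(records=records, params=params)


def simulate_truth_table(
    tree: LineTree,
    rate_per_branch: float = 40.0,
    genome_length: int = 5_000_000,
    type_weights: dict[str, float] | None = None,
    seed: int = 0,
) -> TruthTable:
    """Draw planted-event bookkeeping only (loci on an abstract coordinate
    space, no sequences).  Sufficient input for presence-matrix and tree
    analyses, and orders of magnitude faster than full genome planting."""
    weights = dict(type_weights or DEFAULT_TYPE_WEIGHTS)
    rng = np.random.default_rng(seed)
    types = sorted(weights)
    p = np.array([weights[t] for t in types], dtype=float)
    p /= p.sum()
    records: list[TruthRecord] = []
    used: list[int] = []
    for parent, child, blen in sorted(tree.branches, key=lambda b: (b[0], b[1])):
        carriers = tree.leaves_under(child)
        if not carriers:
            continue
        for _ in range(rng.poisson(rate_per_branch * blen)):
            sv_type = types[rng.choice(len(types), p=p)]
            size = int(rng.integers(50, 10_001))
            for _ in range(300):
                s = int(rng.integers(0, genome_length - size))
                i = bisect_left(used, s)
                if (i == 0 or s - used[i - 1] > size + 2000) and (
                    i == len(used) or used[i] - s > size + 2000
                ):
                    insort(used, s)
                    break
            else:
                raise RuntimeError("could not place event")
            end = s if sv_type == "insertion" else s + size
            records.append(TruthRecord(child, sv_type, "chr1", s, end, size, carriers))
    return TruthTable(records=records, params={"seed": seed})


# ---------------------------------------------------------------------------
# Annotation and label maps
# ---------------------------------------------------------------------------


def simulate_annotation(
    genome: Genome,
    n_genes: int,
    exons_per_gene_range: tuple[int, int] = (2, 6),
    exon_length_range: tuple[int, int] = (100, 500),
    seed: int = 0,
):
    """Random non-overlapping exon models, grouped by gene, on reference
    coordinates.  Returns a list of :class:`svlineage.impact.ExonRecord`."""
    from .impact import ExonRecord

    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    max_gene_span = exons_per_gene_range[1] * (exon_length_range[1] + 500)
    if n_genes * max_gene_span > genome.total_length:
        raise ValueError("requested exon footprint exceeds genome length")

    chroms = genome.chrom_names
    clen = genome.lengths
    w = np.array([clen[c] for c in chroms], dtype=float)
    w /= w.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    exons: list[ExonRecord] = []
    for gi in range(n_genes):
        gene_id = f"g{gi:05d}"
        n_ex = int(rng.integers(exons_per_gene_range[0], exons_per_gene_range[1] + 1))
        ex_lens = rng.integers(exon_length_range[0], exon_length_range[1] + 1, n_ex)
        introns = rng.integers(50, 501, max(0, n_ex - 1))
        span = int(ex_lens.sum() + introns.sum())
        for _ in range(500):
            chrom = chroms[rng.choice(len(chroms), p=w)]
            if clen[chrom] <= span + 2:
                continue
            s = int(rng.integers(0, clen[chrom] - span))
            iv = placed[chrom]
            i = bisect_left(iv, (s, s + span))
            if (i == 0 or s >= iv[i - 1][1]) and (i == len(iv) or s + span <= iv[i][0]):
                insort(iv, (s, s + span))
                break
        else:
            raise ValueError("could not place gene without overlap")
        pos = s
        for ei in range(n_ex):
            e = pos + int(ex_lens[ei])
            exons.append(ExonRecord(chrom=chrom, start=pos, end=e,
                                    gene_id=gene_id, exon_id=f"{gene_id}.e{ei + 1}"))
            pos = e + (int(introns[ei]) if ei < n_ex - 1 else 0)
    return exons


def simulate_label_map(
    genome: Genome,
    motif: str = "CACGAG",
    miss_prob: float = 0.1,
    false_per_100kb: float = 1.0,
    sizing_cv: float = 0.005,
    seed: int = 0,
):
    """Noisy consensus label maps, one per chromosome, emulating nick-site
    labeling: true motif occurrences (both strands) thinned by ``miss_prob``,
    spurious labels added at ``false_per_100kb``, and inter-label distances
    perturbed multiplicatively by Normal(1, sizing_cv) then re-accumulated.

    Returns ``{chrom: LabelMap}``.
    """
    from .omap import LabelMap, digest_sequence

    if len(motif) != 6 or set(motif) - set("ACGT"):
        raise ValueError("motif must be a 6-mer over ACGT")
    if not (0.0 <= miss_prob <= 1.0) or not (0.0 <= false_per_100kb):
        raise ValueError("invalid noise parameters")
    if sizing_cv < 0:
        raise ValueError("sizing_cv must be >= 0")
    rng = np.random.default_rng(seed)

    out = {}
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        true_pos = digest_sequence(seq, motif)
        keep = true_pos[rng.random(len(true_pos)) >= miss_prob]
        n_false = rng.poisson(false_per_100kb * L / 1e5)
        false_pos = rng.integers(0, L, n_false) if n_false else np.empty(0, dtype=np.int64)
        labels = np.unique(np.concatenate([keep, false_pos]).astype(np.int64))
        if sizing_cv > 0 and len(labels) > 0:
            bounds = np.concatenate([[0], labels, [L]]).astype(float)
            gaps = np.diff(bounds)
            factors = np.maximum(rng.normal(1.0, sizing_cv, len(gaps)), 0.05)
            newpos = np.cumsum(gaps * factors)
            labels = np.round(newpos[:-1]).astype(np.int64)
            labels = np.maximum.accumulate(labels + np.arange(len(labels)) * 0)
            # enforce strict increase after rounding
            for i in range(1, len(labels)):
                if labels[i] <= labels[i - 1]:
                    labels[i] = labels[i - 1] + 1
            length = int(max(round(newpos[-1]), (labels[-1] + 1) if len(labels) else 1))
        else:
            length = L
        out[chrom] = LabelMap(
            map_id=f"{genome.id}:{chrom}", length_bp=length,
            labels=np.asarray(labels, dtype=np.int64), chrom=chrom, line_id=genome.id,
        )
    return out
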