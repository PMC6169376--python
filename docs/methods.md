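# Methods

This document records the models, algorithms, parameter choices and known
limitations of `svlineage`. All defaults named here are the study
conditions; the test suite and `scripts/acceptance.py` run against them.

## Simulator (`svlineage.simulate`)

**Ancestor.** A uniform-random A/C/G/T background of the requested length is
split across `n_chroms` chromosomes, then salted with two repeat families
whose coordinates are recorded: tandem arrays (default 300 arrays; unit
length 5–50 bp, 4–60 copies) and one dispersed-repeat family (default 40
copies of a 400 bp element). Repeat footprints are *added* to the requested
background length, so the requested length is the unique-sequence budget.

**Line tree and planting.** Five lines sit under a fixed tree,
`((B10,I03),((N15,T29),ZH26))`, below a stem branch representing divergence
from the reference lineage. Events are drawn per branch
(Poisson, `rate_per_branch` × branch length, default 40) and inherited by
every leaf below that branch, giving nested carrier sets and a complete
truth table (branch, class, reference locus, size, carriers). Sizes are
log-uniform on [50, 10000] bp; inversions are drawn separately on
[12, 30] kb so they are visible to optical maps. Planted loci are kept
≥ 2 kb apart and away from feature boundaries so each event's alignment
signature is unambiguous. Each leaf genome is produced by applying its
branch path's edits right-to-left; by construction
`leaf length = ancestor length + Σ signed sizes` (asserted in tests for
every seed).

Copy-number classes (tandem/repeat expansion/contraction) are planted on
tandem arrays: a copy-number change of G bp on an array of span A produces
exactly the Assemblytics gap signature of its class
(expansion: tandem if G ≥ A, repeat if G < A; contraction: tandem if
G ≥ A/2, repeat if G < A/2). A new dispersed-repeat copy inserted away from
existing copies would instead produce a plain-insertion signature under
exact anchoring — there is no self-similar sequence at the breakpoint — so
copy-number events are realized through arrays, while dispersed repeats
still exist to stress anchoring and chaining.

**Annotation.** Non-overlapping exon models (default 400 genes, 2–6 exons
of 100–500 bp) on reference coordinates.

**Label maps.** Reference maps are in-silico digests: occurrences of the
BssSI-like hexamer CACGAG on either strand (~1 label / 2 kb of random
sequence). Line maps are digests of the *line* genome passed through a
noise model: each label dropped independently with `miss_prob` (default
0.1), false labels added as a Poisson process (`false_per_100kb`, default
1.0), and sizing error applied multiplicatively per inter-label gap,
`gap × Normal(1, sizing_cv)` (default 0.005), re-accumulated so positions
stay strictly increasing.

## Alignment (`svlineage.align`)

Anchors are k-mers (k = 21) unique in both genomes, found by intersecting
packed 2-bit k-mer sets, pruned to consistent diagonals, and extended to
maximal exact matches. A per-(chromosome pair, strand) dynamic program
chains anchors maximizing total anchored length subject to collinearity and
a gap cap (50 kb). Published match filters apply: a block ≥ 500 bp stands
alone; blocks of 100–500 bp survive only inside a chain with ≥ 2 such
blocks; < 100 bp is dropped.

## Sequence SV calling (`svlineage.svcall`)

Between consecutive blocks of a chain, the reference gap `rg` and query gap
`qg` classify the event (Assemblytics scheme): size = `qg − rg`; gains are
insertions (`rg ≥ 0`), tandem expansions (`rg < 0 ≤ qg`) or repeat
expansions (`qg < 0`); losses mirror this. Sizes below 50 bp or above
50 kb are not calls. Within CIGAR-bearing blocks, I/D runs ≥ 50 bp are
called directly. Inversions come from chain segments whose strand flips and
whose flanks agree (minimum 10 kb). Breakpoints are exact where the
alignment is exact; the acceptance suite asserts ±1 bp on matched indels.

## Optical maps (`svlineage.omap`)

**Reference aligner (`align_map`).** A banded DP over monotone label
matchings maximizing
`−Σ sizing_weight·|Δq−Δr|/max(Δr,1000) − miss·(ref skips) − false·(query
skips)`; it is verified against an exhaustive-DP oracle on all map sizes
≤ 12 labels. This objective charges the aligner for every *reported*
discrepancy, so when two nearby SVs have opposite signs it is cheaper to
mis-pair across both and report only their net — structurally unfixable by
reweighting (the hiding path's sizing cost is strictly lower). It is kept
and tested, but the pipeline detects SVs with the aligner below.

**SV-aware aligner (`align_map_sv`).** Scores structure instead of sizing
error: +R per matched pair (R = 1); −0.25 per skipped label; consecutive
steps whose gap discrepancy is within tolerance
(max(100 bp, 2% of Δr)) are free; any larger discrepancy is taken as a
flat-penalty SV "jump" (Γ = 1.5) from any earlier cell (computed with a 2-D
prefix maximum, so jumps span arbitrarily many labels at one cost).
Calibration is analytic: Γ > R + skip (mis-pairing a label inside a real
event never beats skipping it) and Γ < 2R (two events separated by ≥ 2
matchable labels are reported separately rather than bridged); the defaults
sit mid-range. Band 10 covers the ~5 consecutive labels a 10 kb deletion
removes, plus misses.

**Detection and floor.** `detect_map_svs` emits one call per aligned step
whose gap discrepancy `d = Δq − Δr` satisfies `|d| ≥ 1000` (the optical
resolution floor): insertion if positive, deletion if negative, located on
the reference interval of the step.

**Reflection-artifact suppression.** An inverted segment carries the mirror
image of the reference label pattern, and mirroring preserves pairwise
label distances — so the aligner can profitably mis-pair labels across the
segment and emit a ladder of compensating ±-size calls (observed in ~91% of
synthetic noiseless inversions). `suppress_reflection_artifacts` removes
runs of consecutive calls whose window (bounded by the matched pairs just
outside the run) spans ≤ 60 kb (twice the maximum planted inversion),
telescopes to net ≈ 0 (≤ max(500 bp, 1% of span)), and whose interior query
labels are explained strictly better by a *reflection* than by a
*translation*: a Hough search over candidate mirror centers
`C = u_i + v_j` (with C/2 constrained inside the window) counts query
labels landing within 150 bp (≈4σ of accumulated sizing noise over such a
window) of a reference label in *order-reversing* fashion (longest
decreasing subsequence); the translation alternative uses the same
machinery order-preservingly over candidate offsets `u_i − v_j`. Real
insertion+deletion pairs of equal size are net-zero too, but their interior
is translated, not mirrored, so the comparison keeps them (0/200 lost in
synthetic sweeps, both noiseless and at study noise). Residual
un-suppressed artifact rate per inversion: 4/200 noiseless, 17/200 at study
noise — dominated by windows with < 3 interior query labels, where
reflection and translation are indistinguishable in principle.

**Cross-validation.** A sequence SV is validated when an optical call of
the same sign overlaps its interval padded by one flanking label interval
per side (optical breakpoint uncertainty is bounded by label spacing).
Inversions carry no optical size signal and are never validated.

## Cohort structure (`svlineage.popstruct`)

**Coincidence.** SVs across lines coincide when chromosome and class match
and both breakpoints agree within 3 bp; loci are single-linkage closures of
this relation (union-find), verified against an exhaustive O(n²) oracle.
Loci × lines give the presence/absence matrix.

**Distance and tree.** Line distance is 1 − Jaccard over matrix columns.
UPGMA (average linkage, heights = distance/2, deterministic lexicographic
tie-break) builds the tree; scipy's average linkage is the test oracle on
tie-free random matrices.

**Bootstrap.** For each scale r in 0.5…1.4, B resamples of ⌈r·n⌉ loci are
re-clustered; BP is the clade recovery frequency at r = 1, and AU comes
from the multiscale fit z(r) = v√r + c/√r by weighted least squares
(binomial weights), AU = 100·(1 − Φ(v − c)). When fewer than half the
scales have BP_r strictly inside (0, 1) the profile is saturated — there is
no curvature to fit and a tail extrapolation would be arbitrary — so AU
falls back to 100·BP at scale 1. Closed forms hold: BP_r ≡ 0.5 gives
AU = 50.

**Rate.** `rate = sv_count / (2 · divergence_my · genome_mb)`; the factor 2
counts both lineages separating a line from the reference.

## Impact (`svlineage.impact`)

Half-open interval intersection of SVs with exons via a sorted sweep,
verified against brute force. A zero-length record (insertion point)
overlaps an exon only when strictly inside it. Summaries count exons
affected per line and overlap counts/bp per class, with insertions
contributing their full inserted length.

## Numerical and engineering choices

- All label coordinates are int64; DP scores are float64.
- Every stage seed is derived from the run seed via `numpy.random.SeedSequence`
  spawning, so runs are bit-reproducible and stages are independently
  re-runnable.
- All intermediates are plain text (FASTA, PAF, BED6+3, GFF3, TSV, Newick,
  JSON).
- Buy-not-build: Biopython for FASTA, gffutils for GFF3, scipy for Φ and
  the UPGMA test oracle, pandas for tabular I/O; the alignment/DP kernels
  that *are* the method are implemented here and oracle-tested.

## Limitations

- **Optical resolution.** Events < 1 kb are invisible to label maps by
  construction; optical breakpoints are only accurate to the flanking label
  positions.
- **Close opposite-sign events.** Two optical SVs of opposite sign with
  fewer than ~2 matchable labels between them cannot be separated by any
  monotone aligner (bridging them is cheaper than any faithful path); they
  are reported as their net size or not at all.
- **Residual reflection artifacts.** The mirror test needs ≥ 3 interior
  query labels; sparser inverted segments can still leak compensating ±
  pairs (measured ~2% of noiseless and ~8.5% of noisy synthetic
  inversions). These inflate raw optical call counts but do not propagate
  into validated-SV analyses, because cross-validation requires a
  coinciding sequence call of the same sign.
- **No translocations or nested events.** Planted loci are disjoint; the
  caller does not model rearrangements that reorder chains across
  chromosomes.
- **Clock-like assumption.** UPGMA assumes equal rates along lineages; the
  simulator's tree is compatible, but rate-heterogeneous cohorts would need
  a different linkage.
- **Dispersed-repeat copy numbers.** Copy-number classes are planted on
  tandem arrays (see Simulator); a dispersed-repeat copy inserted away from
  existing copies presents as a plain insertion to any exact aligner, which
  is a property of the gap signature, not of this caller.
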