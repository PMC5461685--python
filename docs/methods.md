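# Methods

## Coordinate model

Every coordinate in the package is 0-based, half-open (the BED convention);
1-based display formats (UCSC position strings) convert at the output
boundary only. Chromosome names are compared as exact strings — no "chr"
prefix normalisation — so mismatched inputs fail loudly rather than merge
silently.

## Signal tracks and the pairwise algebra

A `SignalTrack` is, per chromosome, a sorted list of non-overlapping
`(start, end, value)` segments with strictly positive values; zero coverage
is represented by absence, which keeps `support()` (the set of covered
bases) meaningful. Tracks are built from reads (value = read depth), from
peaks (value = peak pileup, overlaps summing), or from bedGraph rows.

The seven operators act pointwise per base:

| op  | value at base x |
|-----|-----------------|
| AND | a(x) if a(x)>0 and b(x)>0, else 0 |
| OR  | a(x) if a(x)>0, else b(x) |
| NOT | a(x) if b(x)=0, else 0 |
| XOR | the one side's value where exactly one side is covered |
| `+` | a(x)+b(x) |
| `-` | max(a(x)−b(x), 0) |
| SYM | \|a(x)−b(x)\| |

Boolean operators never change pileup heights; where both operands are
covered, the **left** operand's height survives. That choice is deliberate:
expressions are evaluated as a strict left fold
`((Sig1 Op Sig2) Op Sig3) …`, so the accumulated track is naturally the
reference signal and each new operand acts as a mask or modifier. SYM is
defined as the absolute difference, equivalently the union of the two
clamped subtractions — consistent with the clamping rule that any negative
pileup becomes zero and zero-valued stretches are dropped immediately.

All operators are implemented by a single two-pointer sweep over the union
of segment breakpoints (absent coverage contributes 0), followed by
drop-zeros-and-coalesce. The test suite checks every operator against an
independent dense per-base oracle on a 10 kb genome and asserts the algebra
identities (A AND A = A, A − A = ∅, commutativities, support set-algebra).

There is no operator precedence and no parentheses: evaluation order is
strictly left to right by design.

## Stitching, scoring and the SE/TE threshold

Peaks are sorted per chromosome and merged transitively whenever the gap
(next start − previous end) is **strictly** below the stitch distance
(default 12 500 bp); an exact-threshold gap does not stitch, and stitching
never crosses chromosomes. Unsorted input is sorted internally rather than
rejected, since peak-caller output order is not guaranteed. No promoter
exclusion is applied before stitching; TSS handling is purely
annotation-side.

The score of a stitched region is the cumulative read-base signal over its
support: with raw reads, the summed overlap length in bp of every read with
the region; with a combined-signal track, the area under the pileup inside
the region. When both are supplied the track wins (it is the refined
signal) and the reads are ignored with a warning. Regions are ranked by
descending score, rank 1 strongest, ties broken by genomic position.

The SE cutoff scales both the score and the rank axis to [0, 1], forms the
ascending curve, and scans the forward-difference slopes
`s_i = (y_{i+1}−y_i)/(x_{i+1}−x_i)`; the segment whose slope is nearest 1
(the 45° tangent of the hockey stick) fixes θ_SE, counted in descending
ranks, and every region with rank ≤ θ_SE is flagged SE. Numerical choices,
since the tangent rule alone does not fix them:

- slope estimator: plain forward difference, no smoothing by default; an
  odd-width moving-average window over the slopes is available opt-in
  (`smooth_window`);
- ties in |s−1| resolve toward **fewer** SEs (conservative SE set); on a
  perfectly linear curve this yields a single SE, the minimum a slope
  segment can denote;
- fewer than 3 regions: no tangent is defined — everything is flagged TE
  with a warning;
- constant scores: no inflection exists — a degenerate-input error (the
  pipeline catches it, warns, and flags everything TE).

## Annotation

Each region is assigned the gene with the nearest TSS on its chromosome
(edge distance in bp, 0 if the TSS lies inside; ties break alphabetically;
no gene on the chromosome → "NA"). Strand affects only where the TSS is
(txStart on `+`, txEnd−1 on `−`), never the distance. Gene bodies
intersecting the region are "overlapping"; genes with a TSS within the
proximal window (default 50 kb) of either edge, "proximal".

A subpeak is "inside a TSS" iff its interval intersects the closed window
±`tss_window` (default 2 500 bp) around **any** TSS — intersection, not full
containment. Percentage OUTS is 100 × (subpeaks outside)/(subpeaks), and the
enhancer type follows exhaustively: Pure at 100, Only TSS at 0, Mixed
otherwise. The two window defaults are package choices exposed as flags
(2.5 kb is the community default for promoter proximity; 50 kb a common
regulatory-neighbourhood radius).

## Chromosome statistics

Closeness of an SE is the gap in bp to its nearest neighbouring SE on the
same chromosome — for interior SEs the min of the two adjacent gaps, for the
first/last the single adjacent gap, NA for a lone SE. Since called SEs are
disjoint and sorted, the adjacent-gap rule equals the brute-force minimum
over all other SEs (asserted in tests).

Chromosome enrichment substitutes the binomial b(k; K, z), z = n/N for the
hypergeometric h(k; K, n, N) — N genes genome-wide, n on the chromosome, K
SEs genome-wide, k on the chromosome — and computes **exact** binomial tail
sums (no normal approximation): p_enrich = P(X ≥ k), p_deplete = P(X ≤ k).
Marks: ⋏ / ⋏⋏ for enrichment below 0.05 / 0.01, ⋎ / ⋎⋎ for depletion, with
enrichment taking precedence in the degenerate case where both fire. Two
one-sided tails are reported rather than one two-sided test, and no
multiple-testing correction is applied across chromosomes — marks are raw
per-chromosome significance. The binomial substitution is accurate in the
small-sampling-fraction regime (K ≪ N, i.e. hundreds of SEs against tens of
thousands of genes); the suite verifies |Δp| ≤ 0.01 against the exact
hypergeometric for N ≥ 2000, n/N ≤ 0.2, K ≤ N/20.

Rank percentile bins are `ceil(rank·bins/n)` clipped to [1, bins]. Length
and pileup histograms use log10-spaced bins (enhancer lengths span orders of
magnitude); subpeak-count histograms use linear bins at N = 10 and N = 20.

## Scaled-rank evaluation

`s(r) = 100·r/n_se` makes rankings of different lengths comparable:
s ≤ 100 ⇔ the region is a called SE, with the boundary attained exactly at
the last SE. A marker gene is matched case-insensitively against
`closest_gene` only (the gene a region is assigned to), best rank winning. A
marker absent from the prediction receives the sentinel
`s = 100·(n_stitched+1)/n_se` — one step worse than the worst TE. The
sentinel is this package's construction: it keeps the mean finite and
order-consistent (an unpredicted marker always scores worse than any
predicted one) without an arbitrary penalty constant. Goodness is the
arithmetic mean of s over the marker list (lower = better); across
predictors, means are normalised by the largest, so the weakest predictor
scores exactly 1.

## Scheduler

`k = min(C, C_u, ⌊M/m⌋, l)` with per-task memory defaults m = 3 GB for
stitching and 2 GB for profile rendering and the enrichment-style batch
tasks. Data elements are dealt cyclically, element j (1-based) to worker
`((j−1) mod k) + 1` — the residue-0-maps-to-worker-k convention, so 24
chromosomes at k = 7 give worker 1 = {1, 8, 15, 22} and worker 7 =
{7, 14, 21}. Called directly with k > l, the trailing chunks are empty with
a warning; through `n_processes` that case is unreachable because k is
capped at l. `parallel_map` restores element order on merge, so results are
byte-identical for any worker count; with a single non-empty chunk it runs
serially in-process. Machine resources are auto-detected but always
overridable; tests use explicit specs only.

## Synthetic data

The generator emulates an ESC-like enhancer landscape on a 3×3 Mb toy
genome: 20 planted SE clusters of 5–7 subpeaks (the subpeak range typical of
ESC superenhancers) with intra-cluster gaps drawn in [200, 6 000] bp —
safely below the stitch distance, so each cluster stitches to exactly its
planted extent — and 200 isolated typical enhancers separated by at least
20 kb, so they never stitch to anything. Reads are sampled per peak in
proportion to pileup (default 3 reads per pileup unit, 100 bp, uniform
starts), giving stitched scores proportional to planted strength.

Two distributional choices matter and are deliberate:

- **Cluster strengths form a geometric ladder** (ratio 1.12 across the 20
  clusters, cluster pileup budget = strength × 6 split over its subpeaks,
  ±2% noise). Independent identically-distributed strengths would produce
  sorted-score near-ties whose scaled slope is ≈ 1, planting spurious 45°
  tangents inside the SE tail; real SE rankings are smooth continua, which
  the ladder emulates.
- **TE strengths are lognormal** (log-sd 0.5 around a mean pileup of 6, ten
  times below the weakest cluster), i.e. right-skewed like real enhancer
  signal, which places the largest sorted-score gaps just below the elbow.

What the generator does **not** emulate: read error models, GC or
mappability bias, duplicate reads, background noise between peaks, overlap
between clusters and background genes' regulatory structure. Passing
recovery tests therefore demonstrates the correctness of the stitching /
scoring / thresholding machinery under clean hockey-stick conditions, not
calling performance on noisy real libraries.

The hockey-curve generator builds the ascending scaled curve from
geometrically growing per-rank increments `exp(g·(i−i₀))`; solving g so the
mean increment falls exactly at segment i₀ makes the post-scaling slope
exactly 1 there, so the 45° scan recovers the planted rank exactly at zero
noise. Noise is applied to the increments (in units of the slope-1
increment) before integration — additive noise on the integrated curve
would perturb discrete slopes by ~n × noise and make small noise levels
meaningless. A convex curve can only place its tangent in the upper half of
the ascending index range (equivalently, SEs must be fewer than half the
regions); the generator validates this and refuses otherwise.

## Problem sizes and determinism

Default test and demo sizes — 10 kb dense-oracle genomes, 100 kb scoring
oracles, 320-peak landscapes, 200-point rank curves — are chosen so every
property is checked against brute-force or dense evaluation in seconds.
Every stochastic component takes an explicit integer seed (default 0); there
is no global random state, and reruns of any pipeline stage on identical
inputs produce identical bytes (reports included: SVG/HTML are assembled
from sorted inputs with no timestamps).

## Known limitations

- No background/control correction: peak calling is upstream and its output
  is trusted.
- The Boolean-overlap convention (left operand wins) and the SYM definition
  are package decisions among reasonable alternatives; both are documented
  above and pinned by tests.
- The unpredicted-marker sentinel makes goodness means comparable but its
  absolute value depends on the stitched-list length.
- BAM input requires pysam (optional extra); BED reads are the first-class
  path.
- The enrichment marks are uncorrected per-chromosome p-values; with ~24
  chromosomes a 0.05 mark is suggestive, not genome-wide significant.
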