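# Methods

This note documents the models and procedures behind `neurocult`, the
assumptions they make, the parameters that matter, and the places where
the design was genuinely open.

## Coordinate and graph conventions

Coordinates are `(row, col)`, 0-based, row increasing downward;
distances are Euclidean and measured in pixels. All analysis graphs are
simple and undirected: multiple neurites between the same soma pair
collapse to one edge, and self-contacts are ignored — every formula in
the metrics module assumes this. GraphML files store `x = col`,
`y = row` so external viewers match the image orientation.

## Synthetic cultures

The generator emulates a sparse dissociated culture on a
1024×1024 px field (≈0.44 mm² at the default 0.65 µm/px): 30 somas of
radius 15–22 px placed by rejection sampling with a 60 px minimum
separation, connected pairwise with probability `exp(−d/λ)` for
λ = `connect_scale_px` = 100 px. The exponential kernel is the simplest
choice under which physically close cells end up with more
interconnections — the qualitative behavior the analysis must detect —
and is *not* fitted to any measured culture. Neurites are quadratic
Bézier arcs with bounded random curvature (|control offset| ≤ 0.15 of
the chord); curvatures are re-sampled until the arc clears every third
soma by at least `neurite_width + 10` px, because an arc that grazes an
unrelated soma would make the rendered image contradict the edge list.
Edge births are scheduled shortest-first in fixed batches of
`ceil(fraction·|E|)` per snapshot (short neurites complete first in a
growth process), capped at the last snapshot so the final edge set
always equals the ground-truth edge set. Corruption channels: each
neurite receives one gap with probability `gap_rate` (default 0.15,
length 3–8 px, cut from the middle half of the arc *before*
rasterization so rendering stays monotone in time); `debris_count`
sub-threshold bright disks (areas 80–300 px, strictly below the 600 px
segmentation threshold) are placed disjoint from somas, neurites and
each other, because two merged debris could exceed the area threshold
and fabricate a node; Gaussian noise (σ = 0.01 of the intensity range)
is added last and the image clipped to [0, 1].

What the generator does **not** emulate: phase-imaging physics (halo,
shot noise correlations), soma shape variability and touching cells,
neurite branching and fasciculation, cluster migration or merging, cell
death, uneven illumination. Tests passing on these renders therefore
show that the pipeline's logic is correct on geometrically faithful
inputs, not that it is robust to every real microscope artifact.

## Reconstruction

1. **Clarity score.** Mean local intensity variance (7 px window)
   mapped through `v/(v + τ²)` with τ fixed at 5% of the intensity
   scale — deterministic, 0 on constant images, strictly decreasing
   under blur. It replaces a trained clarity classifier whose labels
   and weights are not reproducible artifacts; the role (region triage
   against a config threshold) is preserved.
2. **Soma segmentation.** Grayscale opening with a disk (radius 6 px)
   erases anything thinner than the disk — neurites — while leaving
   round bodies; Otsu on the opened image then yields candidate bodies,
   and components smaller than `min_area_px` (600 neuron mode / 800
   cluster mode) are debris. Because the opening also erases debris
   smaller than its disk, the body mask is completed by an intensity
   split of the robust foreground, accepted only when that foreground
   is genuinely bimodal (class-mean gap > 3× the summed in-class
   spreads). Cluster mode differs from neuron mode only by the area
   threshold.
3. **Neurite binarization.** Otsu on the intensity histogram with all
   bright bodies excluded from the *sample* (they would otherwise pull
   the threshold between neurite and soma levels), floored at
   `median + 6·1.4826·MAD`: in a young culture the foreground can be
   under 0.1% of pixels and an unguarded Otsu thresholds inside
   background noise. Large-scale background subtraction is available
   (`subtract_background=True`) for uneven illumination but off by
   default — the smoothed field is inflated next to bright somas, which
   depresses the apparent contrast of exactly the short neurites
   joining nearby cells.
4. **Skeleton, terminals, gap filling.** The foreground minus dilated
   bodies is thinned (standard morphological skeletonization,
   8-connectivity). Terminals are skeleton pixels with exactly one
   neighbor; isolated pixels are reported separately. Each terminal
   bridges at most once, by a straight segment, to the nearest skeleton
   pixel of a *different* connected component (or a soma pixel) within
   `gap_radius_px` (default 12 px); own-component pixels are never
   candidates, otherwise a terminal would "bridge" to its own branch.
   The union is re-thinned.
5. **Tracing.** Walks start at skeleton pixels inside each soma's halo
   (4 px beyond the mask), heading outward, and follow the skeleton
   depth-first, visiting each pixel at most once per source soma. The
   walk direction is the chord over the last ~15 positions rather than
   the last 1 px step: where two neurites cross at a shallow angle,
   thinning merges them for roughly `width/tan(θ/2)` ≈ 10 px and any
   single-step direction estimate forgets the approach heading. At a
   branch point every candidate branch is probed ~15 px ahead and only
   the best-aligned continuation within `angle_tol_deg` (default 60°)
   is taken; the steerable-filter ridge tangent (second derivative of
   Gaussian, σ = 1.5 px ≈ the neurite half-width, 8 orientations) votes
   when the chord test alone fails. Reaching another soma's halo
   records the unordered pair; walks that die contribute only to a
   logged counter.

On uncorrupted default cultures this recovers the edge set with
F1 ≈ 0.96 (mean over 20 seeds, minimum ≈ 0.89); residual errors are
near-parallel crossings, which no local rule can disambiguate.

## Metrics

Centralities default to the literal unnormalized definitions (degree;
reciprocal summed distance; pair-fraction betweenness over unordered
pairs); `normalized=True` gives the conventional `(n−1)`-scaled
variants, since published CDF axes are often normalized. On
disconnected graphs closeness sums over reachable nodes only, an
isolated node has closeness 0 by the empty-sum convention, and pairs
with no connecting path contribute nothing to betweenness. The mixing
matrix counts both orientations of every edge (symmetric, total mass
2|E|); peak ties are reported in ascending lexicographic order.
Assortativity is the Pearson correlation over the 2|E| oriented
end-degree pairs; degree-regular graphs return NaN (undefined, not an
error), edgeless graphs raise. C and C4 average only over nodes of
degree ≥ 2 and are NaN when no such node exists; a square-clustering
pair with no observed and no possible square (0/0) contributes 0 — no
evidence of cliquishness. The exceedance curve uses the strict
inequality P(L > ℓ).

## Null models

Size matching translates the observed (n, |E|) into family parameters:
ER `p = 2E/(n(n−1))`; WS even ring degree `k = round(2E/n)` with
rewiring β = 0.1 (a conventional small-world operating point; nothing
in the matched quantities pins it); BA `m = round(E/n)`; RR
`d = round(2E/n)` adjusted for parity. The spatial scale-free model
grows from an (m+1)-clique: each arriving node connects to m distinct
existing nodes without replacement with probability
∝ `k_j·exp(−d_ij/r_c)`, positions uniform in the unit square unless an
observed layout is supplied. The weighted multifractal graph assigns
every node a uniform coordinate in [0, 1], derives its K-level address
under the interval partition `l_1..l_m`, links pairs with probability
`c·Π_t P[i_t][j_t]`, and bisects the global scale c (probabilities
clipped at 1) until the expected edge count hits the target; WMG shape
parameters are chosen by a coarse grid search (m ∈ {2,3} with diagonal
dominance levels, K ∈ {2,3}) minimizing the summed metric error over
pilot realizations before the final evaluation. Comparisons report the
realization mean, the 95% *percentile* interval — robust to the skewed
clustering distributions of sparse graphs, unlike a normal
approximation — and the absolute error |observed − mean| per metric.
Everything is deterministic given (observed network, seed, repetition
count); a family whose generator fails is skipped and logged, never
fatal.

## Multifractal analysis

`r` is a box *diameter* in shortest-path hops; boxes grow as balls of
radius ⌊r/2⌋ around uniformly chosen uncovered seeds, the best of
`n_covers` restarts (fewest boxes) is kept, and a compaction pass then
migrates nodes from larger boxes into adjacent undersized ones whenever
the pairwise-diameter constraint allows. Compaction matters: plain
random-sequential covers strand near-empty boxes whose masses dominate
the q < 0 moments (on a 200-ring the estimated D(−5) collapses toward 0
without it, and is 0.89–0.91 with it). Each move strictly decreases the
sum of squared box sizes, so the pass terminates; box count is
unchanged. Note that a ball cover yields one box only when
⌊r/2⌋ reaches the graph *radius* — on cycles that is the diameter
itself, so "one box covers everything" is only guaranteed for
r ≥ 2·diameter.

The scaling fit uses log-spaced integer r from 2 to ⌈diameter/2⌉ (≥ 4
distinct values required; graphs of diameter < 4, such as stars, are
flagged degenerate rather than rejected), abscissa ln(r/d), partition
sums averaged over `n_covers` = 20 covers per r, and q from −10 to 10
in steps of 0.5 with q = 1 through the entropy-sum limit. Fits with
R² < 0.8 are flagged per q. The Legendre transform uses central finite
differences on the q-grid (one-sided at the ends); the identity
f(α(q)) = qα − (q−1)D(q) then holds to machine precision by
construction, and a non-monotone α(q) attaches a warning (noisy
estimate) instead of failing. Validity anchors: a 200-node ring gives
D(q) within 0.1 of 1 across q ∈ [−5, 5] (the residual bias comes from
odd ball sizes 2⌊r/2⌋+1 versus nominal r), a generation-5 (2,2)-flower
gives D(0) ≈ 1.96 against the transfinite value ln(u+v)/ln u = 2, and
the closed-form binomial cascade reproduces its spectrum endpoints
−log₂p and −log₂(1−p). Disconnected inputs are reduced to the largest
component, with a warning.

## Pipeline

One global seed is expanded into per-stage seeds by a fixed counter
scheme (`SeedSequence((seed, stage_index))`), so stages can be re-run in
isolation; re-running a config at a fixed seed reproduces every CSV,
JSON and GraphML byte for byte, and the manifest records no timestamps.
Stage errors abort with the stage name and the last valid artifact;
exit codes are 0/2/3 for ok / config error / stage failure.

## Problem sizes in the test-suite and acceptance runs

The shipped validation runs use 30-soma cultures on 1024² px fields
(5 clean cultures for recovery, 50 gapped cultures for the gap-filling
contrast, 20 in the acceptance script), 1000 realizations for
null-model comparisons at n = 200 (the paper-scale ER/WS contrast) and
on the reconstructed 30-node culture, 100–500 seeds per point for the
spatial-kernel sweep at n = 300, and 15–20 covers per radius for MFA.
These sizes give stable Monte-Carlo contrasts while keeping a full run
in minutes on one CPU core.

## Known limitations

* Tracing is local: near-parallel neurite crossings and true neurite
  branch points are indistinguishable from merged strokes, bounding
  edge F1 below 1 on dense cultures.
* Touching somas are not sub-segmented; in cluster mode a merged blob
  *is* the node, by design.
* The WMG fit is a coarse grid search, not a likelihood fit; it bounds
  the family's explanatory power from below.
* Multifractal estimates on graphs with diameter ≲ 8 rest on very few
  scaling points; treat flagged fits as qualitative.
* The synthetic generator's parameters describe a plausible sparse
  culture, not a calibrated model of any particular preparation.
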