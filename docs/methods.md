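# Methods

This note documents the models and procedures implemented in `dartfish`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic benchmarks do and do not demonstrate.

## Barcoding model

A gene is encoded by a *compact barcode*: a length-`n` string over
`{0,1,2,3}` where position = decoding round, `0` = dark round, and `1–3` =
the fluorescent channel lighting up in that round. Valid barcodes are "on"
in exactly `k` rounds, giving `C(n,k)·3^k` possibilities in total
(540 for `n=6, k=3`; 945 for `n=7, k=3`; 5670 for `n=8, k=4`). The
*multi-color* restriction additionally drops barcodes whose on-rounds all
use one channel — the codes most vulnerable to channel-wide artifacts —
leaving `C(n,k)·(3^k − 3)` (480 and 840 for the two designs above).

Each barcode maps to a one-hot column of the codebook matrix `X`
(shape `3n × N`), with a 1 at flat index `3·(round−1) + (channel−1)`.
Rounds-outermost flattening is used by every module (stacks, coefficient
vectors, weight maps).

### Codebook selection

Decoding confuses barcodes that differ in a single round, so selection
works on a *conflict graph*: nodes are candidate barcodes, edges join
pairs at Hamming distance exactly 1. The pipeline is:

1. **Seed set** `Q`: a randomized greedy search with restarts (default
   1000) for a large subset with pairwise Hamming distance > 2. Greedy
   construction over random orders is used because the exact maximum is a
   hard combinatorial problem; the restart count is exposed.
2. **Maximal independent set**: a randomized MIS containing `Q`, run many
   times (20,000 by default) keeping the largest. One run adds the seeds,
   then repeatedly picks a uniformly random still-eligible node — realized
   as a random-permutation greedy sweep, which draws from exactly the same
   distribution but runs in O(V+E) per sweep. Any MIS of the conflict
   graph has pairwise Hamming distance ≥ 2. With the default seeds the
   search attains 160 barcodes on the (6,3) multi-color graph and 269 on
   the (7,3) graph; being a stochastic search, sizes within a few barcodes
   of these are expected for other seeds.
3. **Augmentation** (when more codes are needed than the MIS provides):
   random draws of the extra barcodes from the remaining pool, keeping the
   draw that induces the fewest distance-1 edges over `n_trials` trials.
4. **Gene assignment**: a seeded random bijection of gene names onto
   barcodes, plus `n_empty` additional barcodes flagged *empty* — decoys
   carried through decoding so that false discoveries become observable.

## Image model and simulator

A field of view is a stack of `3n` registered planes with intensities in
[0, 1]. A rolony is rendered as an isotropic 2-D Gaussian, parameterized by
its *peak* intensity (not its integrated mass), drawn into each on-plane of
its barcode; overlapping rolonies add; plane `j` is then multiplied by a
channel gain `c_j`; finally intensities clip at 1.

Simulator defaults mirror the benchmarking conditions the decoder targets:
1024×1024 px fields, peak ~ U(0.25, 0.7), sigma ~ U(2, 2.5) px, gains
~ U(0.75, 1.25), uniform spatial placement, gene identity uniform over the
non-empty codebook (empties are never simulated — they have no probes),
spot counts 5×10³–4×10⁵ per field. Gaussians are truncated at ±4σ
(relative truncation error < 4×10⁻⁴). The default benchmark codebook is
121 genes plus 10 empty barcodes from the (6,3) multi-color design.

Deliberately not modeled: camera noise and background offset (an optional
additive-Gaussian flag exists but defaults to off, since the reference
protocol states none), optical PSF structure beyond an isotropic Gaussian,
autofluorescence, registration error, and 3-D structure (decoding operates
on maximum-projected 2-D images). Passing benchmarks on these simulations
therefore demonstrates correctness of the decoding mathematics and
spot-level bookkeeping — not robustness to real-tissue nuisances.

## SpD decoding

Pixels mix at most a handful of rolonies, so the observed pixel vector
`y` (length `3n`) is modeled as a sparse non-negative combination of
codebook columns, `y ≈ c ⊙ Xw`. After normalizing by the channel gains,
each foreground pixel (`‖y/c‖₂ > 0.25`) is decoded by

    minimize_{w ≥ 0}   1/(2·3n)·‖y − Xw‖² + α‖w‖₁ + (α′/2)‖w‖₂²

with `α′ = α/100`. The data-term scaling is pinned by the detection
analysis: with `α′ = 0`, a pixel made purely of one barcode at intensity
`w` stays exactly at zero iff `w ≤ w_max = (3n/k)·α` (e.g. 0.3 at
`n=6, k=3, α=0.05`); the implementation reproduces this boundary to
within solver tolerance, which fixes the objective convention among the
scalings in common use.

**Solver.** Decoding a field of view means 10⁵–10⁶ instances of the same
small problem (shared design `X`, different `y`). The solver is a FISTA
proximal-gradient iteration vectorized across pixels — each iteration is a
pair of `(3n×N)·(N×P)` matrix products — with per-pixel adaptive restart
(momentum reset on the gradient criterion), periodic freezing of converged
pixels, and an explicit non-convergence counter (stragglers at the
iteration cap are zeroed, counted and logged). Because `w ≥ 0` makes the
L1 term linear, solutions carry exact zeros through the proximal step.
Tests cross-check the solver against two independent routes: coordinate
descent (scikit-learn's `ElasticNet`, which minimizes the same objective
under the mapping `alpha_sk = α+α′, l1_ratio = α/(α+α′)`) and a smooth
bound-constrained L-BFGS-B solve. Default stopping: max coordinate change
< 10⁻⁶, cap 2000 iterations.

**Elbow filter and refit.** The codebook supports confident decomposition
of at most two barcodes per pixel. Sorted weights pass if the second is
below 50% of the top (keep one) or, failing that, the third is below 30%
of the top (keep two); otherwise the pixel is rejected. Ties sort stably
by barcode index. Accepted supports are refit by ordinary least squares
for unbiased weights; a negative refit weight (physically meaningless)
drops that barcode and refits the survivor alone.

**Channel gains.** Starting from `c = 1`, a fixed random sample of
foreground pixels is iterated twice through: normalize by `c`, decode at
`α = 0.05`, keep pixels with exactly one accepted barcode whose refit
weight lies in [0.1, 0.5] (dominant but unsaturated), and update each
`c_j` by the scalar least-squares fit of observed `y_j` on predicted
`(Xw)_j`. Planes with no qualifying pixels keep their current value and
log a warning. The default sample is 20,000 pixels: the model has only
`3n = 18` free gains, and thousands of qualifying pixels per plane
estimate them to a median relative error of a few percent; the size is
configurable.

One subtlety is deliberate: `y = c ⊙ Xw` is invariant under
`(c, w) → (s·c, w/s)`, so the data determine the gains only up to a global
factor, and the scale the raw iteration settles in is an artifact of its
first, gain-mismatched pass (measured ≈ 6% below truth on simulations).
The estimate is therefore reported in the *unit-mean gauge*
(`mean(c) = 1`), consistent with the `c = 1` initialization. On simulated
gains drawn U(0.75, 1.25) this leaves the gain pattern accurate to ~1%,
with the residual error dominated by the realized mean of the drawn gains
(s.d. 3.4% for 18 draws) — information no gauge-invariant estimator can
recover.

**Adaptive regularization.** A single α cannot serve both dim rolonies
(which need small α to be detected at all) and bright crowded pixels
(which need large α for a clean elbow). α is therefore chosen per pixel
by norm: for every α on the grid 0.01–0.1 (step 0.005) the full SpD chain
runs on a training sample (default 10,000 foreground pixels), and for
every norm `u` on a 50-step grid over [0, 2.8] the α maximizing the
Gaussian-weighted (bandwidth σ = 0.1 ≈ two norm-grid steps; the reference
procedure leaves σ unstated) sum of refit L1 norms is tabulated. Ties go
to the larger, sparser α. Queries clamp to the grid and take the nearest
entry. The α sweep runs warm-started from the next-larger α, which makes
the 19-α training pass cost only a few cold solves.

Ordering: gains are estimated first (at fixed α = 0.05), then the lookup
is trained on gain-normalized pixels, then the field is decoded — matching
the dependency structure (the lookup needs normalized norms).

## Spot calling and filtering

Per barcode, the OLS weight map is Gaussian-smoothed (default σ = 1 px),
local maxima (default minimum separation 2 px) seed a watershed, and the
watershed runs over the *unsmoothed* non-zero support so spot areas stay
inside the barcode's decoded region (regions whose marker falls outside
the support are discarded). Each region yields area, weight-weighted
centroid, and max/mean weight. Smoothing and peak-separation defaults are
package choices (unstated in the reference protocol) scaled to the ~2 px
rolony sigma; both are exposed.

Empty-barcode spots are known false positives. A 100-tree random forest
(seeded; any probabilistic binary classifier satisfies the interface) is
trained on (area, max weight, mean weight) with empty/non-empty labels on
a seeded spot subsample, and every spot receives an emptiness probability.
Filtering removes spots at or above the threshold (default 0.325, midpoint
of the recommended 0.3–0.35 band). The empty rate — the fraction of kept
spots still carrying empty barcodes — is the observable proxy for
specificity; both the pre-filter and post-filter rates are computable
(`empty_rate_of` vs. the rate returned by `filter_spots`) since reporting
conventions differ.

## Cell assignment

Cell boundaries are the mask pixels whose 8-neighborhood touches another
label or background. A spot inside a cell is assigned to it at distance 0
regardless of thresholds. An exterior spot is assigned to the cell with
the nearest boundary pixel (Euclidean, converted to micrometers by the
pixel size; e.g. 0.284 or 0.366 µm/px for the two reference tissues) if
that distance is within the global threshold or a per-gene override
(supplied as a `gene → µm` map, so rules like "0 µm for myelin transcripts"
need no hard-coded gene names). Equidistant ties go to the smaller label
and are logged. The nearest-cell search considers all cells via one KD-tree
over all boundary pixels.

## Benchmarking

Decoded spots are matched one-to-one to ground-truth spots of the same
barcode at centroid distance strictly below 6 px, nearest pairs first
(an optimal-assignment variant is available behind a flag; at a 6 px
radius the two differ negligibly). Sensitivity = matched/truth;
specificity = matched/decoded; empty rate = decoded-empty/decoded.
Undefined ratios (empty denominators) are reported as missing, not zero.

The naive baseline matches each foreground pixel to its nearest barcode
after L2-normalizing both (threshold 0.7 on the Euclidean distance between
unit vectors), then groups labeled pixels into spots by per-barcode
8-connected components with intensity-weighted centroids; the grouping
rule is a package choice, as the cited baseline does not specify one. No
post-hoc filtering is applied to either decoder in sweeps.

### Problem sizes in the shipped test suite

The acceptance suite exercises the full chain at sizes chosen to probe the
claims without redundant computation: channel-gain recovery uses twenty
1024² fields at 10⁴ spots; the density sweep uses a 512² tile with spot
counts {1250, 5000, 25000, 50000} — the 1024²-field densities
5×10³–2×10⁵ scaled by the area ratio, keeping per-pixel crowding in the
regime the protocol actually covers. (Simulating 2×10⁵ spots directly on a
512² tile saturates every plane at the clip level; no pixel-based decoder,
including the baseline, recovers any spot there, so that condition would
compare zeros.)

## Numerical and degenerate-input choices

* Solver tolerance 10⁻⁶ (max coordinate change); single-pixel API uses
  10⁻⁹. Non-converged pixels are zeroed, counted, logged — never silently
  kept.
* Elbow ties: stable sort by (weight desc, barcode index asc).
* Lookup ties: larger α wins (sparser solutions).
* All-zero pixels, empty maps, empty masks, empty spot tables: empty
  results, not errors; undefined metrics: missing values.
* Raw stacks exceeding [0, 1] are rejected unless an explicit per-plane
  percentile scaling (default 99.9th) is requested, since the raw-to-unit
  mapping is acquisition-specific.
* All randomness flows through explicit integer seeds (`numpy` default
  generators); identical seeds reproduce spot tables and sweep CSVs
  byte-identically.

## Known limitations

* Per-pixel decoding shares no information between neighboring pixels; a
  joint spatial model would be stronger at extreme densities.
* The emptiness classifier sees only three features; morphology-aware
  features could sharpen the empty/real boundary.
* The simulator's idealizations (no background, perfect registration,
  isotropic PSF) mean measured sensitivities are upper bounds on
  real-tissue performance.
* The randomized independent-set search is a heuristic; reported set sizes
  are best-of-runs, not certified optima.
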