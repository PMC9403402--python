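# Methods

## Discriminant model

Given a cells × features matrix X (n × p) and k classes, the package forms
the pooled within-class scatter S_w = Σ_c Σ_{i∈c} (x_i − m_c)(x_i − m_c)ᵀ /
(n − k) and the between-class scatter S_b = Σ_c π_c (m_c − x̄)(m_c − x̄)ᵀ,
with class priors π_c the empirical class frequencies by default (a
`priors="uniform"` flag is available; which convention the method's original
description used is not stated, and empirical priors match the common
reference implementations). The discriminant axes are the top min(k − 1,
p) eigenvectors of the generalized eigenproblem S_b w = λ S_w w, computed
with `scipy.linalg.eigh`. Eigenvectors are S_w-orthonormal, so the pooled
within-class covariance of the projected coordinates is the identity;
centroid distances in LD space are therefore Mahalanobis-type distances in
units of within-class spread. Consequences of this convention are used
throughout: classification is nearest-centroid-plus-log-prior (exactly the
shared-covariance Gaussian rule), and separation scores are scale-free.

Numerical choices:

* **Ridge.** When S_w's condition number exceeds 1e12 — routine when the
  subset search fits tiny or collinear feature pairs — ε·trace(S_w)/p with
  ε = 1e−8 is added to its diagonal, a warning is logged, and the applied
  ridge is stored on the model. If the solver still fails, the ridge is
  escalated once (ε = 1e−4) before the fit is abandoned; inside the search
  an abandoned fit scores −∞ and is skipped.
* **Sign convention.** Each scaling column is flipped so its
  largest-magnitude loading is positive; fits are bit-deterministic and
  plots reproducible.
* **Eigenvalues** are clipped at zero (tiny negative values can arise
  numerically) and sorted non-increasing.

## Separation metrics

All metrics score the biaxial view (first two LDs; with k = 2 the single
axis is zero-padded). Each carries an explicit orientation, and the search
always maximizes the oriented score (negated when lower is better).

* **euclidean** — minimum pairwise Euclidean distance between class means:
  rewarding only embeddings that separate *all* labels.
* **silhouette** — mean silhouette coefficient (scikit-learn). Above 5,000
  cells a class-stratified, seeded subsample (≥ 2 cells per class) is scored
  instead: silhouette is O(n²) and the search evaluates hundreds of
  subsets. The cap is a tractability device, not part of the statistic.
* **pce** — the biaxial plot is pixelated into a 100 × 100 grid whose bounds
  are the exact per-axis data min/max, bins half-open with the maximum edge
  closed (no cell is lost). Each occupied pixel contributes
  1 − H(class proportions)/log₂ k with H Shannon entropy in bits; the score
  is the unweighted mean over occupied pixels. Averaging over occupied
  pixels only is a deliberate choice: empty pixels carry no class
  information, and counting them would reward sparse spreads.
* **pixeldensity** — mean per-pixel majority-class impurity
  (1 − max proportion) on the same grid; lower is better. The published
  prose for this score is ambiguous; this impurity form is the simplest
  definition consistent with "lower is better separation" and should be
  read as this package's dialect.

Pixel metrics are only informative when typical occupied pixels hold
several cells; at ≲ 1 cell per pixel every pixel is trivially pure and both
scores saturate. With 100 × 100 bins that means ≳ 10⁴–10⁵ cells; the tests
use coarser grids on small fixtures for this reason.

## The subset search

Step order: (1) fit all C(p, 2) feature pairs and keep the best pair; (2)
forward: evaluate all single-feature additions and add the best one —
unconditionally, because the walk must reach the full feature set; (3)
backward: evaluate removing each feature *except the one just added* and
remove the one whose absence most strictly improves the score, else remove
nothing; (4) repeat 2–3 until all p features are included; (5) take the
best score at each size 2…p; (6) refit on the subset at the elbow of that
curve.

The just-added guard in step 3 is this package's resolution of a loop that,
as literally described, could oscillate (add f, remove f, add f, …): with
the guard each iteration has net growth ≥ 0 and removal requires a strict
score improvement, so the walk terminates; a 2p iteration cap additionally
forces forward-only completion in pathological cases. Scores are compared
with absolute tolerance 1e−12 and all ties break lexicographically by
feature name, making the whole search deterministic and column-order
invariant. Every candidate evaluation is recorded in the trace (cached fits
are re-recorded, so candidate counts per step are auditable), and the trace
is always persisted by the CLI — it is the method's audit surface.

The search is refused above 100 features (override flag available): the
sweep is O(p²) fits per iteration and stepwise selection over hundreds of
features is rarely sensible. An advisory log message suggests stratified
subsampling when the cell count is outside roughly 50,000–200,000, the
range in which running the search on a subset loses little.

**Elbow.** Subset size and score are incommensurable, so both axes are
min-max normalized to [0, 1] (disable with a flag) before finding the point
farthest (perpendicular distance) from the chord joining the first and last
points; ties go to the smaller size. Two properties follow from the
geometry and should temper expectations. First, the endpoints are at
distance zero from the chord, so the smallest size can only be selected
through the degenerate collinear tie-break — on any noisy curve the elbow
is an interior size. Second, when the score curve is nearly flat (e.g.
min-centroid-distance on well-separated data, where estimated
Mahalanobis-type distances grow slightly but monotonically as features are
added), normalization amplifies sampling wiggles and the elbow lands on
whichever interior size wiggled highest: expect the selected set to contain
the informative features plus a small number of uninformative ones rather
than the minimal informative set. Inspecting the persisted score curve is
the intended remedy.

## Angular pseudotime

The rotation centre is the centroid of all cells (the mean of class
centroids, more robust to imbalance, is available by flag; the original
description fixes neither). Each cell's angle is its planar atan2 about the
centre, rotated so the designated start cell sits at 0 and wrapped to
[0, 360). Angles are continuous degrees; descriptions that number them
1–360 are treated as a presentation convention. The start cell maximizes
the mean of two designated phase scores (defaults G1.S and M.G1, the phases
flanking division). Orientation: explicit clockwise/counterclockwise, or
auto via a reference class expected to *follow* the start — the direction
in which that class's centroid comes within half a turn of the start is
chosen; without a reference, counterclockwise. A cell exactly at the centre
has no angle and raises. Division deconvolution adds 360°·d for division ID
d (any non-negative integers, generalizing 0/360/720 for d = 0/1/2).

Curves of a feature along pseudotime use a circular boxcar local mean on a
360-point grid (plain boxcar over the observed range once deconvolved) —
an intentionally simple substitute for the generalized additive models used
in presentation-grade figures; grid points with no cell within the
bandwidth are NaN rather than extrapolated.

`circular_rank_correlation` is the Fisher–Lee circular correlation applied
to uniform rank-angles (2π·rank/n), invariant to monotone circular
reparametrisation — the right yardstick for comparing a recovered
pseudotime with a generating angle.

## Preprocessing

Mass-cytometry pipeline, in this order: asinh(x/5) (cofactor flaggable),
then each feature divided by its own empirical 0.999-quantile
(linear-interpolation convention, so results are bit-reproducible) and
clipped to [0, 1]. Whether the published normalization clips is unstated;
clipping is the default here (standard CyTOF practice, keeps pixel metrics
scale-stable) and can be disabled. A feature whose quantile is ≤ 0 has no
meaningful scale and raises by name. Stratified subsampling keeps a floor
of min(20, class size) cells per class — rare populations survive — and
fills the remaining budget proportionally to class frequency
(largest-remainder rounding); if the target cannot cover the floors, a
warning is issued and the floor-only sample returned.

FCS ingestion is out of scope; CSV/TSV tables (cells × features, first
column cell ID, optional label column) are the I/O contract.

## Synthetic data

The generators produce the statistical structure each analysis assumes, at
desk scale; they are the package's study conditions, not emulations of any
particular instrument.

* **make_blobs** — k Gaussian classes (unit within-class SD) whose means
  differ only on the informative features and sit on a regular simplex
  (k ≤ p_informative) or regular k-gon under a random rotation, so the
  minimum pairwise centroid distance is exactly `separation` within-class
  SDs; noise features are shared N(0, 1) across classes. Default
  separation 6: clearly separated but overlapping tails, the regime the
  discrete-label analyses target. 500 cells / 6 features is the canonical
  search fixture (exhaustive enumeration stays cheap).
* **make_trajectory** — class t mean = t·drift·u along a fixed random unit
  direction in 3 informative dimensions plus noise features; a
  `drift_scale` flag produces a stunted cohort for held-out projection
  tests (its late time points project between the reference cohort's
  earlier centroids).
* **make_cycle** — each cell gets a true angle θ (uniform by default, or a
  von Mises mixture with the given concentration); phase j's score is a
  raised-cosine bump of circular distance from centre j·(360/k), support
  ±2 phase widths, amplitude 1, plus N(0, score_noise_sd) noise; the label
  is the arg-max score. The bump overlap gives the characteristic
  correlation pattern of real cell-cycle scores (adjacent phases ≈ +0.27,
  opposite phases ≈ −0.77 at the defaults) and the arg-max rule places all
  label confusion at phase boundaries (transitional cells). Default noise
  SD 0.1 — 10% of bump amplitude — leaves ~4% of labels off by one phase,
  a moderate-noise regime; n = 2,000 keeps the full pipeline under a
  minute.

What the generators deliberately do not emulate: realistic marker panels,
spillover, count noise, batch effects, or doublets. Passing tests
demonstrate the algorithmic contracts (oracle equivalence, search
optimality on easy instances, truth recovery) — not robustness to the
artefacts of real acquisitions.

## Known limitations

* The elbow rule cannot select the smallest subset size except on exactly
  collinear curves (see above); on flat score curves the selected size
  over-counts by 1–2 features.
* Stepwise search is a heuristic: its best-per-size can fall below the
  exhaustive optimum on hard (redundant, weakly informative) instances,
  and relevant collinear features may be dropped because keeping both does
  not improve separability.
* Pixel metrics saturate on sparse embeddings (few cells per pixel).
* Quadratic/regularized discriminant variants, kernel LDA, and the
  embedding algorithms an exported initialization feeds (UMAP, PHATE) are
  out of scope; the package only emits coordinate matrices for the
  handoff.
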