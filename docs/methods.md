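# Methods

## Scope and model

`flimcyte` implements the computational chain of label-free optical
metabolic imaging (OMI) of somatic-cell reprogramming: two-photon
fluorescence-lifetime (FLIM/TCSPC) image cubes of the autofluorescent
coenzymes NAD(P)H and FAD are fit per pixel, segmented into single
cells, summarized into 11 metabolic and 8 nuclear parameters per cell,
and fed to classification and pseudotime-trajectory stages.  Every
stage is exercised against a ground-truthed synthetic scene generator,
so the chain is testable without raw microscope data.

### Decay model

Each pixel's photon-arrival histogram is modeled as

    I(t) = A [ α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂) ] + C,   α₁ + α₂ = 1, τ₁ ≤ τ₂,

convolved with the instrument response function (IRF), with mean
lifetime τ_m = α₁τ₁ + α₂τ₂.  Both coenzymes have quenched (short) and
unquenched (long) lifetime configurations, hence two components; C is
ambient background light.  The forward model evaluates the
biexponential at bin centers, normalizes by the analytic integral
α₁τ₁ + α₂τ₂ so the noiseless signal integrates to the photon amplitude
A, and applies linear discrete convolution with the unit-sum IRF
kernel, truncated to the record window.  Bin-center (midpoint)
sampling keeps the discretization error of the integral at O(Δt²),
well below photon noise at realistic budgets.

Defaults: 512 bins over 12.5 ns (the 80 MHz repetition period of a
typical Ti:sapphire source), Gaussian IRF of 240 ps FWHM positioned
0.6 ns into the window (leaving pre-rise bins for background
estimation).  A tabulated IRF can be substituted.

### Fitting

`fit_pixel` minimizes weighted squared residuals with
`scipy.optimize.least_squares` (TRF, box constraints).  Weights follow
the Poisson variance approximation.  A first pass uses data-derived
weights 1/max(n,1); because empty tail bins then pull the fit low (the
Neyman-χ² bias — at ~10⁵ photons it reaches ≈ −0.03 ns on a 2.13 ns
monoexponential standard, comparable to the calibration tolerance),
converged fits are re-solved with model-derived weights 1/max(m,1e−3)
(two reweighting passes, skipped when the first fit is already
near-perfect, reduced χ² < 0.05).  A Poisson-deviance maximum-
likelihood objective is available as `objective="poisson"`.

Initialization: background from the 5th percentile of the histogram;
τ₂ from a weighted log-linear fit of the tail restricted to bins with
meaningful signal; τ₁ = 0.3 τ_tail; α₁ = 0.7.  Multi-start (three
scaled τ initializations) runs only when the first solution describes
the data poorly (reduced χ² ≥ 1.5).  Amplitude is parameterized on a
log scale.  If the optimizer crosses the components, they are swapped
and α₁ relabeled as 1−α₁, so τ₁ ≤ τ₂ always holds; α₁+α₂ = 1 holds by
construction.  Fits with τ₂−τ₁ below 0.05 ns collapse to a
monoexponential report with α₁ = 1 and a `degenerate` flag.

Pixels are pooled over a 3×3 neighborhood (configurable radius,
zero-padded at borders — photon counts outside the detector are zero;
reflective padding would fabricate photons) and excluded when the
pooled peak bin holds fewer than 50 photons (the published protocol
thresholds low-signal pixels without stating the value; 50 is this
package's default).  Intensity images are integrated from the raw,
un-binned cube.  Invalid pixels carry NaN.

### Segmentation

Nuclei appear dark inside bright cytoplasm (NAD(P)H is cytosolic).
The rule-based nucleus-probability backend inverts and min-max
normalizes the Gaussian-smoothed intensity over the hole-filled
foreground (smoothed intensity ≥ `foreground_threshold`, default 120
photons).  Probability is zeroed within `edge_margin` = 3 px of the
foreground boundary: smoothing mixes cell and background intensities
there, creating inverted rings that would otherwise mimic nuclei.
The backend is pluggable so a trained pixel classifier can replace it.
Object detection is smooth (σ = 1 px) → threshold (0.3) → 8-connected
labeling → area filter (15–500 px), matching the published detection
settings; 8-connectivity avoids splitting diagonal necks.

Cells grow outward from nuclei by exact multi-source Dijkstra
(`skimage.graph.MCP_Geometric`) over a per-pixel step cost
λ + |∇I|/max|∇I| with λ = `propagation_reg` = 0.05, restricted to the
foreground — the classic seeded "propagate" secondary-object
algorithm: growth is geodesic distance penalized by intensity drops.
Labels are assigned in stable order of increasing cumulative cost, so
the partition is deterministic; with uniform intensity the boundary
between two seeds is the perpendicular bisector to within a pixel.
Cytoplasm is the per-label set difference cell ∖ nucleus; labels whose
cytoplasm is empty are flagged.

### Features

Metabolic parameters are means of the fitted maps over valid cytoplasm
pixels; intensities are cytoplasm means of integrated counts; the
optical redox ratio I_NADPH/(I_NADPH+I_FAD) uses the cell's mean
intensities (ratio of means — robust to photon noise; a mean-of-ratios
variant is exposed).  Nuclear morphometry conventions: perimeter by
Crofton (isotropically corrected) boundary length; nuclear shape index
NSI = P/(2√(πA)) (1 for a disc, larger otherwise); mean radius = mean
distance-to-boundary over nucleus pixels; solidity and extent from
region properties; a neighbor is another nucleus whose boundary comes
within 5 px (configurable); first-neighbor distance is centroid-based
and NaN for a lone cell.  z-scores standardize each parameter across
cells with the population (N) standard deviation; zero-variance rows
are flagged and set to 0.  Heatmap ordering uses average-linkage
Euclidean agglomeration (scipy), verified in tests against a naive
O(n³) implementation.

### Classification

Repeated stratified k-fold cross-validation (default 15 folds, 100
repeats; fold assignments re-drawn each repeat).  Stratification deals
shuffled within-class cells to the currently smallest fold, keeping
fold sizes within one of each other — for 2137 cells and 15 folds the
largest test fold is 143 cells against a 1994-cell training
complement.  The default model is a 100-tree random forest with √p
features per split; logistic regression, k-nearest-neighbor and
Gaussian naive Bayes share the interface.  Out-of-fold predictions are
pooled per repeat; accuracy (micro-averaged), one-vs-rest ROC/AUC per
class (trapezoidal, tie-handled — equal to the Mann–Whitney
statistic), and the confusion matrix are averaged over repeats.
Feature weights use the gain ratio GR = [H(C) − H(C|A)]/H(A) in bits,
with continuous features discretized into 10 equal-frequency bins
(configurable; MDL-based supervised discretization, common in
machine-learning toolkits, is not reproduced) and GR ≔ 0 when
H(A) = 0.  The
accuracy-vs-k curve retrains on the top-k gain-ratio parameters; the
FAD-lifetime-only preset {FAD τ_m, τ₁, τ₂, α₁} covers the
single-channel configuration.

### Trajectories

Features are min-max scaled; the UMAP metric "Jaccard" is interpreted
for continuous data as the weighted (Ruzicka) Jaccard similarity
Σmin/Σmax converted to distance 1−s and passed to UMAP as a
precomputed matrix (plain set-Jaccard is meaningless on reals;
Euclidean is the fallback).  Defaults: 20 neighbors, min_dist 0.3, 2
components, fixed seed.  Clustering is Leiden community detection on
the symmetrized kNN graph (resolution parameter exposed; seeded) or
k-means.  The principal graph is the Euclidean minimum spanning tree
of cluster centroids with edges longer than 3× the median MST edge
removed — a deliberate simplification of principal-graph learning that
reproduces branches and disconnected components but makes no claim of
matching any particular tool's cluster count or branch count on real
data.  Branch points are nodes of degree ≥ 3.  The root defaults to
the cluster richest in EPCs.  Pseudotime projects each cell onto the
nearest point of its component's edges and measures geodesic distance
from the root; cells in rootless components are NaN.  Moran's I uses
binary kNN weights (k = 10) symmetrized by maximum, zero diagonal;
zero-variance parameters are undefined and reported NaN.

## Synthetic data

The generator emulates micropatterned ("μFeature") scenes: a circular
adhesion island holding non-overlapping disc cells with concentric
disc nuclei, rendered into two photon cubes with per-bin Poisson
noise.  Per-cell decay parameters are drawn from truncated-normal
class-conditional distributions for the three reprogramming stages
(erythroid progenitor EPC → intermediate IM → induced pluripotent
iPSC).  Published effect *directions* constrain the defaults; the
numeric centers are this package's choices:

| parameter | EPC | IM | iPSC | rationale |
|---|---|---|---|---|
| redox ratio | 0.40 | 0.50 | 0.62 | rises monotonically with reprogramming (iPSC > IM > EPC) |
| FAD α₁ | 0.86 | 0.60 | 0.74 | biphasic dip at IM (transient OXPHOS burst); largest standardized separation of any parameter |
| FAD τ_m | ≈0.52 | ≈1.05 | ≈0.72 | biphasic in the opposite phase, as implied by α₁ at near-constant component lifetimes |
| NAD(P)H α₁/τ₁/τ₂ | 0.78/0.35/2.30 | 0.74/0.40/2.60 | 0.70/0.45/2.80 | canonical free/bound coenzyme ranges, mild monotone drift |

Channel amplitudes encode the redox ratio: A_FAD = A_NADPH(1−r)/r with
A_NADPH = 1000 signal photons per cytoplasm pixel (per-pixel budgets
are not published; 1000 is realistic for the stated count rates and
dwell times).  Nuclei are rendered at 0.15× the cytoplasm amplitude —
dim enough to read as dark nuclei, bright enough to stay above the
ambient background (0.1 photons/bin) that the foreground mask must
separate them from.  Cell discs (radius 7–10 px) are placed by
rejection sampling (≤10⁴ retries, then an "overcrowded scene" error)
fully inside the island; the default 192×192 field with a 90 px island
keeps ≈25% packing.  Tabular generators (`sample_feature_table`,
`sample_progression`) produce the full 19-column schema directly from
the class distributions for population-scale testing of the
classification and trajectory stages, with a 2% multiplicative
measurement noise standing in for the photon-limited estimation error
of the imaging chain.

What the generator does **not** emulate — and what passing tests
therefore do not demonstrate on real data: optical point-spread blur,
photobleaching, detector afterpulsing, non-disc cell shapes, touching
or overlapping cells, intra-cell parameter gradients, day-to-day
instrument drift, and donor-to-donor variability.  Real-data headline
numbers (per-class AUCs near 0.99, a particular cluster or
branch-point count) are dataset-dependent and are covered only by
qualitative property checks.

## Numerical choices and degenerate inputs

* Fit bounds: α₁ ∈ [0,1], τ ∈ [0.01, 10] ns (both components, ordering
  restored post hoc), background ≥ 0 and ≤ the histogram maximum.
* Optimizer tolerances 1e−10; noiseless round trips recover parameters
  to well under 0.1%.
* Constant images yield an all-zero nucleus-probability map; empty
  probability maps yield zero labels; propagation without nuclei warns
  and returns an empty cell image.
* Both intensities zero → redox ratio NaN and flagged; zero-variance
  z-score rows → 0 and flagged; zero-variance Moran's I → error.
* All randomness flows from explicit seeds (`numpy.random.default_rng`);
  the pipeline derives per-stage seeds from the global seed, and two
  runs with the same configuration produce bit-identical cell tables.

## Problem sizes

The test suite and the acceptance script run reduced problem sizes
chosen as the smallest instances that still exercise every code path
meaningfully: 96×96 scenes with 9 cells and 256 time bins for
segmentation/feature recovery, 80×80 scenes with 6 cells and 128 bins
for end-to-end determinism, 150 cells/class tabular populations for
classification, 250-cell progressions for pseudotime.  The library
defaults remain at the full protocol scale (512 bins, 15×100 CV,
etc.).

## Known limitations

* The rule-based nucleus detector assumes dark-nucleus contrast; real
  images with bright nucleoli or low cytoplasm signal need the
  pluggable classifier backend.
* The propagation tie-break is deterministic but resolves equal-cost
  pixels in queue order rather than by label id.
* Gain-ratio values depend on the discretization; only rankings, not
  absolute weights, should be compared across discretizers.
* MST-over-centroids is a coarse principal graph; fine-grained
  branching inside a cluster is invisible to it.
* The fitter estimates a constant background only; no afterpulsing or
  incomplete-decay (wraparound) model.
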