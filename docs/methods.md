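# Methods

## Per-cell threshold selection and the clustering index

The package's central operation scores how much of a cell's fluorescence
is concentrated in bright puncta. For a cell C (a set of pixels from a
label mask) in channel I:

* whole-cell statistics: `m = mean(I[C])`, `s = sd(I[C])`. The SD uses the
  sample (n−1) normalization by default (`sd_mode="sample"`), the common
  default of spreadsheet and image-analysis environments; a population
  option is exposed for sensitivity checks. Statistics are computed in a
  single pass over the whole cell — aggregate pixels are not excluded and
  the threshold is never re-estimated iteratively. With bright puncta
  present this inflates both `m` and `s`, making the rule conservative for
  heavily aggregated cells; that behaviour is part of the statistic's
  definition, not an artifact.
* selection: pixels with `I > m + k·s`, default `k = 3`. The comparison is
  strict, so a perfectly constant cell (s = 0) selects nothing and scores
  index 0 instead of selecting every pixel.
* clustering index: `CI = Σ I[selected] / m`, with `CI = 0` for an empty
  selection. The numerator sums over the selected (aggregate-region)
  pixels only; summing over the whole cell instead would reduce the ratio
  to the constant pixel count and could not discriminate conditions. A
  zero mean with a nonempty selection is degenerate and raises rather
  than returning infinity.

Units: `CI` is dimensionless (AU·px / AU). It scales linearly with the
number and brightness of selected pixels, so it conflates "more puncta"
with "brighter puncta" by design — it is a concentration measure, not a
count.

Puncta are the connected components of the selection, 8-connected by
default (bright microscopy blobs touch diagonally), with components below
`min_punctum_px = 4` pixels discarded from counts and area statistics to
suppress single-pixel noise. The index always uses the raw, unfiltered
selection so the headline statistic matches the definitional formula
exactly.

Key invariants, all enforced by tests: selection equals an independent
per-pixel brute-force evaluation; `CI(c·I) = CI(I)` for any `c > 0`
(multiplicative invariance — which is also what gives the time-lapse
index first-order robustness to photobleaching); `CI` is *not* invariant
under additive offsets, so background subtraction policy matters and is
deliberately left to the caller (none is applied).

## Colocalization

Per-cell Pearson product-moment correlation of two channels over the
mask's pixels only; background cannot influence the coefficient. No
Costes-style pre-thresholding and no Manders coefficients. Zero variance
in either channel within the cell raises rather than propagating NaN. A
mask with a single whole-field label degenerates to a per-image
coefficient.

## PLA scoring

Nuclei: global Otsu threshold on the nuclear-stain channel, hole filling,
removal of objects under 50 px, connected-component labeling. Touching
nuclei merge into one label — no watershed splitting; this is a known
limitation for crowded fields.

Dots: scale-normalized Laplacian-of-Gaussian response at a single scale
`dot_sigma` (default 2 px), local maxima above `min_response`. For a
Gaussian spot of amplitude A and width `dot_sigma` the peak response is
A/2, which is how `min_response` is calibrated in intensity units; the
default 10 sits far above the filtered-noise floor at the generator's
noise level (σ = 5 AU) yet at only one fifth of an SNR-20 spot's response.

Assignment: a dot belongs to the nucleus whose label contains its
centroid's nearest pixel; dots on background are reported as unassigned,
never dropped, so assigned + unassigned always equals the detection
count. All segmented nuclei are reported, including zero-dot nuclei.

## Time-lapse trajectories

Each frame is scored independently by the static per-cell pipeline — no
temporal smoothing, no bleaching correction (the index's ratio form
absorbs multiplicative decay), no tracking (cell identity comes from the
supplied per-frame masks, matching the practice of following individual
transfected cells manually). A cell missing from a frame truncates its
trajectory at the last continuous frame with a warning. Group curves are
pointwise mean and SEM (sample SD / √n) over cells on a shared time grid;
trajectories are averaged raw, without per-cell normalization. The default
frame interval is 15 min, the cadence of overnight aggregation movies
(97 frames = 24 h).

## Escape-response classification

Within the 3 s window after the touch (t = 0): **normal** if the maximum
radial distance from the well center reaches `(1 − edge_tol)·R` with
`edge_tol = 0.05` — a finite-size tadpole cannot reach the wall exactly,
so "swam to the edge" is operationalized as 95% of the radius; **none**
if the total path length is below `move_tol·R` with `move_tol = 0.02` —
"failed to move forward at all" up to tracking jitter; **reduced**
otherwise, which covers every swim shorter than the well radius. The
"then around the well" clause of the normal response is not separately
enforced: reaching the wall in time suffices, since the other two
categories partition on distance alone. Classification is invariant under
rotation about the well center and under rigid translation of track and
well together, and scaling a track's displacements up never demotes its
category. Each animal is scored as the best of its first three trials
(normal > reduced > none); extra trials are ignored with a warning. Well
radius and sampling rate are inputs, not constants.

## Survival and group comparisons

Membrane bursting marks death; intact cells are right-censored at the end
of observation. The survival curve is the product-limit (Kaplan–Meier)
estimate, computed with `lifelines`; with no censoring it reduces exactly
to the empirical survival function, and this identity is asserted in
tests. The median survival time is the smallest t with S(t) ≤ 0.5 (NaN if
the curve never falls that far).

Mann–Whitney U is two-sided: exact enumeration when the combined sample
is untied with n ≤ 12, the tie- and continuity-corrected normal
approximation otherwise; a U at its null mean reports p = 1. Fisher's
exact test uses the standard two-sided rule (sum of hypergeometric
probabilities no larger than the observed table's), with p = 1 by
convention for a zero margin. One-way ANOVA reports the F test plus
pairwise t comparisons on the pooled within-group variance (residual
df = N − k), each raw p multiplied by the number of pairs and capped at 1
— adjusted p-values in the style of figure legends, rather than an
adjusted α.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their spec; the seed fixes
everything.

* **Scenes** (`SceneSpec`): disk cell (radius 40 px on a 128×128 field)
  over uniform background 100 AU, additive Gaussian read noise σ = 5 AU
  (clipped at 0), puncta as isotropic Gaussian profiles truncated at 3
  radii (radius 2 px, amplitude 50 AU ⇒ SNR 10), placed uniformly in the
  cell at least 3 radii from its edge and 4 radii apart. Gaussian rather
  than Poisson noise keeps the mean + 3·SD selection analytically
  predictable; truncated profiles give closed-form truth mass.
* **Time-lapse** (`TimelapseSpec`): per frame, amplitudes grow by a fixed
  increment, then lose a clearance fraction; new puncta nucleate
  (Poisson); puncta with centers within the coalescence distance merge,
  summing mass with a mass-weighted center — the minimal rule producing
  "small clusters that eventually coalesce". Zero clearance guarantees
  monotone truth mass.
* **PLA scenes**: disjoint disk nuclei (radius 18 px) plus Gaussian dots
  of width `dot_sigma` and amplitude `snr·σ_noise`, at least `4·dot_sigma`
  apart and well inside their nucleus.
* **Trajectories**: each animal draws its true category from its group's
  proportions; all its trials are built to satisfy that category's
  defining inequality with margin (normal reaches 0.97 R before 2.4 s,
  reduced stops at 0.15–0.45 R, none jitters with path length ≪ 0.02 R).
* **Event tables**: exponential burst times with the chosen group median
  (`None` = no deaths), right-censored at the end of a 48 h observation
  window by default. The window is chosen long enough that a group with a
  median in the 900–1600 min range — the scale of proteasome-inhibition
  survival experiments — crosses 50% survival inside it; a window barely
  past the median leaves the Kaplan–Meier median inestimable in a
  substantial fraction of simulated experiments.

Not emulated: optics (no PSF convolution of the whole scene), Poisson
photon statistics, photobleaching, cell motility or shape change, nucleus
texture, uneven illumination, tracking errors in behavioral data. Passing
recovery tests on these generators therefore demonstrates correctness of
the *computations* under controlled conditions, not robustness to every
real-microscopy artifact; on real data, segmentation quality and
background structure will dominate accuracy long before the index
arithmetic does.

## Problem sizes and numerical choices

Recovery rates are measured over 100 seeded scenes (puncta, PLA,
colocalization) and 50 replicate group comparisons of 10 + 10 simulated
cells × 16 frames (clearance discrimination); ANOVA type-I error uses
2000 null replicates of 3 × 10 Gaussians; survival medians use 2000
subjects per group. These sizes put binomial/sampling error well inside
the asserted bands. Floating-point: scale invariance is asserted to 1e-9
relative; the brute-force selection oracle must agree bit-exactly;
degenerate inputs (constant cells, empty selections, zero margins,
all-censored groups) are defined above rather than left to NaN
propagation. Image intensities are promoted to float64 at read time and
never normalized, since every index is a ratio of raw values.
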