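# Methods

## Induced time series

The observed variable is the RR tachogram x[n], the sequence of inter-beat
intervals of a beat-time record.  Induced variables are obtained by the
forward finite difference dx/dt[n] ≈ (x[n+1] − x[n])/(t_{n+1} − t_n),
applied repeatedly up to order 10.  Two conventions are fixed throughout:

* **Time base.**  Interval x[n] is stamped with the occurrence time of the
  beat that *terminates* it.  This is causal (computable in real time) and
  unambiguous; backward/central differences are expected to behave
  similarly and are not implemented.
* **Timestamp propagation.**  Each differencing step carries the *left*
  endpoint of the pair, so all orders stay aligned on their leading
  timestamps and repeated differencing is well defined.  An order-k series
  has length L − k for an order-0 length L.

Window truncation for short-observation analysis is anchored at the first
beat of the record with an inclusive boundary.

## State variables

Each series of the derivative stack is reduced by the arithmetic mean and
the standard deviation, defined everywhere as the square root of the
*unbiased* (n−1 denominator) sample variance.  Orders 0–10 give the
22-variable state space with the canonical ordering `mean_d0..mean_d10,
sd_d0..sd_d10` (units s^(1−k) at order k).  Extracting the full grid
requires at least max_order + 3 beats so the top order retains two samples
for its SD.

The derivative-order correlation matrix uses |Pearson r| on the shared
leading index range of each pair (the longer series' tail is trimmed).
Zero-variance series — detected by exact constancy, because floating-point
`std` of a constant vector need not be exactly 0 — yield NaN entries: a
degenerate correlation is reported as undefined rather than fabricated as
decorrelation.

## The γ-metric

Each group, restricted to a candidate variable subset, is modelled by its
1-SD ellipsoid: center μ (per-feature mean) and shape Σ (unbiased sample
covariance).  With u the unit vector from μ₁ to μ₂, the radius of ellipsoid
k along u is the ray–surface intersection r_k = 1/√(uᵀΣ_k⁻¹u), and

d = (‖μ₂ − μ₁‖ − r₁ − r₂)/(r₁ + r₂).

γ_M is the sum of d over unordered group pairs.  Properties relied on (and
asserted in tests): symmetry; γ ≥ −1 for two groups with equality exactly
at coincident centers; invariance under a common affine map of both groups'
samples; strict decrease when both covariances are inflated by a common
factor > 1; exact reduction to (|μ₁−μ₂| − (σ₁+σ₂))/(σ₁+σ₂) in 1-D.  The
normalization by (r₁ + r₂) is the simple choice that reproduces the
published 1-D γ table to its printed precision.

Numerical choices:

* **Ridge.**  Sample covariances receive ε·mean(diag(Σ))·I with ε = 1e−10;
  a fully degenerate (all-constant) group falls back to ε·I so the matrix
  stays invertible.
* **Singular Σ.**  If the solve still fails, the pseudo-inverse is used;
  a direction outside range(Σ) has radius 0 (flattened ellipsoid).
* **Degenerate configurations.**  Coincident centers give d = −1 (the gap
  is −(r₁+r₂)) unless both groups have zero extent, which is an error;
  distinct centers with two zero radii give +∞.

## Subset search

For each requested size n, all C(M, n) subsets of the M candidate variables
are scored by γ and the maximum kept; ties break to the lexicographically
smallest subset in canonical feature order.  Group means and covariances
are computed once and indexed per subset, so the search is exact by
default (the full 22-variable space, Σ C(22,k) ≈ 4.19 M subsets, is
enumerable in hours on one CPU; desk-scale runs restrict `sizes`).  An
optional per-size budget (`exact_limit`) switches to a greedy beam search
that grows subsets one feature at a time keeping the best `beam_width`
(default 64) at each level; such results are flagged `mode="beam"`.
Features with zero sample variance in *both* groups are excluded up front
with a diagnostic — γ along such an axis would be a ridge artifact.

## Classification

The classifier is unregularized logistic regression (scikit-learn's
IRLS/`newton-cholesky` solver, gradient tolerance 1e−8, 100 iterations).
Features are standardized internally with train-set statistics — the
high-order derivative features span several orders of magnitude — and the
weights are reported back on the original scale, so this is mathematically
neutral for maximum likelihood.  A perfectly separated training set has no
finite ML optimum; this is diagnosed (zero training error with saturated
margins, |η| > 10 for all samples) and the model is returned with
`converged=False` and a warning — expected behavior on well-separated
synthetic groups.  Evaluation uses a seeded *stratified* 80/20 split
(stratification keeps both classes present at small n).

The observation-time sweep truncates every record to the window,
re-extracts exactly the orders the subset needs, and re-evaluates.  Records
too short for the subset's top order at that window are excluded from that
cell and the usable count is reported; a cell whose surviving classes are
too small carries an error note instead of an accuracy.

Baselines: the Fisher/multiple-discriminant axis w ∝ S_pooled⁻¹(μ₂ − μ₁)
(unit norm, projection usable as a 1-D classifier input) and label-blind
PCA of the pooled feature matrix with explained-variance fractions.

## Perturbation models

* **TU** — independent U[−T, T] shifts per beat, T in ms at the interface
  (seconds internally).  A shift that produces a non-positive interval
  raises rather than re-sorting: silently re-sorting would change the
  noise model.
* **MB** — round(u·L) distinct beats removed, uniformly without
  replacement.
* **PAC** — round(u·L) insertions (L fixed from the original record;
  insertions do not beget more insertions).  Each event picks a gap
  uniformly among those wider than 400 ms, draws the ectopic time
  uniformly at least 200 ms from both neighbours, and shifts all later
  beats by the prematurity offset.  Eligibility is recomputed after every
  event; exhaustion raises an error carrying the number of applied events.
* **PVC** — same placement, but the next scheduled beat is deleted
  (compensatory pause); the beat count is invariant.

The pooled noisy database splits the NSR group into four quarters —
original, MB, PAC, PVC (remainder beats stay original) — drawing per-record
parameters uniformly from the sweep pools (MB up to 20%, ectopy up to
30%); AF passes through unperturbed in this builder.  A per-record manifest
(kind, parameter, sub-seed) enables exact replay.

## Synthetic generator

The generator emulates the *statistical* structure the analysis assumes,
not ECG morphology.  Group-level targets (per-series mean RR and per-series
beat-to-beat SD, across-series):

| group | mean RR (s)   | within-series SD (s) | lag-1 autocorr |
|-------|---------------|----------------------|----------------|
| NSR   | 0.80 ± 0.15   | 0.04 ± 0.02          | 0.95           |
| AF    | 0.61 ± 0.08   | 0.12 ± 0.03          | 0.10           |

Per series, the mean is drawn truncated-normal (NSR on [0.5, 1.2] s, AF on
[0.35, 0.9] s) and the SD lognormal with exactly the target mean/SD (always
positive, no truncation distortion).  NSR beat-to-beat dynamics are AR(1)
mixed with a ~0.25 Hz sinusoidal respiratory modulation carrying 30% of the
within-series variance; AF dynamics are near-independent standardized gamma
innovations (skewed, as AF interval histograms are).  The realized
deviations are standardized and rescaled so each series' sample mean and
SD equal its drawn targets exactly — calibration is then governed directly
by the draw distributions.  Physiological floors (0.30 s NSR, 0.25 s AF)
are enforced by redrawing the *deviations only*, keeping the drawn
per-series targets so group-level statistics stay unbiased; a rare
stubborn series is floored instead.

What the generator does **not** emulate: heavier-than-gamma AF tails,
nonstationarity within a minute, true respiratory coupling to heart rate,
or inter-subject record structure.  Passing tests therefore demonstrate
that the pipeline recovers the *assumed* moment structure and separability,
not clinical performance on real recordings.

## Problem sizes and test design

The acceptance-level property tests run at desk scale, chosen as the
smallest sizes at which the asserted statistics are stable: ellipsoid
oracle on 1,000 random 2-D/3-D pairs; search/brute-force equality on the
12-variable (orders ≤ 5) grid; variable-selection recovery on 450 NSR +
290 AF 1-min series over 10 seeds (majority rules on the selected-variable
class and ≥ 95% pair accuracy); window-shortening on 200 + 130 series over
5 seeds (3 s accuracy ≥ 85% and ≤ the 60 s accuracy in a majority of
seeds).  Stochastic assertions use fixed seeds and majority rules rather
than per-seed bounds, because single draws of the lognormal SD targets can
legitimately fall outside any fixed band.

## Known limitations

* The γ-metric compares groups along the mean–mean axis only; two
  ellipsoids can overlap off-axis while γ is positive.  This is the
  intended computational trade-off versus intersection-volume approaches.
* The exhaustive search is exponential in the variable count; beyond the
  22-variable space of this problem the beam fallback is advisory, not
  exact.
* `extract_features` requires two samples at the top order even when a
  subset only needs that order's mean — slightly conservative for the
  shortest windows.
* Timing-uncertainty stress at T = 100 ms can legitimately collide with
  short AF intervals; this surfaces as a typed error by design.
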