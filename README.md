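# rrgamma

Heart-rhythm state characterization from RR-interval tachograms using
**induced variables** — time derivatives of the inter-beat-interval series —
and the **γ separation metric** for discriminative variable selection.

## The problem

Atrial fibrillation (AF) produces "irregularly irregular" inter-beat (RR)
intervals, while normal sinus rhythm (NSR) is smooth and slowly modulated.
Automatic AF screening from wearable devices must decide from *short* RR
records, so every bit of information in the series matters.  By kinematic
analogy (position → velocity → acceleration → jerk), the tachogram's
dynamics are exposed by differentiating it: with the forward finite
difference

```
dx/dt[n] ≈ (x[n+1] − x[n]) / (t_{n+1} − t_n)
```

applied repeatedly up to order 10, each 1-min record yields 11 series, and
two operators (arithmetic mean and SD, the square root of the unbiased
sample variance) reduce them to 22 candidate state variables.

## The γ-metric

In the space of a selected variable subset, each rhythm group is modelled by
its 1-standard-deviation ellipsoid (center μ = feature means, axes from the
eigenvectors of the sample covariance Σ).  The pairwise distance is the
normalized surface-to-surface gap along the mean–mean axis,

```
u = (μ₂ − μ₁)/‖μ₂ − μ₁‖ ,   r_k = 1/√(uᵀ Σ_k⁻¹ u)
d = (‖μ₂ − μ₁‖ − r₁ − r₂) / (r₁ + r₂)
```

and γ_M sums d over all unordered group pairs (γ = d for two groups).
Positive γ means the ellipsoid surfaces do not overlap along that axis;
γ = −1 exactly when the centers coincide; in 1-D it reduces to
(|μ₁−μ₂| − (σ₁+σ₂))/(σ₁+σ₂).  Ranking all n-variable combinations by γ
selects a minimal subset of high discriminative power to feed a simple
classifier (unregularized logistic regression).

The package also provides the perturbation models used to stress the
analysis — R-peak timing jitter (TU), missing beats (MB), premature atrial
and ventricular contractions (PAC/PVC, with the 200 ms placement rule and
compensatory-pause structure) — plus PCA and Fisher-discriminant baselines,
an observation-time sweep, and a calibrated synthetic NSR/AF generator so
the full pipeline is testable without any external database.

## Worked example

```python
import rrgamma as rg

ds = rg.make_dataset(n_nsr=30, n_af=30, duration_s=60.0, seed=7)
table = rg.extract_feature_table(ds)

rank = rg.exhaustive_subset_search(table, sizes=[1, 2, 3])
for n in (1, 2, 3):
    sub, g = rank.best_per_size[n]
    print(f"best gamma_{n}: {[f.column for f in sub]}  gamma = {g:.2f}")

report = rg.evaluate_split(table, rank.best_per_size[2][0], seed=7)
print(f"validation accuracy (best pair): {report.accuracy:.3f} "
      f"(n_train={report.n_train}, n_val={report.n_val})")
```

prints

```
best gamma_1: ['sd_d1']  gamma = 0.96
best gamma_2: ['mean_d1', 'sd_d1']  gamma = 5.06
best gamma_3: ['mean_d1', 'mean_d5', 'sd_d1']  gamma = 6.33
validation accuracy (best pair): 1.000 (n_train=48, n_val=12)
```

The single most discriminative variable is the SD of a low-order derivative
(here `sd_d1`, the variability of the heart-rate change), adding its mean
raises γ further, and the γ-selected pair separates the two synthetic
rhythm groups perfectly on the held-out 20% split.  (A perfectly separated
training set makes the unregularized likelihood unbounded; the fit warns
and returns the capped-iteration model.)

The same pipeline is scriptable from the shell via the `rrgamma` console
command (`simulate`, `derive`, `features`, `gamma`, `select`, `perturb`,
`classify`, `sweep`); every run writes a manifest for exact replay.

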