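# chickvision

Analysis pipeline for studying **viewpoint-invariant object recognition in
newly hatched chicks** raised in automated controlled-rearing chambers.  In
this paradigm a chick is imprinted to a single virtual object seen only from
a narrow frontal viewpoint range (three images, ±15° azimuth, 1 image/s) and
then tested, two-alternative forced choice, on whether it approaches that
object rather than an unfamiliar one when the imprinted object appears from
novel viewpoints.  The test space is the full 9 × 9 grid of azimuth ×
elevation rotations (−60°…+60° in 15° steps), organized into 27 three-frame
animations; the unfamiliar object always appears from its frontal range.

The package implements every stage needed to analyze such an experiment —
and, because raw stimuli and animal data from published work are not
redistributable, ships synthetic stand-ins for both:

* **`stimuli`** — the viewpoint grid and animation structure, plus a
  deterministic orthographic renderer for synthetic 3D part-assembly
  objects (matched in size and mean foreground luminance, differing in
  shape).
* **`pixel_model`** — the retina-like null model: mean absolute per-pixel
  brightness difference, with the animation-level difference defined as the
  mean over all 9 ordered frame pairs.
* **`gabor_model`** — the V1-like null model: a 40-channel Gabor-jet bank
  (8 orientations × 5 scales), complex-cell magnitudes
  √(even² + odd²) sampled on a spatial grid, and dissimilarity
  `1 − r` (Pearson) in [0, 2].
* **`identity_model`** — identity prediction from image similarity: a model
  is *correct* for a condition when the within-object difference (test
  animation of the imprinted object vs its imprinting animation) is
  strictly smaller than the between-object difference (unfamiliar object's
  frontal animation vs the same imprinting animation); model and subject
  condition-level performance are compared with a Pearson χ² (df = 1, no
  continuity correction).
* **`behavior`** — trial scoring (preference = 100·t_imp/(t_imp+t_unf),
  correct iff > 50%), per-subject one-tailed exact binomial tests, group
  mean/SEM, rest-period imprinting checks, the 27-cell viewpoint map,
  elevation-magnitude and foreground-pixel correlations, the pairwise
  inter-subject correlation matrix with hierarchical-cluster ordering,
  day-by-day ANOVA, the familiar-range novelty-preference control, and
  regression of preference on image difference.
* **`stats`** — the statistical procedures written out explicitly:
  χ², exact binomial tail, Pearson/t/ANOVA/OLS, and intercept-only
  mixed-effects models with a subject random intercept (logistic via
  adaptive Gauss–Hermite marginal ML; linear via profiled REML).
* **`synthetic_behavior`** — a seed-deterministic cohort generator with the
  random-intercept structure the models assume:
  P(correct) = logistic(b + uᵢ + range effect), uᵢ ~ N(0, σᵤ).
* **`pipeline` / `cli`** — end-to-end orchestration and a `chickvision`
  command-line tool.

## Worked example

```python
from chickvision import behavior, identity_model, stimuli
from chickvision.synthetic_behavior import CohortParams, simulate_trials

# a synthetic cohort at the default generative parameters
trials = simulate_trials(CohortParams(seed=1))
mean_pct, sem = behavior.group_performance(trials)
mixed = behavior.mixed_intercept_tests(trials)
print(f"group: {mean_pct:.1f}% correct (SEM {sem:.1f})")
print(f"logistic intercept b={mixed['logistic'].b:.3f}, "
      f"z={mixed['logistic'].stat:.2f}, p={mixed['logistic'].p_value:.4f}")

# both null models over the 54 (object x range) conditions
obj1, obj2 = stimuli.default_objects()
outs = identity_model.evaluate_all_conditions(obj1, obj2, metric="pixel")
print("pixel model:", identity_model.model_performance(outs)["pooled"])

# chick-vs-model comparison on published condition tallies
chi2 = identity_model.compare_chick_vs_model((35, 19), (11, 43))
print(f"chi2(1, N=108) = {chi2.statistic:.2f}, p = {chi2.p_value:.2g}")
```

Output:

```
group: 59.9% correct (SEM 3.4)
logistic intercept b=0.418, z=3.06, p=0.0022
pixel model: 1.0
chi2(1, N=108) = 21.81, p = 3e-06
```

The group mean near 59%, the positive mixed-model intercept, and χ² = 21.81
are the kinds of readouts the pipeline produces: subjects above chance while
a pixel-level account of the same conditions performs very differently
(here, on the synthetic stand-in objects, the pixel model happens to score
100% — image-level results depend on the object geometry).

The same analyses are available from the shell:

```bash
chickvision simulate --seed 1 --out trials.csv
chickvision report --trials trials.csv --outdir out/
```

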