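# Methods

## The experimental design being modeled

A subject is imprinted to one virtual object shown only as a three-frame
animation (azimuths −15°, 0°, +15° at elevation 0°, looped at 1 image/s on
a white background).  Recognition is then probed two-alternative forced
choice: the imprinted object from one of 27 viewpoint ranges on one wall,
the unfamiliar object from its frontal range on the other, and
zone-occupancy time is the response measure.  The 27 ranges tile the 9 × 9
(azimuth, elevation) grid in 15° steps: azimuth centers {−45°, 0°, +45°}
crossed with the 9 elevations, each range rocking ±15° in azimuth around
its center.  Range ids are assigned elevation-major (id 14 is the familiar
frontal range).  Each subject sees every range once per day for 7 test
days: 27 trials/day, 189/subject, 1,890 for a 10-subject cohort.  Test
trials last 17 min, separated by 32-min rest periods during which the
imprinting animation is replayed on one wall (used to verify imprinting).

## Synthetic stimuli

The original virtual objects are not available, so `stimuli` renders
stand-in objects: assemblies of axis-aligned 3D boxes and ellipsoids,
drawn by an orthographic ray cast (nearest part per pixel ray, flat part
shades, white background).  Rotation convention (fixed and documented;
every analysis is symmetric in sign): positive azimuth rotates the object
rightward about the vertical axis, positive elevation upward about the
horizontal axis, azimuth applied first.  The default raster is 128 × 128
with luminance in [0, 1]; rendering is deterministic down to the byte.

The two default objects share the part count, shade palette, and bounding
size, and their mean rendered foreground luminance at the frontal view
agrees within 5% (measured: ~2.7%), while their shapes clearly differ —
the similarity contract of the paradigm ("similar in size and color,
different in shape").  Both occupy 30–70% of the raster frontally.
Because these are stand-ins, image-dependent outcomes (e.g. what fraction
of conditions a pixel-level model gets right) are properties of this
geometry, not reproductions of any published figure; on the default pair
both null models happen to score far above chance.

## Similarity models

**Pixel (retina-like).**  The difference between two equal-size images is
the mean absolute per-pixel luminance difference.  The difference between
two animations is the mean over all 9 ordered frame pairs (frame i of the
test animation against frame j of the input animation, i, j = 1..3).  The
mean (not the sum) over pixels makes values resolution-independent; only
orderings enter downstream decisions, and those are invariant to that
choice.  A corollary of the 9-pair definition worth stating: an animation
compared with itself does *not* give zero — 6 of the 9 pairs compare
distinct frames — so the within-object difference at the familiar range
equals the input animation's internal frame-to-frame variation.

**Gabor jet (V1-like).**  A bank of 40 quadrature pairs: 8 orientations
uniformly spaced over [0, π) × 5 wavelengths in a geometric series from 4
to 32 px (at the 128-px raster), Gaussian envelope set by a 1-octave
spatial-frequency bandwidth (σ ≈ 0.56 λ), kernels truncated at 2.5 σ, even
kernels DC-corrected so a uniform image produces no response.  The "jet"
of an image is the complex-cell magnitude √(even² + odd²) of every channel
sampled at a 10 × 10 interior grid (4,000 values).  Dissimilarity between
two images is 1 − Pearson r of their jets, in [0, 2]; animation-level
dissimilarity is the same 9-pair mean.  Convolution uses reflect padding,
so jets near borders are defined but border-dependent — magnitude
comparisons in tests use interior points.  Jet placement, wavelengths, and
raster size are conventions of the model family rather than dictated
values; they live in one config block (`GaborBankSpec`, `RunConfig`) and
results that depend on them are treated as qualitative.

**Identity model.**  For each of the 54 conditions (27 ranges × 2 choices
of imprinted object) the model is *correct* iff within-object difference <
between-object difference, with the unfamiliar object always at its
frontal range.  Ties score incorrect (the correctness condition is a
strict inequality in both directions; ties are a measure-zero event on
real images but occur exactly for degenerate object pairs).  Model vs
subject condition-level performance is compared with a Pearson χ² on the
2 × 2 correct/incorrect table, df = 1, **without** Yates correction — the
convention validated by reproducing both published statistics (21.81 and
14.90) from their printed count tables; the corrected values differ.

## Behavioral scoring

Preference = 100 · t_imprinted / (t_imprinted + t_unfamiliar); correct iff
preference > 50 (exactly 50 scores incorrect); trials with zero occupancy
of both zones are undefined and excluded, with exclusion counts reported.
Correctness is invariant to rescaling both times by a common factor.

Group-level inference uses intercept-only mixed models with a subject
random intercept: logistic on trial correctness, and linear on the
adjusted preference (preference − 50)/100 ∈ [−0.5, 0.5].  The 0–1 adjusted
scale is the one consistent with published coefficients of this design
(an intercept of ~0.07 corresponds to 7 percentage points).  Both analyses
are run with and without the familiar-range trials.  Other stages:
one-tailed exact binomial per subject (alternative "greater than chance"
throughout); rest-period binomials per subject; per-range percent correct
(the viewpoint map; empty ranges are NaN cells, not errors); Pearson
correlation of mean preference with elevation-change magnitude
(5 points: 0/15/30/45/60, df = 3); Pearson correlation of per-range
performance with mean visible foreground pixels (averaged over the three
frames and, when both objects are in play, over objects); the 45 pairwise
inter-subject Pearson correlations of per-range preference profiles with
their one-sample t against 0 (df = 44) and an average-linkage hierarchical
clustering on distance 1 − r for display ordering (linkage configurable;
constant-profile subjects yield undefined pairs and are excluded and
reported); one-way ANOVA over the 7 test days with day-level subject means
as the unit (df_between = 6, df_within = 63 for 10 subjects); and OLS of
per-condition mean preference on per-condition image difference
(54 conditions → slope t on 52 df).

## Statistical core

All procedures are written out in `chickvision.stats`; only distribution
tails (`scipy.stats` survival functions, `scipy.special.betainc`/`gammaln`)
are delegated.  The exact binomial tail uses the regularized incomplete
beta identity, stable to n ~ 10⁴.

**Logistic mixed model.**  Marginal maximum likelihood with **adaptive**
Gauss–Hermite quadrature: per subject, the integrand is re-centered at its
posterior mode (found by Newton iterations on the strictly concave
integrand) and rescaled by its curvature before applying the nodes.
Non-adaptive quadrature is *not* adequate here — with ~189 trials per
subject the integrand is an order of magnitude narrower than the
random-effect prior, and estimates drift visibly as the node count
changes; with adaptation, doubling the default 21 nodes changes the
estimate by < 10⁻⁶.  The Wald statistic is z = b/SE with SE from the
finite-difference observed information (2 × 2 in (b, σᵤ); 1-D in b when
σ̂ᵤ is pinned at zero), two-sided normal p.  Complete separation and
optimizer failure set `converged=False`, marking estimates unreliable.
With 10 subjects the Wald z behaves like a t with ~9 df, so its true level
at nominal α = 0.05 is ≈ 0.08; the acceptance suite budgets for this.
ML variance estimates carry the usual finite-cluster shrinkage
(≈ √((m−1)/m) on σᵤ for m subjects).

**Linear mixed model.**  REML for the one-way random-intercept model with
the variance ratio λ = σᵤ²/σₑ² profiled out and optimized on the log scale
(closed forms for the GLS intercept, profiled σₑ², and the restricted
likelihood).  Verified against statsmodels `MixedLM(reml=True)` to ~10⁻⁶
on fixtures.  The reported Wald t uses df = N − n_subjects − 1; df
conventions for this model vary across packages, so exact df agreement
with any particular one is not a goal.

## Synthetic cohort generator

`synthetic_behavior` emulates the design and the generative structure the
models assume.  Per subject i, uᵢ ~ N(0, σᵤ); per test trial,
P(correct) = logistic(b + uᵢ + δ_range); given the correctness draw, the
preference is placed on the matching side of 50 with spread
50·Beta(2, 4) (graded scores rather than 0/100), and zone times split the
occupied fraction (default 0.8) of the 1,020-s trial.  Rest periods favor
the imprinting wall with probability 0.88.  Defaults are the study
conditions: 10 subjects (4 imprinted to object 1, 6 to object 2), 7 days,
b = 0.394, σᵤ = 0.5.  The default shared range effect is a linear
elevation gradient of 0.015 log-odds/degree, calibrated once so a default
cohort shows the qualitative structure the analyses probe — viewpoint-map
cells spanning roughly 30–80% correct, mean inter-subject profile
correlation ≈ 0.3, group mean ≈ 58–60% — and not revisited.  Output is
fully determined by the seed; per-subject substreams derive from
`SeedSequence(seed, subject_index)`, so per-subject data are stable under
cohort-size changes.

What the generator does **not** emulate: spatial movement within the
chamber, imprinting dynamics, within-day fatigue or order effects,
autocorrelated occupancy, or any image-driven component of behavior
(range effects are imposed, not computed from the renders).  Passing
parameter-recovery and type-I tests therefore validates the estimators
and the pipeline's plumbing under the assumed generative model — not
claims about real animals.

## Numerical and design choices

* Foreground pixels: luminance differing from background by > 0.5/255
  (half an 8-bit step), so PNG round-trips preserve counts.
* χ²: zero marginals raise (degenerate table).  Correlation: zero variance
  raises; identical inputs return r = 1 exactly (guarding roundoff below
  1, which would otherwise make identity dissimilarities ~10⁻¹⁶ instead of
  0).  Blank-image jets (zero variance) raise rather than returning a
  conventional value — the design never compares blank frames.
* Jet activations are computed as windowed dot products at the sample
  points (identical to reflect-padded convolution sampled there, verified
  against `scipy.ndimage.convolve`), with renders and jets cached by image
  content during condition evaluation.
* Test-suite problem sizes: metric axioms on 4 × 4 brute-force fixtures
  and 96-px gratings; identity-model oracles at 64–96 px; mixed-model
  recovery at 200 replicates of the 10 × 189 design and type-I checks at
  150–400 replicates, with tolerance bands derived beforehand from the
  design's sampling variance (SE of a 200-replicate mean of b̂ ≈ 0.012)
  plus the known small-sample effects above.
* The report embeds the config hash and the operation name behind each
  section; identical config + seed yields byte-identical JSON.

## Known limitations

* The renderer is a flat-shaded painter's projection: no lighting,
  texture, perspective, or color, so it cannot reproduce the appearance of
  any specific published stimulus — only the structural contract (two
  same-size, same-brightness, differently shaped objects on white).
* Identity-model percentages on the synthetic pair are geometry-dependent
  and intentionally not compared against published image-dependent values.
* The logistic mixed model covers the intercept-only Bernoulli case the
  pipeline needs (no covariates, slopes, or other GLMM families).
* Wald inference with 10 clusters is anticonservative at the ~3-point
  level noted above; a cluster-robust or likelihood-ratio alternative is
  out of scope.
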