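# Methods

## Colour Pattern Modelling

Each wing image (RGB in [0, 1] plus a wing mask) is categorised pixel-wise
into C ∈ {3, 4} colour classes by nearest RGB centroid (Euclidean metric;
exact ties go to the earlier class in the centroid ordering). The default
centroids are the synthetic renderer's class colours; for photographs they
should be replaced with measured patch colours, or initialised by k-means.
Categorisation happens in raw RGB — no colour-constancy correction is
attempted, so photographs must be taken under standardised light.

Specimens of one wing side are aligned to an **average template** so that a
pixel position means the same anatomical location on every wing:

1. *Pre-normalisation*: each specimen's mask centroid is translated to the
   grid centre and its mask area scaled to the median area. The translation
   is snapped to whole pixels and the scale to 1 when within 2% — sub-pixel
   pre-adjustments are below the label-grid resolution and are left to the
   registration step, which keeps already-aligned specimens exactly fixed.
2. *Template iteration*: the template starts as the per-pixel modal class
   (background counts as a category; ties favour background, keeping the
   template mask conservative). Each sweep registers every specimen to the
   template with the similarity transform (translation, rotation, isotropic
   scale) maximising in-mask class agreement, then recomputes the modal
   template from the aligned maps. Iteration stops when no template pixel
   changes (tol = 0) or after 50 sweeps.

Registration maximises a smooth surrogate — the correlation of linearly
interpolated one-hot class channels (background included, so drifting off
the wing is penalised) — by Powell's method from three initial rotations
(−10°, 0°, +10°), parameterised as (θ, log s, t_x, t_y) about the grid
centre so scale stays positive. The final transform is accepted only if it
beats the identity on exact nearest-neighbour agreement; ties keep the
identity, which makes alignment idempotent. Label resampling is always
nearest-neighbour, so alignment can move a pixel's class but never invent
one. Registration is on full in-mask class agreement (outline *and*
pattern); the choice is recorded in the aligned map's transform metadata.
A full affine family is deliberately not offered: shear/anisotropy have no
anatomical meaning for flattened wings and would let the optimiser trade
pattern distortion for agreement.

**Encodings.** The *binary* encoding writes, per template pixel, a one-hot
vector over the C classes (background = all zeros, so a wing-shape
difference costs 1 per pixel in squared distance, not 2). The *quantum
catch* (QC) encoding replaces the one-hot values with the pixel class's
quantum catches under a chosen observer, each receptor channel first
range-normalised across the classes so no channel dominates the PCA purely
by scale (raw and log modes are available and tagged in outputs; which
scaling the perceptual analysis "should" use is genuinely open, and the
default was fixed before any downstream result was inspected).

**PCA and distances.** The specimen × feature matrix is mean-centred and
decomposed by full-SVD PCA. All non-trivial components are retained
internally; phenotypic distance is the Euclidean distance on the first
`n_components` scores (default 8 — with the small specimen sets used here,
eight components capture all or nearly all variance, since rank ≤ n − 1).
If fewer components exist, all are used and a warning logged. Because PCA
is a rotation, distances over all components equal raw-space distances
exactly; this identity is used as a test oracle throughout. Fore- and
hindwings would be encoded separately and concatenated per specimen; the
synthetic demonstrations use a single wing.

## Receptor-noise-limited discrimination

Quantum catches are trapezoidal integrals Q_i = ∫ R(λ) I(λ) S_i(λ) dλ on a
1 nm grid clipped to the observer's wavelength range (UV-type vision
300–700 nm, V-type and human 400–700 nm) intersected with the spectra's
supports. Catches are linear in reflectance and illuminant by construction.

Channel noise is e_i = ω·√(η_max/η_i) with Weber fraction ω = 0.05 anchored
on the *most abundant* cone class — the dominant convention for this model
family; an alternative per-class anchor can be had by passing uniform
ratios. Chromatic contrast uses Fechnerian log-catch differences
Δf_i = ln(Qa_i/Qb_i) in the standard closed forms: for a dichromat
ΔS = |Δf_1 − Δf_2|/√(e_1² + e_2²); tri- and tetrachromats use the quadratic
forms over pairwise Δf differences weighted by complementary noise
products. ΔS is symmetric, zero for identical stimuli, and invariant to a
common illuminant scaling; 1 JND is the conventional discrimination
threshold, used by `print_fidelity_check` to flag colour reproductions a
given observer could tell apart. Achromatic (double-cone) contrast is out
of scope.

Receptor sensitivities are parametric Gaussian pigment templates (unit
peak, σ = 40 nm; peaks UVS 370 / SWS 450 / MWS 540 / LWS 605 nm for birds,
with the violet-shifted SWS1 at 420 nm for the V-type preset, and 442 /
543 / 570 nm for humans). These are deliberately simple stand-ins: they
preserve the qualitative ordering of spectral overlap that drives the
model, but are not measured curves, and any quantitative JND for a real
animal requires replacing them (CSV-loadable) along with a measured
illuminant (default: flat).

## Synthetic data

The generator emulates the *structure* of a mimicry predation study, not
any particular dataset:

- **Morphs** are elliptical/band patches in wing-fraction coordinates on an
  elliptical wing, painted in order over a background class, so class areas
  and pairwise pixel differences are analytic — every rendering test has a
  closed-form oracle. Noise is i.i.d. Gaussian RGB jitter (default
  σ = 0.02), which keeps nearest-centroid categorisation essentially exact;
  real photographs have structured variation (shading, scale texture,
  specularity) that this does not represent.
- **Heterozygotes** interpolate each pattern element's centre and size
  between the parents with dominance coefficient d (d = 1 reproduces the
  dominant parent exactly); the colour class follows the heavier parent.
  Intermediates therefore remain valid 4-colour patterns, as the pixel
  categorisation requires — a pixel-wise alpha blend would not.
- **Reflectances** are smooth parametric curves: black ≈ 5% flat, white
  ≈ 80% flat, yellow a sigmoidal step up near 500 nm, orange near 550 nm.
  They reproduce the coarse ordering of real patch spectra (long-wave steps
  for yellow/orange) without claiming spectrophotometric accuracy.
- **Predation** draws one Bernoulli attack per dummy (roles: two local
  homozygotes at 0.04, heterozygote and exotic at 0.08, palatable control
  at 0.045) and an independent recovery flag (default 0.984); attack
  outcomes exist only for recovered dummies. Defaults encode the study
  conditions they emulate — exotic and intermediate morphs attacked about
  twice as often as locals, ~5% overall attack rate, ~98% recovery — and
  are fully overridable. Between 180 and 300 stations per site, five roles
  per station. Attacks are independent across dummies (no station- or
  predator-level correlation), matching the per-trial binomial GLMs used
  downstream; if real predators attack in correlated bouts, the simulated
  standard errors are optimistic. Field sessions are treated as
  exchangeable. An optional hook makes the heterozygote's attack
  probability an arbitrary function of its phenotypic distance to the local
  peak, used for parameter-recovery checks.

Passing tests on these inputs show the *machinery* is correct (encodings,
transforms, estimators, closed forms), not that any biological conclusion
transfers to real wings or predators.

## Statistics

Unrecovered dummies are excluded everywhere. Across-station summaries use
the sample (n − 1) standard deviation; the standard error of per-group
attack counts is s.d./√n_groups and reported as undefined for a single
group. Site homogeneity of the palatable control is a 2 × k χ² test
without continuity correction (df = k − 1).

The attack GLM is binomial with logit link and phenotype as the sole
predictor. Because the one-factor model is saturated, every pairwise
contrast equals the closed-form 2 × 2 log-odds difference with Wald s.e.
√(Σ 1/cell); both routes are computed and must agree. Fitting uses
role-aggregated binomial counts (identical likelihood up to a constant),
but deviance and AIC are reported on the per-trial Bernoulli scale, where
the saturated log-likelihood is zero and AIC = deviance + 2k holds as an
exact identity. Roles with zero or all dummies attacked are flagged as
separated and their contrasts suppressed rather than reported as ±∞. The
phenotype factor is tested by analysis of deviance (likelihood-ratio χ² on
k − 1 df). The pooled model's reference level is the exotic morph; since
all pairwise contrasts are emitted, the choice is cosmetic. No
multiple-testing correction is applied by default.

Attack ratios (heterozygote / dominant homozygote) use a Haldane–Anscombe
0.5 correction when the homozygote has zero attacks, and the record is
flagged. Ratio-versus-distance regressions are OLS; both plain and
adjusted R² are reported, as small-n F/R² pairs are only mutually
consistent under one of the two conventions and users should see both. The
peak-distance model comparison fits the nested binomial GLMs {1}, {D},
{R}, {D+R}, {D+R+D×R} (D = het-homD, R = het-homR), reports Bernoulli-scale
AIC and ΔAIC, flags |r| > 0.999 collinearity between D and R, and returns
the interaction's Wald test from the full model.

## Landscape

Peak and valley calls are one-sided Wald tests at α = 0.05 on the log-odds
contrast against the pooled exotic baseline (one-sided because the peak
definition is directional; 0.5 is added to all cells only when a count is
degenerate, and only for the annotation z-score). A local homozygote
significantly below the baseline is a *peak*; a heterozygote not
significantly below it is a *valley*; a significantly protected
heterozygote is left undetermined with a `protected` flag, since "peak" is
reserved for the mimetic homozygotes. Peak height is reported simply as
1 − attack rate (height in the frequency-dependent sense would require
local morph abundances, which are outside this package's inputs). Ridge
scores are continuous, not categorical: the OLS slope of attack ratio
versus het-homD over a homozygote pair's records, or with a single record
the secant slope through the ideal protection point (distance 0, ratio 1).
Annotations are a pure function of (counts, α), so a saved landscape can be
re-derived from its own tables; this is tested.

## Pipeline defaults and problem sizes

The demonstration configuration uses 5 morph sets (dominance coefficients
0.9 → 0.35, so het-homD grows monotonically across sets), 64 × 64 px
renders, 8 sites combined into 5 site-groups (the first three sets tested
at two sites each), 200 stations per site, and all three observer presets —
about 8,000 dummies and 20 specimens per run, completing in roughly a
minute on one CPU. Stochastic properties (peak/valley call reliability,
coefficient recovery, AIC model recovery) are asserted over 200 seeds at
2,000–10,000 dummies per role; these sizes give the binomial tests enough
power that the asserted frequencies (≥ 90–95%) hold with margin. Landscape
coordinates default to the QC PCA under the blue-tit (UV) observer, with
binary coordinates always co-emitted.

## Known limitations

- Similarity-transform alignment cannot express non-rigid wing
  deformation; badly folded or torn wings should be excluded upstream.
- The registration objective is non-convex; the multi-start heuristic
  covers rotations within roughly ±15°. Specimens imaged upside-down or
  rotated further need a coarse pre-orientation.
- Gaussian sensitivities, a flat illuminant and synthetic reflectances make
  all JND values illustrative, not species-accurate.
- Bernoulli attacks ignore predator heterogeneity, spatial autocorrelation
  between stations and the 72 h exposure dynamics; exposure differences
  enter only through exclusion of unrecovered dummies.
- With one ratio record per homozygote pair the ridge score is a secant
  slope, which conflates intercept and slope information; it is labelled by
  `n_records` so users can filter.
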