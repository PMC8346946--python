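# Methods

This note documents the models, conventions and numerical choices behind
`glyphcomplexity`, in the order data flows through the pipeline.

## Image standardization

Characters are binary masks (foreground = true).  Grayscale inputs are
re-binarized at 50% of their dynamic range, dark side = character by
default.  Four stages:

1. **raw** — a 500×500 canvas.  Optional font rendering draws each
   codepoint at point size 60; if any glyph of a script overflows the
   canvas the whole script is re-rendered at 5 points less, repeating
   until everything fits.  A codepoint the font cannot ink yields a
   missing-symbol marker, which feeds the per-script missing count.
2. **trimmed** — tight bounding box of the ink.
3. **resized** — one ratio per script, `490 / (largest dimension of the
   script's largest trimmed glyph)`, applied to every glyph of the script
   (aspect preserved, target dimensions rounded half away from zero and
   clamped to 490), then re-centered on the 500×500 canvas.  A single
   shared ratio equalizes scripts while preserving the size variation
   *within* a script.  Centering is a deliberate convention: both
   complexity metrics are translation-invariant, but the half-split needs
   a well-defined placement.
4. **skeleton-standardized** — medial axis (`skimage.morphology.medial_axis`
   with a fixed tie-break rng, so the pipeline is bit-deterministic),
   branch pruning, then dilation with a square structuring element of
   half-width 2, giving every stroke a uniform 2·2+1 = 5 px thickness.

**Pruning rule.** A branch is a skeleton path from a degree-1 pixel to the
nearest pixel of degree ≥ 3 (8-connectivity); branches with Euclidean path
length strictly below 35 px are removed.  Whole components without any
junction are never pruned, so small genuine marks survive.  Each sweep
evaluates all branches against the same snapshot and removes them
simultaneously — sequential in-place removal would merge sibling branches
into the main path and make the output depend on traversal order — and
ends with a topology-preserving thinning pass that clears the redundant
pixels left where a removed branch attached diagonally.  Sweeps repeat to
a fixed point.  The exact pruning rule of comparable toolchains is not
published; this one is declared, not inferred.

Inclusion rules: scripts with more than 5 missing symbols are excluded;
character-level exclusions (punctuation, diacritics, numerals, ligatures)
are upstream curation supplied as a boolean column; order analyses keep
only scripts whose dominant direction is LR or RL (vertical,
boustrophedon, variable and uncertain directions drop out).

## Perimetric complexity

C = P²/(4πA) with A the foreground pixel count and P the summed sub-pixel
length of all contours (component outlines plus hole outlines), traced by
marching squares at the 0.5 iso-level on a padded copy of the mask (so
shapes touching the border still close).

A raw marching-squares polygon overestimates the length of smooth curves
by up to ~11% (staircase effect) — enough to push a disk from C = 1 to
C ≈ 1.11 — while any naive smoothing rounds off genuine corners and
underestimates polygons.  The estimator therefore:

* detects corners as vertices whose turning angle, measured between chords
  spanning ±7 vertices, exceeds 45°, collapsing runs of candidates to the
  sharpest vertex;
* pins corners exactly, and on the spans between them applies a moving
  average of half-width 5 followed by chord subsampling every 5th vertex;
* closed contours without corners are smoothed and subsampled wholesale.

These four constants are fixed once for all analyses.  The test suite
checks the resulting estimates against analytic ground truth: disk
C = 1.000 ± 0.03 at r = 100 with discretization error monotonically
shrinking from r = 25 to r = 200, square 4/π ± 0.03, annulus
(R+r)/(R−r) ± 0.05.

## Algorithmic complexity

The glyph outline (same contour tracing) is serialized to a canonical
closed-path vector form: coordinates are anchored to the foreground
bounding box (translation invariance), rounded to 0.1 px, each path is
oriented counter-clockwise and rotated to start at its lexicographically
smallest vertex, and paths are sorted deterministically.  The byte stream
is compressed with DEFLATE at maximum level; AC = compressed byte count.
A blank canvas yields the baseline (header-only) count, the smallest value
the canvas admits.  Determinism and monotonicity with visual structure are
the properties downstream analyses rely on; absolute byte counts are
implementation-specific and not portable across toolchains.  The
serialization is *not* exactly mirror-symmetric (mirrored glyphs compress
to slightly different sizes, empirically within a few percent), which is
why half-level AC comparisons are treated statistically rather than as
exact identities.

## Halves

The 500-wide standardized glyph splits at column 250 (columns 0–249 left,
250–499 right; no pixel lost or duplicated).  Each half is padded with 50
background columns on the cut side to 300×500 so the fresh cut edge does
not sit on the image border, and both metrics are measured on padded
halves.  A blank half has undefined PC (the character is dropped from PC
differential analyses only) and baseline AC (kept for AC analyses) — the
policy that minimizes data loss given that PC is undefined on empty masks.
Discrepancy scores z-normalize each metric over the pooled population of
all analyzed halves, with no grouping, then take D = z(PC) − z(AC).

## Mixed models

All inferential models are variance-components linear mixed models:
y = Xβ + Σ_k Z_k b_k + ε with independent random intercepts per grouping
factor.  Crossed factors are separate columns; nesting is expressed by a
column holding the nested combination (e.g. `family:script`).  The
in-house fitter profiles β and σ²_e out of the (RE)ML criterion and
optimizes the variance ratios on the log scale (Nelder–Mead from three
starts), with all linear algebra in the q-dimensional random-effect space
via the Woodbury identity.  It is validated against statsmodels `MixedLM`
(estimates, variance components and log-likelihoods agree to ~1e-4 on
shared test problems).

* **Degrees of freedom.** Fixed-effect t-tests use Satterthwaite-style df:
  df = 2g²/Var(g) with g = Var(β̂_j), the gradient taken by finite
  differences over the variance parameters and their covariance from the
  observed REML information (finite-difference Hessian).  Components
  estimated at the zero boundary are treated as known zeros and excluded —
  keeping them leaves the information matrix near-singular and collapses
  the df spuriously.  When every cluster variance is zero the df reduce to
  the residual n − p, as they should.
* **Model comparison.** Both models are refit with ML;
  ΔAIC = AIC(null) − AIC(test), positive favoring the test model.  AIC
  counts p fixed effects + k variance components + 1 residual variance.
* **Singular fits** (a variance ratio below 1e-6, or a factor with one
  level per observation) are flagged, with the component reported as 0.
* **ICC** is the one-way estimator σ²_b/(σ²_b + σ²_w) from a REML fit,
  truncated at 0; computed on raw values for PC and log-transformed values
  for AC (whose distribution is strongly right-skewed).  For *recovery*
  checks against generator truth the package uses `variance_partition`
  instead — a joint decomposition over all factors at once — because
  one-way ICCs of nested factors estimate overlapping quantities: when
  scripts inherit their type's mean, ICC(script) and ICC(type) coincide in
  expectation and their ordering is sampling noise, whereas the joint fit
  attributes the shared variance to the factor that carries it and drives
  the redundant one to zero.
* **Size models** log-transform both the outcome and the inventory size,
  use type and script-within-family random intercepts, and offer a
  sensitivity switch excluding scripts with ≥ 200 characters.
* The idiosyncratic-script test nests characters by type and script (no
  family: such scripts have no single ancestral family), with a flag for
  the script-only nesting variant.

## Ancestry differentials and the Bayesian t-test

Per ancestor–descendant pair, the differential is descendant mean
complexity minus ancestor mean complexity; differentials are averaged per
*ancestor* before testing, so prolific ancestors contribute one value, not
many.  The one-sample JZS Bayes factor places a Cauchy(0, r) prior on the
standardized effect (default r = √2/2, the conventional scale of this test
family) and integrates the noncentral-t marginal by adaptive quadrature
(relative tolerance 1e-10); BF_01 > 1 favors "no drift".  The test suite
cross-checks it against the independent inverse-gamma mixture formulation
and against pingouin to within 1%.  An all-zero set of differentials is
reported as infinite support for the null rather than an error.  A
pair-level regression with ancestor as a random effect accompanies the
test.

## Order/laterality suite

Given the half table: (a) Δ_FL ~ 1 with family and script-within-family
intercepts (positive intercept = first halves more complex); (b) the same
plus a directionality fixed effect; (c) half-level complexity with order
(first/last) vs side (left/right) fixed effects under character/script/
family nesting, compared by ΔAIC; (d) discrepancy D ~ side + order under
character/script/type nesting (side alone if the corpus has a single
direction, where the two indicators are collinear); (e) Δ_LR ~
directionality with family/script nesting, where a negative RL coefficient
means the left-half advantage shrinks when the right half is read first.

## Synthetic corpus generator

The generator reproduces the *statistical* structure the analyses assume,
not typography.  Glyphs are random strokes (straight segments and
quadratic arcs, ~5 px thick to match standardization output) on the 500×500
canvas; log stroke count = log(base) + type effect + script effect +
character noise, with independent Gaussian effects.  Defaults: base 6
strokes, type SD 0.25, script SD 0.15, character SD 0.25; 78% of scripts
LR (the share observed in real horizontal-script corpora); stroke
placement lands in the first-read half with probability
`first_half_share` (default 0.5 = no asymmetry); the first script of each
family is the family ancestor and descendants' log stroke count shifts by
the drift δ (default 0 = null).  Everything is bit-reproducible given
(spec, seed), and a truth sidecar records realized effects so recovery
tests never re-derive ground truth from generator internals.

What the generator does **not** emulate: real stroke topology and ligature
behavior, font rendering artifacts, unbalanced inventory sizes, correlated
evolution along lineages, or any resemblance to actual scripts.  Passing
recovery tests therefore show that the pipeline measures what the
generator encodes and that the estimators are calibrated — not that any
particular empirical claim about real writing systems holds.

## Problem sizes and runtime

Test corpora are desk-scale by design: the shared fixture is 9 scripts ×
8 characters; the sign-law corpus 50 × 20 = 1,000 glyphs; the order-effect
corpus 20 × 15 = 300 glyphs with first-half share 0.60; the type-I
calibration uses 200 replicates of a 6 × 8 corpus with share 0.50,
checking that the first-half test rejects at ≤ 0.05 + 3 Monte-Carlo SEs;
simulation-based recovery uses 40 groups × 25 and 50 × 20 designs.  The
full suite runs in minutes on one CPU.

## Known limitations

* PC is highly sensitive to contour length, so cutting characters in half
  inflates it via the fresh cut edge; the discrepancy model exists to
  diagnose exactly this metric-specific bias, and order conclusions should
  lean on AC and on the Δ_LR-by-directionality design.
* AC byte counts depend on the serialization and compressor; only
  within-implementation comparisons are meaningful.
* The branch-pruning rule is a declared convention; other toolchains'
  pruning may retain or remove different marginal strokes.
* Satterthwaite df from finite differences can be conservative near
  variance boundaries; boundary components are excluded, but heavily
  unbalanced designs may still see reduced df.
* The generator's strokes are spatially independent within a half, so
  within-character spatial correlation structure of real scripts is not
  represented.
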