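# Methods

## Display construction

A display is 1024×768 px with eight vertical stripes in two tones.  Seven
interior colour boundaries sit at nominal positions 128k (k = 1..7); all
but the midline (x = 512, a fixed design anchor) are jittered by
independent N(0, 16²) draws rounded to whole pixels.  Rounding adds 1/12
px² of variance (SD 16.003 instead of 16) — far inside any stated
tolerance — and integer geometry makes every downstream placement rule
exact.  If jitter produces an unordered or out-of-range boundary set the
whole set is redrawn, which preserves the normal marginal distribution
better than clamping would.  The left-to-right tone order is AB or BA with
probability 0.5.

Each non-midline boundary carries four colour-reversed squares (side 32 or
64 px), one per vertical quadrant of height 192 px, with top edge at a
uniform integer offset in [1, 192 − 2·side].  Because the offset never
exceeds 192 − 2·side, squares cannot touch either within or across
quadrants, and adjacent boundaries are far enough apart that squares never
collide horizontally.

The target is a 16 px disc whose pixels take the local background colour
multiplied by 1.10 ("10% lighter"), so each half of a two-tone target is
lightened relative to its own side's tone; this single rule produces the
correct monotone, in-phase stripe, in-square and border appearances.
Values pushed past the display maximum are clipped and flagged in the
metadata (the shipped palettes never clip).  Placement is rejection
sampling over the treatment's eligible set, with the whole disc at least
1 px inside one screen half (so the left/right answer is unambiguous) and
a 2 px clearance between Dark/Light/Stripe targets and any square.  If no
eligible location exists the generator signals for a fresh scene layout
rather than silently accepting a biased placement.

Grey tones are 40% and 60% of maximum intensity: symmetric about
mid-grey, and 0.6×1.1 = 0.66 stays in gamut.  The chromatic pairs are
sRGB renderings of CIELab colours matched at L* = 58 (red/green and
blue/yellow), chosen so the lightened targets also stay in gamut.  The
lightening is multiplicative per channel on the stored display values.
Rasters are produced as float RGB in [0, 1]; the exact 10% relation holds
there, and 8-bit PNG export quantises afterwards.

## Session design

Four blocks of 50 trials, each a uniform random permutation of 5
replicates of the 10 treatment × size cells, give 20 replicates per cell
and 200 main trials per subject.  Ten practice trials precede them.  A
practice set of "two replicates of each treatment combination" cannot
cover 10 cells in 10 trials; practice is therefore two replicates of each
of the five treatments with the square size drawn at random, and practice
trials are flagged and excluded from every analysis.  Per-trial scene
seeds are spawned from the session master seed through a counter-based
seed tree (reproducible sessions, independent scenes, all seeds < 2³¹).

## Observer model

Latent detection time in cell (t, s) for subject j is

    T = exp(mu[t,s] + u_j + sigma·z),  u_j ~ N(0, tau_rt²),  z ~ N(0,1).

Times ≥ 15 s are right-censored ("no response"); recorded times are
rounded to 10 ms *after* the censoring check.  Given a response, it is on
the wrong side with probability logistic(beta[t,s] + v_j),
v_j ~ N(0, tau_err²).  Errors are independent of RT within a cell — the
simplest generative structure consistent with the analysis chain, and a
known simplification: real observers presumably trade speed against
accuracy.  Time-outs are never errors; the error denominator counts only
trials with a response.

### Preset calibration

No trial-level human data exist for this task, so the presets are the
package's own calibration, fixed a priori:

* `chromatic_like`: median RTs 1.5 / 2.5 / 3.5 s for (Dark = Light) /
  (Stripe = Square) / Border, identical across sizes; sigma = 0.9,
  tau_rt = 0.12.  With the 15 s deadline this implies an overall time-out
  rate of 2.28% analytically (~2.2% simulated), matching the ~2% rate a
  well-practised searcher produces.  Error logits −4.6 / −2.9 / −1.7
  (≈1%, 5%, 15% wrong-side rates) were set by a power analysis so that
  the planted ordering is recoverable at the standard scale of 25
  subjects under Tukey-adjusted all-pairs testing; the resulting
  treatment deviance statistics (χ² of order 10² at df = 4) are the
  magnitude typical of strong published effects in this paradigm.
* `achromatic_like`: same monotone baseline but Square = Border slowest
  for small squares (3.0 vs Stripe 2.2 s) and Stripe slowest for large
  (3.2 vs 2.4 s), planting a genuine size × treatment interaction.
* `null`: all treatments identical (2.0 s, logit −3) for
  type-I-error studies.

What the generator does **not** emulate: speed–accuracy coupling,
learning/fatigue across blocks, spatial effects of the specific target
location within a treatment, guessing near the deadline, and
subject-specific sigma.  Passing recovery tests therefore validates the
statistical machinery under the stated model, not the full richness of
human data.

## Censored estimation

Each subject × treatment × size cell is fit by maximum likelihood under a
log-normal with right-censoring: uncensored trials contribute the normal
density of log t, censored trials the survivor function at log 15.  With
no censored trials the closed-form normal MLE of the log times is returned
directly.  Otherwise L-BFGS-B maximises over (mu, log sigma) with analytic
gradients, starting from the closed form on the uncensored subset
(objective tolerance 1e-8; robust on 20-trial cells).  The corrected cell
mean exp(mu + sigma²/2) is the downstream response.  Cells with fewer than
two uncensored trials are non-estimable: reported with the naive mean of
recorded times as a lower bound, flagged `converged=False`, logged, and
dropped (with a warning) by the model stage rather than imputed.

Note the plug-in mean carries the usual finite-sample upward bias
(≈ exp(sigma²/2n)·Jensen terms, about +2% at n = 20, sigma = 0.9).  This
is a property of the estimator itself, not of the censoring correction;
the tests compare against the estimator's own small-sample expectation.

## Inference

Both responses are modelled with a single subject random intercept and
fixed effects drawn from {size, treatment, size × treatment}, always by
maximum likelihood — REML deviances are not comparable across
fixed-effect structures, and every test here is a deviance difference
referred to chi-square (interaction df 4, treatment df 4, size df 1).

* Normal response (cell mean RTs): statsmodels `MixedLM` with ML; on
  balanced designs the fixed effects coincide with GLS/OLS, which the
  tests exploit as an oracle.
* Binomial response (error counts): cell-level (errors, responded)
  binomial with logit link — identical likelihood to Bernoulli rows at a
  fraction of the cost.  The marginal likelihood integrates the subject
  intercept by Laplace-centred adaptive Gauss–Hermite quadrature
  (default order 15; likelihood-ratio statistics are stable to well
  beyond 3 significant figures for orders ≥ 5).  Treatment levels with
  zero (or all) errors have no information on the logit scale; fits are
  returned with the affected contrasts flagged non-estimable rather than
  continuity-corrected.
* Single-subject data degrade to fixed-effect fits (OLS / plain
  logistic) with a warning; the intercept variance is reported as 0.

The decision tree mirrors standard practice: the interaction is tested
first; if significant, treatment is tested and ordered within each square
size, otherwise contrasts come from the additive model.

Contrast families: (a) the a-priori simple contrasts of each treatment
against Border, tested simultaneously and deliberately uncorrected;
(b) all 10 pairwise comparisons with single-step adjustment
P(max|Z| ≥ |z_i|) under the joint normal distribution of the estimable
contrast statistics with their fitted correlation, computed by Monte
Carlo with 10⁵ draws and a fixed, recorded seed (20140128).  The MC
estimate is floored at the raw p so the adjustment property
p_adj ≥ p_raw holds exactly.

Ordering summaries sort treatments by model-predicted marginal mean and
group maximal runs whose internal pairs are all non-significant at
alpha = 0.05.  Disjoint runs render as `Border>(Square = Stripe)>(Dark =
Light)`; a non-transitive significance pattern yields overlapping runs,
rendered with `>=` between overlapping groups plus a warning.
Non-estimable pairs cannot support a difference and are treated as
non-significant.

The classical cross-check is a repeated-measures ANOVA (subject as the
blocking factor, all other effects fixed) on the cell means and on
arc-sine-square-root transformed error proportions; it requires a
balanced table and at least two subjects, and its conclusions should —
and in the tests do — agree with the deviance tests on planted effects.

## Numerical and operating characteristics

* All simulation randomness descends from user seeds through
  `numpy.random.SeedSequence` trees; identical configs are bit-identical
  for exact stages.
* `MixedLM`'s default L-BFGS optimiser occasionally hits a singular
  information matrix at the optimum; the fit retries across BFGS,
  L-BFGS, CG and Powell.
* Under the null observer profile the df = 4 treatment LRT rejects at
  the 5% level at an empirical rate of ≈0.06 over 1,000 reduced-size
  experiments (8 subjects, 1 block) — the mild anticonservatism expected
  of ML deviance tests at 80 observations.
* Under `chromatic_like` at 25 subjects the planted ordering is
  reported for ~98% (RT) and ~96% (errors) of seeds.  The residual
  failures are honest operating characteristics: the cell-mean noise is
  heteroscedastic across treatments (variance grows with the mean),
  which slightly inflates the interaction test (~7% observed at
  alpha = 0.05) and routes those runs down the per-size branch.
* Problem sizes in the test suite (e.g. 1,000 calibration replicates at
  8 subjects × 1 block; 50 recovery replicates at the standard
  25-subject scale; 10,000 stripe fields for jitter statistics) were
  chosen as the smallest studies that pin each property to its stated
  tolerance.

## Known limitations

* Monitor calibration and per-subject isoluminance are out of scope; the
  chromatic palettes are nominal CIELab matches, not measured ones.
* The observer presets are qualitative: they reproduce ordering
  structure and realistic censoring/error magnitudes, not any specific
  human dataset.
* Random slopes, speed–accuracy coupling and alternative survival
  families (Weibull, gamma) are deliberately not modelled.
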