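# Methods

`gazehmm` models how young children look at faces. Each child's
fixation sequence on a face is summarized by a hidden Markov model
whose hidden states are person-specific regions of interest (ROIs);
children's models are clustered into two representative viewing
patterns — *holistic* (broad ROIs over the face center and contour)
and *analytic* (tight ROIs on the eyes and face center, frequent
switching) — and every child is placed on a bounded holistic–analytic
(H-A) scale. A synthetic cohort generator provides ground truth for
validating every stage.

## Preprocessing

Raw input is binocular gaze at 90 Hz on a 1920×1080 px screen showing a
centered 900×940 px face for 8000 ms. Stages, in order:

1. **Eye averaging.** The analysis unit is the mean of the two eyes;
   when only one eye is tracked that eye is used (maximizes retained
   data; discarding single-eye frames is the conservative alternative).
2. **Blink interpolation.** Maximal missing runs flanked by valid
   samples are filled linearly when their duration is ≤ 75 ms (an eye
   blink); longer runs and runs touching the stream edges stay missing.
   A gap's duration is the time between its flanking valid samples
   minus one sample interval (1000/90 ms).
3. **Screen-time QC.** Total screen time = (number of valid on-screen
   samples) × sample interval. Trials under 4000 ms — more than half
   the trial missing — are excluded; exactly 4000 ms is retained.
4. **Fixation detection.** Dispersion-threshold segmentation (I-DT):
   maximal windows whose dispersion (x-range + y-range) stays within
   50 px and that last ≥ 100 ms become fixations at the window
   centroid. 90 Hz is too coarse for velocity-based saccade detection,
   so a dispersion criterion is the appropriate choice; both thresholds
   are configurable.

Coordinates are 0-based pixels, origin top-left, y downward, shared by
all modules.

## The per-child gaze HMM

Observations are fixation centroids (x, y) only; durations are not
modelled. A K-state HMM with Gaussian emissions (the ROIs) is estimated
by variational-Bayesian EM with conjugate priors:

* symmetric Dirichlet (concentration 1) on the start vector and each
  transition row;
* Normal–Wishart on each emission, centered on the stimulus center with
  precision scale κ₀ = 0.05 (the ROI mean is essentially free to move
  over the stimulus), ν₀ = 5 degrees of freedom, and an anisotropic
  scale matrix with SD (200, 50) px — the shape of a typical horizontal
  face band (eyes, mouth, contour).

The emission prior deserves comment. A "weakly informative" prior with
covariance scaled to the whole stimulus makes the per-state KL penalty
(~15–20 nats) larger than the likelihood gain any real second ROI can
deliver in a single 8-s trial (~25 fixations), so state-count selection
collapses to one ROI. A band-scaled prior keeps the penalty
commensurate with the information in tens of fixations while still
letting broad ROIs be learned; one-ROI data still selects K = 1 (40/40
in our seeded checks). This mirrors the practice of established
variational gaze-HMM tools, which use deliberately tight emission
scale priors.

Fitting details: restarts (default 100; studies of this size are
well-served by 10) are initialized by k-means on the pooled fixations
with randomly drawn starting centers (uniform-random ROI means remain
available as `init="random"`). The E-step is a batched log-space
forward–backward; the variational lower bound (data term minus
Dirichlet and Normal–Wishart KL terms) is non-decreasing over
iterations and is the convergence criterion (relative tolerance 1e-6,
max 200 iterations). After convergence, states with expected count
below 0.1 are pruned, so the effective state count can be below the
requested K. The returned point estimate uses posterior means; the
point-estimate covariance eigenvalues are floored at 1 px² to prevent
collapse onto single fixations.

**Model selection.** One model is fit per K in 1…6 and the model with
the highest variational lower bound wins, ties toward fewer states.
The bound's built-in complexity penalty is what makes the ROI count
selectable at all; "highest log-likelihood" is read as the quantity
VBEM actually maximizes.

**Likelihood evaluation** uses the exact scaled forward algorithm on
the point-estimate model, in nats.

## Clustering and representative models

Per-child HMMs (per face type) are grouped into two clusters, each
summarized by a representative HMM, via a hierarchical-EM scheme with
virtual samples: each input HMM generates N_v = 100 sequences of
L_v = 20 fixations; the algorithm alternates (a) assigning each input
to the representative giving its virtual samples the highest mean
log-likelihood and (b) refitting each representative (VBEM, 3 states
before pruning, k-means init, capped at 60 iterations) on its members'
virtual samples, until assignments stabilize. The objective — total
mean virtual-sample log-likelihood under assigned representatives — is
kept non-decreasing by accepting a refit only when it does not lower
the objective; an emptied cluster is re-seeded from the worst-fit
member. Two seeded restarts are run and the best objective kept. This
is a Monte-Carlo stand-in for closed-form hierarchical EM over HMMs
with the same objective and is far easier to verify against oracles.

**Labeling.** The two groups receive holistic/analytic labels by a
heuristic mirroring how the field labels such clusters by inspection:
the group whose representative has the larger total ROI spread (sum of
covariance traces) is the holistic candidate; the group with more
stationary probability mass inside a configured eye-region box
(default: a 600×140 px band at 38 % of face height) is the analytic
candidate. If both point to the same group the labels are withheld
with a warning; explicit overrides always win.

## The H-A scale and model comparison

For each child and face, the fixation sequence is evaluated under both
representatives, giving log-likelihoods H and A:

    H-A = (H − A) / (|H| + |A|)  ∈ [−1, 1]

positive values mean the holistic representative explains the child
better. A per-child "mean face" value is the unweighted mean over the
three faces. Two representatives are compared by Monte-Carlo KL
divergence: d = E_{x~P}[log P(x) − log Q(x)] estimated from n = 2000
sequences of 20 fixations (both knobs configurable and reported), with
a paired t-test across the per-sequence log-likelihood differences.
The sampling direction matters and both directions can be reported.

## Inferential statistics

Pearson chi-square tests (goodness-of-fit and independence) without
continuity correction; classical one-way ANOVA; between-subjects
two-way ANOVA with Type-II sums of squares for unbalanced cells;
Spearman correlation with mid-ranks and t-approximation p-values.
A-priori sample size for a one-way fixed-effects ANOVA uses
noncentral-F power with noncentrality λ = f²·N, df₁ = groups − 1,
df₂ = N − groups, returning the smallest N whose power reaches the
target; the companion inflation step is ⌈n / ((1 − loss) × inclusion)⌉.
Under f = 0.25, eight groups, α = 0.05 and power 0.90 this yields
N = 300 (achieved power 0.9004; 299 gives 0.8992) — a figure the code
computes rather than assumes. No multiplicity corrections are applied
by default (matching the analysis style this package reproduces);
Benjamini–Hochberg can be added downstream.

## The synthetic cohort generator

The generator emulates the acquisition: 8000 ms trials at 90 Hz, three
face types per child, binocular samples. Children are drawn from two
archetype HMMs placed on the stimulus rectangle:

| | ROI 1 | ROI 2 | transitions |
|---|---|---|---|
| holistic | lower contour band, mean at 77 % face height, SD (240, 60) px | upper center band, 40 %, SD (200, 80) px | sticky (0.80/0.85 self) |
| analytic | eye band, 35 %, SD (150, 40) px | center/mouth, 65 %, SD (60, 60) px | switching (0.70/0.65 cross) |

The holistic archetype has ~3.4× the total covariance trace of the
analytic one and starts at the contour with probability 0.7; the
analytic archetype concentrates stationary mass in the eye region and
switches ROIs most steps. Vertical ROI separation is ≥ 4 SD in both
archetypes so that the two-ROI structure is identifiable from a single
trial's ~25 fixations — with weaker separation no estimator could
recover it at this n.

Fixation durations are truncated-normal (mean 300 ms, SD 100 ms, floor
100 ms — standard free-viewing values). Fixations are expanded to 90 Hz
samples with Gaussian within-fixation jitter (SD 6 px, emulating
post-filter tracker noise and chosen so that a fixation's dispersion
stays below the 50 px I-DT threshold: the generator must be consistent
with its own detector), a horizontal binocular disparity (8 px between
eyes plus 1 px per-eye noise), and Poisson blinks (0.2/s, lognormal
durations around 60 ms, so most blinks are interpolated and QC passes).
A synthetic cognitive score is `baseline + slope × true H-A + noise`
(default 95 − 40·HA + N(0, 8)), giving the moderate negative
rank-correlation structure the analysis should recover. Ground truth
(archetype identity, true H-A, fixation counts) is written alongside
the data and never read by analysis stages.

What the generator does *not* emulate: saliency-driven scan paths,
calibration drift, head movement, smooth pursuit, or age effects.
Passing the recovery checks therefore shows the pipeline is correct
and well-calibrated on data matching its model class — not that real
children's gaze obeys two-state Gaussian HMMs.

## Problem sizes and numerical choices

The end-to-end validation cohort is 60 children × 3 faces with 10
restarts per fit — sizes at which the whole pipeline (preprocess →
select_model over K = 1…6 → clustering → labeling) completes in a few
minutes on one CPU while leaving the recovery rates (≥ 90 % correct
state counts and pattern identities) statistically meaningful.
Degenerate inputs raise typed errors rather than returning NaNs: empty
trials, fewer fixations than states, all-constant ANOVA groups,
constant correlation vectors, zero expected chi-square cells. Paired
t-tests on zero-variance differences report t = ±inf with p = 0 by
convention. Serialization round-trips models exactly to 1e-12.

## Known limitations

* Fixation durations carry pattern information that the positional
  HMM ignores by design.
* The holistic/analytic labeling heuristic is geometry-dependent; for
  non-face stimuli, supply overrides.
* Monte-Carlo KL has sampling error ~1/√n; the reported SE should
  accompany any quoted d.
* The VB lower bound comparison across K is exact only up to the
  variational gap; with very short sequences the selected state count
  is conservative.
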