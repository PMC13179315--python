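# Methods

This note documents the models, algorithms and design choices behind the
package, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Annotations and normalisation

Input is one interval tier per speaker marking speech vs. silence, in
seconds. Intervals are half-open `[start, end)`; adjacency means
`prev.end == next.start` exactly, which removes double counting at
boundaries. Tiers tile their full duration: parsing inserts silence into
uncovered stretches, and overlapping intervals within a tier are a
validation error.

Turn-timing annotation conventionally ignores very short silences inside a
speaker's talk, so `normalise_tier` absorbs every internal silence shorter
than the minimum silence length (default 0.200 s) into the surrounding
speech. A silence of exactly the threshold is kept. Leading and trailing
silence is never absorbed, whatever its length. The operation is idempotent
and conserves total tier duration; both properties are tested. Whether a
given corpus enforced the 200 ms minimum at annotation time or not,
normalisation makes the rule machine-checkable either way.

TextGrid reading supports the long and short text dialects with UTF-8/16
detection. Labels are mapped to silence if, after whitespace stripping,
they are in a configurable silence-label set (default: empty string,
`sil`, `<p>`); every other label counts as speech. The writer emits
microsecond-precision times, so a write→read round trip is exact well
inside the 1 ms tolerance used for FTO values.

## Floor transfers and FTO

All talkspurts of both speakers are processed in onset order while
tracking the floor holder F (initialised to the earliest-starting
talkspurt; simultaneous starts resolve to the later-ending spurt, then to
the lexicographically smaller speaker id — an arbitrary but deterministic
rule, logged when used). For a talkspurt T by the other speaker B:

* **within-speaker overlap** iff some *single* talkspurt of F starts
  strictly before T and ends strictly after it; the floor does not move.
  A spurt of B that spans a pause of F (starts inside one F-spurt, ends
  after it) is therefore a floor transfer, not a within-overlap —
  containment is evaluated against one talkspurt, not the union of F's
  speech. This is the deterministic, local reading of talkspurt-level
  floor rules in the turn-timing literature.
* otherwise the floor transfers with
  `FTO = T.start − max{end of F-spurts starting at or before T.start}`.
  Classification uses the millisecond-rounded value: FTO ≥ 0 ms is a gap,
  FTO < 0 ms a between-speaker overlap, so an event within half a
  millisecond of zero counts as a gap on both sides of the pipeline.
* consecutive talkspurts of the same speaker produce no event
  (within-speaker pause).

Degenerate identical-boundary talkspurts transfer the floor with
FTO = −duration (neither strictly contains the other). A transfer whose
floor-holder end cannot be determined is dropped and counted in the log,
mirroring the usual treatment of annotation lapses. FTO = 0 rows belong to
the full model subset but to neither the gaps-only (FTO > 0) nor the
overlaps-only (FTO < 0) subset.

The extractor is verified against an independently written brute-force
reference (full pair enumeration, no incremental state) on an exhaustive
coarse lattice of two-speaker timelines (1 s grid over 8 s, ≤ 2 spurts per
speaker; >25 000 timelines) plus thousands of random fine-grid (100 ms)
timelines with up to six talkspurts.

## Transition typology

Five mutually exclusive categories partition the FTO line, in ms:
long overlap (fto ≤ −700), overlap (−700 < fto ≤ −100), smooth
(−100 < fto < 100), gap (100 ≤ fto < 700), long gap (fto ≥ 700). The
700 ms threshold reflects perception research on when silences start to
sound unusual; 100 ms bounds transitions heard as seamless. Integer
captions such as "−99 to 99" describe the same rule at millisecond
resolution.

## Descriptive statistics

FTO summaries are arithmetic means, sample SDs (ddof = 1, undefined for
n < 2) and medians (midpoint convention for even samples). Speaker balance
is `|%time(speaker 1) − %time(speaker 2)|` with the dyad's *combined
speech time* as denominator — not context wall-clock time — so scores are
comparable across contexts with different silence amounts; the absolute
value reflects that balance is a magnitude (0 = perfectly balanced).

## The hierarchical ex-Gaussian model

Likelihood: FTO_i ~ ExGaussian(μ_i, σ, τ), where the ex-Gaussian is the
sum of a Normal(μ, σ²) and an independent Exponential(τ) (mean μ + τ,
variance σ² + τ²). Its log-density is computed in the log-CDF form with
`log_ndtr`, stable in both tails (tested against an independent
implementation and by quadrature). Only μ carries the regression
structure; σ and τ are global per model, matching the default behaviour of
mainstream distributional-regression tooling. Fixed effects: Group × Task
with treatment coding (reference Group = ASD, Task = Introduction).
Random effects: by-dyad intercept and Task slopes. Dyads are not nested in
groups (each dyad appears in one group).

Priors, all centred at zero and spanning the feasible FTO range (a few
seconds): Normal(0, 1000 ms) on fixed effects, half-Normal(0, 500 ms) on
σ, τ and the random-effect SDs. Random effects are modelled as
independent across coefficient kinds (diagonal covariance, one SD per
kind) rather than correlated; with ≤ 23 dyads the data carry little
information about those correlations, and the simplification admits a
fully conjugate sampler.

### Sampler

The fit uses data augmentation: writing y_i = μ_i + σ z_i + e_i with
e_i ~ Exp(τ) makes every conditional tractable:

1. e_i | rest ~ Normal(d_i − σ²/τ, σ²) truncated to [0, ∞), where
   d_i = y_i − μ_i (exact draws via `scipy.stats.truncnorm`);
2. all fixed and random effects jointly | rest ~ multivariate normal
   (Gaussian model for y − e with normal priors; one Cholesky solve per
   sweep, with the cross-product matrix precomputed);
3. σ, τ and each random-effect SD by univariate slice sampling
   (stepping-out and shrinkage) on the log scale.

Sampling the fixed and random effects in one joint block removes the
classic slow mixing between the intercept and the random-effect mean.
The remaining slow direction is the funnel between near-zero
random-effect SDs and their effects; split-chain R-hat on those SDs can
exceed 1.01 at desk scale and triggers a warning, while the reported
contrasts (functions of the fixed effects) mix well — their R-hat and
bulk ESS are attached to every `PosteriorSummary`. Default settings are
4 chains × 4000 iterations with 2000 warm-up (8000 retained draws);
`ModelSpec.desk_scale()` (2 chains × 1000/500) is a documented reduced
setting for pipelines and tests, not the headline configuration.

Chain initialisation is moment-based (skewness-split of the sample mean
and SD); each chain draws from an independently spawned seed sequence, so
a fit is exactly reproducible from (data, spec).

The overlaps-only subset is sign-flipped before fitting (the right-skewed
ex-Gaussian then applies to overlap magnitudes) and contrast draws are
flipped back, so all reported δ values live on the signed FTO scale.
Contrasts are linear functions of the fixed-effect draws: per-context
group contrasts, a marginal group contrast (equal weight over the contexts
present), and within-group context contrasts. The robustness rule is:
95% equal-tailed CI excludes zero, or includes it by no more than 2% of
the interval width measured from the nearer endpoint, and
max(P(δ>0), 1−P(δ>0)) ≥ 0.89. The 2% margin operationalises "only
narrowly includes zero", which is not quantified more precisely anywhere
we know of.

Posterior predictive checks simulate full replicate datasets from thinned
posterior draws (same design matrix and random effects) and report the
tail-area probability P(T_rep ≤ T_obs) for the mean, SD, median and the
five typology-category shares; values outside (0.01, 0.99) are flagged.
A Gaussian-likelihood baseline (`likelihood="gaussian"`) exists to
demonstrate what misfit looks like: fitted to heavy-tailed timing data it
reproduces mean and SD but fails the median and tail-category checks.

## Synthetic corpora

The generator builds each dyad × context timeline by alternating floor
holders. Per turn: a log-normal duration (default mean 2.6 s, log-SD 0.6,
chosen so a 10-minute context yields on the order of 200 transitions,
matching the transition density of conversational corpora); a sequence of
events drawn from the type mixture — within-speaker overlaps are placed
strictly inside the current turn with ≥ 200 ms clearance from its edges
and from the intruder's other speech; the closing transfer draws an FTO
from the dyad's ex-Gaussian and places the next onset at exactly
`turn_end + FTO`. Turns may be split by a ≥ 200 ms within-speaker pause
(probability 0.15 per eligible turn). All geometric constraints (tier
separations, containment, next turn outlasting an overlapped end) are
enforced at generation time, so extraction recovers every injected
transition exactly — the module's core guarantee, and the anchor for all
recovery tolerances: observed-vs-truth comparisons are exact, and
observed-vs-configured comparisons use sampling-error bounds.

Dyad-level variation: a Normal(0, 150 ms) shift of the ex-Gaussian
location and a Normal(0, 0.3) logit shift of the within-overlap rate,
drawn once per dyad and shared across contexts (a random intercept). The
150 ms default reflects the strong between-dyad spread visible in dyadic
turn-timing data while keeping groups distinguishable at ~10 dyads.

Sign handling has two modes. In `exgauss` mode one draw decides both FTO
and the gap/overlap label, so the empirical FTO mean converges to μ + τ.
In `fixed` mode (used by the study-scale preset) the gap/overlap split
follows the configured mixture and the draw is rejected until its sign
matches. The two are equivalent exactly when the configured split equals
the distribution's own sign mass.

**Preset calibration.** The study-scale preset (9 ASD + 14 non-ASD dyads,
three 10-minute contexts) targets published group × context FTO summaries
(mean, SD, median) and per-group type mixtures. Because the published
mixtures imply a gap share different from any matching ex-Gaussian's own
sign mass, the preset uses `fixed` mode and calibrates (μ, σ, τ) per cell
so that the *realised sign-split mixture* matches the targets: for each
candidate τ, (μ, σ) are solved to reproduce mean and SD exactly (moments
of the reweighted density computed by dense-grid integration); τ then
minimises the median error. Published medians sit below what the
ex-Gaussian family can reach at the published mean/SD — real FTO
distributions are more sharply peaked — so calibrated medians are the
closest attainable values (about 40–110 ms above target in the ASD cells,
near-exact in the non-ASD cells); the calibration logs the residual.
Recovery tests therefore compare against the calibrated predictions, not
the unreachable published medians.

What the generator does *not* emulate: speaker asymmetry (both speakers
share turn-duration parameters, so speaker-balance scores are small);
lexical/prosodic content; gaze or gesture; time-course changes within a
context; annotation noise. Passing tests show the pipeline's measurement
chain is exact and the inference calibrated under the generative model —
they do not validate the behavioural realism of any particular corpus.

Two small artefacts are counted and surfaced in `SimTruth.counters`:
within-overlaps skipped for lack of room in short turns (a few percent,
biasing the realised within-rate slightly below the configured one — tests
use the logged count as an explicit allowance), and the final transfer of
each fixed-length recording window, whose censoring is size-biased toward
large FTOs (as in any real fixed-duration recording; negligible for long
recordings, bounded in tests via the counter).

## Numerical choices

* Times in float seconds internally; FTOs as millisecond-rounded
  integers; ±1 ms is the round-trip tolerance everywhere.
* Boundary ties: FTO = 0 is a gap; exact 200 ms silences survive
  normalisation; typology boundaries are as listed above.
* Ex-Gaussian MLE optimises (μ, log σ, log τ) by L-BFGS-B from
  moment-based starts; non-convergence raises with diagnostics rather
  than returning a bad fit.
* Grid integration for calibration uses 20 001 points spanning
  μ ± 7σ to μ + 7σ + 14τ.
* Test and acceptance problem sizes are scaled for quick desk runs:
  150 s contexts for shared fixtures, the full 600 s preset for the
  round-trip acceptance check, 60 s contexts for the 20-replicate
  zero-effect coverage study, desk-scale sampler settings throughout.

## Known limitations

* Random-effect correlations are not modelled (see above); σ and τ carry
  no regression structure, so group differences in spread or tail weight
  load onto μ.
* The marginal group contrast weights contexts equally, not by their
  transition counts.
* The sampler is exact but single-threaded; very large corpora (≫10⁵
  transitions) would want the truncated-normal step vectorised further or
  thinned storage for the random-effect draws.
* The generator's feasibility constraints mildly truncate extreme
  overlap magnitudes in short turns; the effect is logged and bounded in
  tests but not removed.
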