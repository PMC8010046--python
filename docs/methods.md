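# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `masslmm`.

## The per-timepoint model comparison

The response at each timepoint is a trial-level, signed, noise-normalised
source-activation value (dSPM-like arbitrary units) averaged within one ROI.
The full model is a Gaussian linear mixed model with a single participant
random intercept,

    y = X_full β + Z b + e,   b ~ N(0, σ_b²),   e ~ N(0, σ² I),

and the reduced model removes the columns of the variables of interest from
`X_full` while keeping everything else.  Both models are estimated by
**maximum likelihood, not REML**: the likelihood-ratio test compares fixed
effects, and REML likelihoods of models with different fixed-effect
structures are not comparable.  The statistic per timepoint is
χ² = 2(ℓ_full − ℓ_reduced), asymptotically χ²(df) with df equal to the
number of dropped columns.

Random slopes and crossed item effects are deliberately out of scope; in
data of this kind richer random-effect structures routinely fail to
converge, and the per-timepoint design would multiply that failure rate by
the number of samples.

### Fitting

For a fixed variance ratio λ = σ_b²/σ², the GLS estimate of β and the ML
estimate of σ² have closed forms; with one grouping factor, the inverse
covariance factorises per participant via Sherman–Morrison, so the profiled
log-likelihood needs only the sufficient statistics X'X, X'y, y'y and the
per-participant column sums.  The 1-D profile over λ is maximised by a
coarse grid on log₁₀λ ∈ [−6, 5] (step 0.5, with λ = 0 always evaluated)
followed by 40 golden-section iterations around the grid optimum.  This is
accurate to well below 1e−6 in log-likelihood (checked against statsmodels
`MixedLM` with ML in the tests) and fast enough — a few microseconds per fit
once compiled — that full permutation runs are practical on one CPU.

Numerical safeguards:

- a response with (numerically) zero variance saturates both models; the
  statistic is defined as 0 there rather than amplifying floating-point
  noise in the residual sums;
- a negative LR difference can only arise from optimiser tolerance; values
  below −1e−6 clear a per-timepoint convergence flag, and the statistic is
  clipped at 0 either way;
- residual sums of squares are floored at 1e−300 before taking logs.

### Design matrices

Factors are coded with treatment contrasts (reference = alphabetically
first observed level) or, optionally, sum-to-zero contrasts; the EMMs are
coding-invariant (tested).  Covariates are z-scored over the trials
entering the analysis — the natural scope when each analysis subsets trials
differently.  `a*b` expands to main effects plus all interactions;
interaction columns are element-wise products of the component codings.
Rank deficiency is detected at build time and reported with the aliased
column names.  A trial-gender covariate can be added to any spec by listing
`gender` among the fixed terms; the bundled presets omit it because the
synthetic generator assigns gender by set, where it is orthogonal to
everything of interest.

### The bundled analysis presets

| preset | trials | VOI | df | window (s) |
|---|---|---|---|---|
| syntactic-complexity | two-word | 3-level structure | 2 | 0.700–1.100 |
| noun-definiteness | two-word | binary definiteness | 1 | 0.100–0.500 |
| block-definiteness | two-word + single nouns | block × definiteness | 3 | 0.100–0.500 |
| single-word | single-word | category × definiteness | 3 | 0.100–0.500 |
| composition | two-word + single adjectives | noun type × adj typicality × adj definiteness | 11 | 0.750–0.950 |

Windows are closed intervals; boundary samples are included.

## Cluster inference

Clusters are maximal runs of contiguous timepoints whose χ² **strictly
exceeds** the 95th-percentile of the central χ²(df) distribution ("exceeds"
is read literally).  Cluster mass is the sum of member χ² values, and the
biggest mass per ROI is the test statistic.

The Monte-Carlo null shuffles the variables-of-interest labels **within
each participant**; nuisance covariates stay bound to their trials, so the
test targets the conditional association the LRT measures.  Because the
reduced model contains no VOI columns, its likelihoods are invariant under
the shuffle and only the full model is re-fitted, halving the cost.  The
raw p-value is the literal proportion of permutations whose biggest mass
strictly exceeds the observed one (permutations without clusters contribute
mass 0); the conventional (b+1)/(m+1) smoothing is available as an option.
p-values are BH-FDR-corrected across ROIs.  Permutation random streams are
spawned per permutation from one master seed, and independent streams are
used per ROI.

## Estimated marginal means

Cluster-averaged trial activity is regressed against the full model; EMMs
are model predictions on a reference grid that crosses the family factor's
levels, averages the remaining factors with equal weights, and holds
(z-scored) covariates at their means.  Contrast standard errors use the GLS
coefficient covariance at the ML variance ratio with *t* reference
distribution on n − p degrees of freedom — the large-sample default;
Satterthwaite/Kenward–Roger small-sample corrections are intentionally not
implemented.  All-pairwise families use Tukey's studentized-range
adjustment by default (Bonferroni and none available); when an explicit
subset of planned contrasts is requested, the family size for adjustment is
the number of requested contrasts.

## Spectral analysis

Single-trial Morlet decomposition (4 cycles at every frequency, 8–32 Hz in
1-Hz steps) uses `mne.time_frequency.tfr_array_morlet`.  Baseline
correction is **per epoch**: log₁₀ of the power divided by that epoch's
mean baseline power (−100–0 ms) per frequency, then decimation by taking
every 5th time sample, then averaging across trials (and sensors when
present) into one subject × time × frequency matrix per condition.  Log
base 10 is a documented constant; the base only rescales the maps and
cannot change any test decision.

Two properties of the per-epoch log-ratio are worth knowing:

- for stochastic signals it carries a negative bias (E ln of an
  exponential power estimate is −γ), which cancels in any between-condition
  comparison but means single-condition maps of pure noise sit near −0.2
  rather than 0;
- samples whose wavelet support extends beyond the epoch are contaminated
  by zero-padding; the decomposition returns an edge mask, and a baseline
  lying entirely inside the edge region at some frequency sets a warning
  flag on the resulting stack.

The paired comparison uses the pointwise one-tailed *t* statistic on
subject difference maps, thresholded at the 95th percentile of the *t*
distribution with n−1 degrees of freedom (the distributional reading of
"95 % percentile"; thresholding at the empirical map percentile is the
alternative we did not take).  Clusters are 4-connected on the
time–frequency lattice.  The permutation null randomly sign-flips each
subject's difference map — the exchangeability-correct scheme for a paired
design — and the raw p is again the strict proportion rule, FDR-corrected
over the requested set of comparisons (three, for the full condition
triangle).

The evoked-response control averages trials in the time domain per subject
and condition *before* the wavelet transform, then applies the identical
baseline/aggregation/cluster pipeline.  Phase cancellation removes induced
components from the average, so genuine oscillations disappear from the
evoked maps while phase-locked components survive.

## The factorial design generator

Each stimulus set carries four abstract word tokens (high/low-specificity
noun, high/low-typicality adjective) with Zipf frequencies drawn from
N(4.5, 0.7²) truncated to [1, 7]; orthography is never represented because
no statistic consumes it.  A set contributes 20 cells: 12 two-word
(3 syntactic structures × 2 noun specificities × 2 adjective typicalities;
the structure determines both words' definiteness marking) and 8 one-word
controls (nouns: specificity × definiteness; adjectives: typicality ×
definiteness).  With 36 sets this gives 720 trials.

Blocks: 6 two-word and 4 one-word.  The 12 two-word cells split into 6
word-disjoint pairs (per structure, the (high, high)+(low, low) and
(high, low)+(low, high) noun–adjective pairings); one-word noun cell *k* is
paired with adjective cell *k*.  Sets rotate cyclically across block slots
(a cyclic Latin square), so each set contributes each cell exactly once per
experiment and every word token appears at most once per block.  The
rotation requires the set count to be divisible by 12 (lcm of the block
counts); other counts raise an explicit infeasibility error.  The true
experiment's square is not public; this scheme satisfies every stated
constraint and is the documented choice.

Task items cover 1/3 of trials (round-robin over cells, so the assignment
is counterbalanced across conditions), half resulting in good sentences and
a quarter each in grammatical and plausibility violations.  Trial timing
accumulates 300 ms on / 300 ms off elements, a uniform 466.66–700 ms
inter-trial jitter, uniform 1–3 s task response times, 10 s block breaks,
and a 30 s clock origin for the instruction period (so the log-onset-time
covariate is defined from the first trial).

## The trial simulator

ROI activation is built as

    participant intercept + Σ slopes × z-scored covariates
      + Σ effect kernels × contrast weights + AR(1) noise,

with boxcar or Gaussian temporal kernels and a stationary AR(1) residual
(default coefficient 0.5 — single-trial source estimates are strongly
autocorrelated, but no specific value is canonical; it is configurable).
The default sampling rate is 200 Hz (261 samples across −100–1200 ms),
trading the original recording rate for desk-scale model loops.  The
generator returns the noiseless expected signal and the drawn intercepts so
recovery is testable exactly; on noiseless data the fitted covariate slopes
reproduce the generating slopes to 1e−6.

Oscillatory trials are sinusoidal bursts gated by a time window, with one
shared phase across trials (phase-locked, evoked-like) or an independent
uniform phase per trial (induced), plus white noise.  What this does *not*
emulate: 1/f background spectra, sensor topographies and field spread,
eye/heart artefacts, trial-loss imbalance, or any leakage between ROIs —
so passing tests demonstrate the statistics behave correctly under the
assumed data-generating process, not that real MEG meets those assumptions.

For the induced/evoked dissociation scenario the defaults are 12
participants, 144 trials per syntactic condition (the count the 36-set
design actually yields), and an 18-Hz burst of amplitude 0.35 against
unit-variance noise, i.e. a ~30 % band-power increase.  The modest size is
deliberate: the log-ratio contrast is scale-free, so with white noise the
induced effect survives in the *mean* of the evoked maps, and what makes
the evoked control correctly fail to detect it — as it does on real data —
is that an evoked power map is a single high-variance estimate (one
averaged "trial") while the single-trial analysis averages over all trials.
A grossly oversized effect would defeat the control in any pipeline.

## Operating characteristics (validation module)

`masslmm.validation` measures, by replicate simulation: (i) the family-wise
false-positive rate of the cluster permutation test on pure-noise
experiments (12 participants, 3 × 24 trials each, 50 timepoints, 200
permutations, 200 replicates — sized so a full calibration takes about
three minutes on one CPU), which should sit near the nominal 5 %; and (ii)
detection and EMM-recovery rates for a 3σ injected effect over 50
replicates.  The acceptance script reports both.

## Information-theoretic metrics

Entropy, entropy reduction (floored at zero, with a signed option) and
surprisal are computed in bits (base 2 — no base is canonical; it rescales
all three metrics identically) over transition tables that map contexts to
continuation distributions.  Tables can come from a corpus (CSV) or from
the generated design via exact conditional relative frequencies.  The
module is agnostic about context granularity — tables are data, not
assumptions.  End of trial is defined as zero posterior entropy.  In the
balanced design, the start-of-trial structure distribution is uniform over
three outcomes (1.585 bits); an indefinite noun is fully predictive
(reduction 1.585 bits, adjective surprisal 0) while a definite noun leaves
a binary choice (reduction 0.585 bits, adjective surprisal 1 bit), and the
indefinite noun itself is the rarer, more surprising first word (1.585 vs.
0.585 bits).

## Known limitations

- The χ²(df) reference for the LRT is asymptotic; the permutation test, not
  the pointwise reference distribution, carries the inferential weight.
- EMM p-values use large-sample *t* approximations; with very few
  participants they are optimistic.
- Whether the original analysis kept covariates trial-bound under the
  shuffle, and whether permutations were shared across ROIs, is not
  determinable; both choices here (trial-bound, independent streams) are
  explicit and configurable in principle but fixed in the presets.
- HDF5 epoch containers store one ROI per file; multi-ROI stores are out of
  scope.
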