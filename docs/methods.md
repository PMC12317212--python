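# Methods

`pupilforget` implements the full analysis chain for item-method directed
forgetting experiments with pupillometry: a generative model of the
experiments, preprocessing of 1-kHz pupil traces, multilevel
signal-detection behavioral analysis, and binned time-series inference
corrected by a cluster-based permutation test. This note records the
models, the parameters that matter, and the design choices taken where the
procedure is genuinely open.

## The experimental design being modeled

Subjects study natural scenes, each followed by a Remember (R) or Forget
(F) cue (or, in the memory-strength variant, scenes are Previewed vs.
Non-Previewed with no cues). At test every scene appears once, either in
its studied form ("Old") or mirror-flipped ("Lure"), for 3 s while pupil
size is recorded at 1000 Hz; the subject then judges Old vs. Lure. The
scientific question is whether pupil dilation at test indexes *successful
intentional forgetting* — i.e., whether forget-cued misses dilate
differently from remember-cued misses, while hits do not differ by cue.

## Synthetic experiments (`simulate`)

The generator's defaults are the study conditions: 90 subjects, 40 scenes,
a counterbalanced 2 (cue) × 2 (image type) within-subject design (items
rotate through cells across subjects), and a 2-s masked baseline before
the 3-s test window.

**Behavior.** Responses come from an equal-variance signal-detection
model: P(respond "old") = Φ(±d′/2 − c) for Old/Lure images. Condition
d′/c defaults are back-derived from the reported probit coefficients of
the cueing experiment (d′_R = 1.755, d′_F = 1.265; c ≈ −0.28/−0.29);
additive Gaussian subject (SD 0.4) and item (SD 0.3) effects on d′ create
the heterogeneity the multilevel models exist to absorb. Reaction times
are lognormal (location 7.0 log-ms ≈ 1.1 s, scale 0.35) with +0.12 for
lures and +0.07 for F-cued scenes on the log scale, and a 0.5%
contamination of +6-SD draws so the 3-SD screening rule has real work.

**Pupil traces.** No generative pupil model is prescribed by the analysis
itself, so the simplest structure that reproduces the event-locked,
late-window condition difference is used:

    trace = baseline level (800 a.u.)
          + subject intercept (SD 10)
          + AR(1) noise (stationary SD 20, lag-1 r = 0.995 at 1 kHz)
          + stimulus-locked dilation (60 a.u., all trials)
          + cell-specific late dilation (condition × subsequent accuracy)

Both dilation components are boxcars convolved with the classic
Erlang-shaped pupil impulse response h(t) = t^n · exp(−n·t/t_max)
(n = 10.1, t_max = 930 ms), peak-normalized so amplitudes are in trace
units. The late component's boxcar spans 1880–2820 ms, the reported effect
window; its default amplitude is 30 a.u. (1.5 × noise SD) on F-cued miss
trials and 0 elsewhere, directly encoding the finding the cluster analysis
should recover. Accuracy is simulated first and the pupil cell chosen from
the realized accuracy, matching the back-sorting logic of the analysis.
Blinks are a Poisson process (0.3/s, duration 120 ± 40 ms) masking samples
as missing. Everything is driven by one integer seed; identical configs
produce bit-identical output.

**What the generator does not emulate:** gaze position, luminance
responses beyond a constant baseline, item-level pupil effects,
slow non-stationarity across trials, and asymmetric blink artifacts
(partial-occlusion ramps). Passing recovery tests therefore show the
*inference machinery* is correct and calibrated under the stated noise
model, not that real recordings satisfy that model.

## Preprocessing (`preprocess`)

Pipeline order: detect missing runs → extend each run by 100 ms on both
sides and linearly interpolate (edge runs filled with the nearest valid
value) → zero-phase low-pass → spike check → trial exclusion → participant
exclusion → baseline correction → binning.

Choices the procedure leaves open, and what this package does:

* **Low-pass filter**: third-order Butterworth, 4 Hz cutoff, applied
  forward-backward (`sosfiltfilt`, DC gain exactly 1). These are the
  standard pupillometry-guideline defaults; both are config-exposed.
* **Spike rule**: a trial is flagged when its maximum absolute
  sample-to-sample dilation speed exceeds median + 16 × MAD of the
  within-trial speeds. The multiplier is config-exposed; 16 flags only
  interpolation failures, not ordinary dilation.
* **20% missing rule**: computed on the *pre-interpolation* validity mask
  grown by the blink extension, over baseline plus test window (a corrupted
  baseline invalidates the correction). The same threshold applies to each
  participant's pooled samples.
* **Binning**: the analysis grid is 150 half-open 20-ms bins over
  [0, 3000) ms (bin k = mean over [20k, 20(k+1))). A 20-Hz downsampling
  would give 60 bins over 3 s and is inconsistent with a 150-bin grid;
  the 150 × 20-ms grid is authoritative here because it defines the
  cluster analysis.
* **Baseline**: subtractive, mean of the half-open window [−400, 0) ms,
  time 0 = test-scene onset.

Exclusions are data, not errors: every input trial is returned with a flag
and reason, and the report's counts always conserve the input total.

## Behavioral models (`behavior`)

* **Accuracy**: a probit-link GLMM of P(respond "old") on
  condition × image type (±0.5 sum coding: F and Old are +0.5). Under this
  coding the image-type coefficient is the average d′, the interaction is
  d′(F) − d′(R), and the condition main effect is (minus) the criterion
  shift. The maximal random structure has crossed subject/item intercepts
  plus independent subject and item slopes for both factors.
* **Estimation**: no installed Python library fits frequentist probit
  GLMMs with crossed random effects, so the model is fit here by maximum
  likelihood with a Laplace approximation — damped Newton for the joint
  (β, u) conditional mode, a profiled Laplace log-likelihood maximized
  over the random-effect SDs by Nelder–Mead, and Wald SEs from the joint
  curvature. On test datasets the fit matches lme4's `glmer` (the field's
  reference) to ~0.01 in coefficients, SEs and variance components; one
  test in the suite performs that comparison through Rscript.
* **Random-effect reduction ladder** (used on any non-convergence): drop
  item-side slopes, then subject-side slopes, then item intercepts;
  subject intercepts are never dropped; the final rung is an ordinary
  probit GLM / OLS fit. The structure actually used is recorded in every
  result.
* **Subject-level SDT**: hit/false-alarm rates get the loglinear
  correction (count + 0.5)/(n + 1) before z-transforming, keeping d′ and
  c finite at 0% and 100%; conditions are compared with classical paired
  t-tests, effect size Cohen's d_z = mean(diff)/SD(diff) (the appropriate
  paired-design label).
* **Reaction times**: the 3-SD outlier rule is applied once, globally, on
  the raw-ms scale before the log transform (scope is config-exposed);
  log RT is then modeled with a linear mixed model
  (condition × accuracy × image type) via statsmodels `MixedLM`, crossed
  random effects encoded as variance components.

## Cluster-based permutation inference (`cluster`)

Per 20-ms bin, a model of baseline-corrected pupil with a fixed condition
effect; maximal runs of ≥ 10 consecutive bins with p < 0.05 and a common
effect sign form clusters scored by the sum of their t statistics; each
observed cluster's corrected p is the proportion of label-shuffled
experiments whose maximal cluster statistic is at least as large.

Decisions where the procedure is underdetermined:

* **Shuffle scope**: condition labels are permuted *within subject*
  (default), preserving subject-level pupil idiosyncrasies; labels are
  exchangeable under the null. A global shuffle is available as an option.
* **Sign handling**: clusters are sign-homogeneous and the null statistic
  is max |mass| (two-sided); a signed-maximum option exists for one-sided
  use.
* **Null iterations with no qualifying cluster contribute mass 0**, which
  can only make p conservative.
* **p estimator**: the plain proportion (faithful to the procedure's
  definition); the (b+1)/(n+1) estimator is available as an option.
* **Per-bin model specs** (permutations always reuse the observed spec):
  `"mixed"` fits crossed subject/item intercepts with by-item condition
  slopes per bin (reduced stepwise; a bin that defeats the whole ladder
  gets p = 1 and cannot seed clusters); `"subject"` — the desk-scale
  default — absorbs subject intercepts as fixed effects (per-subject
  demeaning) and is fully vectorized across bins and permutation
  iterations, which is what makes 1000-iteration corrections and the
  calibration simulations cheap. For the condition contrast in a balanced
  within-subject design the two give essentially the same t; the fixed-
  intercept form is used inside permutation loops because refitting a
  mixed model 150 × 1000 times is not desk-scale.
* **Degenerate bins** (zero variance) get statistic 0, p = 1.

Calibration and power were verified by simulation: over 400 null
experiments (20 subjects × 20 trials, no condition effect) the family-wise
false-positive rate at α = 0.05 was 0.037; with the default injected
F-miss amplitude (1.5 × noise SD) and the default 90-subject sample,
≈ 90% of replicates detect a significant cluster overlapping the injected
1880–2820 ms window while matched hit-trial subsets stay at the nominal
false-positive rate. The test suite re-runs scaled versions of both
checks (200 null experiments with 100 permutations each; 50 recovery
replicates with 200 permutations each).

## Numerical conventions

Time is integer milliseconds relative to test-scene onset (baseline
negative); all intervals are half-open. CSV files are comma-separated
UTF-8 with "." decimals; missing pupil samples are empty fields with
`valid=0`; sample values are written with 17 significant digits and read
with round-trip float parsing so files reproduce in-memory arrays exactly.
Paired t-tests with zero-variance nonzero-mean differences raise an
overflow error rather than reporting an infinite statistic; all-zero
differences give t = 0. Pipeline runs write a manifest (config hash
excluding the output path, seed, package versions, exclusion counts)
sufficient to replay a run; fixed config + seed gives byte-identical
outputs.

## Known limitations

* Exact reproduction of the deposited human data's printed statistics
  (e.g., the 7.8%/10.1% exclusion figures, the 1880–2820 ms window) is
  not expected: the original low-pass parameters and spike rule are not
  recoverable, and the synthetic data are not the deposited recordings.
  The defaults land in the same regime (typical runs remove ~8% of
  trials and localize the miss-trial cluster in the final second).
* The Laplace approximation shares `glmer`'s known small-cluster bias for
  binary outcomes (variance components and |β| slightly attenuated at few
  subjects); adaptive quadrature is not implemented because crossed random
  effects do not factorize.
* The detected cluster window lags the injected boxcar onset because the
  pupil impulse response peaks ~930 ms after input; window-overlap, not
  window-equality, is therefore the recovery criterion.
* EDF/ASC tracker files are out of scope; the documented sample-CSV
  contract (subject, trial, time_ms, pupil, valid; common 1-ms grid) is
  the ingestion boundary.
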