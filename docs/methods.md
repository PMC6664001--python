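# Methods

## Scientific problem

In a continuous source task, participants study words at locations on a
circle and later reproduce each word's location; the signed angle between
response and target is the trial's retrieval error. Two questions drive the
analyses this package implements:

1. **Is recollection thresholded?** Under the some-or-none (threshold)
   account, recollection succeeds on a proportion λ of trials — yielding
   errors concentrated around the target — and fails outright on the rest,
   yielding uniform guesses. Under the continuous account every response
   carries some signal (λ = 1), only its precision varies.
2. **Does the parietal retrieval-success ERP effect track retrieval
   accuracy once single-trial latency jitter is removed?** In older
   adults especially, trial-to-trial variability in the latency of
   endogenous ERP components smears the conventional average and can hide
   graded effects. RIDE (residual iteration decomposition) estimates
   per-trial component latencies and reconstructs a latency-compensated
   average (the rERP).

## Behavioral model

Errors θ ∈ (−180°, 180°] follow the two-parameter mixture

    f(θ) = λ · WC(θ; s) + (1 − λ) / 360,

where WC is the wrapped Cauchy centred on 0°. **Parameterization:** `s_deg`
is the scale of the unwrapped Cauchy in degrees; wrapping gives
concentration ρ = exp(−s·π/180). Published applications of this model state
only that larger s means larger mean error, not a formula; this convention
is therefore a package-level choice, flagged here deliberately. Both models
are fitted by bounded maximum likelihood (L-BFGS-B) with a multi-start grid
(λ ∈ {0.1,…,0.9} × s ∈ {5°, 15°, 45°}; bounds λ ∈ [0,1],
s ∈ [0.1°, 120°]) because the likelihood can be multimodal near the
boundaries; a 101×101 grid-search oracle in the tests confirms the
optimizer attains the global optimum to 1e-4.

The threshold vs continuous comparison is a likelihood-ratio test of the
full model against the λ = 1 restriction (df = 1). Because λ = 1 lies on
the boundary of the parameter space, the plain χ²(1) p-value is
conservative under the null and both it and the ½χ²₀ + ½χ²₁
boundary-adjusted p-value are reported; the plain χ² is the default, for
fidelity with how such tests are conventionally reported. The group test
sums per-participant deviances with df = number of participants (the
convention matching a printed group statistic with df equal to the sample
size); a binomial-mixture boundary version is also provided.

**A caution on power.** With this parameterization the wrapped Cauchy's
heavy tails let the restricted model absorb much of the guessing plateau by
inflating ŝ: at the generative point (λ = 0.66, s = 15.39°, 240 trials) the
per-participant deviance averages ≈ 19 and about 15 % of datasets fall
short of the p < 0.001 threshold (verified against a brute-force grid MLE,
so this is a property of the model, not the optimizer). Real cohorts whose
participants vary in λ produce larger summed deviances, because deviance is
convex in λ.

## Synthetic EEG generator

Each trial is

    trial_i(t) = S(t) + a(bin_i) · C(t − τ_i) + ε_i(t),

with Hann-bump components (smooth, compactly supported, analytically
shiftable so no resampling error enters). Defaults, chosen once:

| parameter | default | why |
| --- | --- | --- |
| channels | CP5/CP3/CP1/CP2/CP4/CP6, P5/P3/P1/P2/P4/P6 | the twelve electrodes the PR ROIs need |
| sampling / epoch | 250 Hz, −104…1936 ms | acquisition values of the study emulated |
| S component | peak 200 ms, width 200 ms, 5 μV | early stimulus-locked activity, inside the 0–450 ms S window |
| C component | peak 650 ms, width 300 ms, 5 μV | support exactly the 500–800 ms retrieval window; under ±100 ms uniform jitter the conventional peak attenuates to 0.5 + sin(u)/(2u), u = 2π·100/300 ≈ 0.71 — visibly smeared |
| amplitude map | High 1.0, Low 0.6, Guess 0, Baseline 0 | encodes the some-or-none hypothesis: guesses carry no retrieval signal |
| jitter | uniform ±100 ms | no study reports the magnitude; chosen to smear visibly while keeping the shifted C inside the epoch |
| noise | white Gaussian, 10 μV SD | realistic single-trial EEG amplitude scale; white (not 1/f) so closed-form oracles exist |
| behavioral defaults | λ = 0.66, s = 15.39°, 240 trials, 21 participants | the group-level statistics of the emulated cohort |

What the generator does **not** emulate: ocular artifacts, 1/f background
spectra, realistic topographic gradients (all channel gains default to 1),
or between-participant variability in λ, s, component amplitude or noise.
Passing tests therefore show that the pipeline recovers what the model
assumes, under ideal mixture/jitter structure — not that real aged EEG
satisfies those assumptions.

## RIDE

The decomposition assumes `trial = S + C(shifted) + noise` with a single C
process per trial. Steps:

1. **Template matching.** A single latency per trial maximizes the
   cross-correlation between the C-window template and the trial signal
   averaged over the matching channels, within ±300 ms; ties break toward
   the smaller |shift|; latencies are re-centred to median 0 and clipped to
   the search range. Matching uses 10 Hz low-passed copies only; the
   decomposition sees unfiltered data. The initial template is the
   conventional average in the C window; afterwards the current C (matched
   against `trial − S`).
2. **Median decomposition.** Alternating updates: S ← pointwise median of
   `trial − Ĉ(at its latency)` in the S window (0–450 ms); C ← pointwise
   median of latency-aligned `trial − Ŝ` in the C window (200–1600 ms).
   Medians protect the iteration from noise amplification. The stage is
   initialized at the mean-statistic fixed point and capped at 6 passes
   (tolerance 1e-3 μV RMS): where the two windows overlap the split is not
   identifiable, so later passes move the components only along directions
   the data cannot determine — movements that the low-passed template
   cannot transmit to the latencies and that the final stage resolves.
   Measured effect of the cap on 500–800 ms window means is < 0.002 μV.
3. **Outer loop.** Latency re-estimation and decomposition repeat until the
   largest latency change is ≤ 1 sample (max 10 iterations). Pure-noise
   epochs never settle; a futility stop (two consecutive non-improving
   changes) returns `converged=False` instead of looping.
4. **Restore-to-mean.** With latencies frozen, S and C are recomputed as
   means, in line with standard ERP averaging. The mean of latency-shifted
   copies of a waveform equals its convolution with the empirical latency
   histogram, so this stage iterates windowed Toeplitz-kernel updates to a
   1e-6 fixed point. The iteration (rather than a direct linear solve) is
   deliberate: the stationary system is near-singular along the
   window-overlap directions, and inverting it amplifies noise into C; the
   iteration leaves those directions at their warm start, where only the
   S + C sum is data-determined.
5. **Reconstruction.** Each trial's C contribution is re-shifted from its
   estimated latency to the median latency; the rERP is the mean of the
   re-synchronized trials. With zero jitter this is exactly the
   conventional average.

Shifts are integer samples with zero padding; samples shifted past the
epoch edges are discarded, never wrapped. No response-locked (R) cluster is
estimated: the analyzed window precedes the responses.

In the cohort pipeline RIDE is applied per participant **and per response
bin**: the generative model gives each bin its own C amplitude, and a
pooled decomposition provably leaves the bin contrast smeared (the bin-mean
reconstruction error is (a_bin − ā)(smeared C − C)). Bins with fewer than
10 artifact-free trials are left unreconstructed (their trials enter the
fine-bin analysis as conventional data); this floor sits below the
16-trial inclusion rule, so such bins are excluded from the ANOVA anyway.

## ERP pipeline

Identical configuration for conventional averages and rERPs: baseline
correction over −104–0 ms; artifact rejection (any baseline-relative sample
beyond ±75 μV = drift; within-epoch peak-to-peak above 100 μV = signal
change — both operationalizations, since neither rule is defined precisely
anywhere); accuracy bins on |error| as half-open intervals (0,10], (10,35],
(35,90], (90,180] with 0° assigned to High; ≥ 16 artifact-free trials per
critical bin, with excluded participants logged; 5-point boxcar smoothing of
the averaged waveforms (kernel shape unstated in the emulated procedure;
boxcar chosen); mean amplitude over 500–800 ms inclusive (76 samples at
250 Hz); PR ROIs averaging exactly two electrodes each; min/max rescaling of
difference topographies for shape comparisons.

## Group statistics

The fully within-subject ANOVA (Category × Hemisphere × Site) uses the
orthonormal-contrast (univariate) approach: for each effect the cell means
are projected onto Kronecker products of Helmert contrasts, giving
F = (n Σ z̄²/q) / (Σ(z − z̄)²/q(n−1)), partial η² = SS_eff/(SS_eff+SS_err),
and Box's ε̂ from the contrast-score covariance (exactly 1 for two-level
effects; clipped into [1/q, 1] with a warning if numerically outside).
GG-corrected p-values use ε-scaled degrees of freedom. This is implemented
in-package because no installed library fits a three-way fully-within
design with GG correction; one- and two-way cases are cross-checked against
pingouin in the tests.

Fine-binned effects: nine 10°-wide bins over (0°, 90°], per participant and
hemisphere, each minus that participant's Baseline (> 90°) amplitude; bin
centres for the regression are the midpoints 5.5°, 15.5°, …, 85.5° of the
integer-degree bin labels. The group regression is weighted least squares
(statsmodels) with weights 1/(across-participant variance of the bin
effect); the weighted correlation r carries the sign of the relationship
and R² = r². No multiple-testing correction is applied across the ANOVA
family, matching conventional reporting; a Bonferroni flag is out of scope.

## Problem sizes

Simulation sizes used by the test suite and the acceptance script:
parameter recovery, 100 datasets of 240 trials; test calibration, 400 null
datasets; power, 100 datasets; RIDE checks, 60–200 trials per decomposition
and 100 noise seeds for the no-inflation control; the end-to-end cohort
check, 21 participants × 240 trials with RIDE per bin, repeated over 50
seeds in the tests and 30 seeds in `scripts/acceptance.py`.

## Known limitations

- The s parameterization is a convention; fitted ŝ values are comparable
  across this package's analyses but not necessarily to published fits
  using an unstated parameterization.
- Latency estimation is pooled across channels (one latency per trial);
  per-electrode latencies are not supported.
- The S/C split inside the window overlap is reported as produced by the
  warm-started iteration; only the S + C sum is identified there.
- The synthetic cohort is homogeneous across participants, which makes
  group F statistics far larger than real data would give; qualitative
  (significant / not significant) patterns, rates over seeds, and recovery
  errors are the meaningful outputs.
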