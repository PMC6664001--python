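# ridemix

Threshold mixture modeling of continuous source-memory errors and RIDE
latency-jitter correction of event-related potentials (ERPs).

## What this package is for

In a continuous source-memory task, participants study items at locations
on a circle and later reproduce each location; the signed angular error
between response and target is the behavioral unit of analysis. Two linked
analyses ask whether episodic recollection — particularly in older adults —
is *thresholded and variable*:

1. **Behavioral.** Per participant, errors θ are modelled as a mixture of
   recollection and guessing,

       f(θ) = λ·WC(θ; s) + (1 − λ)/360,

   where λ is the proportion of recollected trials, WC is a wrapped Cauchy
   centred on the target with scale *s* (degrees), and the remainder are
   uniform guesses. A likelihood-ratio test against the continuous
   restriction λ = 1 decides threshold vs continuous recollection;
   per-participant deviances sum into a group χ² with df = number of
   participants.

2. **Electrophysiological.** The parietal retrieval-success effect
   (500–800 ms, centro-parietal/parietal electrode pairs PR1–PR6) is
   measured for response-accuracy bins High (≤10°), Low (10–35°], Guess
   (35–90°] and Baseline (>90°), each against Baseline. Because
   trial-to-trial latency jitter of endogenous components smears and
   attenuates conventional averages, single-trial epochs are decomposed
   with RIDE (residual iteration decomposition) into a stimulus-locked S
   cluster and a latency-variable C cluster via template matching and
   median-based iteration, and latency-compensated averages (rERPs) are
   reconstructed before the binned analysis. Group inference uses
   repeated-measures ANOVA (Category × Hemisphere × Site) with
   Greenhouse–Geisser correction, and a weighted-least-squares regression
   of fine-binned (10°) effect sizes on response error with
   inverse-variance weights.

The study data this pipeline targets are available only on request, so the
package ships a synthetic-data module that generates behavioral errors and
single-trial EEG epochs with exactly the statistical structure the analysis
assumes (threshold mixture; jittered, accuracy-scaled endogenous component;
white noise), with ground truth recorded for recovery testing. See
`docs/methods.md` for the model details, defaults and their rationale, and
known limitations.

## Worked example

Behavioral fits on a simulated 21-participant cohort at the generative
values λ = 0.66, s = 15.39°, 240 trials each:

```python
import numpy as np
from ridemix import BehaviorSimSpec, simulate_errors, fit_participants
from ridemix.mixture import MixtureFit, group_lrt

errors, _ = simulate_errors(BehaviorSimSpec(lam=0.66, s_deg=15.39, n_trials=240,
                                            n_participants=21, seed=42))
fits = fit_participants(errors)
pairs = [
    (MixtureFit(r.lam, r.s_deg, r.loglik_full, int(r.n_trials), True, 27),
     MixtureFit(1.0, np.nan, r.loglik_restricted, int(r.n_trials), True, 5, True))
    for r in fits.itertuples()
]
group = group_lrt(pairs)
print(f"mean lambda = {fits['lam'].mean():.3f}   mean s = {fits['s_deg'].mean():.2f} deg")
print(f"group chi2({group.df}) = {group.chi2:.2f}, p = {group.p:.3g}")
print(f"threshold supported in {(fits['p'] < 0.05).sum()}/21 participants")
```

```
mean lambda = 0.660   mean s = 15.45 deg
group chi2(21) = 406.35, p = 4.5e-73
threshold supported in 20/21 participants
```

The recollection rate and precision recover the generative values, and the
likelihood-ratio test detects the threshold (guessing) component in nearly
every simulated participant.

RIDE on one participant's High-accuracy epochs (endogenous component: 5 μV
peak, jittered uniformly ±100 ms):

```python
import numpy as np, pandas as pd
from ridemix import EEGSimSpec, simulate_epochs, decompose

trials = pd.DataFrame({"participant": 0, "trial": range(60),
                       "error_deg": 0.0, "rt_ms": 900.0})
epochs, _ = simulate_epochs(EEGSimSpec(noise_sd=0.0, seed=7), trials)
decomp = decompose(epochs)
window = (epochs.times_ms >= 450) & (epochs.times_ms <= 850)
print(f"conventional C peak: {decomp.conventional[0][window].max():.2f} uV (truth 5.00)")
print(f"rERP C peak:         {decomp.rerp[0][window].max():.2f} uV")

noisy, truth = simulate_epochs(EEGSimSpec(noise_sd=5.0, seed=7), trials)
dn = decompose(noisy)
r = np.corrcoef(truth.table['latency_ms'], dn.c_latency_samples)[0, 1]
print(f"single-trial latency recovery r = {r:.3f} (noise SD 5 uV)")
```

```
conventional C peak: 3.56 uV (truth 5.00)
rERP C peak:         4.99 uV
single-trial latency recovery r = 0.997 (noise SD 5 uV)
```

Jitter smears the conventional average to ~71 % of the true amplitude; the
reconstructed ERP restores it, and template matching tracks the true
single-trial latencies even at unit signal-to-noise.

The full cohort analysis (simulate → preprocess → RIDE per bin → binned
effects → ANOVA and fine-bin regression) is one call:

```python
from ridemix import analyze_cohort
res = analyze_cohort()                # 21 participants, default generator
res.anovas[("ride", "High")]          # Category x Hemisphere x Site table
res.wls[("ride", "Left")]             # fine-bin WLS: slope, r, p
```

## Command line

```bash
ridemix simulate --behavior-spec spec.json --out data/ --seed 1
ridemix fit-behavior data/errors.csv --out fits.csv
ridemix ride data/participant_00/ --out decomp/
ridemix pipeline data/ --ride --out results/
ridemix report results/ --out report/
```

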