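"""End-to-end cohort analysis: simulate -> preprocess -> (RIDE) -> bins ->
effects -> group statistics.

Runs the identical conditionalization pipeline on conventional bin averages
and on RIDE-reconstructed ERPs (byte-identical configuration for the two
sources), producing the participant x category x hemisphere x site effect
matrix, the per-category ANOVAs against Baseline, and the fine-binned
weighted regression of effect size on response error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import pipeline as pl
from .containers import EpochSet
from .ride import RideConfig, decompose
from .stats import fine_bin_effects, rm_anova, trial_window_amplitudes, wls_regression
from .synthetic import BehaviorSimSpec, EEGSimSpec, simulate_epochs, simulate_errors

__all__ = ["PipelineConfig", "CohortResult", "process_participant", "analyze_cohort"]

#: RIDE needs this many trials in a bin to attempt decomposition; bins
#: below it keep their raw trials in the re-synchronized set
RIDE_HARD_FLOOR = 10


@dataclass(frozen=True)
class PipelineConfig:
    """One configuration applied to both ERP sources."""

    baseline_window_ms: tuple[float, float] = (-104.0, 0.0)
    drift_uv: float = 75.0
    range_uv: float = 100.0
    smooth_points: int = 5
    min_trials: int = pl.MIN_TRIALS
    window_ms: tuple[float, float] = pl.ANALYSIS_WINDOW_MS
    ride: RideConfig = field(default_factory=RideConfig)


@dataclass
class ParticipantResult:
    participant: object
    bin_erps: dict  # (source, bin) -> channels x samples (smoothed)
    counts: pd.DataFrame  # bin, n_trials, included
    trial_amplitudes: pd.DataFrame  # per source/hemisphere/trial window amps
    n_rejected: int
    ride_converged: bool
    channel_names: list[str] = field(default_factory=list)
    sfreq: float = 250.0
    tmin_ms: float = -104.0


@dataclass
class CohortResult:
    effect_matrix: pd.DataFrame
    anovas: dict  # (source, category) -> rm_anova table
    fine_bins: dict  # source -> FineBinTable
    wls: dict  # (source, hemisphere) -> WlsResult
    counts: pd.DataFrame
    errors: pd.DataFrame


def process_participant(
    epochs: EpochSet, config: PipelineConfig | None = None, sources=("conventional", "ride")
) -> ParticipantResult:
    """Preprocess one participant's epochs and form per-bin ERPs.

    Baseline-corrects, rejects artifact trials, assigns accuracy bins, and
    builds conventional bin averages; for the 'ride' source each bin is
    decomposed separately (the endogenous component's amplitude is
    bin-specific under the some-or-none hypothesis) and its rERP used
    instead. Smoothing is applied to the resulting average waveforms.
    """
    config = config or PipelineConfig()
    pid = epochs.trial_meta["participant"].iloc[0] if "participant" in epochs.trial_meta else 0

    n_before = epochs.n_trials
    epochs = pl.baseline_correct(epochs, config.baseline_window_ms)
    epochs, _rej = pl.reject_artifacts(epochs, config.drift_uv, config.range_uv)
    meta = epochs.trial_meta
    if "bin" not in meta.columns:
        meta = meta.assign(bin=pl.assign_bin(meta["error_deg"].to_numpy()))
        epochs.trial_meta = meta
    labels = meta["bin"].to_numpy()

    count_rows = []
    bin_erps: dict = {}
    ride_converged = True
    resynced = epochs.copy() if "ride" in sources else None
    for b in pl.BIN_LABELS:
        mask = labels == b
        n = int(mask.sum())
        count_rows.append(
            {"participant": pid, "bin": b, "n_trials": n, "included": n >= config.min_trials}
        )
        if n == 0:
            continue
        if "conventional" in sources:
            bin_erps[("conventional", b)] = pl.smooth(
                epochs.data[mask].mean(axis=0), config.smooth_points
            )
        if "ride" in sources and n >= RIDE_HARD_FLOOR:
            with warnings.catch_warnings():
                # convergence is recorded in the ride_converged flag instead
                warnings.filterwarnings("ignore", message="C latencies did not converge")
                warnings.filterwarnings("ignore", message="decomposing only")
                decomp = decompose(epochs.subset(mask), config.ride)
            ride_converged &= decomp.converged
            bin_erps[("ride", b)] = pl.smooth(decomp.rerp, config.smooth_points)
            resynced.data[mask] = decomp.resynchronized().data
        elif "ride" in sources and n:
            bin_erps[("ride", b)] = pl.smooth(epochs.data[mask].mean(axis=0), config.smooth_points)

    amp_frames = []
    if "conventional" in sources:
        df = trial_window_amplitudes(epochs, window_ms=config.window_ms)
        df["source"] = "conventional"
        amp_frames.append(df)
    if "ride" in sources:
        df = trial_window_amplitudes(resynced, window_ms=config.window_ms)
        df["source"] = "ride"
        amp_frames.append(df)

    return ParticipantResult(
        participant=pid,
        bin_erps=bin_erps,
        counts=pd.DataFrame(count_rows),
        trial_amplitudes=pd.concat(amp_frames, ignore_index=True),
        n_rejected=n_before - epochs.n_trials,
        ride_converged=ride_converged,
        channel_names=list(epochs.channel_names),
        sfreq=epochs.sfreq,
        tmin_ms=epochs.tmin_ms,
    )


def _participant_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(v & 0x7FFFFFFF) for v in state]


def analyze_cohort(
    behavior: BehaviorSimSpec | None = None,
    eeg: EEGSimSpec | None = None,
    config: PipelineConfig | None = None,
    categories=("High", "Low", "Guess"),
    sources=("conventional", "ride"),
) -> CohortResult:
    """Simulate a cohort and run the full group analysis.

    Each participant's epochs are generated (seeded independently from the
    EEG spec's seed) and processed one at a time to bound memory; the group
    stage assembles the effect matrix, runs the per-category ANOVAs against
    Baseline per source, and fits the fine-bin WLS regressions per
    hemisphere.
    """
    behavior = behavior or BehaviorSimSpec()
    eeg = eeg or EEGSimSpec()
    config = config or PipelineConfig()
    errors, _truth = simulate_errors(behavior)
    seeds = _participant_seeds(eeg.seed, behavior.n_participants)

    results = []
    for pid, err_p in errors.groupby("participant", sort=True):
        epochs, _gt = simulate_epochs(replace(eeg, seed=seeds[int(pid)]), err_p)
        results.append(process_participant(epochs, config, sources))

    counts = pd.concat([r.counts for r in results], ignore_index=True)
    roi = pl.ROISpec()

    # effect matrix: participant x source x category x hemisphere x site
    rows = []
    for r in results:
        inc = r.counts.set_index("bin")["included"]
        for (source, b), wave in r.bin_erps.items():
            if not inc.get(b, False):
                continue
            for pr, pair in roi.regions.items():
                idx = [r.channel_names.index(c) for c in pair]
                amp = pl.window_mean(
                    wave[idx].mean(axis=0), r.sfreq, r.tmin_ms, config.window_ms
                )
                rows.append(
                    {
                        "participant": r.participant,
                        "source": source,
                        "category": b,
                        "region": pr,
                        "hemisphere": roi.hemisphere[pr],
                        "site": roi.site[pr],
                        "mean_uv": float(amp),
                    }
                )
    effect_matrix = pd.DataFrame(rows)

    anovas = {}
    for source in sources:
        for cat in categories:
            sub = effect_matrix[
                (effect_matrix["source"] == source)
                & (effect_matrix["category"].isin([cat, "Baseline"]))
            ]
            complete = (
                sub.groupby("participant")["category"].nunique().pipe(lambda s: s[s == 2]).index
            )
            sub = sub[sub["participant"].isin(complete)]
            if sub["participant"].nunique() >= 2:
                anovas[(source, cat)] = rm_anova(sub)

    fine_bins: dict = {}
    wls: dict = {}
    all_amps = pd.concat([r.trial_amplitudes for r in results], ignore_index=True)
    for source in sources:
        table = fine_bin_effects(all_amps[all_amps["source"] == source])
        fine_bins[source] = table
        for hemi in ("Left", "Right"):
            summ = table.summary[table.summary["hemisphere"] == hemi]
            wls[(source, hemi)] = wls_regression(summ)

    return CohortResult(
        effect_matrix=effect_matrix,
        anovas=anovas,
        fine_bins=fine_bins,
        wls=wls,
        counts=counts,
        errors=errors,
    )
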