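"""ERP preprocessing and accuracy-binned conditionalization.

Implements the preprocessing chain applied identically to conventional
averages and to RIDE-reconstructed ERPs: baseline correction against the
pre-stimulus interval, threshold-based artifact rejection, 5-point boxcar
smoothing, averaging into response-accuracy bins with a minimum-trial
inclusion rule, retrieval-success subtractions against the Baseline bin,
parietal ROI window amplitudes, and min/max rescaling of difference
topographies.

Response-accuracy bins on the absolute angular error (half-open intervals;
0 deg is included in High):

=========  ================
High       [0, 10] deg
Low        (10, 35] deg
Guess      (35, 90] deg
Baseline   (90, 180] deg
=========  ================

Baseline trials come from the half of the circle opposite the target, where
responses cannot be based on recollection — the ERP analogue of "miss"
trials in a binary old/new design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import EpochSet

__all__ = [
    "BIN_LABELS",
    "BIN_EDGES_DEG",
    "ROISpec",
    "ConditionERP",
    "assign_bin",
    "baseline_correct",
    "reject_artifacts",
    "smooth",
    "average_bins",
    "window_mean",
    "roi_window_table",
    "retrieval_success_effect",
    "minmax_rescale",
]

BIN_LABELS = ("High", "Low", "Guess", "Baseline")
#: upper edges of the |error| intervals (each interval is open below,
#: closed above, except High which includes 0)
BIN_EDGES_DEG = (10.0, 35.0, 90.0, 180.0)

ANALYSIS_WINDOW_MS = (500.0, 800.0)
MIN_TRIALS = 16


def assign_bin(error_deg):
    """Response-accuracy bin label(s) for signed error(s) in (-180, 180].

    Boundary convention: 10 deg -> High, 35 deg -> Low, 90 deg -> Guess.
    """
    err = np.abs(np.asarray(error_deg, dtype=float))
    if np.any(err > 180.0):
        raise ValueError("error_deg must lie in (-180, 180]")
    idx = np.searchsorted(BIN_EDGES_DEG, err, side="left")
    labels = np.asarray(BIN_LABELS, dtype=object)[idx]
    return labels if err.ndim else str(labels)


# --------------------------------------------------------------------- #
# preprocessing


def baseline_correct(epochs: EpochSet, baseline_window=( -104.0, 0.0)) -> EpochSet:
    """Subtract the mean over the pre-stimulus baseline per trial/channel."""
    sl = epochs.window_slice(*baseline_window)
    if sl.stop - sl.start < 1:
        raise ValueError("empty baseline window")
    out = epochs.copy()
    out.data -= out.data[:, :, sl].mean(axis=2, keepdims=True)
    return out


def reject_artifacts(
    epochs: EpochSet, drift_uv: float = 75.0, range_uv: float = 100.0
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop trials breaching amplitude thresholds; return survivors and a log.

    A trial is rejected if on any channel a baseline-relative sample exceeds
    ``drift_uv`` in absolute value (drift rule), or the within-epoch
    peak-to-peak range exceeds ``range_uv`` (signal-change rule). Input must
    already be baseline-corrected. The log lists trial, channel and rule for
    every violation.
    """
    data = epochs.data
    drift_bad = np.abs(data).max(axis=2) > drift_uv  # (trials, channels)
    rng_bad = np.ptp(data, axis=2) > range_uv
    log_rows = []
    for rule, bad in (("drift", drift_bad), ("range", rng_bad)):
        for t, c in zip(*np.nonzero(bad)):
            log_rows.append(
                {"trial": int(t), "channel": epochs.channel_names[c], "rule": rule}
            )
    log = pd.DataFrame(log_rows, columns=["trial", "channel", "rule"])
    keep = ~(drift_bad.any(axis=1) | rng_bad.any(axis=1))
    if not keep.any():
        raise ValueError("artifact rejection removed every trial")
    return epochs.subset(keep), log


def smooth(waveform: np.ndarray, kernel_points: int = 5) -> np.ndarray:
    """Centred boxcar moving average along the last (time) axis.

    Edges use shrinking windows so the output has the same length and a
    constant signal is left unchanged.
    """
    if kernel_points % 2 != 1:
        raise ValueError("kernel_points must be odd")
    waveform = np.asarray(waveform, dtype=float)
    n = waveform.shape[-1]
    if kernel_points > n:
        raise ValueError("kernel longer than the signal")
    half = kernel_points // 2
    csum = np.cumsum(waveform, axis=-1)
    csum = np.concatenate([np.zeros_like(csum[..., :1]), csum], axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1) + 1
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


# --------------------------------------------------------------------- #
# conditionalization


@dataclass
class ConditionERP:
    """Per participant x bin average waveforms for one source.

    ``erps`` maps ``(participant, bin)`` to a channels x samples array.
    ``counts`` is a table of trial counts per participant and bin, with an
    ``included`` flag implementing the minimum-trial rule; ``exclusions``
    lists every (participant, bin) that failed the rule with its reason.
    """

    erps: dict
    counts: pd.DataFrame
    exclusions: pd.DataFrame
    sfreq: float
    tmin_ms: float
    channel_names: list[str]
    source: str = "conventional"

    def participants_complete(self, bins: Iterable[str]) -> list:
        """Participants with every requested bin included."""
        bins = list(bins)
        ok = []
        for pid, grp in self.counts.groupby("participant", sort=True):
            inc = grp.set_index("bin")["included"]
            if all(b in inc.index and inc[b] for b in bins):
                ok.append(pid)
        return ok


def average_bins(
    epochs: EpochSet,
    bins: Mapping[str, str] | None = None,
    min_trials: int = MIN_TRIALS,
    source: str = "conventional",
) -> ConditionERP:
    """Average trials into accuracy bins per participant.

    Bin labels are taken from ``epochs.trial_meta['bin']`` if present,
    otherwise derived from ``error_deg``. Bins with fewer than
    ``min_trials`` trials are flagged and excluded from group analyses
    involving that bin.
    """
    meta = epochs.trial_meta
    if "bin" in meta.columns:
        labels = meta["bin"].to_numpy()
    elif "error_deg" in meta.columns:
        labels = assign_bin(meta["error_deg"].to_numpy())
    else:
        raise ValueError("trial_meta must provide 'bin' or 'error_deg'")
    participants = (
        meta["participant"].to_numpy()
        if "participant" in meta.columns
        else np.zeros(epochs.n_trials, dtype=int)
    )

    erps: dict = {}
    count_rows, excl_rows = [], []
    for pid in pd.unique(participants):
        pmask = participants == pid
        for b in BIN_LABELS:
            tmask = pmask & (labels == b)
            n = int(tmask.sum())
            included = n >= min_trials
            count_rows.append(
                {"participant": pid, "bin": b, "n_trials": n, "included": included}
            )
            if not included:
                excl_rows.append(
                    {
                        "participant": pid,
                        "bin": b,
                        "n_trials": n,
                        "reason": f"only {n} artifact-free trials (< {min_trials})",
                    }
                )
            if n:
                erps[(pid, b)] = epochs.data[tmask].mean(axis=0)
    if not any(r["included"] for r in count_rows):
        raise ValueError("no participant has any bin meeting the minimum-trial rule")
    return ConditionERP(
        erps=erps,
        counts=pd.DataFrame(count_rows),
        exclusions=pd.DataFrame(excl_rows, columns=["participant", "bin", "n_trials", "reason"]),
        sfreq=epochs.sfreq,
        tmin_ms=epochs.tmin_ms,
        channel_names=list(epochs.channel_names),
        source=source,
    )


# --------------------------------------------------------------------- #
# ROI / effect extraction


@dataclass(frozen=True)
class ROISpec:
    """Parietal Region (PR) ROIs: paired centro-parietal/parietal channels.

    PR5/PR3/PR1 lie over the left hemisphere (inferior/middle/superior
    sites), PR2/PR4/PR6 over the right.
    """

    regions: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "PR5": ("CP5", "P5"),
            "PR3": ("CP3", "P3"),
            "PR1": ("CP1", "P1"),
            "PR2": ("CP2", "P2"),
            "PR4": ("CP4", "P4"),
            "PR6": ("CP6", "P6"),
        }
    )
    hemisphere: Mapping[str, str] = field(
        default_factory=lambda: {
            "PR5": "Left",
            "PR3": "Left",
            "PR1": "Left",
            "PR2": "Right",
            "PR4": "Right",
            "PR6": "Right",
        }
    )
    site: Mapping[str, str] = field(
        default_factory=lambda: {
            "PR5": "Inferior",
            "PR6": "Inferior",
            "PR3": "Middle",
            "PR4": "Middle",
            "PR1": "Superior",
            "PR2": "Superior",
        }
    )

    def channels(self, hemisphere: str | None = None) -> list[str]:
        chans: list[str] = []
        for pr, pair in self.regions.items():
            if hemisphere is None or self.hemisphere[pr] == hemisphere:
                chans.extend(pair)
        return chans


def window_mean(
    waveform: np.ndarray, sfreq: float, tmin_ms: float, window_ms=ANALYSIS_WINDOW_MS
) -> np.ndarray:
    """Mean over the analysis window (inclusive at both edges), per channel."""
    step = 1000.0 / sfreq
    lo = int(round((window_ms[0] - tmin_ms) / step))
    hi = int(round((window_ms[1] - tmin_ms) / step))
    return np.asarray(waveform, dtype=float)[..., lo : hi + 1].mean(axis=-1)


def roi_window_table(
    cond: ConditionERP,
    roi: ROISpec | None = None,
    window_ms=ANALYSIS_WINDOW_MS,
    bins: Iterable[str] = BIN_LABELS,
) -> pd.DataFrame:
    """Window-mean amplitude per participant x bin x hemisphere x site.

    One row per participant, bin (category), PR region; only participants
    with all requested bins included survive.
    """
    roi = roi or ROISpec()
    bins = list(bins)
    keep = cond.participants_complete(bins)
    rows = []
    for pid in keep:
        for b in bins:
            wave = cond.erps[(pid, b)]
            for pr, pair in roi.regions.items():
                idx = [cond.channel_names.index(c) for c in pair]
                amp = window_mean(wave[idx].mean(axis=0), cond.sfreq, cond.tmin_ms, window_ms)
                rows.append(
                    {
                        "participant": pid,
                        "source": cond.source,
                        "category": b,
                        "region": pr,
                        "hemisphere": roi.hemisphere[pr],
                        "site": roi.site[pr],
                        "mean_uv": float(amp),
                    }
                )
    if not rows:
        raise ValueError("no participant satisfies the minimum-trial rule for all bins")
    return pd.DataFrame(rows)


def retrieval_success_effect(
    cond: ConditionERP,
    bin_label: str,
    roi: ROISpec | None = None,
    window_ms=ANALYSIS_WINDOW_MS,
) -> pd.DataFrame:
    """Bin and (bin - Baseline) window amplitudes per hemisphere x site.

    Returns one row per participant x region with the bin amplitude, the
    Baseline amplitude and their difference (the retrieval-success effect).
    """
    table = roi_window_table(cond, roi, window_ms, bins=[bin_label, "Baseline"])
    wide = table.pivot_table(
        index=["participant", "region", "hemisphere", "site"],
        columns="category",
        values="mean_uv",
    ).reset_index()
    if "Baseline" not in wide.columns:
        raise ValueError("Baseline bin unavailable")
    wide["baseline_uv"] = wide["Baseline"]
    wide["bin_uv"] = wide[bin_label]
    wide = wide.drop(columns=list({bin_label, "Baseline"}))
    wide["effect_uv"] = wide["bin_uv"] - wide["baseline_uv"]
    wide["category"] = bin_label
    return wide


def minmax_rescale(topography: np.ndarray) -> np.ndarray:
    """Min/max rescaling of a difference topography to [0, 1].

    Removes overall effect-size differences so that shape comparisons
    across conditions are not confounded by amplitude. Applied per
    participant along the last (channel) axis.
    """
    x = np.asarray(topography, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("need at least two channels")
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    if np.any(hi == lo):
        raise ValueError("degenerate (constant) topography cannot be rescaled")
    return (x - lo) / (hi - lo)
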