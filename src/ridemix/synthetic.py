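"""Synthetic behavioral and EEG data with the generative structure the
analysis assumes.

Behavioral errors follow the threshold mixture: with probability ``lam`` a
trial is recollected and its signed angular error is wrapped-Cauchy around
0 deg with scale ``s_deg``; otherwise the response is a uniform guess on
the circle. Defaults (``lam = 0.66``, ``s_deg = 15.39``, 240 trials per
participant, 21 participants) reproduce the group-level statistics reported
for older adults performing the continuous source task.

EEG epochs are built as ``trial(t) = S(t) + a(bin) * C(t - tau) + noise``:
a stimulus-locked component S at fixed latency, plus an endogenous
component C whose trial latency ``tau`` is jittered and whose amplitude
scale ``a`` depends on the trial's response-accuracy bin, plus white
Gaussian noise. The default amplitude map encodes the some-or-none
hypothesis — High = 1.0, Low = 0.6, Guess = Baseline = 0.0 — so guessed
trials carry no retrieval signal at all. Ground truth (per-trial latency
shift, bin label, noiseless signal) is recorded for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import EpochSet, wrap_degrees
from .pipeline import assign_bin

__all__ = [
    "PARIETAL_CHANNELS",
    "BehaviorSimSpec",
    "ComponentSpec",
    "JitterSpec",
    "EEGSimSpec",
    "GroundTruth",
    "simulate_errors",
    "make_component_waveform",
    "simulate_epochs",
    "default_eeg_spec",
]

#: the six centro-parietal / parietal electrode pairs used by the PR ROIs
PARIETAL_CHANNELS = (
    "CP5", "CP3", "CP1", "CP2", "CP4", "CP6",
    "P5", "P3", "P1", "P2", "P4", "P6",
)


@dataclass(frozen=True)
class BehaviorSimSpec:
    """Generative parameters of the threshold mixture of response errors."""

    lam: float = 0.66
    s_deg: float = 15.39
    n_trials: int = 240
    n_participants: int = 21
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.s_deg <= 0:
            raise ValueError("s_deg must be > 0")
        if self.n_trials < 1 or self.n_participants < 1:
            raise ValueError("n_trials and n_participants must be >= 1")


@dataclass(frozen=True)
class ComponentSpec:
    """A smooth unimodal (Hann-windowed) ERP component.

    The waveform is ``peak_amplitude_uv * cos^2(pi (t - peak) / width)`` for
    ``|t - peak| <= width/2`` and zero outside, scaled per channel by
    ``topography``.
    """

    peak_latency_ms: float
    width_ms: float
    peak_amplitude_uv: float
    topography: tuple[float, ...] = tuple(1.0 for _ in PARIETAL_CHANNELS)

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ValueError("width_ms must be > 0")


@dataclass(frozen=True)
class JitterSpec:
    """Trial-to-trial latency jitter of the endogenous component.

    ``width_ms`` is the half-width of a uniform distribution (shifts drawn
    on [-width, +width]) or the standard deviation of a Gaussian.
    """

    family: str = "uniform"
    width_ms: float = 100.0

    def __post_init__(self):
        if self.family not in ("uniform", "gaussian"):
            raise ValueError("jitter family must be 'uniform' or 'gaussian'")
        if self.width_ms < 0:
            raise ValueError("jitter width must be >= 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "uniform":
            return rng.uniform(-self.width_ms, self.width_ms, size=n)
        return rng.normal(0.0, self.width_ms, size=n)

    @property
    def max_abs_ms(self) -> float:
        # Gaussian support is truncated at 4 SD for the epoch-fit check
        return self.width_ms if self.family == "uniform" else 4.0 * self.width_ms


@dataclass(frozen=True)
class EEGSimSpec:
    """Single-trial epoch generator: S + a(bin)*C(t - tau) + white noise."""

    channel_names: tuple[str, ...] = PARIETAL_CHANNELS
    sfreq: float = 250.0
    epoch_window_ms: tuple[float, float] = (-104.0, 1936.0)
    s_component: ComponentSpec = field(
        default_factory=lambda: ComponentSpec(200.0, 200.0, 5.0)
    )
    c_component: ComponentSpec = field(
        default_factory=lambda: ComponentSpec(650.0, 300.0, 5.0)
    )
    amplitude_map: Mapping[str, float] = field(
        default_factory=lambda: {"High": 1.0, "Low": 0.6, "Guess": 0.0, "Baseline": 0.0}
    )
    jitter: JitterSpec = field(default_factory=JitterSpec)
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        t0, t1 = self.epoch_window_ms
        if not t0 <= 0.0 < t1:
            raise ValueError("epoch window must contain 0 ms")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for comp in (self.s_component, self.c_component):
            if len(comp.topography) != len(self.channel_names):
                raise ValueError("topography length must match channel count")
        c = self.c_component
        lo = c.peak_latency_ms - c.width_ms / 2 - self.jitter.max_abs_ms
        hi = c.peak_latency_ms + c.width_ms / 2 + self.jitter.max_abs_ms
        if lo < t0 or hi > t1:
            raise ValueError("jittered C support extends outside the epoch")
        s = self.s_component
        if s.peak_latency_ms - s.width_ms / 2 < t0 or s.peak_latency_ms + s.width_ms / 2 > t1:
            raise ValueError("S support extends outside the epoch")

    @property
    def times_ms(self) -> np.ndarray:
        t0, t1 = self.epoch_window_ms
        n = int(round((t1 - t0) / 1000.0 * self.sfreq))
        return t0 + np.arange(n) * 1000.0 / self.sfreq


def default_eeg_spec(**overrides) -> EEGSimSpec:
    """The default epoch generator, with keyword overrides."""
    return replace(EEGSimSpec(), **overrides) if overrides else EEGSimSpec()


@dataclass
class GroundTruth:
    """Per-trial generative state, the oracle for recovery tests."""

    table: pd.DataFrame  # participant, trial, bin, latency_ms, c_scale
    noiseless: np.ndarray  # (n_trials, n_channels, n_samples)


# --------------------------------------------------------------------- #


def simulate_errors(spec: BehaviorSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-trial angular errors from the threshold mixture.

    Returns ``(errors, truth)``: the error table (participant, trial,
    error_deg, rt_ms) and a ground-truth table carrying the latent
    ``recollected`` flag for each trial.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_trials * spec.n_participants
    recollected = rng.random(n_total) < spec.lam
    # wrapping a Cauchy(0, s_deg) onto the circle yields the wrapped Cauchy
    # with concentration rho = exp(-s_deg * pi/180)
    wc = wrap_degrees(rng.standard_cauchy(n_total) * spec.s_deg)
    uniform = 180.0 - rng.uniform(0.0, 360.0, size=n_total)
    error = np.where(recollected, wc, uniform)
    rt = rng.lognormal(mean=np.log(1500.0), sigma=0.3, size=n_total)
    errors = pd.DataFrame(
        {
            "participant": np.repeat(np.arange(spec.n_participants), spec.n_trials),
            "trial": np.tile(np.arange(spec.n_trials), spec.n_participants),
            "error_deg": error,
            "rt_ms": rt,
        }
    )
    truth = errors[["participant", "trial"]].copy()
    truth["recollected"] = recollected
    return errors, truth


def _bump(times_ms: np.ndarray, peak_ms, width_ms: float) -> np.ndarray:
    """Unit-amplitude Hann bump(s); ``peak_ms`` may be an array (per trial)."""
    peak = np.asarray(peak_ms, dtype=float)
    dt = times_ms - peak[..., None] if peak.ndim else times_ms - peak
    inside = np.abs(dt) <= width_ms / 2.0
    return np.where(inside, np.cos(np.pi * dt / width_ms) ** 2, 0.0)


def make_component_waveform(spec: ComponentSpec, times_ms: np.ndarray) -> np.ndarray:
    """Evaluate a component on a time axis -> (n_channels, n_samples)."""
    times_ms = np.asarray(times_ms, dtype=float)
    lo, hi = spec.peak_latency_ms - spec.width_ms / 2, spec.peak_latency_ms + spec.width_ms / 2
    if spec.peak_amplitude_uv != 0.0 and (lo < times_ms[0] or hi > times_ms[-1]):
        raise ValueError("component support exceeds the time axis")
    profile = _bump(times_ms, spec.peak_latency_ms, spec.width_ms)
    gains = np.asarray(spec.topography, dtype=float)
    return spec.peak_amplitude_uv * gains[:, None] * profile[None, :]


def simulate_epochs(
    spec: EEGSimSpec, errors: pd.DataFrame
) -> tuple[EpochSet, GroundTruth]:
    """Generate one epoch per behavioral trial.

    Each epoch is the stimulus-locked S plus the endogenous C shifted by a
    per-trial latency drawn from the jitter distribution and scaled by the
    amplitude-map entry for the trial's accuracy bin, plus i.i.d. Gaussian
    noise per sample and channel. C shifts are applied analytically (the
    bump is re-evaluated at the shifted latency), so no resampling error is
    introduced.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.times_ms
    n_trials = len(errors)
    n_ch = len(spec.channel_names)

    bins = assign_bin(errors["error_deg"].to_numpy()) if n_trials else np.array([], dtype=object)
    missing = set(np.unique(bins)) - set(spec.amplitude_map)
    if missing:
        raise ValueError(f"amplitude_map lacks entries for bins: {sorted(missing)}")
    scales = np.array([spec.amplitude_map[b] for b in bins], dtype=float)
    tau = spec.jitter.draw(rng, n_trials)

    s_wave = make_component_waveform(spec.s_component, times)  # (ch, samp)
    c = spec.c_component
    c_gain = c.peak_amplitude_uv * np.asarray(c.topography, dtype=float)
    c_profiles = _bump(times, c.peak_latency_ms + tau, c.width_ms)  # (trials, samp)

    noiseless = (
        s_wave[None, :, :]
        + scales[:, None, None] * c_gain[None, :, None] * c_profiles[:, None, :]
    )
    if n_trials == 0:
        noiseless = np.zeros((0, n_ch, times.size))
    data = noiseless
    if spec.noise_sd > 0 and n_trials:
        data = noiseless + rng.normal(0.0, spec.noise_sd, size=noiseless.shape)

    meta = errors.reset_index(drop=True).copy()
    meta["bin"] = bins
    epochs = EpochSet(
        data=data,
        sfreq=spec.sfreq,
        tmin_ms=spec.epoch_window_ms[0],
        channel_names=list(spec.channel_names),
        trial_meta=meta,
    )
    truth_table = meta[[c for c in ("participant", "trial") if c in meta.columns]].copy()
    truth_table["bin"] = bins
    truth_table["latency_ms"] = tau
    truth_table["c_scale"] = scales
    return epochs, GroundTruth(table=truth_table, noiseless=noiseless)
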