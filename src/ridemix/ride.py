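"""Residual iteration decomposition (RIDE) of single-trial ERP epochs.

The model is ``trial_i(t) = S(t) + C(t - tau_i) + noise``: a stimulus-locked
component cluster S at fixed latency plus an endogenous cluster C whose
latency ``tau_i`` varies from trial to trial. Latency jitter smears the
conventional trial average and attenuates its amplitude; RIDE estimates the
per-trial C latencies by template matching (cross-correlation), separates S
and C by an alternating median-based decomposition, and reconstructs a
latency-compensated average (the rERP) by re-synchronizing each trial's C
contribution to the median latency.

The iteration scheme:

1. The C template is initialized from the conventional average restricted
   to the C window; per-trial latencies are the cross-correlation maxima
   within the search range.
2. Inner loop: S is the pointwise median over trials of ``trial - C``
   placed at that trial's latency, restricted to the S window; C is the
   pointwise median over trials of the latency-aligned residuals
   ``trial - S``, restricted to the C window. Medians immunize the
   iteration against noise amplification. The loop stops when the
   components stop changing; where the S and C windows overlap the split
   is not identifiable and the iteration is capped rather than run to a
   tolerance it cannot reach (see ``max_inner_iter``).
3. Latencies are re-estimated with the current C as template (matched
   against ``trial - S``) and re-centred to median zero; steps 2-3 repeat
   until the latency estimates converge.
4. A final pass with latencies frozen recomputes S and C as *means*, in
   line with standard ERP averaging. The mean of latency-shifted copies of
   a waveform is its convolution with the empirical latency histogram, so
   this stage is iterated to a tight fixed point in closed form.

No response-locked (R) cluster is estimated: the analyzed retrieval window
precedes the responses, so the decomposition reduces to S + C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import EpochSet

__all__ = [
    "RideConfig",
    "RideDecomposition",
    "LatencyEstimate",
    "estimate_c_latency",
    "decompose",
    "reconstruct",
]


@dataclass(frozen=True)
class RideConfig:
    """Decomposition settings.

    ``s_window_ms`` / ``c_window_ms`` bound the support of the two
    clusters; ``search_range_ms`` is the largest |latency shift| explored by
    template matching (the shifted C window must stay inside the epoch).
    ``template_lowpass_hz`` low-passes *copies* of the template and trials
    for matching only (the decomposition itself uses unfiltered data); set
    to ``None`` to disable. ``matching_channels`` names the channels
    averaged into the single matching signal (one C process per trial);
    ``None`` averages all channels.

    ``max_inner_iter`` caps the median-based alternating updates: within
    the S/C window overlap the split is non-identifiable, so late passes
    move the components along a direction the data cannot determine (and
    that the final restored-to-mean stage resolves anyway) at well below
    ``inner_tol_uv`` per pass; the cap cuts that tail off.
    """

    s_window_ms: tuple[float, float] = (0.0, 450.0)
    c_window_ms: tuple[float, float] = (200.0, 1600.0)
    search_range_ms: float = 300.0
    max_outer_iter: int = 10
    max_inner_iter: int = 6
    latency_tol_samples: int = 1
    inner_tol_uv: float = 1e-3
    template_lowpass_hz: float | None = 10.0
    matching_channels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.max_outer_iter < 1 or self.max_inner_iter < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.search_range_ms < 0:
            raise ValueError("search_range_ms must be >= 0")


@dataclass(frozen=True)
class LatencyEstimate:
    """Single-trial C latency from template matching."""

    trial: int
    shift_samples: int
    match_score: float


@dataclass
class RideDecomposition:
    """S and C component waveforms, per-trial C latencies and the rERP.

    ``c_latency_samples`` are integer shifts relative to the median latency
    (re-centred so their median is 0). ``rerp`` is the reconstructed,
    latency-compensated average; ``conventional`` the plain trial average.
    """

    S: np.ndarray
    C: np.ndarray
    c_latency_samples: np.ndarray
    match_scores: np.ndarray
    rerp: np.ndarray
    conventional: np.ndarray
    n_outer_iters: int
    converged: bool
    config: RideConfig
    sfreq: float
    tmin_ms: float
    channel_names: list[str]
    epochs: EpochSet = field(repr=False, default=None)  # type: ignore[assignment]

    def resynchronized(self) -> EpochSet:
        """Trials with their C contribution re-shifted to the median latency."""
        if self.epochs is None:
            raise ValueError("decomposition holds no reference to its epochs")
        data = _resynchronize(self.epochs.data, self.C, self.c_latency_samples)
        out = self.epochs.copy()
        out.data = data
        return out


# --------------------------------------------------------------------- #
# primitives


def _shift(wave: np.ndarray, k: int) -> np.ndarray:
    """Shift along the last axis by k samples (positive = later), zero-padded.

    Samples shifted past the epoch edges are discarded, not wrapped.
    """
    if k == 0:
        return wave.copy()
    out = np.zeros_like(wave)
    if k > 0:
        out[..., k:] = wave[..., :-k]
    else:
        out[..., :k] = wave[..., -k:]
    return out


def _lowpass(x: np.ndarray, sfreq: float, cutoff_hz: float | None) -> np.ndarray:
    if cutoff_hz is None:
        return x
    sos = signal.butter(4, cutoff_hz / (sfreq / 2.0), btype="low", output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _window_mask(n_samples: int, sfreq: float, tmin_ms: float, window_ms) -> np.ndarray:
    times = tmin_ms + np.arange(n_samples) * 1000.0 / sfreq
    return (times >= window_ms[0]) & (times <= window_ms[1])


def _xcorr_latencies(
    signals: np.ndarray, template: np.ndarray, max_shift: int
) -> tuple[np.ndarray, np.ndarray]:
    """Best integer shift per row of ``signals`` against ``template``.

    The score of shift k is ``sum_t signals[t] * template[t - k]``; ties are
    broken toward the smaller |shift|.
    """
    n_samp = signals.shape[-1]
    corr = signal.fftconvolve(signals, template[::-1][None, :], mode="full", axes=-1)
    shifts = np.arange(-max_shift, max_shift + 1)
    scores = corr[:, n_samp - 1 + shifts]  # (n_trials, n_shifts)
    order = np.argsort(np.abs(shifts), kind="stable")
    best = order[np.argmax(scores[:, order], axis=1)]
    return shifts[best], scores[np.arange(len(signals)), best]


def estimate_c_latency(
    trial: np.ndarray,
    template: np.ndarray,
    config: RideConfig,
    sfreq: float,
    tmin_ms: float,
) -> LatencyEstimate:
    """Template-matching latency of C in one trial (1-D signals).

    The template is restricted to the C window; both signals are low-passed
    (matching copies only) when ``template_lowpass_hz`` is set. The returned
    shift maximizes the cross-correlation over +-search_range; a true shift
    beyond the search range is clamped to the range edge by construction.
    """
    trial = np.asarray(trial, dtype=float)
    template = np.asarray(template, dtype=float)
    mask = _window_mask(template.shape[-1], sfreq, tmin_ms, config.c_window_ms)
    template = template * mask
    if not np.any(template):
        raise ValueError("degenerate (all-zero) template")
    t_f = _lowpass(template, sfreq, config.template_lowpass_hz)
    x_f = _lowpass(trial, sfreq, config.template_lowpass_hz)
    max_shift = int(round(config.search_range_ms * sfreq / 1000.0))
    shift, score = _xcorr_latencies(x_f[None, :], t_f * mask, max_shift)
    return LatencyEstimate(trial=0, shift_samples=int(shift[0]), match_score=float(score[0]))


def _center_clip(latencies: np.ndarray, max_shift: int) -> np.ndarray:
    centered = latencies - int(round(np.median(latencies)))
    return np.clip(centered, -max_shift, max_shift)


def _resynchronize(data: np.ndarray, C: np.ndarray, latencies: np.ndarray) -> np.ndarray:
    """trial - C(at its latency) + C(at the median latency, i.e. shift 0)."""
    out = np.empty_like(data)
    shifted = {k: _shift(C, k) for k in np.unique(latencies)}
    for i, k in enumerate(latencies):
        out[i] = data[i] - shifted[k] + C
    return out


# --------------------------------------------------------------------- #
# decomposition internals


class _Workspace:
    """Per-decomposition caches for the alternating updates."""

    def __init__(self, data: np.ndarray, s_cols: np.ndarray, c_cols: np.ndarray, max_shift: int):
        self.data = data
        self.n, self.n_ch, self.n_samp = data.shape
        self.s_cols, self.c_cols = s_cols, c_cols
        self.max_shift = max_shift
        self.conv = data.mean(axis=0)
        self.data32 = data.astype(np.float32)
        # trial-major-last buffers make the per-column medians contiguous
        self.data_s = np.ascontiguousarray(np.moveaxis(self.data32[:, :, s_cols], 0, -1))
        self.buf_s = np.empty_like(self.data_s)
        self.buf_c = np.empty((self.n_ch, c_cols.size, self.n), dtype=np.float32)
        self.data_c_al: np.ndarray | None = None
        self._latencies: np.ndarray | None = None

    def set_latencies(self, latencies: np.ndarray) -> None:
        if self._latencies is not None and np.array_equal(latencies, self._latencies):
            return
        self._latencies = latencies.copy()
        if self.data_c_al is None:
            self.data_c_al = np.empty_like(self.buf_c)
        for i, k in enumerate(latencies):
            self.data_c_al[:, :, i] = self.data32[i][:, self.c_cols + k]

    def aligned_mean(self) -> np.ndarray:
        out = np.zeros((self.n_ch, self.n_samp))
        for i, k in enumerate(self._latencies):
            out += _shift(self.data[i], -k)
        return out / self.n

    def latency_kernel(self) -> np.ndarray:
        h = np.zeros(2 * self.max_shift + 1)
        np.add.at(h, self._latencies + self.max_shift, 1.0)
        return h / self.n


def _median_lastaxis(buf: np.ndarray) -> np.ndarray:
    """In-place partition median along the last axis (buf is scratch)."""
    n = buf.shape[-1]
    k = (n - 1) // 2
    if n % 2:
        buf.partition(k, axis=-1)
        return buf[..., k].astype(np.float64)
    buf.partition((k, k + 1), axis=-1)
    return 0.5 * (buf[..., k].astype(np.float64) + buf[..., k + 1].astype(np.float64))


def _median_pass(ws: _Workspace, latencies, S, C, config: RideConfig):
    """Alternating windowed-median updates of S and C (capped)."""
    ws.set_latencies(latencies)
    uniq = np.unique(latencies)
    n_ch, n_samp = ws.n_ch, ws.n_samp
    for _ in range(config.max_inner_iter):
        shifted_c = {k: _shift(C, k)[:, ws.s_cols].astype(np.float32) for k in uniq}
        for i, k in enumerate(latencies):
            np.subtract(ws.data_s[:, :, i], shifted_c[k], out=ws.buf_s[:, :, i])
        s_win = _median_lastaxis(ws.buf_s)
        S_new = np.zeros((n_ch, n_samp))
        S_new[:, ws.s_cols] = s_win

        s_gather = {k: S_new[:, ws.c_cols + k].astype(np.float32) for k in uniq}
        for i, k in enumerate(latencies):
            np.subtract(ws.data_c_al[:, :, i], s_gather[k], out=ws.buf_c[:, :, i])
        c_win = _median_lastaxis(ws.buf_c)
        C_new = np.zeros((n_ch, n_samp))
        C_new[:, ws.c_cols] = c_win

        change = max(
            float(np.sqrt(np.mean((S_new - S) ** 2))),
            float(np.sqrt(np.mean((C_new - C) ** 2))),
        )
        S, C = S_new, C_new
        if change < config.inner_tol_uv:
            break
    return S, C


def _mean_solve(ws: _Workspace, latencies, S0, C0, max_iter=80, tol=1e-6):
    """Mean-statistic fixed point with latencies frozen, from a warm start.

    The mean of latency-shifted copies of a waveform is its convolution
    with the empirical latency histogram h, so the alternating updates

        S <- [conv - h * C]   on the S window,
        C <- [A - h~ * S]     on the C window  (A = aligned-trial mean)

    cost one convolution per component per pass. The iteration contracts in
    every direction the jitter can separate; directions in which the
    overlapping windows are (nearly) indistinguishable barely move and so
    retain the warm-start split — the S + C sum is determined by the data
    even where the split is not. (A direct solve of the stationary system
    would invert those near-singular directions and amplify noise.)
    """
    ws.set_latencies(latencies)
    h = ws.latency_kernel()
    aligned = ws.aligned_mean()
    r = ws.max_shift
    # Toeplitz slice of h linking the two windows: smearing C onto the S
    # window is s_win = C_win @ k1.T, smearing S onto the C window uses k1
    diff = ws.s_cols[:, None] - ws.c_cols[None, :]
    k1 = np.where(np.abs(diff) <= r, h[np.clip(diff + r, 0, 2 * r)], 0.0)  # (n_s, n_c)
    conv_s = ws.conv[:, ws.s_cols]
    a_c = aligned[:, ws.c_cols]
    s_win, c_win = S0[:, ws.s_cols], C0[:, ws.c_cols]
    norm = 1.0 / np.sqrt(ws.n_samp)
    for _ in range(max_iter):
        s_new = conv_s - c_win @ k1.T
        c_new = a_c - s_new @ k1
        change = max(
            float(np.sqrt(np.sum((s_new - s_win) ** 2))),
            float(np.sqrt(np.sum((c_new - c_win) ** 2))),
        ) * norm
        s_win, c_win = s_new, c_new
        if change < tol:
            break
    S = np.zeros((ws.n_ch, ws.n_samp))
    C = np.zeros((ws.n_ch, ws.n_samp))
    S[:, ws.s_cols] = s_win
    C[:, ws.c_cols] = c_win
    return S, C


def decompose(epochs: EpochSet, config: RideConfig | None = None) -> RideDecomposition:
    """Iterative S/C decomposition with single-trial C latency estimation.

    A single latency per trial is estimated from the average over the
    matching channels and applied to all channels (one C process per
    trial). Raises below 10 trials; warns below 30.
    """
    config = config or RideConfig()
    n = epochs.n_trials
    if n < 10:
        raise ValueError(f"decompose needs at least 10 trials, got {n}")
    if n < 30:
        warnings.warn(f"decomposing only {n} trials (< 30 recommended)", stacklevel=2)

    data = epochs.data
    n_samp = epochs.n_samples
    s_mask = _window_mask(n_samp, epochs.sfreq, epochs.tmin_ms, config.s_window_ms)
    c_mask = _window_mask(n_samp, epochs.sfreq, epochs.tmin_ms, config.c_window_ms)
    for name, mask in (("s_window", s_mask), ("c_window", c_mask)):
        if not mask.any():
            raise ValueError(f"{name} lies outside the epoch")
    max_shift = int(round(config.search_range_ms * epochs.sfreq / 1000.0))
    c_cols = np.flatnonzero(c_mask)
    if c_cols[0] - max_shift < 0 or c_cols[-1] + max_shift >= n_samp:
        raise ValueError("search range pushes the C window outside the epoch")
    ws = _Workspace(data, np.flatnonzero(s_mask), c_cols, max_shift)

    if config.matching_channels is not None:
        ch_idx = epochs.channel_indices(config.matching_channels)
    else:
        ch_idx = np.arange(epochs.n_channels)
    x_match_f = _lowpass(
        data[:, ch_idx, :].mean(axis=1), epochs.sfreq, config.template_lowpass_hz
    )

    def match(template_1d: np.ndarray, s_match_1d: np.ndarray):
        t = template_1d * c_mask
        if not np.any(t):
            raise ValueError("degenerate (all-zero) template")
        t_f = _lowpass(t, epochs.sfreq, config.template_lowpass_hz) * c_mask
        resid = x_match_f - _lowpass(s_match_1d, epochs.sfreq, config.template_lowpass_hz)
        return _xcorr_latencies(resid, t_f, max_shift)

    # initial template: conventional average within the C window
    latencies, scores = match(ws.conv[ch_idx].mean(axis=0), np.zeros(n_samp))
    latencies = _center_clip(latencies, max_shift)

    # initialize the median iteration at the mean-statistic fixed point
    zeros = np.zeros((epochs.n_channels, n_samp))
    S, C = _mean_solve(ws, latencies, zeros, zeros)
    converged = False
    n_outer = 0
    best_delta = None
    stalled = 0
    for n_outer in range(1, config.max_outer_iter + 1):
        S, C = _median_pass(ws, latencies, S, C, config)
        new_lat, scores = match(C[ch_idx].mean(axis=0), S[ch_idx].mean(axis=0))
        new_lat = _center_clip(new_lat, max_shift)
        delta = int(np.max(np.abs(new_lat - latencies)))
        latencies = new_lat
        if delta <= config.latency_tol_samples:
            converged = True
            break
        # futility stop: latency estimates bouncing without improvement
        # (pure-noise epochs never settle below the tolerance)
        if best_delta is not None and delta >= best_delta:
            stalled += 1
            if stalled >= 2:
                break
        else:
            best_delta = delta
            stalled = 0
    if not converged:
        warnings.warn(
            f"C latencies did not converge within {n_outer} outer iterations",
            stacklevel=2,
        )
    # final pass: frozen latencies, components restored to average waveforms
    S, C = _mean_solve(ws, latencies, S, C)

    rerp = _resynchronize(data, C, latencies).mean(axis=0)
    return RideDecomposition(
        S=S,
        C=C,
        c_latency_samples=latencies,
        match_scores=scores,
        rerp=rerp,
        conventional=ws.conv,
        n_outer_iters=n_outer,
        converged=converged,
        config=config,
        sfreq=epochs.sfreq,
        tmin_ms=epochs.tmin_ms,
        channel_names=list(epochs.channel_names),
        epochs=epochs,
    )


def reconstruct(decomp: RideDecomposition) -> np.ndarray:
    """Latency-compensated average: mean of the re-synchronized trials.

    Equals ``S + C`` (at the median latency) in the noiseless exact case and
    the conventional average when there is no jitter to correct.
    """
    return _resynchronize(
        decomp.epochs.data, decomp.C, decomp.c_latency_samples
    ).mean(axis=0)
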