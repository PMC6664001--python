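"""Group-level inference: repeated-measures ANOVA with Greenhouse-Geisser
correction, fine-binned retrieval-success effects, and weighted
least-squares regression of effect size on response error.

The fully-within-subject ANOVA uses the univariate (orthonormal-contrast)
approach: for each effect, the cell means are projected onto the Kronecker
product of orthonormal contrast matrices for the involved factors (and
normalized averaging vectors for the others); the F ratio, Box's epsilon
and partial eta squared are computed from the resulting contrast scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats as sps

from .containers import EpochSet
from .pipeline import ANALYSIS_WINDOW_MS, ROISpec, window_mean

__all__ = [
    "gg_epsilon",
    "rm_anova",
    "FineBinTable",
    "fine_bin_effects",
    "trial_window_amplitudes",
    "WlsResult",
    "wls_regression",
]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) matrix of orthonormal contrasts (columns sum to zero)."""
    return linalg.helmert(k, full=False).T


def _epsilon_from_scores(z: np.ndarray) -> float:
    """Box's epsilon from (n, q) orthonormal-contrast scores."""
    q = z.shape[1]
    if q == 1:
        return 1.0
    cov = np.cov(z, rowvar=False, ddof=1)
    trace = float(np.trace(cov))
    denom = q * float(np.sum(cov**2))
    if denom <= 0 or not np.isfinite(denom):
        warnings.warn("singular contrast covariance; epsilon set to 1", stacklevel=3)
        return 1.0
    eps = trace**2 / denom
    lo, hi = 1.0 / q, 1.0
    if eps < lo - 1e-12 or eps > hi + 1e-12:
        warnings.warn(f"epsilon {eps:.4f} clipped into [{lo:.4f}, 1]", stacklevel=3)
    return float(np.clip(eps, lo, hi))


def gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for an (n_participants, k_levels) array.

    Computed from the sample covariance of the orthonormal within-subject
    contrasts (Box's formula); equals 1 under sphericity and exactly 1 for
    k = 2.
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 participants and >= 2 levels")
    return _epsilon_from_scores(scores @ _orthonormal_contrasts(k))


def rm_anova(
    table: pd.DataFrame,
    dv: str = "mean_uv",
    within: tuple[str, ...] = ("category", "hemisphere", "site"),
    subject: str = "participant",
) -> pd.DataFrame:
    """Fully within-subject ANOVA with GG correction, one row per effect.

    ``table`` is long-format with one value per subject x cell of the
    crossed within-subject design (cells averaged if replicated). Returns
    F, uncorrected and corrected df, epsilon, uncorrected and GG-corrected
    p, and partial eta squared for every main effect and interaction.
    """
    from itertools import product

    within = tuple(within)
    levels = {f: sorted(pd.unique(table[f])) for f in within}
    cells = list(product(*[levels[f] for f in within]))
    keyed = table.assign(_cell=list(zip(*[table[f] for f in within])))
    wide = keyed.pivot_table(index=subject, columns="_cell", values=dv, aggfunc="mean")
    wide = wide.reindex(columns=cells)
    if wide.isna().any().any():
        na = wide.isna()
        subj = na.any(axis=1).idxmax()
        cell = na.loc[subj].idxmax()
        raise ValueError(f"missing design cell: subject {subj}, cell {cell}")
    y = wide.to_numpy()  # (n, prod k_f)
    n = y.shape[0]

    rows = []
    for r in range(1, len(within) + 1):
        for subset in combinations(within, r):
            mats = []
            for f in within:
                k = len(levels[f])
                if f in subset:
                    mats.append(_orthonormal_contrasts(k))
                else:
                    mats.append(np.full((k, 1), 1.0 / np.sqrt(k)))
            m = mats[0]
            for other in mats[1:]:
                m = np.kron(m, other)
            z = y @ m  # (n, q)
            q = z.shape[1]
            zbar = z.mean(axis=0)
            ss_eff = n * float(np.sum(zbar**2))
            ss_err = float(np.sum((z - zbar) ** 2))
            df1, df2 = q, q * (n - 1)
            # guard against pure round-off when a cell layout is degenerate
            tiny = 1e-20 * (float(np.sum((y - y.mean()) ** 2)) + 1.0)
            if ss_err <= tiny:
                f_stat = 0.0 if ss_eff <= tiny else np.inf
            else:
                f_stat = (ss_eff / df1) / (ss_err / df2)
            eps = _epsilon_from_scores(z) if ss_err > tiny else 1.0
            p_unc = float(sps.f.sf(f_stat, df1, df2))
            p_gg = float(sps.f.sf(f_stat, eps * df1, eps * df2))
            rows.append(
                {
                    "effect": " x ".join(subset),
                    "F": f_stat,
                    "df1": df1,
                    "df2": df2,
                    "eps": eps,
                    "df1_gg": eps * df1,
                    "df2_gg": eps * df2,
                    "p_unc": p_unc,
                    "p_gg": p_gg,
                    "eta_p2": ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# fine-binned effects and regression


@dataclass
class FineBinTable:
    """Fine (10 deg) response bins of the retrieval-success effect.

    ``per_participant``: one row per participant x hemisphere x bin with the
    baseline-subtracted window amplitude. ``summary``: group mean, across-
    participant variance and n per hemisphere x bin. ``omissions`` logs
    participants lacking trials in a bin.
    """

    per_participant: pd.DataFrame
    summary: pd.DataFrame
    omissions: pd.DataFrame


def trial_window_amplitudes(
    epochs: EpochSet, roi: ROISpec | None = None, window_ms=ANALYSIS_WINDOW_MS
) -> pd.DataFrame:
    """Per-trial ROI window amplitude, one row per trial x hemisphere."""
    roi = roi or ROISpec()
    meta = epochs.trial_meta
    frames = []
    for hemi in ("Left", "Right"):
        idx = epochs.channel_indices(roi.channels(hemi))
        amp = window_mean(
            epochs.data[:, idx, :].mean(axis=1), epochs.sfreq, epochs.tmin_ms, window_ms
        )
        df = meta[[c for c in ("participant", "trial", "error_deg") if c in meta.columns]].copy()
        df["hemisphere"] = hemi
        df["mean_uv"] = amp
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def fine_bin_effects(
    trials,
    roi: ROISpec | None = None,
    window_ms=ANALYSIS_WINDOW_MS,
    bin_width_deg: float = 10.0,
    max_deg: float = 90.0,
    baseline_above_deg: float = 90.0,
) -> FineBinTable:
    """Baseline-subtracted window amplitude in 10-deg error bins.

    ``trials`` is an :class:`EpochSet` (per-trial amplitudes are extracted
    from the ROI) or an already-long DataFrame with columns ``participant,
    hemisphere, error_deg, mean_uv``. Per participant and hemisphere, each
    bin's mean amplitude has that participant's Baseline amplitude
    (|error| > 90 deg) subtracted; bins a participant lacks are omitted for
    that participant and logged.
    """
    if isinstance(trials, EpochSet):
        trials = trial_window_amplitudes(trials, roi, window_ms)
    n_bins = int(round(max_deg / bin_width_deg))
    edges = bin_width_deg * np.arange(n_bins + 1)
    centers = edges[:-1] + (bin_width_deg + 1.0) / 2.0  # midpoint of e.g. 1..10 deg

    pp_rows, omit_rows = [], []
    for (pid, hemi), grp in trials.groupby(["participant", "hemisphere"], sort=True):
        err = np.abs(grp["error_deg"].to_numpy())
        amp = grp["mean_uv"].to_numpy()
        base_mask = err > baseline_above_deg
        if not base_mask.any():
            raise ValueError(f"participant {pid}: no Baseline (> {baseline_above_deg} deg) trials")
        baseline = float(amp[base_mask].mean())
        for b in range(n_bins):
            mask = (err > edges[b]) & (err <= edges[b + 1])
            if b == 0:
                mask |= err == 0.0
            if not mask.any():
                omit_rows.append(
                    {
                        "participant": pid,
                        "hemisphere": hemi,
                        "bin": b + 1,
                        "reason": f"no trials in ({edges[b]:g}, {edges[b+1]:g}] deg",
                    }
                )
                continue
            pp_rows.append(
                {
                    "participant": pid,
                    "hemisphere": hemi,
                    "bin": b + 1,
                    "center_deg": centers[b],
                    "n_trials": int(mask.sum()),
                    "effect_uv": float(amp[mask].mean()) - baseline,
                }
            )
    per_participant = pd.DataFrame(pp_rows)
    summary = (
        per_participant.groupby(["hemisphere", "bin", "center_deg"], sort=True)["effect_uv"]
        .agg(mean_uv="mean", var_uv=lambda s: s.var(ddof=1), n_participants="count")
        .reset_index()
    )
    return FineBinTable(
        per_participant=per_participant,
        summary=summary,
        omissions=pd.DataFrame(omit_rows, columns=["participant", "hemisphere", "bin", "reason"]),
    )


@dataclass(frozen=True)
class WlsResult:
    """Weighted least-squares fit of bin effect on bin-centre error."""

    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    n_bins: int


def wls_regression(summary: pd.DataFrame) -> WlsResult:
    """Inverse-variance weighted regression of group bin effects on error.

    ``summary`` needs columns ``center_deg, mean_uv, var_uv`` (one
    hemisphere at a time). Weights are 1/variance, so better-estimated bins
    count more. The weighted correlation r carries the sign of the
    relationship; R^2 = r^2.
    """
    if len(summary) < 3:
        raise ValueError("need at least 3 bins for regression")
    x = summary["center_deg"].to_numpy(dtype=float)
    y = summary["mean_uv"].to_numpy(dtype=float)
    var = summary["var_uv"].to_numpy(dtype=float)
    if np.any(~np.isfinite(var)) or np.any(var <= 0):
        raise ValueError("degenerate bin variance (weights must be finite and positive)")
    w = 1.0 / var
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    wn = w / w.sum()
    xbar, ybar = wn @ x, wn @ y
    cov = wn @ ((x - xbar) * (y - ybar))
    vx, vy = wn @ (x - xbar) ** 2, wn @ (y - ybar) ** 2
    r = float(cov / np.sqrt(vx * vy))
    return WlsResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r=r,
        r2=r * r,
        p=float(res.pvalues[1]),
        n_bins=len(summary),
    )
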