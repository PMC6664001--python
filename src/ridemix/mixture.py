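"""Threshold (some-or-none) mixture model of continuous source-memory errors.

The model assumes that on a proportion ``lam`` of trials recollection
succeeds and the angular response error follows a wrapped Cauchy
distribution centred on the target, while on the remaining ``1 - lam``
trials the participant guesses and the error is uniform on the circle.
Fitting the two-parameter model per participant and comparing it, by
likelihood-ratio test, with the one-parameter restriction ``lam = 1``
("continuous" recollection: every response carries some signal) asks
whether recollection is thresholded.

Parameterization
----------------
``s_deg`` is the scale of the *unwrapped* Cauchy in degrees; wrapping a
Cauchy(0, gamma) onto the circle yields exactly the wrapped Cauchy with
concentration ``rho = exp(-gamma_rad)`` where ``gamma_rad = s_deg * pi/180``.
Larger ``s_deg`` means broader errors (lower precision). This mapping is a
package convention: published fits of this model state only that larger
``s`` means larger mean error, not the exact scale definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import validate_error_table

__all__ = [
    "S_MIN_DEG",
    "S_MAX_DEG",
    "MixtureFit",
    "LRTResult",
    "wc_density",
    "mixture_density",
    "mixture_loglik",
    "fit_mixture",
    "fit_restricted",
    "likelihood_ratio_test",
    "group_lrt",
    "fit_participants",
]

S_MIN_DEG = 0.1
S_MAX_DEG = 120.0

#: multi-start grid for the full model (likelihood can be multimodal near
#: the boundaries)
_LAM_STARTS = np.arange(0.1, 1.0, 0.1)
_S_STARTS = np.array([5.0, 15.0, 45.0])
_S_STARTS_RESTRICTED = np.array([2.0, 5.0, 15.0, 45.0, 90.0])


@dataclass(frozen=True)
class MixtureFit:
    """Maximum-likelihood fit of the threshold mixture model."""

    lam: float
    s_deg: float
    loglik: float
    n: int
    converged: bool
    n_starts: int
    restricted: bool = False


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of the full model vs the lam=1 restriction.

    ``p`` is the plain chi-square(df) p-value; ``p_boundary`` uses the
    50:50 mixture of chi-square(0) and chi-square(1) appropriate when the
    restriction pins ``lam`` to the boundary of its parameter space.
    """

    chi2: float
    df: int
    p: float
    p_boundary: float
    boundary_adjusted: bool = False

    @property
    def p_value(self) -> float:
        return self.p_boundary if self.boundary_adjusted else self.p


# --------------------------------------------------------------------- #
# densities


def wc_density(theta_deg, s_deg):
    """Wrapped-Cauchy density *per degree* at angle(s) ``theta_deg``.

    With ``gamma = s_deg * pi/180`` and ``rho = exp(-gamma)`` the density in
    radians is ``(1 - rho^2) / (2 pi (1 + rho^2 - 2 rho cos(theta)))``;
    the returned value is that density times ``pi/180``.
    """
    s_deg = float(s_deg)
    if s_deg <= 0:
        raise ValueError("s_deg must be > 0")
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    rho = np.exp(-np.deg2rad(s_deg))
    f_rad = (1.0 - rho**2) / (2.0 * np.pi * (1.0 + rho**2 - 2.0 * rho * np.cos(theta)))
    f_deg = f_rad * np.pi / 180.0
    return f_deg if f_deg.ndim else float(f_deg)


def mixture_density(theta_deg, lam, s_deg):
    """Density per degree of the wrapped-Cauchy + uniform mixture."""
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    return lam * wc_density(theta_deg, s_deg) + (1.0 - lam) / 360.0


def _as_error_array(errors) -> np.ndarray:
    if isinstance(errors, pd.DataFrame):
        errors = validate_error_table(errors)["error_deg"].to_numpy()
    err = np.asarray(errors, dtype=float).ravel()
    if err.size == 0:
        raise ValueError("empty error table")
    return err


def mixture_loglik(errors, lam, s_deg) -> float:
    """Natural-log likelihood of the mixture for the given errors."""
    err = _as_error_array(errors)
    return float(np.sum(np.log(mixture_density(err, lam, s_deg))))


# --------------------------------------------------------------------- #
# fitting


def _negloglik_terms(err: np.ndarray):
    """Precompute the per-trial cos(theta) for fast repeated evaluation."""
    return np.cos(np.deg2rad(err))


def _negloglik(params, cos_t, n, full):
    if full:
        lam, s = params
    else:
        lam, s = 1.0, params[0]
    rho = np.exp(-np.deg2rad(s))
    f = (1.0 - rho**2) / (2.0 * np.pi * (1.0 + rho**2 - 2.0 * rho * cos_t)) * np.pi / 180.0
    dens = lam * f + (1.0 - lam) / 360.0
    return -np.sum(np.log(dens))


def _fit(err: np.ndarray, full: bool) -> MixtureFit:
    cos_t = _negloglik_terms(err)
    n = err.size
    if n < 20:
        warnings.warn(f"fitting mixture on only {n} trials (< 20)", stacklevel=3)
    if np.ptp(err) == 0.0:
        warnings.warn("all errors identical: boundary (degenerate) fit", stacklevel=3)

    if full:
        starts = [(l, s) for l in _LAM_STARTS for s in _S_STARTS]
        bounds = [(0.0, 1.0), (S_MIN_DEG, S_MAX_DEG)]
    else:
        starts = [(s,) for s in _S_STARTS_RESTRICTED]
        bounds = [(S_MIN_DEG, S_MAX_DEG)]

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            _negloglik,
            x0=np.asarray(x0, dtype=float),
            args=(cos_t, n, full),
            method="L-BFGS-B",
            bounds=bounds,
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    lam, s = (best.x[0], best.x[1]) if full else (1.0, best.x[0])
    return MixtureFit(
        lam=float(lam),
        s_deg=float(s),
        loglik=-float(best.fun),
        n=n,
        converged=any_success,
        n_starts=len(starts),
        restricted=not full,
    )


def fit_mixture(errors) -> MixtureFit:
    """Fit (lam, s_deg) by bounded maximum likelihood with multi-start."""
    return _fit(_as_error_array(errors), full=True)


def fit_restricted(errors) -> MixtureFit:
    """Fit the continuous restriction (lam pinned to 1; s_deg free)."""
    return _fit(_as_error_array(errors), full=False)


# --------------------------------------------------------------------- #
# inference


def likelihood_ratio_test(
    full: MixtureFit, restricted: MixtureFit, boundary_adjusted: bool = False
) -> LRTResult:
    """Deviance test of the full mixture against the lam=1 restriction."""
    if full.n != restricted.n:
        raise ValueError("full and restricted fits use different trial counts")
    chi2 = 2.0 * (full.loglik - restricted.loglik)
    if chi2 < -1e-6:
        raise ValueError(f"negative deviance {chi2}: fits are inconsistent")
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=1))
    p_boundary = 1.0 if chi2 == 0.0 else 0.5 * p
    return LRTResult(
        chi2=chi2, df=1, p=p, p_boundary=p_boundary, boundary_adjusted=boundary_adjusted
    )


def group_lrt(fits, boundary_adjusted: bool = False) -> LRTResult:
    """Group-level test: per-participant deviances summed, df = #participants."""
    fits = list(fits)
    if not fits:
        raise ValueError("group_lrt requires at least one participant")
    chi2 = 0.0
    for full, restricted in fits:
        chi2 += likelihood_ratio_test(full, restricted).chi2
    df = len(fits)
    p = float(stats.chi2.sf(chi2, df=df))
    # boundary-adjusted group null: sum of df independent (1/2 chi2_0 + 1/2
    # chi2_1) variables, a binomial mixture of chi-square distributions
    k = np.arange(df + 1)
    weights = stats.binom.pmf(k, df, 0.5)
    tail = np.where(k == 0, float(chi2 == 0.0), stats.chi2.sf(chi2, df=np.maximum(k, 1)))
    p_boundary = float(np.sum(weights * tail))
    return LRTResult(
        chi2=float(chi2), df=df, p=p, p_boundary=p_boundary, boundary_adjusted=boundary_adjusted
    )


def fit_participants(errors: pd.DataFrame) -> pd.DataFrame:
    """Per-participant full + restricted fits and LRTs.

    Returns a table with one row per participant: ``lam, s_deg,
    loglik_full, loglik_restricted, chi2, p, p_boundary``.
    """
    errors = validate_error_table(errors)
    rows = []
    for pid, grp in errors.groupby("participant", sort=True):
        err = grp["error_deg"].to_numpy()
        full = fit_mixture(err)
        restr = fit_restricted(err)
        lrt = likelihood_ratio_test(full, restr)
        rows.append(
            {
                "participant": pid,
                "n_trials": full.n,
                "lam": full.lam,
                "s_deg": full.s_deg,
                "loglik_full": full.loglik,
                "loglik_restricted": restr.loglik,
                "chi2": lrt.chi2,
                "p": lrt.p,
                "p_boundary": lrt.p_boundary,
            }
        )
    return pd.DataFrame(rows)
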