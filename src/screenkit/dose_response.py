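"""Four-parameter logistic dose-response fitting and potency metrics.

The model is the Hill form

    y(x) = L - h / (1 + (alpha / x)**beta)

with L the top plateau (response at vanishing dose), h the span (top minus
bottom plateau), alpha the relative IC50 in concentration units, and beta the
Hill slope.  By construction y(alpha) = L - h/2: alpha IS the concentration
at the halfway point between the two plateaus, i.e. the relative IC50 (as
opposed to an absolute IC50 referenced to 0%/100% anchors).

Fitting is nonlinear least squares with fixed starting values: L0 = maximum
response at the smallest concentration, h0 = mean response at the smallest
concentration minus the minimum response at the largest concentration,
alpha0 = 4 (concentration units), beta0 = 2.  When the optimizer fails or no
plateau is observed (|beta| < 0.2, or alpha outside [0.1 * min dose,
10 * max dose]), the curve is instead smoothed by local regression (lowess on
log-concentration) and the relative IC50 is read off as the interpolated
crossing of the midpoint between the smoothed extremes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = [
    "FourPLFit",
    "four_pl",
    "fit_4pl",
    "fit_smoothed",
    "relative_ic50",
    "pct_max_inhibition",
    "ic50_ci",
    "viability_gate",
    "fit_dose_table",
]

# Fallback triggers: essentially flat slope, or a midpoint far outside the
# tested dose range, mean the plateaus are not observed.
MIN_ABS_SLOPE = 0.2
ALPHA_RANGE_FACTOR = 10.0
LOWESS_FRAC = 0.45


@dataclass
class FourPLFit:
    """Result of a dose-response fit.

    ``method`` is ``"nls"`` for a converged parametric fit and ``"smoothed"``
    for the local-regression fallback, in which case L, h and beta are None
    and ``alpha`` (if defined) is the interpolated midpoint crossing.
    """

    L: float | None
    h: float | None
    alpha: float | None
    beta: float | None
    converged: bool
    method: str
    rss: float | None = None
    n_points: int = 0
    message: str = field(default="")


def four_pl(x, L, h, alpha, beta):
    """Evaluate y(x) = L - h / (1 + (alpha/x)**beta) for positive x, alpha."""
    x = np.asarray(x, float)
    with np.errstate(over="ignore"):  # (alpha/x)**beta -> inf means y -> L
        return L - h / (1.0 + (alpha / x) ** beta)


def _check_series(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("concentration and response arrays must align")
    if (x <= 0).any():
        raise ValueError("concentrations must be positive")
    if np.unique(x).size < 4:
        raise ValueError("need >=4 distinct doses to fit a 4PL model")
    return x, y


def _start_values(x, y):
    xmin, xmax = x.min(), x.max()
    at_min = y[x == xmin]
    at_max = y[x == xmax]
    L0 = float(at_min.max())
    h0 = float(at_min.mean() - at_max.min())
    if h0 == 0.0:
        h0 = 1e-6
    return L0, h0, 4.0, 2.0


def fit_4pl(x, y) -> FourPLFit:
    """Least-squares 4PL fit with fixed starting values and a smoothing fallback."""
    x, y = _check_series(x, y)
    if np.ptp(y) == 0.0:
        fit = fit_smoothed(x, y)
        fit.message = "all responses equal; no dose dependence"
        return fit
    p0 = _start_values(x, y)
    try:
        popt, _ = curve_fit(
            four_pl,
            x,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9, -np.inf], [np.inf, np.inf, 1e9, np.inf]),
            method="trf",
            max_nfev=10000,
        )
    except (RuntimeError, ValueError) as exc:  # singular gradient / failed step
        logger.info("4PL optimizer failed (%s); falling back to smoothing", exc)
        fit = fit_smoothed(x, y)
        fit.message = f"optimizer failure: {exc}"
        return fit
    L, h, alpha, beta = map(float, popt)
    if abs(beta) < MIN_ABS_SLOPE or not (
        x.min() / ALPHA_RANGE_FACTOR <= alpha <= x.max() * ALPHA_RANGE_FACTOR
    ):
        fit = fit_smoothed(x, y)
        fit.message = (
            f"plateau not observed (beta={beta:.3g}, alpha={alpha:.3g}); smoothed"
        )
        return fit
    rss = float(np.sum((y - four_pl(x, *popt)) ** 2))
    return FourPLFit(
        L=L, h=h, alpha=alpha, beta=beta,
        converged=True, method="nls", rss=rss, n_points=int(x.size),
    )


def fit_smoothed(x, y) -> FourPLFit:
    """Local-regression fallback: IC50 = midpoint crossing of the lowess smooth."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    logx = np.log(x)
    order = np.argsort(logx)
    sm = lowess(y[order], logx[order], frac=LOWESS_FRAC, return_sorted=True)
    xs, ys = sm[:, 0], sm[:, 1]
    flat_tol = 1e-8 * max(1.0, float(np.abs(ys).max()))
    if np.ptp(y) == 0.0 or np.ptp(ys) <= flat_tol:
        return FourPLFit(None, None, None, None, False, "smoothed",
                         n_points=int(x.size), message="flat smooth; IC50 undefined")
    mid = 0.5 * (ys.max() + ys.min())
    alpha = None
    # Scan from low to high concentration for the first midpoint crossing.
    for i in range(len(xs) - 1):
        y0, y1 = ys[i], ys[i + 1]
        if (y0 - mid) == 0.0:
            alpha = float(np.exp(xs[i]))
            break
        if (y0 - mid) * (y1 - mid) < 0:
            t = (mid - y0) / (y1 - y0)
            alpha = float(np.exp(xs[i] + t * (xs[i + 1] - xs[i])))
            break
    converged = alpha is not None
    msg = "" if converged else "midpoint not crossed within the tested range"
    return FourPLFit(None, None, alpha, None, converged, "smoothed",
                     n_points=int(x.size), message=msg)


def relative_ic50(fit: FourPLFit) -> float | None:
    """Relative IC50: alpha for a parametric fit, the midpoint crossing otherwise."""
    if fit.alpha is None:
        logger.info("relative IC50 undefined (%s)", fit.message or fit.method)
        return None
    return float(fit.alpha)


def pct_max_inhibition(x, y) -> float:
    """Percent maximum inhibition from the observed dose extremes.

    100 * (mean response at lowest dose - mean response at highest dose)
        / mean response at lowest dose.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    low = y[x == x.min()].mean()
    high = y[x == x.max()].mean()
    if low == 0:
        raise ValueError("mean response at the lowest dose is zero")
    return float(100.0 * (low - high) / low)


def ic50_ci(x, y, fit: FourPLFit, n_boot: int = 1000, seed: int = 0,
            level: float = 0.95) -> tuple[float, float] | None:
    """Percentile bootstrap CI for the relative IC50 by residual resampling.

    Returns None (with a flag logged) if the fit is not a converged
    parametric fit or if more than half of the bootstrap refits fail.
    """
    if fit.method != "nls" or not fit.converged:
        logger.info("IC50 CI skipped: no converged parametric fit")
        return None
    x, y = _check_series(x, y)
    params = (fit.L, fit.h, fit.alpha, fit.beta)
    yhat = four_pl(x, *params)
    resid = y - yhat
    rng = np.random.default_rng(seed)
    alphas = []
    for _ in range(n_boot):
        yb = yhat + rng.choice(resid, size=resid.size, replace=True)
        boot = fit_4pl(x, yb)
        if boot.method == "nls" and boot.converged:
            alphas.append(boot.alpha)
    if len(alphas) < n_boot / 2:
        logger.warning("IC50 CI unstable: %d/%d bootstrap refits converged",
                       len(alphas), n_boot)
        return None
    lo, hi = np.percentile(alphas, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def viability_gate(ic50: float | None, conc, viability,
                   threshold: float = 70.0) -> bool | None:
    """Flag a compound toxic if viability at its IC50 falls below ``threshold``.

    Viability is interpolated at the IC50 on the log-concentration axis, so a
    viability drop confined to doses above the IC50 does not trip the gate.
    Returns None (gate skipped, logged) when viability data or the IC50 is
    missing.
    """
    if viability is None:
        logger.info("viability gate skipped: no viability series")
        return None
    v = np.asarray(viability, float)
    if np.isnan(v).all():
        logger.info("viability gate skipped: no viability series")
        return None
    if ic50 is None:
        logger.info("viability gate skipped: IC50 undefined")
        return None
    c = np.asarray(conc, float)
    keep = ~np.isnan(v)
    c, v = c[keep], v[keep]
    order = np.argsort(c)
    v_at_ic50 = float(np.interp(np.log(ic50), np.log(c[order]), v[order]))
    return v_at_ic50 < threshold


def fit_dose_table(df: pd.DataFrame, n_boot: int = 0, seed: int = 0,
                   viability_threshold: float = 70.0) -> pd.DataFrame:
    """Fit every (compound, assay context) series of a long-format dose table.

    Returns one row per series with the fitted parameters, relative IC50,
    percent maximum inhibition, optional bootstrap CI (``n_boot > 0``), and
    the viability gate where a viability column is present.
    """
    rows = []
    for (cid, ctx), grp in df.groupby(["compound_id", "assay_context"], sort=True):
        x = grp["concentration_uM"].to_numpy(float)
        y = grp["response"].to_numpy(float)
        fit = fit_4pl(x, y)
        ic50 = relative_ic50(fit)
        ci = ic50_ci(x, y, fit, n_boot=n_boot, seed=seed) if n_boot else None
        viab = grp["viability"].to_numpy(float) if "viability" in grp else None
        toxic = viability_gate(ic50, x, viab, threshold=viability_threshold)
        rows.append(
            {
                "compound_id": cid,
                "assay_context": ctx,
                "L": fit.L,
                "h": fit.h,
                "alpha_uM": fit.alpha,
                "beta": fit.beta,
                "method": fit.method,
                "converged": fit.converged,
                "relative_ic50_uM": ic50,
                "pct_max_inhibition": pct_max_inhibition(x, y),
                "ci_low_uM": ci[0] if ci else None,
                "ci_high_uM": ci[1] if ci else None,
                "toxic": toxic,
            }
        )
    return pd.DataFrame(rows)
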