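"""Nonlinear estimation of the mixing-model parameters.

Given paired observations of carbon fraction and gravimetric bulk density,
the two self-packing densities (delta_p, delta_m) are estimated by
Gauss-Newton nonlinear least squares with step-halving.  The conversion
factor f is held fixed during the fit (it is estimated separately from a
loss-on-ignition calibration; co-estimating it with delta_p is confounded).

Fit quality is assessed with a pseudo-R^2 and a lack-of-fit test that
splits the residual sum of squares into pure error (within replicate
groups) and lack of fit (group means vs the fitted curve).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core_model import MixingParams, bulk_density_from_carbon

__all__ = [
    "FitResult",
    "LackOfFit",
    "fit_mixing_model",
    "lack_of_fit_test",
    "r_squared_nonlinear",
    "carbon_fraction_bins",
    "calibrate_conversion_factor",
]

logger = logging.getLogger(__name__)

_PARAM_FLOOR = 1e-6  # positivity floor for delta_p, delta_m during iteration


@dataclass(frozen=True)
class LackOfFit:
    """Lack-of-fit variance-ratio test: F = MS(lack of fit)/MS(pure error)."""

    F: float
    df1: int
    df2: int
    p: float
    ss_lack_of_fit: float
    ss_pure_error: float


@dataclass
class FitResult:
    """Result of a Gauss-Newton fit of the mixing model.

    ``params_hat`` holds the estimated (delta_p, delta_m) with f fixed at its
    input value; standard errors come from the linearised Jacobian at the
    optimum, ``sigma^2 (J'J)^-1`` with ``sigma^2 = SSres/(n-2)``.
    """

    params_hat: MixingParams
    se_delta_p: float
    se_delta_m: float
    n: int
    r2: float
    ss_res: float
    ss_tot: float
    residuals: np.ndarray
    fitted: np.ndarray
    n_iterations: int
    converged: bool
    lack_of_fit: LackOfFit | None = None

    def to_dict(self) -> dict:
        out = {
            "delta_p": self.params_hat.delta_p,
            "delta_m": self.params_hat.delta_m,
            "f": self.params_hat.f,
            "se_delta_p": self.se_delta_p,
            "se_delta_m": self.se_delta_m,
            "n": self.n,
            "r2": self.r2,
            "ss_res": self.ss_res,
            "ss_tot": self.ss_tot,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }
        if self.lack_of_fit is not None:
            lof = self.lack_of_fit
            out["lack_of_fit"] = {"F": lof.F, "df1": lof.df1, "df2": lof.df2, "p": lof.p}
        return out


def _jacobian(c: np.ndarray, dp: float, dm: float, f: float) -> np.ndarray:
    """Partials of the predicted bulk density w.r.t. (delta_p, delta_m).

    With A = delta_p (1 - fC) + delta_m fC the model is delta = dp dm / A and
      d delta/d dp = dm^2 f C / A^2,   d delta/d dm = dp^2 (1 - f C) / A^2.
    """
    fc = f * c
    A = dp * (1.0 - fc) + dm * fc
    return np.column_stack([dm**2 * fc / A**2, dp**2 * (1.0 - fc) / A**2])


def fit_mixing_model(
    carbon_fraction,
    bulk_density,
    f: float = 2.2,
    init: tuple[float, float] = (0.1, 1.6),
    tol_ss: float = 1e-10,
    tol_step: float = 1e-8,
    max_iter: int = 100,
    max_halvings: int = 20,
) -> FitResult:
    """Estimate (delta_p, delta_m) from (carbon fraction, bulk density) pairs.

    Parameters
    ----------
    carbon_fraction, bulk_density : array-like
        Paired observations; carbon as a proportion in [0, 1/f], bulk
        density in g cm^-3 (strictly positive).
    f : float
        Fixed carbon->organic-matter conversion factor.
    init : (float, float)
        Starting values for (delta_p, delta_m).
    tol_ss, tol_step : float
        Convergence when the relative change in the residual sum of squares
        falls below ``tol_ss`` or the parameter step norm below ``tol_step``.

    Returns
    -------
    FitResult
        Non-convergence after ``max_iter`` iterations is flagged on the
        result (``converged=False``), never silent.

    Raises
    ------
    ValueError
        Fewer than 3 pairs, all carbon fractions identical (parameters not
        identifiable), or non-positive bulk density.
    """
    c = np.asarray(carbon_fraction, dtype=float)
    y = np.asarray(bulk_density, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValueError("carbon_fraction and bulk_density must be equal-length 1-D arrays")
    n = c.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs to fit 2 parameters, got {n}")
    if np.unique(c).size < 2:
        raise ValueError("all carbon fractions identical: (delta_p, delta_m) not identifiable")
    if np.any(y <= 0):
        raise ValueError("bulk density must be strictly positive")

    dp, dm = float(init[0]), float(init[1])

    def predict(dp_, dm_):
        fc = f * c
        return dp_ * dm_ / (dp_ * (1.0 - fc) + dm_ * fc)

    resid = y - predict(dp, dm)
    ss = float(resid @ resid)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J = _jacobian(c, dp, dm, f)
        # Gauss-Newton step: solve (J'J) step = J'r
        try:
            step = np.linalg.solve(J.T @ J, J.T @ resid)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular Jacobian: parameters not identifiable") from exc

        # step-halving on residual-sum increase
        lam = 1.0
        for _ in range(max_halvings + 1):
            dp_new, dm_new = dp + lam * step[0], dm + lam * step[1]
            if dp_new < _PARAM_FLOOR or dm_new < _PARAM_FLOOR:
                logger.warning(
                    "parameter excursion below positivity floor clamped "
                    "(delta_p=%.3g, delta_m=%.3g)", dp_new, dm_new
                )
                dp_new = max(dp_new, _PARAM_FLOOR)
                dm_new = max(dm_new, _PARAM_FLOOR)
            resid_new = y - predict(dp_new, dm_new)
            ss_new = float(resid_new @ resid_new)
            if ss_new <= ss or lam < 2.0 ** (-max_halvings):
                break
            lam *= 0.5

        step_norm = float(np.hypot(dp_new - dp, dm_new - dm))
        rel_change = abs(ss - ss_new) / max(ss, np.finfo(float).tiny)
        dp, dm, resid, ss = dp_new, dm_new, resid_new, ss_new
        if rel_change < tol_ss or step_norm < tol_step:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Gauss-Newton did not converge in {max_iter} iterations "
            f"(last relative SS change {rel_change:.2e})",
            RuntimeWarning,
        )

    fitted = predict(dp, dm)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss / ss_tot if ss_tot > 0 else np.nan

    J = _jacobian(c, dp, dm, f)
    sigma2 = ss / (n - 2)
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
        se_dp, se_dm = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        se_dp = se_dm = np.nan

    return FitResult(
        params_hat=MixingParams(delta_p=dp, delta_m=dm, f=f),
        se_delta_p=se_dp,
        se_delta_m=se_dm,
        n=n,
        r2=r2,
        ss_res=ss,
        ss_tot=ss_tot,
        residuals=resid,
        fitted=fitted,
        n_iterations=it,
        converged=converged,
    )


def r_squared_nonlinear(bulk_density, fitted) -> float:
    """Pseudo-R^2 for a nonlinear fit: 1 - SSres / sum((y - mean y)^2)."""
    y = np.asarray(bulk_density, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total sum of squares: response is constant")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def carbon_fraction_bins(carbon_fraction, width: float = 0.005) -> np.ndarray:
    """Replicate-group labels from binning the carbon fraction.

    Used when no site/depth hierarchy exists: samples whose carbon fractions
    fall in the same bin of the given width are treated as replicates.
    """
    c = np.asarray(carbon_fraction, dtype=float)
    return np.floor(c / width).astype(int)


def lack_of_fit_test(bulk_density, groups, fit: FitResult) -> LackOfFit:
    """Lack-of-fit vs pure-error variance-ratio test for a fitted model.

    Pure error is the within-replicate-group variation of the observed bulk
    densities around their group means; lack of fit is the remainder of the
    fit's residual sum of squares.  With g groups, n observations and the 2
    fitted parameters:

        F = [SS(lack of fit)/(g - 2)] / [SS(pure error)/(n - g)]

    ``groups`` assigns each observation to its replicate group (site x depth
    stratum, or carbon-fraction bin from :func:`carbon_fraction_bins`).
    """
    y = np.asarray(bulk_density, dtype=float)
    groups = np.asarray(groups)
    if y.size != groups.size or y.size != fit.n:
        raise ValueError("bulk_density, groups and fit must refer to the same samples")

    labels, inverse, counts = np.unique(groups, return_inverse=True, return_counts=True)
    g = labels.size
    if not np.any(counts >= 2):
        raise ValueError(
            "no replicate group has 2 or more members: pure error is undefined"
        )
    df2 = int(y.size - g)
    df1 = int(g - 2)
    if df1 < 1:
        raise ValueError(f"need at least 3 replicate groups for lack of fit, got {g}")
    if df2 < 1:
        raise ValueError("pure-error degrees of freedom n - g must be >= 1")

    group_means = np.bincount(inverse, weights=y) / counts
    ss_pe = float(np.sum((y - group_means[inverse]) ** 2))
    ss_res = float(np.sum((y - fit.fitted) ** 2))
    ss_lof = max(ss_res - ss_pe, 0.0)
    F = (ss_lof / df1) / (ss_pe / df2)
    p = float(stats.f.sf(F, df1, df2))
    return LackOfFit(F=float(F), df1=df1, df2=df2, p=p, ss_lack_of_fit=ss_lof, ss_pure_error=ss_pe)


def calibrate_conversion_factor(carbon_fraction, loi_fraction):
    """Estimate the carbon->organic-matter factor f from paired elemental
    carbon and loss-on-ignition measurements.

    Ordinary least squares of LOI on carbon fraction, with intercept; the
    slope is the conversion factor and the intercept is reported as a
    diagnostic (it should be near zero if LOI is a clean organic-matter
    proxy).  Returns ``(f_hat, se, intercept)``.
    """
    c = np.asarray(carbon_fraction, dtype=float)
    loi = np.asarray(loi_fraction, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 calibration pairs")
    if np.any(c < 0) or np.any(loi < 0):
        raise ValueError("carbon and LOI fractions must be non-negative")
    if np.ptp(c) == 0:
        raise ValueError("zero variance in carbon fraction: slope not identifiable")
    res = sm.OLS(loi, sm.add_constant(c)).fit()
    return float(res.params[1]), float(res.bse[1]), float(res.params[0])
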