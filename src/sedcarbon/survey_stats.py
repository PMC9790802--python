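"""Corer-comparison and diagnostic statistics for core-sample surveys.

Works on tidy sample tables (one row per core segment) with at least the
columns ``instrument``, ``site``, ``depth_label`` and ``bulk_density``;
surveys generated by :mod:`sedcarbon.synthetic_data` or read by
:mod:`sedcarbon.io` have this shape.

Provides pairwise instrument matching, major-axis regression through the
origin with a jackknifed slope standard error, a sequential variance
decomposition of bulk density after the nonlinear mixing-model stage,
a within-site replicate-consistency comparison of two bulk-density
estimators, and the squared-residual heteroscedasticity diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairwiseComparison",
    "VarianceDecomposition",
    "pairwise_overlap",
    "major_axis_slope_origin",
    "identity_slope_test",
    "compare_instruments",
    "comparison_matrix",
    "variance_decomposition",
    "within_stratum_decomposition",
    "replicate_consistency_test",
    "heteroscedasticity_test",
]

_STRATUM_COLS = ["site", "depth_label"]


@dataclass(frozen=True)
class PairwiseComparison:
    """One instrument pair: correlation, major-axis slope through the origin
    with jackknife SE, and a test of the slope against the identity line."""

    instrument_a: str
    instrument_b: str
    n_pairs: int
    pearson_r: float
    p_value: float
    ma_slope_b: float
    jackknife_se: float
    identity_t: float
    identity_p: float


@dataclass(frozen=True)
class VarianceDecomposition:
    """Ordered variance-decomposition table.

    ``rows`` is a DataFrame with columns (source, df, SS, percent); percents
    are relative to the total sum of squares of the observed bulk density
    and sum to 100 by construction.
    """

    rows: pd.DataFrame
    ss_total: float


def pairwise_overlap(samples: pd.DataFrame) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Match samples between every pair of instruments on site x depth stratum.

    Two instruments are compared on the strata they both sampled; within a
    stratum each instrument contributes its (mean) bulk density once, so
    every matched observation enters a pair exactly once.  Returns
    ``{(instr_a, instr_b): (delta_a, delta_b)}`` with instruments in sorted
    order; pairs with no overlap map to empty arrays.
    """
    required = set(_STRATUM_COLS + ["instrument", "bulk_density"])
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples table lacks columns {sorted(missing)}")

    per_stratum = (
        samples.groupby(["instrument"] + _STRATUM_COLS, sort=True)["bulk_density"]
        .mean()
        .unstack("instrument")  # rows: strata, cols: instruments
    )
    out: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for a, b in combinations(sorted(samples["instrument"].unique()), 2):
        both = per_stratum[[a, b]].dropna()
        out[(a, b)] = (both[a].to_numpy(), both[b].to_numpy())
    return out


def _ma_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form major-axis slope through the origin (uncentred sums)."""
    sxx = float(x @ x)
    syy = float(y @ y)
    sxy = float(x @ y)
    if sxy == 0.0:
        raise ValueError("sum of cross-products is zero: major-axis orientation undefined")
    return ((syy - sxx) + np.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)


def major_axis_slope_origin(x, y) -> tuple[float, float]:
    """Major-axis slope of a line through the origin, with jackknife SE.

    The slope b minimises the summed squared perpendicular distances
    sum (y_i - b x_i)^2 / (1 + b^2) over lines through the origin; it is
    the appropriate symmetric regression when both variables carry
    measurement error.  Closed form with uncentred sums Sxx, Syy, Sxy:

        b = [(Syy - Sxx) + sqrt((Syy - Sxx)^2 + 4 Sxy^2)] / (2 Sxy)

    The standard error is the delete-one jackknife
    sqrt((n-1)/n * sum (b_(i) - mean b_(.))^2) over leave-one-out slopes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs for a jackknifed slope")
    if not np.any(x != 0):
        raise ValueError("all x are zero: slope undefined")
    b = _ma_slope(x, y)
    loo = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        loo[i] = _ma_slope(x[mask], y[mask])
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    return float(b), se


def identity_slope_test(b: float, se: float, n: int) -> tuple[float, float]:
    """Two-sided t test of H0: slope = 1, with df = n - 1.

    Returns ``(t, p)``.  Used to ask whether two corers measure the same
    bulk density up to noise.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    t = (b - 1.0) / se
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), p


def compare_instruments(samples: pd.DataFrame) -> list[PairwiseComparison]:
    """Full pairwise comparison of every instrument pair with >= 3 matched
    strata: Pearson correlation (with p), major-axis slope through the
    origin, jackknife SE, and the identity-slope test."""
    results = []
    for (a, b), (xa, xb) in pairwise_overlap(samples).items():
        if xa.size < 3:
            continue
        r, p_r = stats.pearsonr(xa, xb)
        slope, se = major_axis_slope_origin(xa, xb)
        t, p_t = identity_slope_test(slope, se, xa.size)
        results.append(
            PairwiseComparison(
                instrument_a=a,
                instrument_b=b,
                n_pairs=int(xa.size),
                pearson_r=float(r),
                p_value=float(p_r),
                ma_slope_b=slope,
                jackknife_se=se,
                identity_t=t,
                identity_p=p_t,
            )
        )
    return results


def comparison_matrix(comparisons: list[PairwiseComparison]) -> pd.DataFrame:
    """Square instrument-by-instrument matrix: upper triangle 'r (n)',
    lower triangle 'b +/- SE'; diagonal empty."""
    names = sorted({c.instrument_a for c in comparisons} | {c.instrument_b for c in comparisons})
    mat = pd.DataFrame("", index=names, columns=names, dtype=object)
    for c in comparisons:
        mat.loc[c.instrument_a, c.instrument_b] = f"r={c.pearson_r:.2f} (n={c.n_pairs})"
        mat.loc[c.instrument_b, c.instrument_a] = f"b={c.ma_slope_b:.2f}, SE={c.jackknife_se:.2f}"
    return mat


def variance_decomposition(
    bulk_density,
    fitted,
    factors: pd.DataFrame,
    factor_order: list[str] | None = None,
) -> VarianceDecomposition:
    """Sequential variance decomposition of observed bulk density.

    The first row credits the nonlinear mixing-model stage with
    SStot - SSres.  Each subsequent factor is then tested by ordinary
    linear regression (with intercept) of the *running* residuals on its
    category dummies, in the given order, taking as its sum of squares the
    drop in residual SS it achieves (sequential, order-dependent type-I SS).
    The final row is what remains.  Percents are relative to the total SS
    of the observed bulk density and sum to 100 exactly by the telescoping
    construction.
    """
    y = np.asarray(bulk_density, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if factor_order is None:
        factor_order = [c for c in ("instrument", "site", "location", "depth_label")
                        if c in factors.columns]
    missing = set(factor_order) - set(factors.columns)
    if missing:
        raise ValueError(f"factor table lacks columns {sorted(missing)}")

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total sum of squares")
    resid = y - yhat
    ss_res0 = float(resid @ resid)
    rows = [("mixing_model", 2, ss_tot - ss_res0)]

    current = resid
    for name in factor_order:
        X = pd.get_dummies(factors[name].astype(str), dtype=float).to_numpy()
        X = np.column_stack([np.ones(len(current)), X])
        coef, _, rank, _ = np.linalg.lstsq(X, current, rcond=None)
        new_resid = current - X @ coef
        ss_before = float(current @ current)
        ss_after = float(new_resid @ new_resid)
        explained = max(ss_before - ss_after, 0.0)
        rows.append((name, max(rank - 1, 0), explained))
        current = new_resid

    ss_final = float(current @ current)
    rows.append(("residual", len(y) - 2 - sum(r[1] for r in rows[1:]), ss_final))
    table = pd.DataFrame(rows, columns=["source", "df", "SS"])
    table["percent"] = 100.0 * table["SS"] / ss_tot
    return VarianceDecomposition(rows=table, ss_total=ss_tot)


def within_stratum_decomposition(values, strata) -> tuple[float, int, float]:
    """One-way decomposition of ``values`` by stratum label.

    Treats the instruments that sampled a stratum as replicates of that
    stratum's value.  Returns ``(within_percent, residual_df, residual_ms)``
    where within_percent is the within-stratum SS as a percent of the total
    SS; strata with a single member contribute no within-SS (and no df).
    """
    y = np.asarray(values, dtype=float)
    strata = np.asarray(strata)
    labels, inverse, counts = np.unique(strata, return_inverse=True, return_counts=True)
    if not np.any(counts >= 2):
        raise ValueError("no stratum has 2 or more replicates")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total sum of squares")
    means = np.bincount(inverse, weights=y) / counts
    ss_within = float(np.sum((y - means[inverse]) ** 2))
    df = int(np.sum(counts - 1))
    return 100.0 * ss_within / ss_tot, df, ss_within / df


def replicate_consistency_test(values_a, values_b, strata) -> dict:
    """Compare the replicate consistency of two bulk-density estimators.

    Both estimators are evaluated on the same samples and strata; each is
    decomposed one-way by stratum, and the residual (within-stratum) mean
    squares are compared with a variance-ratio test, F = MS_a / MS_b in the
    order given, with a two-sided p.  An F well above 1 means estimator a
    is the noisier of the two within replicated strata.

    Returns a dict with per-estimator ``within_percent`` and ``df`` plus
    ``F``, ``df1``, ``df2`` and ``p``.
    """
    pct_a, df_a, ms_a = within_stratum_decomposition(values_a, strata)
    pct_b, df_b, ms_b = within_stratum_decomposition(values_b, strata)
    F = ms_a / ms_b
    # two-sided: double the smaller tail
    p = 2.0 * min(stats.f.sf(F, df_a, df_b), stats.f.cdf(F, df_a, df_b))
    return {
        "within_percent_a": pct_a,
        "within_percent_b": pct_b,
        "F": float(F),
        "df1": df_a,
        "df2": df_b,
        "p": float(min(p, 1.0)),
    }


def heteroscedasticity_test(residuals, fitted) -> dict:
    """Squared-residuals-vs-fitted diagnostic for funnel-shaped dispersion.

    Correlates the squared residuals with the fitted values; under
    homoscedastic errors this correlation is zero.  Reports the Pearson r,
    the regression F = r^2 (n-2) / (1 - r^2) on (1, n-2) df and its
    upper-tail p.
    """
    resid = np.asarray(residuals, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    n = resid.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sq = resid**2
    if np.ptp(sq) == 0 or np.ptp(yhat) == 0:
        if np.ptp(yhat) == 0:
            raise ValueError("fitted values are constant: correlation undefined")
        # constant squared residuals: perfectly homoscedastic
        return {"r": 0.0, "F": 0.0, "df1": 1, "df2": n - 2, "p": 1.0}
    r = float(np.corrcoef(sq, yhat)[0, 1])
    F = r**2 * (n - 2) / (1.0 - r**2)
    p = float(stats.f.sf(F, 1, n - 2))
    return {"r": r, "F": float(F), "df1": 1, "df2": n - 2, "p": p}
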