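"""Phenotype transformations for multi-year trial data.

Covers growing-degree-day conversion of phenology dates, a conservative
data-entry-error removal rule, a principal-component composite of fruit
length and width, and subtraction of estimated fixed effects from
observations (the target used when scoring prediction accuracy).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "validate_phenotypes",
    "growing_degree_days",
    "gdd_lookup",
    "flag_outliers",
    "studentized_residuals",
    "remove_outliers",
    "fruit_dimension_score",
    "adjust_for_fixed_effects",
]

PHENO_COLUMNS = ("individual", "year", "trait", "value")


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format contract: one record per (individual, year,
    trait), finite values."""
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    if pheno.duplicated(subset=["individual", "year", "trait"]).any():
        raise ValueError("duplicate (individual, year, trait) records")
    if not np.isfinite(pheno["value"].to_numpy(dtype=float)).all():
        raise ValueError("phenotype values must be finite")
    return pheno


def growing_degree_days(
    weather: pd.DataFrame,
    base: float = 4.5,
    cap: float = 30.0,
) -> pd.DataFrame:
    """Daily and cumulative growing degree days.

    Per day: tmax above ``cap`` is reduced to ``cap``, negative
    temperatures (tmin or tmax) are set to zero, and the daily increment
    is ``max((tmax' + tmin')/2 - base, 0)``.  The input must be a
    contiguous daily series with columns date, tmin, tmax.
    """
    w = weather.copy()
    for col in ("date", "tmin", "tmax"):
        if col not in w.columns:
            raise ValueError(f"weather table lacks column {col!r}")
    w["date"] = pd.to_datetime(w["date"])
    w = w.sort_values("date").reset_index(drop=True)
    if w["date"].duplicated().any():
        raise ValueError("duplicate weather dates")
    if (w["tmax"] < w["tmin"]).any():
        raise ValueError("tmax below tmin")
    deltas = w["date"].diff().dropna()
    gaps = w["date"][1:][deltas != pd.Timedelta(days=1)]
    if len(gaps):
        raise ValueError(f"missing days before: {list(gaps.dt.date)[:10]}")
    tmax = np.minimum(w["tmax"].to_numpy(float), cap)
    tmax = np.maximum(tmax, 0.0)
    tmin = np.maximum(w["tmin"].to_numpy(float), 0.0)
    daily = np.maximum((tmax + tmin) / 2.0 - base, 0.0)
    out = pd.DataFrame({"date": w["date"], "gdd_daily": daily, "gdd_cum": np.cumsum(daily)})
    return out


def gdd_lookup(gdd: pd.DataFrame, day_of_year, year: int | None = None) -> np.ndarray:
    """Convert calendar day-of-year values to cumulative GDD by lookup."""
    g = gdd.copy()
    g["doy"] = pd.to_datetime(g["date"]).dt.dayofyear
    if year is not None:
        g = g[pd.to_datetime(g["date"]).dt.year == year]
    table = g.set_index("doy")["gdd_cum"]
    doy = np.atleast_1d(np.asarray(day_of_year, dtype=int))
    missing = [d for d in doy if d not in table.index]
    if missing:
        raise KeyError(f"day(s) of year outside the weather series: {missing[:5]}")
    return table.loc[doy].to_numpy()


def flag_outliers(values, studentized_resid) -> np.ndarray:
    """Keep mask for one trait-year vector.

    A value is removed iff it is larger than twice the largest remaining
    value or smaller than half the smallest remaining value, AND its
    studentized residual exceeds 5 in absolute value.  Both conditions
    guard against deleting genuine extremes.
    """
    v = np.asarray(values, dtype=float)
    r = np.asarray(studentized_resid, dtype=float)
    if v.shape != r.shape:
        raise ValueError("values and residuals must align")
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    keep = np.ones(v.size, dtype=bool)
    for k in range(v.size):
        others = np.delete(v, k)
        extreme = v[k] > 2.0 * others.max() or v[k] < 0.5 * others.min()
        if extreme and abs(r[k]) > 5.0:
            keep[k] = False
    return keep


def studentized_residuals(values, groups=None) -> np.ndarray:
    """Externally studentized residuals from a group-mean (default:
    grand-mean) linear model, for feeding :func:`flag_outliers`."""
    v = np.asarray(values, dtype=float)
    if groups is None:
        X = np.ones((v.size, 1))
    else:
        X = pd.get_dummies(pd.Series(np.asarray(groups)), dtype=float).to_numpy()
    fit = sm.OLS(v, X).fit()
    return np.asarray(fit.get_influence().resid_studentized_external)


def remove_outliers(pheno: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the removal rule per (trait, year); returns (cleaned, log)."""
    validate_phenotypes(pheno)
    keep = np.ones(len(pheno), dtype=bool)
    for (_, _), idx in pheno.groupby(["trait", "year"]).groups.items():
        idx = np.asarray(idx)
        if idx.size < 3:
            continue
        vals = pheno.loc[idx, "value"].to_numpy(float)
        resid = studentized_residuals(vals)
        keep[pheno.index.get_indexer(idx)] = flag_outliers(vals, resid)
    removed = pheno.loc[~keep].copy()
    return pheno.loc[keep].reset_index(drop=True), removed.reset_index(drop=True)


def fruit_dimension_score(length, width) -> tuple[np.ndarray, float]:
    """First principal component of standardized fruit length and width.

    PCA is done on the 2x2 correlation matrix; the score is oriented so
    that larger fruit get larger scores.  Returns (scores,
    variance-explained fraction); with two standardized variables the
    fraction is ``(1 + |r|) / 2``.
    """
    L = np.asarray(length, dtype=float)
    W = np.asarray(width, dtype=float)
    if L.shape != W.shape or L.ndim != 1:
        raise ValueError("length and width must be aligned 1-D vectors")
    if L.size < 3:
        raise ValueError("need at least 3 paired observations")
    if L.std(ddof=1) == 0.0 or W.std(ddof=1) == 0.0:
        raise ValueError("zero variance in length or width")
    zl = (L - L.mean()) / L.std(ddof=1)
    zw = (W - W.mean()) / W.std(ddof=1)
    corr = np.corrcoef(zl, zw)
    vals, vecs = np.linalg.eigh(corr)
    v1 = vecs[:, -1]
    scores = zl * v1[0] + zw * v1[1]
    size_proxy = zl + zw
    if np.dot(scores, size_proxy) < 0.0:
        scores = -scores
    explained = float(vals[-1] / vals.sum())
    return scores, explained


def adjust_for_fixed_effects(pheno: pd.DataFrame, fit) -> pd.DataFrame:
    """Subtract the fitted intercept and year effect from each record.

    ``fit`` is a fitted :class:`~cherryblup.model.KernelGBLUP` (or any
    object exposing ``fixed_effects_`` keyed ``intercept`` /
    ``year:<level>``).  The returned table carries an ``adjusted`` column.
    """
    validate_phenotypes(pheno)
    fe = fit.fixed_effects_ if hasattr(fit, "fixed_effects_") else dict(fit)
    out = pheno.copy()
    adj = np.empty(len(out))
    for k, (_, rec) in enumerate(out.iterrows()):
        key = f"year:{rec['year']}"
        if key not in fe and rec["year"] not in getattr(fit, "years_", (rec["year"],)):
            raise KeyError(f"year {rec['year']} absent from the fit")
        adj[k] = rec["value"] - fe.get("intercept", 0.0) - fe.get(key, 0.0)
    out["adjusted"] = adj
    return out
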