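"""Model comparison and heritability decomposition.

Reduced models drop variance components from the full ADI model; because
the dropped parameters sit on the boundary of the parameter space
(variances are nonnegative), the likelihood-ratio statistic is referred
to a chi-bar-square distribution: an equal-weight binomial mixture of
chi-square distributions with 0..q degrees of freedom, where q is the
number of dropped variance parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .model import ALL_TERMS, ModelSpec, VarianceEstimates

__all__ = [
    "model_ladder",
    "chibar_sf",
    "LRTResult",
    "lrt_mixture",
    "HeritabilityEstimates",
    "heritability",
    "variance_table",
    "significance_stars",
]

#: the 13 reduced models examined against the full ADI model, with the
#: number of dropped variance parameters
_LADDER = [
    (("a", "d", "i", "aY", "dY"), 1),
    (("a", "d", "i", "aY", "iY"), 1),
    (("a", "d", "i", "dY", "iY"), 1),
    (("a", "d", "aY", "dY"), 2),
    (("a", "i", "aY", "iY"), 2),
    (("d", "i", "dY", "iY"), 2),
    (("a", "aY"), 4),
    (("d", "dY"), 4),
    (("i", "iY"), 4),
    (("a", "d", "i"), 3),
    (("a",), 5),
    (("d",), 5),
    (("i",), 5),
]


def model_ladder(full: ModelSpec | None = None) -> list:
    """Reduced specs (with dropped-parameter df) for the full ADI model."""
    full = full or ModelSpec()
    if set(full.terms) != set(ALL_TERMS):
        raise ValueError("the ladder is defined for the full ADI model")
    return [
        (ModelSpec(terms=terms, residual=full.residual), df)
        for terms, df in _LADDER
    ]


def chibar_sf(statistic: float, q: int) -> float:
    """Tail probability of the equal-weight chi-bar-square mixture.

    P(X >= x) = sum_{k=0..q} 2^-q C(q, k) P(chi2_k >= x); the k = 0
    component is a point mass at zero.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if statistic < 0.0:
        raise ValueError("statistic must be nonnegative")
    p = 0.0
    for k in range(q + 1):
        tail = 1.0 if statistic <= 0.0 else (stats.chi2.sf(statistic, k) if k > 0 else 0.0)
        p += comb(q, k) * tail
    return p / 2.0**q


@dataclass
class LRTResult:
    full_terms: tuple
    reduced_terms: tuple
    statistic: float
    df: int
    p_value: float


def lrt_mixture(full_fit, reduced_fit) -> LRTResult:
    """Boundary-corrected likelihood-ratio test of a reduced model.

    The statistic ``2 (logL_full - logL_reduced)`` is clipped at zero
    (convergence noise can leave the reduced model marginally higher)
    and referred to the chi-bar-square mixture with q equal to the
    number of dropped variance parameters.
    """
    full_spec, red_spec = full_fit.spec_, reduced_fit.spec_
    if not red_spec.is_nested_in(full_spec):
        raise ValueError(
            f"{red_spec.label()} is not nested in {full_spec.label()}"
        )
    q = len(set(full_spec.terms) - set(red_spec.terms))
    if q < 1:
        raise ValueError("specs are identical; nothing to test")
    stat = max(0.0, 2.0 * (full_fit.loglik_ - reduced_fit.loglik_))
    return LRTResult(
        full_terms=full_spec.terms,
        reduced_terms=red_spec.terms,
        statistic=stat,
        df=q,
        p_value=chibar_sf(stat, q),
    )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "+"
    return ""


@dataclass
class HeritabilityEstimates:
    h2: float
    H2: float
    percentages: dict  # component (six genetic + error) -> share of 100

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages sum to {total}, not 100")


def heritability(est) -> HeritabilityEstimates:
    """Narrow- and broad-sense heritability from variance components.

    h2 = s2_a / T and H2 = (s2_a + s2_d + s2_aa) / T with T the sum of
    all six genetic components plus the residual, so the component
    percentages sum to 100 and h2 equals the additive percentage.

    ``est`` may be a :class:`VarianceEstimates`, a fitted estimator, or a
    plain mapping with keys among the six terms plus ``error``.
    """
    if hasattr(est, "variance_components_"):
        comp = dict(est.variance_components_)
    elif isinstance(est, VarianceEstimates):
        comp = est.components()
    else:
        comp = {k: float(v) for k, v in dict(est).items()}
    comp = {t: comp.get(t, 0.0) for t in (*ALL_TERMS, "error")}
    if any(v < 0 for v in comp.values()):
        raise ValueError("variance components must be nonnegative")
    T = sum(comp.values())
    if T <= 0.0:
        raise ValueError("total variance is zero")
    return HeritabilityEstimates(
        h2=comp["a"] / T,
        H2=(comp["a"] + comp["d"] + comp["i"]) / T,
        percentages={k: 100.0 * v / T for k, v in comp.items()},
    )


def variance_table(fits: dict) -> pd.DataFrame:
    """Per-trait variance decomposition report.

    ``fits`` maps trait name -> fitted estimator.  Rows carry component
    estimates, their standard errors (AI-matrix inverse), percentage
    shares, h2 and H2; unconverged fits are flagged.
    """
    rows = []
    for trait, fit in fits.items():
        comp = fit.variance_components_
        h = heritability(fit)
        row = {"trait": trait, "converged": bool(fit.converged_)}
        for t in (*ALL_TERMS, "error"):
            row[f"sigma2_{t}"] = comp.get(t, 0.0)
            se_key = "e" if t == "error" else t
            row[f"se_{t}"] = fit.param_se_.get(se_key, np.nan)
            row[f"pct_{t}"] = h.percentages[t]
        row["h2"] = h.h2
        row["H2"] = h.H2
        rows.append(row)
    return pd.DataFrame(rows)


def ladder_table(full_fit, reduced_fits: list) -> pd.DataFrame:
    """Model-comparison table: terms, df, 2*delta(logL), stars."""
    rows = []
    for fit in reduced_fits:
        res = lrt_mixture(full_fit, fit)
        rows.append(
            {
                "model": fit.spec_.label(),
                "df": res.df,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "signif": significance_stars(res.p_value),
                "converged": bool(fit.converged_),
            }
        )
    return pd.DataFrame(rows)
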