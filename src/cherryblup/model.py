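"""Multi-kernel repeated-measures GBLUP fitted by REML.

The observation model for a single trait is

    y = X b + Z1 a + Z2 d + Z3 i + Z4 aY + Z5 dY + Z6 iY + e

with a ~ N(0, G_a s2_a), d ~ N(0, D s2_d), i ~ N(0, G_aa s2_aa), the
year-interaction terms N(0, I_Y kron K s2) and a repeated-measures
residual: records of one individual share a Y x Y error covariance
(homogeneous variance with free year-pair correlations by default),
records of different individuals are independent.

Variance parameters enter V linearly, so the engine is a generic
average-information (AI) REML over V(theta) = sum_k theta_k B_k, with
EM-REML fallback steps when the AI update is invalid or non-improving,
and nonnegativity enforced by pinning variances at a small positive
floor.  Convergence requires both a relative log-likelihood change below
``loglik_rtol`` (default 0.002) and all free parameters moving less than
``param_rtol`` (default 1%) between iterations.

BLUPs are recovered at the converged theta as
``u_t = s2_t K_t Z_t' V^-1 (y - X b)``; individuals carried in the
kernels without phenotypes receive predictions through the kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "ALL_TERMS",
    "ModelSpec",
    "DesignSet",
    "VarianceEstimates",
    "assemble_design",
    "reml_loglik",
    "KernelGBLUP",
    "solve_mme",
    "wald_test_fixed",
    "extended_hat_diagonal",
    "influence_diagnostics",
    "residual_only_reml_loglik",
    "spectral_additive_reml",
]

ALL_TERMS = ("a", "d", "i", "aY", "dY", "iY")
_INTERACTIONS = {"aY", "dY", "iY"}


@dataclass(frozen=True)
class ModelSpec:
    """Which random terms are included; year is always a fixed effect."""

    terms: tuple = ALL_TERMS
    residual: str = "correlated"  # "correlated" | "independent" | "heterogeneous"

    def __post_init__(self) -> None:
        terms = tuple(t for t in ALL_TERMS if t in self.terms)
        unknown = set(self.terms) - set(ALL_TERMS)
        if unknown:
            raise ValueError(f"unknown model terms {sorted(unknown)}")
        if not terms:
            raise ValueError("at least one random genetic term is required")
        object.__setattr__(self, "terms", terms)
        if self.residual not in ("correlated", "independent", "heterogeneous"):
            raise ValueError(f"unknown residual structure {self.residual!r}")

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.terms) <= set(other.terms) and self.residual == other.residual

    def label(self) -> str:
        return "+".join(self.terms)


@dataclass
class DesignSet:
    """Design information for the phenotyped records of one trait."""

    y: np.ndarray
    X: np.ndarray
    ind_idx: np.ndarray   # observation -> position in `individuals`
    year_idx: np.ndarray  # observation -> position in `years`
    years: np.ndarray
    individuals: np.ndarray
    fixed_names: list = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_years(self) -> int:
        return len(self.years)


def assemble_design(
    pheno: pd.DataFrame,
    individual_order,
    trait: str | None = None,
    years=None,
) -> DesignSet:
    """Build the fixed design and incidence indices from a long table.

    ``individual_order`` is the kernel ordering; every phenotyped
    individual must appear in it (unphenotyped individuals may appear in
    the kernels without contributing rows).  Year is coded intercept +
    reference-level contrasts (first year is the reference).
    """
    df = pheno
    if trait is not None:
        df = df[df["trait"] == trait]
    elif "trait" in df.columns and df["trait"].nunique() > 1:
        raise ValueError("multiple traits present; pass trait=")
    if df.duplicated(subset=["individual", "year"]).any():
        raise ValueError("duplicate (individual, year) records for this trait")
    individuals = np.asarray(individual_order, dtype=object)
    pos = {ind: k for k, ind in enumerate(individuals)}
    missing = sorted(set(df["individual"]) - set(pos))
    if missing:
        raise KeyError(f"phenotyped individuals absent from the kernels: {missing[:5]}")
    years = np.array(sorted(df["year"].unique()) if years is None else list(years))
    ypos = {yv: k for k, yv in enumerate(years)}
    ind_idx = df["individual"].map(pos).to_numpy(dtype=int)
    year_idx = df["year"].map(ypos).to_numpy(dtype=int)
    N = len(df)
    X = np.ones((N, len(years)))
    names = ["intercept"]
    for j, yv in enumerate(years[1:], start=1):
        X[:, j] = (year_idx == j).astype(float)
        names.append(f"year:{yv}")
    return DesignSet(
        y=df["value"].to_numpy(dtype=float),
        X=X,
        ind_idx=ind_idx,
        year_idx=year_idx,
        years=years,
        individuals=individuals,
        fixed_names=names,
    )


def incidence_matrix(design: DesignSet, term: str) -> sp.csr_matrix:
    """Sparse observation -> effect-level incidence matrix Z_t.

    Main effects map to the n individuals; interactions to the n*Y
    individual-year cells (year-major ordering).
    """
    N, n = design.n_obs, design.n_individuals
    rows = np.arange(N)
    if term in _INTERACTIONS:
        cols = design.year_idx * n + design.ind_idx
        shape = (N, n * design.n_years)
    else:
        cols = design.ind_idx
        shape = (N, n)
    return sp.csr_matrix((np.ones(N), (rows, cols)), shape=shape)


# ---------------------------------------------------------------------------
# linear variance structure


def _term_vdot(K: np.ndarray, design: DesignSet, interaction: bool) -> np.ndarray:
    """Z_t K_t Z_t' as a dense N x N matrix."""
    V = K[np.ix_(design.ind_idx, design.ind_idx)]
    if interaction:
        V = V * (design.year_idx[:, None] == design.year_idx[None, :])
    return V


def _residual_components(design: DesignSet, residual: str):
    """Residual derivative matrices (all linear in the parameters).

    correlated:   e      -> I_N                (common year variance)
                  c(p,q) -> same-individual year-pair indicator
    heterogeneous: e<y>  -> diag(year == y), plus the c(p,q) patterns
    independent:  e      -> I_N only
    """
    N = design.n_obs
    comps: list = []
    if residual == "heterogeneous":
        for j, yv in enumerate(design.years):
            comps.append((f"e:{yv}", np.diag((design.year_idx == j).astype(float)), "res_var"))
    else:
        comps.append(("e", np.eye(N), "res_var"))
    if residual != "independent" and design.n_years > 1:
        same = design.ind_idx[:, None] == design.ind_idx[None, :]
        for p in range(design.n_years):
            for q in range(p + 1, design.n_years):
                pat = same & (
                    ((design.year_idx[:, None] == p) & (design.year_idx[None, :] == q))
                    | ((design.year_idx[:, None] == q) & (design.year_idx[None, :] == p))
                )
                comps.append(
                    (f"c:{design.years[p]}:{design.years[q]}", pat.astype(float), "res_cov")
                )
    return comps


def _structure(design: DesignSet, kernels, spec: ModelSpec):
    """Ordered parameter structure: (name, B_k, kind, em_weight)."""
    n, Y = design.n_individuals, design.n_years
    out = []
    for t in spec.terms:
        B = _term_vdot(kernels.kernel_for(t), design, t in _INTERACTIONS)
        out.append((t, B, "variance", n * (Y if t in _INTERACTIONS else 1)))
    for name, B, kind in _residual_components(design, spec.residual):
        out.append((name, B, kind, design.n_obs if kind == "res_var" else None))
    return out


def _residual_cov_matrix(theta: dict, design: DesignSet, residual: str) -> np.ndarray:
    """The Y x Y residual covariance implied by the parameter dict."""
    Y = design.n_years
    S = np.zeros((Y, Y))
    if residual == "heterogeneous":
        for j, yv in enumerate(design.years):
            S[j, j] = theta[f"e:{yv}"]
    else:
        np.fill_diagonal(S, theta["e"])
    if residual != "independent":
        for p in range(Y):
            for q in range(p + 1, Y):
                key = f"c:{design.years[p]}:{design.years[q]}"
                if key in theta:
                    S[p, q] = S[q, p] = theta[key]
    return S


@dataclass
class VarianceEstimates:
    """Converged variance parameters on the trait scale."""

    sigma2: dict                       # term -> variance (absent terms 0)
    residual_sigma2: float
    residual_correlations: np.ndarray | None = None
    residual_variances: np.ndarray | None = None  # per year, heterogeneous only

    def components(self) -> dict:
        """All six genetic components plus 'error', zeros for absent terms."""
        out = {t: float(self.sigma2.get(t, 0.0)) for t in ALL_TERMS}
        out["error"] = float(self.residual_sigma2)
        return out


def _embed(vals: np.ndarray, idx: np.ndarray, size: int) -> np.ndarray:
    out = np.zeros(size)
    out[idx] = vals
    return out


def _loglik_from_parts(theta_vec, parts, design):
    V = np.zeros((design.n_obs, design.n_obs))
    for val, (_, B, _, _) in zip(theta_vec, parts):
        if val != 0.0:
            V += val * B
    try:
        c, low = sla.cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return None
    logdetV = 2.0 * np.log(np.diag(c)).sum()
    Vinv = sla.cho_solve((c, low), np.eye(design.n_obs), check_finite=False)
    X, y = design.X, design.y
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return None
    XtViX_inv = np.linalg.inv(XtViX)
    beta = XtViX_inv @ (ViX.T @ y)
    P = Vinv - ViX @ XtViX_inv @ ViX.T
    Py = P @ y
    N, f = design.n_obs, X.shape[1]
    logl = -0.5 * (logdetV + logdetX + y @ Py + (N - f) * math.log(2.0 * math.pi))
    return {
        "logl": float(logl), "V": V, "Vinv": Vinv, "P": P, "Py": Py,
        "beta": beta, "beta_cov": XtViX_inv,
    }


def reml_loglik(theta, design: DesignSet, kernels, y=None, spec: ModelSpec | None = None) -> float:
    """Restricted log-likelihood of the data at fixed variance parameters.

    ``theta`` may be a :class:`VarianceEstimates` or a flat dict with the
    genetic terms plus ``e`` and optional ``c:<year>:<year>`` covariance
    entries.  Includes the -(N - f)/2 log(2 pi) constant.
    """
    if y is not None:
        design = DesignSet(
            y=np.asarray(y, float), X=design.X, ind_idx=design.ind_idx,
            year_idx=design.year_idx, years=design.years,
            individuals=design.individuals, fixed_names=design.fixed_names,
        )
    flat = _flatten_theta(theta, design)
    if spec is None:
        terms = tuple(t for t in ALL_TERMS if flat.get(t, 0.0) != 0.0) or ("a",)
        residual = "correlated" if any(k.startswith("c:") for k in flat) else "independent"
        spec = ModelSpec(terms=terms, residual=residual)
    parts = _structure(design, kernels, spec)
    vec = np.array([flat.get(name, 0.0) for name, *_ in parts])
    state = _loglik_from_parts(vec, parts, design)
    if state is None:
        raise ValueError("V(theta) is not positive definite")
    return state["logl"]


def _flatten_theta(theta, design: DesignSet) -> dict:
    if isinstance(theta, VarianceEstimates):
        flat = {t: v for t, v in theta.sigma2.items()}
        if theta.residual_variances is not None:
            for j, yv in enumerate(design.years):
                flat[f"e:{yv}"] = float(theta.residual_variances[j])
        else:
            flat["e"] = float(theta.residual_sigma2)
        if theta.residual_correlations is not None:
            C = np.asarray(theta.residual_correlations)
            for p in range(design.n_years):
                for q in range(p + 1, design.n_years):
                    sp_ = flat.get(f"e:{design.years[p]}", flat.get("e"))
                    sq_ = flat.get(f"e:{design.years[q]}", flat.get("e"))
                    flat[f"c:{design.years[p]}:{design.years[q]}"] = (
                        C[p, q] * math.sqrt(sp_ * sq_)
                    )
        return flat
    return dict(theta)


class KernelGBLUP(BaseEstimator):
    """AI-REML estimator for the additive/dominance/epistasis (ADI) model.

    Parameters
    ----------
    terms : random genetic terms to include, subset of
        ``("a", "d", "i", "aY", "dY", "iY")``.
    residual : "correlated" (homogeneous variance, free year-pair
        correlations), "independent", or "heterogeneous" (per-year
        variances plus covariances).
    loglik_rtol, param_rtol : the two convergence criteria; both must
        hold on the final iteration.
    variance_floor_scale : variances stepping below
        ``variance_floor_scale * var(y)`` are pinned there; a parameter
        pinned for 3 consecutive iterations is profiled out.
    trait : trait to select from a multi-trait table.

    Attributes (after :meth:`fit`)
    ------------------------------
    variance_components_ : dict, all six genetic terms plus ``error``.
    residual_correlations_ : Y x Y correlation matrix (unit diagonal).
    fixed_effects_ : dict, ``intercept`` and ``year:<level>`` contrasts.
    blups_ : dict, term -> (n,) main-effect or (Y, n) interaction BLUPs.
    loglik_ : REML log-likelihood; converged_, n_iter_, trace_.
    param_se_ : dict of asymptotic standard errors (AI-matrix inverse).
    """

    def __init__(
        self,
        terms: tuple = ALL_TERMS,
        residual: str = "correlated",
        max_iter: int = 100,
        loglik_rtol: float = 0.002,
        param_rtol: float = 0.01,
        variance_floor_scale: float = 1e-8,
        trait: str | None = None,
        verbose: int = 0,
    ):
        self.terms = terms
        self.residual = residual
        self.max_iter = max_iter
        self.loglik_rtol = loglik_rtol
        self.param_rtol = param_rtol
        self.variance_floor_scale = variance_floor_scale
        self.trait = trait
        self.verbose = verbose

    # -- fitting ------------------------------------------------------------

    def fit(self, phenotypes: pd.DataFrame, kernels, trait: str | None = None):
        spec = ModelSpec(terms=tuple(self.terms), residual=self.residual)
        design = assemble_design(phenotypes, kernels.ids, trait=trait or self.trait)
        self.spec_ = spec
        self.design_ = design
        self.kernels_ = kernels
        self._run_ai_reml(design, kernels, spec)
        self._solve_blups()
        return self

    def _run_ai_reml(self, design: DesignSet, kernels, spec: ModelSpec) -> None:
        parts = _structure(design, kernels, spec)
        names = [p[0] for p in parts]
        kinds = [p[2] for p in parts]
        # scale-setting variance taken after projecting out the fixed
        # effects, so initialization is invariant to year-mean shifts
        beta0, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        var_y = float(np.var(design.y - design.X @ beta0)) or 1.0
        floor = self.variance_floor_scale * var_y
        n_var = sum(1 for k in kinds if k in ("variance", "res_var"))
        theta = np.empty(len(parts))
        for k, kind in enumerate(kinds):
            theta[k] = var_y / n_var if kind in ("variance", "res_var") else 0.1 * var_y / n_var
        free = np.ones(len(parts), dtype=bool)
        pinned_count = np.zeros(len(parts), dtype=int)

        cov_idx = [k for k, kind in enumerate(kinds) if kind == "res_cov"]

        def project(vec: np.ndarray) -> np.ndarray:
            """Clip variances at the floor and pull residual covariances
            back inside the positive-definite region if needed."""
            v = vec.copy()
            for k, kind in enumerate(kinds):
                if kind in ("variance", "res_var") and v[k] < floor:
                    v[k] = floor
            for _ in range(200):
                S = _residual_cov_matrix(dict(zip(names, v)), design, spec.residual)
                if np.linalg.eigvalsh(S).min() > 1e-6 * np.mean(np.diag(S)):
                    break
                for k in cov_idx:
                    v[k] *= 0.9
            return v

        state = _loglik_from_parts(theta, parts, design)
        if state is None:
            raise ValueError("initial V is not positive definite")
        trace = [{"iteration": 0, "loglik": state["logl"],
                  **dict(zip(names, theta))}]
        converged = False
        it = 0
        AI_free = None
        for it in range(1, self.max_iter + 1):
            P, Py = state["P"], state["Py"]
            # release boundary-pinned variances whose score turned positive
            for k in np.flatnonzero(~free):
                B = parts[k][1]
                sc_k = -0.5 * (float(np.sum(P * B)) - Py @ (B @ Py))
                if sc_k > 0.0:
                    free[k] = True
                    pinned_count[k] = 0
            idx = np.flatnonzero(free)
            score = np.empty(len(idx))
            Wcols = np.empty((design.n_obs, len(idx)))
            trPB = np.empty(len(idx))
            for j, k in enumerate(idx):
                B = parts[k][1]
                BPy = B @ Py
                trPB[j] = float(np.sum(P * B))
                score[j] = -0.5 * (trPB[j] - Py @ BPy)
                Wcols[:, j] = BPy
            AI = 0.5 * Wcols.T @ (P @ Wcols)
            AI_free = (idx, AI)
            try:
                delta = sla.solve(AI + 1e-10 * np.eye(len(idx)) * max(AI.max(), 1.0),
                                  score, assume_a="sym")
            except np.linalg.LinAlgError:
                delta = np.linalg.pinv(AI) @ score

            tol_accept = 1e-9 * max(1.0, abs(state["logl"]))
            new_theta, new_state = None, None
            step = 1.0
            for _ in range(10):  # AI update with step halving
                cand = project(theta + _embed(step * delta, idx, len(parts)))
                st = _loglik_from_parts(cand, parts, design)
                if st is not None and st["logl"] >= state["logl"] - tol_accept:
                    new_theta, new_state = cand, st
                    break
                step *= 0.5
            if new_state is None:
                # EM-REML fallback for the variance parameters (covariance
                # parameters are held for the iteration)
                em = theta.copy()
                for j, k in enumerate(idx):
                    if kinds[k] in ("variance", "res_var"):
                        q = parts[k][3]
                        yPBPy = Py @ (parts[k][1] @ Py)
                        em[k] = theta[k] + theta[k] ** 2 * (yPBPy - trPB[j]) / q
                for frac in (1.0, 0.5, 0.25):
                    cand = project(theta + frac * (em - theta))
                    st = _loglik_from_parts(cand, parts, design)
                    if st is not None and st["logl"] >= state["logl"] - tol_accept:
                        new_theta, new_state = cand, st
                        break
            if new_state is None:
                # no direction improves the likelihood beyond numerical
                # resolution: a (possibly boundary-constrained) maximum
                converged = True
                break

            dl = abs(new_state["logl"] - state["logl"])
            denom = np.maximum(np.abs(theta[free]), 1e-3 * var_y)
            dp = np.max(np.abs(new_theta[free] - theta[free]) / denom) if free.any() else 0.0
            for k, kind in enumerate(kinds):
                if kind in ("variance", "res_var"):
                    pinned_count[k] = pinned_count[k] + 1 if new_theta[k] <= floor * (1 + 1e-12) else 0
                    if pinned_count[k] >= 3:
                        free[k] = False  # profiled out at the boundary
            theta, state = new_theta, new_state
            trace.append({"iteration": it, "loglik": state["logl"],
                          **dict(zip(names, theta))})
            if self.verbose:
                print(f"iter {it}: logL={state['logl']:.6f}")
            if dl < self.loglik_rtol * abs(state["logl"]) and dp < self.param_rtol:
                converged = True
                break

        self.theta_ = dict(zip(names, theta))
        self.loglik_ = state["logl"]
        self.converged_ = converged
        self.n_iter_ = it
        self.trace_ = trace
        self.beta_ = state["beta"]
        self.beta_cov_ = state["beta_cov"]
        self._Vinv_ = state["Vinv"]
        self.years_ = design.years
        self.fixed_effects_ = dict(zip(design.fixed_names, self.beta_))
        # standard errors from the final AI matrix over free parameters
        self.param_se_ = {}
        if AI_free is not None:
            idx, AI = AI_free
            try:
                cov = np.linalg.inv(AI)
                for j, k in enumerate(idx):
                    self.param_se_[names[k]] = float(math.sqrt(max(cov[j, j], 0.0)))
            except np.linalg.LinAlgError:
                pass
        # public decomposition
        S = _residual_cov_matrix(self.theta_, design, self.spec_.residual)
        d = np.sqrt(np.diag(S))
        self.residual_correlations_ = S / np.outer(d, d)
        self.residual_sigma2_ = float(np.mean(np.diag(S)))
        self.variance_components_ = {t: float(self.theta_.get(t, 0.0)) for t in ALL_TERMS}
        self.variance_components_["error"] = self.residual_sigma2_

    def _solve_blups(self) -> None:
        design, kernels = self.design_, self.kernels_
        n, Y = design.n_individuals, design.n_years
        resid = design.y - design.X @ self.beta_
        w = self._Vinv_ @ resid
        blups: dict = {}
        for t in self.spec_.terms:
            K = kernels.kernel_for(t)
            s2 = self.theta_[t]
            if t in _INTERACTIONS:
                u = np.zeros((Y, n))
                for j in range(Y):
                    mask = design.year_idx == j
                    s = np.bincount(design.ind_idx[mask], weights=w[mask], minlength=n)
                    u[j] = s2 * (K @ s)
                blups[t] = u
            else:
                s = np.bincount(design.ind_idx, weights=w, minlength=n)
                blups[t] = s2 * (K @ s)
        self.blups_ = blups

    # -- downstream summaries ----------------------------------------------

    def variance_estimates(self) -> VarianceEstimates:
        S = _residual_cov_matrix(self.theta_, self.design_, self.spec_.residual)
        het = self.spec_.residual == "heterogeneous"
        return VarianceEstimates(
            sigma2={t: float(self.theta_.get(t, 0.0)) for t in ALL_TERMS},
            residual_sigma2=self.residual_sigma2_,
            residual_correlations=self.residual_correlations_.copy(),
            residual_variances=np.diag(S).copy() if het else None,
        )

    def predict(self, individuals=None, kind: str = "genetic") -> np.ndarray:
        """Predicted values per individual.

        kind: "genetic" (a + d + i), "breeding" (a only), "dominance",
        "epistatic".  Individuals default to the kernel order; any
        individual in the kernels (phenotyped or not) may be requested.
        """
        pick = {"genetic": ("a", "d", "i"), "breeding": ("a",),
                "dominance": ("d",), "epistatic": ("i",)}[kind]
        n = self.design_.n_individuals
        total = np.zeros(n)
        for t in pick:
            if t in self.blups_:
                total = total + self.blups_[t]
        if individuals is None:
            return total
        pos = {ind: k for k, ind in enumerate(self.design_.individuals)}
        return np.array([total[pos[i]] for i in individuals])


# ---------------------------------------------------------------------------
# Henderson mixed-model equations, hat matrix, Wald test


def _mme_blocks(fit: KernelGBLUP):
    design, kernels, spec = fit.design_, fit.kernels_, fit.spec_
    Zs, Gs = [], []
    for t in spec.terms:
        Z = incidence_matrix(design, t).toarray()
        K = kernels.kernel_for(t)
        s2 = max(fit.theta_[t], 1e-12)
        G = s2 * (np.kron(np.eye(design.n_years), K) if t in _INTERACTIONS else K)
        Zs.append(Z)
        Gs.append(G)
    S = _residual_cov_matrix(fit.theta_, design, spec.residual)
    R = S[np.ix_(design.year_idx, design.year_idx)] * (
        design.ind_idx[:, None] == design.ind_idx[None, :]
    )
    return Zs, Gs, R


def solve_mme(fit: KernelGBLUP):
    """Solve Henderson's mixed-model equations at the converged theta.

    Returns ``(beta, {term: blup})``; an independent route to the
    ``s2 K Z' V^-1 (y - X beta)`` solutions stored on the fit.
    """
    design = fit.design_
    Zs, Gs, R = _mme_blocks(fit)
    X, y = design.X, design.y
    Rinv = np.linalg.inv(R)
    W = np.hstack([X] + Zs)
    Ginv_blocks = [np.linalg.inv(G) for G in Gs]
    f = X.shape[1]
    q = W.shape[1]
    C = W.T @ Rinv @ W
    ofs = f
    for G_inv in Ginv_blocks:
        d = G_inv.shape[0]
        C[ofs:ofs + d, ofs:ofs + d] += G_inv
        ofs += d
    try:
        sol = sla.solve(C, W.T @ Rinv @ y, assume_a="sym")
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular mixed-model coefficient matrix")
    beta = sol[:f]
    out, ofs = {}, f
    for t, G in zip(fit.spec_.terms, Gs):
        d = G.shape[0]
        u = sol[ofs:ofs + d]
        out[t] = u.reshape(design.n_years, design.n_individuals) if t in _INTERACTIONS else u
        ofs += d
    return beta, out


def extended_hat_diagonal(X, Zs, Gs, R) -> np.ndarray:
    """Diagonal of the extended hat matrix W C^-1 W' with
    C = W' R^-1 W + blockdiag(0, G^-1) and W = [X Z]."""
    X = np.asarray(X, float)
    W = np.hstack([X] + [np.asarray(Z, float) for Z in Zs]) if Zs else X
    Rinv = np.linalg.inv(np.asarray(R, float))
    C = W.T @ Rinv @ W
    ofs = X.shape[1]
    for G in Gs:
        G = np.asarray(G, float)
        d = G.shape[0]
        C[ofs:ofs + d, ofs:ofs + d] += np.linalg.inv(G)
        ofs += d
    try:
        CiWt = sla.solve(C, W.T, assume_a="sym")
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular coefficient matrix C")
    return np.einsum("ij,ji->i", W, CiWt)


def influence_diagnostics(fit: KernelGBLUP, threshold: float = 2.0):
    """Hat diagonal and influential-observation flags for a converged fit.

    An observation is flagged when its leverage exceeds ``threshold``
    times the mean of the nonzero hat diagonal.
    """
    Zs, Gs, R = _mme_blocks(fit)
    diag = extended_hat_diagonal(fit.design_.X, Zs, Gs, R)
    nonzero = diag[np.abs(diag) > 1e-12]
    mean = nonzero.mean() if nonzero.size else 0.0
    flags = diag > threshold * mean
    return diag, flags


def wald_test_fixed(fit: KernelGBLUP, term: str = "year"):
    """Wald chi-square test of a fixed factor using the estimated
    contrast covariance; returns (statistic, df, p)."""
    names = fit.design_.fixed_names
    cols = [k for k, nm in enumerate(names) if nm.split(":")[0] == term]
    if not cols:
        raise KeyError(f"fixed term {term!r} not in the model")
    if len(cols) < 1 or (term == "year" and fit.design_.n_years < 2):
        raise ValueError(f"fixed term {term!r} has a single level")
    b = fit.beta_[cols]
    C = fit.beta_cov_[np.ix_(cols, cols)]
    stat = float(b @ np.linalg.solve(C, b))
    df = len(cols)
    return stat, df, float(stats.chi2.sf(stat, df))


def residual_only_reml_loglik(X: np.ndarray, y: np.ndarray) -> float:
    """Closed-form REML log-likelihood of the fixed-effects-plus-iid-noise
    model (no genetic terms); the reduced model under a boundary null."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    N, f = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / (N - f)
    return -0.5 * (
        N * math.log(s2) + np.linalg.slogdet(X.T @ X)[1] - f * math.log(s2)
        + (N - f) + (N - f) * math.log(2.0 * math.pi)
    )


# ---------------------------------------------------------------------------
# independent single-kernel REML via spectral reparameterization


def spectral_additive_reml(K: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Single-kernel REML (V = s2_g K + s2_e I) by eigendecomposition.

    Rotating by the eigenvectors of K diagonalizes V, so the restricted
    likelihood is profiled down to the single ratio delta = s2_g / s2_e
    and optimized by a bounded scalar search.  Serves as an independent
    cross-check of the AI-REML engine on additive-only, single-year
    models.  Returns (s2_g, s2_e, logl).
    """
    K = np.asarray(K, float)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    N, f = X.shape
    vals, U = np.linalg.eigh(K)
    yt = U.T @ y
    Xt = U.T @ X

    def profile(log_delta: float):
        delta = math.exp(log_delta)
        w = 1.0 / (delta * vals + 1.0)
        XtWX = (Xt * w[:, None]).T @ Xt
        XtWy = (Xt * w[:, None]).T @ yt
        beta = np.linalg.solve(XtWX, XtWy)
        r = yt - Xt @ beta
        rss = float(np.sum(w * r * r))
        s2e = rss / (N - f)
        logl = -0.5 * (
            np.sum(np.log(delta * vals + 1.0)) + N * math.log(s2e)
            + np.linalg.slogdet(XtWX / s2e)[1]
            + (N - f) + (N - f) * math.log(2.0 * math.pi)
        )
        return -logl, s2e

    res = optimize.minimize_scalar(
        lambda t: profile(t)[0], bounds=(-25.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    neg_logl, s2e = profile(res.x)
    delta = math.exp(res.x)
    return delta * s2e, s2e, -neg_logl
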