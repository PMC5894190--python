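"""Genetic-value summaries and cross-validation of genomic predictions.

Three validation schemes are provided: repeated k-fold over individuals
(all of a held-out individual's years removed together), leave one
full-sib family out (predicting unphenotyped relatives), and leave one
year out (predicting an unobserved year).  In every scheme the variance
components are re-estimated on the training records only, held-out
individuals receive predictions through the relationship kernels, and
accuracy is the Pearson correlation between predicted genetic values and
held-out observations adjusted for the training fit's fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .model import KernelGBLUP

__all__ = [
    "GeneticSummary",
    "genetic_summaries",
    "midparent_value",
    "CVResult",
    "kfold_cv",
    "leave_family_out_cv",
    "leave_year_out_cv",
    "rank_stability",
]


@dataclass
class GeneticSummary:
    """Per-individual genetic decomposition from one fit.

    ``values`` holds breeding (a), dominance (d), epistatic (i) and total
    genetic (a + d + i) values per individual; ``gxy`` holds the summed
    genotype-by-year deviations (aY + dY + iY) per individual and year.
    Terms absent from the model contribute exactly zero.
    """

    values: pd.DataFrame
    gxy: pd.DataFrame


def genetic_summaries(fit: KernelGBLUP) -> GeneticSummary:
    design = fit.design_
    n = design.n_individuals
    main = {t: fit.blups_.get(t, np.zeros(n)) for t in ("a", "d", "i")}
    values = pd.DataFrame(
        {
            "individual": design.individuals,
            "breeding_value": main["a"],
            "dominance_value": main["d"],
            "epistatic_value": main["i"],
        }
    )
    values["genetic_value"] = (
        values["breeding_value"] + values["dominance_value"] + values["epistatic_value"]
    )
    rows = []
    for j, yv in enumerate(design.years):
        g = np.zeros(n)
        for t in ("aY", "dY", "iY"):
            if t in fit.blups_:
                g = g + fit.blups_[t][j]
        rows.append(pd.DataFrame({"individual": design.individuals, "year": yv, "gxy_value": g}))
    return GeneticSummary(values=values, gxy=pd.concat(rows, ignore_index=True))


def midparent_value(bv_parent1: float, bv_parent2: float) -> float:
    """Expected offspring breeding value: the mean of the two parents'."""
    return 0.5 * (bv_parent1 + bv_parent2)


@dataclass
class CVResult:
    scheme: str
    accuracies: list          # one mean accuracy per repeat
    fold_accuracies: list     # per repeat, per fold
    fold_assignments: list    # per repeat: {fold label: individuals}
    seed: int | None = None
    skipped: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def _prototype(model, trait):
    proto = model if model is not None else KernelGBLUP()
    proto = clone(proto)
    if trait is not None:
        proto.set_params(trait=trait)
    return proto


def _score_fold(train, test, kernels, proto, adjust_years: bool = True):
    """Refit on the training records; correlate kernel-propagated genetic
    values of held-out individuals with their adjusted observations."""
    fit = clone(proto).fit(train, kernels)
    preds = fit.predict(test["individual"].to_numpy(), kind="genetic")
    fe = fit.fixed_effects_
    adj = test["value"].to_numpy(dtype=float) - fe.get("intercept", 0.0)
    if adjust_years:
        adj = adj - np.array([fe.get(f"year:{yv}", 0.0) for yv in test["year"]])
    if len(test) < 3 or np.std(preds) == 0.0 or np.std(adj) == 0.0:
        return np.nan
    return float(np.corrcoef(preds, adj)[0, 1])


def _select_trait(pheno: pd.DataFrame, trait):
    if trait is not None:
        return pheno[pheno["trait"] == trait]
    if "trait" in pheno.columns and pheno["trait"].nunique() > 1:
        raise ValueError("multiple traits present; pass trait=")
    return pheno


def kfold_cv(
    pheno: pd.DataFrame,
    kernels,
    model: KernelGBLUP | None = None,
    k: int = 5,
    repeats: int = 25,
    seed: int = 0,
    trait: str | None = None,
) -> CVResult:
    """Repeated k-fold cross-validation over phenotyped individuals.

    A held-out individual loses all of its years of records at once.
    Fold sizes differ by at most one (shuffled round-robin assignment).
    """
    df = _select_trait(pheno, trait)
    proto = _prototype(model, trait)
    individuals = np.array(sorted(df["individual"].unique()), dtype=object)
    if k > len(individuals):
        raise ValueError(f"k={k} exceeds the {len(individuals)} phenotyped individuals")
    root = np.random.default_rng(seed)
    accuracies, fold_acc_all, assignments = [], [], []
    for rep in range(repeats):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        perm = rng.permutation(individuals)
        folds = {f: perm[f::k] for f in range(k)}
        fold_accs = []
        for f, held in folds.items():
            held_set = set(held)
            test = df[df["individual"].isin(held_set)]
            train = df[~df["individual"].isin(held_set)]
            fold_accs.append(_score_fold(train, test, kernels, proto))
        accuracies.append(float(np.nanmean(fold_accs)))
        fold_acc_all.append(fold_accs)
        assignments.append({f: list(v) for f, v in folds.items()})
    return CVResult(
        scheme="kfold", accuracies=accuracies, fold_accuracies=fold_acc_all,
        fold_assignments=assignments, seed=seed,
    )


def leave_family_out_cv(
    pheno: pd.DataFrame,
    kernels,
    family_map: dict,
    model: KernelGBLUP | None = None,
    trait: str | None = None,
) -> CVResult:
    """One fold per full-sib family; the whole family is held out."""
    df = _select_trait(pheno, trait)
    proto = _prototype(model, trait)
    phenotyped = set(df["individual"].unique())
    families: dict = {}
    for ind, fam in family_map.items():
        if ind in phenotyped:
            families.setdefault(fam, []).append(ind)
    skipped = sorted(set(family_map.values()) - set(families))
    fold_accs, assignments = [], {}
    for fam in sorted(families):
        held = set(families[fam])
        train = df[~df["individual"].isin(held)]
        if train.empty:
            raise ValueError(f"family {fam} spans the whole phenotyped population")
        test = df[df["individual"].isin(held)]
        fold_accs.append(_score_fold(train, test, kernels, proto))
        assignments[fam] = sorted(held)
    return CVResult(
        scheme="leave_family_out", accuracies=[float(np.nanmean(fold_accs))],
        fold_accuracies=[fold_accs], fold_assignments=[assignments],
        skipped=skipped,
    )


def leave_year_out_cv(
    pheno: pd.DataFrame,
    kernels,
    model: KernelGBLUP | None = None,
    trait: str | None = None,
) -> CVResult:
    """One fold per year: refit without that year, predict its records.

    The held-out year's fixed effect cannot be estimated from the
    training data; since every held-out record shares that single year,
    the unknown year constant does not affect the Pearson correlation,
    so observations are adjusted for the intercept only.
    """
    df = _select_trait(pheno, trait)
    proto = _prototype(model, trait)
    years = sorted(df["year"].unique())
    if len(years) < 2:
        raise ValueError("leave-year-out needs at least 2 years")
    fold_accs, assignments = [], {}
    for yv in years:
        train = df[df["year"] != yv]
        test = df[df["year"] == yv]
        fold_accs.append(_score_fold(train, test, kernels, proto, adjust_years=False))
        assignments[yv] = sorted(test["individual"].unique())
    return CVResult(
        scheme="leave_year_out", accuracies=[float(np.nanmean(fold_accs))],
        fold_accuracies=[fold_accs], fold_assignments=[assignments],
    )


def rank_stability(single_year_fits: dict, multi_year_fit: KernelGBLUP) -> pd.DataFrame:
    """Spearman rank correlation of single-year genetic values against the
    multi-year ranking, per year."""
    multi = genetic_summaries(multi_year_fit).values.set_index("individual")["genetic_value"]
    rows = []
    for yv, fit in single_year_fits.items():
        single = genetic_summaries(fit).values.set_index("individual")["genetic_value"]
        common = multi.index.intersection(single.index)
        if len(common) < 3:
            raise ValueError(f"fewer than 3 common individuals for year {yv}")
        rho, p = stats.spearmanr(single.loc[common], multi.loc[common])
        rows.append({"year": yv, "spearman_rho": float(rho), "p_value": float(p),
                     "n": len(common)})
    return pd.DataFrame(rows)
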