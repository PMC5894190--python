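"""Synthetic breeding-germplasm generator.

Emulates a clonally evaluated fruit-crop population: a founder pool in
Hardy-Weinberg equilibrium, full-sib families produced by Mendelian
gene-dropping at unlinked biallelic loci, and multi-year phenotypes whose
genetic effects are drawn from zero-mean multivariate normals with
covariances proportional to the additive, dominance and epistatic kernels
(plus year-interaction analogues) and a correlated repeated-measures
residual.  Because the effects are drawn directly from the kernel
covariances, the downstream mixed model is exactly correctly specified,
which makes parameter recovery a clean test surface.

The default scenario mirrors a population of 505 individuals (43 founders
plus 66 full-sib families of 7), 1615 markers and 3 trial years with the
first year the sparsest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, KernelSet

__all__ = [
    "PedigreeRecord",
    "SimulationScenario",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_founders",
    "make_pedigree",
    "gene_drop",
    "simulate_phenotypes",
    "simulate_dataset",
]

FOUNDER = "0"  # sire/dam marker for pedigree founders

GENETIC_TERMS = ("a", "d", "i")
INTERACTION_TERMS = ("aY", "dY", "iY")
#: scenario variance keys -> model term names
_SIGMA_KEYS = {"a": "a", "d": "d", "aa": "i", "aY": "aY", "dY": "dY", "aaY": "iY"}


@dataclass
class PedigreeRecord:
    individual_id: str
    sire_id: str = FOUNDER
    dam_id: str = FOUNDER
    family_id: str = ""

    @property
    def is_founder(self) -> bool:
        return self.sire_id == FOUNDER and self.dam_id == FOUNDER


def _check_corr(rho: tuple, n_years: int) -> np.ndarray:
    n_pairs = n_years * (n_years - 1) // 2
    rho = tuple(rho)
    if len(rho) != n_pairs:
        raise ValueError(f"need {n_pairs} residual year correlations for {n_years} years")
    C = np.eye(n_years)
    k = 0
    for i in range(n_years):
        for j in range(i + 1, n_years):
            if not -1.0 < rho[k] < 1.0:
                raise ValueError("residual year correlations must lie in (-1, 1)")
            C[i, j] = C[j, i] = rho[k]
            k += 1
    if np.linalg.eigvalsh(C).min() <= 0.0:
        raise ValueError("residual year correlation matrix is not positive definite")
    return C


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic trait.

    Variance components default to a bloom-date-like decomposition in
    which additive, dominance and epistatic main effects carry roughly
    33%, 11% and 17% of phenotypic variance, year interactions 11%, 4%
    and 2%, and the residual 21%.
    """

    n_founders: int = 43
    n_families: int = 66
    offspring_per_family: int = 7
    n_markers: int = 1615
    maf_distribution: tuple = (0.1, 0.5)
    sigma2: dict = field(
        default_factory=lambda: {
            "a": 0.3320, "d": 0.1080, "aa": 0.1747,
            "aY": 0.1116, "dY": 0.0423, "aaY": 0.0206,
        }
    )
    residual_variance: float = 0.2108
    residual_year_correlations: tuple = (0.2, 0.2, 0.2)
    n_years: int = 3
    years: tuple = (2010, 2011, 2012)
    year_means: tuple = (10.0, 12.0, 11.0)
    missing_pattern: tuple = (0.30, 0.05, 0.05)
    n_unphenotyped: int = 0
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        for key in _SIGMA_KEYS:
            self.sigma2.setdefault(key, 0.0)
            if self.sigma2[key] < 0.0:
                raise ValueError(f"variance component {key} must be nonnegative")
        if self.residual_variance < 0.0:
            raise ValueError("residual variance must be nonnegative")
        if len(self.years) != self.n_years or len(self.year_means) != self.n_years:
            raise ValueError("years/year_means length must equal n_years")
        if len(self.missing_pattern) != self.n_years:
            raise ValueError("missing_pattern length must equal n_years")
        self.residual_corr_matrix = _check_corr(self.residual_year_correlations, self.n_years)

    @property
    def n_individuals(self) -> int:
        return self.n_founders + self.n_families * self.offspring_per_family


@dataclass
class SimulationTruth:
    """Generating values recorded for parameter-recovery tests."""

    true_sigma2: dict
    residual_variance: float
    residual_corr_matrix: np.ndarray
    true_effects: dict  # term -> (n,) for a/d/i, (Y, n) for aY/dY/iY
    true_fixed: dict    # year -> mean

    def total_variance(self) -> float:
        return sum(self.true_sigma2.values()) + self.residual_variance

    def percentages(self) -> dict:
        """Generating variance shares on the 0-100 scale, residual included."""
        tot = self.total_variance()
        out = {k: 100.0 * v / tot for k, v in self.true_sigma2.items()}
        out["error"] = 100.0 * self.residual_variance / tot
        return out


def _coerce_maf(maf_distribution) -> tuple:
    if np.isscalar(maf_distribution):
        lo = hi = float(maf_distribution)
    else:
        lo, hi = map(float, maf_distribution)
        if lo >= hi:
            raise ValueError(f"degenerate maf bounds (min {lo} >= max {hi})")
    if not (0.05 < lo <= 0.5) or not (0.05 < hi <= 0.5):
        raise ValueError(f"maf bounds ({lo}, {hi}) must lie within (0.05, 0.5]")
    return lo, hi


def simulate_founders(
    n_founders: int,
    n_markers: int,
    maf_distribution=(0.1, 0.5),
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Unrelated founders in Hardy-Weinberg equilibrium.

    Per marker, an allele frequency is drawn uniformly from the MAF
    bounds (or fixed when a scalar is given) and dosages are sampled
    binomial(2, p), recoded to {-1, 0, 1}.  Markers whose realized MAF
    falls below 0.05 are redrawn.
    """
    if n_founders < 2 or n_markers < 1:
        raise ValueError("need n_founders >= 2 and n_markers >= 1")
    lo, hi = _coerce_maf(maf_distribution)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = rng.uniform(lo, hi, size=n_markers) if lo < hi else np.full(n_markers, lo)
    dosage = rng.binomial(2, p[None, :], size=(n_founders, n_markers)).astype(float) - 1.0
    for _ in range(200):
        freq = (dosage + 1.0).mean(axis=0) / 2.0
        bad = np.minimum(freq, 1.0 - freq) < 0.05
        if not bad.any():
            break
        dosage[:, bad] = rng.binomial(
            2, p[None, bad], size=(n_founders, int(bad.sum()))
        ).astype(float) - 1.0
    else:
        raise RuntimeError("could not realize MAF >= 0.05 for all markers")
    ids = np.array([f"F{k:04d}" for k in range(n_founders)], dtype=object)
    markers = np.array([f"snp{j:05d}" for j in range(n_markers)], dtype=object)
    return GenotypeMatrix(ids=ids, markers=markers, dosage=dosage)


def make_pedigree(
    n_founders: int,
    n_families: int,
    offspring_per_family: int,
    seed: int | np.random.Generator = 0,
) -> list:
    """Founders plus full-sib families from random distinct founder pairs."""
    if n_founders < 2:
        raise ValueError("need at least two founders to form families")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    founders = [f"F{k:04d}" for k in range(n_founders)]
    records = [PedigreeRecord(f) for f in founders]
    seen_pairs = set()
    for fam in range(n_families):
        for _ in range(1000):
            sire, dam = rng.choice(n_founders, size=2, replace=False)
            if (min(sire, dam), max(sire, dam)) not in seen_pairs:
                break
        seen_pairs.add((min(sire, dam), max(sire, dam)))
        fam_id = f"Fam{fam + 1:02d}"
        for k in range(offspring_per_family):
            records.append(
                PedigreeRecord(
                    individual_id=f"{fam_id}_{k + 1:02d}",
                    sire_id=founders[sire],
                    dam_id=founders[dam],
                    family_id=fam_id,
                )
            )
    return records


def gene_drop(
    founders: GenotypeMatrix,
    pedigree: list,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Drop founder alleles through the pedigree, one Mendelian sample per
    marker per parent (loci unlinked)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if not founders.is_complete:
        raise ValueError("founder genotypes must be complete")
    m = founders.n_markers
    genotyped: dict = {str(i): founders.dosage[k] for k, i in enumerate(founders.ids)}
    ids, rows = [], []
    for rec in pedigree:
        if rec.is_founder:
            if rec.individual_id not in genotyped:
                raise ValueError(f"founder {rec.individual_id} has no genotype")
            ids.append(rec.individual_id)
            rows.append(genotyped[rec.individual_id])
            continue
        for parent in (rec.sire_id, rec.dam_id):
            if parent not in genotyped:
                raise ValueError(
                    f"parent {parent} of {rec.individual_id} is not genotyped"
                )
        p1 = (genotyped[rec.sire_id] + 1.0) / 2.0  # transmission probabilities
        p2 = (genotyped[rec.dam_id] + 1.0) / 2.0
        child = (
            (rng.random(m) < p1).astype(float)
            + (rng.random(m) < p2).astype(float)
            - 1.0
        )
        genotyped[rec.individual_id] = child
        ids.append(rec.individual_id)
        rows.append(child)
    return GenotypeMatrix(
        ids=np.array(ids, dtype=object),
        markers=founders.markers.copy(),
        dosage=np.vstack(rows),
    )


def _chol_or_raise(K: np.ndarray, name: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"kernel {name} is not positive definite; bend it first "
            "(bend_to_invertible)"
        ) from None


def simulate_phenotypes(
    M: GenotypeMatrix,
    kernels: KernelSet,
    scenario: SimulationScenario,
    seed: int | np.random.Generator | None = None,
):
    """Draw one trait's multi-year phenotypes from the generating model.

    Returns ``(PhenotypeTable, SimulationTruth)`` where the table is a
    long-format DataFrame (individual, year, trait, value) with records
    deleted per the per-year missingness pattern.
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if not np.array_equal(M.ids, kernels.ids):
        raise ValueError("kernel individual order must match the genotype matrix")
    n, Y = M.n_individuals, scenario.n_years
    sig = {_SIGMA_KEYS[k]: v for k, v in scenario.sigma2.items()}

    chol_cache: dict = {}

    def draw(term: str, size: int) -> np.ndarray:
        s2 = sig[term]
        if s2 == 0.0:
            return np.zeros((size, n))
        base = {"a": "Ga", "d": "D", "i": "Gaa"}[term[0]]
        if base not in chol_cache:
            chol_cache[base] = _chol_or_raise(getattr(kernels, base), base)
        z = rng.standard_normal((size, n))
        return np.sqrt(s2) * z @ chol_cache[base].T

    effects = {t: draw(t, 1)[0] for t in GENETIC_TERMS}
    effects.update({t: draw(t, Y) for t in INTERACTION_TERMS})

    if scenario.residual_variance > 0.0:
        Lc = np.linalg.cholesky(scenario.residual_corr_matrix)
        E = np.sqrt(scenario.residual_variance) * rng.standard_normal((n, Y)) @ Lc.T
    else:
        E = np.zeros((n, Y))

    P = np.array(scenario.year_means)[None, :] + E
    for t in GENETIC_TERMS:
        P = P + effects[t][:, None]
    for t in INTERACTION_TERMS:
        P = P + effects[t].T

    observed = rng.random((n, Y)) >= np.asarray(scenario.missing_pattern)[None, :]
    if scenario.n_unphenotyped > 0:
        blank = rng.choice(n, size=scenario.n_unphenotyped, replace=False)
        observed[blank, :] = False

    ind_idx, year_idx = np.nonzero(observed)
    pheno = pd.DataFrame(
        {
            "individual": M.ids[ind_idx],
            "year": np.array(scenario.years)[year_idx],
            "trait": scenario.trait,
            "value": P[ind_idx, year_idx],
        }
    )
    truth = SimulationTruth(
        true_sigma2={_SIGMA_KEYS[k]: scenario.sigma2[k] for k in _SIGMA_KEYS},
        residual_variance=scenario.residual_variance,
        residual_corr_matrix=scenario.residual_corr_matrix.copy(),
        true_effects=effects,
        true_fixed=dict(zip(scenario.years, scenario.year_means)),
    )
    return pheno, truth


@dataclass
class SimulatedDataset:
    scenario: SimulationScenario
    genotypes: GenotypeMatrix
    pedigree: list
    family_map: dict
    kernels: KernelSet
    phenotypes: pd.DataFrame
    truth: SimulationTruth


def simulate_dataset(scenario: SimulationScenario | None = None) -> SimulatedDataset:
    """Run the whole generator: founders -> gene drop -> kernels -> phenotypes."""
    scenario = scenario or SimulationScenario()
    rng = np.random.default_rng(scenario.seed)
    founders = simulate_founders(
        scenario.n_founders, scenario.n_markers, scenario.maf_distribution, rng
    )
    pedigree = make_pedigree(
        scenario.n_founders, scenario.n_families, scenario.offspring_per_family, rng
    )
    genotypes = gene_drop(founders, pedigree, rng)
    kernels = KernelSet.from_genotypes(genotypes)
    phenotypes, truth = simulate_phenotypes(genotypes, kernels, scenario, rng)
    family_map = {
        r.individual_id: r.family_id for r in pedigree if r.family_id
    }
    return SimulatedDataset(
        scenario=scenario,
        genotypes=genotypes,
        pedigree=pedigree,
        family_map=family_map,
        kernels=kernels,
        phenotypes=phenotypes,
        truth=truth,
    )
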