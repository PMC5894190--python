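"""SNP dosage curation and genomic relationship matrices.

Dosages are coded -1/0/1 (copies of the positively counted allele minus
one); missing calls are ``nan``.  Three kernels are built from a curated
matrix:

* additive ``G_a`` — VanRaden: centered dosages ``H`` with
  ``G_a = H H' / (2 * sum_j p_j (1 - p_j))``;
* dominance ``D`` — Su: heterozygosity coding ``Z`` with
  ``D = Z Z' / sum_j 2 p_j q_j (1 - 2 p_j q_j)``;
* additive-by-additive epistasis ``G_aa = G_a ∘ G_a`` (Hadamard square).

Rank-deficient kernels are bent to positive definiteness by eigenvalue
clipping so that they can be inverted inside the mixed-model equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "GenotypeMatrix",
    "KernelSet",
    "GenotypeCurator",
    "curate_genotypes",
    "impute_missing",
    "additive_kernel",
    "dominance_kernel",
    "epistatic_kernel",
    "bend_to_invertible",
]

_LEGAL_DOSAGES = (-1.0, 0.0, 1.0)


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage calls.

    Attributes
    ----------
    ids : array of str, shape (n,)
    markers : array of str, shape (m,)
    dosage : float array, shape (n, m), entries in {-1, 0, 1} or nan
    allele_freq : per-marker frequency of the positively counted allele;
        populated after curation/imputation.
    """

    ids: np.ndarray
    markers: np.ndarray
    dosage: np.ndarray
    allele_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.markers = np.asarray(self.markers, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.markers)} markers"
            )
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not np.isin(finite, _LEGAL_DOSAGES).all():
            raise ValueError("dosage entries must be -1, 0, 1 or nan")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.dosage).any()

    def missing_fraction(self, axis: int = 1) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=axis)

    def compute_allele_freq(self) -> np.ndarray:
        """Frequency of the positive allele per marker, ignoring missing."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean((self.dosage + 1.0) / 2.0, axis=0)
        return p

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            ids=self.ids.copy(),
            markers=self.markers.copy(),
            dosage=self.dosage.copy(),
            allele_freq=None if self.allele_freq is None else self.allele_freq.copy(),
        )


class GenotypeCurator(BaseEstimator, TransformerMixin):
    """Filter individuals/markers, then impute remaining missing calls.

    The filter order is fixed: individuals missing more than
    ``max_missing`` of their calls are removed first, then markers are
    screened for missingness and minor allele frequency on the surviving
    individuals.  Allele frequencies are recomputed after imputation.

    Parameters
    ----------
    maf_min : minimum minor allele frequency retained (default 0.05).
    max_missing : maximum tolerated missing fraction for an individual or
        a marker (default 0.25).
    impute : whether to mean-impute after filtering (default True).
    """

    def __init__(self, maf_min: float = 0.05, max_missing: float = 0.25, impute: bool = True):
        self.maf_min = maf_min
        self.max_missing = max_missing
        self.impute = impute

    def fit(self, X: GenotypeMatrix, y=None) -> "GenotypeCurator":
        if X.n_individuals < 2 or X.n_markers < 1:
            raise ValueError("need at least 2 individuals and 1 marker")
        keep_ind = X.missing_fraction(axis=1) <= self.max_missing
        sub = X.dosage[keep_ind]
        with np.errstate(invalid="ignore"):
            marker_missing = np.isnan(sub).mean(axis=0)
            p = np.nanmean((sub + 1.0) / 2.0, axis=0)
        maf = np.minimum(p, 1.0 - p)
        keep_mark = (marker_missing <= self.max_missing) & np.isfinite(maf) & (maf >= self.maf_min)
        if not keep_mark.any():
            raise ValueError(
                f"all {X.n_markers} markers removed by curation "
                f"({int((~keep_ind).sum())} individuals dropped, "
                f"{int((marker_missing > self.max_missing).sum())} over the "
                f"missingness bound, remainder under MAF {self.maf_min})"
            )
        self.keep_individuals_ = keep_ind
        self.keep_markers_ = keep_mark
        self.n_individuals_removed_ = int((~keep_ind).sum())
        self.n_markers_removed_ = int((~keep_mark).sum())
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        if X.n_individuals != len(self.keep_individuals_):
            raise ValueError("matrix shape differs from the fitted one")
        dosage = X.dosage[np.ix_(self.keep_individuals_, self.keep_markers_)].copy()
        out = GenotypeMatrix(
            ids=X.ids[self.keep_individuals_],
            markers=X.markers[self.keep_markers_],
            dosage=dosage,
        )
        if self.impute:
            out = impute_missing(out)
        else:
            out.allele_freq = out.compute_allele_freq()
        return out


def curate_genotypes(
    raw: GenotypeMatrix, maf_min: float = 0.05, max_missing: float = 0.25
) -> GenotypeMatrix:
    """Apply the missingness and MAF filters (no imputation)."""
    return GenotypeCurator(maf_min=maf_min, max_missing=max_missing, impute=False).fit_transform(raw)


def impute_missing(M: GenotypeMatrix, seed: int | None = None) -> GenotypeMatrix:
    """Replace missing calls with the marker mean dosage rounded to the
    nearest legal dosage.

    Deterministic; ``seed`` is accepted for interface stability but
    unused.  Allele frequencies are recomputed on the completed matrix.
    """
    dosage = M.dosage.copy()
    col_mean = np.nanmean(np.where(np.isnan(dosage), np.nan, dosage), axis=0)
    if np.isnan(col_mean).any():
        bad = M.markers[np.isnan(col_mean)]
        raise ValueError(f"markers entirely missing, cannot impute: {list(bad)[:5]}")
    legal = np.array(_LEGAL_DOSAGES)
    rounded = legal[np.argmin(np.abs(col_mean[:, None] - legal[None, :]), axis=1)]
    rows, cols = np.nonzero(np.isnan(dosage))
    dosage[rows, cols] = rounded[cols]
    out = GenotypeMatrix(ids=M.ids.copy(), markers=M.markers.copy(), dosage=dosage)
    out.allele_freq = out.compute_allele_freq()
    return out


def _frequencies(M: GenotypeMatrix) -> np.ndarray:
    if not M.is_complete:
        raise ValueError("genotype matrix must be complete (curate and impute first)")
    p = M.allele_freq if M.allele_freq is not None else M.compute_allele_freq()
    p = np.asarray(p, dtype=float)
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("monomorphic marker (p in {0,1}); remove it before building kernels")
    return p


def additive_kernel(M: GenotypeMatrix) -> np.ndarray:
    """VanRaden additive genomic relationship matrix."""
    p = _frequencies(M)
    H = M.dosage - 2.0 * (p - 0.5)[None, :]
    denom = 2.0 * np.sum(p * (1.0 - p))
    return (H @ H.T) / denom


def dominance_kernel(M: GenotypeMatrix) -> np.ndarray:
    """Su dominance relationship matrix from heterozygosity coding."""
    p = _frequencies(M)
    w = 2.0 * p * (1.0 - p)  # expected heterozygosity per marker
    Z = np.where(M.dosage == 0.0, 1.0 - w[None, :], -w[None, :])
    denom = np.sum(w * (1.0 - w))
    if denom <= 0.0:
        raise ValueError("degenerate dominance scale (all markers at MAF 0.5 boundary?)")
    return (Z @ Z.T) / denom


def epistatic_kernel(Ga: np.ndarray) -> np.ndarray:
    """Additive-by-additive epistatic kernel: Hadamard square of G_a."""
    Ga = np.asarray(Ga, dtype=float)
    return Ga * Ga


def bend_to_invertible(
    K: np.ndarray, epsilon: float = 1e-6, return_info: bool = False
):
    """Make a symmetric kernel positive definite by eigenvalue clipping.

    Eigenvalues below ``epsilon`` are raised to ``epsilon`` and the matrix
    reconstructed; eigenvectors are untouched.  A matrix that already has
    all eigenvalues >= ``epsilon`` is returned unchanged.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kernel must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kernel must be symmetric")
    vals, vecs = np.linalg.eigh(K)
    if vals.min() >= epsilon:
        return (K, False, float(vals.min())) if return_info else K
    bent = (vecs * np.maximum(vals, epsilon)[None, :]) @ vecs.T
    bent = 0.5 * (bent + bent.T)
    return (bent, True, float(vals.min())) if return_info else bent


@dataclass
class KernelSet:
    """The three n x n relationship matrices over a fixed individual order."""

    ids: np.ndarray
    Ga: np.ndarray
    D: np.ndarray
    Gaa: np.ndarray
    bending_applied: dict = field(default_factory=dict)
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        for name in ("Ga", "D", "Gaa"):
            k = np.asarray(getattr(self, name), dtype=float)
            if k.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            setattr(self, name, k)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def kernel_for(self, term: str) -> np.ndarray:
        base = {"a": self.Ga, "d": self.D, "i": self.Gaa,
                "aY": self.Ga, "dY": self.D, "iY": self.Gaa}
        return base[term]

    @classmethod
    def from_genotypes(
        cls, M: GenotypeMatrix, bend: bool = True, epsilon: float = 1e-6
    ) -> "KernelSet":
        """Build G_a, D and G_aa = G_a ∘ G_a from a complete curated matrix.

        The Hadamard square is taken before bending, then each kernel is
        bent independently when ``bend`` is set.
        """
        Ga = additive_kernel(M)
        D = dominance_kernel(M)
        Gaa = epistatic_kernel(Ga)
        bending: dict = {}
        if bend:
            out = {}
            for name, K in (("Ga", Ga), ("D", D), ("Gaa", Gaa)):
                bent, applied, _ = bend_to_invertible(K, epsilon, return_info=True)
                out[name] = bent
                bending[name] = applied
            Ga, D, Gaa = out["Ga"], out["D"], out["Gaa"]
        return cls(ids=M.ids.copy(), Ga=Ga, D=D, Gaa=Gaa,
                   bending_applied=bending, epsilon=epsilon)
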