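"""Per-trait score statistics and their covariance for single-variant tests.

For each of K correlated phenotypes measured on N unrelated individuals, the
association between a genetic variant (minor-allele count G in {0,1,2}) and
the k-th phenotype is summarised by the score statistic

    T_k = U_k / sqrt(V_k),
    U_k = sum_i Y_ik (G_i - Gbar),
    V_k = (1/N) sum_i (Y_ik - Ybar_k)^2 * sum_i (G_i - Gbar)^2,

which is asymptotically N(0, 1) under the per-trait null of no association.
The vector T = (T_1, ..., T_K) is asymptotically multivariate normal; under
the global null its covariance converges to the phenotype correlation matrix,
estimated here by the Pearson sample correlation of Y.

Covariates are handled by residualising both the genotype and every phenotype
on [1, Z] with ordinary least squares and running the score test on the
residuals; the same linear residualisation is applied to binary traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

QUANTITATIVE = "quantitative"
BINARY = "binary"


def _as_matrix(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.ndim != 2:
        raise ValueError("phenotypes must be a vector or an N x K matrix")
    return y


@dataclass
class AssociationInput:
    """Genotype vector, N x K phenotype matrix and optional covariates.

    Genotypes are minor-allele counts (or real-valued residuals after
    covariate adjustment); binary phenotypes are coded 0/1. Rows with missing
    values must be removed by the caller before construction (complete-case).
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    covariates: np.ndarray | None = None
    trait_types: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=float).ravel()
        self.phenotypes = _as_matrix(self.phenotypes)
        n, k = self.phenotypes.shape
        if self.genotypes.shape[0] != n:
            raise ValueError(
                f"genotype length {self.genotypes.shape[0]} != phenotype rows {n}"
            )
        if n < 3:
            raise ValueError("need at least N = 3 individuals")
        if k < 1:
            raise ValueError("need at least one phenotype")
        if self.covariates is not None:
            self.covariates = _as_matrix(self.covariates)
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows do not match sample size")
        if not self.trait_types:
            self.trait_types = [QUANTITATIVE] * k
        if len(self.trait_types) != k:
            raise ValueError("trait_types length must equal number of phenotypes")
        for arr, what in ((self.genotypes, "genotypes"), (self.phenotypes, "phenotypes")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{what} contain missing or non-finite values")
        if np.ptp(self.genotypes) == 0:
            raise ValueError("genotype vector is constant (zero variance)")
        spans = np.ptp(self.phenotypes, axis=0)
        if np.any(spans == 0):
            bad = int(np.flatnonzero(spans == 0)[0])
            raise ValueError(f"phenotype column {bad} is constant (zero variance)")

    @property
    def n_samples(self) -> int:
        return self.phenotypes.shape[0]

    @property
    def n_traits(self) -> int:
        return self.phenotypes.shape[1]


@dataclass
class ScoreSummary:
    """Score-statistic vector T and its estimated covariance (correlation of Y)."""

    T: np.ndarray
    sigma_hat: np.ndarray
    N: int

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float).ravel()
        self.sigma_hat = np.asarray(self.sigma_hat, dtype=float)
        k = self.T.shape[0]
        if self.sigma_hat.shape != (k, k):
            raise ValueError("sigma_hat must be K x K")
        if not np.allclose(self.sigma_hat, self.sigma_hat.T, atol=1e-10):
            raise ValueError("sigma_hat must be symmetric")
        if not np.allclose(np.diag(self.sigma_hat), 1.0, atol=1e-8):
            raise ValueError("sigma_hat must have unit diagonal")

    @property
    def n_traits(self) -> int:
        return self.T.shape[0]


def _collinear_columns(design: np.ndarray) -> list[int]:
    """Indices of design columns (0 = intercept) linearly dependent on earlier ones."""
    bad = []
    rank = 0
    for j in range(design.shape[1]):
        r = np.linalg.matrix_rank(design[:, : j + 1])
        if r == rank:
            bad.append(j)
        rank = r
    return bad


def adjust_for_covariates(inp: AssociationInput) -> AssociationInput:
    """Replace genotypes and phenotypes by OLS residuals on [1, covariates].

    Returns a copy with the covariates field cleared; every residual column
    has mean zero. Raises on a rank-deficient design (naming the offending
    columns) or when N <= p + 1.
    """
    if inp.covariates is None or inp.covariates.shape[1] < 1:
        raise ValueError("no covariates to adjust for")
    z = inp.covariates
    n, p = z.shape
    if n <= p + 1:
        raise ValueError(f"N = {n} too small for p = {p} covariates (need N > p + 1)")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < p + 1:
        bad = _collinear_columns(design)
        names = ", ".join(
            "intercept" if j == 0 else f"covariate {j - 1}" for j in bad
        )
        raise ValueError(f"rank-deficient covariate design; collinear columns: {names}")
    targets = np.column_stack([inp.genotypes, inp.phenotypes])
    coef, *_ = np.linalg.lstsq(design, targets, rcond=None)
    resid = targets - design @ coef
    return AssociationInput(
        genotypes=resid[:, 0],
        phenotypes=resid[:, 1:],
        covariates=None,
        trait_types=list(inp.trait_types),
    )


def score_vector(genotypes: np.ndarray, phenotypes: np.ndarray) -> np.ndarray:
    """Vector of score statistics T_k = U_k / sqrt(V_k) for every column of Y."""
    g = np.asarray(genotypes, dtype=float).ravel()
    y = _as_matrix(phenotypes)
    n = g.shape[0]
    gc = g - g.mean()
    ssg = gc @ gc
    if ssg == 0:
        raise ValueError("zero variance: genotype vector is constant")
    yc = y - y.mean(axis=0)
    ssy = np.einsum("ij,ij->j", yc, yc)
    if np.any(ssy == 0):
        bad = int(np.flatnonzero(ssy == 0)[0])
        raise ValueError(f"zero variance: phenotype column {bad} is constant")
    u = yc.T @ gc
    return u / np.sqrt(ssy * ssg / n)


def score_statistic(genotypes: np.ndarray, phenotype_column: np.ndarray) -> float:
    """Score statistic for a single phenotype; asymptotically N(0,1) under H0."""
    return float(score_vector(genotypes, np.asarray(phenotype_column))[0])


def summarize(inp: AssociationInput) -> ScoreSummary:
    """Score statistics for every trait plus the sample correlation of Y.

    If covariates are present they are residualised out first (the
    correlation matrix is then the correlation of the residualised traits).
    """
    if inp.covariates is not None:
        inp = adjust_for_covariates(inp)
    t = score_vector(inp.genotypes, inp.phenotypes)
    k = inp.n_traits
    if k == 1:
        sigma = np.array([[1.0]])
    else:
        sigma = np.corrcoef(inp.phenotypes, rowvar=False)
        sigma = (sigma + sigma.T) / 2.0
        np.fill_diagonal(sigma, 1.0)
    return ScoreSummary(T=t, sigma_hat=sigma, N=inp.n_samples)


def align_signs(
    phenotypes: np.ndarray, reference_column: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Flip phenotype columns negatively correlated with a reference column.

    A convenience for making trait correlations predominantly positive before
    clustering (analogous to flipping traits like FEV1 whose clinical sign
    runs against the rest of a panel). Guarantees non-negative correlation of
    every column with the reference, not positivity of all pairwise
    correlations. Returns the aligned matrix and a boolean flip indicator.
    """
    y = _as_matrix(phenotypes).copy()
    k = y.shape[1]
    if k < 2:
        raise ValueError("sign alignment needs at least two phenotypes")
    if not 0 <= reference_column < k:
        raise ValueError("reference column out of range")
    corr = np.corrcoef(y, rowvar=False)[reference_column]
    flipped = corr < 0
    flipped[reference_column] = False
    y[:, flipped] *= -1.0
    if flipped.any():
        logger.info("align_signs flipped %d column(s): %s",
                    flipped.sum(), np.flatnonzero(flipped).tolist())
    return y, flipped


def drop_incomplete_rows(
    genotypes: np.ndarray,
    phenotypes: np.ndarray,
    covariates: np.ndarray | None = None,
):
    """Complete-case filter: remove rows with any missing value, logging the count."""
    g = np.asarray(genotypes, dtype=float).ravel()
    y = _as_matrix(phenotypes)
    keep = np.isfinite(g) & np.all(np.isfinite(y), axis=1)
    z = None
    if covariates is not None:
        z = _as_matrix(covariates)
        keep &= np.all(np.isfinite(z), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d incomplete row(s) of %d", dropped, keep.size)
    return g[keep], y[keep], (z[keep] if z is not None else None), dropped
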