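"""Factor-model simulator for correlated multi-trait GWAS data.

One common biallelic variant is drawn per dataset under Hardy-Weinberg
equilibrium at a given minor-allele frequency, and K quantitative traits are
generated from the factor model

    Y = lambda * G + c * gamma f + sqrt(1 - c^2) * eps,

with f ~ MVN(0, (1 - rho) I + rho J) a vector of R shared factors (J the
all-ones matrix), gamma a K x R block-diagonal loading matrix, eps i.i.d.
standard normal residuals, and lambda the vector of per-trait genetic
effects. Under the null (beta = 0) each trait is standard normal with
within-factor correlation c^2 and between-factor correlation rho * c^2.

Four effect layouts are provided:

* model 1 — one factor, the variant affects all traits: lambda = beta*(1..K);
* model 2 — two factors, the variant affects the second half of the traits
  with constant effect beta;
* model 3 — five factors, effects 0 on blocks 1-3, -beta on block 4 and an
  increasing ramp 2*beta/(k+1)*(1..k) on block 5 (k = K/5);
* model 4 — five factors, block effects 0, +beta, -beta, -ramp, +ramp.

Binary traits are produced by a liability threshold: an individual is
affected when the underlying quantitative value is at least one standard
deviation above (or, optionally, below) the trait mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MODEL_FACTORS = {1: 1, 2: 2, 3: 5, 4: 5}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class FactorModelSpec:
    """One simulation scenario: effect layout, trait panel and sample size."""

    model_id: int
    K: int
    N: int
    beta: float = 0.0
    c: float = 0.5
    rho: float = 0.6
    maf: float = 0.3
    binary_mask: np.ndarray | None = None
    seed: int | None = None
    binary_tail: str = "upper"

    def __post_init__(self):
        if self.model_id not in _MODEL_FACTORS:
            raise ValueError("model_id must be one of 1, 2, 3, 4")
        if self.K < 1 or self.N < 1:
            raise ValueError("K and N must be positive")
        r = self.R
        if self.K % r != 0:
            raise ValueError(f"model {self.model_id} needs K divisible by {r}")
        if not 0.0 <= self.c < 1.0:
            raise ValueError("c must lie in [0, 1)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.binary_mask is not None:
            self.binary_mask = np.asarray(self.binary_mask, dtype=bool).ravel()
            if self.binary_mask.size != self.K:
                raise ValueError("binary_mask length must equal K")
        if self.binary_tail not in ("upper", "lower"):
            raise ValueError("binary_tail must be 'upper' or 'lower'")

    @property
    def R(self) -> int:
        return _MODEL_FACTORS[self.model_id]


def half_binary_mask(K: int) -> np.ndarray:
    """Mask dichotomizing the second half of the trait panel (mixed setting)."""
    mask = np.zeros(K, dtype=bool)
    mask[K // 2:] = True
    return mask


def gen_genotypes(N: int, maf: float, seed=None) -> np.ndarray:
    """Minor-allele counts under HWE: P(g) = ((1-q)^2, 2q(1-q), q^2)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    if N < 1:
        raise ValueError("N must be positive")
    return _rng(seed).binomial(2, maf, size=N)


def build_effects(spec: FactorModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-trait genetic effects lambda and the K x R factor loading matrix gamma."""
    K, r, beta = spec.K, spec.R, spec.beta
    k = K // r
    gamma = np.kron(np.eye(r), np.ones((k, 1)))
    if spec.model_id == 1:
        lam = beta * np.arange(1, K + 1, dtype=float)
    elif spec.model_id == 2:
        lam = np.concatenate([np.zeros(k), np.full(k, beta)])
    elif spec.model_id == 3:
        ramp = 2.0 * beta / (k + 1) * np.arange(1, k + 1)
        lam = np.concatenate([np.zeros(3 * k), np.full(k, -beta), ramp])
    else:
        ramp = 2.0 * beta / (k + 1) * np.arange(1, k + 1)
        lam = np.concatenate([np.zeros(k), np.full(k, beta), np.full(k, -beta),
                              -ramp, ramp])
    return lam, gamma


def gen_factors(R: int, rho: float, N: int, seed=None) -> np.ndarray:
    """N x R factor draws, rows i.i.d. MVN(0, (1 - rho) I + rho J)."""
    if R < 1:
        raise ValueError("R must be positive")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    rng = _rng(seed)
    z = rng.standard_normal((N, R))
    if R == 1 or rho == 0.0:
        return z
    # Exact factorisation of the exchangeable covariance: shared + unique part.
    shared = rng.standard_normal((N, 1))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z


def gen_phenotypes(spec: FactorModelSpec, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw (genotypes, N x K quantitative phenotype matrix) from the factor model."""
    rng = _rng(spec.seed if seed is None else seed)
    g = gen_genotypes(spec.N, spec.maf, rng)
    lam, gamma = build_effects(spec)
    f = gen_factors(spec.R, spec.rho, spec.N, rng)
    eps = rng.standard_normal((spec.N, spec.K))
    y = np.outer(g, lam) + spec.c * (f @ gamma.T) + np.sqrt(1.0 - spec.c**2) * eps
    return g, y


def dichotomize(
    phenotypes: np.ndarray, binary_mask: np.ndarray, tail: str = "upper"
) -> np.ndarray:
    """Liability-threshold coding of masked columns at one SD from the mean.

    Affected (1) means at least one sample standard deviation above the column
    mean (tail='upper'; 'lower' thresholds one SD below). For a normal
    liability the case fraction is about Phi(-1) ~ 0.159.
    """
    y = np.array(phenotypes, dtype=float, copy=True)
    if y.ndim != 2:
        raise ValueError("phenotypes must be an N x K matrix")
    mask = np.asarray(binary_mask, dtype=bool).ravel()
    if mask.size != y.shape[1]:
        raise ValueError("binary_mask length must equal number of columns")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    if not mask.any():
        return y
    cols = y[:, mask]
    mu = cols.mean(axis=0)
    sd = cols.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(mask)[np.flatnonzero(sd == 0)[0]])
        raise ValueError(f"cannot dichotomize constant column {bad}")
    if tail == "upper":
        coded = cols >= mu + sd
    else:
        coded = cols <= mu - sd
    y[:, mask] = coded.astype(float)
    return y


def simulate_dataset(spec: FactorModelSpec, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes and phenotype matrix with any masked traits dichotomized."""
    g, y = gen_phenotypes(spec, seed=seed)
    if spec.binary_mask is not None and spec.binary_mask.any():
        y = dichotomize(y, spec.binary_mask, tail=spec.binary_tail)
    return g, y
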