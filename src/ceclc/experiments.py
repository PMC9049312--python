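"""Monte-Carlo type-I-error and power studies for the joint-trait tests.

Each replicate draws a fresh dataset from a factor-model scenario, runs the
full pipeline (score statistics, sample correlation, hierarchical clustering,
the requested tests) and records the p-values. Type-I-error runs require a
null scenario (beta = 0) and report, per nominal level alpha, the empirical
rejection rate divided by alpha together with the 95% binomial band around 1;
power runs require beta > 0 and report the rejection rate itself.

Replicate r uses the RNG stream default_rng([seed, r]), so results are
bit-identical regardless of how replicates are distributed over workers.
"""

from __future__ import annotations

import io
import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import clc
from .assoc import score_vector
from .clustering import all_cut_labels, build_tree
from .simulate import FactorModelSpec, simulate_dataset

logger = logging.getLogger(__name__)

METHODS = ("ceclc", "clc", "obrien", "omnibus")


@dataclass
class ExperimentConfig:
    """Scenario plus replication plan for one simulation experiment."""

    spec: FactorModelSpec
    n_replicates: int
    alpha_levels: tuple[float, ...] = (0.05,)
    methods: tuple[str, ...] = ("ceclc",)
    mc_for_clc: int = 1000
    seed: int = 0
    workers: int = 1
    linkage: str = "average"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for a in self.alpha_levels:
            if not 0.0 < a < 1.0:
                raise ValueError("alpha levels must lie in (0, 1)")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        amin = min(self.alpha_levels)
        if self.n_replicates < 1000 and amin <= 0.01:
            logger.warning(
                "only %d replicates at alpha = %g: rejection counts will be "
                "granular", self.n_replicates, amin,
            )


@dataclass
class ExperimentResult:
    """Rejection counts per (method, alpha) with ratio-to-nominal and 95% CI."""

    cells: dict
    n_replicates: int
    n_failures: int
    spec: FactorModelSpec
    seed: int
    kind: str
    runtime: float = 0.0

    def rate(self, method: str, alpha: float) -> float:
        return self.cells[(method, alpha)] / self.n_replicates

    def ratio(self, method: str, alpha: float) -> float:
        return self.rate(method, alpha) / alpha

    def ci(self, alpha: float) -> tuple[float, float]:
        return ci_for_ratio(alpha, self.n_replicates)


def ci_for_ratio(alpha: float, n_replicates: int) -> tuple[float, float]:
    """95% band for (empirical rate / alpha) under exact nominal calibration.

    1 -+ 1.96 * sqrt(alpha (1 - alpha) / n) / alpha, rounded to 4 decimals.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    half = 1.96 * np.sqrt(alpha * (1.0 - alpha) / n_replicates) / alpha
    return (round(1.0 - half, 4), round(1.0 + half, 4))


def _replicate_pvalues(
    spec: FactorModelSpec,
    rep_seed,
    methods: tuple[str, ...],
    mc_for_clc: int,
    linkage: str,
) -> dict[str, float]:
    rng = np.random.default_rng(rep_seed)
    g, y = simulate_dataset(spec, seed=rng)
    t = score_vector(g, y)
    if spec.K == 1:
        sigma = np.array([[1.0]])
    else:
        sigma = np.corrcoef(y, rowvar=False)
        sigma = (sigma + sigma.T) / 2.0
        np.fill_diagonal(sigma, 1.0)

    out: dict[str, float] = {}
    need_cuts = "ceclc" in methods or "clc" in methods
    if need_cuts:
        tree = build_tree(sigma, linkage=linkage, check=False)
        labels_all = all_cut_labels(tree)
    s_inv = clc._sigma_inverse(sigma)
    if need_cuts:
        comp_stats = clc._component_stats(t, s_inv, labels_all)
        p_l = stats.chi2.sf(comp_stats, df=np.arange(1, spec.K + 1))
    if "ceclc" in methods:
        guarded = clc._guard_pvalues(p_l)
        w = np.full(spec.K, 1.0 / spec.K)
        out["ceclc"] = clc._cauchy_pvalue(clc._cauchy_statistic(guarded, w))
    if "clc" in methods:
        out["clc"] = clc.clc_minp_test(
            t, sigma, n_mc=mc_for_clc, seed=rng, linkage=linkage
        ).p_value
    if "obrien" in methods:
        stat = clc._quadratic_stat(t, s_inv, np.zeros(spec.K, dtype=np.intp))
        out["obrien"] = float(stats.chi2.sf(stat, df=1))
    if "omnibus" in methods:
        stat = float(t @ s_inv @ t)
        out["omnibus"] = float(stats.chi2.sf(stat, df=spec.K))
    return out


def _run_chunk(config: ExperimentConfig, rep_indices) -> tuple[np.ndarray, int]:
    alphas = np.asarray(config.alpha_levels)
    counts = np.zeros((len(config.methods), alphas.size), dtype=np.int64)
    failures = 0
    for r in rep_indices:
        try:
            pv = _replicate_pvalues(
                config.spec, [config.seed, int(r)], config.methods,
                config.mc_for_clc, config.linkage,
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("replicate %d failed: %s", r, exc)
            failures += 1
            continue
        for mi, m in enumerate(config.methods):
            counts[mi] += pv[m] <= alphas
    return counts, failures


def _run(config: ExperimentConfig, kind: str) -> ExperimentResult:
    start = time.perf_counter()
    indices = np.arange(config.n_replicates)
    chunks = [indices[i: i + 1000] for i in range(0, config.n_replicates, 1000)]
    if config.workers > 1:
        from joblib import Parallel, delayed

        parts = Parallel(n_jobs=config.workers)(
            delayed(_run_chunk)(config, ch) for ch in chunks
        )
    else:
        parts = [_run_chunk(config, ch) for ch in chunks]
    counts = sum(p[0] for p in parts)
    failures = sum(p[1] for p in parts)
    if failures > 0.001 * config.n_replicates:
        raise RuntimeError(
            f"{failures} of {config.n_replicates} replicates failed (> 0.1%)"
        )
    cells = {
        (m, float(a)): int(counts[mi, ai])
        for mi, m in enumerate(config.methods)
        for ai, a in enumerate(config.alpha_levels)
    }
    return ExperimentResult(
        cells=cells,
        n_replicates=config.n_replicates,
        n_failures=failures,
        spec=config.spec,
        seed=config.seed,
        kind=kind,
        runtime=time.perf_counter() - start,
    )


def run_type1(config: ExperimentConfig, _allow_alternative: bool = False) -> ExperimentResult:
    """Empirical type-I-error study; requires a null scenario (beta = 0)."""
    if config.spec.beta != 0.0 and not _allow_alternative:
        raise ValueError("type-I-error study requires beta = 0 (null scenario)")
    return _run(config, kind="type1")


def run_power(config: ExperimentConfig, _allow_null: bool = False) -> ExperimentResult:
    """Empirical power study; requires an alternative scenario (beta > 0)."""
    if config.spec.beta <= 0.0 and not _allow_null:
        raise ValueError("power study requires beta > 0 (alternative scenario)")
    return _run(config, kind="power")


def render_tables(results) -> str:
    """TSV report of one or more experiment results (one row per cell).

    The `flag` column marks type-I-error ratios falling outside the 95%
    binomial band ci_for_ratio(alpha, n_replicates).
    """
    if isinstance(results, ExperimentResult):
        results = [results]
    rows = []
    for res in results:
        for (method, alpha), count in sorted(res.cells.items()):
            lo, hi = res.ci(alpha)
            ratio = res.ratio(method, alpha)
            rows.append({
                "kind": res.kind,
                "model": res.spec.model_id,
                "K": res.spec.K,
                "N": res.spec.N,
                "beta": res.spec.beta,
                "method": method,
                "alpha": alpha,
                "n_replicates": res.n_replicates,
                "rejections": count,
                "rate": res.rate(method, alpha),
                "ratio": ratio,
                "ci_low": lo,
                "ci_high": hi,
                "flag": "" if lo <= ratio <= hi else "outside_ci",
            })
    cols = ["kind", "model", "K", "N", "beta", "method", "alpha", "n_replicates",
            "rejections", "rate", "ratio", "ci_low", "ci_high", "flag"]
    df = pd.DataFrame(rows, columns=cols)
    return df.to_csv(sep="\t", index=False)


def parse_tables(text: str) -> pd.DataFrame:
    """Inverse of render_tables for the numeric grid."""
    return pd.read_csv(io.StringIO(text), sep="\t")
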