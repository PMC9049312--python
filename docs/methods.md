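# Methods

## Model and test construction

The package tests `H₀: β₁₁ = … = β₁K = 0` — no association between one
genetic variant and any of `K` correlated traits — without fitting the
per-trait generalized linear models that define those coefficients. Each
trait enters through the score statistic `T_k = U_k/√V_k` with
`U_k = Σᵢ Y_ik (Gᵢ − Ḡ)` and `V_k = (1/N) ΣᵢY²c Σᵢ G²c` (centered sums of
squares). The same formula serves quantitative and 0/1 traits: for a binary
trait it is the logistic score numerator with a pooled variance estimate,
which is asymptotically equivalent under the null. Only the square root of
`V_k` gives the statistic unit null variance, which the multivariate normal
approximation for `T` requires; the implementation therefore uses `U/√V`
throughout.

Under the null the covariance of `T` converges to the trait correlation
matrix, so Σ is estimated by the Pearson sample correlation `P^s(Y)` of the
phenotype matrix — after covariate residualization when covariates are
supplied, since the residualized traits are what generate the statistics.
Covariate adjustment is ordinary least squares of both `G` and each `Y_k`
on `[1, Z]`, for binary traits as well; this is the standard linear
projection trick and keeps the score statistics free of confounding by
measured covariates. Rows with any missing value are dropped before
analysis (complete-case) with a logged count.

## Clustering

Traits are clustered agglomeratively on the dissimilarity `1 − r`.
Negative correlations give distances above 1 and are deliberately not
folded by absolute value: the linear combinations pool *positively*
correlated traits, and anticorrelated traits should join clusters last (or
be sign-aligned first; `align_signs` flips columns negatively correlated
with a chosen reference trait, mirroring the common practice of reversing
clinically inverted measures such as FEV1 before a joint analysis).

Average linkage (UPGMA) is the default, with complete and single linkage
selectable; the literature behind the CLC family does not pin the linkage
down, and UPGMA is the usual choice for correlation-distance trait
clustering. The agglomeration is implemented in-package so ties are broken
deterministically — at equal merge heights the pair whose smallest leaf
indices are lexicographically least merges first — which makes trees
reproducible across platforms (scipy's linkage agrees whenever distances
are distinct, and is used as a cross-check in the tests). Merge heights are
monotone for all three linkages, so every cut `L = 1…K` is well defined by
undoing the last `L − 1` merges; the cuts form a refinement chain.

## Aggregation over the number of clusters

For each cut the CLC quadratic form is evaluated as
`v ᵀ M⁻¹ v` with `v = Zᵀ Σ̂⁻¹ T` and `M = Zᵀ Σ̂⁻¹ Z` (`Z` the cluster
indicator), an algebraic collapse of `(WT)ᵀ(WΣWᵀ)⁻¹(WT)` that avoids
forming `W`. Degrees of freedom equal the number of clusters in the cut.
Two closed forms are used where they are exact: `L = 1` gives
`(1ᵀΣ̂⁻¹T)²/(1ᵀΣ̂⁻¹1)` and `L = K` gives `TᵀΣ̂⁻¹T`.

* **ceCLC** transforms each `p_L` to `tan{(0.5 − p_L)π}` and averages with
  equal weights `1/K`; the p-value is `0.5 − arctan(·)/π`. The Cauchy tail
  is insensitive to dependence among the `p_L`, which is what licenses the
  closed form. The computation is entirely deterministic — a test asserts
  that no random draw happens anywhere in it.
* **min-p CLC** keeps the historical statistic `min_L p_L` and evaluates
  its null by Monte Carlo: draws `T′ ~ MVN(0, Σ̂)` reuse the membership
  matrices of the observed Σ̂, because the clustering input does not change
  across draws under this null, so re-clustering every draw would
  reproduce identical cuts at extra cost. The p-value uses the add-one
  estimator `(1 + #{min′ ≤ min})/(n_mc + 1)`, which can never return 0.

Numerical guards: `p_L < 10⁻¹⁵` replaces the tangent by its asymptotically
exact tail form `1/(p·π)` (avoiding cancellation in the tangent argument);
combined statistics above `10¹⁵` use the matching tail `1/(π·stat)` for the
p-value; p-values of exactly 0 or 1 are clipped (to `10⁻³⁰⁰` and
`1 − 10⁻¹⁵`) with a warning. A singular or near-singular Σ̂ — duplicate
traits being the typical cause — receives a ridge of `10⁻⁸·I` before
inversion, with a warning; the ridge leaves well-conditioned matrices
essentially untouched (pivots of a 20-trait sample correlation are orders
of magnitude larger) while keeping every quadratic form finite.

## The simulator

`Y = λG + cγf + √(1−c²)·ε` with `G ~ Binomial(2, MAF)` (Hardy–Weinberg),
factors `f ~ MVN(0, (1−ρ)I + ρJ)` generated exactly via the exchangeable
decomposition `√ρ·shared + √(1−ρ)·unique`, loadings `γ` block-diagonal over
equal-size factor blocks, and standard normal residuals. Defaults follow
the study conditions this family of tests was characterized under:
`MAF = 0.3`, `c = 0.5`, `ρ = 0.6`, so under the null each trait is
standard normal with within-block correlation `c² = 0.25` and cross-block
correlation `ρc² = 0.15`. The four effect layouts (`model_id`):

1. one factor, effects `β·(1,…,K)` on all traits;
2. two factors, effect `β` on the second half of the traits only;
3. five factors, blocks `0, 0, 0, −β, +ramp` where
   `ramp = 2β/(k+1)·(1,…,k)`, `k = K/5`;
4. five factors, blocks `0, +β, −β, −ramp, +ramp`.

Binary traits come from the liability threshold: affected ⇔ the underlying
quantitative value is at least one *sample* standard deviation above the
column mean (≈ 15.9% cases for a normal liability). The threshold uses the
sample mean/SD rather than the theoretical 0/1 because real analyses only
ever see the sample; a flag selects the lower tail instead, which is
distributionally equivalent by symmetry. In the mixed
quantitative-plus-binary setting the *second* half of the trait vector is
dichotomized by default (configurable) — the layout is symmetric under
Model 1, the setting where the mixed panel is studied here. One variant is
simulated per dataset; linkage disequilibrium, rare variants and
population structure are out of scope.

What passing simulation tests does *not* show: the generator has no LD, no
confounding, no trait-specific measurement error, exact exchangeable factor
structure, and normal liabilities; calibration and power on real panels
with heavier-tailed traits or misspecified clusters can differ.

## Experiments

`run_type1` / `run_power` draw a fresh dataset per replicate and run the
full pipeline. Replicate `r` uses the stream `default_rng([seed, r])`, so
rejection counts are bit-identical for any worker count (joblib parallelism
over fixed 1000-replicate chunks). A replicate that fails validation (e.g.
a degenerate binary column) is logged and skipped; more than 0.1% failures
aborts the run. The reported quantity per `(method, α)` cell is the
rejection count, the rate, the rate/α ratio, and the 95% band
`1 ± 1.96·√(α(1−α)/n)/α` around perfect calibration (rounded to 4
decimals, as conventionally reported).

Problem sizes used by the shipped studies: the null-calibration cells run
10⁵ replicates of `K = 20`, `N = 1000` (the historical tables use 10⁶; at
10⁵ the 95% band is (0.8041, 1.1959), wide enough to be meaningful while
cheap enough for a desk run); uniformity checks use 2×10⁴ replicates of
`K = 10`, `N = 500`; power comparisons use 500 replicates at `N = 3000`,
`K = 20`. The power effect sizes (β around 0.015–0.045) were chosen to put
ceCLC in the informative mid-power range at `N = 3000`, since power
orderings are uninformative at floor or ceiling; published power curves for
these tests are graphical only, so all power checks are property-based
(null ≈ α, monotone in β, ceCLC ≥ omnibus under group structure) rather
than numeric targets.

## Known limitations

* The Cauchy-combination p-value is designed for, and accurate in, the
  deep tail (the genome-wide regime, α ≤ 10⁻³, where the calibration
  studies run). At moderate significance levels (α around 0.05–0.1) the
  combination of strongly dependent `p_L` is mildly anticonservative — the
  empirical size runs on the order of 10% above nominal. This is a
  property of the aggregation itself, not of the pipeline: it persists
  when `T` is drawn exactly from MVN(0, Σ) with Σ known and the clustering
  fixed. Size-style checks at α = 0.05 in this package therefore use
  bands that tolerate that mild inflation, while the tail calibration
  checks use the strict binomial bands.
* The multivariate normal approximation for `T` (and hence every p-value)
  is asymptotic; very small `N`, very rare variants or extremely
  unbalanced binary traits will degrade tail calibration.
* The "O'Brien" and "omnibus" entries are interpretations: they implement
  the `L = 1` and `B = I` special cases of the CLC framework, which is how
  those comparisons are conventionally realized, but they are not
  re-derivations of the original publications' estimators.
* `align_signs` is a greedy convenience (non-negative correlation with one
  reference trait); it does not guarantee an all-positive correlation
  matrix, and trait-flip choices driven by domain knowledge should be made
  upstream.
* Related individuals, imputation, mixed models and GWAS-summary-only
  operation are out of scope.
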