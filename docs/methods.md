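# Methods

## Hybridization metrics from flora counts

The unit of observation is a (genus, flora) record: the number of nonhybrid
species and the number of distinct hybrid combinations (a hybrid is a unique
pair of parental species that has interbred, counted once per flora however
often the pair hybridized there). Intergeneric hybrids are split between the
two parent genera at weight ½ each; half-integer counts are carried exactly
through all downstream computation. Records flagged as "multiple hybrids
without specification" have their hybrid count replaced by
max(2, 0.2 · species present), applied per record before any summation.

Per genus, n and H are plain sums over floras — no de-duplication of species
or hybrid pairs that recur in several regions — so the metrics mix how many
taxa hybridize with how often they do so across regions, and genus-level
propensity can exceed 100%. An alternative that counts distinct species
across floras is deliberately not implemented: summation is the documented
convention of this kind of compilation, and the package's validators treat
the summed quantities as canonical. Genera observed a single time, with one
nonhybrid species and no hybrids, carry no information about hybridization
and are excluded. Family metrics are genus metrics averaged with
genus-species-count weights (family n and H are sums), which equals pooling
species directly.

Both metrics include zeros, so the log transform used before regression is
ln(x + offset) with offset 1 by default (on the percent scale for
propensity and the ratio scale for the ratio). Offset 1 maps zero to zero
and preserves ordering; it is configurable, and a zero offset is rejected
whenever a metric contains zeros.

## Trait scoring

Categorical traits are coded 0 / 0.5 / 1 (0.5 for mixed or combined states);
the Red List scale runs 0 (LC) to 5 (EX/EW); outcrossing rate t is a
proportion; agricultural status is the crop fraction. Compound life-history
states split unit mass equally over the listed categories. The perenniality
score is w(perennial) + ½·w(biennial): a pure biennial is treated as halfway
between annual and perennial, which makes the three-way compound
annual/biennial/perennial score 0.5 and keeps the scale monotone in
life-span. Taxon values are unweighted means over all scored species;
family means pool species directly. Missing traits are never imputed or
zero-filled — each analysis prunes to its complete cases, so sample sizes
differ per trait and are logged.

Genome size (C-value, picograms) is summarized in a fixed order: mean over
ploidy variants within a species → mean over species within the taxon → log.
The coefficient of variation is sd/mean across the per-(species,
ploidy-level) mean C-values of the taxon, with the sample sd (ddof = 1) by
default (population sd available via `ddof=0`); a single value gives CV 0.
CV is scale-invariant and the log-mean shifts by ln k under rescaling, which
the tests assert.

## Tree covariances

Trees are rooted, branch lengths required, polytomies allowed and never
randomly resolved (the covariance construction handles them natively;
random resolution would inject undocumented stochasticity). Pruning takes
the induced subtree and keeps the removed basal path as the root edge, so
root-to-tip depths — and hence covariances — of retained taxa are unchanged;
this makes pruning commute exactly with row/column selection of the BM
matrix, which is tested on random trees.

- BM: C_ij = shared root-to-tip path length; diagonal = depths.
- Pagel's λ: off-diagonals × λ, λ ∈ [0, 1]. The positive-semidefinite
  extension above 1 is not implemented; reported estimates live in [0, 1].
- OU (stationary form), requiring ultrametricity within relative tip-depth
  spread 1e-6: C_ij = exp(−2α(T − t_ij))(1 − exp(−2α t_ij))/(2α); below
  α = 1e-9 the BM limit is returned analytically.
- EB: C_ij = (exp(r t_ij) − 1)/r for r < 0, BM at r = 0.

Zero-length terminal branches make BM covariance singular; they trigger a
warning and a diagonal jitter of 1e-8 × tree depth on the affected tips.
Any covariance that fails Cholesky factorization receives a one-off
diagonal jitter of 1e-10 × trace before erroring out.

## GLS, Pagel's λ, and PGLS

All fits are maximum likelihood, not REML, because λ likelihood-ratio tests
and AIC comparisons across models with different fixed effects require
comparable likelihoods; standard errors use the small-sample n − p residual
variance. The estimator is Cholesky-whitened OLS; its agreement with the
explicit GLS normal equations (to 1e-10) and with regression through the
origin on independent contrasts (to 1e-8, the module's primary correctness
anchor) is asserted in the acceptance tests. Designs with condition number
above 1e12 raise a collinearity error; responses with zero residual
variance are flagged degenerate rather than producing spurious statistics.

λ is profiled by bounded scalar ML on [0, 1] (tolerance 1e-8), with the
boundary values always evaluated as candidates so the reported optimum
dominates both endpoints. The LRT against λ = 0 is referred to χ²₁ and the
statistic clamped at zero — λ̂ on the boundary can yield tiny negative
differences that are numerical noise. The χ²₁ reference is anti-conservative
at the λ = 0 boundary (the asymptotic null is a 50:50 mix of 0 and χ²₁);
the conventional χ²₁ version is kept because it is the standard reported
form for this quantity.

PGLS under OU/EB profiles the covariance parameter by bounded ML with
bounds tied to tree depth T — α ∈ [1e-8, 50/T], r ∈ [−10/T, 0] — to prevent
overflow at effectively infinite pull or decay; boundary candidates compete
with the interior optimum. AIC counts regression coefficients + σ² + any
profiled covariance parameter; slope p-values are two-sided t on n − p df.
R² is deviance-based: 1 − RSS_C(model)/RSS_C(intercept-only) with both fits
under the model's own fitted covariance, adjusted as
1 − (1 − R²)(n − 1)/(n − p − 1); small negative adjusted values are expected
for null predictors. When every covariance model lies within 2 AIC of the
best, BM is reported as representative (ties are uninformative about the
covariance, and BM is the simplest member); otherwise the AIC-best model is.
Benjamini–Hochberg runs within each metric × taxonomic-level family of
tests at q = 0.05 by default.

## Path analysis

Candidate DAGs are ranked on a single common complete-case taxon set (so C
and CICc are comparable), with all variables z-scored on that set —
standardized coefficients are the interpretable scale for cross-trait paths.
The d-separation basis pairs each non-adjacent (x, y) — x before y in a
lexicographic topological order — with conditioning set parents(x) ∪
parents(y); each claim is tested by the two-sided p-value of x in a
BM-PGLS of y on the conditioning set plus x. Claim p-values are floored at
1e-300 before logs. The CICc parameter count is q = edges + nodes (the
convention of the d-separation software family this mirrors; configurable
to edges only). Ties in CICc break by fewer edges, then model name. The
default candidate set holds five DAGs over woodiness W, perenniality P and
hybridization H: the two chains W→P→H and P→W→H, each chain plus the
remaining direct edge, and the fully-saturated variant with both direct
paths.

A structural property of CICc worth knowing: a model nested inside a
saturated competitor differs by ~2 penalty units per extra parameter at
large n, while its extra d-separation claim contributes C = −2 ln p ~ χ²₂
when true. The sparser true model therefore wins only when its claim's
p-value exceeds ≈ e⁻¹ ≈ 0.37, i.e. in about 64% of datasets no matter how
strong the true paths are or how many taxa are sampled — CICc selection
between a true chain and its saturated extension is not consistent. The
package's own recovery experiment (`path_chain_recovery_rate` in
`scripts/acceptance.py`, and the corresponding acceptance test) measures
exactly this: observed rates near 0.64–0.70 at n = 500. Whenever the chain
does win, the winning fit retains the direct perenniality→hybridization
path and no direct woodiness path (`path_winner_structure_ok`). The firm
conclusions from such an analysis are directional — which chain is rejected
(the reverse chain's claim fails catastrophically under strong true paths)
and what the best model's coefficients are — not the sparse-vs-saturated
choice itself.

## Synthetic data

The generator emulates the structure of a flora-compilation study: a Yule
(pure-birth, hence ultrametric) phylogeny; taxon-level trait scores evolved
as correlated Brownian motion with per-trait λ (bounded scores squashed to
(0, 1) by the logistic); and hybrid counts from
H_i ~ Poisson(exp(β₀ + Σβ_t z_ti + ε_i) · n_i(n_i − 1)/2), where n_i is a
shifted negative-binomial genus size (minimum 2, mean 8, shape 1 — genus
sizes are heavily right-skewed), z are standardized trait scores, and ε is
unit-scaled Brownian noise (sd 0.5). The pair-count offset makes planted
effects act on propensity rather than raw counts. β₀ = −3.5 sets baseline
propensity near exp(−3.5) ≈ 3%, the few-percent scale typical of such
compilations. Counts are scattered over 8 floras in proportion to each
flora's share of the genus's species, so aggregation recovers the totals
exactly (asserted). Scenario defaults: the null plants no effects; the
perenniality-driven scenario uses a log-rate slope of 0.8 per trait SD;
the chain-causal scenario couples woodiness→perenniality at path 0.5 and
perenniality→hybrid rate at 0.3; the family-structured scenario adds a
genus→family map cut from clades older than 35% of tree depth.

For calibration and path-recovery experiments there is a separate Gaussian
generator (`simulate_path_dataset`) that draws W, P, H directly under the
chain DAG with unit-diagonal BM errors — count noise would otherwise
confound the exactness of the χ² calibration being tested.

What the generator does not emulate: flora-specific recording effort and
geographic bias, taxonomic error, hybrid age/type structure, correlations
between genus size and traits, and non-Brownian trait evolution. Passing
tests therefore demonstrate correctness of the estimators under their
assumed models, not robustness of the biological conclusions to violations
of those assumptions.

All generators are pure functions of (configuration, seed); benchmark
datasets serialize byte-identically across runs, and child seeds are spawned
from one root sequence so component experiments are independently
reproducible.

## Problem sizes

The default verification experiments use: 10⁴ random count pairs for the
metric identity; 100 GLS instances of 10–50 taxa; 50 contrasts trees of 32
tips; λ recovery at 500 tips × 20 replicates per generating λ; PGLS type-I
error over 500 replicates at 200 taxa; Fisher's C calibration over 500–1000
replicates at 300 taxa; CICc recovery over 100 replicates at 500 taxa; and
an end-to-end study of 200 genera across 8 floras. These sizes give stable
rates while keeping a full verification run in the minutes range.

## Known limitations

- λ is restricted to [0, 1]; the boundary LRT uses the conventional χ²₁.
- OU assumes ultrametric trees (the stationary form is not defined
  otherwise here); non-ultrametric input errors out rather than silently
  rescaling.
- Multivariate PGLS with many predictors is out of scope: with per-trait
  missingness, complete-case multivariate designs collapse; the univariate
  regressions plus the path analysis over the two near-complete traits are
  the supported designs.
- CICc cannot consistently prefer a true sparse DAG over its saturated
  extension (see above); interpret model selection output accordingly.
- The flora counting conventions (summation across floras, the 20% rule,
  the ½ intergeneric split) are faithful to compilation practice but are
  conventions, not estimators of a population quantity.
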