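# Methods

## The model

Body weight of bird *i* with dam *j* is modelled as

    y_ij = x_i' b + a_i + m_j + pe_j + e_i + eps_i

where `b` are fixed effects (hatch within selection round, sex, dam-age
class), `a_i` is the bird's direct additive genetic effect, `m_j` the
dam's maternal genetic effect, `pe_j` her permanent environmental effect
on offspring, `e_i` the bird's own environmental deviation and `eps_i` a
*dummy residual*. Genetic effects are distributed `(a, m) ~ N(0, A ⊗ G0)`
with `A` the pedigree numerator relationship matrix. The defining feature
of the parameterization is on the environmental side: the residual `e` is
declared an ordinary random effect with one level per phenotyped animal,
and a dam's own `e` and her `pe` form a joint per-individual block

    Var(e_j, pe_j) = E0 = [[σ²_e, σ_e.pe], [σ_e.pe, σ²_pe]],

while `eps ~ N(0, σ²_dummy I)` with `σ²_dummy` *fixed* (default 1, never
estimated). Because the least-squares residual of the equations is only
the fixed dummy, `σ²_e` becomes estimable as a variance component that
may covary with `pe` — this is what makes the direct–maternal
*environmental* covariance reachable with ordinary REML machinery. The
operational residual variance of the trait is `σ²_e + σ²_dummy`.

Five nested variants are supported (free-parameter counts in the
univariate case):

| model    | maternal genetic | Cov(a,m) | Cov(e,pe) | free |
|----------|------------------|----------|-----------|------|
| moda     | –                | 0        | 0         | 3    |
| modam    | yes              | 0        | 0         | 4    |
| coram    | yes              | free     | 0         | 5    |
| corepe   | yes              | 0        | free      | 5    |
| coramepe | yes              | free     | free      | 6    |

In bivariate mode female and male body weight are distinct traits of
distinct individuals. A dam keeps one `pe` per offspring sex; her own
residual is the female-trait `e_F`, so every covariance of the male
residual with maternal effects is structurally zero, and `Cov(e_F,e_M)`
is zero because no individual has both records.

### Conventions

* Heritability: `h² = σ²_a / (σ²_a + σ²_m + σ²_pe + σ²_e + σ²_dummy)`,
  the maternal term omitted when the model excludes it and covariance
  terms never included. This convention reproduces published
  heritabilities from the corresponding component sets to two decimals,
  which is how it was chosen; the dummy contribution (1 g² against ~21000)
  is numerically irrelevant but kept for exactness.
* Restricted likelihood: `-2logL = log|C| + log|G| + log|R| + y'Py`,
  identical to the dense form `log|V| + log|X'V⁻¹X| + y'Py`; the additive
  constant `(n − rank X) log 2π` is dropped everywhere, consistently
  between the sparse path and the dense reference oracle.
* Fixed-effect identifiability: one intercept per trait plus
  drop-first-level contrasts per factor.
* Records with an unknown dam keep their own `a` and `e` but carry no
  maternal links; their count is reported by the design builder.

## Estimation

Free (co)variance parameters are estimated by average-information (AI)
REML. Per iteration the mixed-model equations are assembled
(`C = W'R⁻¹W + diag(0, A⁻¹ ⊗ G0⁻¹, Σ_env⁻¹)`, `R = σ²_dummy I`) and
factorized as sparse LDL'; the BLUP solution, the log-determinant and
*selected* entries of `C⁻¹` (posterior covariances, computed by Takahashi
recurrences on the factor pattern) feed three quantities:

* the exact gradient of `-2logL` in the free parameters,
* the AI matrix from working variates solved against the same equations,
* the EM update (for the environmental covariance the EM treats each
  individual's `(e, pe)` profile as a multivariate normal vector with a
  per-individual missingness pattern, filling absent components by their
  conditional moments).

An AI proposal whose blocks leave the positive-definite cone, or that
fails to decrease `-2logL`, is step-halved; if no damped step is
acceptable the EM update is used for that iteration, so `-2logL` never
increases beyond numerical noise. Projection ("bending", eigenvalue
clipping at 1e-8 of the block's largest eigenvalue) is applied only to
starting values and EM output, never to AI proposals — projecting a
Newton proposal destroys its descent property and traps iterates on the
cone boundary.

Numerical choices worth knowing:

* The sparsity pattern of `C` is constant across iterations, so the
  fill-reducing ordering and symbolic analysis are done once per fit and
  only the numeric factorization repeats.
* Free covariances that sit exactly at zero would put exact zeros into
  the precision matrices, and sparse kernels prune such entries from
  their stored patterns — losing exactly the inverse entries the trace
  terms need. Assembly therefore offsets such entries by a relative
  1e-10, which is invisible at the likelihood's resolution.
* `-2logL` evaluated through refactorization is reproducible to about
  1e-7 relative; with datasets of 10^4 records the likelihood magnitude
  is ~10^5, so absolute changes below ~0.01 are noise. Step acceptance
  and convergence account for this floor: the iteration stops when the
  relative parameter change falls below `tol_param` (1e-8) with a flat
  likelihood, or after two consecutive iterations at the noise floor
  with parameters moving less than 1e-4 relative; the best visited point
  is returned.
* Default starting values split the raw phenotypic variance 40% residual
  / 30% direct / 10% maternal / 10% permanent environmental, covariances
  zero. Warm-starting a model from the optimum of the model nested in it
  both saves iterations and guarantees non-negative likelihood-ratio
  statistics; the likelihood-ratio helper reports degrees of freedom as
  the plain difference in free-parameter counts (no boundary mixture
  correction, matching common practice in this literature).
* Standard errors come from the inverse AI matrix at convergence.

Datasets with weakly identified maternal components (few offspring per
dam, shallow pedigrees) can have their REML optimum on or near the
boundary (`σ²_m → 0`); there AI proposals are mostly rejected and the EM
fallback converges only geometrically, so such fits may end with status
`max_iterations` while being numerically adequate. The boundary is a
property of the data, not of the optimizer; well-structured maternal
designs (≥10 offspring per dam) converge in 6–15 AI iterations.

## The simulator

`simulate.run_program` emulates a pedigreed broiler breeding programme:
discrete selection rounds, hierarchical mating (each dam to one sire,
each sire to `dams_per_sire` dams), overlapping parent use with a fixed
service life, random parent replacement during burn-in and truncation
selection on pedigree-BLUP breeding values afterwards, with variance
components estimated once at the end of burn-in (univariate moda model)
and reused — selection thus operates on the *misspecified* model, as in
practice. Defaults mirror the full-scale design: 40 rounds × 7800 birds,
52 active sires / 520 active dams (13 males and 130 females selected per
round, serving 4 rounds), 6 hatches per round with per-dam-per-hatch
offspring declining linearly from 2.49 to 2.15 with dam age, sex assigned
1:1, 312 000 phenotypes in total.

Genetics follow the infinitesimal model with exact Mendelian-sampling
variances `½ G0 (1 − (F_s + F_d)/2)` (inbreeding recomputed each round).
Every female receives a joint `(e, pe)` draw from `E0` at birth — the
physical origin of the direct–maternal environmental covariance: the
environment she grows up in is correlated with the mothering environment
she later provides. Males draw `e` only. Phenotypes add fixed effects
(hatch ~ N(0, (0.1 σ_P)²), +207 g for males, −2 g per dam-age class,
means are configurable and deliberately modest) plus an independent
unit-variance noise matching the dummy residual, so estimation with
`σ²_dummy = 1` targets exactly the generating `σ²_e`. Every component of
every phenotype is stored; their sum reproduces the phenotype to the
last bit, and true breeding values are exact.

What the generator does *not* emulate: finite-locus genomes, mortality
and fertility variation, heterogeneous residual variance across rounds,
drifting fixed-effect structures, or selection on anything but the moda
EBV. Passing tests therefore demonstrate correct inference under the
stated generative model, not robustness to the additional structure real
data carry.

### Study scales

The spec of a full-scale programme is kept in the defaults; analyses in
the test-suite and the acceptance script run down-scaled programmes that
preserve the family structure exactly (10 dams per sire, 15 offspring
per dam and round, 4-round service, selection intensity 2/600 in males
and 20/600 in females → 8 active sires, 80 active dams, 1200 birds per
round):

* `SimConfig.reduced()`: 10 rounds (burn-in 3) — the small profile for
  unit-level work.
* Replicated study: 20 rounds (burn-in 6, validation = last 5 rounds),
  24 000 phenotypes per replicate, 12 replicates in the acceptance
  script and 4 in the test-suite.

The round count is a compromise forced by effective population size.
Accuracy and inflation contrasts between the models grow with the length
of the selection history, but with only 8 active sires, truncation
selection on BLUP breeding values co-selects close relatives so strongly
that longer programmes inbreed catastrophically (mean F beyond 0.6 after
~25 rounds, with the within-round genetic variance — and any validation
signal — collapsing, replicate by replicate, in unpredictable ways). At
20 rounds the replicates are homogeneous and every variance component is
recovered accurately, while the accuracy gains of the covariance models
over the no-maternal model, and the inflation of the latter, are
directionally present but much smaller than in a full-scale programme
(hundreds of active parents, ~34 selected rounds). The ranking reversal
between the corrected-phenotype correlation and the true-breeding-value
correlation, and the likelihood-ratio ordering of the five models, are
robust at this scale.

## Cross-validation

Forward prediction masks all phenotypes of the last five rounds;
half-sib prediction masks a random half of each paternal half-sib group
in those rounds and correlates a masked bird's EBV with the corrected
phenotype `y_c = y − Xb̂` of a paternal half-sib *from a different dam*
(pairs drawn without replacement within a resample; odd animals stay in
training; 50 resamples by default, their seeds derived from one master
seed). Variance components always come from the full-data fit of the
same model; `y_c` uses the full-data fixed-effect solutions. All
correlations and regression slopes are computed on values centred within
selection round — the standard construction of (co)variances conditional
on a group factor, here the genetic trend. Accuracy is the correlation
of `EBV_reduced` with `y_c`, with `EBV_full`, with the half-sib `y_c`,
and (in simulation) with the true breeding value; inflation is the slope
of each reference on `EBV_reduced`, 1 meaning calibrated dispersion.

When relative accuracy gains between models are aggregated over
replicates, the acceptance script uses the ratio of replicate-mean
correlations rather than the mean of per-replicate ratios: a
per-replicate ratio has unbounded influence whenever one replicate's
baseline accuracy drifts toward zero, which down-scaled populations
occasionally produce.

## Known limitations

* No prediction-error variances / reliabilities.
* At most two traits (the female/male body-weight pair).
* LRT p-values at variance boundaries are conservative (no mixture df).
* The dense oracles are O(n²) in memory and meant for ≤ ~50-record
  checks (the grid oracle up to a few hundred).
* Boundary-optimum datasets converge slowly (see above); the fit status
  reports this honestly rather than masking it.
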