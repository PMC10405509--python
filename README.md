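# willham

Pedigree-based genetic evaluation for maternally influenced traits:
Willham maternal animal models with direct–maternal genetic **and**
environmental covariances, REML variance components, BLUP breeding
values, a stochastic breeding-program simulator, and cross-validation
statistics for the accuracy and inflation of predicted breeding values.

## The problem

Juvenile traits such as broiler body weight are shaped both by the
bird's own genes and environment and by its dam: her maternal genetic
effect `m` and her permanent environmental effect `pe`. Because the dam
is herself an animal with a direct genetic effect `a` and an
environmental deviation `e`, two covariances arise naturally —
`Cov(a, m)` between her direct and maternal genetic effects, and
`Cov(e, pe)` between the environment she grew up in and the mothering
environment she provides. Ignoring them biases variance components,
inflates predicted breeding values and can reverse model rankings in
cross-validation.

`Cov(a, m)` is routine to fit; `Cov(e, pe)` is not, because the residual
of a mixed model is normally not a random effect that can covary with
anything. The trick implemented here: declare the residual `e` an
ordinary random effect (one level per phenotyped animal, joined with the
dam's `pe` in a small per-individual covariance block) and add a *dummy
residual* whose variance is fixed to a small constant (1 g²). The true
residual variance is then `σ²_e + σ²_dummy`, and `Cov(e, pe)` becomes an
estimable parameter of standard average-information REML. Five nested
models are provided — `moda` (no maternal genetics), `modam` (maternal
effects, no covariances), `coram` (+`Cov(a,m)`), `corepe`
(+`Cov(e,pe)`), `coramepe` (both) — in univariate form or with female
and male body weight as two traits.

## Worked example

```python
import numpy as np
from willham import (SimConfig, run_program, estimate, ModelConfig,
                     crossval, derived_ratios)

# a down-scaled breeding program: 10 selection rounds x 1200 birds,
# 8 active sires / 80 active dams, BLUP truncation selection
pop = run_program(SimConfig.reduced(), seed=55)

fit = estimate(pop.data, pop.ped, ModelConfig("coramepe"))
print(fit.status, fit.n_iter)
for name, value in fit.free_estimates().items():
    print(f"{name:12s} {value:9.1f}")
print({k: round(v, 3) for k, v in
       derived_ratios(fit.vc, ModelConfig("coramepe")).items()})
```

prints (seed 55):

```
converged 11
var(a)          9224.8
cov(a,m)        -801.9
var(m)          1174.9
var(e)         19286.1
cov(e,pe)        557.4
var(pe)          570.5
{'h2': 0.305, 'r_am': -0.244, 'r_epe': 0.168}
```

The generating values were `var(a)=8046`, `cov(a,m)=-912`, `var(m)=829`,
`var(e)=19860`, `cov(e,pe)=1272`, `var(pe)=906`: one small replicate
recovers them within its (wide) sampling error, and replicate averages
centre on the truth. `fit.se` carries average-information standard
errors, `fit.solution` the BLUPs of every effect.

Cross-validation (forward prediction on the last five rounds, plus
paternal half-sib prediction) compares models fitted with full-data
components:

```python
comps = {m: estimate(pop.data, pop.ped, ModelConfig(m))
         for m in ("moda", "modam", "coramepe")}
report = crossval(pop.data, pop.ped, comps, truth=pop.truth, seed=1)
print(report.table)
```

The same pipeline is scriptable: `willham simulate | fit | crossval |
report` (see `willham --help`).

## Layout

| module | contents |
|---|---|
| `willham.pedigree` | topological sorting, inbreeding (Meuwissen–Luo), sparse A-inverse (Henderson) |
| `willham.varmodels` | the five model structures, parameter maps, ratios, PD bending |
| `willham.mme` | design matrices, per-individual (e, pe) blocks, Henderson equations, BLUP |
| `willham.reml` | AI-REML with EM fallback, likelihood-ratio tests |
| `willham.sparsela` | sparse LDL' with reusable symbolic analysis and Takahashi selected inverse |
| `willham.simulate` | the breeding-program simulator |
| `willham.validate` | forward / half-sib cross-validation, trend correction, accuracy & inflation |
| `willham.oracles` | dense brute-force references used by tests and `willham selftest` |
| `willham.io`, `willham.cli` | flat-file formats and the command-line surface |

`docs/methods.md` documents the model, the estimation algorithm, the
simulator's assumptions and the numerical choices in detail.
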