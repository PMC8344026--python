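# gomprisk

Parametric competing-risks survival analysis with the improper
three-parameter Gompertz model, built for the setting of small hemodialysis
registries in which death on dialysis competes with kidney transplantation.

For a patient with covariates `x`, each cause `k ∈ {1 = death, 2 =
transplant}` has a sub-distribution (cumulative incidence) function

```
F_k(t | x) = [1 − exp(−(λ_k(x)/γ_k)(e^{γ_k t} − 1))]^{θ_k},
λ_k(x) = λ_k · exp(xᵀβ_k),
```

with power `θ_k > 0`, shape `γ_k` and rate `λ_k > 0` per year.  When
`γ_k < 0` the curve plateaus at `[1 − exp(λ_k(x)/γ_k)]^{θ_k} < 1`: the
distribution is *improper*, and the residual mass is exactly the room left
for the competing cause.  Both causes enter one likelihood —

```
ℓ = Σ_i  [δ_i=1] log f_1(t_i|x_i) + [δ_i=2] log f_2(t_i|x_i)
      + [δ_i=0] log(1 − F_1(t_i|x_i) − F_2(t_i|x_i))
```

— which is maximized by quasi-Newton multistart on the transformed scale
(log θ, γ, log λ, β).  Effects are reported as sub-hazard ratios
S-HR = exp(β) with Wald intervals at configurable levels (the screening
workflow defaults to 75% univariate / 90% adjusted intervals with retention
thresholds p < 0.25 and p < 0.10).

The package contains four layers:

| module | contents |
|---|---|
| `gomprisk.gompertz` | closed-form cdf/pdf/quantile/plateau/sampling of the (possibly improper) generalized Gompertz |
| `gomprisk.model` | two-cause likelihood, MLE fitting, Wald S-HR inference, model-based cumulative incidence |
| `gomprisk.cohort` | synthetic registry generator; the packaged default is calibrated to a 109-patient dialysis cohort (71.6% male, mean age 57.99, 26.6% deaths, 17.4% transplants, 4-year CIFs 48.4%/29.2%) |
| `gomprisk.pipeline` | clinical-band categorization, univariate → collinearity → multivariate screening, incidence tables, markdown/TSV reports |

The numbered scripts under `analysis/` run the whole study workflow:
calibration of the default truth (`01`), cohort simulation (`02`), the
incidence table (`03`) and the prognostic-factor screen (`04`), writing
their tables under `results/`.

## Worked example

```python
import numpy as np
from gomprisk import fit_mle, shr_table, cif_curve
from gomprisk.cohort import default_config, generate_cohort

cohort = generate_cohort(default_config(n=1000), seed=2)   # time,event,covariates
fit = fit_mle(cohort, covariates1=("age", "uric_acid"),
              covariates2=("age", "uric_acid"), seed=0)
print(shr_table(fit, levels=(0.75, 0.90)))
```

```
 cause  variable      shr  ci75_lo  ci75_hi  ci90_lo  ci90_hi        p
     1       age 1.004597 1.002526 1.006672 1.001637 1.007566 0.010561
     1 uric_acid 0.944032 0.919477 0.969244 0.909118 0.980287 0.011942
     2       age 0.992920 0.989150 0.996703 0.987535 0.998334 0.031615
     2 uric_acid 1.105810 1.054062 1.160098 1.032568 1.184246 0.015774
```

Each row is one covariate's effect on one cause's sub-distribution: a
one-mg/dl rise in serum uric acid multiplies the transplant sub-hazard by
≈1.11 (90% CI 1.03–1.18, p ≈ 0.016) while lowering the death sub-hazard by
≈6%; each year of age raises the death sub-hazard by ≈0.5% and lowers the
transplant sub-hazard — the signs the generator's truth encodes.
Model-based cumulative incidence for a covariate profile comes from the
same fit:

```python
F_death, F_transplant = cif_curve(fit, {"age": 58.0, "uric_acid": 7.0},
                                  np.array([1.0, 2.0, 3.0, 4.0]))
```

The screening pipeline (`gomprisk.pipeline.run_pipeline`, or the
`gomprisk screen` CLI) chains categorization, the univariate screen on both
causes, a collinearity check and the adjusted models, and writes
`univariate.tsv`, `multivariate.tsv`, `cumulative_incidence.tsv`,
`report.md` and a run log; `analysis/04_screen_prognostic_factors.py` shows
a full run in which, at n = 1000, the screen retains the generating
truth's age, uric-acid, gender and phosphorus-band effects.

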