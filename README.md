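# crossr2

Pseudo-R² separability indices for survival markers whose hazard functions
**cross** over time.

## Why

Genome-wide prognostic screens usually rank markers with statistics derived
from the Cox proportional-hazards (PH) model. PH assumes the hazard ratio
between marker levels is constant in time. When two markers in the same
pathway modulate each other's effect (effect modification), the *marginal*
hazard functions of a single marker can cross: the marker is harmful early
and protective late (or vice versa), the average effect is near zero, and
every PH-based index scores it as noise. `crossr2` implements a
separability index, **D₀**, built for exactly this situation, together with
its PH counterpart and four classical pseudo-R² baselines, the simulators
that generate crossing-hazards survival data, and a marker-screening
pipeline.

## The index

The crossing-hazards model specifies the survival function

S(t | Z) = exp{ −Λ₀(t)^exp(βZ) },

a semi-parametric generalisation of the Weibull distribution whose binary
group hazard ratio e^β Λ₀(t)^{e^β−1} passes through 1 at a finite crossing
time. The score function of this model at β = 0 gives per-subject
contributions

Û_i = ω̂(t_i) δ_i (Z_i − Ē(t_i)),  ω̂(s) = 1 + log Λ̂₀(s⁻),

with Ē(t) the risk-set mean of the marker and Λ̂₀ the left-continuous
Nelson–Aalen estimate. The time-dependent weight ω changes sign at
Λ̂₀ = 1/e, so early and late events pull in opposite directions — the
signature of a crossing effect. Robust (per-subject, Lin–Wei-type) score
residuals Ŵ_i turn the score into a statistic, and

**D₀ = (Σᵢ Ŵᵢ)² / (k · Σᵢ Ŵᵢ²)**,  k = number of distinct uncensored failure times,

is interpreted as a percentage of separability between subjects who fail
and those who fail later. Setting ω ≡ 1 gives the PH counterpart D_PH. No
regression coefficient is estimated, so a 50,000-marker screen is cheap.
Comparator indices (Allison `1−exp(−G/n)`, its event-normalised
modification, Nagelkerke, Xu–O'Quigley) are computed from a built-in
univariate Cox partial-likelihood fitter.

## Worked example

Simulate one study cell — binary marker, quadrupled crossing effect
(e^β = 4), n = 100, uniform censoring calibrated to 25% — and score it with
all six indices:

```python
import numpy as np
from crossr2 import SimulationConfig, generate_dataset, all_indices

cfg = SimulationConfig(covariate_law="bernoulli_half", beta=float(np.log(4)),
                       event_law="weibull_crossing", censoring_law="uniform",
                       target_censoring=0.25, n=100, seed=42)
data, truth = generate_dataset(cfg)
print("events observed:", data.n_events, "of", data.n)
print("calibrated uniform upper bound r = %.4f" % truth["censoring_param"])
for name, value in all_indices(data, "z").items():
    print(f"{name:>12s}  {value:.4f}")
```

```
events observed: 75 of 100
calibrated uniform upper bound r = 3.7665
          D0  0.3144
        D_PH  0.0014
     allison  0.0009
 allison_mod  0.0012
  nagelkerke  0.0009
 xu_oquigley  -0.0013
```

The marker separates strongly under the crossing-hazards reading
(D₀ ≈ 0.31, i.e. ~31% separability) while every PH-based index is
indistinguishable from noise — the crossing effect cancels out of any
time-constant summary.

The same operations are exposed on the command line:

```bash
crossr2 index  --input data.tsv --marker-col geneX --mode crossing
crossr2 study  --config grid.yaml --reps 200 --seed 42 --out results/
crossr2 screen --matrix expr.tsv --meta surv.tsv --indices d0,dph --top 200 --out screen.tsv
```

## Scope

Univariate indices only; no confidence intervals for D₀; left truncation,
interval censoring, competing risks, time-varying covariates, Efron tie
handling and optimal-cutpoint search are out of scope. See
`docs/methods.md` for the model details, numerical conventions and known
limitations (in particular the behaviour of the k-normalisation under
heavily tied failure times).
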