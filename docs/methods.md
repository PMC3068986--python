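# Methods

## Models

### Semi-parametric crossing-hazards model

For a marker value `z`, the survival function is

    S(t | z) = exp{ -Lambda0(t) ^ exp(beta z) },

with `Lambda0` an increasing baseline cumulative hazard and `beta` a real
coefficient. The hazard is `exp(beta z) * lambda0(t) * Lambda0(t)^(exp(beta z) - 1)`.
For a binary marker the group hazard ratio `exp(beta) * Lambda0(t)^(exp(beta)-1)`
is monotone in `t` and equals 1 at

    tau = Lambda0^{-1}( exp(-beta / (exp(beta) - 1)) ),

so the two group hazards cross at a single finite time whenever
`beta != 0`. With the identity baseline `Lambda0(t) = t` the model is a
Weibull with scale 1 and shape `exp(beta z)`; the Z = 1 group's survival at
the crossing time is then 0.78, 0.82, 0.85 for `exp(beta)` = 2, 3, 4.
Baselines are restricted to named families (identity; power
`(t/eta)^a`) so that crossing-time solvers stay closed-form; arbitrary
user-supplied baselines are out of scope.

### Modulating-effect (effect-modification) model

Two binary markers with joint distribution `p_{z1,z2}`; conditional on both,
hazards are proportional with multiplier `exp(gamma z2 + alpha z1 z2)` —
`Z1` acts only where `Z2 = 1`. Marginalising over a hidden `Z2` by Bayes'
rule yields the mixture survival

    S(t | z1) = sum_{z2} P(z2 | z1) * exp(-Lambda0(t) * m(z1, z2)),
    m(z1, z2) = exp(gamma z2 + alpha z1 z2),

and the marginal hazard is the mixture of cell hazards weighted by the
probability of still being at risk in each cell:

    lambda(t | z1) = lambda0(t) * sum P(z2|z1) m e^{-Lambda0 m} / sum P(z2|z1) e^{-Lambda0 m}.

For `alpha, gamma` of the same sign and a balanced joint distribution the
marginal hazard ratio of `Z1` crosses 1 at a unique finite time: a purely
proportional conditional model produces marginally crossing hazards once
the partner is unobserved. This is the biological rationale for screening
with a crossing-aware index. The crossing time is found by sign-change
bracketing plus Brent root-finding on `log HR` over `t in [1e-6, 50]`
(baseline scale; configurable), which covers every parameterisation used
in the simulations.

## The D0 index

At each distinct failure time the score of the crossing model at `beta = 0`
weighs the difference between the failing subject's marker and the risk-set
mean by `omega(s) = 1 + log Lambda0(s)`; `Lambda0` is plugged in as the
left-continuous Nelson-Aalen estimate. Per-subject robust (Lin-Wei-type)
score residuals

    W_i = omega(t_i) d_i (Z_i - Ebar(t_i))
          - sum_{t_j <= T_i} omega(t_j) (Z_i - Ebar(t_j)) d(t_j)/n(t_j)

satisfy `sum W_i = sum U_i` exactly (the compensator telescopes to zero
over risk sets), and the index is the normalised robust score statistic

    D0 = (sum W_i)^2 / (k * sum W_i^2),

with `k` the number of distinct uncensored failure times. `omega ≡ 1`
gives the proportional-hazards counterpart D_PH. Both are invariant to
affine rescaling of the marker, deterministic, and free of any coefficient
estimation.

### Numerical conventions

- **First-event weight.** The left-continuous Nelson-Aalen estimate is 0 at
  the earliest failure time, where `1 + log 0` is undefined. Default
  convention (`first_event_weight="right_continuous"`): use the
  right-continuous value `d1/n1` inside the log for that single term; it is
  consistent in the continuous-time limit and touches exactly one term. The
  alternative `"drop_term"` zeroes the first event's weight entirely.
- **Ties.** Failures tied at one time each contribute their own `U_i` with
  the shared weight and risk-set mean; compensator increments are
  Breslow-style `d/n`. Censorings tied with failures stay in the risk set
  at that time. Times are compared exactly; no epsilon-merging.
- **Flat markers.** A marker with zero range is scored 0 by convention (no
  separability), never an error, so genome-wide screens cannot abort.
  Markers are centred before the suffix-sum pass purely for numerical
  conditioning; risk-set centring makes this a no-op mathematically.
- **Degenerate variance.** `sum W_i^2 = 0` returns 0.

### The [0, 1] range and its limits

`D0` behaves as a percentage of separability throughout the regimes the
index is designed for. Empirically, with untied failure times the value
stayed within [0, 1] in 20,000 random datasets spanning n in [50, 500],
censoring up to 50% and effects up to `exp(beta) = 4` (maximum observed
0.75). The bound is **not** algebraic, however: `k` counts *distinct*
failure times, so coarsely rounded follow-up (many tied failures) shrinks
the denominator while the robust score keeps the information of all
events, and the ratio can exceed 1 — at a quarter-unit rounding grid about
10% of strong-effect datasets do. Very small event counts with extreme
censoring (k <= 2) can do the same. Users with heavily tied data should
read `D0` as a ranking score, not a percentage. A per-failure-time
aggregation of the residuals would restore a provable bound but measurably
degrades the index's censoring-insensitivity, so the per-subject
construction is kept.

## Comparator indices

A self-contained univariate Cox partial-likelihood fitter (Breslow ties,
Newton-Raphson with step halving, convergence `|score| < 1e-9` within 50
iterations, `|beta| capped at 20` with a non-convergence flag for monotone
likelihoods) backs four baselines: Allison `1 - exp(-G/n)`; its modified
version `1 - exp(-G/d)` with `d` the event count; Nagelkerke
`(1 - exp(-G/n)) / (1 - exp(2 l(0)/n))`; and Xu-O'Quigley's
explained-variation ratio

    1 - sum_events (Z_i - Ebar_bhat(t_i))^2 / sum_events (Z_i - Ebar_0(t_i))^2,

with `Ebar_b` the `exp(bZ)`-weighted risk-set mean and unit event weights
(the weight is a configuration hook; several variants of this index exist
in the literature and the dispersion-ratio form is the one implemented).
`lifelines`' Cox fitter is used in the test suite as an independent
cross-check of the hand-written fitter, never as the implementation.

## Synthetic data

The generators define the study conditions under which every distributional
claim in the test suite is evaluated.

- **Covariates**: Bernoulli(0.5); log-normal (log-scale sd 0.5); uniform —
  the latter two affinely standardised to mean 0, variance 1/4 using exact
  moments, anchoring all three at the Bernoulli variance. The uniform
  interval and the log-normal's "variance 1/4" scale are interpreted on
  the symmetric-interval and log scale respectively; both choices are
  conventions, and affine invariance of every index makes the centring
  immaterial.
- **Event times**: inverse transform of the crossing model with identity
  baseline, `X = (-log U)^{exp(-beta z)}` (Z = 0 subjects are unit
  exponential), or log-normal with median 1 and log-scale sd
  `exp(-beta z)`. Effects `exp(beta)` in {1, 2, 3, 4}.
- **Censoring**: uniform on (0, r) or exponential, independent of the
  marker (the censoring laws carry no marker parameter, so conditional
  independence is realised as full independence). The parameter solving
  `P(C < X) = p_c` for targets 25% / 50% is found by Brent root-finding on
  a numerically integrated censoring probability, mixing over the
  covariate law by exact enumeration (Bernoulli) or Gaussian quadrature
  (24 nodes, Legendre / Hermite). Closed-form anchor: Exp(1) events with
  exponential censoring give `P(C < X) = rate/(1 + rate)`, so `p_c` = 25%
  means rate = 1/3 (reproduced by the solver at 1e-6).
- **Study grid**: n in {50, 100, 500}, 1,000 replications per cell by
  default; per-replication seeds derive from the cell seed by a counter
  scheme (`default_rng([seed, replication])`), making summaries
  order-independent and reproducible. Scaled-down replication counts
  (200 per cell, 60 in smoke tests) are used where distributional patterns
  rather than tail quantiles are being checked.

### Screening fixture

A 2,000 x 100 expression-like matrix whose survival outcome is driven by a
hidden modulating pair `(L1, L2)` (`alpha = gamma = 2.5`, both assigned to
exactly half the samples — stratified randomisation keeping all four cells
populated) and an independent proportional driver `P` (`beta_ph = log 3`).
Twenty "crossing" markers are noisy copies of `L1` (sd 0.3), twenty "ph"
markers noisy copies of `P`, the rest standard normal noise — a minimal
model of co-expressed modules around latent drivers. Light exponential
censoring (rate 0.1, roughly 8%) keeps the late follow-up, where the
hazard reversal shows, informative. The interaction coefficients are set
so that planted markers carry separability values in the range the index
is meant to flag (D0 of order 0.1–0.3 at n = 100); weaker settings leave
single-realisation recovery dominated by sampling noise. What the fixture
does *not* emulate: measurement-level normalisation artefacts, correlated
null markers, batch structure, or many small independent effect pathways —
recovery results on it demonstrate the ranking behaviour of the indices,
not performance on any real cohort.

## Design decisions taken where the design was open

- Per-subject robust residuals (with the documented bound caveat) rather
  than per-failure-time aggregation: chosen for markedly better censoring
  insensitivity (mean D0 moved by < 0.01 between 0% and 50% censoring at
  `exp(beta)` = 4, versus ~0.05 for the aggregated variant).
- Median dichotomisation in the four-group comparison assigns exact-median
  values to "low"; "high" means strictly above the median.
- Top-N overlap breaks score ties deterministically by marker id.
- No multiple-testing correction in screening: selection is by fixed
  top-N, mirroring ranking practice for this kind of index.

## Known limitations

- D0 can exceed 1 under heavily tied failure times or tiny event counts
  (see above); it is then still a valid ranking score.
- The Cox fitter is univariate by design; the four-group hazard ratios in
  `dichotomize_and_compare` are unadjusted pairwise contrasts.
- Censoring calibration assumes the configured covariate and event laws;
  it is not re-estimated from data.
- The power (Weibull) baseline family covers the solvers; arbitrary
  baselines would require numeric inversion not implemented here.
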