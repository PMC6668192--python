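# Methods

`crbias` is a simulation framework for quantifying how unmeasured confounding
biases treatment-effect estimates when competing risks are analysed with
cause-specific (Cox) or subdistribution (Fine–Gray) proportional-hazards
models. Everything is synthetic: the package generates the data, fits the
misspecified analysis models, computes the relevant "true" values, and pools
bias measures across repetitions.

## Data-generating model

Each subject carries an unmeasured confounder `U ~ N(0, 1)` and a binary
treatment `Z` with prevalence `P(Z = 1) = pi` and Pearson correlation
`Corr(U, Z) = rho`. Event times follow two cause-specific hazards sharing a
baseline `lambda0(t)`:

    lambda_1(t | U, Z) = k * exp(beta1*U + gamma1*Z) * lambda0(t)   (event of interest)
    lambda_2(t | U, Z) =     exp(beta2*U + gamma2*Z) * lambda0(t)   (competing event)

with `k > 0` the baseline ratio of event 1 to event 2 and `lambda0` one of

* `constant`: `lambda0(t) = 1` (exponential failure times),
* `weibull`: `lambda0(t) = 2t` (linearly increasing),
* `plausible`: `exp(-18 + 7.3 t - 11.5 sqrt(t) log t + 9.5 sqrt(t))`, a
  biologically plausible human-mortality-like curve (at `t = 0` the
  `sqrt(t) log t` term is defined by its limit, 0).

There is deliberately no censoring: every subject experiences exactly one of
the two events. This keeps the Fine–Gray partial likelihood exact (all
inverse-probability-of-censoring weights are 1) and makes the bias
decomposition interpretable.

### Confounded covariate construction

`(U, Z)` are produced by latent bivariate-normal thresholding: `(U, V)` are
bivariate standard normal with latent correlation `r`, and `Z = 1{V > c}`
with `c = Phi^{-1}(1 - pi)`. Since `Corr(U, Z) = r * phi(c) / sqrt(pi(1-pi))`
is linear in `r`, the target `rho` is obtained by inverting this map, and the
attainable correlation is bounded by `phi(c)/sqrt(pi(1-pi))` — 0.7979 at
`pi = 0.5`, 0.585 at `pi = 0.1` or `0.9`. Infeasible `rho` raises an error
rather than clipping, so a scenario grid can never silently run at an
unattainable correlation.

### Event simulation

Because both causes share `lambda0`, the all-cause hazard factorises as
`A * lambda0(t)` with `A = k e^{eta1} + e^{eta2}` and the cause ratio
`k e^{eta1} / A` is constant in time. Simulation is exact inverse-transform
sampling: `T = H0^{-1}(E / A)` with `E ~ Exp(1)` and `H0` the cumulative
baseline hazard, plus one Bernoulli cause draw per subject. `H0` is `t` or
`t^2` in closed form; for the plausible shape it is tabulated once per
process by composite 10-point Gauss–Legendre quadrature on segments of width
0.005 (accurate far past the 1e-8 relative target for this analytic
integrand) and inverted by bracketed Newton iteration; the grid extends
geometrically on demand (the `e^{7.3 t}` growth guarantees termination).

A fixed seed yields identical uniform draws across baseline shapes, so time
*ranks* and causes are identical and only the time scale changes. This is the
mechanism behind the Weibull and plausible scenarios reproducing the
constant-baseline results exactly: both partial-likelihood estimators depend
on the data only through ranks and event labels.

## Analysis models

The analysis deliberately omits `U` (it is "unmeasured") and fits a single
binary covariate `Z`. Both fitters maximise the one-parameter partial
likelihood by Newton–Raphson from 0 (convergence `|score| < 1e-9` or step
`< 1e-10`, max 50 iterations, step-halving safeguard), differing only in the
risk set:

* cause-specific: subjects with `T >= t` (the competing event censors);
* subdistribution: additionally all subjects whose competing event occurred
  before `t` — they remain "at risk" forever.

For a binary covariate the score and information reduce to per-event-time
risk-set counts per arm, computed by sorting and binary search (O(n log n)
per fit). Ties — probability zero with continuous times, possible after CSV
round-tripping — use Breslow's approximation. Standard errors are
model-based (inverse root of the observed information); the study's
estimands are point-estimate biases, so SEs serve diagnostics only.
Degenerate inputs raise typed errors: no events of the modelled type, or a
single treatment arm (non-identifiable). Monotone-likelihood (separation)
data leave the fitter marching to a large coefficient, mirroring what any
unpenalised partial-likelihood maximiser does.

## True effects

The cause-specific truths are the prescribed `gamma1`, `gamma2`. The
subdistribution truths `Gamma1`, `Gamma2` cannot be prescribed: when the
cause-specific hazards are proportional, the subdistribution hazards are
not, so the Fine–Gray model is misspecified and its "true" value is a
*least-false* parameter. We define it operationally as the root of the
expected subdistribution partial-likelihood score under the generating law —
the probability limit of the Fine–Gray estimator, which is the unique value
the simulated estimates converge to. It depends on `rho`, `pi` and all
hazard parameters.

Two independent numerical routes are implemented and cross-validated:

* `mega_fit`: average Fine–Gray coefficients over `R = 20` simulated
  populations of `N = 200,000` (defaults put the Monte-Carlo SE near 0.003
  on the log scale, an order below the biases of interest); assumption-free
  reference.
* `expected_score`: solve the population score equation directly. On the
  `s = H0(t)` scale the event-`i` intensity for a `(U, Z)` stratum is
  `a_i e^{-A s}` and the expected risk indicator is `1 - p_i (1 - e^{-A s})`;
  the `(U, Z)` expectation uses 96-node Gauss–Hermite quadrature with the
  latent-threshold conditional `P(Z = 1 | U)`, the time integral adaptive
  quadrature (rescaled by the mean all-cause rate so the integrand's mass
  sits at O(1) even for extreme `k`), and the root bracketed bisection.

`validate=True` requires agreement within three combined standard errors.
Because the score depends on time only through `s`, `Gamma` is provably
invariant to the baseline shape, consistent with the rank-invariance argument
above.

## Bias measures

Per event `i`, pooled over repetitions with normal-approximation 95% CIs
(Monte-Carlo SE of the mean):

* `theta_RCT,i = E[Gamma_hat_i - Gamma_hat_i0]`, against the subdistribution
  estimate from a paired hypothetical RCT population (`rho = 0, pi = 0.5`,
  same hazard parameters), generated independently within each repetition
  from a dedicated RNG substream — per-repetition pairing keeps the measure
  a mean of i.i.d. differences with a valid SE;
* `theta_Exp,i = E[Gamma_hat_i - Gamma_i]`, against the least-false truth at
  the current `rho`;
* `theta_CSH,i = E[gamma_hat_i - gamma_i]`, against the prescribed
  cause-specific effect.

`theta_RCT - theta_Exp = Gamma_i - E[Gamma_hat_i0]` isolates the bias due
purely to the confounder–treatment correlation; the remainder is
omitted-variable-type bias. Repetitions with any non-converged fit are
excluded with a count; more than 5% exclusions fails the run loudly.

An important consequence of the least-false definition: since `Gamma_i` *is*
the probability limit of the Fine–Gray estimator, `theta_Exp` is zero up to
Monte-Carlo error in every scenario. Under this framework the entire bias of
the subdistribution estimate relative to an RCT is attributable to the
correlation-induced shift of the least-false parameter itself, which
`theta_RCT` captures. Alternative "explicit" truths that freeze the
confounder's within-arm distribution at baseline (ignoring the drift of `U`
among the still-at-risk) would yield systematically nonzero `theta_Exp`;
such variants are not least-false parameters of the fitted estimator and are
not used here.

## Scenario grid

Eight built-in scenarios cross 5 `rho` values with 3 values of one varied
parameter, all else fixed (`pi = 0.5`, `k = 1`, constant baseline unless
varied): (1) no treatment effect, `beta1` varied; (2) protective on both
events, `gamma1 = gamma2 = -1`; (3) differential, `gamma1 = -1`,
`gamma2 = 1`; (4) confounding on the competing event only, `beta2` varied;
(5) uneven arms, `pi` in {0.1, 0.5, 0.9} with `gamma1 = -1`, `beta1 = 1`;
(6) uneven event rates, `k` in {1/2, 1, 2} with `beta1 = 1`; (7)–(8) as (1)
with Weibull / plausible baselines. The `rho` grid is {0, 0.2, 0.4, 0.6,
0.797}, topping out at the attainable bound for `pi = 0.5`; scenario 5 uses
{0, 0.14, 0.29, 0.42, 0.57} because its extreme prevalences tighten the
bound to 0.585. Defaults are 100 repetitions of 10,000 subjects per cell
(1,500 simulation runs per scenario); both are overridable for desk-scale
work, and the reported Monte-Carlo CIs keep scaled-down runs interpretable.

Reproducibility: every repetition's RNG seed derives from `(master_seed,
scenario id, cell index, repetition index)`, with disjoint substreams for
population generation, event simulation and the paired RCT population, so
results are bitwise identical for any worker count and unaffected by added
diagnostics.

## What the generator does and does not emulate

The synthetic populations realise exactly the stated study conditions: a
single standard-normal confounder, a binary treatment, two competing events
with shared baseline, no censoring, no measured covariates. Real
observational data differ in all of these ways (multiple and non-normal
confounders, censoring, covariate adjustment, cause-specific baselines of
different shapes), so passing tests demonstrate correctness of the machinery
and the direction/magnitude of bias *under these conditions*, not effect
sizes transferable to any particular dataset.

## Numerical choices and limitations

* Feasibility of `rho` is strict; the latent-threshold bound at `pi = 0.1`
  is 0.585 (some treatments of this construction quote a more conservative
  0.57; the closed form is used here).
* The expected-score integrand is smooth; 96 Hermite nodes give far more
  than the required accuracy, and the reported numerical precision (1e-5) is
  deliberately conservative.
* The one-parameter Newton fits are concave problems; non-convergence is
  effectively limited to separation, which at n = 10,000 with these
  parameter ranges does not occur.
* Scaled-down problem sizes used in the test suite (50 repetitions of
  10,000 subjects for end-to-end checks; 50,000–400,000-subject single fits
  for consistency checks) were chosen so Monte-Carlo error is an order of
  magnitude below the effects being verified.
* Baseline-hazard and cumulative-incidence *estimation* are out of scope;
  only regression coefficients are fitted.
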