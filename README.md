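# crbias

Simulation framework for studying how **unmeasured confounding** biases
treatment-effect estimates in a **competing risks** setting, under both the
cause-specific (Cox) and subdistribution (Fine–Gray) analysis perspectives.

Observational studies estimate treatment effects without randomisation, so an
unmeasured common cause `U` of treatment `Z` and outcome biases the estimate.
When patients can also experience a *competing* event (for example
cancer death competing with cardiovascular death), that bias propagates
differently through the two standard competing-risks analyses: the Cox model
censors competing events, while the Fine–Gray model keeps those patients in
the risk set forever. `crbias` generates fully synthetic populations under
known confounding, fits both (deliberately misspecified, `U`-omitting) models,
and measures the resulting bias.

## Model

Each of `n` subjects has `U ~ N(0,1)`, a treatment `Z ~ Bernoulli(pi)` with
`Corr(U, Z) = rho` (latent bivariate-normal thresholding; the attainable
`|rho|` is bounded by `phi(Phi^{-1}(1-pi)) / sqrt(pi(1-pi))`, 0.7979 at
`pi = 0.5`), and an event time/type drawn from two cause-specific hazards
sharing a baseline `lambda0(t)` (constant, Weibull `2t`, or a biologically
plausible curve):

    lambda_1(t | U, Z) = k e^{beta1 U + gamma1 Z} lambda0(t)
    lambda_2(t | U, Z) =   e^{beta2 U + gamma2 Z} lambda0(t)

There is no censoring. The analysis fits `lambda_i(t|Z) = lambda_i0(t)
e^{gamma_hat_i Z}` (cause-specific) and `h_i(t|Z) = h_i0(t) e^{Gamma_hat_i Z}`
(subdistribution) with `Z` only. Three bias measures are pooled over
repetitions, per event `i`:

* `theta_RCT,i = E[Gamma_hat_i - Gamma_hat_i0]` — shift of the
  subdistribution estimate relative to a paired hypothetical RCT population
  (`rho = 0`, `pi = 0.5`);
* `theta_Exp,i = E[Gamma_hat_i - Gamma_i]` — bias from the *least-false*
  subdistribution effect `Gamma_i`, the root of the expected Fine–Gray score
  at the current `rho` (computed two independent ways: a mega-population
  Monte-Carlo fit and Gauss–Hermite/adaptive quadrature on the population
  score equation);
* `theta_CSH,i = E[gamma_hat_i - gamma_i]` — bias of the cause-specific
  estimate from the prescribed effect.

Eight built-in scenarios cross 5 values of `rho` with 3 values of one varied
parameter (`beta1`, `beta2`, `pi` or `k`), 100 repetitions of 10,000 subjects
per cell. See `docs/methods.md` for the full account.

## Worked example

The "differential effect" setting — treatment protective for the event of
interest (`gamma1 = -1`) but harmful for the competing event (`gamma2 = 1`),
confounder suppressing the event of interest (`beta1 = -1`) — at a moderate
correlation `rho = 0.4`:

```python
from crbias import HazardParams, run_cell

hp = HazardParams(beta1=-1.0, beta2=0.0, gamma1=-1.0, gamma2=1.0, k=1.0)
table, _, truths = run_cell(hp, rho=0.4, pi=0.5, n=10_000, reps=50,
                            master_seed=42, scenario_id=3, cell_idx=3)
print(f"Gamma1 = {truths.Gamma1:.3f}, Gamma2 = {truths.Gamma2:.3f}")
print(table.round(3).to_string(index=False))
```

prints

```
Gamma1 = -2.005, Gamma2 = 1.376
 event   measure  estimate  ci_low  ci_high  n_reps
     1 theta_RCT    -0.631  -0.646   -0.615      50
     1 theta_Exp     0.000  -0.013    0.013      50
     1 theta_CSH    -0.518  -0.530   -0.506      50
     2 theta_RCT     0.328   0.319    0.337      50
     2 theta_Exp     0.000  -0.007    0.008      50
     2 theta_CSH    -0.000  -0.009    0.008      50
```

Reading this: even though the prescribed treatment effect on the event of
interest is `-1`, confounding at `rho = 0.4` drags the subdistribution
estimate 0.63 below what an RCT on the same population would find
(`theta_RCT,1`), and the cause-specific estimate 0.52 below its true value
(`theta_CSH,1`). The least-false subdistribution effect itself moves from
`-1.376` at `rho = 0` to `-2.005` at `rho = 0.4`; because `Gamma_i` is the
exact probability limit of the Fine–Gray estimator, `theta_Exp` is zero up to
Monte-Carlo error, i.e. the entire RCT-relative bias is carried by the
correlation-induced shift of the estimand. The competing event shows the
mirror image (`theta_RCT,2 = +0.33`), while its cause-specific fit is
unbiased (`beta2 = 0`: no confounding on that pathway).

The same is available from the shell:

```sh
crbias bounds --pi 0.5                 # 0.797885
crbias simulate --n 10000 --rho 0.4 --beta1 -1 --gamma1 -1 --gamma2 1 \
    --seed 1 --out pop.csv
crbias fit --data pop.csv --model fine-gray --event 1
crbias true-gamma --rho 0.4 --beta1 -1 --gamma1 -1 --gamma2 1 --event 1
crbias run --scenario 3 --reps 100 --n 10000 --seed 42 --out results/
```

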