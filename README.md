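# costbayes

Cost-constrained Bayesian observers of binary sequences: simulation, fitting,
model selection, and sequential-effect analysis for human prediction
experiments.

## The problem

When people repeatedly predict the next outcome of a stationary Bernoulli
process (probability *p* of outcome A), their predictions do not settle: they
track the stimulus probability too softly, and they are pulled toward (or,
more subtly, pushed away from) the last few outcomes even though those carry
no information. `costbayes` implements a family of *resource-rational*
observer models in which these sequential effects arise from otherwise optimal
Bayesian inference performed under a cognitive cost, together with everything
needed to test such models against trial-level choice data.

An observer of Markov order *m* infers the parameter vector
q ∈ [0,1]^(2^m) of an assumed order-*m* Markov process (m = 0 is a plain
Bernoulli observer; m ≥ 1 infers transition probabilities). After each
observation the observer adopts the distribution P̂ minimizing

    D_KL(P̂ ‖ P_bayes) + λ C(P̂)

with one of two costs:

* **Precision cost** C = −H[P̂] (precise posteriors are expensive). The
  optimum is the Bayesian posterior computed from *exponentially filtered*
  pattern counts with decay γ = 1/(1+λ): leaky integration. Beliefs never
  converge; they follow the recent stimulus history, producing attractive
  sequential effects — and, for Markov observers, a characteristic
  *repulsive* effect of the third-to-last stimulus at moderate *p*.
* **Unpredictability cost** C = E_P̂[H(X;q)] (believing in unpredictable
  environments is expensive). The posterior converges, but to a biased value
  q\*(p) that is more extreme (more predictable) than the truth; Markov
  variants converge to beliefs in serial dependencies and hence show
  sequential effects without any forgetting.

A hybrid observer carries both costs. Responses follow generalized
probability matching: A is predicted with probability
p̄ᵏ / (p̄ᵏ + (1−p̄)ᵏ), optionally mixed with a repetition/alternation
propensity η. Subjects are fit by maximum likelihood (bounded quasi-Newton
over log-parameters), compared by BIC, and aggregated with random-effects
Bayesian model selection (Dirichlet posterior over model frequencies,
expected and exceedance probabilities).

## Worked example

Simulate one subject from the leaky (precision-cost) Markov observer and fit
two competing models:

```python
from costbayes import (CostlyInferenceModel, ModelSpec, simulate_subject,
                       pool_by_symmetry, conditional_proportions,
                       effect_differences)

spec = ModelSpec.precision(m=1, lambda_p=0.5, kappa=2.8)
trials = simulate_subject(spec, seed=0, subject_id="demo")   # 10 blocks x 400 trials

for cost in ("precision", "unpredictability"):
    est = CostlyInferenceModel(cost=cost, m=1).fit(trials)
    print(cost, est.lambda_p_, est.lambda_u_, est.kappa_, est.bic_)
```

prints (abbreviated)

```
precision-m1:        lambda_p=0.543  kappa=2.76  logL=-799.9   BIC=1615.0
unpredictability-m1: lambda_u=0.973  kappa=0.48  logL=-1057.2  BIC=2129.7
```

The generating parameters (λ_p = 0.5, κ = 2.8) are recovered and the true
cost family wins by ~515 BIC points. Sequential effects, pooled across
mirror-image probabilities:

```python
pooled = pool_by_symmetry(trials)
fx = effect_differences(conditional_proportions(pooled, 1), ("A", "B"))
```

```
  p  diff   bar    n1   n2
0.5 0.350 0.132   100  100
0.7 0.232 0.150   141   59
0.9 0.512 0.194   173   27
```

`diff` is p̄(A|A) − p̄(A|B), the attractive effect of the last stimulus
(positive throughout), with `bar` = 2·√(se₁² + se₂²).

A command-line pipeline mirrors the library:
`costbayes simulate | fit | select | confusion | seqfx | run`.

## Layout

| module | contents |
| --- | --- |
| `costbayes.design` | task structure, block probabilities, stimulus generation |
| `costbayes.observers` | belief updates for all cost families and orders 0–3; stationary distributions, implied entropy, asymptotic modes |
| `costbayes.response` | generalized probability matching, repetition propensity |
| `costbayes.synthetic` | full-experiment simulation of model subjects |
| `costbayes.fitting` | likelihoods, maximum-likelihood fits, `CostlyInferenceModel` estimator |
| `costbayes.selection` | random-effects Bayesian model selection, confusion matrices |
| `costbayes.seqfx` | symmetry pooling, conditional proportions, exact tests, tree summaries |
| `costbayes.io` / `costbayes.cli` | canonical CSV formats, configuration, pipeline, CLI |

See `docs/methods.md` for the model equations, numerical choices, and known
limitations.
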