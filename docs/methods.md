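# Methods

## Task model

An experiment is a sequence of independent blocks. Within a block, stimuli
x_t ∈ {0, 1} (1 = A) are i.i.d. Bernoulli(p). The block probabilities are
drawn without replacement from a pool of base values (default 0.50–0.95 in
steps of 0.05) and each is independently replaced by its complement with
probability 1/2, so with the default pool the 19 probabilities
0.05, …, 0.95 are each represented by exactly one block per experiment
(counting a probability and its complement as one block viewed from either
side). Each block has 200 passive trials (observation only) followed by 200
active trials (predict, then observe). Observers are reset at block
boundaries: blocks are presented to subjects as unrelated contexts, so no
belief should carry over.

## Observers

All observers infer the parameter vector q of an assumed order-m Markov
process over outcomes (m ∈ {0, 1, 2, 3}; q has 2^m components, the
probability of A after each length-m context) under a uniform prior, but
minimize, at each update, the Kullback–Leibler divergence to the Bayesian
posterior plus a weighted cognitive cost.

**Precision cost** (weight λ_p): the cost is the negative entropy of the
posterior. The optimal posterior is a Dirichlet of order 2^(m+1) whose
parameters are exponentially filtered counts ñ of the (m+1)-length stimulus
patterns, with decay γ = 1/(1+λ_p) applied at every observation:
ñ_t = γ ñ_{t−1} + 1[pattern at t]. The one-step predictive probability given
context c is the Laplace ratio (ñ_{c,A} + 1)/(ñ_{c,A} + ñ_{c,B} + 2). With
λ_p = 0 the counts are the raw counts and the observer is exactly Bayesian.
The decay time of evidence is 1/ln(1+λ_p).

**Unpredictability cost** (weight λ_u): the cost is the posterior expectation
of the outcome entropy H(X;q), the stationary average of the conditional
entropies: H(X;q) = Σ_c π_c(q) H(q_c), where π(q) is the stationary
distribution of the context chain (solved as a linear system; components of q
exactly at 0/1 are clamped inward by 1e−9 so the chain is irreducible). The
optimal posterior after t updates is the Bayesian posterior times
exp(−t λ_u H(X;q)). It has no closed form, so it is evaluated on a per-axis
discretized grid over [0,1]^(2^m) with increments 0.01, 0.02, 0.05, 0.1 for
m = 0, 1, 2, 3; grid points sit at bin centers, strictly inside (0,1), which
keeps all log-weights finite. (Bin centers rather than edges are a choice;
results are insensitive at these resolutions.) For m = 0 the asymptotic
posterior mode q*(p) maximizes p ln q + (1−p) ln(1−q) − λ_u H(q); it is at
least as extreme as p, and for p = 0.5, λ_u > 1 the maximizer is not unique
(two symmetric modes) — `asymptotic_mode` raises a dedicated error carrying
both rather than silently returning one.

**Hybrid** (both weights): the grid posterior is built from the filtered
counts and the entropy factor uses the discounted time S_t = Σ_{i≤t} γ^i
(S_t = γ(1+S_{t−1})), reducing to each pure family when the other weight
vanishes.

For m > 0 the first m stimuli of a block only assemble the conditioning
context: no counts, no cost exponent increments, no predictions. The grid
observers' time index t therefore counts pattern-completing observations
(t = observations − m). With 200 passive trials this warm-up never overlaps
the scored trials.

## Response selection

Given the predictive probability p̄, the subject predicts A with probability
p̄^κ / (p̄^κ + (1−p̄)^κ), computed as expit(κ·logit(p̄)) for numerical
stability at large κ. κ = 0 is a fair coin, κ = 1 probability matching,
κ → ∞ the optimal deterministic rule. An optional propensity η ∈ (−1, 1)
mixes in repetition of the previous *recorded* response (missed trials have
no response to repeat and are skipped): with probability |η| the previous
response is repeated (η > 0) or flipped (η < 0). This leaves the
unconditional response rate unchanged while shrinking (or inflating)
conditional effects: p̄_η(A|A) = (1−η) p̄(A|A) + η p̄(A).

## Likelihood and fitting

The likelihood of a subject's data is the product over non-missing active
trials of the probability assigned to the recorded response; passive stimuli
and the stimuli of missed trials still update the observer. Choice
probabilities are floored at 1e−12 (floored trials are counted and reported).
Optimization is over log-transformed parameters, bounds λ ∈ [1e−4, 1e3],
κ ∈ [1e−3, 50], η ∈ (−0.99, 0.99): a fixed log-spaced 4×4 start grid
(λ ∈ {0.01, 0.1, 1, 10} × κ ∈ {0.5, 1.26, 3.17, 8}) is evaluated, the best
two starts are refined with L-BFGS-B, and the best point wins, so fits are
deterministic. Inside the optimization loop the grid-observer likelihood uses
cached single-precision count×log-grid tables with a matched 1e−4
finite-difference step; the reported likelihood is recomputed in double
precision at the optimum (the test suite pins the cached path to the naive
trial-by-trial recomputation at 1e−10). BIC = −2 logL + d ln N and the
log-evidence approximation logL − (d/2) ln N use N = number of scored
responses. When a fit improves on the coin-flip null by fewer than 3 nats the
cost weight is flagged as unidentifiable (the likelihood is flat in λ when
κ ≈ 0).

## Model selection and recovery

Random-effects Bayesian model selection places a Dirichlet posterior over the
population frequencies of the candidate models, computed by the standard
variational iteration on the per-subject log-evidences (uniform prior
α₀ = 1, convergence at 1e−8). Family expected probabilities are ratios of
summed Dirichlet parameters; exceedance probabilities (the probability that a
family's total frequency exceeds 1/2) are Monte-Carlo estimates from 10^6
Dirichlet draws by default. Model recovery simulates subjects from each
candidate (cost weight log-uniform on [0.05, 5], κ uniform on [1, 4] — a
range bracketing the representative κ = 2.8), refits all candidates, and
classifies by lowest BIC, breaking ties toward the smaller order and then the
precision cost so reports are deterministic.

## Sequential-effect statistics

Analyses run on symmetry-pooled data: each block with p ≠ 0.5 enters twice,
as itself (focal probability p) and A/B-relabeled (focal probability 1−p), so
every mirror identity — p̄(A|p) = 1 − p̄(A|1−p) and its conditional
extensions — holds exactly by construction and each pooled probability
collects all evidence about it. Blocks at p = 0.5 enter once with a
coin-flipped labeling (pooled statistics are invariant up to relabeling).
Conditional proportions p̄(A|history) use stimulus histories up to length 3
(oldest first), which may span the passive/active boundary within a block —
the observer's state does, and conditioning is on stimuli, not responses.
Contrasts between histories differing in the oldest stimulus isolate that
stimulus' influence (positive = attractive); error bars are
2·√(se₁² + se₂²), per-probability comparisons use two-sided Fisher exact
tests with Holm–Šidák correction across probabilities (degenerate tables get
p = 1), and the binary-tree summary averages conditional-minus-unconditional
proportions over probabilities unweighted, with each parent node the plain
average of its two children.

## Representative parameters

Model illustrations and the qualitative test battery use κ = 2.8, a value
typical of subjects' fits, and λ_p = 0.5 for the leaky observers. λ_p = 0.5
(evidence decay time ≈ 2.5 trials) places the order-1 leaky observer in the
empirically relevant regime where the third-to-last stimulus is repulsive
(p̄(A|ABA) < p̄(A|BBA)) for p below ≈ 0.8 and attractive above — the
signature behaviour this model family is distinguished by. The
unpredictability illustrations use λ_u = 1.

## Problem sizes and numerical notes

* Simulation-based checks use predictive-level averaging where possible
  (averaging the model's choice *probability* conditional on a history rather
  than sampled responses), which is the exact expected proportion and removes
  response noise; Monte-Carlo error then comes only from the stimulus paths.
* The qualitative battery uses 300–1200 blocks per probability for order ≤ 1
  observers and 100 blocks at a single probability for the order-2 grid
  observer (its 160 000-point grid makes simulation ~100× dearer); the
  order-3 unpredictability observer (10^8 grid points, entropy table built by
  a chunked batched linear solve) is fully implemented but excluded from the
  default battery — its stationary-distribution and entropy machinery is
  validated directly against eigenvector oracles at m = 3 instead.
* Converging observers retain finite-sample transients after 200 passive
  trials: conditional-probability differences of order 1/t (≲ 0.01) with
  either sign. The "no repulsion for unpredictability-cost observers" check
  therefore requires third-order differences > −0.01, an order of magnitude
  above the leaky Markov observer's repulsion (−0.03 to −0.07).
* Model recovery at 20 subjects per model takes ~10–15 minutes on one CPU;
  parameter recovery of the order-0 leaky observer at experiment scale is
  accurate to well under 20% relative error.

## What the synthetic generator does and does not emulate

It reproduces the task's block structure, probability-drawing scheme,
passive/active split, response generation from any observer + response rule,
and an optional missed-trial rate (the stimulus still updates the observer; only
the response is missing, matching a task where stimulus presentation does not
wait for a response). It does not emulate response times, deadline dynamics,
attention lapses correlated with the stimulus stream, learning across blocks,
or any drift in a subject's parameters — so passing tests demonstrate
correctness of the inference/fitting machinery under the stated generative
assumptions, not that those assumptions exhaust real behaviour. Real
behavioural data can be loaded through `costbayes.io.load_external_trials`
with a user-supplied column mapping.

## Known limitations

* Markov orders above 3 are out of scope; the order-3 unpredictability grid
  is computationally heavy by construction.
* Point maximum-likelihood estimation only; no posterior over (λ, κ).
* The BIC/Laplace log-evidence approximation is shared by fitting and model
  selection; models with equal parameter counts are compared on equal
  footing, but the approximation quality at small trial counts is not
  assessed.
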