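"""Model specifications for cost-constrained observers.

A model subject is characterised by

* the *cost family* penalising its posterior: ``"precision"`` (negative
  posterior entropy; optimal update is exponential forgetting of pattern
  counts), ``"unpredictability"`` (posterior-expected outcome entropy
  ``H(X;q)``; the posterior converges to a biased, more predictable value of
  ``q``), or ``"hybrid"`` (both costs simultaneously);
* the Markov order ``m`` in {0, 1, 2, 3}: the subject infers the probability
  of the next outcome conditional on the last ``m`` outcomes, i.e. a parameter
  vector ``q`` of length ``2**m``;
* the response-selection parameters: the generalised probability-matching
  exponent ``kappa`` and an optional repetition/alternation propensity
  ``eta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

COSTS = ("precision", "unpredictability", "hybrid")
MAX_ORDER = 3

#: representative response exponent for model illustrations (typical of
#: subjects' best-fitting values)
REPRESENTATIVE_KAPPA = 2.8
#: representative precision-cost weight for model illustrations; places the
#: order-1 observer in the regime where the third-to-last stimulus is
#: repulsive below p ~ 0.8 and attractive above
REPRESENTATIVE_LAMBDA_P = 0.5


@dataclass(frozen=True)
class ModelSpec:
    """Full specification of an observer + response-selection model.

    Parameters
    ----------
    cost:
        Cost family, one of ``"precision"``, ``"unpredictability"``,
        ``"hybrid"``.
    m:
        Markov order of the assumed generative process (0 = Bernoulli
        observer).
    lambda_p:
        Weight of the precision cost (decay factor of the evidence counts is
        ``1 / (1 + lambda_p)``). Must be 0 for pure unpredictability models.
    lambda_u:
        Weight of the unpredictability cost. Must be 0 for pure precision
        models.
    kappa:
        Exponent of the generalised probability-matching response rule;
        ``kappa=1`` is classic probability matching, ``kappa=0`` a fair coin.
    eta:
        Repetition (``eta > 0``) or alternation (``eta < 0``) propensity in
        (-1, 1); with probability ``|eta|`` the previous response is repeated
        (or flipped) irrespective of the inference.
    """

    cost: str
    m: int = 0
    lambda_p: float = 0.0
    lambda_u: float = 0.0
    kappa: float = 1.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.cost not in COSTS:
            raise ValueError(f"unknown cost family {self.cost!r}; expected one of {COSTS}")
        if not isinstance(self.m, (int,)) or not 0 <= self.m <= MAX_ORDER:
            raise ValueError(f"Markov order m must be an integer in [0, {MAX_ORDER}], got {self.m!r}")
        for name in ("lambda_p", "lambda_u", "kappa"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.cost == "precision" and self.lambda_u != 0:
            raise ValueError("precision-cost models must have lambda_u = 0")
        if self.cost == "unpredictability" and self.lambda_p != 0:
            raise ValueError("unpredictability-cost models must have lambda_p = 0")
        if not -1 < self.eta < 1:
            raise ValueError(f"eta must lie in (-1, 1), got {self.eta!r}")

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def precision(cls, m: int = 0, lambda_p: float = 1.0, kappa: float = 1.0,
                  eta: float = 0.0) -> "ModelSpec":
        return cls("precision", m=m, lambda_p=lambda_p, kappa=kappa, eta=eta)

    @classmethod
    def unpredictability(cls, m: int = 0, lambda_u: float = 1.0, kappa: float = 1.0,
                         eta: float = 0.0) -> "ModelSpec":
        return cls("unpredictability", m=m, lambda_u=lambda_u, kappa=kappa, eta=eta)

    @classmethod
    def hybrid(cls, m: int = 0, lambda_p: float = 1.0, lambda_u: float = 1.0,
               kappa: float = 1.0, eta: float = 0.0) -> "ModelSpec":
        return cls("hybrid", m=m, lambda_p=lambda_p, lambda_u=lambda_u, kappa=kappa, eta=eta)

    # -- derived quantities -------------------------------------------------------
    @property
    def gamma(self) -> float:
        """Decay factor of the exponentially filtered counts, 1/(1+lambda_p)."""
        return 1.0 / (1.0 + self.lambda_p)

    @property
    def label(self) -> str:
        """Short label identifying the observer structure, e.g. ``precision-m1``."""
        return f"{self.cost}-m{self.m}"

    def with_params(self, **kwargs) -> "ModelSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
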