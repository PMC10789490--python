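"""Experiment design of the binary prediction task.

Each experiment comprises ``n_blocks`` blocks. Within a block the stimulus is
an i.i.d. Bernoulli variable with a fixed probability ``p``; the block starts
with ``n_passive`` passive-observation trials (the subject only watches)
followed by ``n_active`` active trials in which the subject predicts the next
outcome before it is revealed. The block probabilities are drawn from a pool
of base values (by default 0.50 to 0.95 in steps of 0.05) without replacement,
and each drawn value is independently replaced by its complement ``1 - p``
with probability 1/2, so that across blocks every probability in
{0.05, ..., 0.95} is represented by exactly one block (for the default pool).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_POOL = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


class DesignError(ValueError):
    """Raised for invalid experiment designs."""


@dataclass(frozen=True)
class ExperimentDesign:
    n_blocks: int = 10
    n_passive: int = 200
    n_active: int = 200
    probability_pool: tuple = DEFAULT_POOL
    trial_duration: float = 1.25  # seconds, metadata only

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_passive < 0 or self.n_active < 1:
            raise DesignError("n_blocks and n_active must be >= 1, n_passive >= 0")
        if self.n_blocks > len(self.probability_pool):
            raise DesignError(
                f"n_blocks ({self.n_blocks}) exceeds the probability pool size "
                f"({len(self.probability_pool)})"
            )
        for p in self.probability_pool:
            if not 0.05 - 1e-9 <= p <= 0.95 + 1e-9 or abs(round(p / 0.05) * 0.05 - p) > 1e-9:
                raise DesignError(f"pool probabilities must be multiples of 0.05 in [0.05, 0.95]; got {p}")

    @property
    def n_trials_per_block(self) -> int:
        return self.n_passive + self.n_active


def draw_block_probabilities(design: ExperimentDesign, rng: np.random.Generator) -> np.ndarray:
    """Draw one stimulus probability per block.

    Base probabilities are drawn from the design's pool without replacement;
    independently for each block, with probability 1/2 the complement ``1 - p``
    is used instead.
    """
    pool = np.asarray(design.probability_pool, dtype=float)
    base = rng.choice(pool, size=design.n_blocks, replace=False)
    flip = rng.random(design.n_blocks) < 0.5
    p = np.where(flip, 1.0 - base, base)
    return np.round(p, 2)


def generate_stimuli(p: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. Bernoulli(p) stimuli coded as 0 (B) / 1 (A)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"stimulus probability must lie strictly in (0, 1); got {p}")
    if n < 1:
        raise ValueError(f"number of stimuli must be >= 1; got {n}")
    return (rng.random(int(n)) < p).astype(np.int8)
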