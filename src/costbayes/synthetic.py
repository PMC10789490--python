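"""Synthetic experiments: task structure plus model-generated responses.

Generates full experiments with the behavioural task's structure (blocks of
i.i.d. Bernoulli stimuli, 200 passive then 200 active trials by default) and
simulates a subject's responses from any :class:`~costbayes.models.ModelSpec`.
The observer state is reset at each block boundary (blocks are explicitly
signalled to subjects as unrelated contexts); passive stimuli update the
observer but yield no responses; missed trials (optional) have no response but
the stimulus still updates the observer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ExperimentDesign, draw_block_probabilities, generate_stimuli
from .models import ModelSpec
from .observers import predictive_path
from .response import choice_probability, choice_probability_with_propensity

TRIAL_COLUMNS = ["subject_id", "block_index", "p", "trial_index", "phase",
                 "stimulus", "response"]


def _simulate_responses(pbar: np.ndarray, spec: ModelSpec, missed: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw active-trial responses; NaN where the trial was missed."""
    n = pbar.size
    u = rng.random(n)
    if spec.eta == 0.0:
        cp = choice_probability(pbar, spec.kappa)
        resp = (u < cp).astype(float)
    else:
        resp = np.empty(n)
        prev: float | None = None
        base = choice_probability(pbar, spec.kappa)
        for i in range(n):
            cp = choice_probability_with_propensity(base[i], prev, spec.eta)
            resp[i] = float(u[i] < cp)
            if not missed[i]:
                prev = resp[i]
    resp[missed] = np.nan
    return resp


def simulate_subject(spec: ModelSpec, design: ExperimentDesign | None = None, *,
                     rng: np.random.Generator | None = None, seed: int | None = None,
                     missed_rate: float = 0.0, subject_id: str = "synthetic",
                     block_probabilities=None) -> pd.DataFrame:
    """Simulate one subject's full experiment; returns a tidy trial table.

    One experiment-level random generator deterministically spawns a child
    stream per block, so any subset of blocks can be reproduced. Columns:
    ``subject_id, block_index, p, trial_index, phase, stimulus, response``
    (response is NaN on passive and missed trials).
    """
    if not 0.0 <= missed_rate < 1.0:
        raise ValueError("missed_rate must lie in [0, 1)")
    design = design if design is not None else ExperimentDesign()
    if rng is None:
        rng = np.random.default_rng(seed)
    if block_probabilities is None:
        block_probabilities = draw_block_probabilities(design, rng)
    else:
        block_probabilities = np.asarray(block_probabilities, dtype=float)
        if block_probabilities.size != design.n_blocks:
            raise ValueError("need one probability per block")
    block_rngs = rng.spawn(design.n_blocks)

    frames = []
    n_trials = design.n_trials_per_block
    for b, (p, brng) in enumerate(zip(block_probabilities, block_rngs), start=1):
        stim = generate_stimuli(p, n_trials, brng)
        pbar = predictive_path(spec, stim, design.n_passive)
        missed = brng.random(design.n_active) < missed_rate
        active_resp = _simulate_responses(pbar, spec, missed, brng)
        response = np.full(n_trials, np.nan)
        response[design.n_passive:] = active_resp
        frames.append(pd.DataFrame({
            "subject_id": subject_id,
            "block_index": b,
            "p": p,
            "trial_index": np.arange(1, n_trials + 1),
            "phase": np.repeat(["passive", "active"],
                               [design.n_passive, design.n_active]),
            "stimulus": stim.astype(int),
            "response": response,
        }))
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def simulate_cohort(specs, design: ExperimentDesign | None = None, *,
                    rng: np.random.Generator | None = None, seed: int | None = None,
                    missed_rate: float = 0.0, subject_prefix: str = "sim") -> pd.DataFrame:
    """Simulate one subject per spec; subject ids are ``{prefix}-001`` etc."""
    if rng is None:
        rng = np.random.default_rng(seed)
    tables = []
    for i, spec in enumerate(specs, start=1):
        tables.append(simulate_subject(
            spec, design, rng=rng, missed_rate=missed_rate,
            subject_id=f"{subject_prefix}-{i:03d}"))
    return pd.concat(tables, ignore_index=True)
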