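"""Response-selection: generalised probability matching with optional
repetition/alternation propensity.

Given the observer's predictive probability ``pbar`` that the next stimulus is
A, the subject predicts A with probability ``pbar**k / (pbar**k + (1-pbar)**k)``
(exponent ``kappa``): a fair coin at ``kappa=0``, probability matching at
``kappa=1``, the optimal deterministic choice as ``kappa -> inf``. With a
propensity ``eta`` the subject instead repeats (``eta>0``) or flips
(``eta<0``) the previous recorded response with probability ``|eta|``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def choice_probability(pbar, kappa: float):
    """Probability of predicting A under generalised probability matching.

    Computed in log-odds space, ``expit(kappa * logit(pbar))``, which is exact
    for the matching formula and stable for large ``kappa``. Scalar in, scalar
    out; array in, array out.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    p = np.asarray(pbar, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("pbar must lie in [0, 1]")
    if kappa == 0:
        out = np.full_like(p, 0.5)
        return float(out) if np.isscalar(pbar) else out
    with np.errstate(divide="ignore"):
        z = kappa * (np.log(p) - np.log1p(-p))
    out = expit(z)
    return float(out) if np.isscalar(pbar) else out


def choice_probability_with_propensity(p_base, prev_response, eta: float):
    """Mix the matching probability with a repetition/alternation propensity.

    With probability ``1-|eta|`` the response follows ``p_base``; with
    probability ``|eta|`` the previous recorded response is repeated
    (``eta >= 0``) or flipped (``eta < 0``). ``prev_response`` may be None /
    NaN (no recorded response yet: returns ``p_base``), 0 or 1, or an array
    thereof.
    """
    if not -1 < eta < 1:
        raise ValueError("eta must lie in (-1, 1)")
    p = np.asarray(p_base, dtype=float)
    prev = np.asarray(
        np.nan if prev_response is None else prev_response, dtype=float)
    a = abs(eta)
    target = 1.0 if eta >= 0 else 0.0
    stick = (prev == target).astype(float)
    out = np.where(np.isnan(prev), p, (1.0 - a) * p + a * stick)
    if np.isscalar(p_base) and out.ndim == 0:
        return float(out)
    return out
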