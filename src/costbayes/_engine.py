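"""Vectorised predictive-probability paths for whole stimulus blocks.

Computing the observer's predictive probability trial by trial with the
stateful classes in :mod:`costbayes.observers` is exact but slow for model
fitting, which evaluates thousands of parameter settings. This module computes
the same quantities for a whole block at once:

* precision-cost observers: the exponentially filtered pattern counts obey the
  linear recursion ``n_t = gamma * n_{t-1} + onehot_t`` and are evaluated with
  ``scipy.signal.lfilter``;
* grid observers (unpredictability / hybrid): the grid log-posterior before
  each active trial is an affine function of the cumulative (or filtered)
  pattern counts, evaluated as a single matrix product against precomputed
  per-grid-point log tables.

Equality with the stateful reference implementation (to ~1e-12) is enforced by
the test suite. The order-3 grid (10**8 points) has no flattened tables; those
paths fall back to the stateful loop.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.signal import lfilter

from .models import ModelSpec
from .observers import QGridPosterior, grid_axis, implied_entropy

_CHUNK_ELEMS = 4_000_000  # max elements of a (trials x grid) block held at once


def pattern_context_indices(stimuli: np.ndarray, m: int):
    """Context and pattern integer codes along a stimulus sequence.

    Returns ``(ctx, pat)`` where ``ctx[t]`` codes the ``m`` stimuli preceding
    trial ``t`` (valid for ``t >= m``; oldest stimulus in the most significant
    bit) and ``pat[t] = 2*ctx[t] + stimuli[t]`` codes the pattern completed at
    trial ``t``. ``ctx`` has length ``T+1`` so ``ctx[T]`` is the context for a
    hypothetical next trial.
    """
    s = np.asarray(stimuli).astype(np.int64)
    T = s.size
    ctx = np.zeros(T + 1, dtype=np.int64)
    for i in range(1, m + 1):
        ctx[m:] += s[m - i: T + 1 - i] << (i - 1)
    pat = (ctx[:T] << 1) | s
    return ctx, pat


def _pattern_onehot(stimuli: np.ndarray, m: int) -> np.ndarray:
    """(T, 2**(m+1)) indicator of the pattern completed at each trial (0 rows
    during the length-m context warm-up)."""
    T = len(stimuli)
    _, pat = pattern_context_indices(stimuli, m)
    onehot = np.zeros((T, 2 ** (m + 1)))
    t_idx = np.arange(m, T)
    onehot[t_idx, pat[t_idx]] = 1.0
    return onehot


def filtered_counts(stimuli: np.ndarray, m: int, gamma: float) -> np.ndarray:
    """Exponentially filtered pattern counts *after* each trial, shape (T, K)."""
    onehot = _pattern_onehot(stimuli, m)
    if gamma == 1.0:
        return np.cumsum(onehot, axis=0)
    return lfilter([1.0], [1.0, -gamma], onehot, axis=0)


def precision_path(stimuli: np.ndarray, n_skip: int, m: int, lambda_p: float) -> np.ndarray:
    """Predictive probabilities of the precision-cost observer.

    Returns, for each trial ``t`` in ``[n_skip, T)``, the Laplace ratio of the
    filtered counts held *before* observing stimulus ``t``.
    """
    gamma = 1.0 / (1.0 + lambda_p)
    T = len(stimuli)
    F = filtered_counts(stimuli, m, gamma)
    Fpad = np.vstack([np.zeros((1, F.shape[1])), F])  # counts before trial t
    ctx, _ = pattern_context_indices(stimuli, m)
    act = np.arange(n_skip, T)
    pbar = np.full(act.size, 0.5)
    ok = act >= m  # context complete
    c = ctx[act[ok]]
    rows = Fpad[act[ok]]
    a = rows[np.arange(c.size), (c << 1) | 1]
    b = rows[np.arange(c.size), c << 1]
    pbar[ok] = (a + 1.0) / (a + b + 2.0)
    return pbar


@lru_cache(maxsize=None)
def grid_tables(m: int):
    """Flattened grid tables for orders 0-2: (axis, Q, L, H).

    ``Q`` is (G, 2**m) grid coordinates, ``L`` is (2**(m+1), G) with
    ``L[2c+1] = ln q_c`` and ``L[2c] = ln(1-q_c)``, and ``H`` is the implied
    outcome entropy at each grid point. Order 3 (10**8 points) is served by
    the stateful observer instead.
    """
    if m > 2:
        raise ValueError("flattened grid tables are only built for m <= 2")
    axis = grid_axis(m)
    ndim = 2 ** m
    mesh = np.meshgrid(*([axis] * ndim), indexing="ij")
    Q = np.stack([g.ravel() for g in mesh], axis=1)
    L = np.empty((2 ** (m + 1), Q.shape[0]))
    for c in range(ndim):
        L[(c << 1) | 1] = np.log(Q[:, c])
        L[c << 1] = np.log1p(-Q[:, c])
    H = implied_entropy(Q, m)
    return axis, Q, L, H


def grid_path(stimuli: np.ndarray, n_skip: int, m: int, lambda_u: float,
              lambda_p: float = 0.0, count_rows: np.ndarray | None = None,
              tau: np.ndarray | None = None) -> np.ndarray:
    """Predictive probabilities of the grid (unpredictability/hybrid) observer.

    ``count_rows`` / ``tau`` may be passed in to reuse the parameter-free
    cumulative-count state across likelihood evaluations (pure
    unpredictability models only; with a precision cost the counts depend on
    ``lambda_p`` and are recomputed here).
    """
    if m == 3:
        return _grid_path_stateful(stimuli, n_skip, m, lambda_u, lambda_p)
    T = len(stimuli)
    act = np.arange(n_skip, T)
    gamma = 1.0 / (1.0 + lambda_p)
    if lambda_p > 0:
        F = filtered_counts(stimuli, m, gamma)
        Fpad = np.vstack([np.zeros((1, F.shape[1])), F])
        count_rows = Fpad[act]
        n_updates = np.clip(act - m, 0, None).astype(float)
        tau = gamma * (1.0 - gamma ** n_updates) / (1.0 - gamma)
    elif count_rows is None or tau is None:
        count_rows, tau = grid_count_state(stimuli, n_skip, m)

    axis, Q, L, H = grid_tables(m)
    ctx, _ = pattern_context_indices(stimuli, m)
    ctx_act = ctx[act]
    G = Q.shape[0]
    pbar = np.full(act.size, 0.5)
    ok = act >= m
    chunk = max(1, _CHUNK_ELEMS // G)
    idx_ok = np.nonzero(ok)[0]
    for start in range(0, idx_ok.size, chunk):
        sel = idx_ok[start:start + chunk]
        lw = count_rows[sel] @ L
        lw -= lambda_u * tau[sel, None] * H[None, :]
        lw -= lw.max(axis=1, keepdims=True)
        w = np.exp(lw)
        means = (w @ Q) / w.sum(axis=1, keepdims=True)
        pbar[sel] = means[np.arange(sel.size), ctx_act[sel]]
    return pbar


def grid_count_state(stimuli: np.ndarray, n_skip: int, m: int):
    """Cumulative pattern counts before each trial >= n_skip, and update counts.

    Parameter-free state of the pure unpredictability observer; cache this per
    block when fitting."""
    T = len(stimuli)
    act = np.arange(n_skip, T)
    cum = np.cumsum(_pattern_onehot(stimuli, m), axis=0)
    Cpad = np.vstack([np.zeros((1, cum.shape[1])), cum])
    count_rows = Cpad[act]
    tau = count_rows.sum(axis=1)
    return count_rows, tau


def _grid_path_stateful(stimuli, n_skip, m, lambda_u, lambda_p):
    obs = QGridPosterior(m, lambda_u, lambda_p)
    out = np.empty(len(stimuli) - n_skip)
    for t, x in enumerate(stimuli):
        if t >= n_skip:
            out[t - n_skip] = obs.predictive()
        obs.update(int(x))
    return out


def predictive_path(spec: ModelSpec, stimuli: np.ndarray, n_skip: int) -> np.ndarray:
    if n_skip < 0 or n_skip >= len(stimuli):
        raise ValueError("n_skip must lie in [0, len(stimuli))")
    if spec.cost == "precision":
        return precision_path(stimuli, n_skip, spec.m, spec.lambda_p)
    return grid_path(stimuli, n_skip, spec.m, spec.lambda_u, spec.lambda_p)
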