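"""Belief-update rules of the cost-constrained observers.

Three families of observers are provided, all inferring the parameter vector
``q`` (length ``2**m``) of an assumed order-``m`` Markov process over binary
outcomes, under a uniform prior:

``precision`` cost (negative posterior entropy)
    The optimal posterior is the Bayesian posterior with every count replaced
    by an exponentially filtered count with decay ``gamma = 1/(1+lambda_p)``:
    a Dirichlet distribution of order ``2**(m+1)`` over the counts of all
    ``(m+1)``-long stimulus patterns. Beliefs never converge; they track the
    recent stimulus history ("leaky integration").

``unpredictability`` cost (posterior-expected outcome entropy ``H(X;q)``)
    The posterior after ``t`` updates is the Bayesian posterior times
    ``exp(-t * lambda_u * H(X;q))``. It converges, but to a value of ``q``
    biased toward more predictable (less entropic) environments. There is no
    closed form, so the posterior is evaluated on a discretised grid over
    ``[0,1]**(2**m)``.

``hybrid`` (both costs)
    Grid posterior built from the exponentially filtered counts, times
    ``exp(-lambda_u * S_t * H(X;q))`` with ``S_t = sum_{i=1..t} gamma**i``
    (discounted time). Reduces to each pure family when the other weight is 0.

Patterns and contexts are encoded as integers with the oldest outcome in the
most significant bit: the pattern index of ``(s_{t-m}, ..., s_t)`` is
``sum s_i 2**(m-i)``, and a pattern equals ``2*context + outcome``.

The stateful classes here (:class:`PrecisionBelief`, :class:`QGridPosterior`)
are the reference trial-by-trial implementation; the vectorised engine in
``costbayes._engine`` computes whole predictive paths and is checked against
these classes in the test suite.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import xlogy

from .models import ModelSpec

#: per-dimension grid increments of the discretised posterior, by Markov order
GRID_INCREMENTS = {0: 0.01, 1: 0.02, 2: 0.05, 3: 0.1}

_Q_CLAMP = 1e-9  # boundary guard for reducible chains in ad-hoc calls


def grid_axis(m: int) -> np.ndarray:
    """Grid points (bin centres, strictly inside (0,1)) along one dimension."""
    inc = GRID_INCREMENTS[m]
    return np.arange(inc / 2.0, 1.0, inc)


# ---------------------------------------------------------------------------
# stationary distributions and implied entropy
# ---------------------------------------------------------------------------

def binary_entropy(q):
    """Entropy (nats) of a Bernoulli(q) outcome, with 0*ln(0) = 0."""
    q = np.asarray(q, dtype=float)
    return -(xlogy(q, q) + xlogy(1.0 - q, 1.0 - q))


def stationary_distribution(q, m: int) -> np.ndarray:
    """Unconditional probabilities of the ``2**m`` length-``m`` contexts.

    ``q[..., c]`` is the probability of outcome A after context ``c``. For
    ``m=0`` returns ``[1-q, q]`` (probabilities of B and A). Components of
    ``q`` exactly at 0 or 1 are clamped inward by 1e-9 so the implied chain is
    irreducible and the stationary distribution unique; the solver never
    returns NaN silently.

    Supports arbitrary leading batch dimensions on ``q``.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("all components of q must lie in [0, 1]")
    q = np.clip(q, _Q_CLAMP, 1.0 - _Q_CLAMP)
    if m == 0:
        q = q.reshape(q.shape[:-1]) if q.ndim and q.shape[-1] == 1 else q
        return np.stack([1.0 - q, q], axis=-1)
    n = 2 ** m
    if q.shape[-1] != n:
        raise ValueError(f"q must have {n} components for m={m}; got shape {q.shape}")
    batch = q.shape[:-1]
    # transition matrix over contexts: c -> (c<<1 | x) mod n, with prob q_c for x=1
    M = np.zeros(batch + (n, n), dtype=float)
    idx = np.arange(n)
    succ1 = ((idx << 1) | 1) & (n - 1)
    succ0 = (idx << 1) & (n - 1)
    M[..., idx, succ1] = q
    M[..., idx, succ0] = 1.0 - q
    # solve pi (M - I) = 0 with sum(pi) = 1: rows of A are (M^T - I), last row ones
    A = np.swapaxes(M, -1, -2) - np.eye(n)
    A[..., -1, :] = 1.0
    b = np.zeros(batch + (n,))
    b[..., -1] = 1.0
    pi = np.linalg.solve(A, b[..., None])[..., 0]
    # numerical guard: tiny negatives from ill-conditioned corners
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum(axis=-1, keepdims=True)


def implied_entropy(q, m: int) -> np.ndarray:
    """Outcome entropy ``H(X;q)`` (nats) of the order-``m`` chain.

    The average of the conditional outcome entropies, weighted by the
    stationary probabilities of the contexts; lies in [0, ln 2]. Supports
    batch dimensions on ``q``.
    """
    q = np.asarray(q, dtype=float)
    if m == 0:
        return binary_entropy(q if q.ndim == 0 or q.shape[-1:] != (1,) else q[..., 0])
    pi = stationary_distribution(q, m)
    return np.sum(pi * binary_entropy(np.clip(q, 0.0, 1.0)), axis=-1)


class BistableModeError(ValueError):
    """The asymptotic posterior mode is not unique (p=0.5, lambda_u > 1).

    In this regime the inferred probability alternates between two values
    placed symmetrically above and below 0.5; both are stored in ``modes``.
    """

    def __init__(self, modes):
        self.modes = tuple(modes)
        super().__init__(
            f"bistable regime: the asymptotic objective has two modes {self.modes}"
        )


def asymptotic_mode(p: float, lambda_u: float, m: int = 0) -> float:
    """Asymptotic mode ``q*`` of the unpredictability-cost posterior (m=0).

    Maximises ``p ln q + (1-p) ln(1-q) - lambda_u * H(q)`` over ``q`` in
    (0, 1). ``q*`` is always at least as extreme as ``p``; with ``lambda_u=0``
    it equals ``p``. For ``p = 0.5`` and ``lambda_u > 1`` the objective has two
    symmetric maxima and :class:`BistableModeError` is raised.
    """
    if m != 0:
        raise NotImplementedError("asymptotic_mode is defined for the Bernoulli observer (m=0)")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    if lambda_u < 0:
        raise ValueError("lambda_u must be >= 0")

    def objective(q):
        return p * np.log(q) + (1.0 - p) * np.log1p(-q) - lambda_u * binary_entropy(q)

    def grad(q):
        return p / q - (1.0 - p) / (1.0 - q) + lambda_u * (np.log(q) - np.log1p(-q))

    eps = 1e-12
    grid = np.linspace(eps, 1.0 - eps, 20001)
    g = grad(grid)
    sign_change = np.nonzero(np.diff(np.signbit(g)))[0]
    roots = [brentq(grad, grid[i], grid[i + 1], xtol=1e-14) for i in sign_change]
    if not roots:
        # monotone gradient: maximum at the boundary side of p (cannot happen
        # for lambda_u >= 0 with interior p, but guard anyway)
        roots = [p]
    values = [objective(r) for r in roots]
    best = float(np.max(values))
    top = [r for r, v in zip(roots, values) if v >= best - 1e-12]
    if len(top) > 1 and abs(top[0] + top[-1] - 1.0) < 1e-6:
        raise BistableModeError((top[0], top[-1]))
    return float(top[int(np.argmax([objective(r) for r in top]))])


# ---------------------------------------------------------------------------
# precision-cost observer: exponentially filtered pattern counts
# ---------------------------------------------------------------------------

class PrecisionBelief:
    """Sufficient statistic of the precision-cost observer.

    Holds the exponentially filtered counts of all ``2**(m+1)`` patterns of
    ``m+1`` consecutive stimuli, with decay ``gamma = 1/(1+lambda_p)`` applied
    at every update. With ``lambda_p = 0`` the counts are the raw Bayesian
    pattern counts. For ``m > 0`` the first ``m`` stimuli of a sequence only
    build the conditioning context.
    """

    def __init__(self, m: int = 0, lambda_p: float = 0.0):
        if not 0 <= m <= 3:
            raise ValueError("m must be in {0, 1, 2, 3}")
        if lambda_p < 0:
            raise ValueError("lambda_p must be >= 0")
        self.m = m
        self.lambda_p = float(lambda_p)
        self.gamma = 1.0 / (1.0 + lambda_p)
        self.counts = np.zeros(2 ** (m + 1))
        self._context: list[int] = []

    @property
    def context(self) -> tuple:
        """The last ``m`` stimuli seen (oldest first); shorter during warm-up."""
        return tuple(self._context)

    @property
    def context_index(self) -> int | None:
        if len(self._context) < self.m:
            return None
        idx = 0
        for s in self._context:
            idx = (idx << 1) | s
        return idx

    def update(self, x: int) -> "PrecisionBelief":
        """Observe one stimulus: decay all counts, then count the new pattern."""
        x = int(x)
        if x not in (0, 1):
            raise ValueError("stimulus must be 0 or 1")
        self.counts *= self.gamma
        ctx = self.context_index
        if ctx is not None:
            self.counts[(ctx << 1) | x] += 1.0
        self._context.append(x)
        if len(self._context) > self.m:
            self._context = self._context[-self.m:] if self.m else []
        return self

    def predictive(self) -> float:
        """Mean posterior probability that the next stimulus is A.

        Laplace-style ratio of the filtered counts within the current context:
        ``(n_ctx,A + 1) / (n_ctx,A + n_ctx,B + 2)``. Returns 0.5 while the
        context is still incomplete (fewer than ``m`` stimuli seen).
        """
        ctx = self.context_index
        if ctx is None:
            return 0.5
        a = self.counts[(ctx << 1) | 1]
        b = self.counts[ctx << 1]
        return (a + 1.0) / (a + b + 2.0)

    # -- serialization -----------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "kind": "precision", "m": self.m, "lambda_p": self.lambda_p,
            "counts": self.counts.tolist(), "context": self._context,
        })

    @classmethod
    def from_json(cls, blob: str) -> "PrecisionBelief":
        d = json.loads(blob)
        obj = cls(d["m"], d["lambda_p"])
        obj.counts = np.asarray(d["counts"], dtype=float)
        obj._context = [int(s) for s in d["context"]]
        return obj


# ---------------------------------------------------------------------------
# grid posterior: unpredictability-cost and hybrid observers
# ---------------------------------------------------------------------------

_ENTROPY_CACHE: dict[int, np.ndarray] = {}


def entropy_tensor(m: int) -> np.ndarray:
    """``H(X;q)`` evaluated on the full grid, shape ``(n,)*2**m``.

    Cached per order. For ``m=3`` this is a 10**8-point table computed by a
    chunked batched linear solve; building it takes minutes and ~1 GB — it is
    the price of the full transition-probability grid at that order.
    """
    if m in _ENTROPY_CACHE:
        return _ENTROPY_CACHE[m]
    axis = grid_axis(m)
    ndim = 2 ** m
    shape = (axis.size,) * ndim
    if m == 0:
        H = binary_entropy(axis)
    elif m == 1:
        # tensor axis c corresponds to context c: axis 0 = q_B, axis 1 = q_A
        qB, qA = np.meshgrid(axis, axis, indexing="ij")
        pA = qB / (1.0 + qB - qA)
        H = pA * binary_entropy(qA) + (1.0 - pA) * binary_entropy(qB)
    else:
        total = axis.size ** ndim
        H = np.empty(total)
        chunk = 1_000_000
        for start in range(0, total, chunk):
            stop = min(start + chunk, total)
            flat = np.arange(start, stop)
            qs = np.empty((stop - start, ndim))
            for d in range(ndim):
                div = axis.size ** (ndim - 1 - d)
                qs[:, d] = axis[(flat // div) % axis.size]
            H[start:stop] = implied_entropy(qs, m)
        H = H.reshape(shape)
    _ENTROPY_CACHE[m] = H.reshape(shape)
    return _ENTROPY_CACHE[m]


class QGridPosterior:
    """Discretised posterior over ``q`` for unpredictability/hybrid observers.

    The state consists of raw pattern counts (and, when a precision cost is
    present, exponentially filtered counts and the discounted time ``S_t``);
    the log posterior over the grid is a deterministic function of that state,
    so it is recomputed on demand rather than stored.
    """

    def __init__(self, m: int = 0, lambda_u: float = 0.0, lambda_p: float = 0.0):
        if not 0 <= m <= 3:
            raise ValueError("m must be in {0, 1, 2, 3}")
        if lambda_u < 0 or lambda_p < 0:
            raise ValueError("cost weights must be >= 0")
        self.m = m
        self.lambda_u = float(lambda_u)
        self.lambda_p = float(lambda_p)
        self.gamma = 1.0 / (1.0 + lambda_p)
        self.axis = grid_axis(m)
        self.exact_counts = np.zeros(2 ** (m + 1))
        self.filtered_counts = np.zeros(2 ** (m + 1))
        self.t = 0            # number of belief updates (full patterns observed)
        self.S = 0.0          # discounted time  S_t = gamma * (1 + S_{t-1})
        self._context: list[int] = []

    @property
    def context(self) -> tuple:
        return tuple(self._context)

    @property
    def context_index(self) -> int | None:
        if len(self._context) < self.m:
            return None
        idx = 0
        for s in self._context:
            idx = (idx << 1) | s
        return idx

    def update(self, x: int) -> "QGridPosterior":
        x = int(x)
        if x not in (0, 1):
            raise ValueError("stimulus must be 0 or 1")
        ctx = self.context_index
        if ctx is not None:
            self.filtered_counts *= self.gamma
            k = (ctx << 1) | x
            self.exact_counts[k] += 1.0
            self.filtered_counts[k] += 1.0
            self.t += 1
            self.S = self.gamma * (1.0 + self.S)
        self._context.append(x)
        if len(self._context) > self.m:
            self._context = self._context[-self.m:] if self.m else []
        return self

    def _count_state(self):
        """Counts and time factor entering the grid log-weights."""
        if self.lambda_p > 0:
            return self.filtered_counts, self.S
        return self.exact_counts, float(self.t)

    def log_weights(self) -> np.ndarray:
        """Unnormalised log posterior on the grid, shape ``(n,)*2**m``."""
        counts, tau = self._count_state()
        n = self.axis.size
        ndim = 2 ** self.m
        lw = -self.lambda_u * tau * entropy_tensor(self.m)
        log_q = np.log(self.axis)
        log_1mq = np.log1p(-self.axis)
        for c in range(ndim):
            shape = [1] * ndim
            shape[c] = n
            lw = lw + counts[(c << 1) | 1] * log_q.reshape(shape) \
                    + counts[c << 1] * log_1mq.reshape(shape)
        return lw

    def posterior(self) -> np.ndarray:
        """Normalised posterior weights on the grid (sums to 1)."""
        lw = self.log_weights()
        w = np.exp(lw - lw.max())
        return w / w.sum()

    def predictive(self) -> float:
        """Posterior-mean probability that the next stimulus is A.

        The grid-weighted mean of ``q_ctx`` for the current context; 0.5 while
        the context is incomplete.
        """
        ctx = self.context_index
        if ctx is None:
            return 0.5
        w = self.posterior()
        marg = np.moveaxis(w, ctx, 0).reshape(self.axis.size, -1).sum(axis=1)
        return float(marg @ self.axis)

    def map_estimate(self) -> np.ndarray:
        """Grid point with the highest posterior weight (vector of length 2**m)."""
        lw = self.log_weights()
        flat = int(np.argmax(lw))
        idx = np.unravel_index(flat, lw.shape)
        return self.axis[np.asarray(idx)]

    # -- serialization -----------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "kind": "grid", "m": self.m, "lambda_u": self.lambda_u,
            "lambda_p": self.lambda_p, "exact_counts": self.exact_counts.tolist(),
            "filtered_counts": self.filtered_counts.tolist(), "t": self.t,
            "S": self.S, "context": self._context,
        })

    @classmethod
    def from_json(cls, blob: str) -> "QGridPosterior":
        d = json.loads(blob)
        obj = cls(d["m"], d["lambda_u"], d["lambda_p"])
        obj.exact_counts = np.asarray(d["exact_counts"], dtype=float)
        obj.filtered_counts = np.asarray(d["filtered_counts"], dtype=float)
        obj.t = int(d["t"])
        obj.S = float(d["S"])
        obj._context = [int(s) for s in d["context"]]
        return obj


def make_observer(spec: ModelSpec):
    """Instantiate the stateful observer matching a :class:`ModelSpec`."""
    if spec.cost == "precision":
        return PrecisionBelief(spec.m, spec.lambda_p)
    return QGridPosterior(spec.m, spec.lambda_u, spec.lambda_p)


def predictive_path(spec: ModelSpec, stimuli: Sequence[int], n_skip: int) -> np.ndarray:
    """Observer's predictive probability of A before each of the last trials.

    Runs the observer of ``spec`` over ``stimuli`` (one block; the observer
    starts fresh) and returns, for every trial index ``t >= n_skip``, the
    predictive probability evaluated *before* stimulus ``t`` is revealed —
    i.e. the quantity the response model acts on during active trials. This is
    the vectorised engine entry point; it matches the stateful classes to
    floating-point accuracy.
    """
    from . import _engine
    return _engine.predictive_path(spec, np.asarray(stimuli, dtype=np.int8), int(n_skip))
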