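"""Maximum-likelihood fitting of observer models to a subject's responses.

The likelihood of a trial table under a :class:`~costbayes.models.ModelSpec`
is the product, over non-missing active trials, of the probability the
response model assigns to the recorded response given the observer's
predictive probability at that trial. Observer state resets at each block;
passive stimuli (and the stimuli of missed trials) update the observer but
contribute no likelihood terms.

Optimisation is over log-transformed cost weights and matching exponent
(``ln lambda``, ``ln kappa``) with bounded quasi-Newton refinement (L-BFGS-B)
from the best points of a fixed log-spaced start grid, so fits are
deterministic given the data and the grid. :class:`CostlyInferenceModel`
wraps the procedure as a scikit-learn estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import _engine
from .models import ModelSpec
from .response import choice_probability

#: optimisation bounds on the natural scale
DEFAULT_BOUNDS = {"lambda": (1e-4, 1e3), "kappa": (1e-3, 50.0), "eta": (-0.99, 0.99)}
#: fixed multi-start grid (log-spaced), per parameter
START_LAMBDA = (0.01, 0.1, 1.0, 10.0)
START_KAPPA = (0.5, 1.26, 3.17, 8.0)

LIKELIHOOD_FLOOR = 1e-12


class FittingError(RuntimeError):
    """All optimisation starts failed."""


@dataclass
class LikelihoodResult:
    total: float
    per_trial: np.ndarray      # log-probability of each scored response
    n_obs: int
    n_floored: int             # responses whose probability was floored


@dataclass
class FitResult:
    spec: ModelSpec
    log_likelihood: float
    n_obs: int
    n_params: int
    bic: float
    log_evidence: float
    n_starts: int
    converged: bool
    lambda_identifiable: bool = True


def information_criteria(log_likelihood: float, d: int, n_obs: int):
    """BIC and the Laplace/BIC approximation of the log model evidence."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    penalty = 0.5 * d * np.log(n_obs)
    return -2.0 * (log_likelihood - penalty), log_likelihood - penalty


# ---------------------------------------------------------------------------
# prepared per-subject data with parameter-free caches
# ---------------------------------------------------------------------------

class PreparedSubject:
    """Per-block arrays of one subject plus caches reusable across parameter
    evaluations (pattern one-hots, cumulative grid counts, count x log-grid
    products)."""

    def __init__(self, table: pd.DataFrame):
        self.blocks = []
        for _, blk in table.groupby("block_index", sort=True):
            blk = blk.sort_values("trial_index")
            stim = blk["stimulus"].to_numpy(dtype=np.int8)
            phase = blk["phase"].to_numpy()
            n_passive = int((phase == "passive").sum())
            if np.any(phase[:n_passive] != "passive"):
                raise ValueError("passive trials must precede active trials in each block")
            resp = blk["response"].to_numpy(dtype=float)[n_passive:]
            self.blocks.append({"stimuli": stim, "n_passive": n_passive, "responses": resp})
        if not self.blocks:
            raise ValueError("empty trial table")
        self.n_obs = int(sum(np.isfinite(b["responses"]).sum() for b in self.blocks))
        self._grid_cache: dict[int, list] = {}
        self._prev_resp: list[np.ndarray] | None = None

    def grid_state(self, m: int):
        """Cumulative count rows / update counts / contexts per block (pure
        unpredictability observers; independent of parameters).

        The cached count x log-grid products are stored in single precision:
        they feed the optimisation fast path only; reported likelihoods are
        recomputed in double precision at the optimum."""
        if m not in self._grid_cache:
            axis, Q, L, H = _engine.grid_tables(m)
            logF, tau, ctx_all, sizes = [], [], [], []
            for b in self.blocks:
                rows, t = _engine.grid_count_state(b["stimuli"], b["n_passive"], m)
                ctx, _ = _engine.pattern_context_indices(b["stimuli"], m)
                logF.append(rows @ L)
                tau.append(t)
                ctx_all.append(ctx[np.arange(b["n_passive"], len(b["stimuli"]))])
                sizes.append(len(t))
            logF = np.concatenate(logF).astype(np.float32)   # (n_active_total, G)
            self._grid_cache[m] = {
                "logF": logF,
                "tau": np.concatenate(tau).astype(np.float32)[:, None],
                "ctx": np.concatenate(ctx_all),
                "sizes": sizes,
                "H": H.astype(np.float32)[None, :],
                "Q": Q.astype(np.float32),
                "buf": np.empty_like(logF),
            }
        return self._grid_cache[m]

    def prev_responses(self):
        """Last recorded (non-missing) response before each active trial."""
        if self._prev_resp is None:
            out = []
            for b in self.blocks:
                r = pd.Series(b["responses"])
                out.append(r.shift(1).ffill().to_numpy())
            self._prev_resp = out
        return self._prev_resp


def _pbar_blocks(prep: PreparedSubject, spec: ModelSpec, fast: bool = False):
    """Predictive probability of A at each active trial, per block.

    With ``fast=True``, pure unpredictability models use the cached
    single-precision count tables (used inside the optimisation loop)."""
    if spec.cost == "precision":
        return [_engine.precision_path(b["stimuli"], b["n_passive"], spec.m, spec.lambda_p)
                for b in prep.blocks]
    if fast and spec.cost == "unpredictability" and spec.m <= 2:
        st = prep.grid_state(spec.m)
        lw = np.multiply(st["tau"], st["H"], out=st["buf"])
        lw *= np.float32(-spec.lambda_u)
        lw += st["logF"]
        lw -= lw.max(axis=1, keepdims=True)
        w = np.exp(lw, out=lw)
        means = (w @ st["Q"]) / w.sum(axis=1, keepdims=True)
        pbar = means[np.arange(means.shape[0]), st["ctx"]].astype(float)
        return np.split(pbar, np.cumsum(st["sizes"])[:-1])
    return [_engine.grid_path(b["stimuli"], b["n_passive"], spec.m,
                              spec.lambda_u, spec.lambda_p)
            for b in prep.blocks]


def _loglik_prepared(prep: PreparedSubject, spec: ModelSpec,
                     floor: float = LIKELIHOOD_FLOOR, fast: bool = False) -> LikelihoodResult:
    contribs = []
    n_floored = 0
    prevs = prep.prev_responses() if spec.eta != 0 else [None] * len(prep.blocks)
    for b, pbar, prev in zip(prep.blocks, _pbar_blocks(prep, spec, fast=fast), prevs):
        resp = b["responses"]
        scored = np.isfinite(resp)
        cp = choice_probability(pbar, spec.kappa)
        if spec.eta != 0:
            a = abs(spec.eta)
            target = 1.0 if spec.eta >= 0 else 0.0
            stick = (prev == target).astype(float)
            cp = np.where(np.isnan(prev), cp, (1.0 - a) * cp + a * stick)
        p_resp = np.where(resp[scored] == 1.0, cp[scored], 1.0 - cp[scored])
        n_floored += int((p_resp < floor).sum())
        contribs.append(np.log(np.maximum(p_resp, floor)))
    per_trial = np.concatenate(contribs) if contribs else np.empty(0)
    return LikelihoodResult(float(per_trial.sum()), per_trial, per_trial.size, n_floored)


def trial_log_likelihood(spec: ModelSpec, table: pd.DataFrame,
                         floor: float = LIKELIHOOD_FLOOR) -> LikelihoodResult:
    """Log-likelihood of the responses in ``table`` under ``spec``.

    Returns the total and the per-trial log contributions (one per non-missing
    active trial, in table order). Probabilities below ``floor`` are floored
    and counted in ``n_floored``.
    """
    return _loglik_prepared(PreparedSubject(table), spec, floor)


# ---------------------------------------------------------------------------
# maximum-likelihood estimation
# ---------------------------------------------------------------------------

def _param_names(cost: str, fit_eta: bool):
    names = {"precision": ["lambda_p"], "unpredictability": ["lambda_u"],
             "hybrid": ["lambda_p", "lambda_u"]}[cost] + ["kappa"]
    if fit_eta:
        names.append("eta")
    return names


def _spec_from_vector(template: ModelSpec, names, x):
    kw = {}
    for name, v in zip(names, x):
        kw[name] = float(v) if name == "eta" else float(np.exp(v))
    return template.with_params(**kw)


def _start_grid(names):
    axes = []
    for name in names:
        if name.startswith("lambda"):
            axes.append(np.log(START_LAMBDA))
        elif name == "kappa":
            axes.append(np.log(START_KAPPA))
        else:  # eta
            axes.append(np.array([-0.3, 0.0, 0.3]))
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in mesh], axis=1)


def fit_mle(spec_template: ModelSpec, table: pd.DataFrame, *,
            fit_eta: bool = False, bounds: dict | None = None,
            n_refine: int = 2, floor: float = LIKELIHOOD_FLOOR,
            _prepared: PreparedSubject | None = None) -> FitResult:
    """Maximise the likelihood of ``table`` over the free parameters of
    ``spec_template`` (cost weights and kappa; eta too if ``fit_eta``).

    The search evaluates a fixed log-spaced start grid, refines the best
    ``n_refine`` starts with bounded L-BFGS-B in log coordinates, and returns
    the overall best. The inner loop uses the single-precision fast path (with
    a correspondingly coarse finite-difference step); the reported likelihood
    is recomputed in double precision at the optimum. Deterministic given the
    table and grid.
    """
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    prep = _prepared if _prepared is not None else PreparedSubject(table)
    names = _param_names(spec_template.cost, fit_eta)

    lo, hi = [], []
    for name in names:
        key = "lambda" if name.startswith("lambda") else name
        l, h = b[key]
        if name == "eta":
            lo.append(l), hi.append(h)
        else:
            lo.append(np.log(l)), hi.append(np.log(h))
    opt_bounds = list(zip(lo, hi))

    def neg_ll(x):
        spec = _spec_from_vector(spec_template, names, x)
        return -_loglik_prepared(prep, spec, floor, fast=True).total

    starts = np.clip(_start_grid(names), lo, hi)
    start_vals = np.array([neg_ll(x) for x in starts])
    order = np.argsort(start_vals, kind="stable")

    best_x, best_val, converged = None, np.inf, False
    for i in order[:max(1, n_refine)]:
        try:
            res = minimize(neg_ll, starts[i], method="L-BFGS-B", bounds=opt_bounds,
                           options={"maxiter": 200, "eps": 1e-4})
        except Exception:
            continue
        if res.fun < best_val:
            best_x, best_val, converged = res.x, float(res.fun), bool(res.success)
    if best_x is None:
        raise FittingError("all optimisation starts failed")
    # the raw grid may beat a stalled refinement
    i_grid = int(order[0])
    if start_vals[i_grid] < best_val:
        best_x, best_val = starts[i_grid], float(start_vals[i_grid])

    spec = _spec_from_vector(spec_template, names, best_x)
    logL = _loglik_prepared(prep, spec, floor).total
    d = len(names)
    bic, log_ev = information_criteria(logL, d, prep.n_obs)

    # flat-likelihood flag: when the fit barely improves on the coin-flip null
    # (kappa ~ 0), the likelihood is flat in the cost weight
    lambda_identifiable = bool(logL - prep.n_obs * np.log(0.5) >= 3.0)

    return FitResult(spec=spec, log_likelihood=logL, n_obs=prep.n_obs, n_params=d,
                     bic=bic, log_evidence=log_ev, n_starts=len(starts),
                     converged=converged, lambda_identifiable=lambda_identifiable)


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class CostlyInferenceModel(BaseEstimator):
    """Cost-constrained observer model as a scikit-learn estimator.

    Parameters mirror the model structure (cost family, Markov order, whether
    the repetition propensity is fitted); ``fit`` expects a canonical trial
    table (one subject) and estimates the cost weight(s) and the matching
    exponent by maximum likelihood.

    Attributes set by :meth:`fit` (trailing underscore): ``spec_``,
    ``lambda_p_``, ``lambda_u_``, ``kappa_``, ``eta_``, ``log_likelihood_``,
    ``bic_``, ``log_evidence_``, ``n_obs_``, ``converged_``.
    """

    def __init__(self, cost: str = "precision", m: int = 0, fit_eta: bool = False,
                 n_refine: int = 2, bounds: dict | None = None):
        self.cost = cost
        self.m = m
        self.fit_eta = fit_eta
        self.n_refine = n_refine
        self.bounds = bounds

    def _template(self) -> ModelSpec:
        return ModelSpec(self.cost, m=self.m, kappa=1.0,
                         lambda_p=1.0 if self.cost in ("precision", "hybrid") else 0.0,
                         lambda_u=1.0 if self.cost in ("unpredictability", "hybrid") else 0.0)

    def fit(self, X: pd.DataFrame, y=None) -> "CostlyInferenceModel":
        res = fit_mle(self._template(), X, fit_eta=self.fit_eta,
                      bounds=self.bounds, n_refine=self.n_refine)
        self.result_ = res
        self.spec_ = res.spec
        self.lambda_p_ = res.spec.lambda_p
        self.lambda_u_ = res.spec.lambda_u
        self.kappa_ = res.spec.kappa
        self.eta_ = res.spec.eta
        self.log_likelihood_ = res.log_likelihood
        self.bic_ = res.bic
        self.log_evidence_ = res.log_evidence
        self.n_obs_ = res.n_obs
        self.converged_ = res.converged
        return self

    def _check_fitted(self):
        if not hasattr(self, "spec_"):
            raise AttributeError("this CostlyInferenceModel instance is not fitted yet")

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Choice probabilities ``[P(B), P(A)]`` for every active trial of X."""
        self._check_fitted()
        prep = PreparedSubject(X)
        pa = np.concatenate([choice_probability(p, self.spec_.kappa)
                             for p in _pbar_blocks(prep, self.spec_)])
        return np.column_stack([1.0 - pa, pa])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean per-response log-likelihood of the recorded responses."""
        self._check_fitted()
        res = _loglik_prepared(PreparedSubject(X), self.spec_)
        return res.total / max(res.n_obs, 1)
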