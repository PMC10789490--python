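"""Random-effects Bayesian model selection and model-recovery analysis.

Given each subject's (approximate) log model evidence, the random-effects
procedure infers a Dirichlet posterior over the frequencies of the candidate
models in the population via the standard variational iteration, from which
family expected probabilities and exceedance probabilities (the posterior
probability that a family is the most prevalent) are derived by summation and
Monte-Carlo sampling respectively.

``confusion_matrix`` checks model recovery end to end: subjects are simulated
from each candidate model at randomly drawn parameters, refitted with every
candidate, and classified by lowest BIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma

from .design import ExperimentDesign
from .fitting import PreparedSubject, fit_mle
from .models import ModelSpec
from .synthetic import simulate_subject

_COST_ORDER = {"precision": 0, "unpredictability": 1, "hybrid": 2}


@dataclass
class BMSResult:
    """Dirichlet posterior over model frequencies in the population."""
    alpha: np.ndarray
    models: list
    alpha0: float
    n_subjects: int
    n_iter: int

    @property
    def expected_probs(self) -> pd.Series:
        """Expected population frequency of each model, alpha / sum(alpha)."""
        return pd.Series(self.alpha / self.alpha.sum(), index=self.models)

    def _family_mask(self, family) -> np.ndarray:
        family = set(family)
        unknown = family - set(self.models)
        if unknown:
            raise ValueError(f"unknown models in family: {sorted(unknown)}")
        if not family:
            raise ValueError("family must be non-empty")
        return np.array([m in family for m in self.models])


def bms_fit(log_evidence, models=None, alpha0: float = 1.0,
            tol: float = 1e-8, max_iter: int = 10_000) -> BMSResult:
    """Fit the Dirichlet posterior over model frequencies.

    ``log_evidence`` is a subjects x models array or DataFrame (columns are
    model labels). The variational fixed point iterates responsibilities
    ``u_nm  propto  exp(ln p(y_n|m) + psi(alpha_m) - psi(sum alpha))`` and
    ``alpha_m = alpha0 + sum_n u_nm`` until the update changes alpha by less
    than ``tol``.
    """
    if isinstance(log_evidence, pd.DataFrame):
        models = list(log_evidence.columns)
        lev = log_evidence.to_numpy(dtype=float)
    else:
        lev = np.asarray(log_evidence, dtype=float)
        models = list(models) if models is not None else list(range(lev.shape[1]))
    if lev.ndim != 2 or lev.shape[1] < 2:
        raise ValueError("log_evidence must be a subjects x models table with >= 2 models")
    if not np.all(np.isfinite(lev)):
        raise ValueError("log-evidence entries must be finite")
    n, M = lev.shape
    lev = lev - lev.max(axis=1, keepdims=True)
    alpha = np.full(M, float(alpha0))
    for it in range(1, max_iter + 1):
        logu = lev + digamma(alpha) - digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            return BMSResult(alpha_new, models, float(alpha0), n, it)
        alpha = alpha_new
    raise RuntimeError(f"BMS did not converge within {max_iter} iterations")


def family_expected_probability(result: BMSResult, family) -> float:
    """Expected population frequency of a family of models (ratio of summed
    Dirichlet parameters); complementary families sum to 1."""
    mask = result._family_mask(family)
    return float(result.alpha[mask].sum() / result.alpha.sum())


def family_exceedance_probability(result: BMSResult, family, n_samples: int = 1_000_000,
                                  rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo probability that the family's summed frequency exceeds 1/2.

    The complement's exceedance computed from the same draws is exactly
    ``1 - value`` (frequency ties have probability zero).
    """
    if n_samples < 10_000:
        raise ValueError("n_samples must be >= 10_000")
    mask = result._family_mask(family)
    rng = rng if rng is not None else np.random.default_rng(0)
    draws = rng.dirichlet(result.alpha, size=int(n_samples))
    return float((draws[:, mask].sum(axis=1) > 0.5).mean())


# ---------------------------------------------------------------------------
# model recovery
# ---------------------------------------------------------------------------

def default_parameter_sampler(template: ModelSpec, rng: np.random.Generator) -> ModelSpec:
    """Draw generating parameters: cost weight log-uniform on [0.05, 5],
    matching exponent uniform on [1, 4]."""
    lam = float(np.exp(rng.uniform(np.log(0.05), np.log(5.0))))
    kappa = float(rng.uniform(1.0, 4.0))
    kw = {"kappa": kappa}
    if template.cost in ("precision", "hybrid"):
        kw["lambda_p"] = lam
    if template.cost in ("unpredictability", "hybrid"):
        kw["lambda_u"] = float(np.exp(rng.uniform(np.log(0.05), np.log(5.0)))) \
            if template.cost == "hybrid" else lam
    return template.with_params(**kw)


def classify_by_bic(bics, models) -> int:
    """Index of the best (lowest-BIC) model; ties go to the smaller Markov
    order, then to the precision cost."""
    bics = np.asarray(bics, dtype=float)
    best = np.min(bics)
    tied = [i for i in range(len(models)) if bics[i] <= best + 1e-9]
    tied.sort(key=lambda i: (models[i].m, _COST_ORDER[models[i].cost]))
    return tied[0]


def confusion_matrix(model_set, n_subjects_per_model: int,
                     design: ExperimentDesign | None = None, *,
                     rng: np.random.Generator | None = None, seed: int | None = None,
                     param_sampler=default_parameter_sampler,
                     n_refine: int = 2, progress=None) -> pd.DataFrame:
    """Model-recovery matrix: rows = generating model, columns = best-fit model.

    Entry (i, j) is the fraction of subjects simulated from model i whose
    lowest-BIC fit is model j; rows sum to 1.
    """
    design = design if design is not None else ExperimentDesign()
    if rng is None:
        rng = np.random.default_rng(seed)
    model_set = list(model_set)
    labels = [m.label for m in model_set]
    counts = np.zeros((len(model_set), len(model_set)))
    for i, gen_template in enumerate(model_set):
        for s in range(n_subjects_per_model):
            gen_spec = param_sampler(gen_template, rng)
            table = simulate_subject(gen_spec, design, rng=rng,
                                     subject_id=f"{labels[i]}-{s:03d}")
            prep = PreparedSubject(table)
            bics = [fit_mle(fit_template, table, n_refine=n_refine,
                            _prepared=prep).bic
                    for fit_template in model_set]
            j = classify_by_bic(bics, model_set)
            counts[i, j] += 1
            if progress is not None:
                progress(labels[i], s, labels[j])
    return pd.DataFrame(counts / n_subjects_per_model, index=labels, columns=labels)
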