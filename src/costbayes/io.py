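"""Canonical file formats, run configuration, and the end-to-end pipeline.

The canonical trial-table CSV has header
``subject_id,block_index,p,trial_index,phase,stimulus,response`` with an empty
``response`` field on passive and missed trials. ``run_pipeline`` ties the
stages together: simulate (or load) trial tables, fit the model grid per
subject, run Bayesian model selection, and compute sequential-effect tables;
all randomness flows from a single root seed through named substreams so any
stage can be reproduced independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ExperimentDesign
from .fitting import PreparedSubject, fit_mle
from .models import ModelSpec
from .selection import bms_fit, family_exceedance_probability, family_expected_probability
from .seqfx import conditional_proportions, effect_differences, pool_by_symmetry
from .synthetic import TRIAL_COLUMNS, simulate_subject


class TrialTableError(ValueError):
    """A trial-table file violates the canonical schema."""


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a canonical trial-table CSV.

    Schema violations are reported with 1-based data line numbers."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    errors = []
    line = df.index + 2  # header is line 1
    bad = ~df["phase"].isin(["passive", "active"])
    for i in line[bad][:5]:
        errors.append(f"line {i}: phase must be 'passive' or 'active'")
    bad = ~((df["p"] > 0) & (df["p"] < 1))
    for i in line[bad][:5]:
        errors.append(f"line {i}: p must lie strictly in (0, 1)")
    bad = ~df["stimulus"].isin([0, 1])
    for i in line[bad][:5]:
        errors.append(f"line {i}: stimulus must be 0 or 1")
    resp = df["response"]
    bad = resp.notna() & ~resp.isin([0.0, 1.0])
    for i in line[bad][:5]:
        errors.append(f"line {i}: response must be 0, 1, or empty")
    bad = (df["phase"] == "passive") & resp.notna()
    for i in line[bad][:5]:
        errors.append(f"line {i}: passive trials cannot carry a response")
    if errors:
        raise TrialTableError(f"{path}: " + "; ".join(errors))
    const_p = df.groupby(["subject_id", "block_index"])["p"].nunique()
    if (const_p > 1).any():
        raise TrialTableError(f"{path}: p must be constant within each block")
    return df[TRIAL_COLUMNS]


def write_trial_table(table: pd.DataFrame, path) -> None:
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def load_external_trials(path, column_map: dict, *, phase_values=("passive", "active"),
                         a_value=1) -> pd.DataFrame:
    """Adapter for externally deposited behavioural data.

    ``column_map`` maps canonical column names to the columns of the deposit's
    native layout; ``phase_values`` gives the native encodings of the passive
    and active phases and ``a_value`` the native stimulus code for outcome A.
    Returns a validated canonical table.
    """
    raw = pd.read_csv(path)
    out = pd.DataFrame({canon: raw[native] for canon, native in column_map.items()})
    out["phase"] = out["phase"].map({phase_values[0]: "passive", phase_values[1]: "active"})
    out["stimulus"] = (out["stimulus"] == a_value).astype(int)
    if "response" in out:
        out["response"] = np.where(out["response"].isna(), np.nan,
                                   (out["response"] == a_value).astype(float))
    else:
        out["response"] = np.nan
    tmp = Path(path).with_suffix(".canonical.tmp.csv")
    out[TRIAL_COLUMNS].to_csv(tmp, index=False)
    try:
        return read_trial_table(tmp)
    finally:
        tmp.unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    seed: int = 0
    costs: tuple = ("precision", "unpredictability")
    orders: tuple = (0, 1)
    n_synthetic_subjects: int = 4
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    block_filter: str = "all"          # all | medium | extreme
    n_refine: int = 2
    bms_alpha0: float = 1.0
    bms_n_samples: int = 1_000_000
    input_csv: str | None = None       # fit this table instead of simulating

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["design"] = asdict(self.design)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        design = d.pop("design", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        if design:
            design["probability_pool"] = tuple(design.get("probability_pool", ()))
            cfg = RunConfig(**{**asdict(cfg), "design": None})
            cfg.design = ExperimentDesign(**design)
        return cfg


def filter_blocks(table: pd.DataFrame, which: str) -> pd.DataFrame:
    """Restrict to medium-probability (0.3 <= p <= 0.7) or extreme blocks."""
    if which == "all":
        return table
    medium = (table["p"] >= 0.3 - 1e-9) & (table["p"] <= 0.7 + 1e-9)
    if which == "medium":
        return table[medium]
    if which == "extreme":
        return table[~medium]
    raise ValueError("block filter must be 'all', 'medium', or 'extreme'")


def fit_model_grid(table: pd.DataFrame, costs, orders, *, n_refine: int = 2,
                   block_filter: str = "all") -> pd.DataFrame:
    """Fit every cost x order model to every subject; one row per subject x model."""
    table = filter_blocks(table, block_filter)
    rows = []
    for subj, sub in table.groupby("subject_id", sort=True):
        prep = PreparedSubject(sub)
        for cost in costs:
            for m in orders:
                template = ModelSpec(cost, m=m,
                                     lambda_p=1.0 if cost != "unpredictability" else 0.0,
                                     lambda_u=1.0 if cost != "precision" else 0.0)
                res = fit_mle(template, sub, n_refine=n_refine, _prepared=prep)
                rows.append({
                    "subject_id": subj, "model": res.spec.label, "cost": cost, "m": m,
                    "lambda_p": res.spec.lambda_p, "lambda_u": res.spec.lambda_u,
                    "kappa": res.spec.kappa, "eta": res.spec.eta,
                    "log_likelihood": res.log_likelihood, "n_obs": res.n_obs,
                    "bic": res.bic, "log_evidence": res.log_evidence,
                })
    return pd.DataFrame(rows)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run simulate -> fit -> select -> seqfx; returns paths of the artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    sim_seq, bms_seq = root.spawn(2)
    log: dict = {"seed": config.seed}

    if config.input_csv:
        trials = read_trial_table(config.input_csv)
        log["input_sha256"] = _sha256(config.input_csv)
    else:
        rng = np.random.default_rng(sim_seq)
        tables = []
        templates = [ModelSpec(cost, m=m,
                               lambda_p=1.0 if cost != "unpredictability" else 0.0,
                               lambda_u=1.0 if cost != "precision" else 0.0)
                     for cost in config.costs for m in config.orders]
        for i in range(config.n_synthetic_subjects):
            spec = templates[i % len(templates)].with_params(kappa=2.0)
            tables.append(simulate_subject(spec, config.design, rng=rng,
                                           subject_id=f"synth-{i + 1:03d}"))
        trials = pd.concat(tables, ignore_index=True)
    trials_path = outdir / "trials.csv"
    write_trial_table(trials, trials_path)
    log["trials_sha256"] = _sha256(trials_path)

    fits = fit_model_grid(trials, config.costs, config.orders,
                          n_refine=config.n_refine, block_filter=config.block_filter)
    fits_path = outdir / "fits.csv"
    fits.to_csv(fits_path, index=False)

    lev = fits.pivot(index="subject_id", columns="model", values="log_evidence")
    bms = bms_fit(lev, alpha0=config.bms_alpha0)
    rng_bms = np.random.default_rng(bms_seq)
    families = {
        "precision": [m for m in lev.columns if m.startswith("precision")],
        "unpredictability": [m for m in lev.columns if m.startswith("unpredictability")],
        "markov": [m for m in lev.columns if not m.endswith("m0")],
        "bernoulli": [m for m in lev.columns if m.endswith("m0")],
    }
    bms_out = {
        "alpha": dict(zip(bms.models, bms.alpha.tolist())),
        "expected_probs": bms.expected_probs.to_dict(),
        "families": {
            name: {
                "expected_probability": family_expected_probability(bms, fam),
                "exceedance_probability": family_exceedance_probability(
                    bms, fam, n_samples=config.bms_n_samples, rng=rng_bms),
            } for name, fam in families.items() if fam and len(fam) < len(lev.columns)
        },
    }
    bms_path = outdir / "bms.json"
    bms_path.write_text(json.dumps(bms_out, indent=2))

    pooled = pool_by_symmetry(trials)
    cond = pd.concat([conditional_proportions(pooled, k) for k in (0, 1, 2, 3)],
                     ignore_index=True)
    seqfx_path = outdir / "seqfx.csv"
    cond.to_csv(seqfx_path, index=False)
    fx = effect_differences(cond[cond["history"].str.len() == 1], ("A", "B"))
    fx.to_csv(outdir / "first_order_effects.csv", index=False)

    log["artifacts"] = {p.name: _sha256(p) for p in
                        (trials_path, fits_path, bms_path, seqfx_path)}
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"trials": trials_path, "fits": fits_path, "bms": bms_path,
            "seqfx": seqfx_path}
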