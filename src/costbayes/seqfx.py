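"""Sequential-effect statistics on trial tables.

All analyses operate on *pooled* data: because the task is binary, behaviour
at stimulus probability ``p`` with outcome A focal is the mirror image of
behaviour at ``1-p`` with B focal. ``pool_by_symmetry`` therefore re-expresses
every block under both labelings (except at p = 0.5, where a single arbitrary
labeling is used), so each pooled probability in {0.05, ..., 0.95} collects
all the evidence about it and the mirror identities hold exactly by
construction.

Conditional proportions ``pbar(A | history)`` are computed for stimulus
histories up to length 3 (most recent stimulus last); histories may span the
passive/active boundary within a block (the observer's state does). Effect
differences between two histories that differ only in the oldest stimulus
isolate the influence of that stimulus: positive = attractive (the past
stimulus pulls predictions toward itself), negative = repulsive.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests



def _flip_block(blk: pd.DataFrame) -> pd.DataFrame:
    out = blk.copy()
    out["p"] = np.round(1.0 - out["p"], 10)
    out["stimulus"] = 1 - out["stimulus"]
    out["response"] = 1.0 - out["response"]  # NaN stays NaN
    return out


def pool_by_symmetry(table: pd.DataFrame, *, rng: np.random.Generator | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Recode a trial table so analyses are indexed by the focal-outcome
    probability ``pooled_p``.

    Each block with p != 0.5 contributes under both labelings (as-is at
    pooled_p = p, and A/B-swapped at pooled_p = 1-p). Blocks at p = 0.5
    contribute once, with the labeling fixed by a per-block coin flip (pooled
    statistics are invariant to this choice up to relabeling).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pieces = []
    for (subj, b), blk in table.groupby(["subject_id", "block_index"], sort=True):
        p = float(blk["p"].iloc[0])
        if abs(p - 0.5) < 1e-9:
            chosen = _flip_block(blk) if rng.random() < 0.5 else blk.copy()
            chosen["orientation"] = "coin"
            pieces.append(chosen)
        else:
            direct = blk.copy()
            direct["orientation"] = "direct"
            mirrored = _flip_block(blk)
            mirrored["orientation"] = "mirror"
            pieces.extend([direct, mirrored])
    pooled = pd.concat(pieces, ignore_index=True)
    pooled = pooled.rename(columns={"p": "pooled_p"})
    return pooled[["subject_id", "block_index", "orientation", "pooled_p",
                   "trial_index", "phase", "stimulus", "response"]]


def _history_strings(length: int):
    return ["".join(h) for h in product("BA", repeat=length)]


def conditional_proportions(pooled: pd.DataFrame, history_len: int) -> pd.DataFrame:
    """Proportion of predictions A conditional on the ``history_len`` preceding
    stimuli, per pooled probability.

    Histories are strings over {A, B}, oldest stimulus first, most recent
    last; ``history_len=0`` gives the unconditional proportion. Cells with no
    conditioning trials are reported with ``n_total = 0`` and NaN proportion.
    """
    if not 0 <= history_len <= 3:
        raise ValueError("history_len must be in {0, 1, 2, 3}")
    histories = _history_strings(history_len)
    counts: dict = {}
    for key, blk in pooled.groupby(["pooled_p", "subject_id", "block_index",
                                    "orientation"], sort=True):
        p = key[0]
        blk = blk.sort_values("trial_index")
        stim = blk["stimulus"].to_numpy()
        resp = blk["response"].to_numpy(dtype=float)
        active = (blk["phase"].to_numpy() == "active") & np.isfinite(resp)
        idx = np.nonzero(active)[0]
        idx = idx[idx >= history_len]
        if idx.size == 0:
            continue
        if history_len:
            hist_codes = np.zeros(idx.size, dtype=int)
            for j in range(1, history_len + 1):
                hist_codes |= stim[idx - j].astype(int) << (j - 1)
        else:
            hist_codes = np.zeros(idx.size, dtype=int)
        pred_a = resp[idx] == 1.0
        for code in np.unique(hist_codes):
            sel = hist_codes == code
            # code bit j-1 holds the stimulus j trials back -> reverse for oldest-first
            hist = "".join("AB"[1 - int((code >> (history_len - k)) & 1)]
                           for k in range(1, history_len + 1)) if history_len else ""
            cell = counts.setdefault((p, hist), [0, 0])
            cell[0] += int(pred_a[sel].sum())
            cell[1] += int(sel.sum())
    rows = []
    for p in sorted(pooled["pooled_p"].unique()):
        for hist in histories:
            n_a, n_tot = counts.get((p, hist), (0, 0))
            prop = n_a / n_tot if n_tot else np.nan
            se = np.sqrt(prop * (1 - prop) / n_tot) if n_tot else np.nan
            rows.append({"p": p, "history": hist, "n_pred_A": n_a,
                         "n_total": n_tot, "prop": prop, "se": se})
    return pd.DataFrame(rows)


def effect_differences(cond: pd.DataFrame, contrast: tuple) -> pd.DataFrame:
    """Per-probability difference of conditional proportions between two
    histories, with error bars 2*sqrt(se1^2 + se2^2).

    Sign convention: with ``contrast = (Ax, Bx)`` a positive difference is an
    attractive effect of the older stimulus.
    """
    h1, h2 = contrast
    a = cond[cond["history"] == h1].set_index("p")
    b = cond[cond["history"] == h2].set_index("p")
    if a.empty or b.empty:
        raise ValueError(f"histories {contrast} not found in the conditional table")
    out = pd.DataFrame({
        "diff": a["prop"] - b["prop"],
        "bar": 2.0 * np.sqrt(a["se"] ** 2 + b["se"] ** 2),
        "n1": a["n_total"], "n2": b["n_total"],
    })
    return out.reset_index()


def exact_tests(cond: pd.DataFrame, contrast: tuple) -> pd.DataFrame:
    """Two-sided Fisher exact test of the contrast at each probability, with
    Holm-Sidak step-down correction across probabilities.

    Degenerate (zero-margin) tables get p = 1."""
    h1, h2 = contrast
    a = cond[cond["history"] == h1].set_index("p")
    b = cond[cond["history"] == h2].set_index("p")
    ps = sorted(set(a.index) & set(b.index))
    raw = []
    for p in ps:
        t = np.array([
            [a.loc[p, "n_pred_A"], a.loc[p, "n_total"] - a.loc[p, "n_pred_A"]],
            [b.loc[p, "n_pred_A"], b.loc[p, "n_total"] - b.loc[p, "n_pred_A"]],
        ], dtype=int)
        if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
            raw.append(1.0)
        else:
            raw.append(float(fisher_exact(t, alternative="two-sided")[1]))
    raw = np.asarray(raw)
    if raw.size:
        with np.errstate(divide="ignore"):  # raw p of exactly 1 is legitimate
            corrected = multipletests(raw, method="holm-sidak")[1]
    else:
        corrected = raw
    return pd.DataFrame({"p": ps, "pvalue": raw, "pvalue_corrected": corrected})


def best_model_groups(fits: pd.DataFrame) -> pd.Series:
    """Map each subject to the cost family of its lowest-BIC model.

    ``fits`` is the output of the fitting stage (one row per subject x model
    with ``bic`` and ``cost`` columns)."""
    best = fits.loc[fits.groupby("subject_id")["bic"].idxmin()]
    return best.set_index("subject_id")["cost"]


def plot_effect_differences(fx: pd.DataFrame, ax=None, label=None):
    """Plot per-probability effect differences with 2-SE bars (needs matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(fx["p"], fx["diff"], yerr=fx["bar"] / 2.0, fmt="o-", label=label,
                capsize=2)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("stimulus generative probability")
    ax.set_ylabel("difference of prediction proportions")
    if label:
        ax.legend()
    return ax


def tree_summary(pooled: pd.DataFrame, max_len: int = 3) -> pd.DataFrame:
    """Binary-tree summary of conditional effects, averaged over probabilities.

    Leaf nodes (histories of length ``max_len``) hold the mean over pooled
    probabilities of ``pbar(A|history) - pbar(A)``; each shorter history's
    node is the average of its two children (the same history preceded by an
    older A or B), so the parent-child averaging identity holds by
    construction.
    """
    uncond = conditional_proportions(pooled, 0).set_index("p")["prop"]
    leaves = conditional_proportions(pooled, max_len)
    values: dict[str, float] = {}
    for hist, grp in leaves.groupby("history"):
        rel = grp.set_index("p")["prop"] - uncond
        values[hist] = float(np.nanmean(rel.to_numpy()))
    for length in range(max_len - 1, 0, -1):
        for hist in _history_strings(length):
            values[hist] = 0.5 * (values["A" + hist] + values["B" + hist])
    rows = [{"history": h, "depth": len(h), "value": v}
            for h, v in sorted(values.items(), key=lambda kv: (len(kv[0]), kv[0]))]
    return pd.DataFrame(rows)
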