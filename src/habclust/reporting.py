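"""Group-level statistics and per-type summary tables.

Cross-type comparisons use one-way ANOVA with Tukey's HSD post hoc
test at alpha = 0.05; pairwise relationships use Pearson correlation;
the population-level active-vs-quiet contrast uses the paired Wilcoxon
signed-rank test across neurons.  Summary tables report mean +/- SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .embedding import FeatureTable
from .event_modulation import PSTH
from .state_modulation import BSRecord


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA plus all-pairs Tukey HSD for one feature."""

    feature: str
    group_labels: tuple[int, ...]
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, mean_diff, ci_low, ci_high, p_adj

    def pair(self, a: int, b: int) -> pd.Series:
        sel = self.pairwise[
            (self.pairwise.group_a == min(a, b)) & (self.pairwise.group_b == max(a, b))
        ]
        if sel.empty:
            raise KeyError((a, b))
        return sel.iloc[0]


def compare_across_types(
    values: np.ndarray, labels: np.ndarray, feature: str = "value", alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA with Tukey HSD across cluster labels.

    Groups with a single member are dropped with a warning; at least
    two groups of n >= 2 must remain.  ``mean_diff`` for a pair (a, b)
    is mean(b) - mean(a), with its Tukey 95% family-wise interval.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    keep = []
    for g in np.unique(labels):
        if (labels == g).sum() >= 2:
            keep.append(g)
        else:
            warnings.warn(f"dropping single-member group {g}")
    mask = np.isin(labels, keep)
    values, labels = values[mask], labels[mask]
    groups = [values[labels == g] for g in keep]
    if len(groups) < 2:
        raise ValueError("need at least two groups with n >= 2")
    f_stat, p = stats.f_oneway(*groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(
        data=tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    pairwise = pd.DataFrame(
        {
            "group_a": frame["group1"].astype(type(keep[0])),
            "group_b": frame["group2"].astype(type(keep[0])),
            "mean_diff": frame["meandiff"].astype(float),
            "ci_low": frame["lower"].astype(float),
            "ci_high": frame["upper"].astype(float),
            "p_adj": frame["p-adj"].astype(float),
        }
    )
    return GroupComparison(
        feature=feature,
        group_labels=tuple(int(g) for g in keep),
        anova_f=float(f_stat),
        anova_p=float(p),
        pairwise=pairwise,
    )


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least three finite pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def population_state_test(records: list[BSRecord]) -> dict:
    """Paired signed-rank test of active vs quiet rates across neurons.

    Returns the p-value and the two population mean rates.  The test
    pairs each neuron's own active and quiet rates, unlike the
    per-neuron epoch-level test.
    """
    fr_a = np.array([r.fr_active for r in records], dtype=float)
    fr_q = np.array([r.fr_quiet for r in records], dtype=float)
    if fr_a.size < 2:
        raise ValueError("need at least two neurons")
    diffs = fr_a - fr_q
    if np.all(diffs == 0):
        p = 1.0
    else:
        mode = "exact" if fr_a.size < 6 else "auto"
        _, p = stats.wilcoxon(fr_a, fr_q, method=mode)
    return {
        "n": int(fr_a.size),
        "p_value": float(p),
        "mean_active": float(fr_a.mean()),
        "mean_quiet": float(fr_q.mean()),
    }


def summarize_types(
    features: FeatureTable,
    labels: np.ndarray,
    isi_bank: np.ndarray | None = None,
    acg_bank: np.ndarray | None = None,
    psths: dict[str, PSTH] | None = None,
) -> dict:
    """Per-type counts, scalar mean +/- SD, and mean curves.

    ``isi_bank``/``acg_bank`` rows and any PSTHs must follow the
    feature-table neuron order.  Returns a dict with a ``table``
    DataFrame and per-type mean curves where inputs were given.
    """
    labels = np.asarray(labels)
    if labels.size != features.n_neurons:
        raise ValueError("labels length does not match the feature table")
    rows = []
    curves: dict[int, dict[str, np.ndarray]] = {}
    scalar_cols = ["rate", "cv", "burst_index"]
    mat = features.to_frame()
    for g in np.unique(labels):
        members = labels == g
        sub = mat.loc[members, scalar_cols]
        row = {"type": int(g), "n": int(members.sum())}
        for c in scalar_cols:
            row[f"{c}_mean"] = float(sub[c].mean())
            row[f"{c}_sd"] = float(sub[c].std(ddof=0))
        rows.append(row)
        curves[int(g)] = {}
        if isi_bank is not None:
            curves[int(g)]["isi_mean"] = isi_bank[members].mean(axis=0)
        if acg_bank is not None:
            curves[int(g)]["acg_mean"] = acg_bank[members].mean(axis=0)
        if psths:
            ids = [nid for nid, m in zip(features.neuron_ids, members) if m]
            stack = [psths[i].rate for i in ids if i in psths]
            if stack:
                curves[int(g)]["psth_mean"] = np.mean(stack, axis=0)
    table = pd.DataFrame(rows).sort_values("type").reset_index(drop=True)
    return {"table": table, "curves": curves}
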