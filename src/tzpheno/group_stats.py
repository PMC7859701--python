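"""Normality-gated multi-group comparisons.

The analysis convention implemented here: a Shapiro-Wilk test per group
gates between one-way ANOVA with Tukey's HSD post hoc (all groups normal
at 0.05) and Kruskal-Wallis with Dunn's post hoc (otherwise); alpha =
0.05 throughout.  Dunn's test uses tie-corrected rank z statistics with
Bonferroni adjustment over all pairs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_DEFAULT = 0.05


@dataclass
class ComparisonResult:
    """Outcome of one multi-group comparison on one metric."""

    metric: str
    group_n: dict
    test_used: str  # "anova_tukey" or "kruskal_dunn"
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, statistic, p_adj, significant
    alpha: float = ALPHA_DEFAULT
    normality_p: dict = field(default_factory=dict)
    parametric_gate: Optional[bool] = None
    forced: bool = False

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "group_n": self.group_n,
            "test_used": self.test_used,
            "omnibus_stat": self.omnibus_stat,
            "omnibus_p": self.omnibus_p,
            "alpha": self.alpha,
            "normality_p": self.normality_p,
            "parametric_gate": self.parametric_gate,
            "forced": self.forced,
            "pairwise": self.pairwise.to_dict(orient="records"),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict:
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        out[str(name)] = arr
    return out


def shapiro_gate(
    groups: Mapping[str, Sequence[float]], alpha: float = ALPHA_DEFAULT
) -> tuple[dict, bool]:
    """Shapiro-Wilk p per group; parametric iff every group passes at alpha."""
    gs = _as_groups(groups)
    pvals = {}
    for name, arr in gs.items():
        if arr.size < 3:
            raise ValueError(f"group {name!r} has n < 3; Shapiro-Wilk needs at least 3")
        pvals[name] = float(stats.shapiro(arr).pvalue)
    parametric = all(p > alpha for p in pvals.values())
    return pvals, parametric


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA_DEFAULT,
    metric: str = "",
) -> ComparisonResult:
    """One-way ANOVA with Tukey's HSD (Tukey-Kramer for unequal n)."""
    gs = _as_groups(groups)
    names = list(gs)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in gs.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
    pooled_var = sum(((a - a.mean()) ** 2).sum() for a in gs.values())
    if pooled_var == 0:
        raise ValueError("degenerate variance: all within-group values identical")
    f_stat, f_p = stats.f_oneway(*gs.values())
    if not np.isfinite(f_stat):  # between-group variance zero
        f_stat, f_p = 0.0, 1.0
    hsd = stats.tukey_hsd(*gs.values())
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        p_adj = float(np.clip(hsd.pvalue[i, j], 0.0, 1.0))
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "statistic": float(hsd.statistic[i, j]),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return ComparisonResult(
        metric=metric,
        group_n={n: int(gs[n].size) for n in names},
        test_used="anova_tukey",
        omnibus_stat=float(f_stat),
        omnibus_p=float(f_p),
        pairwise=pd.DataFrame(rows),
        alpha=alpha,
    )


def _dunn_pairwise(gs: dict, alpha: float) -> pd.DataFrame:
    """Dunn's z tests on pooled ranks, tie-corrected, Bonferroni-adjusted."""
    names = list(gs)
    pooled = np.concatenate([gs[n] for n in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks = {}
    start = 0
    for n in names:
        k = gs[n].size
        mean_ranks[n] = ranks[start : start + k].mean()
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / gs[a].size + 1.0 / gs[b].size))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = float(min(p * n_pairs, 1.0))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": float(z),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA_DEFAULT,
    metric: str = "",
) -> ComparisonResult:
    """Tie-corrected Kruskal-Wallis with Dunn's post hoc test."""
    gs = _as_groups(groups)
    names = list(gs)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in gs.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
    pooled = np.concatenate(list(gs.values()))
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical; Kruskal-Wallis undefined")
    h_stat, h_p = stats.kruskal(*gs.values())
    return ComparisonResult(
        metric=metric,
        group_n={n: int(gs[n].size) for n in names},
        test_used="kruskal_dunn",
        omnibus_stat=float(h_stat),
        omnibus_p=float(h_p),
        pairwise=_dunn_pairwise(gs, alpha),
        alpha=alpha,
    )


def compare_groups(
    data,
    value_col: str = "value",
    group_col: str = "genotype",
    alpha: float = ALPHA_DEFAULT,
    force_test: Optional[str] = None,
    metric: str = "",
) -> ComparisonResult:
    """Normality-gated comparison of a metric across groups.

    ``data`` is either a tidy DataFrame (``group_col``, ``value_col``) or a
    mapping of group name -> values.  The Shapiro-Wilk gate picks ANOVA +
    Tukey when every group is consistent with normality at ``alpha``, and
    Kruskal-Wallis + Dunn otherwise; ``force_test`` overrides the gate
    (recorded in the result).
    """
    if isinstance(data, pd.DataFrame):
        sub = data.dropna(subset=[value_col])
        groups = {
            str(name): g[value_col].to_numpy(dtype=float)
            for name, g in sub.groupby(group_col, sort=False)
        }
    else:
        groups = dict(data)
    if force_test is not None:
        if force_test not in ("anova_tukey", "kruskal_dunn"):
            raise ValueError("force_test must be 'anova_tukey' or 'kruskal_dunn'")
        # the gate is informational when overridden; tolerate degenerate
        # groups (e.g. constant counts) that Shapiro-Wilk cannot handle
        import warnings

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pvals, parametric = shapiro_gate(groups, alpha)
        except Exception:  # noqa: BLE001
            pvals, parametric = {}, None
        chosen = force_test
        forced = True
    else:
        pvals, parametric = shapiro_gate(groups, alpha)
        chosen = "anova_tukey" if parametric else "kruskal_dunn"
        forced = False
    fn = anova_tukey if chosen == "anova_tukey" else kruskal_dunn
    result = fn(groups, alpha=alpha, metric=metric)
    result.normality_p = pvals
    result.parametric_gate = parametric
    result.forced = forced
    return result
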