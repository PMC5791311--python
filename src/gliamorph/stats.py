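"""Pooled nonparametric comparison of per-cell morphometrics.

Cells pooled per condition are compared with a Kruskal–Wallis omnibus test
(chi-square approximation, mid-rank tie correction).  Two pairwise
procedures are available, reflecting common practice: Dunn's z tests on the
pooled ranks, and Holm–Šidák step-down adjustment of the pairwise p-values
(the default).  Summaries are mean ± SEM per condition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "kruskal_wallis", "dunn_posthoc",
           "holm_sidak_adjust", "summarize", "compare_groups"]


@dataclass
class GroupComparison:
    metric: str
    conditions: list[str]
    n: dict[str, int]
    mean: dict[str, float]
    sem: dict[str, float]
    h_statistic: float
    omnibus_p: float
    pairwise: "object"        # DataFrame: pair, z, raw p, adjusted p, method
    posthoc: str = "holm_sidak"


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H and its chi-square p-value.

    Mid-ranks with the standard tie-correction divisor; all-identical input
    degenerates to H = 0, p = 1 (flagged with a warning).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across groups: degenerate H = 0")
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _pooled_ranks(groups: list[np.ndarray]) -> tuple[list[np.ndarray], float]:
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    out = []
    start = 0
    for g in groups:
        out.append(ranks[start:start + len(g)])
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts ** 3 - counts))
    return out, tie_sum


def dunn_posthoc(groups: list[np.ndarray],
                 labels: list[str] | None = None):
    """Dunn's pairwise z statistics on pooled mid-ranks with tie correction.

    Returns a DataFrame with one row per condition pair: z, raw two-sided
    normal p, and Bonferroni-adjusted p (Dunn's classical correction).
    """
    import pandas as pd

    groups = [np.asarray(g, dtype=float) for g in groups]
    labels = labels or [f"group{i}" for i in range(len(groups))]
    rank_groups, tie_sum = _pooled_ranks(groups)
    n_total = sum(len(g) for g in groups)
    var_factor = (n_total * (n_total + 1) / 12.0
                  - tie_sum / (12.0 * (n_total - 1)))
    rows = []
    pairs = list(itertools.combinations(range(len(groups)), 2))
    for i, j in pairs:
        ni, nj = len(groups[i]), len(groups[j])
        diff = rank_groups[i].mean() - rank_groups[j].mean()
        se = np.sqrt(var_factor * (1.0 / ni + 1.0 / nj))
        z = diff / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "z": z, "p_raw": min(p_raw, 1.0)})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.minimum(df["p_raw"] * len(pairs), 1.0)
    df["method"] = "dunn"
    return df


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Holm–Šidák step-down adjustment, returned in the input order.

    Sorted ascending, ``adj_(i) = max_{j<=i} 1 - (1 - p_(j))^(m - j + 1)``
    clipped to 1; monotone non-decreasing along the sorted sequence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - i)
        running = max(running, val)
        adj_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def summarize(groups: list[np.ndarray], labels: list[str] | None = None):
    """Mean ± SEM table per condition (SEM missing for n = 1, with warning)."""
    import pandas as pd

    labels = labels or [f"group{i}" for i in range(len(groups))]
    rows = []
    for name, g in zip(labels, groups):
        g = np.asarray(g, dtype=float)
        if len(g) < 2:
            warnings.warn(f"group {name!r} has n < 2: SEM undefined")
            sem = np.nan
        else:
            sem = float(np.std(g, ddof=1) / np.sqrt(len(g)))
        rows.append({"condition": name, "n": len(g),
                     "mean": float(g.mean()) if len(g) else np.nan, "sem": sem})
    return pd.DataFrame(rows)


def compare_groups(pooled, metric: str, posthoc: str = "holm_sidak",
                   condition_col: str = "condition") -> GroupComparison:
    """Omnibus + pairwise comparison of one metric from a pooled cell table."""
    import pandas as pd

    df = pd.DataFrame(pooled)
    conditions = sorted(df[condition_col].unique())
    groups = [df.loc[df[condition_col] == c, metric].to_numpy(dtype=float)
              for c in conditions]
    usable = [i for i, g in enumerate(groups) if len(g) >= 2]
    if len(usable) < len(groups):
        dropped = [conditions[i] for i in range(len(groups)) if i not in usable]
        warnings.warn(f"conditions with n < 2 excluded: {dropped}")
        conditions = [conditions[i] for i in usable]
        groups = [groups[i] for i in usable]
    h, p = kruskal_wallis(groups)
    pairwise = dunn_posthoc(groups, conditions)
    if posthoc == "holm_sidak":
        pairwise = pairwise.copy()
        pairwise["p_adj"] = holm_sidak_adjust(pairwise["p_raw"].to_numpy())
        pairwise["method"] = "holm_sidak"
    elif posthoc != "dunn":
        raise ValueError("posthoc must be 'holm_sidak' or 'dunn'")
    summ = summarize(groups, conditions)
    return GroupComparison(
        metric=metric, conditions=conditions,
        n={r.condition: int(r.n) for r in summ.itertuples()},
        mean={r.condition: r.mean for r in summ.itertuples()},
        sem={r.condition: r.sem for r in summ.itertuples()},
        h_statistic=h, omnibus_p=p, pairwise=pairwise, posthoc=posthoc)
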