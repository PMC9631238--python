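"""Group-comparison statistics and superplot tables.

Omnibus tests delegate to scipy (Kruskal-Wallis, Kolmogorov-Smirnov, t test,
D'Agostino-Pearson normality); the Conover-Iman rank post-hoc is implemented
here (no installed package provides it) and its p-values are Holm-adjusted
with statsmodels.  Groups are considered significantly different at p < 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupedMeasurements",
    "ComparisonResult",
    "conover_pairwise",
    "compare_groups",
    "superplot_table",
]

ALPHA = 0.05


@dataclass
class GroupedMeasurements:
    """Values with a group label and an experiment-day label per value."""

    values: np.ndarray
    groups: np.ndarray
    days: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.days is None:
            self.days = np.full(self.values.shape, "day1", dtype=object)
        else:
            self.days = np.asarray(self.days)
            if any(str(d) == "" for d in self.days):
                raise ValueError("experiment-day labels must be non-empty")
        if not (len(self.values) == len(self.groups) == len(self.days)):
            raise ValueError("values, groups and days must be equal length")

    def by_group(self) -> dict[str, np.ndarray]:
        out = {}
        for g in pd.unique(self.groups):
            out[g] = self.values[self.groups == g]
        return out


@dataclass
class ComparisonResult:
    """Omnibus statistic, pairwise adjusted p-values and normality pre-check."""

    family: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame
    normality: pd.DataFrame
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.omnibus_p < ALPHA


def conover_pairwise(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Conover-Iman pairwise comparisons on pooled ranks.

    Uses the t statistic of Conover & Iman with the pooled rank variance and
    the Kruskal-Wallis statistic correction, df = N - k; two-sided p-values
    are returned unadjusted.
    """
    labels = list(samples)
    k = len(labels)
    ns = np.array([len(samples[g]) for g in labels])
    N = int(ns.sum())
    pooled = np.concatenate([samples[g] for g in labels])
    ranks = sps.rankdata(pooled)
    split = np.split(ranks, np.cumsum(ns)[:-1])
    mean_ranks = {g: float(r.mean()) for g, r in zip(labels, split)}
    H = sps.kruskal(*[samples[g] for g in labels]).statistic
    s2 = (np.sum(ranks ** 2) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    df = N - k
    factor = s2 * (N - 1 - H) / df
    rows = []
    for a, b in itertools.combinations(labels, 2):
        na, nb = len(samples[a]), len(samples[b])
        se = math.sqrt(factor * (1.0 / na + 1.0 / nb))
        t = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.t.sf(abs(t), df)
        rows.append({"group_a": a, "group_b": b, "statistic": t, "p": min(p, 1.0)})
    return pd.DataFrame(rows)


def compare_groups(data: GroupedMeasurements,
                   family: str = "kw_conover_holm") -> ComparisonResult:
    """Compare measurement groups with the requested test family.

    ``kw_conover_holm``: Kruskal-Wallis omnibus plus Conover pairwise tests
    with Holm correction (any number of groups).  ``ks`` and ``t_test``
    compare exactly two groups.  Every group needs at least three values; a
    D'Agostino-Pearson normality check is reported alongside (informative,
    not gating).
    """
    samples = data.by_group()
    if len(samples) < 2:
        raise ValueError("at least two groups are required")
    for g, v in samples.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")

    norm_rows = []
    for g, v in samples.items():
        if len(v) >= 8:
            stat, p = sps.normaltest(v)
        else:
            stat, p = math.nan, math.nan
        norm_rows.append({"group": g, "statistic": stat, "p": p,
                          "normal_at_0.05": bool(p > ALPHA) if not math.isnan(p) else None})
    normality = pd.DataFrame(norm_rows)

    values = list(samples.values())
    if family == "kw_conover_holm":
        res = sps.kruskal(*values)
        pairwise = conover_pairwise(samples)
        adj = multipletests(pairwise["p"].to_numpy(), method="holm")[1]
        pairwise["p_adjusted"] = adj
        pairwise["significant"] = (adj < ALPHA) & (res.pvalue < ALPHA)
        return ComparisonResult(family, float(res.statistic), float(res.pvalue),
                                pairwise, normality)
    if family in ("ks", "t_test"):
        if len(samples) != 2:
            raise ValueError(f"{family} compares exactly two groups")
        a, b = values
        if family == "ks":
            res = sps.ks_2samp(a, b)
        else:
            res = sps.ttest_ind(a, b)
        labels = list(samples)
        pairwise = pd.DataFrame([{
            "group_a": labels[0], "group_b": labels[1],
            "statistic": float(res.statistic), "p": float(res.pvalue),
            "p_adjusted": float(res.pvalue),
            "significant": res.pvalue < ALPHA,
        }])
        return ComparisonResult(family, float(res.statistic), float(res.pvalue),
                                pairwise, normality)
    raise ValueError(f"unknown test family {family!r}")


def superplot_table(data: GroupedMeasurements) -> pd.DataFrame:
    """Long-format superplot table: raw values plus per-day summary rows.

    Each raw measurement becomes a ``kind='value'`` row; each (group, day)
    contributes a ``kind='day_mean'`` row; each group additionally carries
    its quartiles and 10/90th percentiles (linear-interpolation quantiles,
    noted in the ``quantile_rule`` column).
    """
    df = pd.DataFrame({"group": data.groups, "day": data.days, "value": data.values})
    rows = [
        {"group": r.group, "day": r.day, "kind": "value", "value": r.value}
        for r in df.itertuples()
    ]
    for (g, d), sub in df.groupby(["group", "day"]):
        rows.append({"group": g, "day": d, "kind": "day_mean",
                     "value": float(sub.value.mean())})
    out = pd.DataFrame(rows)
    qs = df.groupby("group")["value"].quantile([0.10, 0.25, 0.50, 0.75, 0.90]).unstack()
    qs.columns = ["p10", "q1", "median", "q3", "p90"]
    out = out.merge(qs.reset_index(), on="group", how="left")
    out["quantile_rule"] = "linear"
    return out
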