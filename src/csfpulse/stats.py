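"""Nonparametric cohort comparison and summary reporting.

Independent groups are compared with the two-sided Mann-Whitney rank-sum
test, matched pre/post pairs with the Wilcoxon signed-rank test, both at a
0.05 significance level by default.  For small samples the exact null
distribution is enumerated in-package (all C(n, n_a) rank assignments for
Mann-Whitney up to a pooled n of 12; all 2^n sign assignments for Wilcoxon
up to n of 15), conditioning on observed ties via midranks; beyond those
cutoffs the tie-corrected normal approximation (scipy) is used, and the
method taken is recorded on the result.

Summaries follow the cohort-table conventions: ``median [IQR] (min-max)``
with linear-interpolation (type-7) quantiles, or ``mean +/- SEM``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CohortTable

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "summarize",
    "cohort_report",
    "CohortReport",
]

MW_EXACT_MAX_POOLED_N = 12
WILCOXON_EXACT_MAX_N = 15


@dataclass
class GroupComparison:
    """Result of one two-group test."""

    test: str  # mann_whitney | wilcoxon_signed_rank
    groups: tuple
    n: tuple
    statistic: float
    p_value: float
    method: str  # exact_enumeration | asymptotic | degenerate
    alpha: float = 0.05
    degenerate: bool = False
    metric: str | None = None
    notes: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def mann_whitney(a, b, alpha: float = 0.05, metric: str | None = None,
                 groups: tuple = ("a", "b")) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum test.

    Exact permutation null (brute-force enumeration of rank assignments,
    midranks for ties) when n_a + n_b <= 12; tie-corrected normal
    approximation with continuity correction otherwise.  Identical values
    across both groups give p = 1 with the degenerate flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    mu = n_a * n_b / 2.0

    if np.ptp(pooled) == 0:
        return GroupComparison("mann_whitney", groups, (n_a, n_b), u_a, 1.0,
                               "degenerate", alpha, True, metric)

    if n_a + n_b <= MW_EXACT_MAX_POOLED_N:
        n = n_a + n_b
        obs_dev = abs(u_a - mu)
        offset = n_a * (n_a + 1) / 2.0
        count = total = 0
        for idx in combinations(range(n), n_a):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mu) >= obs_dev - 1e-9:
                count += 1
        p = count / total
        method = "exact_enumeration"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
        method = "asymptotic"
    return GroupComparison("mann_whitney", groups, (n_a, n_b), u_a,
                           min(p, 1.0), method, alpha, False, metric)


def wilcoxon_signed_rank(pre, post, alpha: float = 0.05,
                         metric: str | None = None) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on matched pairs.

    Differences are post - pre; zero differences are dropped and the
    reduced n recorded (``notes["n_zero_dropped"]``).  Exact enumeration
    of all 2^n sign assignments (midranks of |d|) for n <= 15; normal
    approximation with continuity correction beyond.  All-zero
    differences give p = 1 with the degenerate flag.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired vectors must have equal length")
    d = post - pre
    n_zero = int((d == 0).sum())
    d = d[d != 0]
    n = len(d)
    notes = {"n_zero_dropped": n_zero, "zero_policy": "drop_and_reduce_n"}
    if n == 0:
        return GroupComparison("wilcoxon_signed_rank", ("pre", "post"),
                               (len(pre), len(post)), 0.0, 1.0, "degenerate",
                               alpha, True, metric, notes)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0

    if n <= WILCOXON_EXACT_MAX_N:
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1  # all sign patterns
        w_all = signs @ ranks
        p = float((np.abs(w_all - mu) >= abs(w_plus - mu) - 1e-9).mean())
        method = "exact_enumeration"
    else:
        res = sps.wilcoxon(d, correction=True, method="approx")
        p = float(res.pvalue)
        method = "asymptotic"
    return GroupComparison("wilcoxon_signed_rank", ("pre", "post"),
                           (len(pre), len(post)), w_plus, min(p, 1.0), method,
                           alpha, False, metric, notes)


def summarize(values, style: str = "median_iqr_range") -> dict:
    """Summary record in the cohort-table reporting styles.

    ``median_iqr_range`` formats as ``median [IQR] (min-max)`` with
    type-7 (linear interpolation) quantiles; ``mean_sem`` and ``mean_sd``
    as ``mean +/- spread``.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 1:
        raise ValueError("need at least one value")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])  # type-7 linear interpolation
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    rec = {
        "n": len(v),
        "median": float(q50),
        "iqr": float(q75 - q25),
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "sd": sd,
        "sem": sd / np.sqrt(len(v)),
        "style": style,
    }
    if style == "median_iqr_range":
        rec["formatted"] = (
            f"{rec['median']:.1f} [{rec['iqr']:.1f}] ({rec['min']:g}-{rec['max']:g})"
        )
    elif style == "mean_sem":
        rec["formatted"] = f"{rec['mean']:g} ± {rec['sem']:g}"
    elif style == "mean_sd":
        rec["formatted"] = f"{rec['mean']:g} ± {rec['sd']:g}"
    else:
        raise ValueError(f"unknown summary style {style!r}")
    return rec


def _stars(p: float, thresholds: dict) -> str:
    """Most extreme star whose threshold exceeds p."""
    best = ""
    for sym, thr in sorted(thresholds.items(), key=lambda kv: -kv[1]):
        if p < thr:
            best = sym
    return best


@dataclass
class CohortReport:
    rows: pd.DataFrame
    comparisons: list
    missing_pairs: list
    star_thresholds: dict

    def to_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(path, index=False)
        return path

    def to_markdown(self) -> str:
        lines = [self.rows.to_markdown(index=False)]
        stars = ", ".join(f"{s} p<{t:g}" for s, t in
                          sorted(self.star_thresholds.items(), key=lambda kv: -kv[1]))
        lines.append(f"\nSignificance: {stars}. Summaries are median [IQR] (range).")
        if self.missing_pairs:
            lines.append(f"Incomplete pairs (listed, not dropped silently): {self.missing_pairs}")
        return "\n".join(lines)


def cohort_report(
    table: CohortTable,
    plan,
    star_thresholds: dict | None = None,
    alpha: float = 0.05,
    holm: bool = False,
) -> CohortReport:
    """Run a comparison plan against a cohort table.

    ``plan`` is a list of dicts: ``{"metric", "site", "kind":
    "independent"|"paired", "group_a", "group_b"}`` (paired contrasts use
    pre_shunt/post_shunt rows linked by pair_id and ignore
    group_a/group_b).  ``star_thresholds`` maps star symbols to p
    cutoffs; the default marks * p<0.05 and ** p<0.001, and can be set
    per table (e.g. ** p<0.01 for paired tables).  ``holm=True`` applies
    a Holm step-down correction across the plan (off by default — the
    reporting convention applies none).
    """
    star_thresholds = star_thresholds or {"*": 0.05, "**": 0.001}
    comparisons: list[GroupComparison] = []
    rows = []
    missing_pairs: list = []
    for item in plan:
        metric, site, kind = item["metric"], item["site"], item.get("kind", "independent")
        if kind == "independent":
            ga, gb = item["group_a"], item["group_b"]
            va = table.values_for(metric, ga, site)
            vb = table.values_for(metric, gb, site)
            cmp_ = mann_whitney(va, vb, alpha=alpha, metric=metric, groups=(ga, gb))
            sa, sb = summarize(va), summarize(vb)
        elif kind == "paired":
            pre, post, ids = table.paired(metric, site)
            sub = table.df[(table.df["site"] == site) & table.df["pair_id"].notna()]
            all_ids = set(sub["pair_id"])
            incomplete = sorted(all_ids - set(ids), key=str)
            if incomplete:
                missing_pairs.append({"metric": metric, "site": site, "pair_ids": incomplete})
            cmp_ = wilcoxon_signed_rank(pre, post, alpha=alpha, metric=metric)
            ga, gb = "pre_shunt", "post_shunt"
            sa, sb = summarize(pre), summarize(post)
        else:
            raise ValueError(f"unknown comparison kind {kind!r}")
        comparisons.append(cmp_)
        rows.append({
            "metric": metric,
            "site": site,
            "test": cmp_.test,
            "group_a": ga,
            "n_a": cmp_.n[0],
            "summary_a": sa["formatted"],
            "group_b": gb,
            "n_b": cmp_.n[1],
            "summary_b": sb["formatted"],
            "p_value": cmp_.p_value,
            "method": cmp_.method,
        })
    df = pd.DataFrame(rows)
    if holm and len(df):
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * df["p_value"].iloc[i])
            adj[i] = min(running, 1.0)
        df["p_holm"] = adj
    if len(df):
        pcol = "p_holm" if holm else "p_value"
        df["stars"] = [_stars(p, star_thresholds) for p in df[pcol]]
    return CohortReport(df, comparisons, missing_pairs, star_thresholds)
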