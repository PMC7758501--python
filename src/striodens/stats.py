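"""Nonparametric group-comparison cascade.

Group differences are tested with a Kruskal–Wallis omnibus followed by
pairwise two-sided Mann–Whitney U tests; raw pairwise p-values are adjusted
by Bonferroni multiplication with an explicit family size (default 10, so
the effective per-test significance threshold at alpha = 0.05 is raw
p < 0.005).  Pairwise results are reported regardless of the omnibus
outcome, flagged when the omnibus is not itself significant.

The rank tests are computed with scipy (tie-corrected H against the
chi-square reference; exact Mann–Whitney by complete enumeration for small
untied samples, otherwise the tie-corrected normal approximation with
continuity correction).  Thin wrappers pin down the degenerate cases the
cascade must survive: constant pooled data give H = 0 / p = 1, a
zero-variance normal approximation gives p = 1, and exact mode refuses tied
data and falls back to the normal approximation with a notice.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "ComparisonPlan",
    "kruskal_wallis",
    "mann_whitney_u",
    "bonferroni",
    "holm",
    "run_cascade",
    "comparisons_table",
]

Mode = Literal["auto", "exact", "normal"]

#: Largest per-group size for which exact Mann-Whitney is the default.
EXACT_N_MAX = 8


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    Requires >= 2 groups, each nonempty, >= 3 observations in total.
    Identical pooled observations give ``(0.0, 1.0)``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least 1 observation")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], mode: Mode = "auto"
) -> tuple[float, float, str]:
    """Two-sided Mann–Whitney U test.

    Returns ``(U, p, mode_used)`` where U counts pairs in which an ``a``
    observation exceeds a ``b`` observation.  ``exact`` enumerates the full
    null distribution (untied data only; tied data fall back to ``normal``
    with a notice in ``mode_used``); ``normal`` is the tie-corrected normal
    approximation with continuity correction.  ``auto`` picks exact when
    both samples have at most 8 untied observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    tied = _has_ties(a, b)
    use = mode
    note = ""
    if mode == "auto":
        use = "exact" if (max(a.size, b.size) <= EXACT_N_MAX and not tied) else "normal"
    elif mode == "exact" and tied:
        use = "normal"
        note = "+ties-fallback"

    # U for "a exceeds b", from midranks (equals scipy's statistic for x=a).
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if use == "exact":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    # Normal approximation; guard the zero-variance case (all ranks tied).
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0, "normal" + note
    z = max((abs(u - mu) - 0.5) / math.sqrt(var), 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return u, float(p), "normal" + note


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values: ``min(1, p * m)``.

    ``m`` defaults to the number of p-values and must be at least that
    number (the family may be larger than the tests actually run).
    """
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than {len(p_values)} tests")
    return [min(1.0, p * m) for p in p_values]


def holm(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Holm step-down adjustment (monotone-enforced), family size ``m``."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than {len(p_values)} tests")
    order = np.argsort(p_values)
    adjusted = [0.0] * len(p_values)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p_values[idx]))
        adjusted[idx] = running
    return adjusted


@dataclass(frozen=True)
class ComparisonPlan:
    """What to compare: one test per metric x panel cell, groups by genotype.

    ``family_m`` is the Bonferroni family size applied to every raw p-value
    (default 10: with alpha = 0.05 the effective raw threshold is 0.005).
    """

    metrics: tuple[str, ...] = (
        "percent_area",
        "strio_intensity",
        "matrix_intensity",
        "ismp",
        "total_intensity",
    )
    group_col: str = "genotype"
    panel_cols: tuple[str, ...] = ("level", "age", "sector")
    alpha: float = 0.05
    family_m: int = 10
    mode: Mode = "auto"
    min_per_group: int = 2
    #: "bonferroni" (default) or "holm" (step-down, behind this flag only).
    correction: str = "bonferroni"


@dataclass
class GroupComparison:
    """One metric in one panel cell: omnibus + pairwise results."""

    metric: str
    panel: dict
    group_labels: list[str]
    group_n: list[int]
    h_statistic: float
    omnibus_p: float
    pairs: list[tuple[str, str]]
    u_statistics: list[float]
    raw_p: list[float]
    adjusted_p: list[float]
    family_m: int
    alpha: float
    significant: list[bool]
    omnibus_significant: bool
    modes: list[str]
    n_ties: int
    notes: list[str] = field(default_factory=list)


def run_cascade(
    table: pd.DataFrame, plan: ComparisonPlan = ComparisonPlan()
) -> list[GroupComparison]:
    """Run the omnibus + pairwise cascade over a long-format metrics table.

    Invalid values (NaN) are dropped per metric; a panel cell whose groups
    fall below ``plan.min_per_group`` after dropping is skipped with a
    warning-style comparison left out of the result.
    """
    comparisons: list[GroupComparison] = []
    panel_cols = list(plan.panel_cols)
    for panel_keys, sub in table.groupby(panel_cols, dropna=False, sort=True):
        if not isinstance(panel_keys, tuple):
            panel_keys = (panel_keys,)
        panel = dict(zip(panel_cols, panel_keys))
        for metric in plan.metrics:
            groups: dict[str, np.ndarray] = {}
            for label, g in sub.groupby(plan.group_col, sort=True):
                vals = g[metric].dropna().to_numpy(dtype=float)
                if vals.size >= plan.min_per_group:
                    groups[str(label)] = vals
            if len(groups) < 2:
                continue
            labels = sorted(groups)
            samples = [groups[lab] for lab in labels]
            h, omni_p = kruskal_wallis(samples)
            pairs = list(itertools.combinations(labels, 2))
            u_stats, raw_ps, modes = [], [], []
            n_ties = 0
            for la, lb in pairs:
                u, p, used = mann_whitney_u(groups[la], groups[lb], mode=plan.mode)
                pooled = np.concatenate([groups[la], groups[lb]])
                n_ties += int(pooled.size - np.unique(pooled).size)
                u_stats.append(u)
                raw_ps.append(p)
                modes.append(used)
            adjust = holm if plan.correction == "holm" else bonferroni
            adj = adjust(raw_ps, m=max(plan.family_m, len(raw_ps)))
            omni_sig = omni_p < plan.alpha
            sig = [q < plan.alpha for q in adj]
            notes = []
            if not omni_sig and any(sig):
                notes.append("pairwise significance without significant omnibus")
            comparisons.append(
                GroupComparison(
                    metric=metric,
                    panel=panel,
                    group_labels=labels,
                    group_n=[int(groups[lab].size) for lab in labels],
                    h_statistic=h,
                    omnibus_p=omni_p,
                    pairs=pairs,
                    u_statistics=u_stats,
                    raw_p=raw_ps,
                    adjusted_p=adj,
                    family_m=max(plan.family_m, len(raw_ps)),
                    alpha=plan.alpha,
                    significant=sig,
                    omnibus_significant=omni_sig,
                    modes=modes,
                    n_ties=n_ties,
                    notes=notes,
                )
            )
    return comparisons


def comparisons_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten cascade results: one row per pairwise test."""
    rows = []
    for c in comparisons:
        for (la, lb), u, p, q, s, mode in zip(
            c.pairs, c.u_statistics, c.raw_p, c.adjusted_p, c.significant, c.modes
        ):
            rows.append(
                {
                    **c.panel,
                    "metric": c.metric,
                    "group_a": la,
                    "group_b": lb,
                    "n_a": c.group_n[c.group_labels.index(la)],
                    "n_b": c.group_n[c.group_labels.index(lb)],
                    "H": c.h_statistic,
                    "omnibus_p": c.omnibus_p,
                    "U": u,
                    "raw_p": p,
                    "adjusted_p": q,
                    "family_m": c.family_m,
                    "significant": s,
                    "omnibus_significant": c.omnibus_significant,
                    "mode": mode,
                    "n_ties": c.n_ties,
                }
            )
    return pd.DataFrame(rows)
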