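"""Group-comparison decision tree, multiplicity adjustment, power conversion.

Routing: all groups normal by Shapiro-Wilk (per group, alpha = 0.05)
-> variance homogeneity by median-centered Levene -> ANOVA or Welch ANOVA;
any group non-normal -> Kruskal-Wallis. Two-group inputs route to Welch's t
or Mann-Whitney under the same normality gate. A significant omnibus test
triggers the matching post hoc family: Tukey's HSD after ANOVA, Dunn's test
with Holm adjustment after Kruskal-Wallis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class PostHocEntry:
    pair: tuple[str, str]
    raw_p: float
    adjusted_p: float
    method: Literal["tukey", "dunn_holm"]


@dataclass
class ComparisonResult:
    omnibus_test: Literal[
        "anova", "welch_anova", "kruskal_wallis", "welch_t", "mann_whitney"
    ]
    statistic: float
    p_value: float
    posthoc: list[PostHocEntry] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class PowerSpec:
    """Inputs/outputs of the two-group power calculation (d = 2f)."""

    cohens_f: Optional[float] = None
    cohens_d: Optional[float] = None
    alpha: float = 0.05
    power: float = 0.90
    n_per_group: Optional[int] = None


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-down Holm adjustment, monotone-enforced and capped at 1."""
    p = _check_pvalues(p_values)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        value = min(1.0, (m - rank) * p[idx])
        running = max(running, value)
        adjusted[idx] = running
    return adjusted.tolist()


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Step-up Benjamini-Hochberg adjusted values (q-values), capped at 1."""
    p = _check_pvalues(p_values)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        value = min(1.0, p[idx] * m / (rank + 1))
        running = min(running, value)
        adjusted[idx] = running
    return adjusted.tolist()


def _check_pvalues(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def welch_anova(samples: Sequence[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA; returns (F, p)."""
    k = len(samples)
    ns = np.array([len(s) for s in samples], dtype=float)
    means = np.array([np.mean(s) for s in samples])
    variances = np.array([np.var(s, ddof=1) for s in samples])
    w = ns / variances
    w_sum = w.sum()
    grand = (w * means).sum() / w_sum
    a = ((w * (means - grand) ** 2).sum()) / (k - 1)
    lam = ((1 - w / w_sum) ** 2 / (ns - 1)).sum()
    b = 1.0 + 2.0 * (k - 2) / (k * k - 1) * lam
    f_stat = a / b
    df1 = k - 1
    df2 = (k * k - 1) / (3.0 * lam)
    return float(f_stat), float(stats.f.sf(f_stat, df1, df2))


def dunn_test(
    labels: Sequence[str], samples: Mapping[str, np.ndarray]
) -> list[tuple[tuple[str, str], float]]:
    """Dunn's rank-based pairwise z-tests with tie correction (raw p)."""
    pooled = np.concatenate([samples[label] for label in labels])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks: dict[str, float] = {}
    start = 0
    for label in labels:
        size = samples[label].size
        mean_ranks[label] = float(ranks[start : start + size].mean())
        start += size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    results = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            se = math.sqrt(base_var * (1.0 / samples[a].size + 1.0 / samples[b].size))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            results.append(((a, b), float(2.0 * stats.norm.sf(abs(z)))))
    return results


def compare_groups(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ComparisonResult:
    """Run the test-selection tree on labelled groups of observations."""
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    labels = list(groups)
    samples = {label: np.asarray(groups[label], dtype=float) for label in labels}
    warnings: list[str] = []

    too_small = [label for label in labels if samples[label].size < 3]
    if too_small:
        warnings.append(
            "groups below the normality-gate size, nonparametric route: "
            + ", ".join(too_small)
        )
        normal = False
    else:
        normal = all(
            stats.shapiro(samples[label]).pvalue > alpha for label in labels
        )

    if len(labels) == 2:
        a, b = (samples[label] for label in labels)
        if normal:
            stat, p = stats.ttest_ind(a, b, equal_var=False)
            return ComparisonResult("welch_t", float(stat), float(p), [], warnings)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult("mann_whitney", float(stat), float(p), [], warnings)

    if normal:
        arrays = [samples[label] for label in labels]
        levene_p = stats.levene(*arrays, center="median").pvalue
        if levene_p > alpha:
            stat, p = stats.f_oneway(*arrays)
            test = "anova"
        else:
            stat, p = welch_anova(arrays)
            test = "welch_anova"
        posthoc: list[PostHocEntry] = []
        if p < alpha:
            hsd = stats.tukey_hsd(*arrays)
            for i, a_label in enumerate(labels):
                for j in range(i + 1, len(labels)):
                    tukey_p = float(hsd.pvalue[i, j])
                    posthoc.append(
                        PostHocEntry((a_label, labels[j]), tukey_p, tukey_p, "tukey")
                    )
        return ComparisonResult(test, float(stat), float(p), posthoc, warnings)

    arrays = [samples[label] for label in labels]
    stat, p = stats.kruskal(*arrays)
    posthoc = []
    if p < alpha:
        raw = dunn_test(labels, samples)
        adjusted = holm_adjust([entry[1] for entry in raw])
        posthoc = [
            PostHocEntry(pair, raw_p, adj_p, "dunn_holm")
            for (pair, raw_p), adj_p in zip(raw, adjusted)
        ]
    return ComparisonResult("kruskal_wallis", float(stat), float(p), posthoc, warnings)


def power_two_group(
    spec: PowerSpec,
    solve_for: Literal["n", "d"],
    use_t_correction: bool = False,
) -> PowerSpec:
    """Two-group power arithmetic under d = 2f.

    Solving for n uses the normal-approximation sample size
    n = 2 (z_{1-alpha/2} + z_{power})^2 / d^2 per group, rounded up. With
    ``use_t_correction`` the quantiles are re-evaluated from the central t
    distribution at df = 2n - 2 and iterated to a fixed point, which adds
    roughly one subject per group at these settings.
    """
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_power = stats.norm.ppf(spec.power)

    if solve_for == "d":
        if spec.cohens_d is not None:
            raise ValueError("cohens_d is already set")
        if spec.cohens_f is not None:
            return replace(spec, cohens_d=2.0 * spec.cohens_f)
        if spec.n_per_group is None:
            raise ValueError("need cohens_f or n_per_group to solve for d")
        d = (z_alpha + z_power) * math.sqrt(2.0 / spec.n_per_group)
        return replace(spec, cohens_d=d, cohens_f=d / 2.0)

    d = spec.cohens_d if spec.cohens_d is not None else (
        None if spec.cohens_f is None else 2.0 * spec.cohens_f
    )
    if d is None:
        raise ValueError("need cohens_d or cohens_f to solve for n")
    if d == 0:
        raise ValueError("d = 0 requires infinite n")
    n = 2.0 * (z_alpha + z_power) ** 2 / (d * d)
    if use_t_correction:
        for _ in range(32):
            df = max(2.0 * n - 2.0, 1.0)
            t_alpha = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
            t_power = stats.t.ppf(spec.power, df)
            new_n = 2.0 * (t_alpha + t_power) ** 2 / (d * d)
            if abs(new_n - n) < 1e-9:
                n = new_n
                break
            n = new_n
    return replace(spec, cohens_d=d, cohens_f=d / 2.0, n_per_group=math.ceil(n))
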