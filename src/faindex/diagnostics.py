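"""ROC construction, DeLong AUC inference, Youden cut-offs, Cliff's delta.

The AUC here is the Mann-Whitney concordance probability that a case ranks
on the disease side of a control (ties counted 1/2), with its standard
error from the DeLong structural-components estimator. Cut-offs maximize
Youden's J over midpoints between adjacent distinct pooled scores, with
mid-plateau tie-breaking. Cliff's delta uses the consistent variance
estimator with a normal-approximation CI clipped to [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

Orientation = Literal["disease_low", "disease_high"]
Rule = Literal["le_is_disease", "ge_is_disease"]

#: Direction in which each index moves with disease, fixed by the group
#: means: lower in disease -> "disease_low" (classify by "<= cutoff").
INDEX_ORIENTATION: dict[str, Orientation] = {
    "omega3_status": "disease_low",
    "aa_epa": "disease_high",
    "omega6_3": "disease_high",
    "c18_ratio": "disease_low",
    "aa_ada": "disease_low",
    "o63bi": "disease_low",
}


class InsufficientDataError(ValueError):
    """A score list required for a diagnostic computation is empty."""


@dataclass
class AUCResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    orientation: Orientation
    degenerate: bool = False


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    sens_ci95: tuple[float, float]
    spec_ci95: tuple[float, float]
    rule: Rule
    youden_j: float


@dataclass
class EffectSize:
    delta: float
    ci95: tuple[float, float]


def _as_array(scores: Sequence[float], label: str) -> np.ndarray:
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise InsufficientDataError(f"{label} score list is empty")
    return arr


def auc_delong(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    orientation: Orientation = "disease_high",
) -> AUCResult:
    """Empirical concordance AUC with the DeLong variance estimator.

    Under ``disease_high`` the AUC is P(case > control) + P(tie)/2; under
    ``disease_low`` it is P(case < control) + P(tie)/2. The 95% CI is the
    plain Wald interval clipped to [0, 1]; the p-value is two-sided for
    AUC = 0.5.
    """
    cases = _as_array(case_scores, "case")
    controls = _as_array(control_scores, "control")
    if orientation == "disease_low":
        cases, controls = -cases, -controls
    m, n = cases.size, controls.size

    pooled = np.concatenate([cases, controls])
    ranks_pooled = stats.rankdata(pooled)
    ranks_cases = stats.rankdata(cases)
    ranks_controls = stats.rankdata(controls)

    auc = (ranks_pooled[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # Structural components (midrank formulation).
    v10 = (ranks_pooled[:m] - ranks_cases) / n
    v01 = 1.0 - (ranks_pooled[m:] - ranks_controls) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)

    lo = max(0.0, auc - 1.959963984540054 * se)
    hi = min(1.0, auc + 1.959963984540054 * se)
    degenerate = False
    if se > 0:
        z = (auc - 0.5) / se
        p = 2.0 * stats.norm.sf(abs(z))
        p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    elif auc == 0.5:
        degenerate = True
        p = 1.0
    else:
        # Complete separation: Wald p degenerates to its limiting value.
        degenerate = True
        p = 0.0
    return AUCResult(float(auc), float(se), (float(lo), float(hi)), float(p),
                     orientation, degenerate)


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    z = stats.norm.ppf(0.5 + level / 2.0)
    phat = successes / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    lo = 0.0 if successes == 0 else max(0.0, center - half)
    hi = 1.0 if successes == n else min(1.0, center + half)
    return (lo, hi)


def _confusion_at(
    cases: np.ndarray, controls: np.ndarray, cutoff: float, rule: Rule
) -> tuple[int, int, int, int]:
    if rule == "le_is_disease":
        tp = int((cases <= cutoff).sum())
        fp = int((controls <= cutoff).sum())
    else:
        tp = int((cases >= cutoff).sum())
        fp = int((controls >= cutoff).sum())
    fn = cases.size - tp
    tn = controls.size - fp
    return tn, fp, fn, tp


def youden_cutoff(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    rule: Rule,
) -> CutoffResult:
    """Cut-off maximizing Youden's J with mid-plateau tie-breaking.

    Candidate thresholds are the midpoints between adjacent distinct pooled
    score values, plus one sentinel below and one above all scores. When a
    contiguous run of candidates attains the maximal J, the midpoint of the
    run is reported (the longest run when several attain the maximum).
    """
    cases = _as_array(case_scores, "case")
    controls = _as_array(control_scores, "control")
    distinct = np.unique(np.concatenate([cases, controls]))
    if distinct.size == 1:
        gap = 1.0
    else:
        gap = float(np.min(np.diff(distinct)))
    candidates = np.concatenate(
        [[distinct[0] - gap], (distinct[:-1] + distinct[1:]) / 2.0,
         [distinct[-1] + gap]]
    )

    js = np.empty(candidates.size)
    for i, t in enumerate(candidates):
        tn, fp, fn, tp = _confusion_at(cases, controls, t, rule)
        js[i] = tp / cases.size + tn / controls.size - 1.0
    best = js.max()
    attains = np.flatnonzero(np.isclose(js, best, rtol=0.0, atol=1e-12))
    # Split into contiguous runs; take the longest (first on ties).
    runs = np.split(attains, np.flatnonzero(np.diff(attains) > 1) + 1)
    run = max(runs, key=len)
    cutoff = float((candidates[run[0]] + candidates[run[-1]]) / 2.0)

    tn, fp, fn, tp = _confusion_at(cases, controls, cutoff, rule)
    sens = tp / cases.size
    spec = tn / controls.size
    return CutoffResult(
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        accuracy=(tp + tn) / (cases.size + controls.size),
        sens_ci95=wilson_interval(tp, cases.size),
        spec_ci95=wilson_interval(tn, controls.size),
        rule=rule,
        youden_j=sens + spec - 1.0,
    )


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> EffectSize:
    """Cliff's delta [#(x_i > y_j) - #(x_i < y_j)] / (n_x * n_y).

    The 95% CI comes from the consistent variance estimator evaluated on
    the dominance matrix (computed in O(n log n) via sorting), with a
    normal approximation clipped to [-1, 1].
    """
    xs = _as_array(x, "x")
    ys = _as_array(y, "y")
    n1, n2 = xs.size, ys.size

    y_sorted = np.sort(ys)
    x_sorted = np.sort(xs)
    # Row means d_i. = (#{y < x_i} - #{y > x_i}) / n2
    lo = np.searchsorted(y_sorted, xs, side="left")
    hi = n2 - np.searchsorted(y_sorted, xs, side="right")
    d_row = (lo - hi) / n2
    # Column means d_.j = (#{x > y_j} - #{x < y_j}) / n1
    greater = n1 - np.searchsorted(x_sorted, ys, side="right")
    lesser = np.searchsorted(x_sorted, ys, side="left")
    d_col = (greater - lesser) / n1
    delta = float(d_row.mean())

    # Number of tied (x_i, y_j) pairs, for sum(d_ij^2) = n1*n2 - ties.
    ties = int(
        sum(
            np.count_nonzero(xs == v) * count
            for v, count in zip(*np.unique(ys, return_counts=True))
        )
    )
    sum_dij_sq = n1 * n2 - ties

    if n1 < 2 or n2 < 2:
        return EffectSize(delta, (-1.0, 1.0))
    ss_row = float(((d_row - delta) ** 2).sum())
    ss_col = float(((d_col - delta) ** 2).sum())
    ss_all = sum_dij_sq - n1 * n2 * delta * delta
    var = (n2 * n2 * ss_row + n1 * n1 * ss_col - ss_all) / (
        n1 * n2 * (n1 - 1) * (n2 - 1)
    )
    var = max(var, 0.0)
    half = 1.959963984540054 * math.sqrt(var)
    return EffectSize(delta, (max(-1.0, delta - half), min(1.0, delta + half)))


def roc_report(
    marker_scores: dict[str, tuple[Sequence[float], Sequence[float]]],
    orientations: dict[str, Orientation] | None = None,
):
    """AUC rows for several markers: {name: (case_scores, control_scores)}.

    Returns a list of (marker, AUCResult) in input order. Orientation falls
    back to :data:`INDEX_ORIENTATION`, then to disease_high.
    """
    orientations = orientations or {}
    rows = []
    for name, (case_scores, control_scores) in marker_scores.items():
        orientation = orientations.get(
            name, INDEX_ORIENTATION.get(name, "disease_high")
        )
        rows.append((name, auc_delong(case_scores, control_scores, orientation)))
    return rows
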