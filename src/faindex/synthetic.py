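"""Synthetic cohorts with the study's group structure.

Two simulation modes:

* analyte scale — per-group molar-percent vectors whose marginals are
  moment-matched (lognormal by default, truncated normal as sensitivity
  analysis) and coupled through a Gaussian copula; a synthetic ``other``
  analyte absorbs the remainder so each sample is a valid molar profile.
* index scale — per-group index values drawn directly from the published
  group means/SDs (Gaussian by default). Single-marker simulations use this
  mode and need no correlation assumption.

Group moments are the printed per-group means and SDs; correlations are not
published, so the default is a modest 0.3 within pathway blocks and 0
elsewhere (config-overridable).
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (
    AA,
    ADA,
    AnalyteSpec,
    C18_0,
    C18_1N9,
    ConcentrationProfile,
    DEFAULT_PANEL,
    DGLA,
    DHA,
    DPA,
    EPA,
    LipidClass,
    MolarProfile,
)

Distribution = Literal["lognormal_moment_matched", "truncated_normal", "normal"]

#: Filler analyte absorbing the unlisted remainder of the composition.
OTHER = "other"

#: Nominal molecular weight for the filler analyte (g/mol).
OTHER_MW = 280.0

CONTROL = "Control"
ATORVASTATIN = "Atorvastatin"
ROSUVASTATIN = "Rosuvastatin"
NO_STATIN = "NoStatin"

#: Atherosclerosis subgroups and their sizes, for pooled-cohort draws.
AS_GROUPS: tuple[tuple[str, int], ...] = (
    (ATORVASTATIN, 19),
    (ROSUVASTATIN, 21),
    (NO_STATIN, 12),
)


class ConfigError(ValueError):
    """Invalid generator configuration (e.g. non-PSD correlation matrix)."""


@dataclass
class GroupSpec:
    """Generative parameters of one study group."""

    label: str
    n: int
    analyte_moments: dict[str, tuple[float, float]] = field(default_factory=dict)
    index_moments: dict[str, tuple[float, float]] = field(default_factory=dict)
    correlation: Optional[np.ndarray] = None  # over analyte_moments keys

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"group {self.label!r} must have n >= 1")
        for name, (mean, sd) in {**self.analyte_moments, **self.index_moments}.items():
            if mean <= 0:
                raise ConfigError(f"mean for {name!r} must be > 0")
            if sd < 0:
                raise ConfigError(f"sd for {name!r} must be >= 0")


@dataclass
class CohortConfig:
    groups: list[GroupSpec]
    seed: int
    total_concentration: tuple[float, float] = (3.0e6, 6.0e5)  # ng/mL
    distribution: Distribution = "lognormal_moment_matched"

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigError("group labels must be unique")


# Published per-group moments: analyte molar percents and index values.
# The last three n-6 analytes per group (C18:2n-6, C18:3n-6, C20:2n-6) are
# NOT published; they are assumptions added so that every index (notably the
# omega-6/omega-3 ratio) is computable from an analyte-scale cohort. The
# linoleic-acid mean is calibrated per group so the implied omega-6/3 ratio
# of the mean composition matches the published group mean.
_ANALYTE_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    CONTROL: {
        C18_0: (9.27, 1.83), C18_1N9: (23.13, 3.38), DGLA: (1.31, 0.31),
        AA: (7.53, 1.99), ADA: (0.17, 0.06), DPA: (0.38, 0.10),
        EPA: (0.59, 0.32), DHA: (1.97, 0.68),
        "C18:2n-6": (24.58, 3.50), "C18:3n-6": (0.35, 0.12),
        "C20:2n-6": (0.25, 0.07),
    },
    ATORVASTATIN: {
        C18_0: (7.42, 0.93), C18_1N9: (27.33, 2.75), DGLA: (1.18, 0.41),
        AA: (6.56, 1.49), ADA: (0.19, 0.06), DPA: (0.39, 0.12),
        EPA: (0.49, 0.26), DHA: (1.84, 0.48),
        "C18:2n-6": (27.46, 3.50), "C18:3n-6": (0.35, 0.12),
        "C20:2n-6": (0.25, 0.07),
    },
    ROSUVASTATIN: {
        C18_0: (7.45, 0.96), C18_1N9: (28.49, 3.49), DGLA: (1.15, 0.29),
        AA: (6.19, 1.79), ADA: (0.17, 0.04), DPA: (0.34, 0.07),
        EPA: (0.45, 0.21), DHA: (1.77, 0.39),
        "C18:2n-6": (24.91, 3.50), "C18:3n-6": (0.35, 0.12),
        "C20:2n-6": (0.25, 0.07),
    },
    NO_STATIN: {
        C18_0: (7.45, 1.01), C18_1N9: (28.01, 3.66), DGLA: (1.20, 0.35),
        AA: (6.67, 1.61), ADA: (0.19, 0.05), DPA: (0.32, 0.06),
        EPA: (0.41, 0.19), DHA: (1.66, 0.34),
        "C18:2n-6": (24.92, 3.50), "C18:3n-6": (0.35, 0.12),
        "C20:2n-6": (0.25, 0.07),
    },
}

_INDEX_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    CONTROL: {
        "omega3_status": (2.70, 1.07), "aa_epa": (13.80, 7.92),
        "omega6_3": (11.63, 4.57), "c18_ratio": (0.42, 0.13),
        "aa_ada": (45.14, 12.84), "o63bi": (12.00, 4.94),
    },
    ATORVASTATIN: {
        "omega3_status": (2.33, 0.71), "aa_epa": (15.47, 8.01),
        "omega6_3": (13.23, 4.94), "c18_ratio": (0.28, 0.05),
        "aa_ada": (36.05, 5.46), "o63bi": (8.35, 2.56),
    },
    ROSUVASTATIN: {
        "omega3_status": (2.22, 0.50), "aa_epa": (16.14, 7.49),
        "omega6_3": (12.90, 2.86), "c18_ratio": (0.27, 0.06),
        "aa_ada": (37.39, 8.64), "o63bi": (7.91, 2.05),
    },
    NO_STATIN: {
        "omega3_status": (2.06, 0.50), "aa_epa": (19.36, 7.99),
        "omega6_3": (14.05, 2.60), "c18_ratio": (0.27, 0.07),
        "aa_ada": (37.01, 9.46), "o63bi": (8.13, 3.32),
    },
}

_GROUP_SIZES = {CONTROL: 50, ATORVASTATIN: 19, ROSUVASTATIN: 21, NO_STATIN: 12}

#: Pathway blocks sharing the default within-block copula correlation.
_PATHWAY_BLOCKS: tuple[tuple[str, ...], ...] = (
    (C18_0, C18_1N9),
    ("C18:2n-6", "C18:3n-6", "C20:2n-6", DGLA, AA, ADA),
    (EPA, DPA, DHA),
)

DEFAULT_BLOCK_CORRELATION = 0.3


def default_correlation(
    analytes: Sequence[str], rho: float = DEFAULT_BLOCK_CORRELATION
) -> np.ndarray:
    """Block correlation matrix: ``rho`` within pathway blocks, 0 across."""
    block_of = {
        name: i for i, block in enumerate(_PATHWAY_BLOCKS) for name in block
    }
    k = len(analytes)
    matrix = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            bi = block_of.get(analytes[i])
            bj = block_of.get(analytes[j])
            if bi is not None and bi == bj:
                matrix[i, j] = matrix[j, i] = rho
    return matrix


def default_specs() -> list[GroupSpec]:
    """The four study groups (n = 50/19/21/12) with published moments.

    Carries every published analyte and index moment plus the three assumed
    n-6 analytes documented on :data:`_ANALYTE_MOMENTS`.
    """
    specs = []
    for label, n in _GROUP_SIZES.items():
        analytes = dict(_ANALYTE_MOMENTS[label])
        specs.append(
            GroupSpec(
                label=label,
                n=n,
                analyte_moments=analytes,
                index_moments=dict(_INDEX_MOMENTS[label]),
                correlation=default_correlation(list(analytes)),
            )
        )
    return specs


def default_config(seed: int, **overrides) -> CohortConfig:
    return CohortConfig(groups=default_specs(), seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Moment matching
# ---------------------------------------------------------------------------


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given mean and sd (closed form)."""
    if mean <= 0:
        raise ConfigError("lognormal mean must be > 0")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def lognormal_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Analytic (mean, sd) of a lognormal — inverse of lognormal_params."""
    mean = math.exp(mu + sigma * sigma / 2.0)
    sd = mean * math.sqrt(math.exp(sigma * sigma) - 1.0)
    return mean, sd


def truncnorm_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Analytic (mean, sd) of a normal(mu, sigma) truncated to [0, inf)."""
    alpha = -mu / sigma
    z = 1.0 - stats.norm.cdf(alpha)
    lam = stats.norm.pdf(alpha) / z
    mean = mu + sigma * lam
    var = sigma * sigma * (1.0 + alpha * lam - lam * lam)
    return float(mean), float(math.sqrt(var))


def truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) such that the [0, inf) truncation matches (mean, sd).

    Solved numerically from the closed-form truncated moments, so the
    generator's analytic moments equal the targets exactly (no silent
    clipping bias). Feasible only for sd/mean < 1: a zero-truncated normal
    approaches (but never reaches) unit coefficient of variation in its
    exponential-tail limit. Every published group moment satisfies this.
    """
    if mean <= 0 or sd <= 0:
        raise ConfigError("truncated-normal targets must be positive")
    if sd >= mean:
        raise ConfigError(
            f"truncated normal cannot reach sd/mean >= 1 (mean={mean}, sd={sd}); "
            "use the lognormal family instead"
        )

    def equations(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        m, s = truncnorm_moments(mu, math.exp(log_sigma))
        return np.array([m - mean, s - sd])

    solution, info, ok, message = optimize.fsolve(
        equations, x0=np.array([mean, math.log(sd)]), full_output=True
    )
    if ok != 1 or np.max(np.abs(info["fvec"])) > 1e-8 * max(mean, sd):
        raise ConfigError(
            f"could not moment-match truncated normal for mean={mean}, sd={sd}: "
            f"{message}"
        )
    return float(solution[0]), float(math.exp(solution[1]))


def _marginal_ppf(u: np.ndarray, mean: float, sd: float,
                  distribution: Distribution) -> np.ndarray:
    if sd == 0:
        return np.full_like(u, mean)
    if distribution == "lognormal_moment_matched":
        mu, sigma = lognormal_params(mean, sd)
        return np.exp(mu + sigma * stats.norm.ppf(u))
    if distribution == "truncated_normal":
        mu, sigma = truncnorm_params(mean, sd)
        a = -mu / sigma
        return stats.truncnorm.ppf(u, a, np.inf, loc=mu, scale=sigma)
    if distribution == "normal":
        return mean + sd * stats.norm.ppf(u)
    raise ConfigError(f"unknown distribution {distribution!r}")


def _copula_uniforms(rng: np.random.Generator, n: int,
                     correlation: np.ndarray) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(correlation)
    except np.linalg.LinAlgError:
        # PSD but singular matrices get an eigenvalue square root.
        eigval, eigvec = np.linalg.eigh(correlation)
        if eigval.min() < -1e-10:
            raise ConfigError("correlation matrix is not positive semidefinite")
        chol = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    z = rng.standard_normal((n, correlation.shape[0])) @ chol.T
    return stats.norm.cdf(z)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def sample_group_analytes(
    spec: GroupSpec,
    rng: np.random.Generator,
    distribution: Distribution = "lognormal_moment_matched",
    n: Optional[int] = None,
) -> pd.DataFrame:
    """Draw n analyte vectors (columns ordered as spec.analyte_moments)."""
    names = list(spec.analyte_moments)
    n = spec.n if n is None else n
    correlation = (
        spec.correlation if spec.correlation is not None else np.eye(len(names))
    )
    if correlation.shape != (len(names), len(names)):
        raise ConfigError(
            f"correlation shape {correlation.shape} does not match "
            f"{len(names)} analytes for group {spec.label!r}"
        )
    if not np.allclose(correlation, correlation.T):
        raise ConfigError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(correlation), 1.0):
        raise ConfigError("correlation matrix must have unit diagonal")
    u = _copula_uniforms(rng, n, correlation)
    columns = {}
    for j, name in enumerate(names):
        mean, sd = spec.analyte_moments[name]
        columns[name] = _marginal_ppf(u[:, j], mean, sd, distribution)
    return pd.DataFrame(columns)


def generate_cohort(config: CohortConfig) -> list[MolarProfile]:
    """Draw molar profiles for every group of the config.

    Each sample gets a synthetic ``other`` analyte equal to
    100 - sum(listed analytes) so the profile is a valid molar composition;
    samples whose listed analytes already exceed 100 (essentially
    impossible at the study moments) are redrawn, with a hard cap.
    """
    rng = np.random.default_rng(config.seed)
    profiles: list[MolarProfile] = []
    for spec in config.groups:
        frame = sample_group_analytes(spec, rng, config.distribution)
        totals = frame.sum(axis=1).to_numpy()
        for _ in range(100):
            bad = np.flatnonzero(totals >= 100.0)
            if bad.size == 0:
                break
            redraw = sample_group_analytes(spec, rng, config.distribution,
                                           n=bad.size)
            frame.iloc[bad] = redraw.to_numpy()
            totals = frame.sum(axis=1).to_numpy()
        else:
            raise ConfigError(
                f"group {spec.label!r} moments leave no room for the filler analyte"
            )
        for i in range(spec.n):
            row = frame.iloc[i]
            mol_percent = {name: float(row[name]) for name in frame.columns}
            mol_percent[OTHER] = float(100.0 - totals[i])
            profiles.append(
                MolarProfile(f"{spec.label}-{i + 1:04d}", spec.label, mol_percent)
            )
    return profiles


def sample_group_indices(
    spec: GroupSpec,
    rng: np.random.Generator,
    names: Optional[Sequence[str]] = None,
    n: Optional[int] = None,
    distribution: Distribution = "normal",
) -> pd.DataFrame:
    """Index-scale draws from the group's published (mean, sd) moments.

    Indices are drawn independently — the source tables publish no index
    correlations — with Gaussian marginals by default.
    """
    names = list(names if names is not None else spec.index_moments)
    n = spec.n if n is None else n
    columns = {}
    for name in names:
        if name not in spec.index_moments:
            raise ConfigError(f"group {spec.label!r} has no moments for {name!r}")
        mean, sd = spec.index_moments[name]
        u = stats.norm.cdf(rng.standard_normal(n))
        columns[name] = _marginal_ppf(u, mean, sd, distribution)
    return pd.DataFrame(columns)


def generate_index_table(
    config: CohortConfig,
    names: Optional[Sequence[str]] = None,
    distribution: Distribution = "normal",
) -> pd.DataFrame:
    """Index-scale cohort: one row per sample, sample_id/group + index columns."""
    rng = np.random.default_rng(config.seed)
    frames = []
    for spec in config.groups:
        frame = sample_group_indices(spec, rng, names, distribution=distribution)
        frame.insert(0, "group", spec.label)
        frame.insert(
            0, "sample_id", [f"{spec.label}-{i + 1:04d}" for i in range(spec.n)]
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def sample_pooled_indices(
    specs: Mapping[str, GroupSpec],
    rng: np.random.Generator,
    n: int,
    names: Sequence[str],
    weights: Optional[Mapping[str, float]] = None,
    distribution: Distribution = "normal",
) -> pd.DataFrame:
    """Draws from the pooled-atherosclerosis mixture.

    Subgroup membership is drawn with probabilities proportional to the
    subgroup sizes (19/21/12 by default).
    """
    if weights is None:
        weights = {label: size for label, size in AS_GROUPS}
    labels = list(weights)
    probabilities = np.array([weights[label] for label in labels], dtype=float)
    probabilities /= probabilities.sum()
    membership = rng.choice(len(labels), size=n, p=probabilities)
    frame = pd.DataFrame(index=range(n), columns=list(names), dtype=float)
    for idx, label in enumerate(labels):
        rows = np.flatnonzero(membership == idx)
        if rows.size == 0:
            continue
        draws = sample_group_indices(
            specs[label], rng, names, n=rows.size, distribution=distribution
        )
        frame.iloc[rows] = draws.to_numpy()
    frame.insert(0, "group", [labels[i] for i in membership])
    return frame


def synthetic_panel(panel: Sequence[AnalyteSpec] = DEFAULT_PANEL) -> list[AnalyteSpec]:
    """The measured panel plus the synthetic filler analyte."""
    return [*panel, AnalyteSpec(OTHER, LipidClass.OTHER, OTHER_MW)]


def to_concentrations(
    cohort: Iterable[MolarProfile],
    config: CohortConfig,
    panel: Optional[Sequence[AnalyteSpec]] = None,
) -> list[ConcentrationProfile]:
    """Back-convert molar profiles to ng/mL concentrations.

    Each sample gets a total mass concentration drawn from
    ``config.total_concentration`` (truncated to positive by resampling,
    with a warning when that triggers); converting the result back to molar
    percent recovers the input composition.
    """
    panel = list(panel) if panel is not None else synthetic_panel()
    mw = {spec.name: spec.molecular_weight for spec in panel}
    rng = np.random.default_rng(config.seed + 1)
    mean, sd = config.total_concentration
    results = []
    resampled = 0
    for profile in cohort:
        total_mass = rng.normal(mean, sd)
        while total_mass <= 0:
            resampled += 1
            total_mass = rng.normal(mean, sd)
        fractions = {k: v / 100.0 for k, v in profile.mol_percent.items()}
        mass_per_mole = sum(f * mw[name] for name, f in fractions.items())
        total_moles = total_mass / mass_per_mole
        concentrations = {
            name: f * total_moles * mw[name] for name, f in fractions.items()
        }
        results.append(
            ConcentrationProfile(profile.sample_id, profile.group, concentrations)
        )
    if resampled:
        _warnings.warn(
            f"resampled {resampled} non-positive total-concentration draws",
            stacklevel=2,
        )
    return results
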