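"""Per-sample lipidomic indices and pathway ratios.

All indices are functions of a sample's molar-percent composition only, so
they are invariant to uniform rescaling of the underlying concentrations.
They are computed per sample and averaged afterwards when group summaries
are needed (mean of ratios, not ratio of means).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .core import AA, ADA, C18_0, C18_1N9, DGLA, DHA, DPA, EPA, MolarProfile

#: Numerator analytes of the omega-6/omega-3 ratio.
N6_ANALYTES: tuple[str, ...] = (
    "C18:2n-6",
    "C18:3n-6",
    "C20:2n-6",
    DGLA,
    AA,
    ADA,
)

#: Denominator analytes of the omega-6/omega-3 ratio.
N3_ANALYTES: tuple[str, ...] = (EPA, DPA, DHA)

INDEX_NAMES: tuple[str, ...] = (
    "omega3_status",
    "aa_epa",
    "omega6_3",
    "c18_ratio",
    "aa_ada",
    "dgla_aa",
    "epa_dpa",
    "epa_dha",
    "dpa_dha",
    "o63bi",
)


class MissingAnalyteError(KeyError):
    """A required analyte is below LOQ / absent from the profile."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep a plain message
        return self.args[0] if self.args else ""


class IndexDomainError(ValueError):
    """An index is undefined for the given composition (e.g. zero denominator)."""


class IndexComputationError(ValueError):
    """Aggregate failure of compute_index_set; names every affected index."""

    def __init__(self, failures: dict[str, Exception]):
        self.failures = failures
        detail = "; ".join(f"{name}: {exc}" for name, exc in sorted(failures.items()))
        super().__init__(f"could not compute indices [{detail}]")


def _get(profile: MolarProfile, analyte: str) -> float:
    try:
        return profile.mol_percent[analyte]
    except KeyError:
        raise MissingAnalyteError(
            f"analyte {analyte!r} is below LOQ or absent in sample "
            f"{profile.sample_id!r}"
        ) from None


def omega3_status(profile: MolarProfile) -> float:
    """EPA + DHA in molar percent."""
    return _get(profile, EPA) + _get(profile, DHA)


def omega6_3_ratio(profile: MolarProfile) -> float:
    """Sum of the six n-6 PUFAs over the sum of the three n-3 PUFAs."""
    numerator = sum(_get(profile, a) for a in N6_ANALYTES)
    denominator = sum(_get(profile, a) for a in N3_ANALYTES)
    if denominator <= 0:
        raise IndexDomainError(
            f"n-3 PUFA sum is zero in sample {profile.sample_id!r}"
        )
    return numerator / denominator


def pairwise_ratio(profile: MolarProfile, numerator: str, denominator: str) -> float:
    """mol%(numerator) / mol%(denominator)."""
    num = _get(profile, numerator)
    den = _get(profile, denominator)
    if den == 0:
        raise IndexDomainError(
            f"denominator analyte {denominator!r} is zero in sample "
            f"{profile.sample_id!r}"
        )
    return num / den


def o63_balance_index(profile: MolarProfile) -> float:
    """Omega-6/3 balance index: (AA * sqrt(EPA * DPA)) / (AdA * DHA).

    Combines the omega-6 elongation ratio AA/AdA with the geometric mean of
    EPA and DPA over DHA. Degree-0 homogeneous in the composition.
    """
    values = {name: _get(profile, name) for name in (AA, ADA, EPA, DPA, DHA)}
    for name, value in values.items():
        if value <= 0:
            raise IndexDomainError(
                f"analyte {name!r} must be > 0 for the balance index "
                f"(got {value}) in sample {profile.sample_id!r}"
            )
    return (
        values[AA]
        * math.sqrt(values[EPA] * values[DPA])
        / (values[ADA] * values[DHA])
    )


@dataclass
class IndexSet:
    """The ten per-sample indices, in the canonical column order."""

    sample_id: str
    group: str
    omega3_status: float
    aa_epa: float
    omega6_3: float
    c18_ratio: float
    aa_ada: float
    dgla_aa: float
    epa_dpa: float
    epa_dha: float
    dpa_dha: float
    o63bi: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


_INDEX_BUILDERS = {
    "omega3_status": omega3_status,
    "aa_epa": lambda p: pairwise_ratio(p, AA, EPA),
    "omega6_3": omega6_3_ratio,
    "c18_ratio": lambda p: pairwise_ratio(p, C18_0, C18_1N9),
    "aa_ada": lambda p: pairwise_ratio(p, AA, ADA),
    "dgla_aa": lambda p: pairwise_ratio(p, DGLA, AA),
    "epa_dpa": lambda p: pairwise_ratio(p, EPA, DPA),
    "epa_dha": lambda p: pairwise_ratio(p, EPA, DHA),
    "dpa_dha": lambda p: pairwise_ratio(p, DPA, DHA),
    "o63bi": o63_balance_index,
}


def compute_index_set(profile: MolarProfile) -> IndexSet:
    """Compute every index for one sample.

    Raises :class:`IndexComputationError` naming *all* indices that cannot
    be computed (e.g. every EPA-dependent index when EPA is below LOQ).
    """
    values: dict[str, float] = {}
    failures: dict[str, Exception] = {}
    for name, builder in _INDEX_BUILDERS.items():
        try:
            values[name] = builder(profile)
        except (MissingAnalyteError, IndexDomainError) as exc:
            failures[name] = exc
    if failures:
        raise IndexComputationError(failures)
    return IndexSet(sample_id=profile.sample_id, group=profile.group, **values)


def index_table(profiles: Iterable[MolarProfile]) -> pd.DataFrame:
    """Index sets for a cohort as a tidy DataFrame (input order preserved)."""
    rows = []
    for profile in profiles:
        index_set = compute_index_set(profile)
        rows.append(
            {"sample_id": index_set.sample_id, "group": index_set.group,
             **index_set.as_dict()}
        )
    return pd.DataFrame(rows, columns=["sample_id", "group", *INDEX_NAMES])
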