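"""Grouping variables: age bands, institutional volume, volume strata.

Five age bands partition ages 0-21 at admission; five volume strata
partition hospitals by total admissions over the study window.  The
published tables use the band convention <1, 1, 2-4, 5-12, >12 (the
accompanying methods text prints "5-13, 14-21"; the two disagree and the
table convention is the one adopted here, since all reproduced numbers
come from the tables).  Band definitions are a module-level constant so an
alternate convention can be swapped in declaratively.

Institutional volume follows the registry definition: total admissions
over the 10-year window divided by 10, i.e. admissions per year.  Hospitals
with extremely small volume and no mortality can be excluded as
non-representative via :func:`exclude_nonrepresentative`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import yaml

from .records import Cohort

__all__ = [
    "AgeBand",
    "VolumeStratum",
    "InstitutionProfile",
    "AGE_BANDS",
    "VOLUME_STRATA",
    "age_band",
    "volume_stratum",
    "institution_profiles",
    "exclude_nonrepresentative",
    "bands_to_yaml",
    "bands_from_yaml",
]


@dataclass(frozen=True)
class AgeBand:
    """Half-open integer age band [lower_inclusive, upper_exclusive)."""

    label: str
    lower_inclusive: int
    upper_exclusive: int

    def __contains__(self, age: int) -> bool:
        return self.lower_inclusive <= age < self.upper_exclusive


@dataclass(frozen=True)
class VolumeStratum:
    """Half-open stratum of total window admissions [lower, upper)."""

    label: str
    lower_inclusive: int
    upper_exclusive: int | None  # None = unbounded above

    def __contains__(self, n: int) -> bool:
        if n < self.lower_inclusive:
            return False
        return self.upper_exclusive is None or n < self.upper_exclusive


# Table convention: {0}, {1}, {2-4}, {5-12}, {13-21}
AGE_BANDS: tuple[AgeBand, ...] = (
    AgeBand("<1", 0, 1),
    AgeBand("1", 1, 2),
    AgeBand("2-4", 2, 5),
    AgeBand("5-12", 5, 13),
    AgeBand(">12", 13, 22),
)

VOLUME_STRATA: tuple[VolumeStratum, ...] = (
    VolumeStratum("<100", 0, 100),
    VolumeStratum("100-199", 100, 200),
    VolumeStratum("200-299", 200, 300),
    VolumeStratum("300-499", 300, 500),
    VolumeStratum(">=500", 500, None),
)


@dataclass(frozen=True)
class InstitutionProfile:
    """Per-hospital totals over the study window.

    ``volume`` is admissions per year (total / window length);
    ``mortality_rate`` is deaths / total admissions.
    """

    institution_id: str
    total_admissions: int
    deaths: int
    volume: float
    mortality_rate: float


def age_band(
    age_years: int, bands: Sequence[AgeBand] = AGE_BANDS
) -> str:
    """Return the label of the unique band containing *age_years*."""
    for band in bands:
        if age_years in band:
            return band.label
    raise ValueError(f"age_years={age_years} outside the banded range 0-21")


def volume_stratum(
    total_admissions: int, strata: Sequence[VolumeStratum] = VOLUME_STRATA
) -> str:
    """Return the label of the volume stratum for a hospital's total
    window admission count."""
    if total_admissions < 0:
        raise ValueError("total_admissions must be non-negative")
    for s in strata:
        if total_admissions in s:
            return s.label
    raise AssertionError("volume strata must partition the non-negatives")


def institution_profiles(
    cohort: Cohort, window_years: int = 10
) -> list[InstitutionProfile]:
    """One profile per distinct hospital, in first-appearance order.

    Totals conserve: per-institution admissions sum to the cohort size and
    per-institution deaths sum to the cohort's deaths.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if window_years <= 0:
        raise ValueError("window_years must be positive")
    order: list[str] = []
    counts: dict[str, int] = {}
    deaths: dict[str, int] = {}
    for r in cohort:
        if r.institution_id not in counts:
            order.append(r.institution_id)
            counts[r.institution_id] = 0
            deaths[r.institution_id] = 0
        counts[r.institution_id] += 1
        deaths[r.institution_id] += r.died
    return [
        InstitutionProfile(
            institution_id=i,
            total_admissions=counts[i],
            deaths=deaths[i],
            volume=counts[i] / window_years,
            mortality_rate=deaths[i] / counts[i],
        )
        for i in order
    ]


def exclude_nonrepresentative(
    profiles: Sequence[InstitutionProfile],
    cohort: Cohort,
    max_volume_threshold: float = 1.0,
    require_zero_deaths: bool = True,
) -> tuple[Cohort, list[InstitutionProfile]]:
    """Drop hospitals with volume below *max_volume_threshold* admissions
    per year (and, if required, zero deaths) as non-representative of
    usual care patterns.

    Returns the filtered cohort and the list of excluded institution
    profiles for audit.  Filtered size + excluded admissions = input size.
    """
    excluded = [
        p
        for p in profiles
        if p.volume < max_volume_threshold
        and (not require_zero_deaths or p.deaths == 0)
    ]
    excluded_ids = {p.institution_id for p in excluded}
    kept = [r for r in cohort if r.institution_id not in excluded_ids]
    return (
        Cohort.from_records(
            kept, provenance=f"{cohort.provenance} [low-volume excluded]"
        ),
        excluded,
    )


def bands_to_yaml(bands: Sequence[AgeBand] = AGE_BANDS) -> str:
    """Serialize a band convention to YAML."""
    return yaml.safe_dump(
        [
            {
                "label": b.label,
                "lower_inclusive": b.lower_inclusive,
                "upper_exclusive": b.upper_exclusive,
            }
            for b in bands
        ],
        sort_keys=False,
    )


def bands_from_yaml(text: str) -> tuple[AgeBand, ...]:
    """Load a band convention from YAML (inverse of :func:`bands_to_yaml`)."""
    return tuple(AgeBand(**d) for d in yaml.safe_load(text))
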