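"""The mortality-related resource utilization fraction (MRRUF).

MRRUF is the fraction of an inpatient resource expended during
hospitalizations that end in inpatient death:

    MRRUF = (resource summed over admissions ending in death)
            / (resource summed over all admissions)

computed separately in the length-of-stay domain (inpatient-days) and the
billed-charges domain (dollars).  Being a ratio of like-denominated sums,
it is invariant to inflation or any rescaling of the resource, and a
cohort's MRRUF equals the resource-weighted mean of per-stratum MRRUFs
over any partition of the cohort (the pooling identity).

A zero denominator (empty cohort, or no resource at all) makes the
fraction undefined; that is represented by an explicit NaN marker that
reports render as "NA" — never as zero, which would falsely signal "no
decedent resource".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .records import AdmissionRecord, Cohort
from .strata import (
    AGE_BANDS,
    VOLUME_STRATA,
    age_band,
    institution_profiles,
    volume_stratum,
)

__all__ = [
    "MrrufResult",
    "StratumSummary",
    "mrruf",
    "mortality_rate",
    "stratified_summary",
    "pooled_mrruf_from_strata",
    "summaries_to_frame",
    "UNDEFINED",
]

#: marker for an undefined fraction (zero denominator)
UNDEFINED = float("nan")

_DOMAINS: dict[str, Callable[[AdmissionRecord], float]] = {
    "los": lambda r: float(r.los_days),
    "charges": lambda r: float(r.billed_charges),
}


@dataclass(frozen=True)
class MrrufResult:
    """MRRUF in one resource domain.

    ``fraction`` is ``decedent_total / grand_total``, or NaN when the
    grand total is zero.
    """

    domain: str
    decedent_total: float
    grand_total: float
    fraction: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.fraction)


@dataclass(frozen=True)
class StratumSummary:
    """One row of a stratified summary table."""

    stratum: str
    n_admissions: int
    n_deaths: int
    death_pct: float
    los_total: int
    charges_total: float
    mrruf_los: float
    mrruf_charges: float


def mrruf(cohort: Cohort, domain: str) -> MrrufResult:
    """Compute MRRUF for *cohort* in the given domain ("los" or "charges").

    Never raises on degenerate input: an empty cohort or a zero grand
    total yields an undefined (NaN) fraction.
    """
    try:
        resource = _DOMAINS[domain]
    except KeyError:
        raise ValueError(
            f"unknown domain {domain!r}; expected one of {sorted(_DOMAINS)}"
        ) from None
    decedent_total = sum(resource(r) for r in cohort if r.died)
    grand_total = sum(resource(r) for r in cohort)
    fraction = decedent_total / grand_total if grand_total > 0 else UNDEFINED
    return MrrufResult(domain, decedent_total, grand_total, fraction)


def mortality_rate(cohort: Cohort) -> float:
    """Inpatient deaths / admissions; NaN on an empty cohort."""
    if len(cohort) == 0:
        return UNDEFINED
    return cohort.n_deaths / len(cohort)


def _grouping_key(
    cohort: Cohort, grouping: str
) -> tuple[Callable[[AdmissionRecord], str], Sequence[str] | None]:
    """Return (record -> stratum label, canonical label order or None)."""
    if grouping == "age_band":
        return (lambda r: age_band(r.age_years)), [b.label for b in AGE_BANDS]
    if grouping == "year":
        years = sorted({r.year for r in cohort})
        return (lambda r: str(r.year)), [str(y) for y in years]
    if grouping == "institution":
        return (lambda r: r.institution_id), None  # first-appearance order
    if grouping == "volume_stratum":
        profiles = institution_profiles(cohort)
        stratum_of = {
            p.institution_id: volume_stratum(p.total_admissions)
            for p in profiles
        }
        return (lambda r: stratum_of[r.institution_id]), [
            s.label for s in VOLUME_STRATA
        ]
    raise ValueError(f"unknown grouping {grouping!r}")


def _summarize(label: str, records: list[AdmissionRecord]) -> StratumSummary:
    sub = Cohort.from_records(records)
    n = len(sub)
    d = sub.n_deaths
    return StratumSummary(
        stratum=label,
        n_admissions=n,
        n_deaths=d,
        death_pct=100.0 * d / n,
        los_total=sum(r.los_days for r in records),
        charges_total=sum(r.billed_charges for r in records),
        mrruf_los=mrruf(sub, "los").fraction,
        mrruf_charges=mrruf(sub, "charges").fraction,
    )


def stratified_summary(cohort: Cohort, grouping: str) -> list[StratumSummary]:
    """Per-stratum counts, resource totals, mortality and MRRUFs.

    ``grouping`` is one of ``age_band``, ``volume_stratum``, ``year``,
    ``institution``.  One row per non-empty stratum, ordered by the
    stratum definition order (first appearance for institutions).  Row
    totals conserve to the whole-cohort totals.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    key, order = _grouping_key(cohort, grouping)
    buckets: dict[str, list[AdmissionRecord]] = {}
    appearance: list[str] = []
    for r in cohort:
        label = key(r)
        if label not in buckets:
            buckets[label] = []
            appearance.append(label)
        buckets[label].append(r)
    labels = [l for l in (order if order is not None else appearance) if l in buckets]
    return [_summarize(l, buckets[l]) for l in labels]


def pooled_mrruf_from_strata(
    stratum_mrrufs: Iterable[tuple[float, float]]
) -> float:
    """Pool per-stratum MRRUFs into a whole-cohort MRRUF.

    Takes (fraction, resource_total) pairs and returns the
    resource-weighted mean  Σ f_g · w_g / Σ w_g , which is algebraically
    identical to computing MRRUF on the concatenated cohort.
    """
    num = 0.0
    den = 0.0
    for fraction, total in stratum_mrrufs:
        if total < 0:
            raise ValueError("resource totals must be non-negative")
        num += fraction * total
        den += total
    if den == 0:
        raise ValueError("all resource totals are zero; pooled MRRUF undefined")
    return num / den


def summaries_to_frame(summaries: Sequence[StratumSummary]) -> pd.DataFrame:
    """Render stratified summaries as a DataFrame in fixed column order."""
    return pd.DataFrame(
        [
            {
                "stratum": s.stratum,
                "n_admissions": s.n_admissions,
                "n_deaths": s.n_deaths,
                "death_pct": s.death_pct,
                "los_total": s.los_total,
                "charges_total": s.charges_total,
                "mrruf_los": s.mrruf_los,
                "mrruf_charges": s.mrruf_charges,
            }
            for s in summaries
        ]
    )
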