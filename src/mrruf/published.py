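"""Published summary statistics of the HLHS admission cohort.

Stratum-level totals from a published multi-institutional registry
analysis of hypoplastic left heart syndrome admissions (PHIS, 43 US
children's hospitals, 2004-2013; 11,122 admissions).  The row-level
admission data are proprietary; only these printed marginals are public.
They serve two purposes here: as desk-scale inputs for reproducing the
pooled headline figures (the pooling identity needs only per-stratum
MRRUFs and resource totals), and as calibration targets for the synthetic
cohort generator.

Charges in the stratum tables are in $ x 10^6 as printed; everything else
is in raw units (admissions, inpatient-days, deaths, dollars, fractions).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PublishedStratumRow",
    "VOLUME_STRATUM_TABLE",
    "AGE_BAND_TABLE",
    "AGE_BAND_MRRUF_LOS",
    "AGE_BAND_MRRUF_CHARGES",
    "AGE_BAND_DEATH_PCT",
    "OVERALL",
]


@dataclass(frozen=True)
class PublishedStratumRow:
    """One printed stratum row: counts and resource totals."""

    label: str
    n_admissions: int
    los_days: int
    charges_musd: float  # $ x 10^6
    deaths: int


# Hospital-volume strata (total admissions over the 10-year window)
VOLUME_STRATUM_TABLE: tuple[PublishedStratumRow, ...] = (
    PublishedStratumRow("<100", 398, 8_260, 138.9, 59),
    PublishedStratumRow("100-199", 1_441, 44_777, 628.9, 199),
    PublishedStratumRow("200-299", 2_528, 64_295, 895.1, 286),
    PublishedStratumRow("300-499", 3_652, 95_722, 1_429.1, 351),
    PublishedStratumRow(">=500", 3_103, 63_973, 836.3, 250),
)

# Age at admission (years)
AGE_BAND_TABLE: tuple[PublishedStratumRow, ...] = (
    PublishedStratumRow("<1", 7_585, 226_939, 3_142.0, 1_055),
    PublishedStratumRow("1", 484, 7_696, 126.0, 22),
    PublishedStratumRow("2-4", 2_422, 34_130, 510.1, 42),
    PublishedStratumRow("5-12", 531, 6_753, 121.4, 18),
    PublishedStratumRow(">12", 100, 1_509, 29.3, 8),
)

# Per-age-band MRRUF as printed (fractions)
AGE_BAND_MRRUF_LOS: dict[str, float] = {
    "<1": 0.178, "1": 0.121, "2-4": 0.057, "5-12": 0.076, ">12": 0.185,
}
AGE_BAND_MRRUF_CHARGES: dict[str, float] = {
    "<1": 0.238, "1": 0.135, "2-4": 0.083, "5-12": 0.111, ">12": 0.220,
}

# Per-age-band inpatient mortality as printed (percent).  Note: the 5-12
# row prints 3.3 while its own counts give 18/531 = 3.39 -> 3.4; the
# printed value is kept verbatim and the discrepancy documented.
AGE_BAND_DEATH_PCT: dict[str, float] = {
    "<1": 13.9, "1": 4.5, "2-4": 1.7, "5-12": 3.3, ">12": 8.0,
}

#: Overall published figures for the full cohort
OVERALL = {
    "n_admissions": 11_122,
    "n_institutions": 43,
    "n_deaths": 1_145,
    "mortality_pct": 10.3,
    "total_los_days": 277_027,
    "total_charges_usd": 3_928_794_660.0,
    "mean_admissions_per_institution": 259,
    "sd_admissions_per_institution": 181,
    "median_los_died": 17,
    "median_los_alive": 12,
    "median_charges_died": 4.09e5,
    "median_charges_alive": 1.63e5,
    "mean_los_days": 24.9,
    "mrruf_los_pct": 16,
    "mrruf_charges_pct": 21,
}
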