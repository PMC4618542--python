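"""Report builders reproducing the published table structures.

:func:`build_report` composes the stratification, MRRUF and hypothesis-
test modules into one :class:`AnalysisReport` with four blocks:

* ``overall`` — cohort totals, mortality and both MRRUFs;
* ``table1`` — per-volume-stratum and per-age-band counts, inpatient-days,
  charges and deaths (charges additionally shown in $ x 10^6, the
  published display unit);
* ``table2`` — per-age-band mortality and MRRUFs with pairwise
  significance flags against the "<1" reference band;
* ``trends`` — year-by-year mortality/MRRUF, the institution-year
  least-squares mortality trend, and Spearman correlations of
  per-institution MRRUF and mortality against institutional volume
  (low-volume zero-mortality hospitals excluded by default, as in the
  published analysis).

Figure content is emitted as tables; there is no plotting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import (
    StratumSummary,
    mortality_rate,
    mrruf,
    stratified_summary,
    summaries_to_frame,
)
from .records import Cohort
from .stats import ols_trend, pairwise_vs_reference, spearman_rho
from .strata import exclude_nonrepresentative, institution_profiles

__all__ = ["AnalysisReport", "ReportOptions", "build_report"]


def _na(x: float):
    """Render NaN as the explicit 'NA' marker for serialization."""
    return "NA" if isinstance(x, float) and math.isnan(x) else x


@dataclass(frozen=True)
class ReportOptions:
    exclude_low_volume: bool = True
    max_volume_threshold: float = 1.0
    correction: str = "bonferroni"
    window_years: int = 10
    reference_band: str = "<1"


@dataclass
class AnalysisReport:
    overall: dict
    table1: dict
    table2: dict
    trends: dict

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "table1": self.table1,
            "table2": self.table2,
            "trends": self.trends,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def write_csv_tables(self, directory: str | Path) -> list[Path]:
        """Write table1/table2/trends blocks as CSV files carrying the
        same numbers as the JSON rendering."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, rows in (
            ("table1_volume", self.table1["by_volume_stratum"]),
            ("table1_age", self.table1["by_age_band"]),
            ("table2_age", self.table2["rows"]),
            ("trends_yearly", self.trends["yearly"]),
        ):
            path = directory / f"{name}.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            written.append(path)
        return written


def _table_rows(summaries: list[StratumSummary]) -> list[dict]:
    return [
        {
            "stratum": s.stratum,
            "n_admissions": s.n_admissions,
            "los_days": s.los_total,
            "charges_musd": round(s.charges_total / 1e6, 1),
            "charges_usd": s.charges_total,
            "deaths": s.n_deaths,
        }
        for s in summaries
    ]


def build_report(
    cohort: Cohort, options: ReportOptions = ReportOptions()
) -> AnalysisReport:
    """Compose the full analysis report for *cohort*.

    Deterministic given the cohort and options.  Every block's totals
    conserve to the overall block.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")

    res_los = mrruf(cohort, "los")
    res_bc = mrruf(cohort, "charges")
    overall = {
        "n_admissions": len(cohort),
        "n_deaths": cohort.n_deaths,
        "mortality_pct": round(100.0 * mortality_rate(cohort), 1),
        "total_los_days": int(res_los.grand_total),
        "total_charges_usd": res_bc.grand_total,
        "mrruf_los": _na(round(res_los.fraction, 3)),
        "mrruf_charges": _na(round(res_bc.fraction, 3)),
        "mrruf_los_pct": _na(round(100.0 * res_los.fraction, 1)),
        "mrruf_charges_pct": _na(round(100.0 * res_bc.fraction, 1)),
    }

    by_volume = stratified_summary(cohort, "volume_stratum")
    by_age = stratified_summary(cohort, "age_band")
    table1 = {
        "by_volume_stratum": _table_rows(by_volume),
        "by_age_band": _table_rows(by_age),
    }

    # pairwise mortality comparisons against the reference band
    age_counts = {
        s.stratum: (s.n_deaths, s.n_admissions - s.n_deaths) for s in by_age
    }
    flags: dict[str, bool] = {}
    if options.reference_band in age_counts and len(age_counts) >= 2:
        for r in pairwise_vs_reference(
            age_counts, options.reference_band, correction=options.correction
        ):
            flags[r.group] = bool(r.significant)
    table2 = {
        "reference_band": options.reference_band,
        "correction": options.correction,
        "rows": [
            {
                "age_band": s.stratum,
                "n": s.n_admissions,
                "deaths_pct": round(s.death_pct, 1),
                "mrruf_los": _na(round(s.mrruf_los, 3)),
                "mrruf_charges": _na(round(s.mrruf_charges, 3)),
                "significant_vs_reference": flags.get(s.stratum),
            }
            for s in by_age
        ],
    }

    trends = _trends_block(cohort, options)
    return AnalysisReport(
        overall=overall, table1=table1, table2=table2, trends=trends
    )


def _trends_block(cohort: Cohort, options: ReportOptions) -> dict:
    yearly = [
        {
            "year": int(s.stratum),
            "n": s.n_admissions,
            "deaths": s.n_deaths,
            "mortality_pct": round(s.death_pct, 1),
            "mrruf_los": _na(round(s.mrruf_los, 3)),
            "mrruf_charges": _na(round(s.mrruf_charges, 3)),
        }
        for s in stratified_summary(cohort, "year")
    ]

    profiles = institution_profiles(cohort, window_years=options.window_years)
    excluded: list[str] = []
    trend_cohort = cohort
    if options.exclude_low_volume:
        trend_cohort, excluded_profiles = exclude_nonrepresentative(
            profiles, cohort, max_volume_threshold=options.max_volume_threshold
        )
        excluded = [p.institution_id for p in excluded_profiles]
        profiles = institution_profiles(
            trend_cohort, window_years=options.window_years
        )

    block: dict = {
        "yearly": yearly,
        "excluded_institutions": excluded,
        "n_institutions_analyzed": len(profiles),
    }

    # institution-year mortality vs calendar year (least squares)
    inst_year: dict[tuple[str, int], list[int]] = {}
    for r in trend_cohort:
        inst_year.setdefault((r.institution_id, r.year), []).append(r.died)
    xs = [year for (_, year) in inst_year]
    ys = [sum(v) / len(v) for v in inst_year.values()]
    if len(set(xs)) >= 2 and len(xs) >= 3:
        fit = ols_trend(xs, ys)
        block["mortality_vs_year"] = {
            "unit": "institution-year",
            "slope_per_year": fit.slope,
            "adjusted_r_squared": round(fit.adjusted_r_squared, 3),
            "p_value": fit.p_value,
            "n": fit.n,
        }

    # per-institution MRRUF / mortality vs volume (Spearman)
    if len(profiles) >= 3:
        by_inst = stratified_summary(trend_cohort, "institution")
        vol = {p.institution_id: p.volume for p in profiles}
        volumes = [vol[s.stratum] for s in by_inst]
        for key, values in (
            ("mrruf_los_vs_volume", [s.mrruf_los for s in by_inst]),
            ("mrruf_charges_vs_volume", [s.mrruf_charges for s in by_inst]),
            ("mortality_vs_volume", [s.death_pct / 100.0 for s in by_inst]),
        ):
            r = spearman_rho(volumes, values)
            block[key] = {
                "rho": _na(round(r.statistic, 3)),
                "p_value": _na(r.p_value),
                "n": r.n[0],
            }
    return block
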