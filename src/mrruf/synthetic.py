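"""Seeded generator of registry-like HLHS admission cohorts.

The real admission-level data are proprietary, so this module provides a
hierarchical simulator whose marginals are calibrated to the published
stratum tables (see :mod:`mrruf.published`): hospital volumes are drawn
from a truncated normal (mean 259, sd 181, minimum 1 admission over the
window), each admission then gets a uniform year, an age band from the
published age mixture, an integer age uniform within the band, a death
indicator from the band-specific mortality rate (with an optional
calendar-year log-odds trend renormalized so the window-average equals
the band rate), a log-normal length of stay, and billed charges equal to
the continuous stay length times an independent log-normal per-diem rate.

LOS and charges are modeled log-normal because only medians, means and
IQRs are published and all three indicate strong right skew (overall
median 12 days vs mean 24.9); log-normal is the minimal two-parameter
skewed family consistent with them.  The default log-sigmas are solved in
closed form so that the configuration's *expected* statistics reproduce
the published headline figures: overall mean LOS 24.9 days, LOS-domain
MRRUF 0.16 and charge-domain MRRUF 0.21, with status-specific LOS medians
17 (deaths) vs 12 (alive) and charge medians $4.09e5 vs $1.63e5.  Charges
use the continuous (pre-rounding) stay length so that the decedent charge
median calibration 17 x $24,058.8/day = $409,000 is exact (a product of
independent log-normals has median equal to the product of medians); the
stored integer ``los_days`` is the stay rounded up to a whole day.

:func:`expected_statistics` gives the closed-form expectations implied by
any configuration and is the analytic oracle against which generated
cohorts are checked.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm, truncnorm

from . import published
from .records import AdmissionRecord, Cohort
from .strata import AGE_BANDS

__all__ = [
    "GeneratorConfig",
    "CohortSpec",
    "ExpectedStats",
    "default_paper_config",
    "generate",
    "expected_statistics",
]

_N_BANDS = 5


def _vec(x, name: str) -> tuple[float, ...]:
    v = tuple(float(t) for t in np.broadcast_to(x, (_N_BANDS,)))
    return v


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic admission cohort.

    All per-band vectors are ordered as the age bands <1, 1, 2-4, 5-12,
    >12.  Medians are in days (LOS) and dollars/day (per-diem); sigmas
    are log-scale standard deviations.
    """

    n_institutions: int = 43
    window: tuple[int, int] = (2004, 2013)
    volume_mean: float = 259.0
    volume_sd: float = 181.0
    age_band_probs: tuple[float, ...] = (0.2,) * 5
    death_prob_by_band: tuple[float, ...] = (0.1,) * 5
    year_trend_log_odds: float = 0.0
    los_median_died: tuple[float, ...] = (17.0,) * 5
    los_median_alive: tuple[float, ...] = (12.0,) * 5
    los_sigma_died: tuple[float, ...] = (1.0,) * 5
    los_sigma_alive: tuple[float, ...] = (1.0,) * 5
    perdiem_median_died: float = 24_000.0
    perdiem_median_alive: float = 13_500.0
    perdiem_sigma_died: float = 0.25
    perdiem_sigma_alive: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        probs = np.asarray(self.age_band_probs, dtype=float)
        if probs.shape != (_N_BANDS,) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("age_band_probs must be 5 values summing to 1")
        if (probs < 0).any():
            raise ValueError("age_band_probs must be non-negative")
        rates = np.asarray(self.death_prob_by_band, dtype=float)
        if rates.shape != (_N_BANDS,) or ((rates < 0) | (rates > 1)).any():
            raise ValueError("death_prob_by_band must be 5 rates in [0,1]")
        for name in (
            "los_median_died", "los_median_alive",
            "los_sigma_died", "los_sigma_alive",
        ):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (_N_BANDS,) or (v <= 0).any():
                raise ValueError(f"{name} must be 5 positive values")
        for name in (
            "perdiem_median_died", "perdiem_median_alive",
            "perdiem_sigma_died", "perdiem_sigma_alive",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_institutions < 1:
            raise ValueError("n_institutions must be >= 1")
        if self.window[1] < self.window[0]:
            raise ValueError("window must be (first_year, last_year)")
        if self.volume_mean <= 0 or self.volume_sd <= 0:
            raise ValueError("volume_mean and volume_sd must be positive")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        d = self.to_dict()
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        d = yaml.safe_load(text)
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass(frozen=True)
class CohortSpec:
    """Metadata sidecar for a generated cohort."""

    config: GeneratorConfig
    seed: int
    n_total: int
    realized_band_counts: tuple[int, ...]
    realized_deaths: int

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "n_total": self.n_total,
            "realized_band_counts": list(self.realized_band_counts),
            "realized_deaths": self.realized_deaths,
            "config": json.loads(json.dumps(self.config.to_dict())),
        }
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class ExpectedStats:
    """Closed-form expectations implied by a configuration."""

    mortality_rate: float
    mrruf_los: float
    mrruf_charges: float
    mean_los: float
    median_los_died: float
    median_los_alive: float
    median_charges_died: float
    median_charges_alive: float


def default_paper_config(seed: int = 0) -> GeneratorConfig:
    """The published-calibrated default configuration.

    The age mixture and band mortality rates come directly from the
    published stratum tables.  LOS log-sigmas are solved in closed form
    from the published overall mean LOS (24.9 days) and the LOS-domain
    MRRUF (0.16), given the status medians 17/12; per-diem medians are
    target charge medians divided by the LOS medians, the decedent
    per-diem sigma is fixed at 0.25, and the survivor per-diem sigma is
    solved from the charge-domain MRRUF (0.21).  The calendar trend is a
    modest decline of 0.05 on the yearly death log-odds.
    """
    counts = np.array([r.n_admissions for r in published.AGE_BAND_TABLE], float)
    probs = counts / counts.sum()
    rates = np.array(
        [published.AGE_BAND_DEATH_PCT[r.label] / 100.0
         for r in published.AGE_BAND_TABLE]
    )
    p_bar = float(probs @ rates)

    mean_los = published.OVERALL["mean_los_days"]           # 24.9
    f_los = published.OVERALL["mrruf_los_pct"] / 100.0      # 0.16
    f_bc = published.OVERALL["mrruf_charges_pct"] / 100.0   # 0.21
    med_d = float(published.OVERALL["median_los_died"])     # 17
    med_a = float(published.OVERALL["median_los_alive"])    # 12

    # E[LOS | died] and E[LOS | alive] from the two headline constraints
    e_los_d = f_los * mean_los / p_bar
    e_los_a = (1.0 - f_los) * mean_los / (1.0 - p_bar)
    sigma_d = math.sqrt(2.0 * math.log(e_los_d / med_d))
    sigma_a = math.sqrt(2.0 * math.log(e_los_a / med_a))

    # per-diem medians fix the status charge medians exactly
    pd_med_d = published.OVERALL["median_charges_died"] / med_d
    pd_med_a = published.OVERALL["median_charges_alive"] / med_a
    tau_d = 0.25
    e_pd_d = pd_med_d * math.exp(tau_d**2 / 2.0)
    num = p_bar * e_los_d * e_pd_d
    e_pd_a = num * (1.0 - f_bc) / f_bc / ((1.0 - p_bar) * e_los_a)
    tau_a = math.sqrt(2.0 * math.log(e_pd_a / pd_med_a))

    return GeneratorConfig(
        n_institutions=published.OVERALL["n_institutions"],
        window=(2004, 2013),
        volume_mean=float(published.OVERALL["mean_admissions_per_institution"]),
        volume_sd=float(published.OVERALL["sd_admissions_per_institution"]),
        age_band_probs=tuple(float(p) for p in probs),
        death_prob_by_band=tuple(float(r) for r in rates),
        year_trend_log_odds=-0.05,
        los_median_died=(med_d,) * 5,
        los_median_alive=(med_a,) * 5,
        los_sigma_died=(sigma_d,) * 5,
        los_sigma_alive=(sigma_a,) * 5,
        perdiem_median_died=pd_med_d,
        perdiem_median_alive=pd_med_a,
        perdiem_sigma_died=tau_d,
        perdiem_sigma_alive=tau_a,
        seed=seed,
    )


def _year_death_probs(config: GeneratorConfig) -> np.ndarray:
    """(band, year-index) death probabilities.

    The log-odds trend is applied around the window midpoint and the
    band intercept is solved so the window-average probability equals
    the configured band rate, keeping the calibration targets exact.
    """
    y0, y1 = config.window
    years = np.arange(y0, y1 + 1)
    offsets = config.year_trend_log_odds * (years - years.mean())
    out = np.empty((_N_BANDS, len(years)))
    for g, p in enumerate(config.death_prob_by_band):
        if p <= 0.0 or p >= 1.0 or config.year_trend_log_odds == 0.0:
            out[g] = p
            continue

        def gap(alpha: float) -> float:
            return float(expit(alpha + offsets).mean()) - p

        span = abs(offsets).max() + 1.0
        alpha = brentq(gap, logit(p) - span, logit(p) + span)
        out[g] = expit(alpha + offsets)
    return out


def generate(config: GeneratorConfig) -> tuple[Cohort, CohortSpec]:
    """Draw one cohort from *config*; identical config gives an identical
    cohort (all randomness flows through ``config.seed``)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.window

    # hospital volumes: truncated normal, minimum 1, rounded to integer
    a = (1.0 - config.volume_mean) / config.volume_sd
    vols = truncnorm.rvs(
        a, np.inf, loc=config.volume_mean, scale=config.volume_sd,
        size=config.n_institutions, random_state=rng,
    )
    vols = np.maximum(1, np.rint(vols).astype(int))
    n = int(vols.sum())
    inst_labels = np.array(
        [f"H{i:03d}" for i in range(config.n_institutions)]
    )
    inst = np.repeat(inst_labels, vols)

    years = rng.integers(y0, y1 + 1, size=n)
    band = rng.choice(_N_BANDS, size=n, p=np.asarray(config.age_band_probs))
    lowers = np.array([b.lower_inclusive for b in AGE_BANDS])
    uppers = np.array([b.upper_exclusive for b in AGE_BANDS])
    ages = lowers[band] + rng.integers(
        0, (uppers - lowers)[band]
    )

    pmat = _year_death_probs(config)
    p_i = pmat[band, years - y0]
    died = rng.random(n) < p_i

    med = np.where(
        died,
        np.asarray(config.los_median_died)[band],
        np.asarray(config.los_median_alive)[band],
    )
    sig = np.where(
        died,
        np.asarray(config.los_sigma_died)[band],
        np.asarray(config.los_sigma_alive)[band],
    )
    los_cont = med * np.exp(sig * rng.standard_normal(n))
    los_days = np.ceil(los_cont).astype(int)

    pd_med = np.where(
        died, config.perdiem_median_died, config.perdiem_median_alive
    )
    pd_sig = np.where(
        died, config.perdiem_sigma_died, config.perdiem_sigma_alive
    )
    perdiem = pd_med * np.exp(pd_sig * rng.standard_normal(n))
    charges = np.round(los_cont * perdiem, 2)

    records = tuple(
        AdmissionRecord(
            institution_id=str(inst[i]),
            year=int(years[i]),
            age_years=int(ages[i]),
            los_days=int(los_days[i]),
            billed_charges=float(charges[i]),
            died=bool(died[i]),
        )
        for i in range(n)
    )
    cohort = Cohort(records=records, provenance=f"synthetic(seed={config.seed})")
    band_counts = tuple(int(c) for c in np.bincount(band, minlength=_N_BANDS))
    spec = CohortSpec(
        config=config,
        seed=config.seed,
        n_total=n,
        realized_band_counts=band_counts,
        realized_deaths=int(died.sum()),
    )
    return cohort, spec


def _mixture_lognormal_median(
    weights: np.ndarray, medians: np.ndarray, sigmas: np.ndarray
) -> float:
    """Median of a finite mixture of log-normals (by CDF root-finding)."""
    w = weights / weights.sum()
    mus = np.log(medians)

    def cdf(x: float) -> float:
        return float(w @ norm.cdf((math.log(x) - mus) / sigmas))

    lo = float(medians.min()) * math.exp(-6 * float(sigmas.max()))
    hi = float(medians.max()) * math.exp(6 * float(sigmas.max()))
    return brentq(lambda x: cdf(x) - 0.5, lo, hi)


def expected_statistics(config: GeneratorConfig) -> ExpectedStats:
    """Closed-form expectations implied by *config*.

    mortality = sum_g pi_g p_g; the MRRUF expectations replace each sum
    of the ratio by its expectation (log-normal mean = median *
    exp(sigma^2/2)); status-conditional medians come from the band
    mixture.  These are the targets for parameter-recovery checks on
    generated cohorts.
    """
    config.validate()
    pi = np.asarray(config.age_band_probs)
    p = np.asarray(config.death_prob_by_band)
    med_d = np.asarray(config.los_median_died)
    med_a = np.asarray(config.los_median_alive)
    sig_d = np.asarray(config.los_sigma_died)
    sig_a = np.asarray(config.los_sigma_alive)

    mortality = float(pi @ p)
    e_los_d = med_d * np.exp(sig_d**2 / 2.0)
    e_los_a = med_a * np.exp(sig_a**2 / 2.0)
    num_los = float(pi @ (p * e_los_d))
    den_los = num_los + float(pi @ ((1.0 - p) * e_los_a))
    mrruf_los = num_los / den_los if den_los > 0 else float("nan")

    e_pd_d = config.perdiem_median_died * math.exp(
        config.perdiem_sigma_died**2 / 2.0
    )
    e_pd_a = config.perdiem_median_alive * math.exp(
        config.perdiem_sigma_alive**2 / 2.0
    )
    num_bc = float(pi @ (p * e_los_d)) * e_pd_d
    den_bc = num_bc + float(pi @ ((1.0 - p) * e_los_a)) * e_pd_a
    mrruf_bc = num_bc / den_bc if den_bc > 0 else float("nan")

    w_d = pi * p
    w_a = pi * (1.0 - p)
    sig_c_d = np.sqrt(sig_d**2 + config.perdiem_sigma_died**2)
    sig_c_a = np.sqrt(sig_a**2 + config.perdiem_sigma_alive**2)
    if w_d.sum() > 0:
        median_los_died = _mixture_lognormal_median(w_d, med_d, sig_d)
        median_charges_died = _mixture_lognormal_median(
            w_d, med_d * config.perdiem_median_died, sig_c_d
        )
    else:
        median_los_died = float("nan")
        median_charges_died = float("nan")
    median_los_alive = _mixture_lognormal_median(w_a, med_a, sig_a)
    median_charges_alive = _mixture_lognormal_median(
        w_a, med_a * config.perdiem_median_alive, sig_c_a
    )

    return ExpectedStats(
        mortality_rate=mortality,
        mrruf_los=mrruf_los,
        mrruf_charges=mrruf_bc,
        mean_los=den_los,
        median_los_died=float(median_los_died),
        median_los_alive=float(median_los_alive),
        median_charges_died=float(median_charges_died),
        median_charges_alive=float(median_charges_alive),
    )
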