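"""Inferential toolkit for cohort comparisons.

Covers the four procedures used in the analysis: Pearson chi-square
homogeneity of mortality across groups (no continuity correction),
pairwise 2x2 comparisons against a reference group with optional
Bonferroni correction, the Mann-Whitney U test (exact permutation p with
midrank ties for small samples, tie-corrected normal approximation
otherwise), Spearman rank correlation on midranks (exact permutation p
for n <= 8), and simple least-squares trend with adjusted r².

The exact Mann-Whitney distribution under ties is computed by dynamic
programming over the rank-sum of all equally likely assignments of
observations to the first sample; midranks are doubled to keep the sums
integral, so the counts are exact rationals.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "TrendFit",
    "chi_square_homogeneity",
    "pairwise_vs_reference",
    "mann_whitney_u",
    "spearman_rho",
    "ols_trend",
    "EXACT_PRODUCT_LIMIT",
]

#: exact Mann-Whitney enumeration is used when n_x * n_y <= this
EXACT_PRODUCT_LIMIT = 400

#: exact Spearman permutation p is used when n <= this
SPEARMAN_EXACT_LIMIT = 8


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method_notes: str = ""
    group: str | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    p_value: float
    n: int


def chi_square_homogeneity(table) -> TestResult:
    """Pearson chi-square for homogeneity of a groups x {died, survived}
    count table, without continuity correction; df = rows - 1."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("expected a groups x 2 table of counts")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("every row (group) must have a positive total")
    if (table.sum(axis=0) == 0).any():
        raise ValueError("both outcome columns must have a positive total")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(
        test_name="chi_square_homogeneity",
        statistic=float(chi2),
        p_value=float(p),
        n=(int(table.sum()),),
        method_notes=f"df={dof}, no continuity correction",
    )


def pairwise_vs_reference(
    counts: dict[str, tuple[int, int]],
    reference: str,
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> list[TestResult]:
    """2x2 chi-square of each group against *reference*.

    *counts* maps group label -> (deaths, survivors).  Under Bonferroni
    the p-value is multiplied by the number of comparisons (capped at 1);
    ``significant`` flags corrected p < *alpha*.
    """
    if reference not in counts:
        raise ValueError(f"reference group {reference!r} not in counts")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    others = [g for g in counts if g != reference]
    if not others:
        raise ValueError("need at least two groups")
    k = len(others)
    results = []
    for g in others:
        table = np.array([counts[reference], counts[g]], dtype=float)
        base = chi_square_homogeneity(table)
        p = base.p_value
        if correction == "bonferroni":
            p = min(1.0, p * k)
        results.append(
            TestResult(
                test_name=f"chi_square_pairwise",
                statistic=base.statistic,
                p_value=p,
                n=(int(table.sum()),),
                method_notes=(
                    f"{g} vs {reference}; raw p={base.p_value:.6g}; "
                    f"correction={correction} (k={k})"
                ),
                group=g,
                significant=bool(p < alpha),
            )
        )
    return results


def _exact_ranksum_tail_counts(ranks2: np.ndarray, nx: int):
    """Counts of subsets of size nx by doubled-rank sum (exact, all ties).

    Returns (sums, counts) arrays over the support of the rank-sum of the
    first sample under the permutation null.
    """
    layers: list[dict[int, int]] = [defaultdict(int) for _ in range(nx + 1)]
    layers[0][0] = 1
    for r in ranks2:
        r = int(r)
        for k in range(min(nx, len(layers) - 1), 0, -1):
            if layers[k - 1]:
                target = layers[k]
                for s, c in layers[k - 1].items():
                    target[s + r] += c
    dist = layers[nx]
    sums = np.array(sorted(dist))
    counts = np.array([dist[s] for s in sums], dtype=object)
    return sums, counts


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    ``mode``: "exact" enumerates the permutation null of the rank-sum
    (valid with ties), "normal" uses the tie-corrected normal
    approximation without continuity correction, "auto" picks exact when
    n_x * n_y <= EXACT_PRODUCT_LIMIT.  The two-sided exact p is
    2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if nx * ny <= EXACT_PRODUCT_LIMIT else "normal"

    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)  # midranks
    rank_sum_x = ranks[:nx].sum()
    u = rank_sum_x - nx * (nx + 1) / 2.0

    n = nx + ny
    if mode == "exact":
        ranks2 = np.rint(2 * ranks).astype(int)  # doubled midranks: integers
        sums, counts = _exact_ranksum_tail_counts(ranks2, nx)
        total = math.comb(n, nx)
        obs = int(round(2 * rank_sum_x))
        lower = sum(int(c) for s, c in zip(sums, counts) if s <= obs)
        upper = sum(int(c) for s, c in zip(sums, counts) if s >= obs)
        p = min(1.0, 2.0 * min(lower, upper) / total)
        notes = "exact permutation null (midrank ties), two-sided"
    else:
        mean_u = nx * ny / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
        var_u = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:  # all observations identical
            return TestResult(
                "mann_whitney_u", float(u), 1.0, (nx, ny),
                "degenerate: zero variance (all values tied)",
            )
        z = (u - mean_u) / math.sqrt(var_u)
        p = 2.0 * sps.norm.sf(abs(z))
        notes = (
            "normal approximation, tie-corrected variance, "
            "no continuity correction"
        )
    return TestResult(
        test_name="mann_whitney_u",
        statistic=float(u),
        p_value=float(p),
        n=(nx, ny),
        method_notes=notes,
    )


def spearman_rho(x, y, mode: str = "auto") -> TestResult:
    """Spearman rank correlation: Pearson correlation of midranks.

    Exact permutation p for n <= 8 (all n! orderings of one variable),
    otherwise the two-sided t-approximation with n - 2 df.  Constant
    input makes rho undefined (NaN statistic, NaN p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d samples")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return TestResult(
            "spearman_rho", float("nan"), float("nan"), (n,),
            "undefined: constant input",
        )

    def _pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    rho = _pearson(rx, ry)
    if mode == "auto":
        mode = "exact" if n <= SPEARMAN_EXACT_LIMIT else "t"
    if mode == "exact":
        obs = abs(rho) - 1e-12
        hits = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_pearson(rx, np.array(perm))) >= obs:
                hits += 1
        p = hits / total
        notes = f"exact permutation p over {total} orderings"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
        notes = "t-approximation, df=n-2"
    return TestResult(
        test_name="spearman_rho",
        statistic=rho,
        p_value=float(p),
        n=(n,),
        method_notes=notes,
    )


def ols_trend(x, y) -> TrendFit:
    """Simple least-squares fit of y on x with adjusted r².

    adjusted r² = 1 - (1 - r²)(n - 1)/(n - 2); slope p-value is the
    two-sided t test of slope = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; trend undefined")
    fit = sps.linregress(x, y)
    r2 = fit.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        adjusted_r_squared=float(adj),
        p_value=float(fit.pvalue),
        n=n,
    )
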