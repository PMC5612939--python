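"""Inferential machinery: migrant-pool resampling null, one-way ANOVA with
Tukey HSD, Mann-Whitney U, and Bonferroni correction.

The migrant-pool null asks whether the observed community mean rrn copy
number could arise by random assembly from the shared genus pool: it
repeatedly draws a fixed number of OTUs (default 150) from the pool
without replacement, records each draw's mean copy number, and reports a
two-sided empirical p for the observed mean against that null
distribution. The add-one convention keeps p strictly positive.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "NullDistribution",
    "TestResult",
    "migrant_pool_null",
    "anova_tukey",
    "mann_whitney",
    "bonferroni",
]

_TINY_P = float(np.nextafter(0, 1))
EXACT_MWU_MAX_N = 12


@dataclass
class NullDistribution:
    """Resampled null for a community mean with its empirical p-value."""

    draws: np.ndarray
    observed: float
    empirical_p: float
    n_draw: int
    n_rep: int
    seed: int

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if len(self.draws) != self.n_rep:
            raise ValueError("draws length must equal n_rep")
        if not 0 < self.empirical_p <= 1:
            raise ValueError("empirical p must lie in (0, 1]")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    group_sizes: tuple
    adjusted: bool = False
    labels: tuple = ()

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def migrant_pool_null(
    pool_rrn,
    observed_mean: float,
    n_draw: int = 150,
    n_rep: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> NullDistribution:
    """Resampling null for the mean rrn of a random OTU subset of the pool.

    Each replicate draws ``n_draw`` copy numbers from ``pool_rrn``
    (without replacement by default) and records their mean. The
    empirical p is two-sided about the null mean with the add-one
    convention:

        p = (1 + #{ |draw_i - m| >= |observed - m| }) / (n_rep + 1)

    where m is the mean of the null draws; p is therefore never zero.
    Deterministic given ``seed``.
    """
    pool = np.asarray(pool_rrn, dtype=float)
    if n_draw <= 0 or n_rep <= 0:
        raise ValueError("n_draw and n_rep must be positive")
    if not replace and len(pool) < n_draw:
        raise ValueError(f"pool of {len(pool)} is smaller than n_draw={n_draw}")
    rng = np.random.default_rng(seed)
    draws = np.empty(n_rep)
    for i in range(n_rep):
        draws[i] = rng.choice(pool, size=n_draw, replace=replace).mean()
    m = draws.mean()
    exceed = int(np.sum(np.abs(draws - m) >= np.abs(observed_mean - m)))
    p = (1 + exceed) / (n_rep + 1)
    return NullDistribution(draws, float(observed_mean), p, n_draw, n_rep, seed)


def _anova_ss(groups):
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return float(ssb), float(ssw), df_b, df_w


def anova_tukey(groups) -> list[TestResult]:
    """One-way fixed-effects ANOVA plus all pairwise Tukey HSD contrasts.

    ``groups`` is a list of ``(label, values)`` pairs, each with at least
    two observations. Returns the omnibus F test first, then one adjusted
    result per pair (studentized-range p-values). Zero within-group
    variance with distinct means is reported as the smallest
    representable positive p with a warning, not an exception.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = [str(lab) for lab, _ in groups]
    arrays = [np.asarray(v, dtype=float) for _, v in groups]
    for lab, a in zip(labels, arrays):
        if len(a) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")
    sizes = tuple(len(a) for a in arrays)
    ssb, ssw, df_b, df_w = _anova_ss(arrays)
    degenerate = ssw == 0.0
    if degenerate and ssb > 0:
        warnings.warn("zero within-group variance; p degenerate", UserWarning, stacklevel=2)
        results = [TestResult(float("inf"), _TINY_P, "anova", sizes)]
        for (i, j) in itertools.combinations(range(len(groups)), 2):
            same = arrays[i].mean() == arrays[j].mean()
            results.append(TestResult(
                0.0 if same else float("inf"), 1.0 if same else _TINY_P,
                "tukey_hsd", (sizes[i], sizes[j]), adjusted=True,
                labels=(labels[i], labels[j]),
            ))
        return results
    if ssb == 0.0:
        F, p = 0.0, 1.0
    else:
        F = (ssb / df_b) / (ssw / df_w)
        p = float(sps.f.sf(F, df_b, df_w))
    results = [TestResult(float(F), max(p, _TINY_P), "anova", sizes)]
    hsd = sps.tukey_hsd(*arrays)
    for (i, j) in itertools.combinations(range(len(groups)), 2):
        results.append(TestResult(
            float(hsd.statistic[i, j]),
            max(float(hsd.pvalue[i, j]), _TINY_P),
            "tukey_hsd",
            (sizes[i], sizes[j]),
            adjusted=True,
            labels=(labels[i], labels[j]),
        ))
    return results


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when the combined sample size is at most 12
    and there are no ties; otherwise the normal approximation with
    midranks, tie-corrected variance and continuity correction. The
    all-tied case (tie-corrected variance zero) reports U = n1*n2/2 and
    p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    n1, n2 = len(x), len(y)
    if np.ptp(combined) == 0:
        return TestResult(n1 * n2 / 2.0, 1.0, "mann-whitney-u", (n1, n2))
    method = "exact" if (n1 + n2 <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    if not np.isfinite(p) or p <= 0:
        p = 1.0 if not np.isfinite(res.pvalue) else _TINY_P
    return TestResult(float(res.statistic), p, f"mann-whitney-u-{method}", (n1, n2))


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni correction: p*m clipped at 1, m = number of tests."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(p * p.size, 1.0)
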