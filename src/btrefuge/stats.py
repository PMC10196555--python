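"""Monitoring statistics: Wilson intervals, genotype tallies, bioassay rates,
log-scale regression/correlation, and pooled-variance t-tests.

Conventions follow standard resistance-monitoring practice: proportions get
continuity-corrected Wilson score intervals; across-site annual means get
site-level bootstrap intervals; trend tests use ordinary least squares on
log10-transformed responses; all tests are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "Interval",
    "GenotypeTally",
    "BioassayRecord",
    "genotype_allele_frequency",
    "wilson_ci_cc",
    "bootstrap_mean_ci",
    "resistance_percentage",
    "log_linear_regression",
    "log_pearson_correlation",
    "two_sample_t_test",
    "RegressionResult",
    "CorrelationResult",
    "TTestResult",
]


@dataclass(frozen=True)
class Interval:
    """A two-sided confidence interval (bounds on the measure's own scale)."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} exceeds upper {self.upper}")

    def __contains__(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class GenotypeTally:
    """Counts of individuals by genotype at a biallelic locus."""

    ss: int
    rs: int
    rr: int

    def __post_init__(self) -> None:
        for name in ("ss", "rs", "rr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")

    @property
    def total(self) -> int:
        return self.ss + self.rs + self.rr

    @property
    def r_copies(self) -> int:
        return 2 * self.rr + self.rs


@dataclass(frozen=True)
class BioassayRecord:
    """Diagnostic-dose bioassay outcome for one site and year.

    ``n_surviving`` of ``n_tested`` larvae survived the diagnostic
    concentration (1 ug Cry1Ac per cm^2 diet), which kills essentially all
    susceptibles, so survivors are scored resistant.
    """

    site_id: str
    year: int
    n_tested: int
    n_surviving: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_surviving <= self.n_tested:
            raise ValueError(
                f"need 0 <= n_surviving <= n_tested, got "
                f"{self.n_surviving}/{self.n_tested}"
            )

    @property
    def survival_percent(self) -> float:
        if self.n_tested == 0:
            raise ValueError(f"site {self.site_id}: no larvae tested")
        return 100.0 * self.n_surviving / self.n_tested


def genotype_allele_frequency(tally: GenotypeTally) -> float:
    """Resistance-allele frequency from individual genotypes: (2 rr + rs) / 2N."""
    if tally.total == 0:
        raise ValueError("empty genotype tally")
    return tally.r_copies / (2.0 * tally.total)


def wilson_ci_cc(successes: int, n: int, confidence: float = 0.95) -> Interval:
    """Wilson score interval with continuity correction for a proportion.

    Uses Newcombe's closed form; the lower bound is 0 when ``successes`` is 0
    and the upper bound is 1 when ``successes`` equals ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    p = successes / n
    q = 1.0 - p
    denom = 2.0 * (n + z * z)
    if successes == 0:
        lower = 0.0
    else:
        lower = (
            2.0 * n * p + z * z - 1.0
            - z * math.sqrt(z * z - 2.0 - 1.0 / n + 4.0 * p * (n * q + 1.0))
        ) / denom
    if successes == n:
        upper = 1.0
    else:
        upper = (
            2.0 * n * p + z * z + 1.0
            + z * math.sqrt(z * z + 2.0 - 1.0 / n + 4.0 * p * (n * q - 1.0))
        ) / denom
    return Interval(max(0.0, lower), min(1.0, upper))


def bootstrap_mean_ci(
    values: Sequence[float],
    reps: int = 1000,
    seed: Optional[int] = None,
    confidence: float = 0.95,
) -> tuple[float, Interval]:
    """Mean of ``values`` with a percentile bootstrap CI over the units.

    Units (here: collection sites) are resampled with replacement ``reps``
    times; the interval is the (1-confidence)/2 and 1-(1-confidence)/2
    quantiles of the resampled means.  Deterministic under a fixed seed.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(reps, arr.size))
    means = arr[idx].mean(axis=1)
    alpha = (1.0 - confidence) / 2.0
    lower, upper = np.quantile(means, [alpha, 1.0 - alpha])
    return float(arr.mean()), Interval(float(lower), float(upper))


def resistance_percentage(
    records: Sequence[BioassayRecord],
    reps: int = 1000,
    seed: Optional[int] = None,
) -> tuple[float, Interval]:
    """Unweighted across-site mean bioassay survival (%) with bootstrap CI."""
    records = list(records)
    if not records:
        raise ValueError("at least one bioassay record is required")
    percents = [r.survival_percent for r in records]
    return bootstrap_mean_ci(percents, reps=reps, seed=seed)


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    df: int


class CorrelationResult(NamedTuple):
    r: float
    p_value: float
    df: int


class TTestResult(NamedTuple):
    t: float
    df: int
    p_value: float


def _check_positive(name: str, values: Sequence[float], labels=None) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    bad = np.nonzero(arr <= 0)[0]
    if bad.size:
        where = labels[bad[0]] if labels is not None else f"index {bad[0]}"
        raise ValueError(
            f"{name} must be strictly positive for the log transform "
            f"(first offender at {where})"
        )
    return arr


def log_linear_regression(
    years: Sequence[float], values: Sequence[float]
) -> RegressionResult:
    """OLS of log10(value) on year: trend test for a monitoring series."""
    years_arr = np.asarray(years, dtype=float)
    if years_arr.size != len(values):
        raise ValueError("years and values must have equal length")
    if years_arr.size < 3:
        raise ValueError("at least 3 points are required")
    vals = _check_positive("values", values, labels=np.asarray(years))
    fit = sps.linregress(years_arr, np.log10(vals))
    r_squared = float(fit.rvalue) ** 2
    p_value = float(fit.pvalue)
    if math.isnan(r_squared) and fit.slope == 0.0:
        # constant response: no trend, no explained variance
        r_squared, p_value = 0.0, 1.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        p_value=p_value,
        df=int(years_arr.size - 2),
    )


def log_pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation of log10(x) with log10(y), two-sided p."""
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("at least 3 pairs are required")
    xs = _check_positive("x", x)
    ys = _check_positive("y", y)
    r, p = sps.pearsonr(np.log10(xs), np.log10(ys))
    return CorrelationResult(r=float(r), p_value=float(p), df=len(x) - 2)


def two_sample_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample t-test (df = n_a + n_b - 2), two-sided."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=True)
    return TTestResult(
        t=float(res.statistic), df=len(a) + len(b) - 2, p_value=float(res.pvalue)
    )
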