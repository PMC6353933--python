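"""Log-log power-law fits for virus-vs-host and ratio-vs-host relationships.

A power law ``y ~ x^alpha`` between virus abundance y and host abundance x
is linear on log axes, so ``alpha`` is estimated as the ordinary
least-squares slope of log10(y) on log10(x).  The companion ratio fit
regresses log10(y/x) on log10(x); since log10(y/x) = log10(y) - log10(x),
its slope ``beta`` satisfies the exact identity

    beta = alpha - 1.

This identity is what makes ratio-vs-denominator regressions hazardous:
when y is unrelated to x (alpha = 0) the ratio slope is -1, not 0, purely
by self-correlation of x with 1/x.

All fits use log10; slopes are invariant to the log base, and log10
matches the axis convention of abundance plots.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .datasets import AbundancePairDataset
from .errors import DegenerateFitError


class StatisticKind(str, Enum):
    """Statistics that can drive a fit or a permutation test."""

    PM_SLOPE = "pm_slope"
    PEARSON_R = "pearson_r"
    SPEARMAN_RHO = "spearman_rho"
    THEIL_SEN_SLOPE = "theil_sen_slope"


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares summary of one pair's log-log relationship.

    ``alpha_hat``/``intercept_hat`` describe log10(virus) vs log10(host);
    ``beta_hat`` is the slope of log10(virus/host) vs log10(host) and
    always equals ``alpha_hat - 1`` up to round-off.  ``r`` is the Pearson
    product-moment correlation of the log10 values (NaN when the virus
    vector is constant, where a correlation is undefined), ``rho`` the
    average-rank Spearman correlation, and ``theil_sen`` the median of
    pairwise log-log slopes.
    """

    pair_id: str
    alpha_hat: float
    intercept_hat: float
    beta_hat: float
    r: float
    rho: float
    theil_sen: float
    n: int


def log_xy(dataset: AbundancePairDataset) -> tuple[np.ndarray, np.ndarray]:
    """Return (log10 host, log10 virus), rejecting nonpositive abundances."""
    if not dataset.all_positive():
        raise DegenerateFitError(
            f"pair {dataset.pair_id!r}: nonpositive abundances; "
            "apply filter_zero_sites first"
        )
    return np.log10(dataset.host_abundance), np.log10(dataset.virus_abundance)


def loglog_fit(dataset: AbundancePairDataset) -> PowerLawFit:
    """Fit the log10 virus vs log10 host least-squares line.

    Raises
    ------
    DegenerateFitError
        If n < 2, any abundance is nonpositive, or the host values are all
        identical (slope undefined).  A constant virus vector is *not* an
        error: the least-squares solution is the flat line (alpha_hat 0)
        and the correlations are reported as NaN.
    """
    x, y = log_xy(dataset)
    n = x.size
    if n < 2:
        raise DegenerateFitError(f"pair {dataset.pair_id!r}: need >= 2 sites, got {n}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DegenerateFitError(
            f"pair {dataset.pair_id!r}: host abundances all identical"
        )
    yc = y - y.mean()
    alpha = float(xc @ y) / sxx
    intercept = float(y.mean() - alpha * x.mean())
    syy = float(yc @ yc)
    if syy == 0.0:
        r = float("nan")
        rho = float("nan")
    else:
        r = float(xc @ yc) / np.sqrt(sxx * syy)
        rho = float(stats.spearmanr(x, y).statistic)
    return PowerLawFit(
        pair_id=dataset.pair_id,
        alpha_hat=alpha,
        intercept_hat=intercept,
        beta_hat=_ratio_slope(x, y, sxx, xc),
        r=r,
        rho=rho,
        theil_sen=theil_sen_slope(dataset),
        n=int(n),
    )


def ratio_fit(dataset: AbundancePairDataset) -> PowerLawFit:
    """Fit log10(virus/host) on log10(host).

    Returned as the same :class:`PowerLawFit` record as :func:`loglog_fit`
    (the two are linked by ``beta_hat = alpha_hat - 1``); provided as a
    named operation because the ratio regression is the diagnostic of
    interest when checking for spurious self-correlation.
    """
    return loglog_fit(dataset)


def _ratio_slope(x: np.ndarray, y: np.ndarray, sxx: float, xc: np.ndarray) -> float:
    # regress (y - x) on x directly rather than relying on the identity,
    # so the beta = alpha - 1 property is a genuine check elsewhere
    z = y - x
    return float(xc @ z) / sxx


def theil_sen_slope(dataset: AbundancePairDataset) -> float:
    """Median pairwise slope of log10(virus) vs log10(host).

    Pairs of points with identical host values are skipped; if every pair
    is skipped the slope is undefined and a :class:`DegenerateFitError` is
    raised.  For the modest site counts of cross-site abundance tables the
    O(n^2) enumeration is exact and cheap.
    """
    x, y = log_xy(dataset)
    if x.size < 2:
        raise DegenerateFitError(
            f"pair {dataset.pair_id!r}: need >= 2 sites, got {x.size}"
        )
    i, j = np.triu_indices(x.size, k=1)
    dx = x[j] - x[i]
    keep = dx != 0
    if not keep.any():
        raise DegenerateFitError(
            f"pair {dataset.pair_id!r}: host abundances all identical"
        )
    return float(np.median((y[j] - y[i])[keep] / dx[keep]))
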