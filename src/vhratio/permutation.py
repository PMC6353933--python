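"""Permutation null distributions, two-tailed p-values and randomized CIs.

For each virus-host pair the null hypothesis is "virus abundance carries no
information about host abundance".  It is simulated directly: the virus
abundance vector is permuted uniformly at random (without replacement)
while the host vector stays fixed, and the statistic of interest — the
log-log least-squares slope, Pearson r, Spearman rho, or the Theil-Sen
slope — is recomputed on each permuted sample.  The resulting empirical
null is centred at 0, and the two-tailed p-value is the add-one exceedance
probability

    p = (1 + #{ |null| >= |observed| }) / (1 + n_perm),

which is never exactly 0 under finite resampling.  The 2.5/50/97.5
percentiles of the null (linear-interpolation definition, numpy's default)
form the 95% randomized confidence interval used in the violin summaries.

Slope and Pearson-r permutation tests are equivalent (slope = r * sd_y/sd_x
with both standard deviations permutation-invariant), so they share one
rejection set; both are offered for reporting convenience.

The Monte-Carlo machinery is vectorized via closed forms: with x fixed,
the permuted slope is dot(x - mean(x), y_perm) / sum((x - mean(x))^2), and
correlations reduce to the same dot product with invariant denominators.
An exhaustive n!-enumeration oracle is provided for small n.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import AbundancePairDataset
from .errors import ConfigurationError, DegenerateFitError
from .regression import StatisticKind, log_xy

DEFAULT_N_PERM = 10_000
EXHAUSTIVE_MAX_N = 8


@dataclass(frozen=True)
class PermutationResult:
    """One pair's permutation test: observed statistic, null, p, CI."""

    pair_id: str
    statistic_kind: StatisticKind
    observed: float
    null_values: np.ndarray
    n_perm: int
    p_two_tailed: float
    ci_low: float
    ci_median: float
    ci_high: float
    seed: int
    n: int
    significant_at: dict[float, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "null_values", np.asarray(self.null_values, dtype=float)
        )


def pair_seed_sequence(seed: int, pair_id: str) -> np.random.SeedSequence:
    """Per-pair RNG substream from (master seed, stable pair_id hash).

    crc32 keys the substream so a pair's null does not depend on which
    other pairs are in the run.
    """
    return np.random.SeedSequence((int(seed), zlib.crc32(pair_id.encode("utf-8"))))


def permutation_test(
    dataset: AbundancePairDataset,
    statistic_kind: StatisticKind | str = StatisticKind.PM_SLOPE,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> PermutationResult:
    """Two-tailed randomized permutation test for one pair.

    Permutes the virus abundances uniformly (independent shuffles, not
    guaranteed distinct) with the host abundances held fixed, recomputing
    ``statistic_kind`` each time.

    Raises
    ------
    DegenerateFitError
        If the statistic is undefined on the data: fewer than 2 sites,
        constant host abundances, or constant virus abundances for the
        correlation statistics.
    ConfigurationError
        If ``n_perm < 1``.
    """
    kind = StatisticKind(statistic_kind)
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be >= 1; got {n_perm}")
    x, y = _checked_log_xy(dataset, kind)
    rng = np.random.default_rng(pair_seed_sequence(seed, dataset.pair_id))
    y_perm = rng.permuted(np.broadcast_to(y, (n_perm, y.size)).copy(), axis=1)
    observed = _statistic(x, y[None, :], kind)[0]
    null_values = _statistic(x, y_perm, kind)
    return _summarize(dataset, kind, observed, null_values, n_perm, seed)


def exhaustive_null(
    dataset: AbundancePairDataset,
    statistic_kind: StatisticKind | str = StatisticKind.PM_SLOPE,
) -> np.ndarray:
    """Statistic over all n! permutations of the virus vector (oracle).

    Only for n <= 8; beyond that the enumeration is deliberately refused.
    """
    kind = StatisticKind(statistic_kind)
    x, y = _checked_log_xy(dataset, kind)
    if x.size > EXHAUSTIVE_MAX_N:
        raise ConfigurationError(
            f"exhaustive enumeration limited to n <= {EXHAUSTIVE_MAX_N}; "
            f"got n = {x.size}"
        )
    perms = np.array(list(itertools.permutations(y)), dtype=float)
    return _statistic(x, perms, kind)


def exact_p_two_tailed(observed: float, null_values: np.ndarray) -> float:
    """Exact two-tailed p from a complete enumeration (no add-one term)."""
    null_values = np.asarray(null_values, dtype=float)
    return float(np.mean(np.abs(null_values) >= abs(observed) - 1e-12))


def randomized_ci(
    null_values: np.ndarray, lower: float = 2.5, upper: float = 97.5
) -> tuple[float, float, float]:
    """(lower, median, upper) percentiles of the null, linear interpolation."""
    if not 0 < lower < upper < 100:
        raise ConfigurationError(
            f"percentile bounds must satisfy 0 < lower < upper < 100; "
            f"got ({lower}, {upper})"
        )
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ConfigurationError("null_values is empty")
    lo, med, hi = np.percentile(null_values, [lower, 50.0, upper])
    return float(lo), float(med), float(hi)


def _summarize(
    dataset: AbundancePairDataset,
    kind: StatisticKind,
    observed: float,
    null_values: np.ndarray,
    n_perm: int,
    seed: int,
) -> PermutationResult:
    # null draws that tie the observed value (e.g. the identity permutation)
    # must count as exceedances; a relative tolerance absorbs the 1-ulp
    # differences that different BLAS summation orders can introduce
    threshold = abs(observed) * (1.0 - 1e-12) - 1e-300
    exceed = int(np.sum(np.abs(null_values) >= threshold))
    p = (1 + exceed) / (1 + n_perm)
    lo, med, hi = randomized_ci(null_values)
    return PermutationResult(
        pair_id=dataset.pair_id,
        statistic_kind=kind,
        observed=float(observed),
        null_values=null_values,
        n_perm=int(n_perm),
        p_two_tailed=float(p),
        ci_low=lo,
        ci_median=med,
        ci_high=hi,
        seed=int(seed),
        n=int(dataset.n_sites),
    )


def _checked_log_xy(
    dataset: AbundancePairDataset, kind: StatisticKind
) -> tuple[np.ndarray, np.ndarray]:
    x, y = log_xy(dataset)
    if x.size < 2:
        raise DegenerateFitError(
            f"pair {dataset.pair_id!r}: need >= 2 sites, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateFitError(
            f"pair {dataset.pair_id!r}: host abundances all identical"
        )
    needs_y_var = kind in (StatisticKind.PEARSON_R, StatisticKind.SPEARMAN_RHO)
    if needs_y_var and np.ptp(y) == 0:
        raise DegenerateFitError(
            f"pair {dataset.pair_id!r}: virus abundances all identical; "
            f"{kind.value} undefined"
        )
    return x, y


def _statistic(x: np.ndarray, y_rows: np.ndarray, kind: StatisticKind) -> np.ndarray:
    """Evaluate the statistic for each row of ``y_rows`` against fixed x."""
    if kind is StatisticKind.SPEARMAN_RHO:
        # ranks are permutation-equivariant: ranking after permuting equals
        # permuting the ranks, so rank each row and correlate with rank(x)
        x = stats.rankdata(x)
        y_rows = stats.rankdata(y_rows, axis=1)
        kind = StatisticKind.PEARSON_R
    if kind is StatisticKind.THEIL_SEN_SLOPE:
        return _theil_sen_rows(x, y_rows)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    num = y_rows @ xc
    if kind is StatisticKind.PM_SLOPE:
        return num / sxx
    # Pearson r; row variance of y is permutation-invariant so computing it
    # per row is exact for permuted rows and general rows alike
    yc = y_rows - y_rows.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", yc, yc)
    with np.errstate(invalid="ignore"):
        return num / np.sqrt(sxx * syy)


def _theil_sen_rows(x: np.ndarray, y_rows: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(x.size, k=1)
    dx = x[j] - x[i]
    keep = dx != 0
    if not keep.any():
        raise DegenerateFitError("host abundances all identical")
    slopes = (y_rows[:, j[keep]] - y_rows[:, i[keep]]) / dx[keep]
    return np.median(slopes, axis=1)
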