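"""Synthetic virus-host abundance collections with known power-law coupling.

The generator emulates the structure of cross-site metagenomic abundance
tables: for each pair, host log10-abundances are drawn i.i.d. Normal (so
abundances are lognormal, the standard null for abundance data), and virus
log10-abundances follow the power law

    log10 y = alpha * log10 x + intercept + e,    e ~ Normal(0, noise_sd)

so ``alpha`` is the ground-truth log-log slope.  Optional zero-inflation
masks each abundance to 0 independently with probability ``zero_rate``,
emulating detection limits and exercising the zero-site filter.

Reproducibility: one master seed; each pair gets an independent substream
derived from ``(seed, pair index)`` via :class:`numpy.random.SeedSequence`,
so a collection is bitwise reproducible and per-pair draws do not shift
when other pairs are added or removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import AbundancePairDataset
from .errors import ConfigurationError


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic abundance generator.

    Attributes
    ----------
    alpha : float
        True power-law exponent (slope of log10 virus vs log10 host).
    intercept : float
        Offset of log10 virus abundance, in log10 units.
    n_sites : int
        Sampling sites per pair; 39 mirrors the cross-site marine tables
        this generator emulates.
    host_log_mean, host_log_sd : float
        Mean and s.d. of host log10-abundance across sites.
    noise_sd : float
        S.d. of the lognormal noise on virus abundance (log10 scale).
    zero_rate : float
        Per-site probability, in [0, 1), that each of the host and virus
        abundances is independently zeroed.
    n_pairs : int
        Number of pairs in a collection.
    seed : int
        Master seed for all randomness.
    level : str
        Taxonomic level stamped on generated pairs.
    """

    alpha: float = 0.0
    intercept: float = 0.0
    n_sites: int = 39
    host_log_mean: float = -3.0
    host_log_sd: float = 1.0
    noise_sd: float = 0.5
    zero_rate: float = 0.0
    n_pairs: int = 1
    seed: int = 0
    level: str = "genus"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError(f"n_sites must be >= 1; got {self.n_sites}")
        if self.host_log_sd <= 0:
            raise ConfigurationError(
                f"host_log_sd must be > 0; got {self.host_log_sd}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0; got {self.noise_sd}")
        if not 0.0 <= self.zero_rate < 1.0:
            raise ConfigurationError(
                f"zero_rate must be in [0, 1); got {self.zero_rate}"
            )
        if self.n_pairs < 1:
            raise ConfigurationError(f"n_pairs must be >= 1; got {self.n_pairs}")


def generate_pair(
    config: SyntheticConfig, pair_id: str, pair_index: int = 0
) -> AbundancePairDataset:
    """Generate one pair's abundances under the configured power law.

    ``pair_index`` selects the pair's RNG substream; pairs generated with
    the same ``(seed, pair_index)`` are identical regardless of what else
    was generated.
    """
    rng = _pair_rng(config.seed, pair_index)
    log_host = rng.normal(config.host_log_mean, config.host_log_sd, config.n_sites)
    noise = rng.normal(0.0, config.noise_sd, config.n_sites) if config.noise_sd > 0 else 0.0
    log_virus = config.alpha * log_host + config.intercept + noise
    host = np.power(10.0, log_host)
    virus = np.power(10.0, log_virus)
    if config.zero_rate > 0:
        host = np.where(rng.random(config.n_sites) < config.zero_rate, 0.0, host)
        virus = np.where(rng.random(config.n_sites) < config.zero_rate, 0.0, virus)
    return AbundancePairDataset(
        pair_id=pair_id,
        level=config.level,
        site_ids=tuple(f"site_{i:03d}" for i in range(config.n_sites)),
        host_abundance=host,
        virus_abundance=virus,
    )


def generate_collection(
    config: SyntheticConfig,
    alphas: Sequence[float] | None = None,
    pair_prefix: str = "pair",
) -> tuple[list[AbundancePairDataset], pd.DataFrame]:
    """Generate ``n_pairs`` datasets plus a ground-truth table.

    Parameters
    ----------
    config
        Generator settings; ``config.alpha`` is used for every pair unless
        ``alphas`` overrides it.
    alphas
        Optional per-pair exponents (length ``n_pairs``).

    Returns
    -------
    (datasets, truth)
        The truth table records ``pair_id, level, true_alpha`` and
        ``true_beta = true_alpha - 1`` (the implied ratio-vs-host slope).
    """
    if alphas is None:
        alphas = [config.alpha] * config.n_pairs
    if len(alphas) != config.n_pairs:
        raise ConfigurationError(
            f"need {config.n_pairs} alphas, got {len(alphas)}"
        )
    datasets = []
    rows = []
    width = max(3, len(str(config.n_pairs - 1)))
    for i, a in enumerate(alphas):
        pair_id = f"{pair_prefix}_{i:0{width}d}"
        datasets.append(generate_pair(replace(config, alpha=float(a)), pair_id, i))
        rows.append(
            {
                "pair_id": pair_id,
                "level": config.level,
                "true_alpha": float(a),
                "true_beta": float(a) - 1.0,
            }
        )
    return datasets, pd.DataFrame(rows)


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _pair_rng(seed: int, pair_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(pair_index))))
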