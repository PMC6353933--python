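"""Spurious self-correlation of ratios: the -1 null slope, quantified.

Regressing a ratio y/x on its own denominator x manufactures correlation:
if y is statistically independent of x, the log-log fit of y/x vs x is the
fit of 1/x vs x plus noise, so its expected slope is -1, not 0.  A cloud
of ratio-vs-denominator slopes near -1 is therefore exactly what no
relationship looks like, and is not evidence that y rises sublinearly
with x.  This module runs that null experiment on synthetic data with a
known exponent of 0 and summarizes the distribution of fitted ratio
slopes, plus the figure-style overlays used to eyeball it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .permutation import PermutationResult
from .regression import PowerLawFit, ratio_fit
from .simulate import SyntheticConfig, generate_pair


@dataclass(frozen=True)
class SpuriousSlopeSummary:
    """Replicate moments of the fitted ratio slope under independence."""

    n_replicates: int
    n_sites: int
    mean_beta_hat: float
    sd_beta_hat: float
    mean_alpha_hat: float
    config: SyntheticConfig

    @property
    def se_mean_beta_hat(self) -> float:
        """Monte-Carlo standard error of the replicate mean."""
        return self.sd_beta_hat / np.sqrt(self.n_replicates)


def null_ratio_slope_experiment(
    n_replicates: int, config: SyntheticConfig, seed: int | None = None
) -> SpuriousSlopeSummary:
    """Fit ratio-vs-host slopes on replicates where virus is independent of host.

    Requires ``config.alpha == 0`` — the experiment *is* the null — and
    returns the mean and s.d. of the fitted beta across replicates, which
    should bracket -1.

    Parameters
    ----------
    n_replicates
        Number of independently generated pairs.
    config
        Generator settings with ``alpha = 0``; ``config.seed`` is used
        unless ``seed`` overrides it.
    """
    if config.alpha != 0:
        raise ConfigurationError(
            "null_ratio_slope_experiment requires alpha = 0 "
            f"(got alpha = {config.alpha}); independence is the null"
        )
    if n_replicates < 1:
        raise ConfigurationError(f"n_replicates must be >= 1; got {n_replicates}")
    if seed is not None:
        config = replace(config, seed=seed)
    betas = np.empty(n_replicates)
    alphas = np.empty(n_replicates)
    for i in range(n_replicates):
        fit = ratio_fit(generate_pair(config, f"null_{i:04d}", i))
        betas[i] = fit.beta_hat
        alphas[i] = fit.alpha_hat
    return SpuriousSlopeSummary(
        n_replicates=n_replicates,
        n_sites=config.n_sites,
        mean_beta_hat=float(betas.mean()),
        sd_beta_hat=float(betas.std(ddof=1)) if n_replicates > 1 else 0.0,
        mean_alpha_hat=float(alphas.mean()),
        config=config,
    )


def guide_line_overlay(
    datasets: Iterable, fits: Sequence[PowerLawFit], out_path: str | Path
):
    """Two-panel scatter: virus vs host, and virus/host ratio vs host.

    Left panel: log10 virus abundance vs log10 host abundance per pair.
    Right panel: log10 ratio vs log10 host abundance with a slope -1
    reference line — the signature of spurious self-correlation under
    independence.  Returns the matplotlib figure (also saved to
    ``out_path``); a no-op with a warning if there is nothing to plot.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    datasets = list(datasets)
    if not datasets:
        import warnings

        warnings.warn("no datasets to plot; skipping overlay figure")
        return None
    fig, (ax_direct, ax_ratio) = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    all_x = []
    for d in datasets:
        keep = (d.host_abundance > 0) & (d.virus_abundance > 0)
        x = np.log10(d.host_abundance[keep])
        y = np.log10(d.virus_abundance[keep])
        all_x.append(x)
        ax_direct.plot(x, y, "o", ms=3, alpha=0.4)
        ax_ratio.plot(x, y - x, "o", ms=3, alpha=0.4)
    xs = np.concatenate(all_x)
    grid = np.array([xs.min(), xs.max()])
    # anchor the -1 guide at the data's median (log host, log ratio) point
    anchor = np.median(np.concatenate(
        [np.log10(d.virus_abundance[(d.host_abundance > 0) & (d.virus_abundance > 0)])
         - np.log10(d.host_abundance[(d.host_abundance > 0) & (d.virus_abundance > 0)])
         for d in datasets]
    ))
    ax_ratio.plot(grid, anchor + np.median(xs) - grid, "k--", lw=1.5,
                  label="slope −1 guide")
    ax_ratio.legend(frameon=False)
    ax_direct.set_xlabel("log$_{10}$ host abundance")
    ax_direct.set_ylabel("log$_{10}$ virus abundance")
    ax_ratio.set_xlabel("log$_{10}$ host abundance")
    ax_ratio.set_ylabel("log$_{10}$ virus:host ratio")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return fig


def violin_null_plot(
    results: Sequence[PermutationResult],
    out_path: str | Path,
    alpha_level: float = 0.05,
):
    """Violin plot of each pair's permutation null with its observed slope.

    Violins show the null distribution of the statistic; dark bars mark the
    2.5/50/97.5 percentiles (the 95% randomized CI) and a red dashed line
    marks the observed value.  Pairs with p < ``alpha_level`` are drawn in
    blue, the rest in gray.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = list(results)
    if not results:
        import warnings

        warnings.warn("no permutation results to plot")
        return None
    fig, ax = plt.subplots(figsize=(max(4.0, 0.5 * len(results)), 4))
    positions = np.arange(1, len(results) + 1)
    parts = ax.violinplot(
        [r.null_values for r in results], positions=positions, showextrema=False
    )
    for body, res in zip(parts["bodies"], results):
        body.set_facecolor(
            "tab:blue" if res.p_two_tailed < alpha_level else "lightgray"
        )
        body.set_alpha(0.8)
    for pos, res in zip(positions, results):
        for q in (res.ci_low, res.ci_median, res.ci_high):
            ax.hlines(q, pos - 0.18, pos + 0.18, color="black", lw=1.2)
        ax.hlines(res.observed, pos - 0.3, pos + 0.3, color="red",
                  linestyles="dashed", lw=1.2)
    ax.set_xticks(positions)
    ax.set_xticklabels(
        [f"{r.pair_id}\n({r.n})" for r in results], rotation=90, fontsize=7
    )
    ax.set_ylabel(results[0].statistic_kind.value)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return fig
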