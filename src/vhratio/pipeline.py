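"""End-to-end study pipeline: filter -> fit -> permute -> correct -> plot.

``run_study`` orchestrates the per-pair operations without adding any
computation of its own, so the pipeline's per-pair numbers equal what the
module functions return when called directly.  Pairs that survive the
zero-site and minimum-site filters are tested; pairs that do not, or whose
statistic is degenerate post-filter, appear in the outputs with an explicit
status rather than vanishing, so the number tested is auditable against
the input pair count.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .datasets import (
    DEFAULT_MIN_SITES,
    AbundancePairDataset,
    filter_zero_sites,
    read_abundance_table,
    write_abundance_table,
    write_filter_reports,
)
from .errors import ConfigurationError, DegenerateFitError
from .multitest import DEFAULT_LEVELS, StudyReport, tally_significance, write_report
from .permutation import DEFAULT_N_PERM, permutation_test
from .regression import StatisticKind, loglog_fit
from .spurious import guide_line_overlay, violin_null_plot

log = logging.getLogger("vhratio")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one full study run (YAML-serializable)."""

    table: str | None = None
    manifest: str | None = None
    min_sites: int = DEFAULT_MIN_SITES
    n_perm: int = DEFAULT_N_PERM
    statistic_kind: StatisticKind = StatisticKind.PM_SLOPE
    family_alpha: float = 0.05
    significance_levels: tuple[float, ...] = DEFAULT_LEVELS
    seed: int = 0
    out_dir: str = "vhratio_out"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigurationError(f"n_perm must be >= 1; got {self.n_perm}")
        object.__setattr__(
            self, "statistic_kind", StatisticKind(self.statistic_kind)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "significance_levels" in raw:
            raw["significance_levels"] = tuple(raw["significance_levels"])
        return cls(**raw)


def run_study(
    config: PipelineConfig,
    datasets: Sequence[AbundancePairDataset] | None = None,
) -> StudyReport:
    """Run the whole pipeline and write all artifacts under ``config.out_dir``.

    ``datasets`` may be supplied directly (e.g. synthetic collections);
    otherwise ``config.table``/``config.manifest`` are read.

    Outputs: filtered abundance TSV, filter-report TSV, fits TSV,
    permutation TSV, per-pair report and summary TSV, figures, and a run
    manifest (seed, n_perm, version, input checksums).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if datasets is None:
        if config.table is None or config.manifest is None:
            raise ConfigurationError("need either datasets or table+manifest paths")
        datasets = read_abundance_table(config.table, config.manifest)
    log.info("loaded %d pairs", len(datasets))

    filtered, reports = [], []
    statuses: dict[str, str] = {}
    for d in datasets:
        fd, rep = filter_zero_sites(d, config.min_sites)
        reports.append(rep)
        if rep.retained:
            filtered.append(fd)
            statuses[d.pair_id] = "tested"
        else:
            statuses[d.pair_id] = "excluded_min_sites"
    write_filter_reports(reports, out_dir / "filter_report.tsv")
    write_abundance_table(filtered, out_dir / "filtered_table.tsv")
    log.info("%d pairs pass filters", len(filtered))

    fits, results, fit_rows = {}, [], []
    tested = []
    for d in filtered:
        try:
            fit = loglog_fit(d)
            res = permutation_test(
                d, config.statistic_kind, config.n_perm, config.seed
            )
        except DegenerateFitError as err:
            log.warning("pair %s untestable: %s", d.pair_id, err)
            statuses[d.pair_id] = "degenerate"
            continue
        fits[d.pair_id] = fit
        results.append(res)
        tested.append(d)
        fit_rows.append(
            {
                "pair_id": d.pair_id,
                "level": d.level,
                "n": fit.n,
                "alpha_hat": fit.alpha_hat,
                "intercept_hat": fit.intercept_hat,
                "beta_hat": fit.beta_hat,
                "r": fit.r,
                "rho": fit.rho,
                "theil_sen": fit.theil_sen,
            }
        )
    pd.DataFrame(fit_rows).to_csv(out_dir / "fits.tsv", sep="\t", index=False)

    report = tally_significance(
        results,
        {d.pair_id: d.level for d in datasets},
        fits=fits,
        levels=config.significance_levels,
        family_alpha=config.family_alpha,
    )
    # carry untested pairs into the per-pair table with a status column
    per_pair = report.per_pair.copy()
    if not per_pair.empty:
        per_pair["status"] = [statuses[p] for p in per_pair["pair_id"]]
    untested = [
        {"pair_id": pid, "status": status}
        for pid, status in statuses.items()
        if status != "tested"
    ]
    if untested:
        per_pair = pd.concat(
            [per_pair, pd.DataFrame(untested)], ignore_index=True
        )
    report = StudyReport(
        per_pair=per_pair,
        m_comparisons=report.m_comparisons,
        family_alpha=report.family_alpha,
        bonferroni=report.bonferroni,
        counts=report.counts,
    )
    write_report(report, out_dir)

    if config.make_plots and tested:
        guide_line_overlay(tested, list(fits.values()), out_dir / "fig_overlay.png")
        violin_null_plot(results, out_dir / "fig_violins.png")

    _write_run_manifest(config, out_dir)
    return report


def _write_run_manifest(config: PipelineConfig, out_dir: Path) -> None:
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "statistic_kind": config.statistic_kind.value,
        "min_sites": config.min_sites,
        "family_alpha": config.family_alpha,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "input_checksums": {
            name: _sha256(path)
            for name, path in (("table", config.table), ("manifest", config.manifest))
            if path is not None and Path(path).exists()
        },
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
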