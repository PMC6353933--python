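"""Family-wise error control and significance tallies across pairs.

With m virus-host pairs tested, per-test significance at 0.05 is a
permissive criterion: under the global null about 0.05*m pairs are
expected to reject by chance.  The strict Bonferroni criterion divides the
family-wise level by the number of comparisons, pooling the genus- and
phylum-level families into one family (m = all tested pairs).  Strict
inequality (p < threshold) decides significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .permutation import PermutationResult
from .regression import PowerLawFit

DEFAULT_LEVELS = (0.05, 0.01)


@dataclass(frozen=True)
class StudyReport:
    """Per-pair significance flags plus family-wise summary counts.

    ``per_pair`` has one row per tested pair with its fit, p-value, CI and
    boolean flags; ``counts`` has one row per taxonomic level with the
    number tested and the number significant at each criterion.
    """

    per_pair: pd.DataFrame
    m_comparisons: int
    family_alpha: float
    bonferroni: float
    counts: pd.DataFrame


def bonferroni_threshold(family_alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni per-comparison threshold family_alpha / m."""
    if m < 1:
        raise ConfigurationError(f"m must be >= 1; got {m}")
    if not 0 < family_alpha < 1:
        raise ConfigurationError(
            f"family_alpha must be in (0, 1); got {family_alpha}"
        )
    return family_alpha / m


def format_threshold(threshold: float, sig_figs: int = 2) -> str:
    """Display form of a threshold, rounded to ``sig_figs`` significant figures.

    E.g. 0.05/64 = 0.00078125 displays as ``"0.00078"``.
    """
    if threshold == 0:
        return "0"
    magnitude = int(np.floor(np.log10(abs(threshold))))
    decimals = max(0, sig_figs - 1 - magnitude)
    return f"{round(threshold, sig_figs - 1 - magnitude):.{decimals}f}"


def tally_significance(
    results: Sequence[PermutationResult],
    pair_levels: Mapping[str, str],
    fits: Mapping[str, PowerLawFit] | None = None,
    levels: Sequence[float] = DEFAULT_LEVELS,
    family_alpha: float = 0.05,
) -> StudyReport:
    """Tally per-pair and per-taxonomic-level significance.

    Parameters
    ----------
    results
        One permutation result per tested pair (duplicates rejected).
    pair_levels
        Map pair_id -> taxonomic level ("genus" / "phylum").
    fits
        Optional pair_id -> PowerLawFit to carry slopes into the report.
    levels
        Per-test significance levels to flag (strict ``p < level``).
    family_alpha
        Family-wise level; the Bonferroni threshold is family_alpha / m
        with m = total pairs tested, genus and phylum pooled.
    """
    ids = [r.pair_id for r in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate pair_id(s): {', '.join(dupes)}")
    m = len(results)
    bonf = bonferroni_threshold(family_alpha, max(m, 1))
    rows = []
    for res in results:
        if res.pair_id not in pair_levels:
            raise ValidationError(f"pair {res.pair_id!r} has no level assigned")
        fit = fits.get(res.pair_id) if fits else None
        row = {
            "pair_id": res.pair_id,
            "level": pair_levels[res.pair_id],
            "n": res.n,
            "statistic_kind": res.statistic_kind.value,
            "observed": res.observed,
            "alpha_hat": fit.alpha_hat if fit else np.nan,
            "beta_hat": fit.beta_hat if fit else np.nan,
            "p_two_tailed": res.p_two_tailed,
            "ci_low": res.ci_low,
            "ci_median": res.ci_median,
            "ci_high": res.ci_high,
        }
        for lv in levels:
            row[_flag_name(lv)] = res.p_two_tailed < lv
        row["significant_bonferroni"] = res.p_two_tailed < bonf
        rows.append(row)
    per_pair = pd.DataFrame(rows)

    count_rows = []
    if m:
        for tax_level, group in per_pair.groupby("level", sort=True):
            entry = {"level": tax_level, "n_tested": len(group)}
            for lv in levels:
                entry[f"n_{_flag_name(lv)}"] = int(group[_flag_name(lv)].sum())
            entry["n_significant_bonferroni"] = int(
                group["significant_bonferroni"].sum()
            )
            entry["bonferroni_threshold"] = bonf
            count_rows.append(entry)
    counts = pd.DataFrame(count_rows)
    return StudyReport(
        per_pair=per_pair,
        m_comparisons=m,
        family_alpha=family_alpha,
        bonferroni=bonf,
        counts=counts,
    )


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write the per-pair and summary tables as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.per_pair.to_csv(out_dir / "report_per_pair.tsv", sep="\t", index=False)
    report.counts.to_csv(out_dir / "report_summary.tsv", sep="\t", index=False)


def _flag_name(level: float) -> str:
    return f"significant_{str(level).replace('0.', '')}"
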