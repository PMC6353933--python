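"""Reading, validating, filtering and partitioning virus-host abundance tables.

The canonical on-disk format is a long-format, UTF-8, tab-separated table
with header columns ``pair_id, site_id, host_abundance, virus_abundance``
(one row per virus-host pair per sampling site), accompanied by a manifest
TSV with columns ``pair_id, level, host_name, virus_name`` assigning each
pair a taxonomic level (``genus`` or ``phylum``).

Abundances are relative-abundance proxies: nonnegative, dimensionless reals.
They are taken as given; no normalization is applied.  Sites where either
member of a pair has zero abundance carry no information about the paired
relationship on log scales, so they are dropped jointly before any fit, and
pairs left with fewer than ``min_sites`` positive sites are excluded from
analysis entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

LEVELS = ("genus", "phylum")

TABLE_COLUMNS = ("pair_id", "site_id", "host_abundance", "virus_abundance")
MANIFEST_COLUMNS = ("pair_id", "level")

#: Minimum number of positive sites for a pair to enter the analysis.
DEFAULT_MIN_SITES = 5


@dataclass(frozen=True)
class AbundancePairDataset:
    """Paired virus and host abundances for one putative pair across sites.

    Attributes
    ----------
    pair_id : str
        Label of the pair, typically the host genus or phylum name.
    level : str
        Taxonomic level of the host assignment, ``"genus"`` or ``"phylum"``.
    site_ids : tuple of str
        Ordered sampling-site labels, unique within the pair.
    host_abundance, virus_abundance : numpy.ndarray
        Nonnegative relative-abundance proxies, one entry per site.
    """

    pair_id: str
    level: str
    site_ids: tuple[str, ...]
    host_abundance: np.ndarray
    virus_abundance: np.ndarray

    def __post_init__(self) -> None:
        host = np.asarray(self.host_abundance, dtype=float)
        virus = np.asarray(self.virus_abundance, dtype=float)
        object.__setattr__(self, "host_abundance", host)
        object.__setattr__(self, "virus_abundance", virus)
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        if self.level not in LEVELS:
            raise ValidationError(
                f"pair {self.pair_id!r}: unknown level {self.level!r}; "
                f"expected one of {LEVELS}"
            )
        n = len(self.site_ids)
        if host.shape != (n,) or virus.shape != (n,):
            raise ValidationError(
                f"pair {self.pair_id!r}: abundance vectors must match the "
                f"{n} site labels (got {host.shape} and {virus.shape})"
            )
        if len(set(self.site_ids)) != n:
            raise ValidationError(f"pair {self.pair_id!r}: duplicate site_id")
        if np.any(host < 0) or np.any(virus < 0):
            raise ValidationError(f"pair {self.pair_id!r}: negative abundance")
        if not (np.all(np.isfinite(host)) and np.all(np.isfinite(virus))):
            raise ValidationError(f"pair {self.pair_id!r}: non-finite abundance")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def all_positive(self) -> bool:
        """True when every site has strictly positive host and virus abundance."""
        return bool(np.all(self.host_abundance > 0) and np.all(self.virus_abundance > 0))


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for the zero-site and minimum-site filters on one pair."""

    pair_id: str
    level: str
    n_sites_raw: int
    n_sites_zero_dropped: int
    n_sites_kept: int
    retained: bool

    def __post_init__(self) -> None:
        if self.n_sites_kept != self.n_sites_raw - self.n_sites_zero_dropped:
            raise ValidationError(
                f"pair {self.pair_id!r}: inconsistent filter counts"
            )


def read_abundance_table(
    path: str | Path, manifest: str | Path
) -> list[AbundancePairDataset]:
    """Read a long-format abundance TSV plus its pairs manifest.

    Parameters
    ----------
    path
        TSV with columns ``pair_id, site_id, host_abundance, virus_abundance``.
    manifest
        TSV with at least ``pair_id, level`` mapping every pair in the table
        to a taxonomic level.

    Returns
    -------
    list of AbundancePairDataset
        One dataset per distinct ``pair_id``, rows in file order.

    Raises
    ------
    FormatError
        If a required column is missing or a value fails to parse.
    ValidationError
        On negative abundances (reported with the offending row number) or
        pairs missing from the manifest.
    """
    table = _read_tsv(path, TABLE_COLUMNS)
    levels = read_manifest(manifest)

    if table.empty:
        return []

    for col in ("host_abundance", "virus_abundance"):
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +2: header + 1-based
            raise FormatError(f"{path}: column {col!r}, row {row}: not a number")
        if values.isna().any():
            row = int(np.flatnonzero(values.isna().to_numpy())[0]) + 2
            raise FormatError(f"{path}: column {col!r}, row {row}: missing value")
        neg = values < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0]) + 2
            raise ValidationError(
                f"{path}: column {col!r}, row {row}: negative abundance"
            )
        # numpy's string parser is correctly rounded (full round-trip);
        # pd.to_numeric above is used only to locate bad values
        table[col] = table[col].astype(float)

    datasets: list[AbundancePairDataset] = []
    for pair_id, group in table.groupby("pair_id", sort=False):
        pid = str(pair_id)
        if pid not in levels:
            raise ValidationError(f"pair {pid!r} present in table but not in manifest")
        datasets.append(
            AbundancePairDataset(
                pair_id=pid,
                level=levels[pid],
                site_ids=tuple(group["site_id"].astype(str)),
                host_abundance=group["host_abundance"].to_numpy(dtype=float),
                virus_abundance=group["virus_abundance"].to_numpy(dtype=float),
            )
        )
    return datasets


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read the pairs manifest, returning the ``pair_id -> level`` map."""
    manifest = _read_tsv(path, MANIFEST_COLUMNS)
    levels: dict[str, str] = {}
    for _, row in manifest.iterrows():
        level = str(row["level"])
        if level not in LEVELS:
            raise ValidationError(
                f"{path}: pair {row['pair_id']!r}: unknown level {level!r}"
            )
        levels[str(row["pair_id"])] = level
    return levels


def write_abundance_table(
    datasets: Iterable[AbundancePairDataset], path: str | Path
) -> None:
    """Write datasets back to the canonical long-format TSV (full precision)."""
    rows = [
        (d.pair_id, s, h, v)
        for d in datasets
        for s, h, v in zip(d.site_ids, d.host_abundance, d.virus_abundance)
    ]
    frame = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_filter_reports(reports: Iterable[FilterReport], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in reports]).to_csv(path, sep="\t", index=False)


def filter_zero_sites(
    dataset: AbundancePairDataset, min_sites: int = DEFAULT_MIN_SITES
) -> tuple[AbundancePairDataset, FilterReport]:
    """Drop sites where either abundance is zero; report the counts.

    Zero abundance in either member makes the pair uninformative at that
    site (log-scale statistics are undefined), so sites are dropped jointly.
    The returned report's ``retained`` flag applies the ``min_sites`` rule.
    """
    keep = (dataset.host_abundance > 0) & (dataset.virus_abundance > 0)
    filtered = replace(
        dataset,
        site_ids=tuple(s for s, k in zip(dataset.site_ids, keep) if k),
        host_abundance=dataset.host_abundance[keep],
        virus_abundance=dataset.virus_abundance[keep],
    )
    report = FilterReport(
        pair_id=dataset.pair_id,
        level=dataset.level,
        n_sites_raw=dataset.n_sites,
        n_sites_zero_dropped=int((~keep).sum()),
        n_sites_kept=filtered.n_sites,
        retained=filtered.n_sites >= _check_min_sites(min_sites),
    )
    return filtered, report


def apply_min_sites(
    dataset: AbundancePairDataset, min_sites: int = DEFAULT_MIN_SITES
) -> FilterReport:
    """Decide retention of an already zero-filtered dataset.

    ``min_sites`` below 2 is rejected: a slope is undefined on fewer than
    two points.
    """
    _check_min_sites(min_sites)
    if not dataset.all_positive():
        raise ValidationError(
            f"pair {dataset.pair_id!r}: apply filter_zero_sites first"
        )
    return FilterReport(
        pair_id=dataset.pair_id,
        level=dataset.level,
        n_sites_raw=dataset.n_sites,
        n_sites_zero_dropped=0,
        n_sites_kept=dataset.n_sites,
        retained=dataset.n_sites >= min_sites,
    )


def partition_by_level(
    datasets: Iterable[AbundancePairDataset],
) -> dict[str, list[AbundancePairDataset]]:
    """Split a collection into its genus-level and phylum-level parts."""
    partitions: dict[str, list[AbundancePairDataset]] = {lv: [] for lv in LEVELS}
    for d in datasets:
        # level validity is enforced at construction; guard anyway
        if d.level not in partitions:
            raise ValidationError(f"pair {d.pair_id!r}: unknown level {d.level!r}")
        partitions[d.level].append(d)
    return partitions


def _check_min_sites(min_sites: int) -> int:
    if min_sites < 2:
        raise ConfigurationError(
            f"min_sites must be >= 2 (a slope needs two points); got {min_sites}"
        )
    return min_sites


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return frame
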