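"""I/O, validation, joint zero-site filtering, and level partitioning."""

import numpy as np
import pytest

from vhratio import (
    ConfigurationError,
    FormatError,
    ValidationError,
    apply_min_sites,
    filter_zero_sites,
    partition_by_level,
    read_abundance_table,
    write_abundance_table,
)
from vhratio.datasets import read_manifest

from conftest import make_dataset


class TestReadAbundanceTable:
    def test_two_pairs_39_sites(self, tsv_tables, rng):
        rows = [
            (pid, f"site{i}", rng.uniform(0.01, 1), rng.uniform(0.01, 1))
            for pid in ("Vibrio", "Cyanobium")
            for i in range(39)
        ]
        table, manifest = tsv_tables(
            rows, [("Vibrio", "genus", "h", "v"), ("Cyanobium", "genus", "h", "v")]
        )
        datasets = read_abundance_table(table, manifest)
        assert [d.pair_id for d in datasets] == ["Vibrio", "Cyanobium"]
        assert all(d.n_sites == 39 for d in datasets)

    def test_empty_table_gives_empty_collection(self, tsv_tables):
        table, manifest = tsv_tables([], [])
        assert read_abundance_table(table, manifest) == []

    def test_negative_abundance_rejected_with_row_number(self, tsv_tables):
        table, manifest = tsv_tables(
            [("p", "s1", 0.5, 0.5), ("p", "s2", -0.1, 0.5)],
            [("p", "genus", "h", "v")],
        )
        with pytest.raises(ValidationError, match="row 3"):
            read_abundance_table(table, manifest)

    def test_missing_column_named_in_error(self, tmp_path, tsv_tables):
        table, manifest = tsv_tables([("p", "s1", 0.5, 0.5)], [("p", "genus", "h", "v")])
        bad = tmp_path / "bad.tsv"
        bad.write_text("pair_id\tsite_id\thost_abundance\np\ts1\t0.5\n")
        with pytest.raises(FormatError, match="virus_abundance"):
            read_abundance_table(bad, manifest)

    def test_pair_absent_from_manifest(self, tsv_tables):
        table, manifest = tsv_tables(
            [("orphan", "s1", 0.5, 0.5)], [("other", "genus", "h", "v")]
        )
        with pytest.raises(ValidationError, match="orphan"):
            read_abundance_table(table, manifest)

    def test_unknown_level_rejected(self, tsv_tables):
        table, manifest = tsv_tables(
            [("p", "s1", 0.5, 0.5)], [("p", "order", "h", "v")]
        )
        with pytest.raises(ValidationError, match="order"):
            read_manifest(manifest)

    def test_non_numeric_abundance_is_format_error(self, tsv_tables):
        table, manifest = tsv_tables(
            [("p", "s1", "abc", 0.5)], [("p", "genus", "h", "v")]
        )
        with pytest.raises(FormatError, match="host_abundance"):
            read_abundance_table(table, manifest)


class TestFilterZeroSites:
    def test_joint_zero_drop_counts(self, rng):
        host = rng.uniform(0.1, 1, 39)
        virus = rng.uniform(0.1, 1, 39)
        virus[:5] = 0.0  # 5 zero-virus sites
        host[5:7] = 0.0  # 2 zero-host sites, disjoint
        d = make_dataset(host, virus)
        filtered, rep = filter_zero_sites(d)
        assert filtered.n_sites == 32
        assert rep.n_sites_raw == 39
        assert rep.n_sites_zero_dropped == 7
        assert rep.n_sites_kept == 32
        assert rep.retained

    def test_all_positive_is_identity(self, rng):
        d = make_dataset(rng.uniform(0.1, 1, 10), rng.uniform(0.1, 1, 10))
        filtered, rep = filter_zero_sites(d)
        assert rep.n_sites_zero_dropped == 0
        np.testing.assert_array_equal(filtered.host_abundance, d.host_abundance)
        np.testing.assert_array_equal(filtered.virus_abundance, d.virus_abundance)
        assert filtered.site_ids == d.site_ids

    def test_all_zero_virus_not_retained(self):
        d = make_dataset([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        filtered, rep = filter_zero_sites(d)
        assert filtered.n_sites == 0
        assert not rep.retained

    def test_idempotent(self, rng):
        host = rng.uniform(0, 1, 30) * (rng.random(30) > 0.2)
        virus = rng.uniform(0, 1, 30) * (rng.random(30) > 0.2)
        once, rep1 = filter_zero_sites(make_dataset(host, virus))
        twice, rep2 = filter_zero_sites(once)
        np.testing.assert_array_equal(once.host_abundance, twice.host_abundance)
        np.testing.assert_array_equal(once.virus_abundance, twice.virus_abundance)
        assert rep2.n_sites_zero_dropped == 0

    def test_kept_values_bitwise_identical_and_ordered(self, rng):
        host = rng.uniform(0, 1, 20)
        virus = rng.uniform(0, 1, 20)
        virus[[3, 7, 11]] = 0.0
        d = make_dataset(host, virus)
        filtered, _ = filter_zero_sites(d)
        keep = (host > 0) & (virus > 0)
        np.testing.assert_array_equal(filtered.host_abundance, host[keep])
        np.testing.assert_array_equal(filtered.virus_abundance, virus[keep])


class TestMinSites:
    @pytest.mark.parametrize(
        "n, retained", [(5, True), (4, False), (39, True)]
    )
    def test_threshold(self, rng, n, retained):
        d = make_dataset(rng.uniform(0.1, 1, n), rng.uniform(0.1, 1, n))
        assert apply_min_sites(d, min_sites=5).retained is retained

    def test_min_sites_floor(self, rng):
        d = make_dataset(rng.uniform(0.1, 1, 5), rng.uniform(0.1, 1, 5))
        with pytest.raises(ConfigurationError):
            apply_min_sites(d, min_sites=1)

    def test_requires_prefiltered_data(self):
        d = make_dataset([1.0, 0.0, 2.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            apply_min_sites(d)


class TestPartitionByLevel:
    def test_counts_preserved(self, rng):
        datasets = [
            make_dataset(rng.uniform(0.1, 1, 5), rng.uniform(0.1, 1, 5),
                         pair_id=f"g{i}", level="genus")
            for i in range(93)
        ] + [
            make_dataset(rng.uniform(0.1, 1, 5), rng.uniform(0.1, 1, 5),
                         pair_id=f"p{i}", level="phylum")
            for i in range(17)
        ]
        parts = partition_by_level(datasets)
        assert len(parts["genus"]) == 93
        assert len(parts["phylum"]) == 17

    def test_single_level_input(self, rng):
        datasets = [
            make_dataset(rng.uniform(0.1, 1, 5), rng.uniform(0.1, 1, 5),
                         pair_id="only", level="phylum")
        ]
        parts = partition_by_level(datasets)
        assert len(parts["phylum"]) == 1
        assert parts["genus"] == []

    def test_unknown_level_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            make_dataset([1.0], [1.0], level="order")


class TestRoundTrip:
    def test_write_read_full_precision(self, tmp_path, tsv_tables, rng):
        datasets = [
            make_dataset(rng.uniform(0.001, 1, 8), rng.uniform(0.001, 1, 8),
                         pair_id=f"pair{i}")
            for i in range(3)
        ]
        table = tmp_path / "roundtrip.tsv"
        write_abundance_table(datasets, table)
        _, manifest = tsv_tables([], [(f"pair{i}", "genus", "h", "v") for i in range(3)])
        back = read_abundance_table(table, manifest)
        assert len(back) == 3
        for orig, re_read in zip(datasets, back):
            np.testing.assert_array_equal(orig.host_abundance, re_read.host_abundance)
            np.testing.assert_array_equal(orig.virus_abundance, re_read.virus_abundance)
            assert orig.site_ids == re_read.site_ids

    def test_filter_count_conservation(self, rng):
        total_raw = 0
        total_accounted = 0
        for i in range(10):
            host = rng.uniform(0, 1, 15) * (rng.random(15) > 0.3)
            virus = rng.uniform(0, 1, 15) * (rng.random(15) > 0.3)
            _, rep = filter_zero_sites(make_dataset(host, virus, pair_id=f"p{i}"))
            total_raw += 15
            total_accounted += rep.n_sites_kept + rep.n_sites_zero_dropped
        assert total_accounted == total_raw
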