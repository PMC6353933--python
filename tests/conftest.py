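import numpy as np
import pytest

from vhratio import AbundancePairDataset


def make_dataset(host, virus, pair_id="pair", level="genus"):
    host = np.asarray(host, dtype=float)
    return AbundancePairDataset(
        pair_id=pair_id,
        level=level,
        site_ids=tuple(f"s{i}" for i in range(len(host))),
        host_abundance=host,
        virus_abundance=np.asarray(virus, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def random_dataset_factory(rng):
    """Datasets with lognormal abundances and arbitrary coupling."""

    def factory(n=10, pair_id="rand"):
        logx = rng.normal(-3, 1, n)
        logy = rng.uniform(-1.5, 1.5) * logx + rng.normal(0, 0.5, n)
        return make_dataset(10.0**logx, 10.0**logy, pair_id=pair_id)

    return factory


@pytest.fixture
def tsv_tables(tmp_path):
    """Write a small canonical table + manifest to disk; return the paths."""

    def writer(rows, manifest_rows, table_name="table.tsv", manifest_name="manifest.tsv"):
        table = tmp_path / table_name
        manifest = tmp_path / manifest_name
        with open(table, "w") as fh:
            fh.write("pair_id\tsite_id\thost_abundance\tvirus_abundance\n")
            for r in rows:
                fh.write("\t".join(str(v) for v in r) + "\n")
        with open(manifest, "w") as fh:
            fh.write("pair_id\tlevel\thost_name\tvirus_name\n")
            for r in manifest_rows:
                fh.write("\t".join(str(v) for v in r) + "\n")
        return table, manifest

    return writer
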