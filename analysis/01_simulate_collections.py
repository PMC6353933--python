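"""Generate the two synthetic study collections used by the later steps.

Null collection: 64 virus-host pairs (48 genus + 16 phylum) with exponent
alpha = 0 — virus abundances carry no information about host abundances.
This mirrors the size of the re-analysis family (64 total comparisons) and
is the regime where ratio-vs-host regressions are expected to slope -1
spuriously.

Coupled collection: 64 pairs with alpha drawn evenly from [0, 1.5], with
zero-inflation so the filtering rules have work to do; the truth table
records each pair's generating exponent.

Outputs (results/synthetic/): table + manifest + truth TSVs per collection.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vhratio import SyntheticConfig, generate_collection, write_abundance_table
from vhratio.simulate import write_truth_table

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20260101


def write_collection(name, datasets, truth):
    out = OUT / name
    out.mkdir(parents=True, exist_ok=True)
    write_abundance_table(datasets, out / "table.tsv")
    pd.DataFrame(
        {
            "pair_id": [d.pair_id for d in datasets],
            "level": [d.level for d in datasets],
            "host_name": [d.pair_id for d in datasets],
            "virus_name": [f"{d.pair_id}_virus" for d in datasets],
        }
    ).to_csv(out / "manifest.tsv", sep="\t", index=False)
    write_truth_table(truth, out / "truth.tsv")
    print(f"{name}: {len(datasets)} pairs -> {out}")


def main():
    # 48 genus + 16 phylum null pairs, independent virus and host
    genus_null, truth_g = generate_collection(
        SyntheticConfig(alpha=0.0, n_pairs=48, noise_sd=0.5, seed=SEED,
                        level="genus"),
        pair_prefix="genus",
    )
    phylum_null, truth_p = generate_collection(
        SyntheticConfig(alpha=0.0, n_pairs=16, noise_sd=0.5, seed=SEED + 1,
                        level="phylum"),
        pair_prefix="phylum",
    )
    write_collection(
        "null64", genus_null + phylum_null,
        pd.concat([truth_g, truth_p], ignore_index=True),
    )

    # coupled pairs spanning sub- to super-linear exponents, with zeros
    rng = np.random.default_rng(SEED + 2)
    alphas = np.round(np.linspace(0.0, 1.5, 64), 3)
    coupled, truth_c = generate_collection(
        SyntheticConfig(n_pairs=64, noise_sd=0.5, zero_rate=0.1,
                        seed=SEED + 3, level="genus"),
        alphas=alphas,
        pair_prefix="coupled",
    )
    write_collection("coupled64", coupled, truth_c)


if __name__ == "__main__":
    main()
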