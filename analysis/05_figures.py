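"""Figure panels for the null collection.

Overlay: log10 virus vs log10 host (no trend under independence) next to
log10 ratio vs log10 host with the -1 guide line the points hug.

Violins: each pair's permutation null of the slope with 2.5/50/97.5
percentile bars; the observed slope in red dashed; blue violins mark pairs
with p < 0.05 (about 3 of 64 expected by chance on null data).

Output: results/figures/*.png.
"""

from pathlib import Path

from vhratio import (
    filter_zero_sites,
    guide_line_overlay,
    loglog_fit,
    permutation_test,
    read_abundance_table,
    violin_null_plot,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260101


def main():
    src = ROOT / "synthetic" / "null64"
    out = ROOT / "figures"
    out.mkdir(parents=True, exist_ok=True)
    datasets = [
        fd
        for d in read_abundance_table(src / "table.tsv", src / "manifest.tsv")
        for fd, rep in [filter_zero_sites(d)]
        if rep.retained
    ]
    fits = [loglog_fit(d) for d in datasets]
    guide_line_overlay(datasets, fits, out / "null64_overlay.png")
    # violins on a readable subset: the first 16 pairs
    results = [
        permutation_test(d, "pm_slope", n_perm=10_000, seed=SEED)
        for d in datasets[:16]
    ]
    violin_null_plot(results, out / "null64_violins.png")
    print(f"figures written to {out}")


if __name__ == "__main__":
    main()
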