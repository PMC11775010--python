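"""Core microbiota and alpha diversity.

Closes the abundance table to relative frequencies, selects the ten most
abundant genera, and summarises group-mean core compositions (by disease
group, delivery mode, and their combination) plus per-sample Shannon,
Simpson and inverse-Simpson indices with median (IQR) group summaries.
"""

import argparse
from pathlib import Path

import pandas as pd

from neocoda import composition, diversity, io_tables


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--k", type=int, default=10)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = io_tables.read_abundance_table(args.datadir / "abundance.tsv")
    meta = {m.sample_id: m
            for m in io_tables.read_metadata(args.datadir / "metadata.csv")}
    comp = composition.from_abundance(table)
    core = composition.select_core(comp, args.k)

    groupings = {
        "group": {s: meta[s].group for s in comp.samples},
        "delivery": {s: meta[s].delivery for s in comp.samples},
        "group_delivery": {s: f"{meta[s].group}/{meta[s].delivery}"
                           for s in comp.samples},
    }
    blocks = []
    for name, grouping in groupings.items():
        means = composition.group_mean_composition(core, grouping)
        block = pd.DataFrame(means.values, index=means.samples,
                             columns=means.parts)
        block.index = pd.MultiIndex.from_product([[name], block.index])
        blocks.append(block)
    pd.concat(blocks).rename_axis(["grouping", "level"]).to_csv(
        args.outdir / "core_composition_means.tsv", sep="\t",
        float_format="%.6g")

    div = diversity.alpha_diversity_frame(comp)
    div.to_csv(args.outdir / "alpha_diversity.tsv", sep="\t",
               float_format="%.6g")
    summary = pd.concat(
        {idx: diversity.group_median_iqr(div[idx], groupings["group_delivery"])
         for idx in div.columns}, names=["index"])
    summary.to_csv(args.outdir / "alpha_diversity_summary.tsv", sep="\t",
                   float_format="%.6g")

    top = blocks[0].loc["group"].T
    print(f"core ({args.k} genera) mean relative abundance by group:")
    print(top.round(3).to_string())
    print("\nalpha diversity median (IQR) by group/delivery:")
    print(summary.round(2).to_string())


if __name__ == "__main__":
    main()
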