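"""Hypothesis-free clustering of the patient microbiota.

Clusters first-visit patient compositions in Aitchison geometry
(complete-linkage on ilr coordinates), cuts the dendrogram at three
clusters, exports the heatmap matrix (genera reaching at least 0.1
relative abundance, columns in leaf order), and compares SpO2 and the
perfusion-derived parameters between clusters with pairwise Wilcoxon
rank-sum tests.
"""

import argparse
from pathlib import Path

import pandas as pd

from neocoda import clustering, composition, io_tables, perfusion


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--k", type=int, default=3)
    ap.add_argument("--linkage", default="complete")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = io_tables.read_abundance_table(args.datadir / "abundance.tsv")
    meta = io_tables.read_metadata(args.datadir / "metadata.csv")
    by_id = {m.sample_id: m for m in meta}
    chd = [m for m in meta if m.group == "CHD"]
    first = io_tables.select_first_visit(
        table.select_samples([m.sample_id for m in chd]), chd)
    comp = composition.impute_zeros(composition.from_abundance(first))

    dend = clustering.hierarchical_cluster(comp, args.linkage)
    assignment = clustering.cut_clusters(dend, args.k)
    assignment.to_frame().to_csv(args.outdir / "clusters.csv")
    dend.merge_table().to_csv(args.outdir / "dendrogram.tsv", sep="\t",
                              index=False, float_format="%.6g")
    clustering.heatmap_matrix(comp, 0.1, dend).to_csv(
        args.outdir / "heatmap_matrix.tsv", sep="\t", float_format="%.6g")

    # clinical parameters per subject (sample ids -> subject ids)
    subj_assign = clustering.ClusterAssignment(
        {by_id[s].subject_id: lab for s, lab in assignment.labels.items()})
    recs = io_tables.read_perfusion(args.datadir / "perfusion.csv")
    derived = perfusion.derive_perfusion(recs)
    params = pd.DataFrame([vars(r) for r in recs]).set_index("subject_id").join(
        pd.DataFrame([vars(d) for d in derived]).set_index("subject_id"))
    compared = []
    for col in ("spo2", "iftoe", "rl_velocity", "ru_velocity",
                "gut_perfusion_per_kg"):
        out = clustering.cluster_compare(params[col], subj_assign)
        out.insert(0, "parameter", col)
        compared.append(out)
    wilcoxon = pd.concat(compared)
    wilcoxon.to_csv(args.outdir / "cluster_wilcoxon.tsv", sep="\t",
                    index=False, float_format="%.6g")

    sizes = assignment.to_frame()["cluster"].value_counts().sort_index()
    print("cluster sizes:", dict(sizes))
    print("\npairwise Wilcoxon p-values per clinical parameter:")
    print(wilcoxon[["parameter", "cluster_a", "cluster_b", "p_value"]]
          .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
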