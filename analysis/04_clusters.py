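"""Respondent clusters: PCA on nine map metrics + Ward clustering on scores.

Computes the nine per-map metrics, runs the standardized PCA with the
stakeholder group as a supplementary variable, clusters respondents in
score space (automatic k), and compares the clusters metric-by-metric
with Student's t tests — the twin of the study's cluster-characteristics
table.  Also compares the two clusters' core zones (shared components).
"""

import argparse
import importlib.util
from pathlib import Path

import pandas as pd

from repmap import (
    compare_clusters,
    compare_zone_tables,
    group_social_maps,
    hcpc,
    metrics_table,
    run_pca,
    zone_table,
)
from repmap import io as rio

_spec = importlib.util.spec_from_file_location(
    "saturation_step", Path(__file__).parent / "02_saturation.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_collection = _mod.load_collection


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fixtures", type=Path, default=Path("results/simulated"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/clusters"))
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()

    collection = load_collection(args.fixtures)
    args.out_dir.mkdir(parents=True, exist_ok=True)

    table = metrics_table(collection)
    rio.write_tsv(table, args.out_dir / "metrics.tsv")

    pca = run_pca(table)
    rio.write_tsv(pca.scores, args.out_dir / "pca_scores.tsv")
    rio.write_tsv(pca.loadings, args.out_dir / "pca_loadings.tsv")
    rio.write_tsv(pca.supplementary_coords, args.out_dir / "pca_supplementary.tsv")

    clusters = hcpc(pca, seed=args.seed)
    rio.write_tsv(clusters.labels.to_frame(), args.out_dir / "clusters.tsv")
    comparison = compare_clusters(table, clusters)
    rio.write_tsv(comparison.stats, args.out_dir / "cluster_comparison.tsv")
    rio.write_tsv(comparison.composition, args.out_dir / "cluster_composition.tsv")

    print(f"PCA: axis 1 explains {pca.percent_variance[0]:.1f}% of variance, "
          f"axis 2 {pca.percent_variance[1]:.1f}% "
          f"(cumulative {pca.cumulative_percent[1]:.1f}%)")
    lead1 = pca.loadings["Dim1"].abs().idxmax()
    lead2 = pca.loadings["Dim2"].abs().idxmax()
    print(f"  axis 1 led by {lead1}, axis 2 by {lead2}")
    print(f"HCPC: k={clusters.k} clusters on {clusters.n_axes} retained axes; "
          f"sizes {clusters.labels.value_counts().sort_index().tolist()}")
    if clusters.k == 2:
        print("cluster comparison (mean +/- SD, Student's t):")
        for metric, row in comparison.stats.iterrows():
            stars = "***" if row["p_value"] < 0.001 else (
                "**" if row["p_value"] < 0.01 else ("*" if row["p_value"] < 0.05 else ""))
            print(f"  {metric:28s} {row.iloc[0]:8.3f}±{row.iloc[1]:.3f} vs "
                  f"{row.iloc[2]:8.3f}±{row.iloc[3]:.3f}  p={row['p_value']:.3g}{stars}")
        # per-cluster group maps and core-zone overlap
        labels = clusters.labels.to_dict()
        for lab, gmap in group_social_maps(collection, labels).items():
            rio.write_tsv(gmap.edges_frame(), args.out_dir / f"group_{lab}_edges.tsv", index=False)
        ids = clusters.labels
        zts = {lab: zone_table(collection.subset(ids.index[ids == lab]))
               for lab in sorted(ids.unique())}
        overlap = compare_zone_tables(zts[1], zts[2])
        rio.write_tsv(overlap.frame, args.out_dir / "zone_overlap.tsv")
        core = overlap.frame.loc["core"]
        print(f"core-zone overlap between clusters: {int(core['n_shared'])} shared "
              f"components ({core['share_of_a']:.0%} and {core['share_of_b']:.0%} "
              "of the two core zones)")
    print(f"  -> {args.out_dir}")


if __name__ == "__main__":
    main()
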