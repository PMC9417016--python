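"""Focal-challenge maps: 1-hop neighborhoods of a key component per cluster.

Picks the most-cited planted-core component with the highest aggregate
centrality (the analogue of a focal environmental challenge such as
anthropogenic fires), and extracts, for each respondent cluster, the
subgraph of components linked to it by interactions cited by >2
respondents of that cluster.
"""

import argparse
import importlib.util
import json
from pathlib import Path

import pandas as pd

from repmap import build_social_map, focus_subgraph
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
    parser.add_argument("--out-dir", type=Path, default=Path("results/focal"))
    parser.add_argument("--edge-min", type=int, default=2)
    parser.add_argument("--focal", default=None, help="component id; default: busiest core component")
    args = parser.parse_args()

    collection = load_collection(args.fixtures)
    truth = json.loads((args.fixtures / "ground_truth.json").read_text())
    args.out_dir.mkdir(parents=True, exist_ok=True)

    scm = build_social_map(collection)
    focal = args.focal
    if focal is None:
        core = {c for c, z in truth["component_zone"].items() if z == "core"}
        degree = {c: 0 for c in scm.node_citations}
        for (s, t), (pos, neg) in scm.edge_counts.items():
            degree[s] += pos + neg
            degree[t] += pos + neg
        focal = max(core & set(degree), key=lambda c: (degree[c], c))
    print(f"focal component: {focal} "
          f"(cited by {scm.node_citations[focal]}/{scm.R} respondents)")

    clusters = pd.Series(truth["respondent_cluster"])
    for name in sorted(clusters.unique()):
        sub_collection = collection.subset(clusters[clusters == name].index)
        gmap = build_social_map(sub_collection)
        if focal not in gmap.node_citations:
            print(f"  {name}: focal component uncited; skipped")
            continue
        sub = focus_subgraph(gmap, [focal], edge_occ_min=args.edge_min)
        rio.write_tsv(sub.edges_frame(), args.out_dir / f"focus_{name}_edges.tsv", index=False)
        rio.write_dot(sub, args.out_dir / f"focus_{name}.dot", catalog=collection.catalog)
        rio.write_graphml(sub, args.out_dir / f"focus_{name}.graphml", catalog=collection.catalog)
        neg = sum(1 for p, (po, ne) in sub.edge_counts.items() if ne > po)
        print(f"  {name}: {sub.n_nodes} linked components, {sub.n_edges} interactions "
              f"cited by >{args.edge_min} respondents ({neg} predominantly negative)")
    print(f"  -> {args.out_dir}")


if __name__ == "__main__":
    main()
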