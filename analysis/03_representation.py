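"""Social representation: social cognitive map + centrality-frequency zones.

Aggregates the individual maps into the social cognitive map, applies the
display filters (components cited by >10% of respondents; interactions
cited by >10 respondents, at type level), and classifies every cited
component into the four zones of the representation by crossing citation
frequency with median within-map centrality rank (median cuts).
"""

import argparse
import importlib.util
from pathlib import Path

from repmap import (
    build_social_map,
    condense_collection,
    filter_social_map,
    zone_summary,
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
    parser.add_argument("--out-dir", type=Path, default=Path("results/representation"))
    parser.add_argument("--node-freq-min", type=float, default=0.10)
    parser.add_argument("--edge-min", type=int, default=10)
    args = parser.parse_args()

    collection = load_collection(args.fixtures)
    args.out_dir.mkdir(parents=True, exist_ok=True)

    scm = build_social_map(collection)
    rio.write_tsv(scm.nodes_frame(), args.out_dir / "scm_nodes.tsv", index=False)
    rio.write_tsv(scm.edges_frame(), args.out_dir / "scm_edges.tsv", index=False)

    typed = condense_collection(collection, "type")
    display = filter_social_map(
        build_social_map(typed), node_freq_min=args.node_freq_min, edge_occ_min=args.edge_min
    )
    rio.write_graphml(display, args.out_dir / "scm_display.graphml", catalog=collection.catalog)
    rio.write_dot(display, args.out_dir / "scm_display.dot", catalog=collection.catalog)

    zt = zone_table(collection)
    df = zt.table.copy()
    df["type"] = [collection.catalog.type_of(c) for c in df.index]
    df["category"] = [collection.catalog.category_of(c, "component") for c in df.index]
    rio.write_tsv(df[["type", "category", "frequency", "median_rank", "zone"]],
                  args.out_dir / "zones.tsv")
    rio.write_tsv(zone_summary(zt, collection.catalog), args.out_dir / "zone_summary.tsv",
                  index=False)

    counts = zt.counts()
    print(f"social map: {scm.n_nodes} components, {scm.n_edges} directed interactions")
    print(f"  display (type level, >{args.node_freq_min:.0%} nodes, >{args.edge_min} edges): "
          f"{display.n_nodes} types, {display.n_edges} interactions")
    ambivalent = sum(1 for p, (pos, neg) in scm.edge_counts.items() if pos and neg)
    print(f"  ambivalent links (judged + by some, - by others): {ambivalent}")
    print(f"zones (freq cut {zt.freq_cut:.3f}, rank cut {zt.rank_cut:.1f}): {dict(counts)}")
    print(f"  -> {args.out_dir}")


if __name__ == "__main__":
    main()
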