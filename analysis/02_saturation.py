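"""Sampling saturation: component accumulation curve over respondents.

The interview campaign stopped when additional respondents contributed no
new components.  This step recomputes that diagnostic on the simulated
collection: the mean number of unique components cited by the first k
respondents, over random respondent orderings.
"""

import argparse
from pathlib import Path

from repmap import accumulation_curve
from repmap import io as rio


def load_collection(fixture_dir: Path):
    if not (fixture_dir / "edge_list.csv").exists():
        raise SystemExit(f"{fixture_dir} missing; run analysis/01_simulate.py first")
    return rio.load_collection(
        fixture_dir / "edge_list.csv",
        catalog_path=fixture_dir / "catalog.csv",
        metadata_path=fixture_dir / "metadata.csv",
        level="component",
    )


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fixtures", type=Path, default=Path("results/simulated"))
    parser.add_argument("--out", type=Path, default=Path("results/saturation.tsv"))
    parser.add_argument("--permutations", type=int, default=200)
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()

    collection = load_collection(args.fixtures)
    curve = accumulation_curve(collection, n_permutations=args.permutations, seed=args.seed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    rio.write_tsv(curve, args.out, index=False)

    total = curve["mean_unique"].iloc[-1]
    # respondents needed to reach 95% of the component pool, on average
    k95 = int(curve.loc[curve["mean_unique"] >= 0.95 * total, "k"].iloc[0])
    last_gain = curve["mean_unique"].iloc[-1] - curve["mean_unique"].iloc[-2]
    print(f"accumulation curve over {collection.R} respondents -> {args.out}")
    print(f"  {total:.0f} unique components in total; 95% reached by k={k95} respondents")
    print(f"  marginal gain of the last respondent: {last_gain:.2f} components")


if __name__ == "__main__":
    main()
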