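"""The centrality-frequency method: four zones of a social representation.

Two per-component indicators are crossed:

* *frequency of citation* — the share of respondents whose map contains
  the component; a proxy for the level of agreement;
* *median centrality rank* — the median, over exactly the maps citing the
  component, of its within-map degree-centrality rank (rank 1 = most
  central); a proxy for perceived importance.

The quadrant rule (high/low frequency x central/peripheral rank) yields
the four classic zones of the structural approach:

===================  ==============  =================
                     central rank    peripheral rank
===================  ==============  =================
frequent             core            first periphery
infrequent           contrasting     second periphery
===================  ==============  =================

Default cuts are the medians of the observed frequency and median-rank
distributions; the cuts actually used are stored in the output for
auditability.  Ties at a cut go to the high-frequency / central side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import node_centrality
from .model import CondensationCatalog, MapCollection, ValidationError, ZONES


def component_frequency(collection: MapCollection) -> pd.Series:
    """frequency(c) = (number of maps citing c) / R, over all cited components."""
    if collection.R == 0:
        raise ValidationError("component frequency of an empty collection")
    counts: dict = {}
    for m in collection.maps:
        for node in m.nodes:
            counts[node] = counts.get(node, 0) + 1
    items = sorted(counts.items())
    return pd.Series(
        [v / collection.R for _, v in items],
        index=pd.Index([k for k, _ in items], name="component"),
        name="frequency",
    )


def median_centrality_rank(collection: MapCollection, mode: str = "raw") -> pd.Series:
    """Median within-map centrality rank per component, over citing maps only.

    ``mode='raw'`` uses the rank itself (1 = most central); ``'relative'``
    uses rank / map size, which removes the map-size dependence when map
    sizes vary widely.  The median of an even-length list is the midpoint
    average.
    """
    if collection.R == 0:
        raise ValidationError("median centrality rank of an empty collection")
    if mode not in ("raw", "relative"):
        raise ValidationError(f"unknown rank mode {mode!r}")
    column = "rank" if mode == "raw" else "relative_rank"
    ranks: dict = {}
    for m in collection.maps:
        table = node_centrality(m)
        for node, value in table[column].items():
            ranks.setdefault(node, []).append(float(value))
    items = sorted(ranks.items())
    return pd.Series(
        [float(np.median(v)) for _, v in items],
        index=pd.Index([k for k, _ in items], name="component"),
        name="median_rank",
    )


@dataclass
class ZoneTable:
    """Per-component zone assignment plus the thresholds that produced it."""

    table: pd.DataFrame  # index component; columns frequency, median_rank, zone
    freq_cut: float
    rank_cut: float
    rank_mode: str

    def counts(self) -> pd.Series:
        return self.table["zone"].value_counts().reindex(ZONES, fill_value=0)

    def components_in(self, zone: str) -> set:
        if zone not in ZONES:
            raise ValidationError(f"unknown zone {zone!r}")
        return set(self.table.index[self.table["zone"] == zone])


def classify_zones(
    freq: pd.Series,
    rank: pd.Series,
    freq_cut="median",
    rank_cut="median",
    rank_mode: str = "raw",
) -> ZoneTable:
    """Assign each component to one of the four representation zones.

    ``freq_cut`` / ``rank_cut`` may be numbers or ``"median"`` (resolved to
    the median over components).  A component is *frequent* when
    frequency >= freq_cut and *central* when median rank <= rank_cut.
    """
    if set(freq.index) != set(rank.index):
        only_f = sorted(set(freq.index) - set(rank.index))
        only_r = sorted(set(rank.index) - set(freq.index))
        raise ValidationError(
            f"frequency/rank domain mismatch (only in frequency: {only_f[:5]}, "
            f"only in rank: {only_r[:5]})"
        )
    rank = rank.reindex(freq.index)
    fcut = float(np.median(freq.to_numpy())) if isinstance(freq_cut, str) else float(freq_cut)
    rcut = float(np.median(rank.to_numpy())) if isinstance(rank_cut, str) else float(rank_cut)
    if isinstance(freq_cut, str) and freq_cut != "median":
        raise ValidationError(f"unknown frequency cut {freq_cut!r}")
    if isinstance(rank_cut, str) and rank_cut != "median":
        raise ValidationError(f"unknown rank cut {rank_cut!r}")
    frequent = freq.to_numpy() >= fcut
    central = rank.to_numpy() <= rcut
    zone = np.where(
        frequent & central,
        "core",
        np.where(
            frequent,
            "first_periphery",
            np.where(central, "contrasting", "second_periphery"),
        ),
    )
    table = pd.DataFrame(
        {"frequency": freq.to_numpy(), "median_rank": rank.to_numpy(), "zone": zone},
        index=freq.index.copy(),
    ).sort_index()
    return ZoneTable(table=table, freq_cut=fcut, rank_cut=rcut, rank_mode=rank_mode)


def zone_table(
    collection: MapCollection,
    freq_cut="median",
    rank_cut="median",
    rank_mode: str = "raw",
) -> ZoneTable:
    """Full chain: frequency -> median centrality rank -> zone classification."""
    freq = component_frequency(collection)
    rank = median_centrality_rank(collection, mode=rank_mode)
    return classify_zones(freq, rank, freq_cut=freq_cut, rank_cut=rank_cut, rank_mode=rank_mode)


def zone_summary(zt: ZoneTable, catalog: CondensationCatalog) -> pd.DataFrame:
    """Per (zone, type): component count and mean citation frequency.

    Zone counts partition the component set; type means are arithmetic
    means of the member components' frequencies.
    """
    df = zt.table.copy()
    level = "component" if set(df.index) <= catalog.ids_at("component") else "type"
    df["type"] = [
        catalog.map_label(c, level, "type") for c in df.index
    ]
    df["category"] = [catalog.category_of(c, level) for c in df.index]
    out = (
        df.groupby(["zone", "type", "category"], sort=True)
        .agg(n_components=("frequency", "size"), mean_frequency=("frequency", "mean"))
        .reset_index()
    )
    # stable zone ordering
    out["zone"] = pd.Categorical(out["zone"], categories=ZONES, ordered=True)
    return out.sort_values(["zone", "type"]).reset_index(drop=True)


@dataclass
class ZoneOverlap:
    """Zone-by-zone overlap between two zone tables."""

    frame: pd.DataFrame  # per zone: n_a, n_b, n_shared, share_of_a, share_of_b
    shared: dict  # zone -> set of shared components


def compare_zone_tables(a: ZoneTable, b: ZoneTable) -> ZoneOverlap:
    """Overlap report between two classifications (e.g. two respondent groups)."""
    rows = []
    shared: dict = {}
    for zone in ZONES:
        in_a = a.components_in(zone)
        in_b = b.components_in(zone)
        common = in_a & in_b
        shared[zone] = common
        rows.append(
            {
                "zone": zone,
                "n_a": len(in_a),
                "n_b": len(in_b),
                "n_shared": len(common),
                "share_of_a": len(common) / len(in_a) if in_a else np.nan,
                "share_of_b": len(common) / len(in_b) if in_b else np.nan,
            }
        )
    return ZoneOverlap(frame=pd.DataFrame(rows).set_index("zone"), shared=shared)
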