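"""Social cognitive map: aggregation by matrix addition, filters, subgraphs.

The social cognitive map (SCM) is the entrywise sum of all individual
signed adjacency matrices, padded to the union node set.  Rather than only
the net sign, each ordered pair retains its positive and negative tallies,
so *ambivalent* links — judged positive by some respondents and negative
by others — stay first-class.  Display filters use strict inequalities
(">10 respondents", ">10% of respondents"), matching how such cut-offs are
conventionally stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence

import pandas as pd

from .model import CognitiveMap, CondensationCatalog, MapCollection, ValidationError


@dataclass
class SocialMap:
    """Aggregate of R individual maps.

    ``node_citations[v]``   number of maps citing v (1 <= c <= R);
    ``edge_counts[(s,t)]``  (pos, neg) counts of maps holding a +1 / -1
                            edge on the ordered pair.  Derived quantities:
                            weight_sum = pos - neg (the matrix-addition
                            entry), occurrence = pos + neg.
    """

    R: int
    level: str
    node_citations: dict = field(default_factory=dict)
    edge_counts: dict = field(default_factory=dict)

    def frequency(self, node: str) -> float:
        return self.node_citations[node] / self.R

    def weight_sum(self, pair) -> int:
        pos, neg = self.edge_counts[pair]
        return pos - neg

    def occurrence(self, pair) -> int:
        pos, neg = self.edge_counts[pair]
        return pos + neg

    @property
    def n_nodes(self) -> int:
        return len(self.node_citations)

    @property
    def n_edges(self) -> int:
        return len(self.edge_counts)

    def nodes_frame(self) -> pd.DataFrame:
        rows = [
            (node, count, count / self.R)
            for node, count in sorted(self.node_citations.items())
        ]
        return pd.DataFrame(rows, columns=["node", "citation_count", "frequency"])

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            (src, tgt, pos, neg, pos - neg, pos + neg)
            for (src, tgt), (pos, neg) in sorted(self.edge_counts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["source", "target", "pos_count", "neg_count", "weight_sum", "occurrence"],
        )

    def weight_matrix(self, order: Sequence | None = None) -> pd.DataFrame:
        """Entrywise-summed signed adjacency matrix over the node set."""
        order = sorted(self.node_citations) if order is None else list(order)
        df = pd.DataFrame(0, index=order, columns=order, dtype=int)
        for (src, tgt), (pos, neg) in self.edge_counts.items():
            df.loc[src, tgt] = pos - neg
        return df


def _maps_of(maps_or_collection) -> list[CognitiveMap]:
    if isinstance(maps_or_collection, MapCollection):
        return list(maps_or_collection.maps)
    return list(maps_or_collection)


def build_social_map(maps_or_collection) -> SocialMap:
    """Aggregate maps (all at a common level) into a social map.

    Conflict edges carried by condensed individual maps contribute neither
    to tallies nor to occurrence: the respondent's net judgement on that
    pair was sign 0, i.e. no signed link.
    """
    maps = _maps_of(maps_or_collection)
    if not maps:
        raise ValidationError("cannot aggregate an empty collection: no maps")
    levels = {m.level for m in maps}
    if len(levels) != 1:
        raise ValidationError(f"cannot aggregate maps at mixed levels: {sorted(levels)}")
    scm = SocialMap(R=len(maps), level=levels.pop())
    for m in maps:
        for node in m.nodes:
            scm.node_citations[node] = scm.node_citations.get(node, 0) + 1
        for pair, sign in m.edges.items():
            pos, neg = scm.edge_counts.get(pair, (0, 0))
            if sign > 0:
                pos += 1
            else:
                neg += 1
            scm.edge_counts[pair] = (pos, neg)
    return scm


def filter_social_map(
    scm: SocialMap, node_freq_min: float = 0.0, edge_occ_min: int = 0
) -> SocialMap:
    """Apply strict display thresholds.

    Keeps nodes with frequency strictly greater than ``node_freq_min`` and
    edges with occurrence strictly greater than ``edge_occ_min`` whose
    endpoints survive.  Counts are unchanged for survivors; raising a
    threshold can only remove material.
    """
    if node_freq_min < 0 or edge_occ_min < 0:
        raise ValidationError("thresholds must be >= 0")
    kept_nodes = {
        node: count
        for node, count in scm.node_citations.items()
        if count / scm.R > node_freq_min
    }
    kept_edges = {
        pair: counts
        for pair, counts in scm.edge_counts.items()
        if sum(counts) > edge_occ_min
        and pair[0] in kept_nodes
        and pair[1] in kept_nodes
    }
    return SocialMap(R=scm.R, level=scm.level, node_citations=kept_nodes, edge_counts=kept_edges)


def group_social_maps(
    collection: MapCollection, labels: Mapping[str, object]
) -> dict:
    """One social map per group of respondents.

    ``labels`` maps every respondent id to a group label.  The groups'
    weight matrices sum to the full social map's weight matrix (aggregation
    is additive over any partition of the maps).
    """
    unlabeled = [m.respondent_id for m in collection.maps if m.respondent_id not in labels]
    if unlabeled:
        raise ValidationError(f"unlabeled respondents: {unlabeled}")
    by_group: dict = {}
    for m in collection.maps:
        by_group.setdefault(labels[m.respondent_id], []).append(m)
    return {group: build_social_map(maps) for group, maps in sorted(by_group.items(), key=lambda kv: str(kv[0]))}


def focus_subgraph(
    scm: SocialMap,
    focal: Iterable[str],
    edge_occ_min: int = 0,
    catalog: CondensationCatalog | None = None,
) -> SocialMap:
    """1-hop, direction-agnostic neighborhood of a focal node set.

    ``focal`` entries may be node ids present in the social map or, when a
    catalog is given and the map is at component level, type labels (then
    expanded to their member components present in the map).  Keeps edges
    incident to the focal set with occurrence strictly above the threshold,
    plus the nodes those edges touch; focal nodes are kept even if no edge
    survives.
    """
    focal = list(focal)
    if not focal:
        raise ValidationError("focal set is empty")
    resolved: set = set()
    for item in focal:
        if item in scm.node_citations:
            resolved.add(item)
        elif catalog is not None and item in catalog.ids_at("type") and scm.level == "component":
            members = {
                c for c in scm.node_citations if catalog.type_of(c) == item
            }
            if not members:
                raise ValidationError(f"focal type {item!r} has no member in the social map")
            resolved |= members
        else:
            raise ValidationError(f"focal node {item!r} absent from the social map")
    kept_edges = {
        pair: counts
        for pair, counts in scm.edge_counts.items()
        if (pair[0] in resolved or pair[1] in resolved) and sum(counts) > edge_occ_min
    }
    kept_nodes = set(resolved)
    for (src, tgt) in kept_edges:
        kept_nodes.add(src)
        kept_nodes.add(tgt)
    return SocialMap(
        R=scm.R,
        level=scm.level,
        node_citations={n: scm.node_citations[n] for n in kept_nodes},
        edge_counts=kept_edges,
    )
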