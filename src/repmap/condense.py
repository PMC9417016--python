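"""Condensation: collapse maps to a coarser label level through the catalog.

Condensing merges all raw edges between the pre-images of each ordered pair
of condensed nodes and re-derives a single sign by majority: the merged
edge carries ``sign(pos - neg)``.  Exact ties (pos == neg > 0) become
sign-0 *conflict edges*, excluded from link counts but retained for
reporting.  Edges whose endpoints condense to the same node (would-be
self-loops) are dropped silently here and counted by the report — they are
an artifact of condensation, not respondent intent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import (
    LEVELS,
    CognitiveMap,
    CondensationCatalog,
    ConflictEdge,
    MapCollection,
    ValidationError,
)


@dataclass(frozen=True)
class EdgeTally:
    """Merge bookkeeping for one condensed ordered pair."""

    source: str
    target: str
    pos_count: int
    neg_count: int

    @property
    def sign(self) -> int:
        return (self.pos_count > self.neg_count) - (self.pos_count < self.neg_count)


def _tally_items(cmap: CognitiveMap):
    """(pair, (pos, neg)) items behind a map's signed edges and conflicts."""
    if cmap.edge_tallies is not None:
        items = list(cmap.edge_tallies.items())
    else:
        items = [
            (pair, (1, 0) if sign > 0 else (0, 1)) for pair, sign in cmap.edges.items()
        ]
    items += [
        ((c.source, c.target), (c.pos_count, c.neg_count)) for c in cmap.conflict_edges
    ]
    return items


def condense_map(
    cmap: CognitiveMap, catalog: CondensationCatalog, level: str
) -> CognitiveMap:
    """Condense one map to ``level`` ('component' or 'type').

    Condensing a map already at ``level`` re-tallies and is the identity,
    which makes the operation idempotent at a fixed level.  Requesting a
    level finer than the map's is an error.
    """
    if level not in LEVELS:
        raise ValidationError(f"unknown level {level!r}")
    if LEVELS.index(level) < LEVELS.index(cmap.level):
        raise ValidationError(
            f"map {cmap.respondent_id!r} at level {cmap.level!r} cannot be "
            f"condensed to finer level {level!r}"
        )
    mapping = {n: catalog.map_label(n, cmap.level, level) for n in cmap.nodes}
    nodes = set(mapping.values())
    tallies: dict = {}
    for (src, tgt), (pos, neg) in _tally_items(cmap):
        csrc = mapping.get(src) or catalog.map_label(src, cmap.level, level)
        ctgt = mapping.get(tgt) or catalog.map_label(tgt, cmap.level, level)
        if csrc == ctgt:
            continue  # would-be self-loop; counted by condensation_report
        acc = tallies.setdefault((csrc, ctgt), [0, 0])
        acc[0] += pos
        acc[1] += neg
    edges: dict = {}
    kept_tallies: dict = {}
    conflicts: list[ConflictEdge] = []
    for pair in sorted(tallies):
        pos, neg = tallies[pair]
        if pos == neg:
            conflicts.append(ConflictEdge(pair[0], pair[1], pos, neg))
        else:
            edges[pair] = 1 if pos > neg else -1
            kept_tallies[pair] = (pos, neg)
    return CognitiveMap(
        respondent_id=cmap.respondent_id,
        nodes=nodes,
        edges=edges,
        respondent_group=cmap.respondent_group,
        level=level,
        conflict_edges=conflicts,
        edge_tallies=kept_tallies,
    )


def condense_collection(collection: MapCollection, level: str) -> MapCollection:
    if collection.catalog is None:
        raise ValidationError("collection has no catalog to condense through")
    return MapCollection(
        maps=[condense_map(m, collection.catalog, level) for m in collection.maps],
        catalog=collection.catalog,
    )


@dataclass
class CondensationReport:
    """Audit of a condensation step: what was merged, dropped, or conflicted."""

    per_respondent: pd.DataFrame
    unique_nodes_before: int
    unique_nodes_after: int

    @property
    def totals(self) -> dict:
        num = self.per_respondent.drop(columns=["respondent_id"]).sum()
        out = {k: int(v) for k, v in num.items()}
        out["unique_nodes_before"] = self.unique_nodes_before
        out["unique_nodes_after"] = self.unique_nodes_after
        return out


def condensation_report(
    before: MapCollection, after: MapCollection
) -> CondensationReport:
    """Compare a collection before/after condensation, per respondent.

    Counts merged nodes, merged raw links, conflicts, and raw links dropped
    because their endpoints condensed to the same node.
    """
    if before.respondent_ids != after.respondent_ids:
        raise ValidationError(
            "condensation report requires the same respondents in the same order"
        )
    catalog = after.catalog or before.catalog
    if catalog is None:
        raise ValidationError("condensation report requires a catalog")
    target = after.level
    rows = []
    for mb, ma in zip(before.maps, after.maps):
        raw_links = 0
        dropped = 0
        for (src, tgt), (pos, neg) in _tally_items(mb):
            raw_links += pos + neg
            if catalog.map_label(src, mb.level, target) == catalog.map_label(
                tgt, mb.level, target
            ):
                dropped += pos + neg
        kept_pairs = ma.n_links + len(ma.conflict_edges)
        rows.append(
            {
                "respondent_id": mb.respondent_id,
                "nodes_before": mb.n_nodes,
                "nodes_after": ma.n_nodes,
                "nodes_merged": mb.n_nodes - ma.n_nodes,
                "links_before": raw_links,
                "links_after": ma.n_links,
                "links_merged": raw_links - dropped - kept_pairs,
                "conflicts": len(ma.conflict_edges),
                "self_loops_dropped": dropped,
            }
        )
    return CondensationReport(
        per_respondent=pd.DataFrame(rows),
        unique_nodes_before=len(set().union(*[m.nodes for m in before.maps]) if before.maps else set()),
        unique_nodes_after=len(set().union(*[m.nodes for m in after.maps]) if after.maps else set()),
    )
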