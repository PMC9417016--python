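"""Readers, writers and graph exports.

One CSV dialect is fixed throughout: UTF-8 encoding, comma delimiter,
decimal point.  Adjacency matrices follow the Mental-Modeler convention:
concept names in the first row and first column, row = cause, column =
effect, cells in {-1, 0, +1}.  Tables are exported as TSV; graphs as
GraphML (via networkx) and DOT (hand-written, attribute-styled).
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import (
    CATEGORIES,
    RESPONDENT_GROUPS,
    CognitiveMap,
    CondensationCatalog,
    MapCollection,
    ValidationError,
    normalize_label,
)

# ---------------------------------------------------------------------------
# individual maps
# ---------------------------------------------------------------------------


def read_adjacency_matrix(
    path,
    respondent_id: str,
    respondent_group: str = "other",
    level: str = "raw",
    drop_self_loops: bool = False,
    coerce_sign: bool = False,
) -> CognitiveMap:
    """Read one respondent's map from a square signed adjacency CSV.

    Isolated concepts (all-zero rows/columns) are kept as nodes.  A nonzero
    diagonal raises unless ``drop_self_loops`` is set (then dropped with a
    warning); a cell outside {-1, 0, +1} raises unless ``coerce_sign`` is
    set (then mapped through ``sign()`` with a warning).
    """
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    cols = [str(c) for c in df.columns]
    rows = [str(r) for r in df.index]
    if len(rows) != len(cols) or rows != cols:
        raise ValidationError(
            f"{path}: adjacency matrix must be square with identical row and "
            "column labels in the same order"
        )
    norm = [normalize_label(c) for c in cols]
    if len(set(norm)) != len(norm):
        dupes = sorted({n for n in norm if norm.count(n) > 1})
        raise ValidationError(f"{path}: duplicate labels after normalization: {dupes}")
    values = df.to_numpy(dtype=float)
    if not np.isin(values, (-1.0, 0.0, 1.0)).all():
        if not coerce_sign:
            raise ValidationError(
                f"{path}: cells outside {{-1, 0, +1}}; pass coerce_sign=True to apply sign()"
            )
        warnings.warn(f"{path}: coercing out-of-range cells with sign()", stacklevel=2)
        values = np.sign(values)
    if np.diagonal(values).any():
        if not drop_self_loops:
            raise ValidationError(
                f"{path}: nonzero diagonal (self-loop); pass drop_self_loops=True to drop"
            )
        warnings.warn(f"{path}: dropping self-loops on the diagonal", stacklevel=2)
        np.fill_diagonal(values, 0.0)
    src_idx, tgt_idx = np.nonzero(values)
    edges = {
        (cols[i], cols[j]): int(values[i, j]) for i, j in zip(src_idx.tolist(), tgt_idx.tolist())
    }
    return CognitiveMap(
        respondent_id=respondent_id,
        nodes=set(cols),
        edges=edges,
        respondent_group=respondent_group,
        level=level,
    )


def write_adjacency_matrix(cmap: CognitiveMap, path) -> None:
    """Write a map as a square signed adjacency CSV (nodes sorted).

    Conflict edges cannot be represented in a single signed matrix; when
    present they are omitted from the matrix and emitted to a TSV sidecar
    at ``<path>.conflicts.tsv``.
    """
    cmap.adjacency_frame().to_csv(path, encoding="utf-8")
    if cmap.conflict_edges:
        sidecar = f"{path}.conflicts.tsv"
        pd.DataFrame(
            [(c.source, c.target, c.pos_count, c.neg_count) for c in cmap.conflict_edges],
            columns=["source", "target", "pos_count", "neg_count"],
        ).to_csv(sidecar, sep="\t", index=False)


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------


def read_edge_list(
    path,
    metadata: Mapping[str, str] | None = None,
    level: str = "raw",
) -> list[CognitiveMap]:
    """Read a multi-respondent edge-list CSV into one map per respondent.

    Expected columns: ``respondent_id, source, target, sign``.  Rows with
    an empty target declare an isolated (cited but unlinked) node.  The
    same ordered pair listed twice with conflicting signs for one
    respondent is an error naming the pair; an exact duplicate collapses.
    """
    df = pd.read_csv(path, encoding="utf-8", dtype={"respondent_id": str, "source": str, "target": str})
    required = {"respondent_id", "source", "target", "sign"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: edge list missing columns {sorted(missing)}")
    maps: list[CognitiveMap] = []
    metadata = dict(metadata or {})
    for rid, sub in df.groupby("respondent_id", sort=False):
        nodes: set = set()
        edges: dict = {}
        for row in sub.itertuples(index=False):
            source = str(row.source)
            nodes.add(source)
            target = row.target
            if pd.isna(target) or str(target) == "":
                continue
            target = str(target)
            nodes.add(target)
            sign = int(float(row.sign))
            if sign not in (1, -1):
                raise ValidationError(
                    f"{path}: respondent {rid!r}: edge ({source!r}, {target!r}) has "
                    f"sign {row.sign!r}, expected +1 or -1"
                )
            pair = (source, target)
            if pair in edges and edges[pair] != sign:
                raise ValidationError(
                    f"{path}: respondent {rid!r}: pair ({source!r}, {target!r}) listed "
                    "with conflicting signs"
                )
            edges[pair] = sign
        maps.append(
            CognitiveMap(
                respondent_id=str(rid),
                nodes=nodes,
                edges=edges,
                respondent_group=metadata.get(str(rid), "other"),
                level=level,
            )
        )
    return maps


def write_edge_list(maps: Iterable[CognitiveMap], path) -> None:
    """Write maps as a multi-respondent edge-list CSV.

    Isolated nodes are declared with an empty target; linked nodes are
    implied by the edges they touch.
    """
    rows = []
    for m in maps:
        for node in sorted(m.isolated_nodes()):
            rows.append((m.respondent_id, node, "", ""))
        for (src, tgt) in sorted(m.edges):
            rows.append((m.respondent_id, src, tgt, m.edges[(src, tgt)]))
    pd.DataFrame(rows, columns=["respondent_id", "source", "target", "sign"]).to_csv(
        path, index=False, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# catalog and respondent metadata
# ---------------------------------------------------------------------------


def read_catalog(path) -> CondensationCatalog:
    """Read a condensation catalog CSV (raw_label, component, type, category)."""
    df = pd.read_csv(path, encoding="utf-8", dtype=str)
    return CondensationCatalog.from_frame(df)


def write_catalog(catalog: CondensationCatalog, path) -> None:
    catalog.to_frame().to_csv(path, index=False, encoding="utf-8")


def read_metadata(path) -> dict[str, str]:
    """Read respondent metadata CSV (respondent_id, group) into a dict."""
    df = pd.read_csv(path, encoding="utf-8", dtype=str)
    missing = {"respondent_id", "group"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: metadata missing columns {sorted(missing)}")
    out: dict[str, str] = {}
    for row in df.itertuples(index=False):
        group = str(row.group).strip()
        if group not in RESPONDENT_GROUPS:
            raise ValidationError(
                f"{path}: respondent {row.respondent_id!r} has unknown group {group!r}"
            )
        out[str(row.respondent_id)] = group
    return out


def write_metadata(groups: Mapping[str, str], path) -> None:
    pd.DataFrame(
        sorted(groups.items()), columns=["respondent_id", "group"]
    ).to_csv(path, index=False, encoding="utf-8")


def load_collection(
    edge_list_path,
    catalog_path=None,
    metadata_path=None,
    level: str = "raw",
) -> MapCollection:
    """Convenience loader: edge list (+ optional catalog and metadata)."""
    metadata = read_metadata(metadata_path) if metadata_path else None
    catalog = read_catalog(catalog_path) if catalog_path else None
    maps = read_edge_list(edge_list_path, metadata=metadata, level=level)
    return MapCollection(maps=maps, catalog=catalog)


# ---------------------------------------------------------------------------
# graph exports
# ---------------------------------------------------------------------------

_CATEGORY_FILL = {
    "biophysical": "#8fbf72",
    "social": "#e8a86a",
    "ecosystem_service": "#7aa6d6",
    "ecosystem_disservice": "#a089c2",
    "positive_human_action": "#f2d675",
    "negative_human_action": "#d98585",
}


def map_to_networkx(cmap: CognitiveMap) -> nx.DiGraph:
    g = nx.DiGraph(respondent_id=cmap.respondent_id, level=cmap.level)
    for node in sorted(cmap.nodes):
        g.add_node(node)
    for (src, tgt) in sorted(cmap.edges):
        g.add_edge(src, tgt, sign=int(cmap.edges[(src, tgt)]))
    return g


def social_map_to_networkx(scm, catalog: CondensationCatalog | None = None) -> nx.DiGraph:
    """Social cognitive map as a DiGraph with tallies on nodes and edges."""
    g = nx.DiGraph(R=scm.R, level=scm.level)
    for node in sorted(scm.node_citations):
        attrs = {
            "citation_count": int(scm.node_citations[node]),
            "frequency": float(scm.frequency(node)),
        }
        if catalog is not None:
            attrs["category"] = catalog.category_of(node, scm.level)
        g.add_node(node, **attrs)
    for (src, tgt) in sorted(scm.edge_counts):
        pos, neg = scm.edge_counts[(src, tgt)]
        g.add_edge(
            src,
            tgt,
            pos_count=int(pos),
            neg_count=int(neg),
            weight_sum=int(pos - neg),
            occurrence=int(pos + neg),
        )
    return g


def write_graphml(graph_or_map, path, catalog: CondensationCatalog | None = None) -> None:
    """Write a CognitiveMap, SocialMap or DiGraph as GraphML."""
    if isinstance(graph_or_map, nx.DiGraph):
        g = graph_or_map
    elif isinstance(graph_or_map, CognitiveMap):
        g = map_to_networkx(graph_or_map)
    else:
        g = social_map_to_networkx(graph_or_map, catalog=catalog)
    nx.write_graphml(g, path)


def _dot_quote(s: str) -> str:
    return '"' + str(s).replace('"', r"\"") + '"'


def write_dot(scm, path, catalog: CondensationCatalog | None = None) -> None:
    """Write a social map as DOT with the field's usual styling.

    Positive links are green, negative red, exactly-cancelling links grey;
    edge width is proportional to occurrence; nodes are filled by category
    when a catalog is given.
    """
    lines = ["digraph social_map {", "  rankdir=LR;", '  node [shape=box, style=filled, fillcolor="#eeeeee"];']
    for node in sorted(scm.node_citations):
        attrs = [f'label="{node}\\n{scm.frequency(node):.2f}"']
        if catalog is not None:
            fill = _CATEGORY_FILL.get(catalog.category_of(node, scm.level))
            if fill:
                attrs.append(f'fillcolor="{fill}"')
        lines.append(f"  {_dot_quote(node)} [{', '.join(attrs)}];")
    for (src, tgt) in sorted(scm.edge_counts):
        pos, neg = scm.edge_counts[(src, tgt)]
        net = pos - neg
        color = "forestgreen" if net > 0 else ("firebrick" if net < 0 else "gray50")
        width = 0.5 + 0.25 * (pos + neg)
        lines.append(
            f"  {_dot_quote(src)} -> {_dot_quote(tgt)} "
            f'[color={color}, penwidth={width:.2f}, label="{pos}+/{neg}-"];'
        )
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a table as TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=index, float_format="%.9g", encoding="utf-8")


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
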