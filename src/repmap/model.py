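"""Core domain model for signed cognitive-map analysis.

A respondent's *individual cognitive map* (ICM) is a signed directed graph:
nodes are components of a social-ecological system, edges are causal links
the respondent perceives as positive (+1) or negative (-1).  Because
respondents phrase components in their own words, a *condensation catalog*
maps verbatim elicited labels onto canonical components, coarser component
types, and a closed set of six categories; condensing maps through the
catalog makes them comparable across respondents.

Three nested label levels exist, from finest to coarsest:

``raw``        the verbatim label as elicited in the interview;
``component``  the canonical component the raw label was merged into;
``type``       a thematic group of components (the study uses 32 types).

Each type belongs to exactly one of the six categories, so a category is
always derivable from a node id at any level.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import pandas as pd

#: The closed set of component categories.
CATEGORIES = (
    "biophysical",
    "social",
    "ecosystem_service",
    "ecosystem_disservice",
    "positive_human_action",
    "negative_human_action",
)

#: Stakeholder groups a respondent may belong to.
RESPONDENT_GROUPS = ("researcher", "ngo_member", "project_member", "tour_operator", "other")

#: Condensation levels, finest first.
LEVELS = ("raw", "component", "type")

#: The four zones of a social representation (centrality-frequency quadrants).
ZONES = ("core", "first_periphery", "contrasting", "second_periphery")


class RepmapError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(RepmapError):
    """An input violates a structural invariant of the data model."""


class PipelineError(RepmapError):
    """A pipeline stage failed; the message names the stage."""


def normalize_label(label: object) -> str:
    """Normalize a label for catalog matching.

    Trims leading/trailing whitespace, collapses internal whitespace runs to
    a single space, and case-folds.  The original spelling is preserved
    elsewhere; normalization is only used as the matching key.
    """
    return " ".join(str(label).split()).casefold()


@dataclass(frozen=True)
class ConflictEdge:
    """A condensed ordered pair whose positive and negative tallies cancel.

    Conflict edges carry sign 0, are excluded from link counts, and are kept
    only for reporting: they record that respondents (or merged raw edges)
    judged the same causal link both positive and negative.
    """

    source: str
    target: str
    pos_count: int
    neg_count: int


@dataclass(frozen=True)
class Component:
    """A canonical component with its merged raw labels, type and category."""

    id: str
    raw_labels: frozenset
    type_group: str
    category: str


class CondensationCatalog:
    """Lookup table raw label -> component -> type -> category.

    Invariants enforced at construction:

    * raw labels are unique after normalization;
    * each component belongs to exactly one type;
    * each type belongs to exactly one category;
    * categories are drawn from the closed six-element set.
    """

    def __init__(self, entries: Iterable[Sequence]):
        cleaned = []
        for entry in entries:
            raw, comp, typ, cat = (str(x).strip() for x in entry)
            cleaned.append((raw, comp, typ, cat))
        self.entries: list[tuple[str, str, str, str]] = cleaned
        self._component_of: dict[str, str] = {}
        self._type_of: dict[str, str] = {}
        self._category_of_type: dict[str, str] = {}
        self._raws_of: dict[str, set] = {}
        for raw, comp, typ, cat in cleaned:
            if cat not in CATEGORIES:
                raise ValidationError(
                    f"unknown category {cat!r} for component {comp!r}; "
                    f"expected one of {CATEGORIES}"
                )
            key = normalize_label(raw)
            if key in self._component_of:
                raise ValidationError(f"duplicate raw label after normalization: {raw!r}")
            if comp in self._type_of and self._type_of[comp] != typ:
                raise ValidationError(
                    f"component {comp!r} assigned two types: "
                    f"{self._type_of[comp]!r} and {typ!r}"
                )
            if typ in self._category_of_type and self._category_of_type[typ] != cat:
                raise ValidationError(
                    f"type {typ!r} assigned two categories: "
                    f"{self._category_of_type[typ]!r} and {cat!r}"
                )
            self._component_of[key] = comp
            self._type_of[comp] = typ
            self._category_of_type[typ] = cat
            self._raws_of.setdefault(comp, set()).add(raw)

    # -- introspection -------------------------------------------------

    @property
    def components(self) -> list[str]:
        return list(self._type_of)

    @property
    def types(self) -> list[str]:
        return list(self._category_of_type)

    @property
    def n_components(self) -> int:
        return len(self._type_of)

    @property
    def n_types(self) -> int:
        return len(self._category_of_type)

    @property
    def categories_used(self) -> list[str]:
        used = set(self._category_of_type.values())
        return [c for c in CATEGORIES if c in used]

    def component_objects(self) -> list[Component]:
        return [
            Component(
                id=comp,
                raw_labels=frozenset(self._raws_of[comp]),
                type_group=typ,
                category=self._category_of_type[typ],
            )
            for comp, typ in self._type_of.items()
        ]

    def ids_at(self, level: str) -> set:
        """All valid node ids at ``level``."""
        if level == "raw":
            return {raw for raw, *_ in self.entries}
        if level == "component":
            return set(self._type_of)
        if level == "type":
            return set(self._category_of_type)
        raise ValidationError(f"unknown level {level!r}")

    # -- mapping -------------------------------------------------------

    def map_label(self, label: str, from_level: str, to_level: str) -> str:
        """Map a node id from one level to the same or a coarser level.

        Raises :class:`ValidationError` if the label is unresolvable at
        ``from_level`` or if ``to_level`` is finer than ``from_level``.
        """
        try:
            fi, ti = LEVELS.index(from_level), LEVELS.index(to_level)
        except ValueError as exc:
            raise ValidationError(f"unknown level in {(from_level, to_level)!r}") from exc
        if ti < fi:
            raise ValidationError(
                f"cannot map from level {from_level!r} to finer level {to_level!r}"
            )
        current, level = label, from_level
        if level == "raw":
            key = normalize_label(current)
            if key not in self._component_of:
                raise ValidationError(f"unresolvable raw label {label!r}")
            if to_level == "raw":
                return current
            current, level = self._component_of[key], "component"
        if level == "component":
            if current not in self._type_of:
                raise ValidationError(f"unresolvable component {current!r}")
            if to_level == "component":
                return current
            current, level = self._type_of[current], "type"
        if current not in self._category_of_type:
            raise ValidationError(f"unresolvable type {current!r}")
        return current

    def category_of(self, label: str, level: str) -> str:
        """Category of a node id given at any level."""
        typ = self.map_label(label, level, "type")
        return self._category_of_type[typ]

    def type_of(self, component_id: str) -> str:
        if component_id not in self._type_of:
            raise ValidationError(f"unresolvable component {component_id!r}")
        return self._type_of[component_id]

    # -- (de)serialization --------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["raw_label", "component", "type", "category"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CondensationCatalog":
        required = {"raw_label", "component", "type", "category"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"catalog missing columns: {sorted(missing)}")
        return cls(df[["raw_label", "component", "type", "category"]].itertuples(index=False))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CondensationCatalog({len(self.entries)} raw labels, "
            f"{self.n_components} components, {self.n_types} types)"
        )


@dataclass
class CognitiveMap:
    """One respondent's signed directed concept graph at a stated level.

    ``edges`` maps ordered node pairs to a sign in {+1, -1}; the dict
    representation enforces at most one signed edge per ordered pair.
    ``conflict_edges`` only arises from condensation, when positive and
    negative tallies on a merged pair cancel exactly.  ``edge_tallies``
    (also condensation bookkeeping) records the (pos, neg) tallies behind
    each surviving signed edge.
    """

    respondent_id: str
    nodes: set
    edges: dict
    respondent_group: str = "other"
    level: str = "raw"
    conflict_edges: list = field(default_factory=list)
    edge_tallies: dict | None = None

    def __post_init__(self):
        self.nodes = set(self.nodes)
        self.edges = dict(self.edges)
        self.validate()

    def validate(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"map {self.respondent_id!r}: unknown level {self.level!r}")
        if self.respondent_group not in RESPONDENT_GROUPS:
            raise ValidationError(
                f"map {self.respondent_id!r}: unknown respondent group "
                f"{self.respondent_group!r}"
            )
        for (src, tgt), sign in self.edges.items():
            if src == tgt:
                raise ValidationError(f"map {self.respondent_id!r}: self-loop on {src!r}")
            if src not in self.nodes or tgt not in self.nodes:
                raise ValidationError(
                    f"map {self.respondent_id!r}: edge ({src!r}, {tgt!r}) has an "
                    "endpoint outside the node set"
                )
            if sign not in (1, -1):
                raise ValidationError(
                    f"map {self.respondent_id!r}: edge ({src!r}, {tgt!r}) has sign "
                    f"{sign!r}, expected +1 or -1"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        """Signed links only; conflict edges are excluded from link counts."""
        return len(self.edges)

    def isolated_nodes(self) -> set:
        linked = {n for pair in self.edges for n in pair}
        return self.nodes - linked

    def adjacency_frame(self, order: Sequence | None = None) -> pd.DataFrame:
        """Square signed adjacency matrix (row = cause, column = effect)."""
        order = sorted(self.nodes) if order is None else list(order)
        df = pd.DataFrame(0, index=order, columns=order, dtype=int)
        for (src, tgt), sign in self.edges.items():
            df.loc[src, tgt] = sign
        return df


@dataclass
class MapCollection:
    """A list of cognitive maps, all intended to be at the same level.

    The constructor is deliberately permissive; :func:`validate_collection`
    reports invariant breaches without repairing them.
    """

    maps: list
    catalog: CondensationCatalog | None = None

    @property
    def R(self) -> int:
        return len(self.maps)

    @property
    def respondent_ids(self) -> list[str]:
        return [m.respondent_id for m in self.maps]

    @property
    def level(self) -> str:
        levels = {m.level for m in self.maps}
        if len(levels) != 1:
            raise ValidationError(f"collection mixes levels: {sorted(levels)}")
        return levels.pop()

    def __iter__(self):
        return iter(self.maps)

    def __len__(self) -> int:
        return len(self.maps)

    def subset(self, respondent_ids: Iterable[str]) -> "MapCollection":
        wanted = set(respondent_ids)
        return MapCollection(
            maps=[m for m in self.maps if m.respondent_id in wanted],
            catalog=self.catalog,
        )


@dataclass(frozen=True)
class ValidationIssue:
    kind: str
    respondent_id: str
    detail: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_collection`; empty means valid."""

    issues: list

    @property
    def valid(self) -> bool:
        return not self.issues

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.kind, i.respondent_id, i.detail) for i in self.issues],
            columns=["kind", "respondent_id", "detail"],
        )

    def __str__(self) -> str:
        if self.valid:
            return "collection valid: no issues"
        lines = [f"{len(self.issues)} issue(s):"]
        lines += [f"  [{i.kind}] {i.respondent_id}: {i.detail}" for i in self.issues]
        return "\n".join(lines)


def validate_collection(collection: MapCollection) -> ValidationReport:
    """Report every invariant breach in a collection; repair nothing.

    Checks: duplicate respondent ids, mixed levels, self-loops, dangling
    edge endpoints, invalid signs, and (when a catalog is attached) node
    labels unresolvable at the map's level.
    """
    issues: list[ValidationIssue] = []
    seen: set = set()
    for m in collection.maps:
        if m.respondent_id in seen:
            issues.append(ValidationIssue("duplicate_respondent", m.respondent_id, "respondent id occurs more than once"))
        seen.add(m.respondent_id)
    levels = {m.level for m in collection.maps}
    if len(levels) > 1:
        issues.append(ValidationIssue("mixed_levels", "*", f"levels present: {sorted(levels)}"))
    for m in collection.maps:
        for (src, tgt), sign in m.edges.items():
            if src == tgt:
                issues.append(ValidationIssue("self_loop", m.respondent_id, f"self-loop on {src!r}"))
            if src not in m.nodes or tgt not in m.nodes:
                issues.append(ValidationIssue("dangling_edge", m.respondent_id, f"edge ({src!r}, {tgt!r}) endpoint outside node set"))
            if sign not in (1, -1):
                issues.append(ValidationIssue("bad_sign", m.respondent_id, f"edge ({src!r}, {tgt!r}) has sign {sign!r}"))
        if collection.catalog is not None:
            for node in sorted(m.nodes):
                try:
                    collection.catalog.map_label(node, m.level, m.level)
                except ValidationError:
                    issues.append(ValidationIssue("unresolvable_label", m.respondent_id, f"label {node!r} not in catalog at level {m.level!r}"))
    return ValidationReport(issues=issues)
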