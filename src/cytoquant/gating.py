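"""Hierarchical template gating.

A :class:`GatingTemplate` is a tree of :class:`GateNode` objects whose
leaves are the reported leukocyte subsets.  Gate geometries are fixed
thresholds/rectangles in linear fluorescence units (gating by a monotone
display transform is equivalent, since both the event value and the cut
would be transformed by the same map), plus a ratio band for doublet
exclusion and a threshold union for "marker A and/or marker B" leaves.

Events are pushed down the tree: an event reaching a node is offered to its
children in document order and follows the first child whose geometry it
satisfies; geometrically disjoint siblings therefore give an
order-independent assignment.  Events failing every child stop at that node
and remain unassigned — they are not errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .events import EventTable

__all__ = [
    "Threshold",
    "Rectangle",
    "RatioBand",
    "AnyOf",
    "GateNode",
    "GatingTemplate",
    "GateResult",
    "ValidationReport",
    "apply_template",
    "list_leaves",
    "validate_template",
]


# ---------------------------------------------------------------------------
# geometries (all half-open: "above" is >= cut, "below" is < cut)


@dataclass(frozen=True)
class Threshold:
    channel: str
    cut: float
    side: str = "above"  # above | below

    def __post_init__(self):
        if self.side not in ("above", "below"):
            raise ValueError(f"threshold side must be above/below, got {self.side!r}")

    def channels(self) -> list[str]:
        return [self.channel]

    def mask(self, table: EventTable) -> np.ndarray:
        x = table.column(self.channel)
        return x >= self.cut if self.side == "above" else x < self.cut


@dataclass(frozen=True)
class Rectangle:
    """Per-channel [lo, hi) bounds; a bound of None is open."""

    bounds: tuple[tuple[str, float | None, float | None], ...]

    def channels(self) -> list[str]:
        return [b[0] for b in self.bounds]

    def mask(self, table: EventTable) -> np.ndarray:
        m = np.ones(table.n_events, dtype=bool)
        for ch, lo, hi in self.bounds:
            x = table.column(ch)
            if lo is not None:
                m &= x >= lo
            if hi is not None:
                m &= x < hi
        return m


@dataclass(frozen=True)
class RatioBand:
    """min <= numerator/denominator < max; nonpositive denominators fail."""

    numerator: str
    denominator: str
    min_ratio: float
    max_ratio: float

    def channels(self) -> list[str]:
        return [self.numerator, self.denominator]

    def mask(self, table: EventTable) -> np.ndarray:
        num = table.column(self.numerator)
        den = table.column(self.denominator)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
        return (ratio >= self.min_ratio) & (ratio < self.max_ratio)


@dataclass(frozen=True)
class AnyOf:
    """Union of thresholds — pass if any holds (e.g. CD56+ and/or CD16+).

    Thresholds on channels absent from the table are skipped so a reduced
    panel still gates on the remaining markers (``validate_template``
    reports the degradation).
    """

    thresholds: tuple[Threshold, ...]

    def channels(self) -> list[str]:
        return [t.channel for t in self.thresholds]

    def mask(self, table: EventTable) -> np.ndarray:
        m = np.zeros(table.n_events, dtype=bool)
        hit = False
        for t in self.thresholds:
            if t.channel in table.channels:
                m |= t.mask(table)
                hit = True
        if not hit:
            raise KeyError(f"none of the channels {self.channels()} present in table")
        return m


Geometry = Threshold | Rectangle | RatioBand | AnyOf


@dataclass
class GateNode:
    """One node of the gating tree.

    ``geometry`` None means pass-through (used for the root).  ``requires``
    lists channels needed for the node's *interpretation* beyond its own
    geometry (e.g. a subset defined by being negative for everything else
    is only trustworthy when the excluding marker was in the panel).
    """

    name: str
    geometry: Geometry | None = None
    children: list["GateNode"] = field(default_factory=list)
    requires: tuple[str, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self):
        yield self
        for child in self.children:
            yield from child.iter_nodes()


@dataclass
class GatingTemplate:
    """Gating tree for one tube; leaves carry the subset population codes."""

    tube: str  # innate | adaptive | custom
    root: GateNode
    phenotypes: dict[str, str] = field(default_factory=dict)  # leaf code -> immunophenotype

    def leaves(self) -> list[GateNode]:
        return [n for n in self.root.iter_nodes() if n.is_leaf]

    def channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for node in self.root.iter_nodes():
            if node.geometry is not None:
                for ch in node.geometry.channels():
                    seen.setdefault(ch, None)
        return list(seen)

    # -- JSON round-trip ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        def enc_geom(g: Geometry | None):
            if g is None:
                return None
            if isinstance(g, Threshold):
                return {"kind": "threshold", "channel": g.channel, "cut": g.cut, "side": g.side}
            if isinstance(g, Rectangle):
                return {"kind": "rectangle",
                        "bounds": [[c, lo, hi] for c, lo, hi in g.bounds]}
            if isinstance(g, RatioBand):
                return {"kind": "ratio_band", "numerator": g.numerator,
                        "denominator": g.denominator,
                        "min_ratio": g.min_ratio, "max_ratio": g.max_ratio}
            if isinstance(g, AnyOf):
                return {"kind": "any_of",
                        "thresholds": [enc_geom(t) for t in g.thresholds]}
            raise TypeError(type(g))

        def enc_node(n: GateNode):
            return {"name": n.name, "geometry": enc_geom(n.geometry),
                    "requires": list(n.requires),
                    "children": [enc_node(c) for c in n.children]}

        text = json.dumps({"tube": self.tube, "root": enc_node(self.root),
                           "phenotypes": self.phenotypes}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GatingTemplate":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        obj = json.loads(text)

        def dec_geom(g):
            if g is None:
                return None
            kind = g["kind"]
            if kind == "threshold":
                return Threshold(g["channel"], g["cut"], g.get("side", "above"))
            if kind == "rectangle":
                return Rectangle(tuple((c, lo, hi) for c, lo, hi in g["bounds"]))
            if kind == "ratio_band":
                return RatioBand(g["numerator"], g["denominator"],
                                 g["min_ratio"], g["max_ratio"])
            if kind == "any_of":
                return AnyOf(tuple(dec_geom(t) for t in g["thresholds"]))
            raise ValueError(f"unknown geometry kind {kind!r}")

        def dec_node(n):
            return GateNode(n["name"], dec_geom(n["geometry"]),
                            [dec_node(c) for c in n["children"]],
                            tuple(n.get("requires", ())))

        return cls(obj["tube"], dec_node(obj["root"]), dict(obj.get("phenotypes", {})))


@dataclass
class GateResult:
    """Per-event leaf assignment plus per-node event counts."""

    assignments: np.ndarray  # object array of leaf code or None
    node_counts: dict[str, int]
    leaf_order: list[str]

    def leaf_mask(self, code: str) -> np.ndarray:
        return self.assignments == code

    def leaf_counts(self) -> dict[str, int]:
        return {code: int(np.sum(self.assignments == code)) for code in self.leaf_order}


def apply_template(table: EventTable, template: GatingTemplate) -> GateResult:
    """Assign every event of a compensated tube to at most one leaf subset.

    Raises ``KeyError`` if a gate references a channel absent from the table
    (except within ``AnyOf`` unions, which degrade — see
    :func:`validate_template`).
    """
    for ch in template.channels():
        if ch not in table.channels:
            node_uses_anyof = any(
                isinstance(n.geometry, AnyOf) and ch in n.geometry.channels()
                and any(t.channel in table.channels for t in n.geometry.thresholds)
                for n in template.root.iter_nodes() if n.geometry is not None
            )
            if not node_uses_anyof:
                raise KeyError(f"template channel {ch!r} missing from table")

    assignments = np.full(table.n_events, None, dtype=object)
    node_counts: dict[str, int] = {}

    def descend(node: GateNode, idx: np.ndarray) -> None:
        node_counts[node.name] = node_counts.get(node.name, 0) + idx.size
        if node.is_leaf:
            assignments[idx] = node.name
            return
        remaining = idx
        for child in node.children:
            if remaining.size == 0:
                node_counts.setdefault(child.name, 0)
                for n in child.iter_nodes():
                    node_counts.setdefault(n.name, 0)
                continue
            mask = child.geometry.mask(table) if child.geometry is not None else \
                np.ones(table.n_events, dtype=bool)
            taken = remaining[mask[remaining]]
            descend(child, taken)
            keep = ~np.isin(remaining, taken, assume_unique=True)
            remaining = remaining[keep]

    start = np.arange(table.n_events)
    root_mask = template.root.geometry.mask(table) if template.root.geometry is not None \
        else np.ones(table.n_events, dtype=bool)
    descend(template.root, start[root_mask])
    leaf_order = [leaf.name for leaf in template.leaves()]
    return GateResult(assignments, node_counts, leaf_order)


def list_leaves(template: GatingTemplate) -> list[str]:
    """Ordered leaf population codes."""
    return [leaf.name for leaf in template.leaves()]


@dataclass
class ValidationReport:
    unknown_channels: list[str] = field(default_factory=list)
    duplicate_leaves: list[str] = field(default_factory=list)
    unavailable_leaves: list[str] = field(default_factory=list)
    degraded_leaves: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.unknown_channels or self.duplicate_leaves
                    or self.unavailable_leaves)


def validate_template(template: GatingTemplate, panel: list[str]) -> ValidationReport:
    """Check a template against a panel's channel list.

    Reports unknown channels, duplicate leaf names, and leaves that become
    unavailable on a reduced panel: a leaf is unavailable when a hard
    geometry channel or a ``requires`` channel is missing, and degraded when
    only part of an ``AnyOf`` union is missing.
    """
    report = ValidationReport()
    panel_set = set(panel)
    missing = [ch for ch in template.channels() if ch not in panel_set]
    report.unknown_channels = []

    leaves = template.leaves()
    seen: set[str] = set()
    for leaf in leaves:
        if leaf.name in seen:
            report.duplicate_leaves.append(leaf.name)
            report.messages.append(f"duplicate leaf name {leaf.name!r}")
        seen.add(leaf.name)

    def path_to(target: GateNode) -> list[GateNode]:
        def walk(node, trail):
            trail = trail + [node]
            if node is target:
                return trail
            for c in node.children:
                got = walk(c, trail)
                if got:
                    return got
            return None
        return walk(template.root, []) or []

    for leaf in leaves:
        hard_missing: list[str] = []
        degraded = False
        for node in path_to(leaf):
            geom = node.geometry
            if geom is None:
                req = list(node.requires)
            else:
                if isinstance(geom, AnyOf):
                    present = [t.channel for t in geom.thresholds if t.channel in panel_set]
                    absent = [t.channel for t in geom.thresholds if t.channel not in panel_set]
                    if not present:
                        hard_missing += absent
                    elif absent:
                        degraded = True
                        report.messages.append(
                            f"leaf {leaf.name!r}: union gate at {node.name!r} reduced "
                            f"to {present} (missing {absent})")
                    req = list(node.requires)
                else:
                    hard_missing += [c for c in geom.channels() if c not in panel_set]
                    req = list(node.requires)
            hard_missing += [c for c in req if c not in panel_set]
        if hard_missing:
            report.unavailable_leaves.append(leaf.name)
            report.messages.append(
                f"leaf {leaf.name!r} unavailable: panel lacks {sorted(set(hard_missing))}")
        elif degraded:
            report.degraded_leaves.append(leaf.name)

    report.unknown_channels = sorted(set(missing))
    for ch in report.unknown_channels:
        report.messages.append(f"channel {ch!r} not in panel")
    return report
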