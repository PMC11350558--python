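"""Declarative panel and gating-hierarchy model.

A *panel* is a fixed set of antibody-fluorochrome conjugates measured
simultaneously on one blood sample; a *gating hierarchy* is the tree of
per-channel threshold gates that resolves the panel's reported immune
subsets.  Three built-in configurations ship with the package (myeloid,
lymphoid, intracellular), each carrying 14 markers; the two
peripheral-blood hierarchies jointly define 42 reported subset variables.

Gates are conjunctions of per-channel threshold conditions (rectangle
gates in transformed intensity space).  Free-hand polygon gates drawn in
acquisition software are not representable here by design: threshold
conjunctions are deterministic, serializable and reviewable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml

SCHEMA_VERSION = 1

#: relations a condition may take on a channel, in transformed space
RELATIONS = ("positive", "negative", "high", "intermediate", "low")
#: relations that require two ordered thresholds on the channel
TWO_THRESHOLD_RELATIONS = ("high", "intermediate", "low")

PANEL_ROLES = ("surface", "intracellular", "viability")

BUILTIN_PANELS = ("myeloid", "lymphoid", "intracellular")


class PanelConfigError(ValueError):
    """Raised when a panel/hierarchy configuration violates the schema.

    Carries *all* violations found, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid panel configuration:\n  - " + "\n  - ".join(self.violations)
        )


@dataclass(frozen=True)
class MarkerSpec:
    """One antibody-fluorochrome assignment within a panel."""

    marker_name: str
    channel_label: str
    panel_role: str = "surface"

    def __post_init__(self):
        if self.panel_role not in PANEL_ROLES:
            raise ValueError(f"unknown panel_role {self.panel_role!r}")


@dataclass(frozen=True)
class GateCondition:
    """A single per-channel threshold condition, AND-ed within a node.

    ``relation`` semantics (transformed intensity x, ties to the
    higher/positive side):

    * positive:      x >= t
    * negative:      x <  t
    * high:          x >= t_upper
    * intermediate:  t_lower <= x < t_upper
    * low:           x <  t_lower
    """

    channel: str
    relation: str
    threshold_source: str = "auto"  # auto | fixed
    fixed_value: float | None = None
    fixed_upper: float | None = None  # second threshold for 3-level fixed gates

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.threshold_source not in ("auto", "fixed"):
            raise ValueError(f"unknown threshold_source {self.threshold_source!r}")

    @property
    def needs_two_thresholds(self) -> bool:
        return self.relation in TWO_THRESHOLD_RELATIONS


@dataclass
class GateNode:
    """A node of the gating tree; its member set is its parent's set
    intersected with all of its conditions."""

    node_name: str
    conditions: list[GateCondition] = field(default_factory=list)
    reported: bool = False
    children: list["GateNode"] = field(default_factory=list)
    parent: "GateNode | None" = field(default=None, repr=False, compare=False)

    def walk(self) -> Iterator["GateNode"]:
        """Yield this node and all descendants, depth-first, parents first."""
        yield self
        for child in self.children:
            yield from child.walk()

    def path_conditions(self) -> list[GateCondition]:
        """All conditions on the root-to-this-node path (root first)."""
        chain: list[GateCondition] = []
        node: GateNode | None = self
        stack = []
        while node is not None:
            stack.append(node)
            node = node.parent
        for n in reversed(stack):
            chain.extend(n.conditions)
        return chain


@dataclass
class GatingHierarchy:
    """The gating tree for one panel.

    ``scatter_gate`` is the root intact-cell rectangle: channel ->
    (low, high) bounds in linear scatter units.  ``leukocyte_node``
    names the node used as denominator for fraction-of-leukocytes
    (the CD45+ gate in the peripheral panels).
    """

    panel_name: str
    root: GateNode
    scatter_gate: dict[str, tuple[float, float]] = field(default_factory=dict)
    leukocyte_node: str | None = None

    def nodes(self) -> list[GateNode]:
        return list(self.root.walk())

    def node_names(self) -> list[str]:
        return [n.node_name for n in self.nodes()]

    def reported_nodes(self) -> list[GateNode]:
        return [n for n in self.nodes() if n.reported]

    def get(self, name: str) -> GateNode:
        for n in self.nodes():
            if n.node_name == name:
                return n
        raise KeyError(name)

    def channels_used(self) -> set[str]:
        used: set[str] = set(self.scatter_gate)
        for n in self.nodes():
            used.update(c.channel for c in n.conditions)
        return used

    def channel_levels(self) -> dict[str, int]:
        """Number of expression levels (2 or 3) each gated channel needs,
        derived from the relations used on it anywhere in the tree."""
        levels: dict[str, int] = {}
        for n in self.nodes():
            for c in n.conditions:
                k = 3 if c.needs_two_thresholds else 2
                levels[c.channel] = max(levels.get(c.channel, 2), k)
        return levels


@dataclass
class PanelDefinition:
    """A named panel: marker/channel registry plus scatter channels."""

    panel_name: str
    markers: list[MarkerSpec]
    scatter_channels: list[str] = field(default_factory=lambda: ["FSC", "SSC"])

    def marker_names(self) -> list[str]:
        return [m.marker_name for m in self.markers]

    def channel_for(self, marker_name: str) -> str:
        for m in self.markers:
            if m.marker_name == marker_name:
                return m.channel_label
        raise KeyError(marker_name)

    @property
    def all_channels(self) -> list[str]:
        """Gateable axes: marker names plus scatter channels.

        Event tables are keyed by marker name (the analysis-facing label);
        the fluorochrome/detector label is registry metadata.
        """
        return self.marker_names() + list(self.scatter_channels)


# ---------------------------------------------------------------------------
# validation


def validate(panel: PanelDefinition, hierarchy: GatingHierarchy) -> list[str]:
    """Return every invariant violation of the pair (empty list = valid)."""
    errs: list[str] = []

    names = panel.marker_names()
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        errs.append(f"duplicate marker names in panel: {sorted(dupes)}")
    chans = [m.channel_label for m in panel.markers]
    dupc = {c for c in chans if chans.count(c) > 1}
    if dupc:
        errs.append(f"duplicate detector channels in panel: {sorted(dupc)}")
    for m in panel.markers:
        if not m.marker_name:
            errs.append("empty marker_name in panel")

    if panel.panel_name in BUILTIN_PANELS and len(panel.markers) != 14:
        errs.append(
            f"panel {panel.panel_name!r} must carry 14 markers, has {len(panel.markers)}"
        )

    known = set(panel.all_channels)
    node_names = hierarchy.node_names()
    dup_nodes = {n for n in node_names if node_names.count(n) > 1}
    if dup_nodes:
        errs.append(f"duplicate node names in hierarchy: {sorted(dup_nodes)}")
    for node in hierarchy.nodes():
        for cond in node.conditions:
            if cond.channel not in known:
                errs.append(
                    f"node {node.node_name!r}: condition on unknown channel "
                    f"{cond.channel!r}"
                )
            if cond.threshold_source == "fixed" and cond.fixed_value is None:
                errs.append(
                    f"node {node.node_name!r}: fixed threshold on "
                    f"{cond.channel!r} without fixed_value"
                )
            if (
                cond.threshold_source == "fixed"
                and cond.needs_two_thresholds
                and cond.fixed_upper is None
            ):
                errs.append(
                    f"node {node.node_name!r}: relation {cond.relation!r} on "
                    f"{cond.channel!r} needs two fixed thresholds"
                )
    for ch in hierarchy.scatter_gate:
        if ch not in panel.scatter_channels:
            errs.append(f"scatter gate on non-scatter channel {ch!r}")
    if hierarchy.leukocyte_node is not None and hierarchy.leukocyte_node not in node_names:
        errs.append(f"leukocyte_node {hierarchy.leukocyte_node!r} not in hierarchy")
    if hierarchy.panel_name != panel.panel_name:
        errs.append(
            f"hierarchy panel {hierarchy.panel_name!r} != panel {panel.panel_name!r}"
        )
    return errs


# ---------------------------------------------------------------------------
# (de)serialization


def _node_from_dict(d: dict, parent: GateNode | None, errs: list[str]) -> GateNode:
    conds = []
    for c in d.get("conditions", []) or []:
        try:
            conds.append(
                GateCondition(
                    channel=str(c["channel"]),
                    relation=str(c["relation"]),
                    threshold_source=str(c.get("threshold_source", "auto")),
                    fixed_value=c.get("fixed_value"),
                    fixed_upper=c.get("fixed_upper"),
                )
            )
        except (KeyError, ValueError) as e:
            errs.append(f"node {d.get('name')!r}: bad condition {c!r} ({e})")
    node = GateNode(
        node_name=str(d["name"]),
        conditions=conds,
        reported=bool(d.get("reported", False)),
        parent=parent,
    )
    for ch in d.get("children", []) or []:
        node.children.append(_node_from_dict(ch, node, errs))
    return node


def _node_to_dict(node: GateNode) -> dict:
    d: dict = {"name": node.node_name}
    if node.reported:
        d["reported"] = True
    if node.conditions:
        d["conditions"] = []
        for c in node.conditions:
            cd: dict = {"channel": c.channel, "relation": c.relation}
            if c.threshold_source != "auto":
                cd["threshold_source"] = c.threshold_source
            if c.fixed_value is not None:
                cd["fixed_value"] = c.fixed_value
            if c.fixed_upper is not None:
                cd["fixed_upper"] = c.fixed_upper
            d["conditions"].append(cd)
    if node.children:
        d["children"] = [_node_to_dict(ch) for ch in node.children]
    return d


def parse_panel_config(doc: dict) -> tuple[PanelDefinition, GatingHierarchy]:
    """Build and validate a panel + hierarchy from a parsed YAML document."""
    errs: list[str] = []
    if doc.get("schema_version") != SCHEMA_VERSION:
        errs.append(
            f"schema_version {doc.get('schema_version')!r} unsupported "
            f"(expected {SCHEMA_VERSION})"
        )
    pd = doc.get("panel")
    hd = doc.get("hierarchy")
    if not isinstance(pd, dict) or not isinstance(hd, dict):
        raise PanelConfigError(errs + ["document must contain 'panel' and 'hierarchy' maps"])

    markers = []
    for m in pd.get("markers", []) or []:
        try:
            markers.append(
                MarkerSpec(
                    marker_name=str(m["marker"]),
                    channel_label=str(m["channel"]),
                    panel_role=str(m.get("role", "surface")),
                )
            )
        except (KeyError, ValueError) as e:
            errs.append(f"bad marker entry {m!r} ({e})")
    panel = PanelDefinition(
        panel_name=str(pd.get("name", "")),
        markers=markers,
        scatter_channels=[str(s) for s in pd.get("scatter_channels", ["FSC", "SSC"])],
    )

    root = _node_from_dict(hd["root"], None, errs)
    scatter_gate = {
        str(ch): (float(lo), float(hi))
        for ch, (lo, hi) in (hd.get("scatter_gate") or {}).items()
    }
    hierarchy = GatingHierarchy(
        panel_name=str(hd.get("panel", pd.get("name", ""))),
        root=root,
        scatter_gate=scatter_gate,
        leukocyte_node=hd.get("leukocyte_node"),
    )
    errs.extend(validate(panel, hierarchy))
    if errs:
        raise PanelConfigError(errs)
    return panel, hierarchy


def load_panel_config(path: str | Path) -> tuple[PanelDefinition, GatingHierarchy]:
    """Load and validate a panel/hierarchy configuration file.

    Raises ``FileNotFoundError`` for a missing file and
    ``PanelConfigError`` enumerating every schema violation otherwise.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise PanelConfigError([f"{path}: not a mapping document"])
    return parse_panel_config(doc)


def save_panel_config(
    panel: PanelDefinition, hierarchy: GatingHierarchy, path: str | Path
) -> None:
    """Serialize a panel/hierarchy pair; round-trips through load."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "panel": {
            "name": panel.panel_name,
            "scatter_channels": list(panel.scatter_channels),
            "markers": [
                {"marker": m.marker_name, "channel": m.channel_label, "role": m.panel_role}
                for m in panel.markers
            ],
        },
        "hierarchy": {
            "panel": hierarchy.panel_name,
            "leukocyte_node": hierarchy.leukocyte_node,
            "scatter_gate": {
                ch: [float(lo), float(hi)]
                for ch, (lo, hi) in hierarchy.scatter_gate.items()
            },
            "root": _node_to_dict(hierarchy.root),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_builtin(name: str) -> tuple[PanelDefinition, GatingHierarchy]:
    """Load one of the shipped panels: myeloid, lymphoid or intracellular."""
    if name not in BUILTIN_PANELS:
        raise KeyError(f"no built-in panel {name!r}; have {BUILTIN_PANELS}")
    ref = resources.files("immunogate") / "panels" / f"{name}.panel.yaml"
    doc = yaml.safe_load(ref.read_text())
    return parse_panel_config(doc)


def count_reported_subsets(hierarchies: list[GatingHierarchy]) -> int:
    """Number of distinct reported subset variables across hierarchies.

    The same subset name reported by two hierarchies in one call is an
    error (reported variables must be unambiguous in a combined table).
    """
    seen: dict[str, str] = {}
    dupes: list[str] = []
    for h in hierarchies:
        for n in h.reported_nodes():
            if n.node_name in seen and seen[n.node_name] != h.panel_name:
                dupes.append(n.node_name)
            seen[n.node_name] = h.panel_name
    if dupes:
        raise ValueError(f"reported subset names duplicated across panels: {sorted(set(dupes))}")
    return len(seen)
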