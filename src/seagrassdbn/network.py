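"""Discrete dynamic Bayesian network structure and expert-elicited CPTs.

A two-slice DBN is described by a set of nodes with ordered discrete state
spaces, directed edges within a monthly time slice, and inter-slice edges
from slice t-1 to slice t.  Conditional probability tables are elicited from
domain experts as *rule tables*: each row is a scenario over the parent
nodes (a single state, a set of states such as a month group, or NA meaning
"any state") together with one linguistic certainty label per child state.
Compilation expands the rules over the full Cartesian product of parent
states, replaces labels by numeric weights and renormalises each row.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "MONTHS",
    "DEFAULT_LABEL_MAP",
    "LABEL_RANKING",
    "NodeSpec",
    "CptRule",
    "CptRuleTable",
    "Cpt",
    "NetworkSpec",
    "NetworkError",
    "CompletenessError",
    "OverlapError",
    "LabelMappingError",
    "StructureError",
    "SchemaError",
    "compile_cpt",
    "load_network",
    "load_label_map",
    "validate_network",
    "default_network_path",
    "load_default_network",
]

MONTHS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
          "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")

#: Linguistic certainty labels and their numeric probability weights.
#: "extremely likely" and "impossible" are set by symmetry with
#: "extremely unlikely" = 0.01; the map is configurable but must stay
#: strictly monotone in the ranking below.
DEFAULT_LABEL_MAP: dict[str, float] = {
    "extremely likely": 0.99,
    "very likely": 5 / 6,
    "likely": 2 / 3,
    "50/50": 0.5,
    "unlikely": 1 / 3,
    "very unlikely": 1 / 6,
    "extremely unlikely": 0.01,
    "impossible": 0.0,
}

#: Labels ordered from most to least certain.
LABEL_RANKING = (
    "extremely likely", "very likely", "likely", "50/50",
    "unlikely", "very unlikely", "extremely unlikely", "impossible",
)

THEMES = ("site_condition", "environmental", "resistance",
          "recovery", "population", "other")


class NetworkError(ValueError):
    """Base class for network definition problems."""


class CompletenessError(NetworkError):
    """A parent-state combination is matched by no rule."""


class OverlapError(NetworkError):
    """A parent-state combination is matched by more than one rule."""


class LabelMappingError(NetworkError):
    """A rule uses a linguistic label absent from the label map."""


class StructureError(NetworkError):
    """The intra-slice graph is cyclic or edges reference unknown nodes."""


class SchemaError(NetworkError):
    """A node, state space or CPT violates the schema."""


@dataclass(frozen=True)
class NodeSpec:
    """A discrete node: name, ordered state labels and display theme."""

    name: str
    states: tuple[str, ...]
    temporal: bool = False
    theme: str = "other"

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise SchemaError(f"node {self.name!r} needs >=2 states, "
                              f"got {list(self.states)}")
        if len(set(self.states)) != len(self.states):
            raise SchemaError(f"node {self.name!r} has duplicate state labels")
        if self.theme not in THEMES:
            raise SchemaError(f"node {self.name!r}: unknown theme {self.theme!r}")


# An antecedent is None (NA: any state), a single state label, or a
# frozenset of state labels (e.g. a month group).
Antecedent = None | str | frozenset


@dataclass(frozen=True)
class CptRule:
    """One elicited scenario row: antecedents per parent, one label per child state."""

    antecedents: tuple[Antecedent, ...]
    labels: tuple[str, ...]

    def matches(self, assignment: tuple[str, ...]) -> bool:
        for ant, state in zip(self.antecedents, assignment):
            if ant is None:
                continue
            if isinstance(ant, frozenset):
                if state not in ant:
                    return False
            elif ant != state:
                return False
        return True


@dataclass(frozen=True)
class CptRuleTable:
    """Expert rule table for one child node."""

    child: str
    parents: tuple[str, ...]
    rows: tuple[CptRule, ...]


@dataclass(frozen=True)
class Cpt:
    """Compiled conditional probability table.

    ``values`` has shape ``(*parent_cards, n_child_states)``; axis order
    follows ``parents``.  Root nodes have ``parents == ()`` and a 1-D table.
    """

    child: str
    parents: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    child_states: tuple[str, ...]
    values: np.ndarray

    def __getitem__(self, assignment: Mapping[str, str] | tuple[str, ...]) -> np.ndarray:
        if isinstance(assignment, Mapping):
            assignment = tuple(assignment[p] for p in self.parents)
        idx = tuple(self.parent_states[i].index(s) for i, s in enumerate(assignment))
        return self.values[idx]

    def combinations(self):
        """Iterate (parent assignment tuple, probability vector)."""
        for combo in itertools.product(*self.parent_states):
            yield combo, self[combo]


def _check_label_map(label_map: Mapping[str, float]) -> None:
    ranked = [label_map[l] for l in LABEL_RANKING if l in label_map]
    for a, b in zip(ranked, ranked[1:]):
        if not a > b:
            raise LabelMappingError(
                "label map must be strictly decreasing along "
                f"{LABEL_RANKING}; got {dict(label_map)}")
    for label, v in label_map.items():
        if not 0.0 <= v <= 1.0:
            raise LabelMappingError(f"label {label!r} weight {v} outside [0, 1]")


def compile_cpt(
    rules: CptRuleTable,
    parent_states: Sequence[Sequence[str]],
    child_states: Sequence[str],
    label_map: Mapping[str, float] | None = None,
) -> Cpt:
    """Expand a rule table into a full, row-normalised CPT.

    Every combination of parent states must be matched by exactly one rule
    (NA and state-set antecedents are enumerated); linguistic labels are
    replaced by their numeric weights and each resulting row is divided by
    its sum, so elicited odds are preserved while rows become proper
    distributions.

    Raises
    ------
    CompletenessError
        if some parent combination matches no rule.
    OverlapError
        if some combination matches more than one rule.
    LabelMappingError
        if a rule label is not in ``label_map`` or the map is not monotone.
    """
    if label_map is None:
        label_map = DEFAULT_LABEL_MAP
    _check_label_map(label_map)

    parent_states = tuple(tuple(s) for s in parent_states)
    child_states = tuple(child_states)
    if len(parent_states) != len(rules.parents):
        raise SchemaError(
            f"CPT for {rules.child!r}: {len(rules.parents)} parents declared "
            f"but {len(parent_states)} state spaces given")

    # Pre-resolve labels to weights once per rule.
    rule_weights: list[np.ndarray] = []
    for rule in rules.rows:
        if len(rule.labels) != len(child_states):
            raise SchemaError(
                f"CPT for {rules.child!r}: rule has {len(rule.labels)} labels "
                f"for {len(child_states)} child states")
        try:
            w = np.array([label_map[l.lower()] for l in rule.labels], dtype=float)
        except KeyError as exc:
            raise LabelMappingError(
                f"CPT for {rules.child!r}: unknown label {exc.args[0]!r}") from None
        rule_weights.append(w)

    cards = tuple(len(s) for s in parent_states)
    values = np.empty(cards + (len(child_states),), dtype=float)
    for idx in itertools.product(*(range(c) for c in cards)):
        combo = tuple(parent_states[i][j] for i, j in enumerate(idx))
        hits = [k for k, rule in enumerate(rules.rows) if rule.matches(combo)]
        if not hits:
            raise CompletenessError(
                f"CPT for {rules.child!r}: no rule covers parent combination "
                f"{dict(zip(rules.parents, combo))}")
        if len(hits) > 1:
            raise OverlapError(
                f"CPT for {rules.child!r}: rules {hits} all match "
                f"{dict(zip(rules.parents, combo))}")
        w = rule_weights[hits[0]]
        total = w.sum()
        if total <= 0:
            raise SchemaError(
                f"CPT for {rules.child!r}: all-zero row for combination "
                f"{dict(zip(rules.parents, combo))}")
        values[idx] = w / total

    return Cpt(rules.child, rules.parents, parent_states, child_states, values)


@dataclass
class NetworkSpec:
    """A validated two-slice DBN.

    ``inter_edges`` are (source, target) pairs read as source at slice t-1
    feeding target at slice t.  ``initial`` optionally gives a slice-1 prior
    for nodes that have inter-slice parents (uniform otherwise).
    """

    nodes: dict[str, NodeSpec]
    intra_edges: tuple[tuple[str, str], ...]
    inter_edges: tuple[tuple[str, str], ...]
    cpts: dict[str, Cpt]
    initial: dict[str, np.ndarray] = field(default_factory=dict)
    name: str = "network"

    def intra_parents(self, node: str) -> tuple[str, ...]:
        return tuple(s for s, t in self.intra_edges if t == node)

    def inter_parents(self, node: str) -> tuple[str, ...]:
        return tuple(s for s, t in self.inter_edges if t == node)

    def interface(self) -> tuple[str, ...]:
        """Nodes whose slice-t value is consumed by slice t+1."""
        seen: list[str] = []
        for s, _ in self.inter_edges:
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def states(self, node: str) -> tuple[str, ...]:
        return self.nodes[node].states

    def intra_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.intra_edges)
        return g

    def initial_distribution(self, node: str) -> np.ndarray:
        """Slice-1 prior for a node with inter-slice parents."""
        if node in self.initial:
            return self.initial[node]
        k = len(self.states(node))
        return np.full(k, 1.0 / k)

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.intra_graph()))


def validate_network(net: NetworkSpec) -> list[str]:
    """Return a human-readable finding per invariant violation (empty if valid)."""
    findings: list[str] = []
    g = net.intra_graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        findings.append(f"intra-slice graph has a cycle: {cycle}")
    for s, t in net.intra_edges + net.inter_edges:
        for n in (s, t):
            if n not in net.nodes:
                findings.append(f"edge ({s}, {t}) references unknown node {n!r}")
    for name in net.nodes:
        cpt = net.cpts.get(name)
        if cpt is None:
            findings.append(f"node {name!r} has no CPT")
            continue
        expected = net.intra_parents(name) + net.inter_parents(name)
        if tuple(sorted(cpt.parents)) != tuple(sorted(expected)):
            findings.append(
                f"node {name!r}: CPT parents {cpt.parents} != graph parents {expected}")
        if cpt.child_states != net.states(name):
            findings.append(f"node {name!r}: CPT child states mismatch node states")
        flat = cpt.values.reshape(-1, cpt.values.shape[-1])
        if np.any(flat < -1e-12) or np.any(flat > 1 + 1e-12):
            findings.append(f"node {name!r}: CPT entries outside [0, 1]")
        bad = np.abs(flat.sum(axis=1) - 1.0) > 1e-9
        if bad.any():
            findings.append(
                f"node {name!r}: {int(bad.sum())} CPT row(s) do not sum to 1")
    for name, prior in net.initial.items():
        if name not in net.nodes:
            findings.append(f"initial distribution for unknown node {name!r}")
        elif len(prior) != len(net.states(name)) or abs(prior.sum() - 1) > 1e-9:
            findings.append(f"initial distribution for {name!r} is not a distribution")
    return findings


# --------------------------------------------------------------------------
# Network definition files
# --------------------------------------------------------------------------

def _parse_antecedent(raw, parent: str, states: Sequence[str]) -> Antecedent:
    if raw is None or (isinstance(raw, str) and raw.strip().upper() == "NA"):
        return None
    if isinstance(raw, (list, tuple)):
        bad = [s for s in raw if s not in states]
        if bad:
            raise SchemaError(f"antecedent states {bad} not in parent {parent!r} "
                              f"state space {list(states)}")
        return frozenset(raw)
    if raw not in states:
        raise SchemaError(f"antecedent {raw!r} not a state of parent {parent!r}")
    return str(raw)


def load_label_map(path: str | Path) -> dict[str, float]:
    """Read a label -> weight override file (YAML mapping)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError(f"label map file {path} must be a mapping")
    label_map = {str(k).lower(): float(v) for k, v in raw.items()}
    _check_label_map(label_map)
    return label_map


def load_network(path: str | Path,
                 label_map: Mapping[str, float] | None = None) -> NetworkSpec:
    """Load and fully compile a network definition file (YAML).

    The file has sections ``nodes`` (name, states, optional theme),
    ``edges`` (intra-slice), ``inter_edges``, optional ``initial`` priors and
    ``cpt_rules`` keyed by child node.  CPT rule rows mirror the elicitation
    table dialect: a list of antecedents (state, list of states, or NA), one
    per parent, and one linguistic label per child state.  Inter-slice
    parents are referenced as ``name[-1]``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError(f"network file {path} must be a mapping")
    if label_map is None and "label_map" in raw:
        label_map = {str(k).lower(): float(v) for k, v in raw["label_map"].items()}

    nodes: dict[str, NodeSpec] = {}
    for nd in raw.get("nodes", []):
        states = tuple(str(s) for s in nd.get("states", ()))
        if not states:
            raise SchemaError(f"node {nd.get('name')!r} has an empty state list")
        spec = NodeSpec(name=str(nd["name"]), states=states,
                        theme=str(nd.get("theme", "other")))
        if spec.name in nodes:
            raise SchemaError(f"duplicate node {spec.name!r}")
        nodes[spec.name] = spec

    def _known(n: str) -> str:
        if n not in nodes:
            raise SchemaError(f"edge references unknown node {n!r}")
        return n

    intra = tuple((_known(s), _known(t)) for s, t in raw.get("edges", []))
    inter = tuple((_known(s), _known(t)) for s, t in raw.get("inter_edges", []))

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(intra)
    if not nx.is_directed_acyclic_graph(g):
        raise StructureError(f"intra-slice graph has a cycle: {nx.find_cycle(g)}")
    dual = set(intra) & set(inter)
    if dual:
        raise SchemaError(
            f"edges {sorted(dual)} appear both within and across slices; "
            "a parent must be either contemporaneous or lagged, not both")

    temporal_targets = {t for _, t in inter}
    nodes = {n: NodeSpec(s.name, s.states, n in temporal_targets, s.theme)
             for n, s in nodes.items()}

    initial: dict[str, np.ndarray] = {}
    for n, prior in (raw.get("initial") or {}).items():
        _known(n)
        p = np.asarray(prior, dtype=float)
        if p.shape != (len(nodes[n].states),) or abs(p.sum() - 1) > 1e-9:
            raise SchemaError(f"initial prior for {n!r} is not a distribution "
                              f"over {nodes[n].states}")
        initial[n] = p

    cpts: dict[str, Cpt] = {}
    for child, block in (raw.get("cpt_rules") or {}).items():
        _known(child)
        declared = tuple(str(p) for p in block.get("parents", ()))
        parent_names: list[str] = []
        for p in declared:
            base = p[:-4] if p.endswith("[-1]") else p
            _known(base)
            parent_names.append(base)
        expected = set(nx.DiGraph(intra).predecessors(child)) if intra else set()
        expected |= {s for s, t in inter if t == child}
        if set(parent_names) != expected:
            raise SchemaError(
                f"CPT for {child!r}: declared parents {parent_names} do not match "
                f"graph parents {sorted(expected)}")
        spaces = [nodes[p].states for p in parent_names]
        rows = []
        for row in block.get("rows", ()):
            ants = row.get("antecedents", [])
            if len(ants) != len(parent_names):
                raise SchemaError(
                    f"CPT for {child!r}: row has {len(ants)} antecedents for "
                    f"{len(parent_names)} parents")
            parsed = tuple(_parse_antecedent(a, p, nodes[p].states)
                           for a, p in zip(ants, parent_names))
            labels = tuple(str(l) for l in row["labels"])
            rows.append(CptRule(parsed, labels))
        table = CptRuleTable(child, tuple(parent_names), tuple(rows))
        cpts[child] = compile_cpt(table, spaces, nodes[child].states, label_map)

    missing = set(nodes) - set(cpts)
    if missing:
        raise SchemaError(f"nodes without CPT rules: {sorted(missing)}")

    net = NetworkSpec(nodes=nodes, intra_edges=intra, inter_edges=inter,
                      cpts=cpts, initial=initial,
                      name=str(raw.get("name", Path(path).stem)))
    findings = validate_network(net)
    if findings:
        raise SchemaError("network failed validation: " + "; ".join(findings))
    return net


def default_network_path(light_states: int = 2) -> Path:
    """Path of the shipped reduced Zostera network (2- or 3-state light)."""
    if light_states not in (2, 3):
        raise ValueError("light_states must be 2 or 3")
    return Path(__file__).parent / "data" / f"default_network_{light_states}state.yaml"


def load_default_network(light_states: int = 2,
                         label_map: Mapping[str, float] | None = None) -> NetworkSpec:
    return load_network(default_network_path(light_states), label_map=label_map)
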