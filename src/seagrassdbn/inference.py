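"""Exact inference on the unrolled monthly DBN.

The two-slice network is unrolled over T monthly steps.  Hard evidence
(site conditions, the cyclic time-of-year indicator) enters as indicator
factors; monthly light probabilities enter as soft *virtual* evidence, i.e.
likelihood factors over the light node's states.  Posterior marginals for
the shoot-density node are computed exactly with an interface
forward-backward sweep: all within-slice variables are eliminated in
temporal order, so the messages live on the (small) set of nodes with
outgoing inter-slice edges.  This is ordinary variable elimination with a
temporal ordering and is exact for any discrete network of this shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import MONTHS, NetworkSpec, SchemaError

__all__ = [
    "Factor",
    "EvidenceSchedule",
    "PosteriorTrajectory",
    "StateValueMap",
    "DEFAULT_STATE_VALUES",
    "InconsistentEvidenceError",
    "unroll",
    "UnrolledDBN",
    "infer_marginals",
    "weighted_mean",
    "run_scenario",
    "month_cycle",
]


class InconsistentEvidenceError(ValueError):
    """The supplied evidence has zero probability under the model."""


Var = tuple[str, int]  # (node name, slice index, 1-based)


class Factor:
    """A non-negative table over a tuple of discrete variables."""

    __slots__ = ("vars", "cards", "values")

    def __init__(self, vars: Sequence[Var], cards: Sequence[int], values: np.ndarray):
        self.vars = tuple(vars)
        self.cards = tuple(cards)
        self.values = np.asarray(values, dtype=float).reshape(self.cards)

    @classmethod
    def ones(cls) -> "Factor":
        return cls((), (), np.array(1.0))

    def __mul__(self, other: "Factor") -> "Factor":
        out_vars = list(self.vars)
        out_cards = list(self.cards)
        for v, c in zip(other.vars, other.cards):
            if v not in out_vars:
                out_vars.append(v)
                out_cards.append(c)
        a = self._expand(out_vars, out_cards)
        b = other._expand(out_vars, out_cards)
        return Factor(out_vars, out_cards, a * b)

    def _expand(self, out_vars: list[Var], out_cards: list[int]) -> np.ndarray:
        if not self.vars:
            return self.values
        pos = [out_vars.index(v) for v in self.vars]
        order = sorted(range(len(self.vars)), key=lambda i: pos[i])
        arr = np.transpose(self.values, order)
        own = set(self.vars)
        shape = [c if v in own else 1 for v, c in zip(out_vars, out_cards)]
        return arr.reshape(shape)

    def marginalize(self, keep: Sequence[Var]) -> "Factor":
        """Sum out every variable not in ``keep``."""
        keep = [v for v in self.vars if v in set(keep)]
        axes = tuple(i for i, v in enumerate(self.vars) if v not in keep)
        values = self.values.sum(axis=axes) if axes else self.values
        cards = tuple(c for v, c in zip(self.vars, self.cards) if v in keep)
        return Factor(keep, cards, values)

    def normalize(self) -> "Factor":
        z = self.values.sum()
        if z <= 0:
            raise InconsistentEvidenceError(
                "evidence combination has zero probability")
        return Factor(self.vars, self.cards, self.values / z)


def _product(factors: Sequence[Factor]) -> Factor:
    out = Factor.ones()
    for f in factors:
        out = out * f
    return out


def indicator(var: Var, card: int, state_idx: int) -> Factor:
    v = np.zeros(card)
    v[state_idx] = 1.0
    return Factor((var,), (card,), v)


def likelihood(var: Var, weights: np.ndarray) -> Factor:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or np.any(w < 0) or not np.any(w > 0):
        raise ValueError("soft evidence must be a non-negative vector with "
                         "at least one positive entry")
    return Factor((var,), (len(w),), w)


@dataclass
class EvidenceSchedule:
    """Evidence entering the unrolled network.

    ``hard`` fixes a node to one state in every slice (site conditions).
    ``cyclic`` gives a repeating state sequence; slice t uses entry
    ``(t-1) % len(seq)`` (the time-of-year indicator).  ``soft`` gives a
    repeating array of likelihood vectors, one row per step of the cycle
    (12 rows for monthly light evidence aligned with the cyclic months, or
    T rows for a full schedule).  ``hard_at`` pins a node at one specific
    slice.
    """

    hard: dict[str, str] = field(default_factory=dict)
    cyclic: dict[str, Sequence[str]] = field(default_factory=dict)
    soft: dict[str, np.ndarray] = field(default_factory=dict)
    hard_at: dict[tuple[str, int], str] = field(default_factory=dict)

    def factors_at(self, net: NetworkSpec, t: int) -> list[Factor]:
        out: list[Factor] = []
        for node, state in self.hard.items():
            states = net.states(node)
            out.append(indicator((node, t), len(states), states.index(state)))
        for node, seq in self.cyclic.items():
            states = net.states(node)
            state = seq[(t - 1) % len(seq)]
            out.append(indicator((node, t), len(states), states.index(state)))
        for node, arr in self.soft.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                arr = arr[None, :]
            if arr.shape[1] != len(net.states(node)):
                raise SchemaError(
                    f"soft evidence for {node!r} has {arr.shape[1]} entries for "
                    f"{len(net.states(node))} states")
            out.append(likelihood((node, t), arr[(t - 1) % arr.shape[0]]))
        for (node, when), state in self.hard_at.items():
            if when == t:
                states = net.states(node)
                out.append(indicator((node, t), len(states), states.index(state)))
        return out

    def check(self, net: NetworkSpec) -> None:
        for node in (*self.hard, *self.cyclic, *self.soft,
                     *(n for n, _ in self.hard_at)):
            if node not in net.nodes:
                raise SchemaError(f"evidence on unknown node {node!r}")
        for node, state in self.hard.items():
            if state not in net.states(node):
                raise SchemaError(f"hard evidence state {state!r} not a state "
                                  f"of {node!r}")


def _slice_factors(net: NetworkSpec, t: int) -> list[Factor]:
    """CPT factors for slice t; slice 1 uses initial priors for temporal nodes."""
    out: list[Factor] = []
    intra = set(net.intra_edges)
    for node in net.nodes:
        cpt = net.cpts[node]
        states = net.states(node)
        if t == 1 and net.inter_parents(node):
            out.append(Factor(((node, 1),), (len(states),),
                              net.initial_distribution(node)))
            continue
        vars: list[Var] = []
        cards: list[int] = []
        for p in cpt.parents:
            lag = 0 if (p, node) in intra else 1
            vars.append((p, t - lag))
            cards.append(len(net.states(p)))
        vars.append((node, t))
        cards.append(len(states))
        out.append(Factor(vars, cards, cpt.values))
    return out


@dataclass
class UnrolledDBN:
    """The fully unrolled model: time-indexed variables, factors and DAG."""

    variables: list[Var]
    cards: dict[Var, int]
    factors: list[Factor]
    graph: nx.DiGraph

    @property
    def node_count(self) -> int:
        return len(self.variables)


def unroll(net: NetworkSpec, T: int,
           evidence: EvidenceSchedule | None = None) -> UnrolledDBN:
    """Unroll the two-slice network over T monthly slices."""
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    variables = [(n, t) for t in range(1, T + 1) for n in net.nodes]
    cards = {(n, t): len(net.states(n)) for n, t in variables}
    factors: list[Factor] = []
    g = nx.DiGraph()
    g.add_nodes_from(variables)
    for t in range(1, T + 1):
        factors.extend(_slice_factors(net, t))
        if evidence is not None:
            factors.extend(evidence.factors_at(net, t))
        for s, d in net.intra_edges:
            g.add_edge((s, t), (d, t))
        if t > 1:
            for s, d in net.inter_edges:
                g.add_edge((s, t - 1), (d, t))
    return UnrolledDBN(variables, cards, factors, g)


@dataclass
class PosteriorTrajectory:
    """Posterior marginals of one query node at every monthly step."""

    node: str
    states: tuple[str, ...]
    probs: np.ndarray            # (T, n_states)
    months: np.ndarray           # 1..T
    calendar_months: list[str] | None = None
    burn_in: int = 0

    @property
    def T(self) -> int:
        return len(self.months)

    def response(self) -> "PosteriorTrajectory":
        """The trajectory restricted to post-initialization months."""
        keep = self.months > self.burn_in
        return PosteriorTrajectory(
            self.node, self.states, self.probs[keep], self.months[keep],
            [m for m, k in zip(self.calendar_months, keep) if k]
            if self.calendar_months else None, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.months):
            for j, s in enumerate(self.states):
                rows.append({
                    "month_index": int(m),
                    "calendar_month": (self.calendar_months[i]
                                       if self.calendar_months else None),
                    "state": s,
                    "probability": self.probs[i, j],
                    "is_burn_in": bool(m <= self.burn_in),
                })
        return pd.DataFrame(rows)


def infer_marginals(net: NetworkSpec, evidence: EvidenceSchedule | None,
                    T: int, query: str = "shoot_density") -> PosteriorTrajectory:
    """Exact posterior marginals of ``query`` at every slice given all evidence.

    Runs an interface forward-backward pass: forward messages are joint
    beliefs over the inter-slice interface; backward messages carry the
    likelihood of future evidence.  The result equals full joint enumeration.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if query not in net.nodes:
        raise SchemaError(f"query node {query!r} not in network")
    if evidence is None:
        evidence = EvidenceSchedule()
    evidence.check(net)

    interface = net.interface()

    def slice_bundle(t: int) -> list[Factor]:
        return _slice_factors(net, t) + evidence.factors_at(net, t)

    # Forward: alpha[t] is an unnormalised factor over the interface at t.
    alphas: list[Factor] = [Factor.ones()]
    for t in range(1, T + 1):
        phi = _product([alphas[t - 1], *slice_bundle(t)])
        keep = [(n, t) for n in interface]
        alpha = phi.marginalize(keep)
        z = alpha.values.sum()
        if z <= 0:
            raise InconsistentEvidenceError(
                f"evidence up to month {t} has zero probability")
        alphas.append(Factor(alpha.vars, alpha.cards, alpha.values / z))

    # Backward: beta[t] over the interface at t (beta[T] = 1).
    betas: list[Factor | None] = [None] * (T + 1)
    betas[T] = Factor.ones()
    for t in range(T, 1, -1):
        phi = _product([*slice_bundle(t), betas[t]])
        keep = [(n, t - 1) for n in interface]
        beta = phi.marginalize(keep)
        z = beta.values.max()
        if z <= 0:
            raise InconsistentEvidenceError(
                f"evidence from month {t} onwards has zero probability")
        betas[t - 1] = Factor(beta.vars, beta.cards, beta.values / z)

    probs = np.empty((T, len(net.states(query))))
    for t in range(1, T + 1):
        phi = _product([alphas[t - 1], *slice_bundle(t), betas[t]])
        marg = phi.marginalize([(query, t)]).normalize()
        # marginalize keeps factor axis order; single var -> direct
        probs[t - 1] = marg.values
    return PosteriorTrajectory(query, net.states(query), probs,
                               np.arange(1, T + 1))


# --------------------------------------------------------------------------
# Weighted-mean aggregation of state trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StateValueMap:
    """Numeric shoot-density ranges per state (shoots per square metre).

    The expectation uses range midpoints; the interquartile range treats
    each month's marginal as a mixture of uniform distributions over the
    state ranges (a zero-width range is a point mass).
    """

    ranges: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        spans = sorted(self.ranges.values())
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise SchemaError(f"state ranges overlap: {spans}")
        for lo, hi in spans:
            if hi < lo or lo < 0:
                raise SchemaError(f"invalid state range ({lo}, {hi})")

    def midpoint(self, state: str) -> float:
        lo, hi = self.ranges[state]
        return 0.5 * (lo + hi)

    def states_ascending(self) -> list[str]:
        return sorted(self.ranges, key=self.midpoint)

    def discretize(self, density: float) -> str:
        """Map a shoot density to its state (edges belong to the lower state)."""
        if density < 0:
            raise ValueError(f"negative shoot density {density}")
        best = None
        for state in self.states_ascending():
            lo, hi = self.ranges[state]
            if density <= hi:
                return state
            best = state
        return best  # above the top range: clamp to the highest state


#: Default shoot-density discretization (shoots per square metre).
DEFAULT_STATE_VALUES = StateValueMap({
    "Zero": (0.0, 0.0),
    "Low": (0.0, 200.0),
    "Moderate": (200.0, 600.0),
    "High": (600.0, 1200.0),
})


def _mixture_quantile(q: float, states: Sequence[str], p: np.ndarray,
                      values: StateValueMap) -> float:
    order = sorted(range(len(states)), key=lambda i: values.midpoint(states[i]))
    acc = 0.0
    for i in order:
        lo, hi = values.ranges[states[i]]
        if p[i] <= 0:
            continue
        if acc + p[i] >= q:
            if hi == lo:
                return lo
            return lo + (q - acc) / p[i] * (hi - lo)
        acc += p[i]
    # numerical slack: return upper end of the topmost occupied range
    occupied = [i for i in order if p[i] > 0]
    return values.ranges[states[occupied[-1]]][1]


def weighted_mean(traj: PosteriorTrajectory,
                  values: StateValueMap = DEFAULT_STATE_VALUES) -> pd.DataFrame:
    """Expected shoot density and interquartile range per month.

    The expectation is sum_state p(state) * midpoint(state); the 25th/75th
    percentiles come from the mixture of within-state uniform distributions.
    """
    missing = set(traj.states) - set(values.ranges)
    if missing:
        raise SchemaError(f"state value map missing states {sorted(missing)}")
    mids = np.array([values.midpoint(s) for s in traj.states])
    means = traj.probs @ mids
    q25 = np.array([_mixture_quantile(0.25, traj.states, p, values)
                    for p in traj.probs])
    q75 = np.array([_mixture_quantile(0.75, traj.states, p, values)
                    for p in traj.probs])
    return pd.DataFrame({
        "month_index": traj.months,
        "weighted_mean": means,
        "iqr_low": q25,
        "iqr_high": q75,
        "is_burn_in": traj.months <= traj.burn_in,
    })


def month_cycle(start_month: str = "Jan") -> list[str]:
    """Calendar months starting at ``start_month`` (cyclic length 12)."""
    i = MONTHS.index(start_month)
    return [MONTHS[(i + k) % 12] for k in range(12)]


def run_scenario(net: NetworkSpec,
                 site_config: Mapping[str, str],
                 light_evidence: np.ndarray | None,
                 T: int,
                 burn_in: int = 24,
                 start_month: str = "Jan",
                 light_node: str = "light",
                 time_node: str = "time_of_year",
                 query: str = "shoot_density") -> PosteriorTrajectory:
    """Simulate one site scenario and return the shoot-density trajectory.

    ``site_config`` fixes the site-condition nodes (species presence,
    location type).  ``light_evidence`` is a (12, n_light_states) array of
    monthly delta vectors in Jan..Dec order, applied as virtual evidence and
    aligned with the cyclic time-of-year indicator; None runs the prior.
    Months <= ``burn_in`` are flagged as initialization.
    """
    if burn_in >= T:
        raise ValueError(f"burn_in ({burn_in}) must be < T ({T})")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    months = month_cycle(start_month)
    cyclic = {time_node: months} if time_node in net.nodes else {}
    soft = {}
    if light_evidence is not None:
        arr = np.asarray(light_evidence, dtype=float)
        if arr.shape != (12, len(net.states(light_node))):
            raise SchemaError(
                f"light evidence must be (12, {len(net.states(light_node))}), "
                f"got {arr.shape}")
        # rows arrive in Jan..Dec order; rotate to the scenario's start month
        idx = [MONTHS.index(m) for m in months]
        soft = {light_node: arr[idx]}
    ev = EvidenceSchedule(hard=dict(site_config), cyclic=cyclic, soft=soft)
    traj = infer_marginals(net, ev, T, query=query)
    traj.burn_in = burn_in
    traj.calendar_months = [months[(t - 1) % 12] for t in range(1, T + 1)]
    return traj
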