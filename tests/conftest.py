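import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seagrassdbn.network import (Cpt, CptRule, CptRuleTable, NetworkSpec,
                                 NodeSpec, load_default_network)

settings.register_profile(
    "ci", max_examples=30, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

MONTH_STATES = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")

#: The published expert rule rows for baseline shoot density: antecedents
#: (month group, species, location type, physiological status NA) and one
#: linguistic label per child state (High, Moderate, Low, Zero).
TABLE3_ROWS = [
    ((("Nov", "Dec", "Jan", "Feb"), "Z. marina", "PTST", None),
     ("extremely unlikely", "extremely unlikely", "50/50", "50/50")),
    ((("Mar", "Apr", "May"), "Z. marina", "PTST", None),
     ("unlikely", "very likely", "very unlikely", "extremely unlikely")),
    ((("Jun", "Jul"), "Z. marina", "PTST", None),
     ("very likely", "very unlikely", "extremely unlikely", "extremely unlikely")),
    ((("Aug", "Sep", "Oct"), "Z. marina", "PTST", None),
     ("50/50", "50/50", "extremely unlikely", "extremely unlikely")),
    ((("Nov", "Dec", "Jan", "Feb"), "Z. noltei", "PTIT", None),
     ("extremely unlikely", "unlikely", "likely", "extremely unlikely")),
    ((("Mar", "Apr", "May"), "Z. noltei", "PTIT", None),
     ("unlikely", "very likely", "very unlikely", "extremely unlikely")),
    ((("Jun", "Jul"), "Z. noltei", "PTIT", None),
     ("very likely", "very unlikely", "extremely unlikely", "extremely unlikely")),
    ((("Aug", "Sep", "Oct"), "Z. noltei", "PTIT", None),
     ("50/50", "50/50", "extremely unlikely", "extremely unlikely")),
]


def _rule(antecedents, labels):
    parsed = tuple(frozenset(a) if isinstance(a, tuple) else a
                   for a in antecedents)
    return CptRule(parsed, tuple(labels))


@pytest.fixture(scope="session")
def baseline_rule_table():
    """Full baseline-shoot-density rule table: the 8 published rows plus
    each species' seasonal pattern mirrored to the other location type."""
    rows = [_rule(a, l) for a, l in TABLE3_ROWS]
    mirror = {"PTST": "PTIT", "PTIT": "PTST"}
    for (months, sp, loc, _), labels in TABLE3_ROWS:
        rows.append(_rule((months, sp, mirror[loc], None), labels))
    return CptRuleTable(
        child="baseline_shoot_density",
        parents=("time_of_year", "species_presence", "location_type",
                 "physiological_status"),
        rows=tuple(rows))


@pytest.fixture(scope="session")
def baseline_parent_states():
    return [MONTH_STATES, ("Z. marina", "Z. noltei"), ("PTST", "PTIT"),
            ("good", "poor")]


DENSITY = ("High", "Moderate", "Low", "Zero")


@pytest.fixture(scope="session")
def default_net():
    return load_default_network(2)


@pytest.fixture(scope="session")
def default_net3():
    return load_default_network(3)


def random_small_dbn(rng, max_nodes=4, max_states=3, p_intra=0.5, p_inter=0.3):
    """A random two-slice network with compiled random CPTs (for oracles)."""
    n_nodes = int(rng.integers(2, max_nodes + 1))
    names = [f"n{i}" for i in range(n_nodes)]
    cards = {n: int(rng.integers(2, max_states + 1)) for n in names}
    nodes = {n: NodeSpec(n, tuple(f"s{j}" for j in range(cards[n])))
             for n in names}
    intra = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_intra:
                intra.append((names[i], names[j]))
    inter = []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if rng.random() < p_inter and (names[i], names[j]) not in intra:
                inter.append((names[i], names[j]))
    if not inter:
        inter = [(names[0], names[0])]
    cpts = {}
    for n in names:
        parents = tuple([s for s, t in intra if t == n] +
                        [s for s, t in inter if t == n])
        shape = tuple(cards[p] for p in parents) + (cards[n],)
        v = rng.random(shape) + 0.1
        v = v / v.sum(axis=-1, keepdims=True)
        cpts[n] = Cpt(n, parents, tuple(nodes[p].states for p in parents),
                      nodes[n].states, v)
    return NetworkSpec(nodes, tuple(intra), tuple(inter), cpts)


def enumerate_marginals(net, evidence, T, query):
    """Brute-force posterior marginals by full joint enumeration.

    Builds the unnormalised joint as a dense tensor by multiplying each CPT
    (and evidence vector) expanded over all time-indexed variables, then
    sums out everything but the query node per slice.  Independent of the
    package's message-passing implementation.
    """
    names = list(net.nodes)
    intra = set(net.intra_edges)
    variables = [(n, t) for t in range(1, T + 1) for n in names]
    cards = [len(net.states(n)) for n, _ in variables]
    axis = {v: i for i, v in enumerate(variables)}

    def expand(vars_, values):
        shape = [1] * len(variables)
        order = sorted(range(len(vars_)), key=lambda i: axis[vars_[i]])
        arr = np.transpose(values, order)
        for v in vars_:
            shape[axis[v]] = cards[axis[v]]
        return arr.reshape(shape)

    joint = np.ones([1] * len(variables))
    for t in range(1, T + 1):
        for n in names:
            cpt = net.cpts[n]
            if t == 1 and net.inter_parents(n):
                joint = joint * expand([(n, 1)], net.initial_distribution(n))
                continue
            vars_ = [(p, t - (0 if (p, n) in intra else 1))
                     for p in cpt.parents] + [(n, t)]
            joint = joint * expand(vars_, cpt.values)
        for f in evidence.factors_at(net, t):
            joint = joint * expand(list(f.vars), f.values)

    out = np.empty((T, len(net.states(query))))
    for t in range(1, T + 1):
        keep = axis[(query, t)]
        other = tuple(i for i in range(len(variables)) if i != keep)
        m = joint.sum(axis=other)
        out[t - 1] = m / m.sum()
    return out
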