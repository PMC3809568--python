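"""Shared fixtures and the independent brute-force attractor oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pluriscreen.boolean_dynamics import Clamp
from pluriscreen.network import SignedNetwork
from pluriscreen.synthetic_data import core_network_fixture, table1_fixture, table1_network


def brute_force_attractors(
    network: SignedNetwork,
    clamps: tuple[Clamp, ...] = (),
    inhibitor_only_sustain: bool = False,
) -> set[tuple[tuple[int, ...], ...]]:
    """All synchronous attractors by exhaustive enumeration of 2^n states.

    Deliberately independent of the package's reduced-core computation: the
    update rule is restated here from first principles and every state of
    the full space is walked.  Attractor cycles are canonically rotated to
    start at their smallest state.  Returns a set of state-tuple cycles over
    sorted node order.
    """
    nodes = network.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    clamp_map = {c.node: c.value for c in clamps}
    signatures = {n: network.regulators_of(n) for n in nodes}

    def step(state: tuple[int, ...]) -> tuple[int, ...]:
        out = []
        for n in nodes:
            if n in clamp_map:
                out.append(clamp_map[n])
                continue
            pos, neg = signatures[n]
            if not pos and not neg:
                out.append(state[idx[n]])
                continue
            if any(state[idx[r]] for r in neg):
                out.append(0)
            elif pos:
                out.append(int(any(state[idx[r]] for r in pos)))
            else:
                out.append(int(inhibitor_only_sustain))
        return tuple(out)

    states = [
        bits
        for bits in itertools.product((0, 1), repeat=len(nodes))
        if all(bits[idx[n]] == v for n, v in clamp_map.items())
    ]
    successor = {s: step(s) for s in states}

    attractors: set[tuple[tuple[int, ...], ...]] = set()
    color: dict[tuple[int, ...], int] = {}
    for start in states:
        if start in color:
            continue
        path = []
        cur = start
        while cur not in color:
            color[cur] = 1
            path.append(cur)
            cur = successor[cur]
        if color[cur] == 1:  # closed a new cycle
            i = path.index(cur)
            cycle = path[i:]
            smallest = min(range(len(cycle)), key=lambda j: cycle[j])
            attractors.add(tuple(cycle[smallest:] + cycle[:smallest]))
        for p in path:
            color[p] = 2
    return attractors


def random_signed_network(
    rng: np.random.Generator,
    n_min: int = 3,
    n_max: int = 12,
    p_activate: float = 0.15,
    p_inhibit: float = 0.10,
) -> SignedNetwork:
    n = int(rng.integers(n_min, n_max + 1))
    net = SignedNetwork()
    names = [f"N{i}" for i in range(n)]
    for name in names:
        net.add_node(name)
    for src in names:
        for dst in names:
            r = rng.random()
            if r < p_activate:
                net.add_edge(src, dst, "+")
            elif r < p_activate + p_inhibit:
                net.add_edge(src, dst, "-")
    return net


def attractor_keys(attractors, nodes) -> set[tuple[tuple[int, ...], ...]]:
    """Package attractors as canonical state-tuple cycles for comparison."""
    return {
        tuple(tuple(state[n] for n in nodes) for state in a.states)
        for a in attractors
    }


@pytest.fixture(scope="session")
def core_network():
    return core_network_fixture()


@pytest.fixture(scope="session")
def table1_rows():
    return table1_fixture()


@pytest.fixture(scope="session")
def candidate_network():
    """Core network plus the 15 tabled candidate genes with their signatures."""
    return table1_network()
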