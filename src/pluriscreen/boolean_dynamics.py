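"""Synchronous Boolean attractors under node clamps, and the steady-state matrix.

The update rule is the inhibitor-dominant convention of qualitative logical
modeling: a node with incoming edges becomes active iff at least one of its
activators is active and none of its inhibitors is; a node with no incoming
edges keeps its current value (a free input).  All nodes update
simultaneously.  Attractors of this deterministic map are fixed points or
cycles; both are collected, each cycle state as one binary vector.

Attractors are found exactly but without enumerating the full state space:
states are enumerated only over the *dynamic core* — nodes on directed cycles
of the clamped network — separately for every assignment of the free inputs.
Nodes strictly upstream of the core converge to constants and are
pre-computed in topological order; pure-output nodes downstream of the core
are back-filled by simulating the full network once per core attractor.
This reduction is exact for synchronous dynamics and is cross-checked in the
test suite against brute-force enumeration of all 2^n states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import SignedNetwork

KNOCKOUT = 0
OVEREXPRESSION = 1

PROVENANCE_COLUMNS = ("model_id", "clamped_node", "clamp_value", "attractor_idx", "state_idx")


@dataclass(frozen=True)
class Clamp:
    """Hold one node at a fixed value: 0 = knockout, 1 = over-expression."""

    node: str
    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"clamp value must be 0 or 1, got {self.value!r}")


@dataclass(frozen=True)
class Attractor:
    """A fixed point (one state) or a synchronous cycle (several states).

    ``states`` are dicts node -> 0/1; successive states are synchronous
    successors of each other, and the successor of the last is the first.
    Cycles are canonically rotated to start at their lexicographically
    smallest state (over sorted node order).
    """

    states: tuple[dict[str, int], ...]

    @property
    def kind(self) -> str:
        return "fixed" if len(self.states) == 1 else "cyclic"

    @property
    def period(self) -> int:
        return len(self.states)


@dataclass
class UpdateSemantics:
    """Switches for the Boolean update rule.

    ``inhibitor_only_sustain``: when True, a node whose regulators are all
    inhibitors is treated as carrying an implicit self-sustaining input — it
    is active iff no inhibitor is active.  Default False: such a node has no
    active activator and is therefore inactive unless clamped.
    """

    inhibitor_only_sustain: bool = False


DEFAULT_SEMANTICS = UpdateSemantics()


class DynamicCoreTooLarge(RuntimeError):
    """The exact reduction would still need too many enumerated states."""


class _DynamicsContext:
    """Per-network precomputation shared across clamp runs of one screen."""

    def __init__(self, network: SignedNetwork):
        self.network = network
        self.nodes: list[str] = network.nodes
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.signatures = {n: network.regulators_of(n) for n in self.nodes}
        self.successors: dict[str, set[str]] = {n: set() for n in self.nodes}
        self.predecessors: dict[str, set[str]] = {n: set() for n in self.nodes}
        for e in network.edges:
            self.successors[e.source].add(e.target)
            self.predecessors[e.target].add(e.source)
        self.graph = network.to_networkx()

    def reach(self, sources: set[str], adjacency: dict[str, set[str]],
              blocked: set[str]) -> set[str]:
        """Multi-source reachability, never passing through blocked nodes."""
        seen: set[str] = set()
        stack = [n for s in sources for n in adjacency[s] if n not in blocked]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(m for m in adjacency[n] if m not in blocked and m not in seen)
        return seen


def _check_clamps(network: SignedNetwork, clamps) -> dict[str, int]:
    clamp_map: dict[str, int] = {}
    for clamp in clamps:
        if clamp.node not in network:
            raise ValueError(f"clamped node {clamp.node!r} is not in the network")
        if clamp.node in clamp_map and clamp_map[clamp.node] != clamp.value:
            raise ValueError(f"inconsistent clamps on node {clamp.node!r}")
        clamp_map[clamp.node] = clamp.value
    return clamp_map


def synchronous_step(
    state: dict[str, int],
    network: SignedNetwork,
    clamps: tuple[Clamp, ...] | list[Clamp] = (),
    semantics: UpdateSemantics = DEFAULT_SEMANTICS,
) -> dict[str, int]:
    """One synchronous update of all nodes.

    Clamped nodes take their clamp value; input-free nodes keep their value;
    every other node applies the inhibitor-dominant rule to the current state.
    """
    clamp_map = _check_clamps(network, clamps)
    missing = [n for n in network.nodes if n not in state]
    if missing:
        raise ValueError(f"state is not total; missing nodes {missing[:5]}")
    nxt: dict[str, int] = {}
    for node in network.nodes:
        if node in clamp_map:
            nxt[node] = clamp_map[node]
            continue
        pos, neg = network.regulators_of(node)
        if not pos and not neg:
            nxt[node] = state[node]
            continue
        inhibited = any(state[r] for r in neg)
        if pos:
            activated = any(state[r] for r in pos)
        else:
            activated = semantics.inhibitor_only_sustain
        nxt[node] = int(activated and not inhibited)
    return nxt


def _canonical_rotation(cycle: list[tuple[int, ...]]) -> tuple[tuple[int, ...], ...]:
    """Rotate a state cycle to start at its lexicographically smallest state."""
    start = min(range(len(cycle)), key=lambda i: cycle[i])
    return tuple(cycle[start:] + cycle[:start])


def _attractors_of_successor(succ: np.ndarray) -> list[list[int]]:
    """All cycles of a functional graph given as a successor array.

    Standard three-color walk: follow successors marking the current path;
    a revisit inside the path closes a new cycle, a hit on a finished node
    drains into a known attractor.
    """
    n = succ.shape[0]
    color = np.zeros(n, dtype=np.int8)  # 0 unseen, 1 on current path, 2 done
    cycles: list[list[int]] = []
    for start in range(n):
        if color[start]:
            continue
        path: list[int] = []
        s = start
        while color[s] == 0:
            color[s] = 1
            path.append(s)
            s = int(succ[s])
        if color[s] == 1:  # new cycle discovered within this path
            idx = path.index(s)
            cycles.append(path[idx:])
        for visited in path:
            color[visited] = 2
    return cycles


def compute_attractors(
    network: SignedNetwork,
    clamps: tuple[Clamp, ...] | list[Clamp] = (),
    semantics: UpdateSemantics = DEFAULT_SEMANTICS,
    core_ceiling: int = 22,
    _context: _DynamicsContext | None = None,
) -> list[Attractor]:
    """The complete set of synchronous attractors of the clamped system.

    Free inputs (unclamped nodes without incoming edges) are enumerated over
    both values — each assignment conditions its own attractor set, so a
    network with m free inputs has at least 2^m attractors.  Output order is
    deterministic (sorted by the canonical first state over sorted nodes).

    Raises :class:`DynamicCoreTooLarge` if the number of cycle nodes plus
    free inputs exceeds ``core_ceiling`` (the enumeration would need more
    than 2^ceiling states); re-run with a larger ceiling for an exact result
    on bigger cores.
    """
    if len(network) == 0:
        raise ValueError("network is empty")
    ctx = _context if _context is not None else _DynamicsContext(network)
    clamp_map = _check_clamps(network, clamps)
    nodes = ctx.nodes

    clamped = set(clamp_map)
    unclamped = [n for n in nodes if n not in clamped]
    free_inputs = sorted(
        n for n in unclamped if not ctx.predecessors[n]
    )

    # Cycle nodes of the clamped network: members of nontrivial SCCs or
    # self-loop nodes, excluding clamped nodes (their value never changes).
    sub = ctx.graph.subgraph(unclamped)
    cyclic: set[str] = set()
    for scc in nx.strongly_connected_components(sub):
        if len(scc) > 1:
            cyclic |= scc
        else:
            (n,) = scc
            if n in ctx.successors[n]:
                cyclic.add(n)

    # The dynamic core is every node whose long-run value can vary AND that
    # feeds a cycle: the cycle nodes themselves plus nodes lying on a path
    # from one cyclic component to another (fed by a cycle, feeding a cycle).
    # Core inputs are then core nodes or converged constants, so the core
    # successor map is self-contained.
    desc_of_cyclic = ctx.reach(cyclic, ctx.successors, clamped)
    anc_of_cyclic = ctx.reach(cyclic, ctx.predecessors, clamped)
    dynamic = cyclic | (desc_of_cyclic & anc_of_cyclic)
    core = sorted(dynamic)
    k = len(core)
    m = len(free_inputs)
    if k + m > core_ceiling:
        raise DynamicCoreTooLarge(
            f"dynamic core has {k} cycle nodes + {m} free inputs "
            f"(> ceiling {core_ceiling}); pass core_ceiling={k + m} for an exact run"
        )

    # Downstream of the core: values are functions of the attractor, back-filled
    # later.  Everything else converges to constants per input assignment.
    downstream = (desc_of_cyclic - dynamic) - clamped
    upstream = [
        n for n in nodes
        if n not in clamped and n not in dynamic
        and n not in downstream and n not in free_inputs
    ]
    upstream_order = list(nx.topological_sort(ctx.graph.subgraph(upstream)))

    signatures = ctx.signatures

    def rule(pos_active: bool, has_pos: bool, neg_active: bool) -> int:
        if neg_active:
            return 0
        if has_pos:
            return int(pos_active)
        return int(semantics.inhibitor_only_sustain)

    attractors: list[Attractor] = []
    core_index = {n: i for i, n in enumerate(core)}
    n_states = 1 << k
    states_arr = np.arange(n_states, dtype=np.int64)

    for assignment in range(1 << m):
        const: dict[str, int] = dict(clamp_map)
        for i, n in enumerate(free_inputs):
            const[n] = (assignment >> i) & 1
        # upstream nodes converge to unique constants (their inputs are
        # constants or earlier upstream nodes; the induced graph is acyclic)
        for n in upstream_order:
            pos, neg = signatures[n]
            const[n] = rule(
                any(const[r] for r in pos), bool(pos), any(const[r] for r in neg)
            )

        if k == 0:
            # no cycles: the whole system settles into one fixed point
            state = {n: const[n] for n in nodes}
            attractors.append(Attractor(states=(state,)))
            continue

        # vectorized successor over all 2^k core states
        succ = np.zeros(n_states, dtype=np.int64)
        for n in core:
            pos, neg = signatures[n]
            pos_mask = 0
            neg_mask = 0
            ext_pos = False
            ext_neg = False
            for r in pos:
                if r in core_index:
                    pos_mask |= 1 << core_index[r]
                elif const[r]:
                    ext_pos = True
            for r in neg:
                if r in core_index:
                    neg_mask |= 1 << core_index[r]
                elif const[r]:
                    ext_neg = True
            if ext_neg or (not pos and not semantics.inhibitor_only_sustain):
                continue  # node is constantly 0 in the core map
            if pos:
                active = ext_pos | ((states_arr & pos_mask) != 0)
            else:
                active = np.ones(n_states, dtype=bool)  # inhibitor_only_sustain
            if neg_mask:
                active &= (states_arr & neg_mask) == 0
            np.bitwise_or(succ, np.where(active, 1 << core_index[n], 0), out=succ)

        for cycle in _attractors_of_successor(succ):
            attractors.append(
                _backfill(ctx, core, const, cycle, downstream, semantics)
            )

    attractors.sort(key=lambda a: tuple(tuple(s[n] for n in nodes) for s in a.states))
    return attractors


def _backfill(
    ctx: _DynamicsContext,
    core: list[str],
    const: dict[str, int],
    core_cycle: list[int],
    downstream: set[str],
    semantics: UpdateSemantics,
) -> Attractor:
    """Recover the full attractor from a core cycle.

    Downstream nodes are delayed Boolean functions of the core trajectory, so
    simulating the full network from any state whose core projection lies on
    the cycle converges to the unique full attractor above it.  Only
    downstream and core nodes are actually updated; everything else is a
    constant of this run.
    """
    nodes = ctx.nodes
    index = ctx.index
    state = [0] * len(nodes)
    for n, v in const.items():
        state[index[n]] = v
    for i, n in enumerate(core):
        state[index[n]] = (core_cycle[0] >> i) & 1

    if not downstream:
        cycle_states = []
        for code in core_cycle:
            s = list(state)
            for i, n in enumerate(core):
                s[index[n]] = (code >> i) & 1
            cycle_states.append(tuple(s))
        canon = _canonical_rotation(cycle_states)
        return Attractor(
            states=tuple({n: t[i] for i, n in enumerate(nodes)} for t in canon)
        )

    # indexed update tables for the nodes that change in this run
    active_nodes = [n for n in nodes if n in downstream or n in set(core)]
    tables = []
    for n in active_nodes:
        pos, neg = ctx.signatures[n]
        tables.append(
            (index[n], [index[r] for r in pos], [index[r] for r in neg], bool(pos))
        )
    sustain = semantics.inhibitor_only_sustain

    seen: dict[tuple[int, ...], int] = {}
    trajectory: list[tuple[int, ...]] = []
    limit = len(nodes) + 5 * len(core_cycle) + 10
    for _ in range(limit + 1):
        key = tuple(state)
        if key in seen:
            cycle = trajectory[seen[key]:]
            canon = _canonical_rotation(cycle)
            return Attractor(
                states=tuple({n: t[i] for i, n in enumerate(nodes)} for t in canon)
            )
        seen[key] = len(trajectory)
        trajectory.append(key)
        nxt = list(state)
        for i, pos_idx, neg_idx, has_pos in tables:
            if any(state[j] for j in neg_idx):
                nxt[i] = 0
            elif has_pos:
                nxt[i] = int(any(state[j] for j in pos_idx))
            else:
                nxt[i] = int(sustain)
        state = nxt
    raise RuntimeError("back-fill simulation did not close a cycle (internal error)")


def perturbation_screen(
    network: SignedNetwork,
    model_id: str = "",
    semantics: UpdateSemantics = DEFAULT_SEMANTICS,
    core_ceiling: int = 22,
    encoding: str = "binary",
    deduplicate: bool = False,
) -> pd.DataFrame:
    """Knock out and over-express every regulatory node; stack all attractors.

    Every node with at least one outgoing edge is clamped once to 0 and once
    to 1; each attractor state of each run contributes one row of the
    steady-state matrix.  Columns are the provenance fields
    (model_id, clamped_node, clamp_value, attractor_idx, state_idx) followed
    by one 0/1 column per node in sorted order.

    ``encoding="summary"`` emits instead one row per attractor with 0.5 in
    oscillating node columns.  ``deduplicate=True`` drops rows identical in
    their node columns across runs (default keeps the plain concatenation).
    """
    if encoding not in ("binary", "summary"):
        raise ValueError(f"unknown encoding {encoding!r}")
    ctx = _DynamicsContext(network)
    nodes = ctx.nodes
    rows: list[list] = []
    for node in network.regulatory_nodes():
        for value in (KNOCKOUT, OVEREXPRESSION):
            found = compute_attractors(
                network, (Clamp(node, value),), semantics, core_ceiling, _context=ctx
            )
            for a_idx, attractor in enumerate(found):
                if encoding == "summary":
                    values = [
                        float(attractor.states[0][n])
                        if len({s[n] for s in attractor.states}) == 1
                        else 0.5
                        for n in nodes
                    ]
                    rows.append([model_id, node, value, a_idx, 0, *values])
                else:
                    for s_idx, state in enumerate(attractor.states):
                        rows.append(
                            [model_id, node, value, a_idx, s_idx,
                             *(state[n] for n in nodes)]
                        )
    matrix = pd.DataFrame(rows, columns=[*PROVENANCE_COLUMNS, *nodes])
    if deduplicate:
        matrix = matrix.drop_duplicates(subset=nodes, ignore_index=True)
    return matrix


def node_columns(matrix: pd.DataFrame) -> list[str]:
    """The node (state) columns of a steady-state matrix."""
    return [c for c in matrix.columns if c not in PROVENANCE_COLUMNS]
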