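"""Signed directed regulatory networks.

The central container of the package: a set of named nodes, each tagged with a
role (``core`` literature gene, ``cluster`` of co-regulated genes, or plain
``gene``), plus signed directed edges where ``+`` denotes activation and ``-``
denotes inhibition.  Edges carry qualitative regulation only — both direct and
indirect effects, as inferred from perturbation experiments, are represented
the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

ACTIVATION = "+"
INHIBITION = "-"
SIGNS = (ACTIVATION, INHIBITION)

ROLE_CORE = "core"
ROLE_CLUSTER = "cluster"
ROLE_GENE = "gene"
ROLES = (ROLE_CORE, ROLE_CLUSTER, ROLE_GENE)


@dataclass(frozen=True, order=True)
class SignedEdge:
    """A directed regulatory interaction with a qualitative sign."""

    source: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}, got {self.sign!r}")


@dataclass
class SignedNetwork:
    """Nodes with role tags plus a set of signed directed edges.

    At most one edge is allowed per (source, target) pair; adding a second
    edge with a conflicting sign raises unless explicitly resolved upstream.
    """

    roles: dict[str, str] = field(default_factory=dict)
    edges: set[SignedEdge] = field(default_factory=set)

    def __post_init__(self) -> None:
        for node, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for node {node!r}")
        for e in self.edges:
            self._check_endpoints(e)
        self._check_unique_pairs()

    # -- construction ------------------------------------------------------

    def add_node(self, node: str, role: str = ROLE_GENE) -> None:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        existing = self.roles.get(node)
        if existing is not None and existing != role:
            raise ValueError(
                f"node {node!r} already has role {existing!r}, cannot retag as {role!r}"
            )
        self.roles[node] = role

    def add_edge(self, source: str, target: str, sign: str) -> SignedEdge:
        edge = SignedEdge(source, target, sign)
        self._check_endpoints(edge)
        for e in self.edges:
            if e.source == source and e.target == target and e.sign != sign:
                raise ValueError(
                    f"conflicting edge {source}->{target}: have {e.sign}, adding {sign}"
                )
        self.edges.add(edge)
        return edge

    def _check_endpoints(self, edge: SignedEdge) -> None:
        for endpoint in (edge.source, edge.target):
            if endpoint not in self.roles:
                raise ValueError(f"edge endpoint {endpoint!r} is not a node")

    def _check_unique_pairs(self) -> None:
        pairs = [(e.source, e.target) for e in self.edges]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (source, target) pair with conflicting signs")

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """All node names in sorted (deterministic) order."""
        return sorted(self.roles)

    def nodes_with_role(self, role: str) -> list[str]:
        return sorted(n for n, r in self.roles.items() if r == role)

    @property
    def core_nodes(self) -> list[str]:
        return self.nodes_with_role(ROLE_CORE)

    @property
    def cluster_nodes(self) -> list[str]:
        return self.nodes_with_role(ROLE_CLUSTER)

    def sorted_edges(self) -> list[SignedEdge]:
        return sorted(self.edges)

    def in_edges(self, node: str) -> list[SignedEdge]:
        return sorted(e for e in self.edges if e.target == node)

    def out_edges(self, node: str) -> list[SignedEdge]:
        return sorted(e for e in self.edges if e.source == node)

    def regulators_of(self, node: str) -> tuple[frozenset[str], frozenset[str]]:
        """Signed incoming-edge signature: (activator set, inhibitor set)."""
        pos = frozenset(e.source for e in self.edges
                        if e.target == node and e.sign == ACTIVATION)
        neg = frozenset(e.source for e in self.edges
                        if e.target == node and e.sign == INHIBITION)
        return pos, neg

    def regulatory_nodes(self) -> list[str]:
        """Nodes with at least one outgoing edge."""
        sources = {e.source for e in self.edges}
        return sorted(sources)

    def in_degree(self, node: str) -> int:
        return sum(1 for e in self.edges if e.target == node)

    def __contains__(self, node: str) -> bool:
        return node in self.roles

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.roles)

    # -- conversions -------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node, role=self.roles[node])
        for e in self.sorted_edges():
            g.add_edge(e.source, e.target, sign=e.sign)
        return g

    def copy(self) -> "SignedNetwork":
        return SignedNetwork(roles=dict(self.roles), edges=set(self.edges))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return self.roles == other.roles and self.edges == other.edges


def network_from_edges(
    edges: Iterable[tuple[str, str, str]],
    roles: dict[str, str] | None = None,
    default_role: str = ROLE_GENE,
) -> SignedNetwork:
    """Build a network from (source, target, sign) triples.

    Nodes named in `roles` get that role; any other endpoint gets
    `default_role`.
    """
    net = SignedNetwork()
    for node, role in (roles or {}).items():
        net.add_node(node, role)
    for source, target, sign in edges:
        for endpoint in (source, target):
            if endpoint not in net:
                net.add_node(endpoint, default_role)
        net.add_edge(source, target, sign)
    return net
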