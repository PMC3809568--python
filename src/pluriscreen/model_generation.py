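"""Enumerate candidate models: reduced network plus one feedback edge.

Each candidate model hypothesizes a single new regulation from a terminal
cluster node (a group of co-regulated receptor/ligand genes, which in the
reduced network only receives edges) back onto a core regulator, closing a
feedback loop.  For every (cluster, core target) pair both an activating and
an inhibiting edge are tried, so the ensemble has |clusters| x |targets| x 2
members, each differing from the shared base network by exactly one edge.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .network import ACTIVATION, INHIBITION, ROLE_CLUSTER, ROLE_CORE, SignedEdge, SignedNetwork
from .synthetic_data import Table1Row, core_network_fixture, table1_fixture

logger = logging.getLogger(__name__)

#: Which core nodes receive candidate feedback edges: "core" = every core
#: node; "regulators" = only core nodes with at least one outgoing edge.
TARGET_POLICIES = ("core", "regulators")


def model_id(cluster: str, target: str, sign: str) -> str:
    return f"{cluster}__{sign}{target}"


@dataclass(frozen=True)
class CandidateModel:
    """The shared reduced network plus exactly one cluster->core edge.

    Models never mutate the base: :meth:`network` materializes a fresh copy
    with the added edge, so the ensemble can share one base object safely.
    """

    id: str
    base: SignedNetwork
    added_edge: SignedEdge

    def __post_init__(self) -> None:
        edge = self.added_edge
        if self.base.roles.get(edge.source) != ROLE_CLUSTER:
            raise ValueError(f"model {self.id}: edge source {edge.source!r} is not a cluster node")
        if self.base.roles.get(edge.target) != ROLE_CORE:
            raise ValueError(f"model {self.id}: edge target {edge.target!r} is not a core node")
        if edge in self.base.edges:
            raise ValueError(f"model {self.id}: added edge already present in the base network")

    @property
    def cluster(self) -> str:
        return self.added_edge.source

    @property
    def target(self) -> str:
        return self.added_edge.target

    @property
    def sign(self) -> str:
        return self.added_edge.sign

    def network(self) -> SignedNetwork:
        net = self.base.copy()
        net.add_edge(self.added_edge.source, self.added_edge.target, self.added_edge.sign)
        return net


def enumerate_models(
    reduced: SignedNetwork,
    target_policy: str = "core",
) -> list[CandidateModel]:
    """The full candidate ensemble, in deterministic order.

    Clusters and targets are iterated in sorted order, activation before
    inhibition, giving exactly |clusters| x |targets| x 2 models.  An empty
    cluster set yields an empty ensemble with a logged warning.
    """
    if target_policy not in TARGET_POLICIES:
        raise ValueError(f"target_policy must be one of {TARGET_POLICIES}")
    clusters = reduced.cluster_nodes
    if target_policy == "core":
        targets = reduced.core_nodes
    else:
        outgoing = set(reduced.regulatory_nodes())
        targets = [n for n in reduced.core_nodes if n in outgoing]
    if not targets:
        raise ValueError("reduced network has no core target nodes")
    if not clusters:
        logger.warning("reduced network has no cluster nodes; empty ensemble returned")
        return []
    models = []
    for cluster in clusters:
        for target in targets:
            for sign in (ACTIVATION, INHIBITION):
                models.append(
                    CandidateModel(
                        id=model_id(cluster, target, sign),
                        base=reduced,
                        added_edge=SignedEdge(cluster, target, sign),
                    )
                )
    return models


_PROPOSAL_RE = re.compile(r"^\s*(->|→|-\||—\||⊣)\s*(\S+)\s*$")
_PROPOSAL_SIGNS = {"->": ACTIVATION, "→": ACTIVATION, "-|": INHIBITION, "—|": INHIBITION, "⊣": INHIBITION}


def parse_proposal(proposal: str) -> tuple[str, str]:
    """Parse a proposed-regulation string into (target, sign).

    Accepts ASCII and typographic arrow forms: "-> ACTA" / "→ ACTA" for
    activation, "-| FGF2" / "—| FGF2" / "⊣ FGF2" for inhibition.
    """
    m = _PROPOSAL_RE.match(proposal)
    if not m:
        raise ValueError(f"malformed proposal string {proposal!r}")
    arrow, target = m.groups()
    return target, _PROPOSAL_SIGNS[arrow]


def model_from_table1(
    row: Table1Row,
    base: SignedNetwork | None = None,
) -> CandidateModel:
    """Materialize the candidate model a fixture row was selected with.

    The added edge runs from the row's cluster node to the proposed core
    target with the proposed sign.  When ``base`` is omitted, the default
    core plus the fixture's eight cluster nodes is used.
    """
    if base is None:
        base = table1_reduced_network()
    target, sign = parse_proposal(row.proposal)
    return CandidateModel(
        id=model_id(row.cluster_id, target, sign),
        base=base,
        added_edge=SignedEdge(row.cluster_id, target, sign),
    )


def table1_reduced_network(core: SignedNetwork | None = None) -> SignedNetwork:
    """Reduced network of the fixture: default core + its 8 cluster nodes.

    Cluster ids are the fixture's verbatim ids (C5, C14, ...), not renumbered.
    """
    from .network_expansion import GeneCluster, reduced_network

    if core is None:
        core = core_network_fixture()
    by_id: dict[str, Table1Row] = {}
    members: dict[str, set[str]] = {}
    for row in table1_fixture():
        by_id[row.cluster_id] = row
        members.setdefault(row.cluster_id, set()).add(row.gene)
    clusters = [
        GeneCluster(
            id=cid,
            members=frozenset(members[cid]),
            signature=(row.positives, row.negatives),
        )
        for cid, row in sorted(by_id.items())
    ]
    return reduced_network(core, clusters)
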