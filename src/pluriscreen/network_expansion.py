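"""Expand a literature core network with edges called from perturbation data.

Each perturbation experiment intervenes on one regulator — either a *gain*
(protein stimulation or over-expression) or a *loss* (RNAi knockdown) — and
records the genome-wide expression response.  Genes responding strongly and
significantly are connected to the perturbed regulator with a signed edge:
up-regulation after a gain perturbation implies activation, down-regulation
implies inhibition, and the signs invert for loss perturbations.

Downstream of edge calling, targets are narrowed to genes under broad core
control (at least ``min_incoming`` distinct core regulators) that carry
receptor-related Gene Ontology annotation, and finally genes sharing an
identical signed incoming-edge signature are collapsed into cluster nodes,
yielding the reduced perturbation network on which Boolean models are built.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .network import (
    ACTIVATION,
    INHIBITION,
    ROLE_CLUSTER,
    ROLE_CORE,
    ROLE_GENE,
    SignedNetwork,
)

logger = logging.getLogger(__name__)

GAIN = "gain"
LOSS = "loss"
DIRECTIONS = (GAIN, LOSS)

UP = "up"
DOWN = "down"

#: Default thresholds for differential calls (log2 fold change, differential
#: p-value, detection p-value).
FC_THRESHOLD = 1.5
P_THRESHOLD = 1.0e-05
DETECTION_THRESHOLD = 1.0e-05

#: Receptor-related Gene Ontology terms used to narrow candidates to cell
#: surface / secreted proteins: cell surface receptor linked signaling
#: pathway, and receptor binding.
RECEPTOR_GO_TERMS = frozenset({"GO:0007166", "GO:0005102"})

REQUIRED_COLUMNS = ("gene", "log2fc", "pvalue", "detection_pvalue")


@dataclass
class PerturbationExperiment:
    """One gain/loss intervention on a regulator plus its expression response.

    ``records`` holds one row per gene with columns ``gene``, ``log2fc``,
    ``pvalue`` (differential) and ``detection_pvalue``.
    """

    id: str
    regulator: str
    direction: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"experiment {self.id}: missing columns {missing}")
        if self.records["gene"].duplicated().any():
            dupes = self.records.loc[self.records["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"experiment {self.id}: duplicate gene records {dupes[:5]}")


@dataclass(frozen=True)
class GeneCluster:
    """Genes sharing an identical signed incoming-edge signature."""

    id: str
    members: frozenset[str]
    signature: tuple[frozenset[str], frozenset[str]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.id}: empty member set")
        pos, neg = self.signature
        if pos & neg:
            raise ValueError(f"cluster {self.id}: regulators {sorted(pos & neg)} both + and -")
        if not pos and not neg:
            raise ValueError(f"cluster {self.id}: empty signature")

    @property
    def positives(self) -> frozenset[str]:
        return self.signature[0]

    @property
    def negatives(self) -> frozenset[str]:
        return self.signature[1]

    @property
    def size(self) -> int:
        return len(self.members)


def call_differential(
    experiment: PerturbationExperiment,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    detection_threshold: float = DETECTION_THRESHOLD,
) -> set[tuple[str, str]]:
    """Call differentially expressed genes in one perturbation experiment.

    A gene is retained iff ``|log2fc| >= fc_threshold`` and both the
    differential and the detection p-value fall strictly below their
    thresholds.  Returns a set of ``(gene, "up"|"down")`` pairs.  Records
    with a non-finite fold change are skipped with a logged warning.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    for name, value in (("p_threshold", p_threshold), ("detection_threshold", detection_threshold)):
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {value}")

    calls: set[tuple[str, str]] = set()
    for row in experiment.records.itertuples(index=False):
        fc = float(row.log2fc)
        if not math.isfinite(fc):
            logger.warning(
                "experiment %s: non-finite log2fc for gene %s, record skipped",
                experiment.id, row.gene,
            )
            continue
        if (
            abs(fc) >= fc_threshold
            and float(row.pvalue) < p_threshold
            and float(row.detection_pvalue) < detection_threshold
        ):
            calls.add((str(row.gene), UP if fc > 0 else DOWN))
    return calls


def infer_edge_sign(direction: str, change: str) -> str:
    """Edge sign implied by a perturbation direction and an expression change.

    Gain perturbations read literally (up => activation, down => inhibition);
    loss perturbations invert, since losing an activator lowers its targets.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if change not in (UP, DOWN):
        raise ValueError(f"change must be 'up' or 'down', got {change!r}")
    if direction == GAIN:
        return ACTIVATION if change == UP else INHIBITION
    return INHIBITION if change == UP else ACTIVATION


def expand_network(
    core: SignedNetwork,
    experiments: list[PerturbationExperiment],
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    detection_threshold: float = DETECTION_THRESHOLD,
) -> SignedNetwork:
    """Add one signed edge regulator->gene for every differential call.

    Returns a new network: the core plus called target genes (role ``gene``).
    If experiments perturbing the same regulator disagree on the sign of a
    target, that (regulator, target) edge is dropped and logged.
    """
    for exp in experiments:
        if exp.regulator not in core or core.roles[exp.regulator] != ROLE_CORE:
            raise ValueError(
                f"experiment {exp.id}: regulator {exp.regulator!r} is not a core node"
            )

    # (regulator, gene) -> set of signs seen across experiments
    signs: dict[tuple[str, str], set[str]] = {}
    for exp in experiments:
        calls = call_differential(exp, fc_threshold, p_threshold, detection_threshold)
        for gene, change in calls:
            sign = infer_edge_sign(exp.direction, change)
            signs.setdefault((exp.regulator, gene), set()).add(sign)

    expanded = core.copy()
    for (regulator, gene), seen in sorted(signs.items()):
        if len(seen) > 1:
            logger.warning(
                "conflicting edge signs for %s -> %s across experiments; edge dropped",
                regulator, gene,
            )
            continue
        if gene not in expanded:
            expanded.add_node(gene, ROLE_GENE)
        (sign,) = seen
        existing = {(e.source, e.target): e.sign for e in expanded.edges}
        prior = existing.get((regulator, gene))
        if prior is None:
            expanded.add_edge(regulator, gene, sign)
        elif prior != sign:
            logger.warning(
                "called edge %s -> %s (%s) conflicts with core edge (%s); core kept",
                regulator, gene, sign, prior,
            )
    return expanded


def filter_targets(
    network: SignedNetwork,
    annotation: dict[str, set[str]],
    min_incoming: int = 5,
    go_terms: frozenset[str] = RECEPTOR_GO_TERMS,
) -> list[str]:
    """Select non-core genes under broad core control with receptor annotation.

    A gene passes iff at least ``min_incoming`` distinct core regulators have
    a signed edge onto it and its GO annotation intersects ``go_terms``.
    Genes missing from the annotation table are treated as unannotated and
    fail the GO filter.
    """
    go_terms = frozenset(go_terms)
    core = set(network.core_nodes)
    kept: list[str] = []
    for gene in network.nodes:
        if network.roles[gene] == ROLE_CORE:
            continue
        pos, neg = network.regulators_of(gene)
        n_core_regulators = len((pos | neg) & core)
        if n_core_regulators < min_incoming:
            continue
        if not (annotation.get(gene, set()) & go_terms):
            continue
        kept.append(gene)
    return kept


def cluster_by_signature(
    genes: list[str] | set[str],
    network: SignedNetwork,
) -> list[GeneCluster]:
    """Partition genes into clusters of identical signed incoming signatures.

    Two genes share a cluster iff their (activator set, inhibitor set) pairs
    are identical.  Cluster ids are assigned deterministically: clusters are
    sorted by total signature size descending, then lexicographically by
    signature, and numbered C1, C2, ...  Gene input order is irrelevant.
    """
    by_signature: dict[tuple[frozenset[str], frozenset[str]], set[str]] = {}
    for gene in sorted(genes):
        signature = network.regulators_of(gene)
        if not signature[0] and not signature[1]:
            raise ValueError(f"gene {gene!r} has no incoming edges; cannot cluster")
        by_signature.setdefault(signature, set()).add(gene)

    def sort_key(item):
        (pos, neg), _members = item
        return (-(len(pos) + len(neg)), tuple(sorted(pos)), tuple(sorted(neg)))

    clusters = []
    for k, ((pos, neg), members) in enumerate(sorted(by_signature.items(), key=sort_key), start=1):
        clusters.append(GeneCluster(id=f"C{k}", members=frozenset(members), signature=(pos, neg)))
    return clusters


def reduced_network(core: SignedNetwork, clusters: list[GeneCluster]) -> SignedNetwork:
    """Replace member genes by one cluster node carrying the signature edges."""
    net = SignedNetwork()
    for node in core.core_nodes:
        net.add_node(node, ROLE_CORE)
    for e in core.sorted_edges():
        if core.roles[e.source] == ROLE_CORE and core.roles[e.target] == ROLE_CORE:
            net.add_edge(e.source, e.target, e.sign)
    for cluster in clusters:
        net.add_node(cluster.id, ROLE_CLUSTER)
        for regulator in sorted(cluster.positives):
            net.add_edge(regulator, cluster.id, ACTIVATION)
        for regulator in sorted(cluster.negatives):
            net.add_edge(regulator, cluster.id, INHIBITION)
    return net
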