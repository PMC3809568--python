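"""Synthetic perturbation data with planted ground truth, plus in-text fixtures.

Emulates the kind of evidence the pipeline consumes — seven gain/loss
perturbation experiments on pluripotency regulators with genome-wide
expression responses — while planting a known signed regulator->target
structure so that every downstream stage (edge calling, filtering, signature
clustering, model enumeration, scoring) can be checked against the truth.

Effect sizes and p-values are drawn on opposite sides of the calling
thresholds by construction: planted targets always pass (|log2 FC| =
``effect_size_true`` > 1.5, p-values below 1e-05) and null genes always fail,
so edge recovery on synthetic data is exact.  The module also registers the
literature core network used throughout, and the table of 15 candidate
cytokine-pathway genes (8 signature clusters) selected for experimental
validation, shipped as an in-memory fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import (
    ACTIVATION,
    INHIBITION,
    ROLE_CORE,
    ROLE_GENE,
    SignedNetwork,
    network_from_edges,
)
from .network_expansion import GAIN, LOSS, PerturbationExperiment

#: The seven perturbed regulators and the direction of each intervention:
#: RNAi knockdowns of the core triad (loss), protein stimulation with bFGF,
#: BMP4 and ACTIVIN A (gain), and GADD45G over-expression (gain).
DEFAULT_REGULATORS = ("NANOG", "SOX2", "OCT3/4", "FGF2", "BMP4", "ACTA", "GADD45G")
DEFAULT_DIRECTIONS = {
    "NANOG": LOSS,
    "SOX2": LOSS,
    "OCT3/4": LOSS,
    "FGF2": GAIN,
    "BMP4": GAIN,
    "ACTA": GAIN,
    "GADD45G": GAIN,
}

RECEPTOR_GO_TERMS = ("GO:0007166", "GO:0005102")
#: An unrelated term handed to annotated genes that should fail the GO filter.
IRRELEVANT_GO_TERM = "GO:0008150"


@dataclass(frozen=True)
class PlantedFeedback:
    """The "true" self-renewal feedback planted into a synthetic run.

    The planted cluster's member genes are generated with exactly this
    signed incoming signature, and the planted model adds the ``sign`` edge
    from that cluster onto ``target``.  The default is an autocrine
    growth-factor loop constructed to yield coherent pluripotency markers
    under the default core's dynamics: a secreted-factor cluster induced by
    the pluripotency program (and the other perturbation-panel regulators)
    but repressed by ACTIVIN, feeding back positively onto bFGF — closing a
    self-sustaining loop that locks the pluripotent state.
    """

    positives: tuple[str, ...] = ("BMP4", "FGF2", "GADD45G", "NANOG", "OCT3/4", "SOX2")
    negatives: tuple[str, ...] = ("ACTA",)
    target: str = "FGF2"
    sign: str = ACTIVATION
    n_members: int = 2


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic study.

    Defaults emulate the scale of the source data: 7 regulators, a universe
    of 200 genes, a block of multi-regulated receptor-like genes (each under
    >= 5 regulators, forming the signature clusters), a handful of planted
    feedback-cluster genes, and sparsely regulated plus null background genes.
    """

    n_genes: int = 200
    regulators: tuple[str, ...] = DEFAULT_REGULATORS
    directions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    planted_edges: list[tuple[str, str, str]] | None = None
    #: number of receptor-like multi-regulated genes when planted_edges is drawn
    n_multiregulated: int = 12
    #: extra sparsely regulated genes per regulator (stay below the >=5 filter)
    n_sparse_per_regulator: int = 12
    effect_size_true: float = 2.5
    effect_size_null: float = 0.3
    p_true: tuple[float, float] = (1.0e-12, 1.0e-06)
    p_null: tuple[float, float] = (5.0e-02, 1.0)
    planted_feedback: PlantedFeedback | None = field(default_factory=PlantedFeedback)
    annotated_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.regulators:
            raise ValueError("regulator list is empty")
        for reg in self.regulators:
            if self.directions.get(reg) not in (GAIN, LOSS):
                raise ValueError(f"regulator {reg!r} has no gain/loss direction")
        if not self.effect_size_true > 1.5 > self.effect_size_null:
            raise ValueError(
                "effect sizes must straddle the calling threshold: "
                f"effect_size_true={self.effect_size_true} > 1.5 > "
                f"effect_size_null={self.effect_size_null} required"
            )
        if not max(self.p_true) < 1.0e-05 < min(self.p_null):
            raise ValueError("p-value ranges must straddle 1e-05")
        if not 0.0 <= self.annotated_fraction <= 1.0:
            raise ValueError("annotated_fraction must lie in [0, 1]")


def gene_universe(config: SyntheticConfig) -> list[str]:
    """Symbols of the synthetic gene universe, G0001..G<n>."""
    return [f"G{i:04d}" for i in range(1, config.n_genes + 1)]


def _draw_planted_edges(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Draw a random planted edge set; returns (edges, feedback cluster genes).

    Layout of the universe: first the multi-regulated receptor-like block
    (random signatures over >= 5 regulators), then the planted feedback
    cluster members (fixed signature), then sparsely regulated genes
    (1-4 regulators each), then unregulated nulls.
    """
    genes = gene_universe(config)
    regs = list(config.regulators)
    fb = config.planted_feedback
    n_fb = fb.n_members if fb is not None else 0
    n_multi = config.n_multiregulated
    n_sparse = config.n_sparse_per_regulator * len(regs)
    if n_multi + n_fb + n_sparse > len(genes):
        raise ValueError("n_genes too small for the requested planted structure")

    edges: list[tuple[str, str, str]] = []
    cursor = 0

    for gene in genes[cursor:cursor + n_multi]:
        k = int(rng.integers(5, len(regs) + 1))
        chosen = rng.choice(len(regs), size=k, replace=False)
        for idx in sorted(chosen):
            sign = ACTIVATION if rng.random() < 0.5 else INHIBITION
            edges.append((regs[idx], gene, sign))
    cursor += n_multi

    feedback_members = genes[cursor:cursor + n_fb]
    if fb is not None:
        for reg in (*fb.positives, *fb.negatives):
            if reg not in regs:
                raise ValueError(f"planted feedback names unknown regulator {reg!r}")
        for gene in feedback_members:
            for reg in fb.positives:
                edges.append((reg, gene, ACTIVATION))
            for reg in fb.negatives:
                edges.append((reg, gene, INHIBITION))
    cursor += n_fb

    sparse = genes[cursor:cursor + n_sparse]
    in_degree = {g: 0 for g in sparse}
    for reg in regs:
        pool = [g for g in sparse if in_degree[g] < 4]
        take = min(config.n_sparse_per_regulator, len(pool))
        chosen = rng.choice(len(pool), size=take, replace=False)
        for idx in sorted(chosen):
            gene = pool[idx]
            sign = ACTIVATION if rng.random() < 0.5 else INHIBITION
            edges.append((reg, gene, sign))
            in_degree[gene] += 1

    return edges, feedback_members


def generate_perturbation_experiments(
    config: SyntheticConfig,
) -> tuple[list[PerturbationExperiment], SignedNetwork]:
    """Generate one experiment table per regulator plus the planted truth.

    Planted targets carry |log2 FC| = ``effect_size_true`` with the sign
    implied by the planted edge sign and the perturbation direction, and
    p-values inside ``p_true``; all other genes fall inside the null ranges.
    The returned network holds the planted regulator->target edges (regulator
    nodes tagged ``core``) and is the recovery oracle for the expansion stage.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = gene_universe(config)
    gene_set = set(genes)

    if config.planted_edges is not None:
        edges = list(config.planted_edges)
        for reg, target, sign in edges:
            if reg not in config.regulators:
                raise ValueError(f"planted edge names unknown regulator {reg!r}")
            if target not in gene_set:
                raise ValueError(f"planted edge names gene {target!r} outside the universe")
            if sign not in (ACTIVATION, INHIBITION):
                raise ValueError(f"planted edge has invalid sign {sign!r}")
    else:
        edges, _ = _draw_planted_edges(config, rng)

    truth = network_from_edges(
        edges,
        roles={r: ROLE_CORE for r in config.regulators},
        default_role=ROLE_GENE,
    )

    targets_of: dict[str, dict[str, str]] = {r: {} for r in config.regulators}
    for reg, target, sign in edges:
        targets_of[reg][target] = sign

    log_p_true = np.log10(config.p_true)
    experiments = []
    for k, reg in enumerate(config.regulators, start=1):
        direction = config.directions[reg]
        planted = targets_of[reg]
        n = len(genes)
        log2fc = rng.uniform(-config.effect_size_null, config.effect_size_null, size=n)
        pvalue = 10.0 ** rng.uniform(np.log10(config.p_null[0]), np.log10(config.p_null[1]), size=n)
        detection = 10.0 ** rng.uniform(np.log10(config.p_null[0]), np.log10(config.p_null[1]), size=n)
        for i, gene in enumerate(genes):
            sign = planted.get(gene)
            if sign is None:
                continue
            if direction == GAIN:
                up = sign == ACTIVATION
            else:
                up = sign == INHIBITION
            log2fc[i] = config.effect_size_true if up else -config.effect_size_true
            pvalue[i] = 10.0 ** rng.uniform(*log_p_true)
            detection[i] = 10.0 ** rng.uniform(*log_p_true)
        records = pd.DataFrame(
            {"gene": genes, "log2fc": log2fc, "pvalue": pvalue, "detection_pvalue": detection}
        )
        experiments.append(
            PerturbationExperiment(
                id=f"E{k}_{direction}_{reg.replace('/', '')}",
                regulator=reg,
                direction=direction,
                records=records,
            )
        )
    return experiments, truth


def generate_annotation(
    config: SyntheticConfig, truth: SignedNetwork
) -> dict[str, set[str]]:
    """Draw a gene -> GO-term table for the synthetic universe.

    Each gene is annotated with one receptor GO term with probability
    ``annotated_fraction``; planted feedback-cluster members are always
    annotated (they must survive the GO filter for the truth to be
    recoverable).  Unannotated genes receive an unrelated term or nothing.

    Uses a seed offset so annotation draws do not perturb the experiment
    tables generated from the same config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 10_007)
    fb_members = _feedback_members(config, truth)
    annotation: dict[str, set[str]] = {}
    for gene in gene_universe(config):
        if gene in fb_members or rng.random() < config.annotated_fraction:
            term = RECEPTOR_GO_TERMS[int(rng.integers(0, len(RECEPTOR_GO_TERMS)))]
            annotation[gene] = {term}
        elif rng.random() < 0.5:
            annotation[gene] = {IRRELEVANT_GO_TERM}
    return annotation


def _feedback_members(config: SyntheticConfig, truth: SignedNetwork) -> set[str]:
    """Genes of the planted feedback cluster, identified by their signature."""
    fb = config.planted_feedback
    if fb is None:
        return set()
    wanted = (frozenset(fb.positives), frozenset(fb.negatives))
    members = set()
    for gene in truth.nodes:
        if truth.roles[gene] == ROLE_GENE and truth.regulators_of(gene) == wanted:
            members.add(gene)
    return members


# ---------------------------------------------------------------------------
# In-text fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1Row:
    """One candidate gene selected for experimental validation."""

    cluster_id: str
    gene: str
    proposal: str  # "-> TARGET" (activation) or "-| TARGET" (inhibition)
    positives: frozenset[str]
    negatives: frozenset[str]


_T1 = [
    # cluster, gene, proposal, positives, negatives
    ("C5", "WNT3", "-> ACTA", ("ACTA", "BMP4", "FGF2", "NANOG", "OCT3/4"), ()),
    ("C14", "CXCL12", "-> ACTA", ("BMP4", "GADD45G", "OCT3/4", "SOX2"), ("ACTA",)),
    ("C15", "FUT8", "-> ACTA", ("ACTA", "BMP4", "FGF2"), ("NANOG", "OCT3/4", "SOX2")),
    ("C16", "CD99", "-> ACTA", ("ACTA", "BMP4"), ("NANOG", "OCT3/4", "SOX2")),
    ("C16", "CXCR7", "-> ACTA", ("ACTA", "BMP4"), ("NANOG", "OCT3/4", "SOX2")),
    ("C16", "EPHB2", "-> ACTA", ("ACTA", "BMP4"), ("NANOG", "OCT3/4", "SOX2")),
    ("C16", "EPHB3", "-> ACTA", ("ACTA", "BMP4"), ("NANOG", "OCT3/4", "SOX2")),
    ("C16", "MAP7D1", "-> ACTA", ("ACTA", "BMP4"), ("NANOG", "OCT3/4", "SOX2")),
    ("C16", "NEDD9", "-> ACTA", ("ACTA", "BMP4"), ("NANOG", "OCT3/4", "SOX2")),
    ("C16", "PLXNA2", "-> ACTA", ("ACTA", "BMP4"), ("NANOG", "OCT3/4", "SOX2")),
    ("C28", "ADRA2C", "-> ACTA", ("ACTA", "BMP4", "NANOG", "OCT3/4", "SOX2"), ()),
    ("C36", "IL11", "-> ACTA", ("BMP4", "FGF2"), ("NANOG", "OCT3/4", "SOX2")),
    ("C36", "JUN", "-> ACTA", ("BMP4", "FGF2"), ("NANOG", "OCT3/4", "SOX2")),
    ("C39", "NRIP1", "-> ACTA", ("ACTA", "BMP4", "FGF2"), ("OCT3/4", "SOX2")),
    ("C41", "FRAT2", "-| FGF2", ("OCT3/4", "SOX2"), ("ACTA", "BMP4", "FGF2")),
]


def table1_fixture() -> list[Table1Row]:
    """The 15 candidate genes (8 signature clusters) proposed for validation.

    Cluster ids are the ones assigned in the original full-scale run and are
    preserved verbatim; the proposal column encodes the feedback edge each
    cluster was selected with ("->" activation, "-|" inhibition of the named
    core target).
    """
    return [
        Table1Row(
            cluster_id=c,
            gene=g,
            proposal=p,
            positives=frozenset(pos),
            negatives=frozenset(neg),
        )
        for c, g, p, pos, neg in _T1
    ]


def table1_network(core: SignedNetwork | None = None) -> SignedNetwork:
    """Signed network of the 15 candidate genes under their tabled signatures.

    Starts from the core network (default registered core) and wires each
    candidate gene's positive and negative regulators onto it, ready for
    signature clustering.
    """
    net = (core or core_network_fixture()).copy()
    for row in table1_fixture():
        net.add_node(row.gene, ROLE_GENE)
        for reg in sorted(row.positives):
            net.add_edge(reg, row.gene, ACTIVATION)
        for reg in sorted(row.negatives):
            net.add_edge(reg, row.gene, INHIBITION)
    return net


_TRIAD = ("NANOG", "OCT3/4", "SOX2")

#: Default 10-gene literature core.  Wiring rationale (see docs/methods.md):
#: bFGF and ACTIVIN/NODAL (here TGFB1 -> ACTA) branches converge on NANOG;
#: the OCT3/4-SOX2-NANOG triad mutually activates itself (the three factors
#: co-occupy their own and each other's promoters); OCT3/4 negatively
#: regulates GADD45G, BMP4, hCG and GCM1; BMP4 drives the differentiation
#: branch (GADD45G and the trophoblast markers hCG, GCM1) and forms a
#: mutual-activation loop with GADD45G.  The "chain" variant wires the triad
#: as a 3-cycle instead.
_BRANCH_EDGES: tuple[tuple[str, str, str], ...] = (
    ("FGF2", "NANOG", ACTIVATION),
    ("TGFB1", "ACTA", ACTIVATION),
    ("ACTA", "NANOG", ACTIVATION),
    ("OCT3/4", "BMP4", INHIBITION),
    ("OCT3/4", "GADD45G", INHIBITION),
    ("OCT3/4", "hCG", INHIBITION),
    ("OCT3/4", "GCM1", INHIBITION),
    ("BMP4", "GADD45G", ACTIVATION),
    ("GADD45G", "BMP4", ACTIVATION),
    ("BMP4", "hCG", ACTIVATION),
    ("BMP4", "GCM1", ACTIVATION),
)

_CORE_REGISTRY: dict[str, tuple[tuple[str, str, str], ...]] = {
    "default": _BRANCH_EDGES + tuple(
        (a, b, ACTIVATION) for a in _TRIAD for b in _TRIAD if a != b
    ),
    "triad-chain": _BRANCH_EDGES + (
        ("NANOG", "OCT3/4", ACTIVATION),
        ("OCT3/4", "SOX2", ACTIVATION),
        ("SOX2", "NANOG", ACTIVATION),
    ),
}

CORE_NODES = ("OCT3/4", "SOX2", "NANOG", "FGF2", "ACTA", "BMP4", "GADD45G", "hCG", "GCM1", "TGFB1")


def core_network_fixture(variant: str = "default") -> SignedNetwork:
    """A registered literature core network (default: 10 genes, 14 edges)."""
    if variant not in _CORE_REGISTRY:
        raise KeyError(
            f"unknown core-network variant {variant!r}; registered: {sorted(_CORE_REGISTRY)}"
        )
    return network_from_edges(
        _CORE_REGISTRY[variant],
        roles={n: ROLE_CORE for n in CORE_NODES},
    )


def register_core_network(variant: str, edges: list[tuple[str, str, str]]) -> None:
    """Register a user-supplied core-network definition under a variant name."""
    _CORE_REGISTRY[variant] = tuple(edges)
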