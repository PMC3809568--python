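"""End-to-end orchestration: expansion -> clustering -> models -> dynamics -> scores.

A single :class:`PipelineConfig` drives the whole screen.  Three input modes
are supported: ``synthetic`` (generate perturbation tables with planted
ground truth), ``table1`` (the in-text fixture of 15 candidate genes and
their 8 signature clusters), and ``files`` (experiment TSVs + manifest +
annotation TSV on disk).  Every stage writes its artifact under the output
directory in a canonical order, and the run report collects the stage counts
so a rerun with the same config and seed reproduces it exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import netio
from .boolean_dynamics import UpdateSemantics, perturbation_screen
from .model_generation import enumerate_models
from .model_scoring import (
    DEFAULT_MARKERS,
    MarkerSets,
    ModelScore,
    plot_score_plane,
    score_matrix,
    scores_to_frame,
    select_models,
)
from .network import SignedNetwork
from .network_expansion import (
    DETECTION_THRESHOLD,
    FC_THRESHOLD,
    P_THRESHOLD,
    RECEPTOR_GO_TERMS,
    call_differential,
    cluster_by_signature,
    expand_network,
    filter_targets,
    reduced_network,
)
from .synthetic_data import (
    SyntheticConfig,
    core_network_fixture,
    generate_annotation,
    generate_perturbation_experiments,
    table1_fixture,
    table1_network,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage, partial artifacts remain."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults are the published study parameters."""

    mode: str = "synthetic"  # synthetic | table1 | files
    outdir: str = "pluriscreen_out"
    seed: int = 0

    # inputs (files mode)
    core_network_path: str | None = None
    core_variant: str = "default"
    experiment_manifest: str | None = None
    annotation_path: str | None = None

    # synthetic block
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    # expansion thresholds
    fc_threshold: float = FC_THRESHOLD
    p_threshold: float = P_THRESHOLD
    detection_threshold: float = DETECTION_THRESHOLD
    min_incoming: int = 5
    go_terms: tuple[str, ...] = tuple(sorted(RECEPTOR_GO_TERMS))

    # model enumeration
    target_policy: str = "core"

    # dynamics
    inhibitor_only_sustain: bool = False
    core_ceiling: int = 22
    matrix_encoding: str = "binary"
    deduplicate_states: bool = False

    # scoring
    aggregate: str = "sum"
    k_clusters: int = 8
    max_diff_angle: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        config = cls(**raw)
        if synth is not None:
            config.synthetic = SyntheticConfig(**synth)
        return config

    def core_network(self) -> SignedNetwork:
        if self.core_network_path:
            return netio.read_network(self.core_network_path, dialect="tsv")
        return core_network_fixture(self.core_variant)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the machine-readable run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "thresholds": {
            "fc_threshold": config.fc_threshold,
            "p_threshold": config.p_threshold,
            "detection_threshold": config.detection_threshold,
            "min_incoming": config.min_incoming,
            "go_terms": list(config.go_terms),
        },
    }
    logger.info("run start: mode=%s seed=%d outdir=%s", config.mode, config.seed, outdir)
    logger.info("thresholds: %s", report["thresholds"])

    core = config.core_network()
    netio.write_network(core, outdir / "core_network.tsv", "tsv")

    # -- stage: inputs / expansion / filtering / clustering ----------------
    if config.mode == "table1":
        clusters, filtered, n_differential = _stage_table1(config, core, outdir)
    elif config.mode in ("synthetic", "files"):
        clusters, filtered, n_differential = _stage_expand(config, core, outdir)
    else:
        raise ValueError(f"unknown pipeline mode {config.mode!r}")

    report["n_differential_genes"] = n_differential
    report["n_filtered_genes"] = len(filtered)
    report["n_clusters"] = len(clusters)
    netio.write_clusters(clusters, outdir / "clusters.tsv")

    try:
        reduced = reduced_network(core, clusters)
    except Exception as err:
        raise PipelineStageError("reduce", err)
    report["n_nodes"] = len(reduced)
    netio.write_network(reduced, outdir / "reduced_network.tsv", "tsv")
    netio.write_network(reduced, outdir / "reduced_network.boolsim", "boolsim")

    # -- stage: model enumeration ------------------------------------------
    try:
        models = enumerate_models(reduced, config.target_policy)
    except Exception as err:
        raise PipelineStageError("enumerate", err)
    report["n_models"] = len(models)
    manifest = pd.DataFrame(
        [{"model_id": m.id, "cluster": m.cluster, "target": m.target, "sign": m.sign}
         for m in models]
    )
    manifest.to_csv(outdir / "model_manifest.tsv", sep="\t", index=False)
    logger.info("enumerated %d models (%d clusters x targets x 2)", len(models), len(clusters))

    # -- stage: dynamics + scoring -----------------------------------------
    semantics = UpdateSemantics(inhibitor_only_sustain=config.inhibitor_only_sustain)
    scores: list[ModelScore] = []
    matrices: list[pd.DataFrame] = []
    for model in models:
        try:
            matrix = perturbation_screen(
                model.network(),
                model_id=model.id,
                semantics=semantics,
                core_ceiling=config.core_ceiling,
                encoding=config.matrix_encoding,
                deduplicate=config.deduplicate_states,
            )
        except Exception as err:
            raise PipelineStageError("dynamics", err)
        matrices.append(matrix)
        try:
            scores.append(score_matrix(matrix, DEFAULT_MARKERS, config.aggregate, model.id))
        except Exception as err:
            raise PipelineStageError("score", err)
    if matrices:
        netio.write_matrix(pd.concat(matrices, ignore_index=True), outdir / "steady_states.tsv")
    report["n_scorable_models"] = sum(1 for s in scores if s.scorable)

    # -- stage: selection ---------------------------------------------------
    try:
        selected = select_models(scores, config.k_clusters, config.max_diff_angle)
    except Exception as err:
        raise PipelineStageError("select", err)
    selected_clusters = sorted({s.cluster for s in selected})
    members: dict[str, frozenset[str]] = {c.id: c.members for c in clusters}
    selected_genes = sorted(
        gene for cid in selected_clusters for gene in members.get(cid, frozenset())
    )
    report["n_selected_models"] = len(selected)
    report["selected_clusters"] = selected_clusters
    report["selected_genes"] = selected_genes

    ranked_ids = {s.model_id: s.pareto_rank for s in selected}
    all_scores = [
        dataclasses.replace(s, pareto_rank=ranked_ids.get(s.model_id, s.pareto_rank))
        for s in scores
    ]
    scores_to_frame(all_scores).to_csv(outdir / "scores.tsv", sep="\t", index=False)
    scores_to_frame(selected).to_csv(outdir / "selected_models.tsv", sep="\t", index=False)
    plot_score_plane(all_scores, selected, str(outdir / "score_plane.png"))

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("run complete: %s", {k: v for k, v in report.items() if isinstance(v, int)})
    return report


def _stage_table1(config: PipelineConfig, core: SignedNetwork, outdir: Path):
    """Fixture mode: the 15 tabled genes under their published signatures.

    Cluster ids come verbatim from the fixture (C5, C14, ...), and the
    signature grouping is cross-checked against the clustering operation.
    """
    from .network_expansion import GeneCluster

    try:
        rows = table1_fixture()
        genes = [r.gene for r in rows]
        members: dict[str, set[str]] = {}
        signatures: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
        for row in rows:
            members.setdefault(row.cluster_id, set()).add(row.gene)
            signatures[row.cluster_id] = (row.positives, row.negatives)
        clusters = [
            GeneCluster(cid, frozenset(members[cid]), signatures[cid])
            for cid in sorted(members)
        ]
        recomputed = cluster_by_signature(genes, table1_network(core))
        if {c.members for c in recomputed} != {c.members for c in clusters}:
            raise ValueError("fixture cluster ids disagree with signature clustering")
    except Exception as err:
        raise PipelineStageError("cluster", err)
    return clusters, genes, 0


def _stage_expand(config: PipelineConfig, core: SignedNetwork, outdir: Path):
    try:
        if config.mode == "synthetic":
            synth = dataclasses.replace(config.synthetic, seed=config.seed)
            experiments, truth = generate_perturbation_experiments(synth)
            annotation = generate_annotation(synth, truth)
            netio.write_experiments(experiments, outdir / "experiments")
            netio.write_annotation(annotation, outdir / "annotation.tsv")
            netio.write_network(truth, outdir / "planted_truth.tsv", "tsv")
        else:
            if not config.experiment_manifest or not config.annotation_path:
                raise ValueError("files mode needs experiment_manifest and annotation_path")
            experiments = netio.read_experiments(config.experiment_manifest)
            annotation = netio.read_annotation(config.annotation_path)
    except PipelineStageError:
        raise
    except Exception as err:
        raise PipelineStageError("inputs", err)

    try:
        differential = set()
        for exp in experiments:
            differential |= {
                gene for gene, _change in call_differential(
                    exp, config.fc_threshold, config.p_threshold, config.detection_threshold
                )
            }
        expanded = expand_network(
            core, experiments,
            config.fc_threshold, config.p_threshold, config.detection_threshold,
        )
        netio.write_network(expanded, outdir / "expanded_network.tsv", "tsv")
    except Exception as err:
        raise PipelineStageError("expand", err)

    try:
        filtered = filter_targets(
            expanded, annotation, config.min_incoming, frozenset(config.go_terms)
        )
    except Exception as err:
        raise PipelineStageError("filter", err)

    try:
        clusters = cluster_by_signature(filtered, expanded)
    except Exception as err:
        raise PipelineStageError("cluster", err)
    return clusters, filtered, len(differential)
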