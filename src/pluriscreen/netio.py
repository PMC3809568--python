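"""Bit-exact file interfaces: networks, experiments, annotation, clusters.

Two network dialects are supported.  The TSV dialect is lossless (node roles
are kept in ``# node`` header comments, so isolated nodes and role tags
round-trip byte-identically).  The boolSim-style dialect writes one edge per
line — ``A -> B`` for activation, ``A -| B`` for inhibition — and is what the
dynamics layer consumes and emits for interoperability; it preserves the edge
set but not role tags, which the reader re-derives from an optional core-node
list.  All writers emit canonically sorted rows so reruns diff cleanly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .network import (
    ACTIVATION,
    INHIBITION,
    ROLE_CLUSTER,
    ROLE_CORE,
    ROLE_GENE,
    SignedNetwork,
)
from .network_expansion import GeneCluster, PerturbationExperiment

_ARROWS = {"->": ACTIVATION, "→": ACTIVATION, "-|": INHIBITION, "—|": INHIBITION, "⊣": INHIBITION}
_ARROW_OF = {ACTIVATION: "->", INHIBITION: "-|"}


def write_network(network: SignedNetwork, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    lines: list[str] = []
    if dialect == "tsv":
        for node in network.nodes:
            lines.append(f"# node\t{node}\t{network.roles[node]}")
        lines.append("source\ttarget\tsign")
        for e in network.sorted_edges():
            lines.append(f"{e.source}\t{e.target}\t{e.sign}")
    elif dialect == "boolsim":
        for e in network.sorted_edges():
            lines.append(f"{e.source} {_ARROW_OF[e.sign]} {e.target}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


def read_network(
    path: str | Path,
    dialect: str = "tsv",
    core_nodes: set[str] | None = None,
) -> SignedNetwork:
    """Read a signed network; unknown sign tokens or dangling nodes raise.

    For the boolsim dialect, node roles are re-derived: members of
    ``core_nodes`` get role ``core``, names matching ``C<number>`` get
    ``cluster``, everything else ``gene``.
    """
    path = Path(path)
    net = SignedNetwork()
    if dialect == "tsv":
        edge_rows: list[tuple[str, str, str]] = []
        header_seen = False
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("# node\t"):
                _, node, role = line.split("\t")
                net.add_node(node, role)
                continue
            if line.startswith("#"):
                continue
            if not header_seen:
                if line.split("\t") != ["source", "target", "sign"]:
                    raise ValueError(f"{path}:{lineno}: expected TSV header 'source target sign'")
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            edge_rows.append((fields[0], fields[1], fields[2]))
        for source, target, sign in edge_rows:
            if sign not in (ACTIVATION, INHIBITION):
                raise ValueError(f"{path}: unknown sign token {sign!r}")
            for endpoint in (source, target):
                if endpoint not in net:
                    raise ValueError(f"{path}: edge references undeclared node {endpoint!r}")
            net.add_edge(source, target, sign)
        return net
    if dialect == "boolsim":
        core_nodes = core_nodes or set()

        def role_of(name: str) -> str:
            if name in core_nodes:
                return ROLE_CORE
            if name.startswith("C") and name[1:].isdigit():
                return ROLE_CLUSTER
            return ROLE_GENE

        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'SOURCE ARROW TARGET'")
            source, arrow, target = tokens
            if arrow not in _ARROWS:
                raise ValueError(f"{path}:{lineno}: unknown sign token {arrow!r}")
            for endpoint in (source, target):
                if endpoint not in net:
                    net.add_node(endpoint, role_of(endpoint))
            net.add_edge(source, target, _ARROWS[arrow])
        return net
    raise ValueError(f"unknown dialect {dialect!r}")


def write_experiments(
    experiments: list[PerturbationExperiment], outdir: str | Path
) -> Path:
    """One TSV per experiment plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for exp in experiments:
        fname = f"{exp.id}.tsv"
        exp.records.to_csv(outdir / fname, sep="\t", index=False, float_format="%.10g")
        manifest_rows.append(
            {"experiment_id": exp.id, "regulator": exp.regulator,
             "direction": exp.direction, "file": fname}
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_experiments(manifest_path: str | Path) -> list[PerturbationExperiment]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    experiments = []
    for row in manifest.itertuples(index=False):
        records = pd.read_csv(base / row.file, sep="\t")
        experiments.append(
            PerturbationExperiment(
                id=str(row.experiment_id),
                regulator=str(row.regulator),
                direction=str(row.direction),
                records=records,
            )
        )
    return experiments


def write_annotation(annotation: dict[str, set[str]], path: str | Path) -> None:
    """gene -> GO-term table as a two-column TSV (one row per pair)."""
    rows = [
        {"gene": gene, "go_id": term}
        for gene in sorted(annotation)
        for term in sorted(annotation[gene])
    ]
    pd.DataFrame(rows, columns=["gene", "go_id"]).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    table = pd.read_csv(path, sep="\t")
    annotation: dict[str, set[str]] = {}
    for row in table.itertuples(index=False):
        annotation.setdefault(str(row.gene), set()).add(str(row.go_id))
    return annotation


def write_clusters(clusters: list[GeneCluster], path: str | Path) -> None:
    """Cluster membership TSV: cluster_id, gene, positives, negatives."""
    rows = [
        {
            "cluster_id": c.id,
            "gene": gene,
            "positives": ",".join(sorted(c.positives)),
            "negatives": ",".join(sorted(c.negatives)),
        }
        for c in clusters
        for gene in sorted(c.members)
    ]
    pd.DataFrame(rows, columns=["cluster_id", "gene", "positives", "negatives"]).to_csv(
        path, sep="\t", index=False
    )


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
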