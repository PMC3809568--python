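"""Score candidate models by PCA-loading angles between marker genes.

The steady-state matrix of a model is reduced with column-centered,
unscaled principal component analysis (prcomp-style).  Each marker gene gets
a 2-D vector from its loadings on PC1 and PC2; angles between these vectors
measure how coherently the markers behave across all in-silico perturbations.
A model supports self-renewal when the pluripotency markers (OCT3/4, SOX2,
NANOG) point the same way — small within-group angle — while the
differentiation markers (BMP4, GADD45G) point away from them — large
between-group angle.  Models are ranked on this plane by Pareto dominance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .boolean_dynamics import node_columns

logger = logging.getLogger(__name__)

AGGREGATES = ("sum", "mean")


@dataclass(frozen=True)
class MarkerSets:
    """Marker genes whose loading geometry defines the score."""

    pluripotency: frozenset[str] = frozenset({"OCT3/4", "SOX2", "NANOG"})
    differentiation: frozenset[str] = frozenset({"BMP4", "GADD45G"})

    def __post_init__(self) -> None:
        if self.pluripotency & self.differentiation:
            raise ValueError("marker sets must be disjoint")
        if len(self.pluripotency) < 2 or len(self.differentiation) < 2:
            raise ValueError("each marker set needs at least two genes")

    @property
    def all(self) -> frozenset[str]:
        return self.pluripotency | self.differentiation


DEFAULT_MARKERS = MarkerSets()


@dataclass(frozen=True)
class PCAResult:
    """Loadings on the first two principal components, or the unscorable flag."""

    loadings: dict[str, np.ndarray] | None
    explained_variance_ratio: tuple[float, float] | None
    scorable: bool
    reason: str | None = None


@dataclass(frozen=True)
class ModelScore:
    """Three angle statistics of one model, all in degrees within [0, 180]."""

    model_id: str
    pluri_angle: float | None
    diff_angle: float | None
    cross_angle: float | None
    scorable: bool
    reason: str | None = None
    pareto_rank: int | None = None

    @property
    def cluster(self) -> str:
        return self.model_id.split("__")[0]


class ZeroVectorError(ValueError):
    """Angle with a zero loading vector is undefined."""


def pca_loadings(matrix: pd.DataFrame) -> PCAResult:
    """Column-centered, unscaled PCA of a steady-state matrix.

    Returns each node's (PC1, PC2) loading and the explained-variance
    fractions.  The sign of each component is fixed deterministically: the
    largest-magnitude loading on that component is made positive (ties broken
    by column order) — a pure reflection, so no angle is affected.

    A matrix with fewer than two rows or fewer than two columns of nonzero
    variance cannot span two components; it is flagged unscorable rather
    than raising.
    """
    cols = node_columns(matrix)
    data = matrix[cols].to_numpy(dtype=float)
    if data.shape[0] < 2:
        return PCAResult(None, None, False, "fewer than 2 steady states")
    variable = int((data.std(axis=0) > 0).sum())
    if variable < 2:
        return PCAResult(None, None, False, "fewer than 2 nonzero-variance columns")
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(data)
    components = pca.components_.copy()  # (2, n_nodes)
    for i in range(2):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    loadings = {node: components[:, idx].copy() for idx, node in enumerate(cols)}
    evr = tuple(float(v) for v in pca.explained_variance_ratio_[:2])
    return PCAResult(loadings, evr, True)


def vector_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two loading vectors in degrees, within [0, 180].

    Scale-invariant (arccos of the cosine similarity).  Raises
    :class:`ZeroVectorError` on a zero vector; callers mark the model
    unscorable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ZeroVectorError("angle with a zero vector is undefined")
    cosine = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosine)))


def _group_direction(loadings: dict[str, np.ndarray], members: frozenset[str]) -> np.ndarray:
    """Mean of unit-normalized member vectors (no single loading dominates)."""
    units = []
    for gene in sorted(members):
        v = loadings[gene]
        norm = np.linalg.norm(v)
        if norm == 0.0:
            raise ZeroVectorError(f"marker {gene} has a zero loading vector")
        units.append(v / norm)
    return np.mean(units, axis=0)


def score_model(
    pca: PCAResult,
    markers: MarkerSets = DEFAULT_MARKERS,
    aggregate: str = "sum",
    model_id: str = "",
) -> ModelScore:
    """Compute the three angle statistics of one model.

    ``pluri_angle`` aggregates (sum or mean) the three pairwise angles among
    the pluripotency markers; ``diff_angle`` is the angle between the two
    differentiation markers; ``cross_angle`` separates the two groups'
    direction vectors.  Degenerate geometry (any zero marker vector, or an
    upstream unscorable PCA) yields an unscorable score with a reason code.
    """
    if aggregate not in AGGREGATES:
        raise ValueError(f"aggregate must be one of {AGGREGATES}")
    if not pca.scorable:
        return ModelScore(model_id, None, None, None, False, pca.reason)
    loadings = pca.loadings
    missing = sorted(g for g in markers.all if g not in loadings)
    if missing:
        raise ValueError(f"markers {missing} are not matrix columns")
    try:
        pairs = list(itertools.combinations(sorted(markers.pluripotency), 2))
        pluri_angles = [vector_angle(loadings[a], loadings[b]) for a, b in pairs]
        pluri = float(sum(pluri_angles))
        if aggregate == "mean":
            pluri /= len(pairs)
        d1, d2 = sorted(markers.differentiation)
        diff = vector_angle(loadings[d1], loadings[d2])
        cross = vector_angle(
            _group_direction(loadings, markers.pluripotency),
            _group_direction(loadings, markers.differentiation),
        )
    except ZeroVectorError as err:
        return ModelScore(model_id, None, None, None, False, str(err))
    return ModelScore(model_id, pluri, diff, cross, True)


def score_matrix(
    matrix: pd.DataFrame,
    markers: MarkerSets = DEFAULT_MARKERS,
    aggregate: str = "sum",
    model_id: str | None = None,
) -> ModelScore:
    """PCA plus angle scoring of one model's steady-state matrix."""
    if model_id is None:
        ids = matrix["model_id"].unique()
        model_id = str(ids[0]) if len(ids) else ""
    return score_model(pca_loadings(matrix), markers, aggregate, model_id)


def _dominates(a: ModelScore, b: ModelScore) -> bool:
    """a dominates b on (minimize pluri_angle, maximize cross_angle)."""
    return (
        a.pluri_angle <= b.pluri_angle
        and a.cross_angle >= b.cross_angle
        and (a.pluri_angle < b.pluri_angle or a.cross_angle > b.cross_angle)
    )


def pareto_ranks(scores: list[ModelScore]) -> list[ModelScore]:
    """Attach Pareto ranks (1 = non-dominated front) to scorable scores."""
    remaining = list(scores)
    ranked: list[ModelScore] = []
    rank = 1
    while remaining:
        front = [
            s for s in remaining
            if not any(_dominates(o, s) for o in remaining if o is not s)
        ]
        if not front:  # cannot happen with a strict dominance relation
            front = remaining
        ranked.extend(replace(s, pareto_rank=rank) for s in front)
        front_ids = {s.model_id for s in front}
        remaining = [s for s in remaining if s.model_id not in front_ids]
        rank += 1
    return ranked


def select_models(
    scores: list[ModelScore],
    k: int = 8,
    max_diff_angle: float | None = None,
) -> list[ModelScore]:
    """Rank scorable models and return those of the top ``k`` clusters.

    Ranking: Pareto rank on (small pluri_angle, large cross_angle), ties
    broken by cross_angle descending, pluri_angle ascending, then model id.
    ``max_diff_angle`` optionally requires the differentiation markers to be
    coherent as well (angle at or below the gate) before ranking.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    scorable = [s for s in scores if s.scorable]
    if max_diff_angle is not None:
        scorable = [s for s in scorable if s.diff_angle <= max_diff_angle]
    if not scorable:
        raise ValueError("no scorable models to select from")
    ranked = pareto_ranks(scorable)
    ranked.sort(key=lambda s: (s.pareto_rank, -s.cross_angle, s.pluri_angle, s.model_id))
    selected_clusters: list[str] = []
    for s in ranked:
        if s.cluster not in selected_clusters:
            selected_clusters.append(s.cluster)
        if len(selected_clusters) >= k:
            break
    chosen = set(selected_clusters)
    return [s for s in ranked if s.cluster in chosen]


def scores_to_frame(scores: list[ModelScore]) -> pd.DataFrame:
    """Tabulate scores (one row per model) for the scores TSV."""
    rows = []
    for s in scores:
        parts = s.model_id.split("__", 1)
        target_sign = parts[1] if len(parts) == 2 else ""
        rows.append(
            {
                "model_id": s.model_id,
                "cluster": s.cluster,
                "target": target_sign[1:] if target_sign else "",
                "sign": target_sign[:1] if target_sign else "",
                "pluri_angle": s.pluri_angle,
                "diff_angle": s.diff_angle,
                "cross_angle": s.cross_angle,
                "scorable": s.scorable,
                "reason": s.reason or "",
                "pareto_rank": s.pareto_rank,
            }
        )
    return pd.DataFrame(rows)


def plot_score_plane(
    scores: list[ModelScore],
    selected: list[ModelScore],
    path: str,
) -> None:
    """Scatter of pluri_angle vs cross_angle with selected models highlighted."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scorable = [s for s in scores if s.scorable]
    chosen = {s.model_id for s in selected}
    fig, ax = plt.subplots(figsize=(6, 5))
    xs = [s.pluri_angle for s in scorable]
    ys = [s.cross_angle for s in scorable]
    colors = ["red" if s.model_id in chosen else "0.6" for s in scorable]
    ax.scatter(xs, ys, c=colors, s=18, alpha=0.8, linewidths=0)
    ax.set_xlabel("sum of angles between pluripotency markers (deg)")
    ax.set_ylabel("angle between pluripotency and differentiation markers (deg)")
    ax.set_title("model score plane (selected models in red)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
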