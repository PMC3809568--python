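"""PCA loadings, angle identities, and Pareto model selection."""

import numpy as np
import pandas as pd
import pytest

from pluriscreen.boolean_dynamics import PROVENANCE_COLUMNS
from pluriscreen.model_scoring import (
    MarkerSets,
    ModelScore,
    ZeroVectorError,
    pareto_ranks,
    pca_loadings,
    score_model,
    score_matrix,
    select_models,
    vector_angle,
)

MARKERS = MarkerSets()
MARKER_NAMES = ("OCT3/4", "SOX2", "NANOG", "BMP4", "GADD45G")


def as_matrix(columns: dict[str, list[int]]) -> pd.DataFrame:
    n = len(next(iter(columns.values())))
    frame = pd.DataFrame(
        {
            "model_id": ["m"] * n,
            "clamped_node": ["x"] * n,
            "clamp_value": [0] * n,
            "attractor_idx": range(n),
            "state_idx": [0] * n,
        }
    )
    for name, values in columns.items():
        frame[name] = values
    return frame


def marker_matrix(rows: list[tuple[int, ...]]) -> pd.DataFrame:
    return as_matrix({name: [r[i] for r in rows] for i, name in enumerate(MARKER_NAMES)})


class TestVectorAngle:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1, 0), (0, 1), 90.0),
            ((1, 1), (2, 2), 0.0),
            ((1, 0), (-1, 0), 180.0),
            ((1, 0), (1, 1), 45.0),
        ],
    )
    def test_reference_angles(self, a, b, expected):
        assert vector_angle(np.array(a), np.array(b)) == pytest.approx(expected, abs=1e-05)

    def test_zero_vector_raises(self):
        with pytest.raises(ZeroVectorError):
            vector_angle(np.zeros(2), np.ones(2))


class TestPCALoadings:
    def test_identical_columns_have_parallel_loadings(self):
        m = as_matrix({"A": [0, 1, 0, 1], "B": [0, 1, 0, 1], "C": [1, 0, 0, 1]})
        result = pca_loadings(m)
        assert result.scorable
        assert vector_angle(result.loadings["A"], result.loadings["B"]) == pytest.approx(0.0, abs=1e-09)

    def test_anti_correlated_columns_have_opposite_loadings(self):
        m = as_matrix({"A": [0, 1, 0, 1], "B": [1, 0, 1, 0], "C": [1, 1, 0, 0]})
        result = pca_loadings(m)
        assert vector_angle(result.loadings["A"], result.loadings["B"]) == pytest.approx(180.0, abs=1e-09)

    def test_rank_one_matrix_puts_all_variance_on_pc1(self):
        m = as_matrix({"A": [0, 1, 0, 1], "B": [0, 1, 0, 1], "C": [0, 1, 0, 1]})
        result = pca_loadings(m)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_constant_matrix_flagged_unscorable(self):
        m = as_matrix({"A": [1, 1, 1], "B": [0, 0, 0], "C": [0, 1, 0]})
        result = pca_loadings(m)
        assert not result.scorable
        assert "nonzero-variance" in result.reason

    def test_single_row_flagged_unscorable(self):
        m = as_matrix({"A": [1], "B": [0]})
        assert not pca_loadings(m).scorable

    def test_sign_convention_largest_loading_positive(self):
        m = as_matrix({"A": [0, 1, 0, 1, 1], "B": [1, 0, 0, 1, 0], "C": [1, 1, 0, 0, 1]})
        result = pca_loadings(m)
        stacked = np.array([result.loadings[c] for c in ("A", "B", "C")])
        for i in range(2):
            j = int(np.argmax(np.abs(stacked[:, i])))
            assert stacked[j, i] > 0


class TestScoreModel:
    def test_identical_pluripotency_columns_give_zero_pluri_angle(self):
        rows = [
            (0, 0, 0, 1, 1),
            (1, 1, 1, 0, 0),
            (0, 0, 0, 1, 0),
            (1, 1, 1, 0, 1),
        ]
        for aggregate in ("sum", "mean"):
            score = score_matrix(marker_matrix(rows), aggregate=aggregate)
            assert score.scorable
            assert score.pluri_angle == pytest.approx(0.0, abs=1e-07)

    def test_orthogonal_groups_give_ninety_degree_cross_angle(self):
        loadings = {
            "OCT3/4": np.array([1.0, 0.0]),
            "SOX2": np.array([1.0, 0.0]),
            "NANOG": np.array([1.0, 0.0]),
            "BMP4": np.array([0.0, 1.0]),
            "GADD45G": np.array([0.0, 1.0]),
        }
        from pluriscreen.model_scoring import PCAResult

        score = score_model(PCAResult(loadings, (0.6, 0.4), True))
        assert score.cross_angle == pytest.approx(90.0)
        assert score.pluri_angle == pytest.approx(0.0)
        assert score.diff_angle == pytest.approx(0.0)

    def test_cross_angle_matches_brute_force_group_means(self):
        rng = np.random.default_rng(123)
        vectors = {name: rng.normal(size=2) for name in MARKER_NAMES}
        from pluriscreen.model_scoring import PCAResult

        score = score_model(PCAResult(vectors, (0.5, 0.3), True))
        unit = lambda v: v / np.linalg.norm(v)
        pluri = np.mean([unit(vectors[g]) for g in ("OCT3/4", "SOX2", "NANOG")], axis=0)
        diff = np.mean([unit(vectors[g]) for g in ("BMP4", "GADD45G")], axis=0)
        expected = np.degrees(
            np.arccos(np.clip(np.dot(unit(pluri), unit(diff)), -1, 1))
        )
        assert score.cross_angle == pytest.approx(expected)

    def test_sum_equals_three_times_mean(self):
        rng = np.random.default_rng(42)
        rows = [tuple(rng.integers(0, 2, size=5)) for _ in range(12)]
        m = marker_matrix(rows)
        s_sum = score_matrix(m, aggregate="sum")
        s_mean = score_matrix(m, aggregate="mean")
        assert s_sum.pluri_angle == pytest.approx(3 * s_mean.pluri_angle)
        assert s_sum.cross_angle == pytest.approx(s_mean.cross_angle)

    def test_angles_invariant_to_row_permutation(self):
        rng = np.random.default_rng(7)
        rows = [tuple(rng.integers(0, 2, size=5)) for _ in range(10)]
        base = score_matrix(marker_matrix(rows))
        shuffled_rows = [rows[i] for i in rng.permutation(len(rows))]
        shuffled = score_matrix(marker_matrix(shuffled_rows))
        assert base.pluri_angle == pytest.approx(shuffled.pluri_angle)
        assert base.diff_angle == pytest.approx(shuffled.diff_angle)
        assert base.cross_angle == pytest.approx(shuffled.cross_angle)

    def test_angles_invariant_to_global_sign_flip(self):
        rng = np.random.default_rng(11)
        vectors = {name: rng.normal(size=2) for name in MARKER_NAMES}
        from pluriscreen.model_scoring import PCAResult

        flipped = {k: -v for k, v in vectors.items()}
        a = score_model(PCAResult(vectors, (0.5, 0.4), True))
        b = score_model(PCAResult(flipped, (0.5, 0.4), True))
        assert a.pluri_angle == pytest.approx(b.pluri_angle)
        assert a.diff_angle == pytest.approx(b.diff_angle)
        assert a.cross_angle == pytest.approx(b.cross_angle)

    def test_zero_marker_vector_is_unscorable_not_an_exception(self):
        vectors = {name: np.ones(2) for name in MARKER_NAMES}
        vectors["BMP4"] = np.zeros(2)
        from pluriscreen.model_scoring import PCAResult

        score = score_model(PCAResult(vectors, (0.5, 0.4), True), model_id="degenerate")
        assert not score.scorable
        assert score.pluri_angle is None

    def test_missing_marker_column_raises(self):
        m = as_matrix({"A": [0, 1, 1], "B": [1, 0, 1]})
        with pytest.raises(ValueError, match="not matrix columns"):
            score_matrix(m)


def make_score(model_id, pluri, cross):
    return ModelScore(model_id, pluri, 10.0, cross, True)


class TestSelectModels:
    def test_dominant_model_ranks_first(self):
        a = make_score("C1__+X", 5.0, 170.0)
        b = make_score("C2__+X", 40.0, 90.0)
        ranked = select_models([a, b], k=2)
        assert ranked[0].model_id == "C1__+X"
        assert ranked[0].pareto_rank == 1
        assert ranked[1].pareto_rank == 2

    def test_incomparable_models_share_the_front(self):
        a = make_score("C1__+X", 5.0, 120.0)
        b = make_score("C2__+X", 20.0, 170.0)
        ranked = pareto_ranks([a, b])
        assert {s.pareto_rank for s in ranked} == {1}

    def test_k_equal_to_cluster_count_returns_all_scorable(self):
        scores = [make_score(f"C{i}__+X", float(i), 100.0 + i) for i in range(1, 6)]
        scores.append(ModelScore("C9__+X", None, None, None, False, "degenerate"))
        selected = select_models(scores, k=5)
        assert {s.model_id for s in selected} == {f"C{i}__+X" for i in range(1, 6)}

    def test_unscorable_models_never_selected(self):
        scores = [
            make_score("C1__+X", 5.0, 170.0),
            ModelScore("C2__+X", None, None, None, False, "zero vector"),
        ]
        selected = select_models(scores, k=8)
        assert all(s.scorable for s in selected)

    def test_diff_angle_gate_filters_before_ranking(self):
        a = make_score("C1__+X", 5.0, 170.0)
        b = ModelScore("C2__+X", 6.0, 120.0, 160.0, True)
        selected = select_models([a, b], k=8, max_diff_angle=45.0)
        assert {s.model_id for s in selected} == {"C1__+X"}

    def test_k_selects_top_clusters_not_top_models(self):
        scores = [
            make_score("C1__+X", 5.0, 170.0),
            make_score("C1__-X", 6.0, 169.0),
            make_score("C2__+X", 7.0, 168.0),
            make_score("C3__+X", 8.0, 167.0),
        ]
        selected = select_models(scores, k=2)
        assert {s.cluster for s in selected} == {"C1", "C2"}
        assert len([s for s in selected if s.cluster == "C1"]) == 2

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            select_models([make_score("C1__+X", 1.0, 1.0)], k=0)


class TestPlantedSelection:
    @pytest.mark.parametrize("seed", [0, 2])
    def test_planted_feedback_model_is_coherent_and_selected(self, seed):
        """End to end: the planted self-renewal loop scores as designed.

        The generator's planted feedback is constructed so its model keeps
        the pluripotency markers coherent (small summed angle) and opposed
        to the differentiation markers (large cross angle); it must land in
        the selected top-k set among the random decoy models.
        """
        from pluriscreen.boolean_dynamics import perturbation_screen
        from pluriscreen.model_generation import enumerate_models
        from pluriscreen.network_expansion import (
            cluster_by_signature,
            expand_network,
            filter_targets,
            reduced_network,
        )
        from pluriscreen.synthetic_data import (
            SyntheticConfig,
            core_network_fixture,
            generate_annotation,
            generate_perturbation_experiments,
        )

        config = SyntheticConfig(seed=seed)
        fb = config.planted_feedback
        core = core_network_fixture()
        experiments, truth = generate_perturbation_experiments(config)
        annotation = generate_annotation(config, truth)
        expanded = expand_network(core, experiments)
        clusters = cluster_by_signature(filter_targets(expanded, annotation), expanded)
        wanted = (frozenset(fb.positives), frozenset(fb.negatives))
        (planted_cluster,) = [c for c in clusters if c.signature == wanted]
        reduced = reduced_network(core, clusters)
        scores = [
            score_matrix(perturbation_screen(m.network(), model_id=m.id), model_id=m.id)
            for m in enumerate_models(reduced)
        ]
        planted_id = f"{planted_cluster.id}__{fb.sign}{fb.target}"
        (planted,) = [s for s in scores if s.model_id == planted_id]
        assert planted.scorable
        assert planted.pluri_angle < 45.0
        assert planted.cross_angle > 120.0
        selected = select_models(scores, k=8)
        assert planted_id in {s.model_id for s in selected}
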