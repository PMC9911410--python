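"""Shapley attributions, embedding, density clustering, driver ranking."""

import numpy as np
import pytest
import xgboost as xgb

from rebel import _treeshap
from rebel.explain import (
    AttributionMatrix,
    cluster_density,
    compute_attributions,
    embed_2d,
    estimate_eps,
    filter_correct_predictions,
    rank_cluster_drivers,
)
from rebel.model import ModelConfig, TrainedModelBundle, train_eval_subsets


def _bundle_from_predictions(probs, labels):
    return TrainedModelBundle(
        comparison="toy",
        best_params=(1, 3),
        n_rounds=1,
        models=(),
        element_ids=tuple(f"e{i}" for i in range(len(labels))),
        labels=np.asarray(labels),
        heldout_predictions=np.asarray(probs),
        source_model=np.zeros(len(labels), dtype=int),
        auc_per_subset=(0.5,) * 5,
    )


class TestCorrectPredictionFilter:
    def test_confident_correct_kept(self):
        b = _bundle_from_predictions([0.9, 0.1], [1, 0])
        np.testing.assert_array_equal(filter_correct_predictions(b), [0, 1])

    def test_half_probability_positive_dropped_negative_kept(self):
        b = _bundle_from_predictions([0.5, 0.5], [1, 0])
        np.testing.assert_array_equal(filter_correct_predictions(b), [1])

    def test_kept_set_equals_direct_scan(self):
        rng = np.random.default_rng(8)
        probs = rng.uniform(size=100)
        labels = rng.integers(0, 2, size=100)
        b = _bundle_from_predictions(probs, labels)
        expected = [
            i for i in range(100)
            if (probs[i] > 0.5) == (labels[i] == 1)
        ]
        np.testing.assert_array_equal(
            filter_correct_predictions(b), expected
        )


def _train_small(X, y, seed=5, rounds=20, depth=3):
    ids = [f"e{i}" for i in range(len(y))]
    config = ModelConfig(seed=seed, boosting_rounds=rounds)
    return train_eval_subsets(X, y, ids, (1, depth), config, n_rounds=rounds)


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(5)
    n = 120
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 6))
    X[:, 0] += 2.5 * y
    X[:, 1] -= 1.5 * y
    return X, y, _train_small(X, y)


class TestAttributions:

    def test_local_accuracy_identity(self, trained):
        X, y, b = trained
        at = compute_attributions(b, X)
        keep = filter_correct_predictions(b)
        margins = np.empty(len(keep))
        for s in np.unique(at.source_model):
            rows = np.flatnonzero(at.source_model == s)
            margins[rows] = _treeshap.margins(
                _treeshap.parse_booster(b.models[s]), X[keep[rows]]
            )
        np.testing.assert_allclose(
            at.values.sum(axis=1) + at.base_values, margins, atol=1e-6
        )

    def test_agrees_with_xgboost_tree_shap(self, trained):
        """Dual route: our float64 TreeSHAP matches the booster's built-in
        contribution predictor to float32 output resolution."""
        X, y, b = trained
        at = compute_attributions(b, X)
        keep = filter_correct_predictions(b)
        for s in np.unique(at.source_model):
            rows = np.flatnonzero(at.source_model == s)
            ref = b.models[s].predict(
                xgb.DMatrix(X[keep[rows]]), pred_contribs=True
            )
            np.testing.assert_allclose(
                at.values[rows], ref[:, :-1], atol=1e-4
            )
            np.testing.assert_allclose(
                at.base_values[rows], ref[:, -1], atol=1e-4
            )
            margins = b.models[s].predict(
                xgb.DMatrix(X[keep[rows]]), output_margin=True
            )
            np.testing.assert_allclose(
                at.values[rows].sum(axis=1) + at.base_values[rows],
                margins, atol=1e-4,
            )

    def test_unused_feature_gets_zero_attribution(self):
        rng = np.random.default_rng(6)
        n = 100
        y = np.repeat([0, 1], n // 2)
        X = np.zeros((n, 4))
        X[:, 0] = y + rng.normal(scale=0.1, size=n)  # only f0 informative
        # other columns constant -> never split on, attribution must be 0
        b = _train_small(X, y, seed=6)
        at = compute_attributions(b, X)
        np.testing.assert_array_equal(at.values[:, 1:], 0.0)

    def test_single_stump_matches_closed_form(self):
        # one tree of depth 1 on a binary feature: the Shapley value of the
        # split feature is f(x) minus the cover-weighted mean leaf value, and
        # all other features get zero
        X = np.array([[0.0], [0.0], [1.0], [1.0], [1.0], [0.0]])
        y = np.array([0, 0, 1, 1, 1, 0])
        params = {
            "objective": "binary:logistic", "max_depth": 1, "eta": 1.0,
            "lambda": 0.0, "tree_method": "hist", "nthread": 1, "seed": 0,
        }
        dtr = xgb.DMatrix(X, label=y)
        bst = xgb.train(params, dtr, num_boost_round=1)
        margin = bst.predict(dtr, output_margin=True)
        df = bst.trees_to_dataframe()
        leaves = df[df["Feature"] == "Leaf"]
        expected_base = float(
            (leaves["Gain"] * leaves["Cover"]).sum() / leaves["Cover"].sum()
        )
        phi, base = _treeshap.shap_values(
            _treeshap.parse_booster(bst), X
        )
        np.testing.assert_allclose(base, expected_base, atol=1e-6)
        np.testing.assert_allclose(phi[:, 0], margin - expected_base,
                                   atol=1e-6)
        # the booster's own contribution predictor agrees
        contrib = bst.predict(dtr, pred_contribs=True)
        np.testing.assert_allclose(contrib[:, -1], expected_base, atol=1e-6)
        np.testing.assert_allclose(
            contrib[:, 0], margin - expected_base, atol=1e-6
        )

    def test_elements_without_source_model_rejected(self):
        b = _bundle_from_predictions([0.9], [1])
        object.__setattr__(b, "source_model", np.array([-1]))
        with pytest.raises(ValueError, match="source model"):
            compute_attributions(b, np.zeros((1, 2)), keep=[0])


class TestEmbedding:
    def test_same_seed_identical_coordinates(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 8))
        a = embed_2d(X, perplexity=10, seed=3)
        b = embed_2d(X, perplexity=10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_duplicated_rows_land_close(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 6))
        X = np.vstack([X, X[:5]])  # duplicates of the first five rows
        coords = embed_2d(X, perplexity=8, seed=1)
        spread = np.linalg.norm(coords.max(0) - coords.min(0))
        for i in range(5):
            d = np.linalg.norm(coords[i] - coords[40 + i])
            assert d < 0.05 * spread

    def test_orthogonal_blocks_separate(self):
        rng = np.random.default_rng(9)
        block1 = np.hstack([rng.uniform(1, 2, size=(40, 5)),
                            np.zeros((40, 5))])
        block2 = np.hstack([np.zeros((40, 5)),
                            rng.uniform(1, 2, size=(40, 5))])
        X = np.vstack([block1, block2])
        coords = embed_2d(X, perplexity=10, seed=2)
        c1, c2 = coords[:40], coords[40:]
        between = np.linalg.norm(c1.mean(0) - c2.mean(0))
        within = np.percentile(
            np.concatenate([
                np.linalg.norm(c1 - c1.mean(0), axis=1),
                np.linalg.norm(c2 - c2.mean(0), axis=1),
            ]), 95,
        )
        assert between > within

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="perplexity"):
            embed_2d(np.zeros((10, 3)), perplexity=10, seed=1)


def _dbscan_oracle(coords, eps, min_pts):
    """Textbook DBSCAN by BFS over the eps-graph (independent of sklearn)."""
    n = len(coords)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = [len(nb) >= min_pts for nb in neighbors]
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        queue = [i]
        labels[i] = cid
        while queue:
            j = queue.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    queue.append(k)
        cid += 1
    return labels


class TestDensityClustering:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(1)
        blob1 = rng.normal(0, 0.1, size=(50, 2))
        blob2 = rng.normal(10, 0.1, size=(50, 2))
        labels = cluster_density(np.vstack([blob1, blob2]), eps=1.0,
                                 min_pts=5)
        assert len(set(labels[:50])) == 1
        assert len(set(labels[50:])) == 1
        assert labels[0] != labels[50]

    def test_identical_points_one_cluster(self):
        coords = np.zeros((30, 2))
        labels = cluster_density(coords, eps=0.5, min_pts=5)
        assert set(labels) == {0}

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValueError):
            cluster_density(np.zeros((5, 2)), eps=0.0)

    def test_matches_independent_dbscan_oracle(self):
        rng = np.random.default_rng(2)
        coords = np.vstack([
            rng.normal(0, 0.5, size=(80, 2)),
            rng.normal(6, 0.5, size=(80, 2)),
            rng.uniform(-10, 20, size=(40, 2)),  # scattered noise
        ])
        eps, min_pts = 0.8, 6
        got = cluster_density(coords, eps=eps, min_pts=min_pts)
        want = _dbscan_oracle(coords, eps, min_pts)
        # compare as partitions: identical noise sets, matching core blocks
        np.testing.assert_array_equal(got == -1, want == -1)
        for cid in set(want) - {-1}:
            members = np.flatnonzero(want == cid)
            core_labels = set(got[members]) - {-1}
            assert len(core_labels) == 1

    def test_eps_estimate_positive_and_deterministic(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(100, 2))
        e1, e2 = estimate_eps(coords), estimate_eps(coords)
        assert e1 == e2 > 0


class TestDriverRanking:
    def _attribs(self, values, counts):
        n, M = values.shape
        return (
            AttributionMatrix(
                element_ids=tuple(f"e{i}" for i in range(n)),
                motif_ids=tuple(f"m{j}" for j in range(M)),
                values=values,
                base_values=np.zeros(n),
                source_model=np.zeros(n, dtype=int),
            ),
            counts,
        )

    def test_single_driver_takes_full_fraction(self):
        values = np.zeros((6, 3))
        values[:, 1] = 2.0
        counts = np.ones((6, 3), dtype=int)
        at, counts = self._attribs(values, counts)
        (drv,) = rank_cluster_drivers(at, [0] * 6, counts, k=3)
        motif, _, mode, frac = drv.top_motifs[0]
        assert motif == "m1"
        assert frac == pytest.approx(1.0)
        assert mode == "present-predictive"

    def test_fractions_sum_to_one_over_all_motifs(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(20, 7))
        counts = rng.integers(0, 3, size=(20, 7))
        at, counts = self._attribs(values, counts)
        (drv,) = rank_cluster_drivers(at, [0] * 20, counts, k=None)
        assert sum(t[3] for t in drv.top_motifs) == pytest.approx(1.0)

    def test_absent_predictive_mode(self):
        # positive attribution concentrated on elements lacking the site
        values = np.zeros((10, 2))
        counts = np.zeros((10, 2), dtype=int)
        counts[:5, 0] = 1
        values[:5, 0] = -1.0   # carriers pushed down
        values[5:, 0] = +1.0   # non-carriers pushed up
        at, counts = self._attribs(values, counts)
        (drv,) = rank_cluster_drivers(at, [0] * 10, counts, k=2)
        assert drv.top_motifs[0][0] == "m0"
        assert drv.top_motifs[0][2] == "absent-predictive"

    def test_present_only_filter(self):
        values = np.zeros((10, 2))
        counts = np.zeros((10, 2), dtype=int)
        counts[:5, 0] = 1
        values[:5, 0] = 1.0
        values[5:, 1] = 1.0  # m1 predictive through absence
        at, counts = self._attribs(values, counts)
        (drv,) = rank_cluster_drivers(at, [0] * 10, counts, k=2,
                                      present_only=True)
        assert [t[0] for t in drv.top_motifs] == ["m0"]

    def test_noise_points_excluded(self):
        values = np.ones((8, 2))
        counts = np.ones((8, 2), dtype=int)
        at, counts = self._attribs(values, counts)
        drivers = rank_cluster_drivers(at, [0, 0, 0, 0, -1, -1, 1, 1],
                                       counts, k=2)
        assert [d.cluster_id for d in drivers] == [0, 1]
        assert len(drivers[0].members) == 4
        assert len(drivers[1].members) == 2
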