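import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from odormetric import (
    DescriptorProfiles,
    concentration_contrast,
    expert_alignment,
    jaccard_dissimilarity,
    pairwise_report,
    retrieve,
    triplet_generalization_accuracy,
)
from odormetric.io import FeatureTable
from odormetric.synthetic import random_triplets, sample_triplets_from_distances


def _setup(n=12, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    D = squareform(pdist(X))
    trips = sample_triplets_from_distances(D, 2000, seed=seed)
    return D, trips


class TestTGA:
    def test_generating_distance_scores_100(self):
        D, trips = _setup()
        assert triplet_generalization_accuracy(D, trips) == 100.0

    def test_negated_distance_scores_0(self):
        D, trips = _setup()
        assert triplet_generalization_accuracy(-D, trips) == 0.0

    def test_complementarity_without_ties(self):
        D, trips = _setup(seed=2)
        t = triplet_generalization_accuracy(D, trips)
        assert t + triplet_generalization_accuracy(-D, trips) == pytest.approx(100.0)

    def test_matches_naive_recount_on_10000_triples(self):
        rng = np.random.default_rng(4)
        n = 25
        D_model = squareform(pdist(rng.normal(size=(n, 4))))
        trips = random_triplets(n, 10_000, seed=4)
        fast = triplet_generalization_accuracy(D_model, trips)
        correct = sum(
            1 for a, p, ng in trips.triples if D_model[a, p] < D_model[a, ng]
        )
        assert fast == pytest.approx(100.0 * correct / len(trips))

    def test_random_embedding_near_chance(self):
        # balanced synthetic triplets vs an unrelated random embedding
        rng = np.random.default_rng(5)
        n = 30
        D_true = squareform(pdist(rng.normal(size=(n, 3))))
        trips = sample_triplets_from_distances(D_true, 10_000, seed=5)
        D_rand = squareform(pdist(rng.normal(size=(n, 3))))
        tga = triplet_generalization_accuracy(D_rand, trips)
        assert 48.0 <= tga <= 52.0  # binomial band at m=10,000

    @pytest.mark.parametrize("transform", [np.square, lambda d: np.log1p(d)])
    def test_invariant_under_monotone_transform(self, transform):
        D, trips = _setup(seed=6)
        base = triplet_generalization_accuracy(D, trips)
        assert triplet_generalization_accuracy(transform(D), trips) == base

    def test_model_side_ties(self):
        D, trips = _setup(seed=7)
        flat = np.ones_like(D)
        np.fill_diagonal(flat, 0.0)
        assert triplet_generalization_accuracy(flat, trips) == 0.0
        assert triplet_generalization_accuracy(flat, trips, tie_credit=0.5) == 50.0

    def test_empty_triplets_rejected(self):
        D, trips = _setup()
        with pytest.raises(ValueError):
            triplet_generalization_accuracy(D, trips.subset(np.array([], dtype=int)))

    def test_callable_distance_agrees_with_matrix(self):
        D, trips = _setup(seed=8)
        small = trips.subset(np.arange(50))
        ids = small.ids
        fn = lambda a, b: D[ids.index(a), ids.index(b)]
        assert triplet_generalization_accuracy(fn, small) == \
            triplet_generalization_accuracy(D, small)


class TestPairwiseReport:
    def test_three_point_normalization(self):
        D = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        out = pairwise_report(D)
        assert out[0, 1] == 0.0 and out[0, 2] == 0.5 and out[1, 2] == 1.0

    def test_idempotent(self, rng):
        D = squareform(pdist(rng.normal(size=(8, 3))))
        once = pairwise_report(D)
        np.testing.assert_allclose(pairwise_report(once), once, atol=1e-12)

    def test_symmetry_and_zero_diagonal(self, rng):
        D = squareform(pdist(rng.normal(size=(6, 2))))
        out = pairwise_report(D)
        np.testing.assert_allclose(out, out.T)
        np.testing.assert_array_equal(np.diag(out), 0.0)

    def test_two_molecules(self):
        out = pairwise_report(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert out[0, 1] == 1.0

    def test_degenerate_warns(self):
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.warns(UserWarning):
            out = pairwise_report(D)
        np.testing.assert_array_equal(out, np.ones((3, 3)) - np.eye(3))
        with pytest.warns(UserWarning):
            out = pairwise_report(np.zeros((3, 3)))
        np.testing.assert_array_equal(out, np.zeros((3, 3)))


class TestRetrieve:
    def test_matches_sort_oracle(self, rng):
        X = rng.normal(size=(10, 3))
        D = squareform(pdist(X))
        ids = [f"m{i}" for i in range(10)]
        got = retrieve(D, ids, "m0", k=4)
        oracle = sorted(range(1, 10), key=lambda i: (D[0, i], ids[i]))[:4]
        assert [g[0] for g in got] == [ids[i] for i in oracle]

    def test_full_ranking(self, rng):
        D = squareform(pdist(rng.normal(size=(6, 2))))
        ids = [f"m{i}" for i in range(6)]
        assert len(retrieve(D, ids, "m2", k=5)) == 5

    def test_duplicate_ranks_first_with_zero_distance(self):
        X = np.array([[0.0, 0], [0, 0], [5, 5], [9, 9]])
        D = squareform(pdist(X))
        got = retrieve(D, ["q", "dup", "b", "c"], "q", k=2)
        assert got[0] == ("dup", 0.0)

    def test_lexicographic_tie_break(self):
        D = np.array([[0, 1, 1], [1, 0, 2], [1, 2, 0]], dtype=float)
        got = retrieve(D, ["q", "zeta", "alpha"], "q", k=2)
        assert [g[0] for g in got] == ["alpha", "zeta"]

    def test_unknown_query(self, rng):
        D = squareform(pdist(rng.normal(size=(4, 2))))
        with pytest.raises(KeyError):
            retrieve(D, ["a", "b", "c", "d"], "nope", k=2)


class TestExpertAlignment:
    def _expert(self, seed=0, n=15):
        rng = np.random.default_rng(seed)
        Y = (rng.random((n, 6)) > 0.5).astype(float)
        Y[Y.sum(axis=1) == 0, 0] = 1.0
        return DescriptorProfiles(
            ids=[f"m{i}" for i in range(n)],
            Y=Y,
            vocabulary=[f"d{j}" for j in range(6)],
            mode="binary",
        )

    def test_self_oracle_scores_100(self):
        prof = self._expert()
        D = jaccard_dissimilarity(prof).values
        # break exact ties the way the triplet builder never emits them
        tga, table = expert_alignment(D, prof, max_triplets=2000)
        assert tga == 100.0
        assert table.empty

    def test_reversed_metric_scores_0_with_full_discord_table(self):
        prof = self._expert(seed=1)
        D = jaccard_dissimilarity(prof).values
        tga, table = expert_alignment(1.0 - D + np.eye(len(prof.ids)), prof,
                                      max_triplets=500, n_examples=5)
        assert tga < 50.0
        assert len(table) == 5
        assert set(table.columns) >= {"anchor", "expert_closer", "expert_farther"}

    def test_too_few_molecules(self):
        prof = DescriptorProfiles(
            ids=["a", "b"], Y=[[1, 0], [0, 1]], vocabulary=["x", "y"], mode="binary"
        )
        with pytest.raises(ValueError):
            expert_alignment(np.zeros((2, 2)), prof)

    def test_controlled_noise_alignment_between_chance_and_ceiling(self):
        # a metric trained on non-expert binarized triplets, scored against a
        # synthetic expert relabeling: 20% descriptor relabeling lands the
        # alignment strictly between the chance level and the noise-free
        # ceiling
        from odormetric import (
            DeepTripletEmbedder,
            SyntheticSpec,
            binarize_profiles,
            build_triplets,
            expert_relabeling,
            generate,
            restrict_vocabulary,
        )
        from odormetric.recovery import _distance_rescale

        seed = 3
        spec = SyntheticSpec(n_molecules=80, latent_dim=4, feature_dim=60, seed=seed)
        data = generate(spec)
        shared = spec.vocabulary[:16]
        nonexpert = restrict_vocabulary(
            binarize_profiles(data.ratings, "high", 0.25, include_pleasant=True),
            shared,
        )
        trips = build_triplets(jaccard_dissimilarity(nonexpert), cap=8_000, seed=seed)
        X = _distance_rescale(data.features_high.X)
        model = DeepTripletEmbedder(
            hidden_layer_sizes=(64, 32), n_components=10, epochs=60,
            random_state=seed,
        ).fit(X, trips.triples)
        D = model.pairwise_distance(X)

        scores = {}
        for flip in (0.0, 0.2):
            expert = restrict_vocabulary(
                expert_relabeling(data, flip_fraction=flip, seed=seed + 1), shared
            )
            scores[flip], _ = expert_alignment(D, expert, max_triplets=8_000,
                                               seed=seed)
        assert 50.0 < scores[0.2] < scores[0.0]


class _IdentityEmbedder:
    def pairwise_distance(self, X, X2=None):
        from scipy.spatial.distance import cdist

        if X2 is None:
            return squareform(pdist(X, metric="sqeuclidean"))
        return cdist(X, X2, metric="sqeuclidean")


def _table(ids, X):
    return FeatureTable(
        ids=ids, X=X, feature_names=[f"f{i}" for i in range(X.shape[1])]
    )


class TestConcentrationContrast:
    def test_identical_tables_no_flags(self, rng):
        X = rng.normal(size=(8, 3))
        ids = [f"m{i}" for i in range(8)]
        out = concentration_contrast(_IdentityEmbedder(), _table(ids, X), _table(ids, X))
        assert (out["self_distance"] == 0).all()
        assert not out["flagged"].any()
        assert len(out) == 8

    def test_planted_swap_is_flagged(self, rng):
        X = rng.normal(size=(8, 3))
        ids = [f"m{i}" for i in range(8)]
        X_low = X.copy()
        X_low[2] = X[5] + rng.normal(scale=0.01, size=3)  # molecule 2 now smells like 5
        out = concentration_contrast(_IdentityEmbedder(), _table(ids, X), _table(ids, X_low))
        assert out.loc[out["cid"] == "m2", "flagged"].item()

    def test_id_mismatch(self, rng):
        X = rng.normal(size=(4, 2))
        a = _table(["a", "b", "c", "d"], X)
        b = _table(["a", "b", "c", "e"], X)
        with pytest.raises(ValueError):
            concentration_contrast(_IdentityEmbedder(), a, b)
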