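"""Planted-structure recovery scenarios.

Each scenario generates data with known perceptual structure, runs one or
more learners end-to-end, and returns the measured quantities.  They serve
three purposes: they are the package's self-tests of the learners, the
backbone of the acceptance checks, and worked examples of the full pipeline.

Problem sizes are chosen so every scenario runs in seconds to a couple of
minutes on one CPU; they are documented in docs/methods.md.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from .deep import DeepTripletEmbedder
from .evaluation import triplet_generalization_accuracy
from .io import average_profiles, rescale_features
from .mahalanobis import MahalanobisTripletMetric
from .mds import OrdinalMDS, dimension_sweep
from .synthetic import (
    SyntheticSpec,
    generate,
    random_triplets,
    sample_triplets_from_distances,
)
from .triplets import DissimilarityMatrix, build_triplets, cosine_dissimilarity


# backwards-compatible alias used by the scenarios and tests
_distance_rescale = rescale_features


def scenario_mds_recovery(
    seed: int = 0,
    n: int = 100,
    q: int = 3,
    n_triplets: int = 20_000,
    max_iter: int = 200,
    sweep_dims: tuple[int, ...] = (1, 2, 3),
) -> dict:
    """Ordinal MDS on noise-free distances from a planted q-D configuration.

    Measures final stress, triplet accuracy on triplets drawn from the same
    matrix, the Procrustes residual against the generating coordinates, the
    monotonicity of the stress trace, and a dimension sweep.
    """
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, q))
    D = squareform(pdist(Z))
    D = D / D.max()
    matrix = DissimilarityMatrix(
        ids=[f"M{i:04d}" for i in range(n)], values=D, measure="cosine"
    )
    triplets = build_triplets(matrix, cap=n_triplets, seed=seed)

    model = OrdinalMDS(
        n_components=q, mode="ordinal", max_iter=max_iter, random_state=seed
    ).fit(matrix)
    tga = triplet_generalization_accuracy(model.pairwise_distance(), triplets)
    _, _, residual = procrustes(Z, model.embedding_)
    trace = model.stress_trace_
    sweep = dimension_sweep(
        matrix, list(sweep_dims), triplets, seed=seed, max_iter=max_iter
    )
    return {
        "stress": model.stress_,
        "tga": tga,
        "procrustes_residual": float(residual),
        "stress_trace_monotone": bool(np.all(np.diff(trace) <= 1e-12)),
        "sweep_tga": sweep["tga_percent"].tolist(),
        "sweep_stress": sweep["stress"].tolist(),
        "sweep_dims": list(sweep_dims),
    }


def scenario_mahalanobis_recovery(
    seed: int = 0,
    n: int = 200,
    d: int = 10,
    n_train: int = 20_000,
    n_test: int = 5_000,
    epochs: int = 200,
    planted_weight: float = 10.0,
) -> dict:
    """Recover a planted diagonal metric diag(w, 1, ..., 1) from triplets.

    Triplets are oriented by the planted metric; the learner starts from the
    Euclidean baseline (identity map) and must beat it on held-out triplets.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d)) / np.sqrt(2 * d)  # squared distances ~ O(1)
    w = np.ones(d)
    w[0] = planted_weight
    D_true = squareform(pdist(X * np.sqrt(w), metric="sqeuclidean"))

    train = sample_triplets_from_distances(D_true, n_train, seed=seed)
    test = sample_triplets_from_distances(D_true, n_test, seed=seed + 10_000)

    model = MahalanobisTripletMetric(
        n_components=d, epochs=epochs, random_state=seed
    ).fit(X, train.triples)
    D_learned = model.pairwise_distance(X)
    D_eucl = squareform(pdist(X, metric="sqeuclidean"))

    eigs = np.linalg.eigvalsh(model.M_)
    return {
        "tga": triplet_generalization_accuracy(D_learned, test),
        "euclidean_tga": triplet_generalization_accuracy(D_eucl, test),
        "min_eigenvalue": float(eigs.min()),
        "final_loss": float(model.loss_trace_[-1]),
    }


def _nonlinear_lift_data(seed: int, n: int, q: int = 2, d: int = 20):
    """Latent plane, fixed random nonlinear lift to feature space, triplets
    from latent Euclidean orderings."""
    spec = SyntheticSpec(
        n_molecules=n,
        latent_dim=q,
        feature_dim=d,
        feature_map="nonlinear-lift",
        feature_noise_sd=0.02,
        hedonic_weight=1.0,
        n_subjects=2,
        subject_noise_sd=0.0,
        lift_scale=4.0,
        lift_hidden=8,
        seed=seed,
    )
    data = generate(spec)
    X = _distance_rescale(data.features_high.X)
    D_true = data.latent_distance("high")
    return X, D_true


def scenario_deep_vs_linear(
    seed: int = 0,
    n: int = 160,
    n_train: int = 15_000,
    n_val: int = 3_000,
    n_test: int = 4_000,
    deep_epochs: int = 120,
    linear_epochs: int = 150,
) -> dict:
    """Deep metric vs Mahalanobis vs raw baselines under a nonlinear lift.

    The planted orderings live in a 2-D latent space lifted nonlinearly into
    feature space; a global linear metric cannot undo the lift, the deep
    embedder can.
    """
    X, D_true = _nonlinear_lift_data(seed, n)
    train = sample_triplets_from_distances(D_true, n_train, seed=seed)
    val = sample_triplets_from_distances(D_true, n_val, seed=seed + 20_000)
    test = sample_triplets_from_distances(D_true, n_test, seed=seed + 30_000)

    maha = MahalanobisTripletMetric(
        n_components=10, epochs=linear_epochs, random_state=seed
    ).fit(X, train.triples)
    deep = DeepTripletEmbedder(
        hidden_layer_sizes=(64, 32),
        n_components=10,
        epochs=deep_epochs,
        random_state=seed,
    ).fit(X, train.triples, validation_triplets=val.triples)

    D_eucl = squareform(pdist(X, metric="sqeuclidean"))
    D_cos = squareform(pdist(X, metric="cosine"))
    return {
        "deep_tga": triplet_generalization_accuracy(deep.pairwise_distance(X), test),
        "mahalanobis_tga": triplet_generalization_accuracy(
            maha.pairwise_distance(X), test
        ),
        "euclidean_tga": triplet_generalization_accuracy(D_eucl, test),
        "cosine_tga": triplet_generalization_accuracy(D_cos, test),
    }


def scenario_random_labels(
    seed: int = 0,
    n: int = 120,
    n_train: int = 8_000,
    n_val: int = 5_000,
    epochs: int = 40,
) -> dict:
    """Label-randomization null: training on coin-flip triplet orientations.

    No signal exists, so validation TGA must hover at the 50% chance level.
    """
    X, _ = _nonlinear_lift_data(seed, n)
    train = random_triplets(n, n_train, seed=seed)
    val = random_triplets(n, n_val, seed=seed + 40_000)
    deep = DeepTripletEmbedder(
        hidden_layer_sizes=(64, 32),
        n_components=10,
        epochs=epochs,
        random_state=seed,
    ).fit(X, train.triples, validation_triplets=val.triples)
    return {
        "final_val_tga": float(deep.val_tga_trace_[-1]),
        "mean_val_tga": float(deep.val_tga_trace_.mean()),
    }


def scenario_hedonic_ablation(
    seed: int = 0,
    n: int = 120,
    feature_dim: int = 60,
    latent_dim: int = 4,
    cap: int = 15_000,
    mds_components: int = 10,
    epochs: int = 100,
) -> dict:
    """Effect of dropping the hedonic ("pleasant") descriptor from triplets.

    The hedonic axis dominates both the ratings and the features, so
    removing it from triplet generation leaves orderings that depend on
    weaker, noisier axes: every learner's TGA should drop.
    """
    spec = SyntheticSpec(
        n_molecules=n,
        latent_dim=latent_dim,
        feature_dim=feature_dim,
        seed=seed,
    )
    data = generate(spec)
    X = _distance_rescale(data.features_high.X)
    results: dict = {}
    rng_split = np.random.default_rng(seed + 1)

    for label, include in (("with_pleasant", True), ("without_pleasant", False)):
        profiles = average_profiles(
            data.ratings, "high", include_pleasant=include
        )
        matrix = cosine_dissimilarity(profiles)
        triplets = build_triplets(matrix, cap=cap, seed=seed)
        m = len(triplets)
        perm = rng_split.permutation(m)
        n_test = m // 5
        n_val = m // 10
        test = triplets.subset(perm[:n_test])
        val = triplets.subset(perm[n_test : n_test + n_val])
        train = triplets.subset(perm[n_test + n_val :])

        mds = OrdinalMDS(
            n_components=mds_components, max_iter=150, random_state=seed
        ).fit(matrix)
        maha = MahalanobisTripletMetric(
            n_components=25, epochs=epochs, random_state=seed
        ).fit(X, train.triples)
        deep = DeepTripletEmbedder(
            hidden_layer_sizes=(64, 32),
            n_components=25,
            epochs=epochs,
            random_state=seed,
        ).fit(X, train.triples, validation_triplets=val.triples)

        results[label] = {
            "mds_tga": triplet_generalization_accuracy(mds.pairwise_distance(), test),
            "mahalanobis_tga": triplet_generalization_accuracy(
                maha.pairwise_distance(X), test
            ),
            "deep_tga": triplet_generalization_accuracy(
                deep.pairwise_distance(X), test
            ),
        }
    results["deltas"] = {
        k: results["with_pleasant"][k] - results["without_pleasant"][k]
        for k in results["with_pleasant"]
    }
    return results


def planted_recovery_suite(seed: int = 0, quick: bool = False) -> dict:
    """Run all planted-structure scenarios and check their thresholds.

    Returns a report with the measured values and per-scenario pass flags:
    (a) ordinal MDS recovers a noise-free planted configuration (stress <
    0.05, TGA >= 95%); (b) the Mahalanobis learner recovers a planted linear
    metric (held-out TGA >= 90%, >= 10 points over Euclidean); (c) the deep
    metric beats the linear one by >= 5 TGA points under a nonlinear lift;
    (d) hedonic-axis ablation lowers every learner's TGA.
    """
    scale = dict(n_train=6_000, n_test=2_000, epochs=60) if quick else {}
    a = scenario_mds_recovery(seed=seed, n=60 if quick else 100)
    b = scenario_mahalanobis_recovery(seed=seed, **scale)
    c = scenario_deep_vs_linear(
        seed=seed, **({"deep_epochs": 60, "linear_epochs": 60} if quick else {})
    )
    d = scenario_hedonic_ablation(seed=seed, **({"epochs": 50, "n": 80} if quick else {}))
    report = {
        "mds_recovery": a,
        "mahalanobis_recovery": b,
        "deep_vs_linear": c,
        "hedonic_ablation": d,
        "passed": {
            "mds_recovery": a["stress"] < 0.05 and a["tga"] >= 95.0,
            "mahalanobis_recovery": (
                b["tga"] >= 90.0 and b["tga"] - b["euclidean_tga"] >= 10.0
            ),
            "deep_vs_linear": c["deep_tga"] - c["mahalanobis_tga"] >= 5.0,
            "hedonic_ablation": all(v > 0 for v in d["deltas"].values()),
        },
    }
    report["all_passed"] = all(report["passed"].values())
    return report
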