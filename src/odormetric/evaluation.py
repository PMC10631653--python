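"""Scoring fitted perceptual metrics: triplet generalization accuracy,
pairwise-distance report surfaces, nearest-neighbor retrieval, expert
alignment and concentration contrasts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import DescriptorProfiles, FeatureTable
from .triplets import TripletSet, build_triplets, jaccard_dissimilarity


def _distance_lookup(distance, triplets: TripletSet):
    """Normalize the distance argument into a row-indexed lookup.

    ``distance`` may be a square matrix aligned with ``triplets.ids`` or a
    callable over molecule keys.
    """
    if callable(distance):
        ids = triplets.ids

        def lookup(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            return np.array([distance(ids[i], ids[j]) for i, j in zip(a, b)])

        return lookup
    Dm = np.asarray(distance, dtype=float)
    n = len(triplets.ids)
    if Dm.shape != (n, n):
        raise ValueError(
            f"distance matrix shape {Dm.shape} does not match {n} molecules"
        )
    return lambda a, b: Dm[a, b]


def triplet_generalization_accuracy(
    distance,
    triplets: TripletSet,
    tie_credit: float = 0.0,
) -> float:
    """Percentage of triplets whose ordering the distance reproduces.

    A triplet (i, j, k) is satisfied when d(i, j) < d(i, k).  Exact ties on
    the model side count as failures by default (``tie_credit=0``);
    ``tie_credit=0.5`` grants half credit instead.
    """
    if len(triplets) == 0:
        raise ValueError("cannot score an empty triplet set")
    lookup = _distance_lookup(distance, triplets)
    a, p, n = triplets.triples.T
    d_ap = lookup(a, p)
    d_an = lookup(a, n)
    correct = (d_ap < d_an).sum() + tie_credit * (d_ap == d_an).sum()
    return 100.0 * float(correct) / len(triplets)


def pairwise_report(distance, molecules: Sequence[str] | None = None) -> np.ndarray:
    """Min-max normalized pairwise distance matrix (0 = most similar pair,
    1 = most dissimilar), diagonal forced to zero.

    ``distance`` is a square matrix, or a callable over the given molecule
    keys.  Idempotent: normalizing a normalized matrix changes nothing.
    """
    if callable(distance):
        if molecules is None:
            raise ValueError("molecule keys required with a callable distance")
        n = len(molecules)
        Dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                Dm[i, j] = Dm[j, i] = distance(molecules[i], molecules[j])
    else:
        Dm = np.asarray(distance, dtype=float).copy()
    n = Dm.shape[0]
    if n < 2:
        raise ValueError("pairwise report needs at least 2 molecules")
    off = ~np.eye(n, dtype=bool)
    lo, hi = Dm[off].min(), Dm[off].max()
    if hi == lo:
        import warnings

        warnings.warn("all off-diagonal distances identical; degenerate normalization")
        out = np.zeros_like(Dm) if lo == 0 else np.ones_like(Dm)
    else:
        out = (Dm - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return out


def retrieve(
    distance,
    ids: Sequence[str],
    query: str,
    k: int = 4,
) -> list[tuple[str, float]]:
    """k nearest non-query molecules in ascending distance.

    ``distance`` is a square matrix aligned with ``ids`` or a callable over
    keys.  Ties are broken lexicographically by molecule id so retrieval is
    reproducible.
    """
    ids = [str(i) for i in ids]
    if query not in ids:
        raise KeyError(f"unknown query molecule {query!r}")
    if not (1 <= k <= len(ids) - 1):
        raise ValueError(f"k must lie in [1, {len(ids) - 1}]")
    qi = ids.index(query)
    if callable(distance):
        dists = [distance(query, m) for m in ids]
    else:
        dists = np.asarray(distance, dtype=float)[qi]
    order = sorted(
        (i for i in range(len(ids)) if i != qi), key=lambda i: (dists[i], ids[i])
    )
    return [(ids[i], float(dists[i])) for i in order[:k]]


@dataclass
class EvaluationReport:
    """TGA over repeated splits plus optional report surfaces."""

    per_split_tga: list[float]
    config: dict = field(default_factory=dict)
    pairwise: np.ndarray | None = None
    retrieval: dict | None = None

    @property
    def mean_tga(self) -> float:
        return float(np.mean(self.per_split_tga))

    @property
    def var_tga(self) -> float:
        """Population variance across splits, on the percent scale."""
        return float(np.var(self.per_split_tga))

    @property
    def std_tga(self) -> float:
        return float(np.std(self.per_split_tga))

    def summary(self) -> dict:
        return {
            "per_split_tga": [float(t) for t in self.per_split_tga],
            "mean_tga": self.mean_tga,
            "var_tga": self.var_tga,
            "std_tga": self.std_tga,
            "config": self.config,
        }


def evaluate_splits(
    model_factory: Callable[[int], object],
    features,
    triplets: TripletSet,
    plan,
) -> EvaluationReport:
    """Train one model per split and score its test triplets.

    ``model_factory(split_index)`` must return an unfitted estimator with a
    ``fit(X, triplets, [validation_triplets])`` signature and a
    ``pairwise_distance(X)`` method.
    """
    X = features.X if isinstance(features, FeatureTable) else np.asarray(features)
    tgas = []
    for s, split in enumerate(plan):
        model = model_factory(s)
        train = triplets.subset(split["train"])
        val = triplets.subset(split["val"])
        test = triplets.subset(split["test"])
        try:
            model.fit(X, train.triples, validation_triplets=val.triples)
        except TypeError:
            model.fit(X, train.triples)
        tgas.append(triplet_generalization_accuracy(model.pairwise_distance(X), test))
    return EvaluationReport(
        per_split_tga=tgas,
        config={"n_splits": plan.n_splits, "unit": plan.unit, "seed": plan.seed},
    )


def expert_alignment(
    distance,
    expert_profiles: DescriptorProfiles,
    nonexpert_profiles: DescriptorProfiles | None = None,
    max_triplets: int | None = 50_000,
    seed: int = 0,
    n_examples: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Agreement between a learned metric and expert similarity assessments.

    Expert triplets are built with the Jaccard distance on the binary expert
    profiles; the metric's TGA against them is returned together with a table
    of discordant triplets (molecule keys, descriptor sets, expert vs
    predicted ordering).

    ``distance`` is a square matrix aligned with ``expert_profiles.ids`` or a
    callable over keys.  ``nonexpert_profiles``, when given, is only used to
    display each molecule's non-expert descriptor set in the examples table.
    """
    if expert_profiles.n_molecules < 3:
        raise ValueError("need at least 3 molecules shared with the expert data")
    expert_D = jaccard_dissimilarity(expert_profiles)
    expert_triplets = build_triplets(expert_D, cap=max_triplets, seed=seed)
    tga = triplet_generalization_accuracy(distance, expert_triplets)

    lookup = _distance_lookup(distance, expert_triplets)
    a, p, n = expert_triplets.triples.T
    disagree = np.where(~(lookup(a, p) < lookup(a, n)))[0][:n_examples]
    rows = []
    for t in disagree:
        ai, pi, ni = expert_triplets.triples[t]
        keys = [expert_triplets.ids[i] for i in (ai, pi, ni)]
        rows.append(
            {
                "anchor": keys[0],
                "expert_closer": keys[1],
                "expert_farther": keys[2],
                "anchor_descriptors": sorted(expert_profiles.descriptor_set(keys[0])),
                "closer_descriptors": sorted(expert_profiles.descriptor_set(keys[1])),
                "farther_descriptors": sorted(expert_profiles.descriptor_set(keys[2])),
                "model_order": "reversed",
            }
        )
    return tga, pd.DataFrame(rows)


def concentration_contrast(
    model,
    features_high: FeatureTable,
    features_low: FeatureTable,
) -> pd.DataFrame:
    """Cross-concentration self-distances under one fitted model.

    Embeds the high- and low-concentration variants of every molecule with
    the same model and reports d_P(mol_high, mol_low); a molecule is flagged
    when its own two concentrations are farther apart than its median
    distance to the other molecules (the "same molecule, different smell"
    phenomenon).
    """
    if list(features_high.ids) != list(features_low.ids):
        raise ValueError("high/low feature tables must share molecule ids in order")
    D_hh = model.pairwise_distance(features_high.X)
    D_hl = model.pairwise_distance(features_high.X, features_low.X)
    self_d = np.diag(D_hl)
    n = len(features_high.ids)
    med = np.array(
        [np.median(np.delete(D_hh[i], i)) for i in range(n)]
    )
    return pd.DataFrame(
        {
            "cid": features_high.ids,
            "self_distance": self_d,
            "median_distance_to_others": med,
            "flagged": self_d > med,
        }
    )
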