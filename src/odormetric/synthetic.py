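"""Synthetic odorant datasets with planted perceptual structure.

The generator emulates the statistical shape of a descriptor-rating study:
molecules live in a low-dimensional latent perceptual space, structural
features are a (possibly nonlinear) function of the latent coordinates plus
noise, and a panel of subjects rates each molecule on a 0-100 analog scale
over a small descriptor vocabulary whose usage distribution is right-skewed
(a few descriptors such as "sweet" and "chemical" dominate).  One latent
axis is hedonic ("pleasant"-like) and is up-weighted both in the descriptor
readout and in the features, so ablating the hedonic descriptor from triplet
generation measurably lowers every learner's accuracy.

Descriptor means are softplus readouts of the latent coordinates whose
linearized loading matrix has orthonormal columns orthogonal to the baseline
profile.  In the noise-free linear regime this makes the cosine
dissimilarity between profiles a monotone function of latent Euclidean
distance, so profile-derived triplets agree with the planted latent
orderings by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import (
    HEDONIC_DESCRIPTOR,
    KELLER_DESCRIPTORS,
    DescriptorProfiles,
    FeatureTable,
)
from .triplets import TripletSet


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-structure dataset.

    Defaults mirror the descriptor-rating study the package targets: 480
    molecules at two concentrations, 55 subjects, 20 descriptors plus
    "pleasant", 379-dim structural features on a 0-100 rating scale.
    """

    n_molecules: int = 480
    latent_dim: int = 6
    feature_dim: int = 379
    feature_map: str = "linear"  # or "nonlinear-lift"
    feature_noise_sd: float = 0.1
    vocab_size: int = 21  # includes the hedonic descriptor
    n_subjects: int = 55
    subject_noise_sd: float = 15.0
    concentration_shift: float = 0.75
    hedonic_weight: float = 3.0
    readout_gain: float = 0.3
    usage_midpoint: float = 25.0
    usage_scale: float = 10.0
    lift_hidden: int = 32
    lift_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_molecules, self.latent_dim, self.feature_dim,
               self.vocab_size, self.n_subjects) < 1:
            raise ValueError("all sizes must be >= 1")
        if self.vocab_size < 2:
            raise ValueError("vocabulary needs at least 2 descriptors")
        if min(self.feature_noise_sd, self.subject_noise_sd,
               self.concentration_shift) < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.feature_map not in ("linear", "nonlinear-lift"):
            raise ValueError(f"unknown feature map {self.feature_map!r}")

    @property
    def vocabulary(self) -> list[str]:
        if self.vocab_size <= len(KELLER_DESCRIPTORS) + 1:
            base = list(KELLER_DESCRIPTORS[: self.vocab_size - 1])
        else:
            base = list(KELLER_DESCRIPTORS) + [
                f"descriptor_{i}" for i in range(self.vocab_size - 1 - len(KELLER_DESCRIPTORS))
            ]
        return base + [HEDONIC_DESCRIPTOR]


@dataclass
class SyntheticData:
    """Everything :func:`generate` produces, including the planted truth."""

    spec: SyntheticSpec
    features_high: FeatureTable
    features_low: FeatureTable
    ratings: pd.DataFrame
    latents_high: np.ndarray
    latents_low: np.ndarray
    descriptor_means_high: np.ndarray = field(repr=False, default=None)
    descriptor_means_low: np.ndarray = field(repr=False, default=None)

    @property
    def ids(self) -> list[str]:
        return list(self.features_high.ids)

    def latent_distance(self, concentration: str = "high") -> np.ndarray:
        """Planted ground-truth dissimilarity: Euclidean in latent space."""
        Z = self.latents_high if concentration == "high" else self.latents_low
        return squareform(pdist(Z))

    def write_csvs(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "features_high": outdir / "features_high.csv",
            "features_low": outdir / "features_low.csv",
            "ratings": outdir / "ratings.csv",
            "latents_high": outdir / "latents_high.csv",
            "latents_low": outdir / "latents_low.csv",
        }
        self.features_high.to_csv(paths["features_high"])
        self.features_low.to_csv(paths["features_low"])
        self.ratings.to_csv(paths["ratings"], index=False)
        for name, Z in (("latents_high", self.latents_high),
                        ("latents_low", self.latents_low)):
            df = pd.DataFrame(Z, columns=[f"z{i}" for i in range(Z.shape[1])])
            df.insert(0, "cid", self.ids)
            df.to_csv(paths[name], index=False)
        return paths


def _orthonormal_columns(rng, rows: int, cols: int,
                         against: list[np.ndarray]) -> np.ndarray:
    """Random orthonormal columns, each orthogonal to the given unit vectors."""
    basis = [v / np.linalg.norm(v) for v in against]
    out = []
    while len(out) < cols:
        v = rng.normal(size=rows)
        for b in basis:
            v -= (v @ b) * b
        nv = np.linalg.norm(v)
        if nv > 1e-8:
            v /= nv
            basis.append(v)
            out.append(v)
    return np.column_stack(out)


def _readout_geometry(spec: SyntheticSpec, rng: np.random.Generator):
    """Baseline profile and loading matrix of the descriptor readout.

    Returns (c, B) with descriptor means softplus(c + gain * B z).  The
    linearization diag(softplus'(c)) @ B has orthonormal columns orthogonal
    to the baseline softplus(c); column 0 (the hedonic axis) is concentrated
    on the "pleasant" entry.
    """
    V, q = spec.vocab_size, spec.latent_dim
    # right-skewed baseline usage: a few common descriptors, many rare ones
    n_common = max(2, V // 5)
    c = np.empty(V)
    c[:] = rng.normal(-1.0, 0.4, size=V)
    common_idx = rng.choice(V - 1, size=n_common, replace=False)  # never "pleasant"
    c[common_idx] = rng.normal(1.5, 0.3, size=n_common)
    c[-1] = 0.5  # the hedonic descriptor is moderately common
    y0 = _softplus(c)
    slope = 1.0 / (1.0 + np.exp(-c))  # softplus'

    a = y0 / np.linalg.norm(y0)
    # hedonic direction: the "pleasant" coordinate, made orthogonal to y0
    e = np.zeros(V)
    e[-1] = 1.0
    u0 = e - (e @ a) * a
    u0 /= np.linalg.norm(u0)
    if q > 1:
        U_rest = _orthonormal_columns(rng, V, q - 1, against=[a, u0])
        U = np.column_stack([u0, U_rest])
    else:
        U = u0[:, None]
    B = U / slope[:, None]
    return c, B


def _feature_map(spec: SyntheticSpec, rng: np.random.Generator):
    """Fixed random map from latent coordinates to structural features."""
    d, q = spec.feature_dim, spec.latent_dim
    if spec.feature_map == "linear":
        G = rng.normal(size=(max(d, q), q))
        A = np.linalg.qr(G)[0][:d, :q]  # orthonormal columns: isometric map

        def apply(Z: np.ndarray) -> np.ndarray:
            return Z @ A.T

    else:
        h = spec.lift_hidden
        W1 = rng.normal(scale=spec.lift_scale / np.sqrt(q), size=(h, q))
        b1 = rng.normal(scale=0.3, size=h)
        W2 = rng.normal(scale=1.0 / np.sqrt(h), size=(d, h))

        def apply(Z: np.ndarray) -> np.ndarray:
            return np.tanh(Z @ W1.T + b1) @ W2.T

    return apply


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Generate a planted-structure dataset.

    Latent coordinates are standard Gaussian with the hedonic axis
    up-weighted; the low-concentration variant shifts each molecule's latent
    point by a random vector of expected norm ``concentration_shift`` before
    the readout, so "same molecule, different smell" cases arise by
    construction.  Ground-truth dissimilarity is Euclidean in latent space.
    """
    rng = np.random.default_rng(spec.seed)
    n, q = spec.n_molecules, spec.latent_dim
    ids = [f"M{i:04d}" for i in range(n)]

    axis_scale = np.ones(q)
    axis_scale[0] = spec.hedonic_weight
    Z_high = rng.normal(size=(n, q)) * axis_scale
    shift = rng.normal(size=(n, q)) * (spec.concentration_shift / np.sqrt(q))
    Z_low = Z_high + shift

    fmap = _feature_map(spec, rng)
    feats = {}
    for conc, Z in (("high", Z_high), ("low", Z_low)):
        X = fmap(Z) + rng.normal(scale=spec.feature_noise_sd, size=(n, spec.feature_dim))
        feats[conc] = FeatureTable(
            ids=ids,
            X=X,
            feature_names=[f"f{i}" for i in range(spec.feature_dim)],
            provenance=f"synthetic-{conc}",
        )

    c, B = _readout_geometry(spec, rng)
    vocab = spec.vocabulary
    means = {}
    raw = {
        conc: _softplus(c + spec.readout_gain * (Z @ B.T))
        for conc, Z in (("high", Z_high), ("low", Z_low))
    }
    ref = max(raw["high"].max(), raw["low"].max())
    for conc in ("high", "low"):
        means[conc] = 100.0 * raw[conc] / ref  # positive rescale: cosine-invariant

    subjects = [f"S{s:02d}" for s in range(spec.n_subjects)]
    frames = []
    for conc in ("high", "low"):
        M = means[conc]
        if spec.subject_noise_sd > 0:
            # a subject reports a descriptor only when they detect it; the
            # detection probability rises with the descriptor's intensity,
            # which is what makes faint descriptors genuinely rare in the
            # per-subject records (and 25%-of-subjects binarization
            # informative) rather than ubiquitous low-level noise
            shape = (spec.n_subjects, n, len(vocab))
            p_use = 1.0 / (1.0 + np.exp(-(M - spec.usage_midpoint) / spec.usage_scale))
            used = rng.random(shape) < p_use[None, :, :]
            noise = rng.normal(scale=spec.subject_noise_sd, size=shape)
            R = np.where(used, np.clip(M[None, :, :] + noise, 1.0, 100.0), 0.0)
        else:
            R = np.broadcast_to(
                np.clip(M, 0.0, 100.0)[None, :, :],
                (spec.n_subjects, n, len(vocab)),
            )
        frames.append(
            pd.DataFrame(
                {
                    "cid": np.tile(np.repeat(ids, len(vocab)), spec.n_subjects),
                    "concentration": conc,
                    "subject": np.repeat(subjects, n * len(vocab)),
                    "descriptor": np.tile(vocab, n * spec.n_subjects),
                    "rating": R.ravel(),
                }
            )
        )
    ratings = pd.concat(frames, ignore_index=True)

    return SyntheticData(
        spec=spec,
        features_high=feats["high"],
        features_low=feats["low"],
        ratings=ratings,
        latents_high=Z_high,
        latents_low=Z_low,
        descriptor_means_high=means["high"],
        descriptor_means_low=means["low"],
    )


def expert_relabeling(
    data: SyntheticData,
    flip_fraction: float = 0.2,
    min_subject_fraction: float = 0.25,
    seed: int = 0,
) -> DescriptorProfiles:
    """A synthetic stand-in for an expert binary-descriptor table.

    An idealized annotator marks a descriptor present when its noise-free
    detection probability reaches the given subject fraction — the same rule
    the non-expert binarization applies to noisy panel data, but without the
    panel noise.  ``flip_fraction`` then relabels that share of each
    molecule's present descriptors to a different, absent descriptor,
    modeling the vocabulary and judgment mismatch between annotation
    dialects while preserving set sizes.
    """
    rng = np.random.default_rng(seed)
    spec = data.spec
    M = data.descriptor_means_high
    # p_use(mean) >= fraction  <=>  mean >= midpoint - scale*ln(1/f - 1)
    thresh = spec.usage_midpoint - spec.usage_scale * np.log(
        1.0 / min_subject_fraction - 1.0
    )
    B = (M > thresh).astype(float)
    # keep every molecule annotatable: give empty sets their top descriptor
    empty = B.sum(axis=1) == 0
    if empty.any():
        B[np.where(empty)[0], M[empty].argmax(axis=1)] = 1.0
    for i in range(B.shape[0]):
        present = np.where(B[i] > 0)[0]
        absent = np.where(B[i] == 0)[0]
        for d in present:
            if len(absent) and rng.random() < flip_fraction:
                j = rng.choice(absent)
                B[i, d], B[i, j] = 0.0, 1.0
                absent = np.where(B[i] == 0)[0]
    return DescriptorProfiles(
        ids=data.ids, Y=B, vocabulary=data.spec.vocabulary, mode="binary"
    )


def sample_triplets_from_distances(
    D: np.ndarray,
    n_triplets: int,
    seed: int = 0,
    ids: list[str] | None = None,
    tie_tolerance: float = 1e-9,
) -> TripletSet:
    """Uniformly sampled triplets oriented by a ground-truth distance matrix.

    Draws random distinct (i, j, k), orients each so d(i, j) < d(i, k), and
    drops ties; a cheap alternative to exhaustive construction for large n.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 molecules")
    rng = np.random.default_rng(seed)
    triples = []
    while len(triples) < n_triplets:
        cand = rng.integers(0, n, size=(2 * (n_triplets - len(triples)) + 16, 3))
        ok = (
            (cand[:, 0] != cand[:, 1])
            & (cand[:, 0] != cand[:, 2])
            & (cand[:, 1] != cand[:, 2])
        )
        cand = cand[ok]
        d_ij = D[cand[:, 0], cand[:, 1]]
        d_ik = D[cand[:, 0], cand[:, 2]]
        gap = d_ik - d_ij
        keep = np.abs(gap) > tie_tolerance
        cand = cand[keep]
        swap = gap[keep] < 0
        cand[swap] = cand[swap][:, [0, 2, 1]]
        triples.extend(map(tuple, cand))
    triples = np.array(triples[:n_triplets], dtype=int)
    return TripletSet(
        ids=ids if ids is not None else [str(i) for i in range(n)],
        triples=triples,
        provenance={"source": "sampled-from-distances", "seed": seed},
    )


def random_triplets(
    n_molecules: int, n_triplets: int, seed: int = 0, ids: list[str] | None = None
) -> TripletSet:
    """Triplets with uniformly random orientation (a label-randomization null)."""
    rng = np.random.default_rng(seed)
    triples = []
    while len(triples) < n_triplets:
        cand = rng.integers(0, n_molecules, size=(2 * (n_triplets - len(triples)) + 16, 3))
        ok = (
            (cand[:, 0] != cand[:, 1])
            & (cand[:, 0] != cand[:, 2])
            & (cand[:, 1] != cand[:, 2])
        )
        triples.extend(map(tuple, cand[ok]))
    return TripletSet(
        ids=ids if ids is not None else [str(i) for i in range(n_molecules)],
        triples=np.array(triples[:n_triplets], dtype=int),
        provenance={"source": "random-orientation", "seed": seed},
    )
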