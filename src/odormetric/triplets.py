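"""Perceptual dissimilarities and triplet-constraint construction.

A triplet constraint (i, j, k) states that molecule i smells more like j
than k; formally d_ij < d_ik under a perceptual dissimilarity d.  Triplets
are the supervision unit shared by all three metric learners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import DescriptorProfiles


@dataclass
class DissimilarityMatrix:
    """Symmetric, zero-diagonal pairwise dissimilarity with entries in [0, 1]."""

    ids: list[str]
    values: np.ndarray
    measure: str = "cosine"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("dissimilarity entries must lie in [0, 1]")
        np.fill_diagonal(self.values, 0.0)
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, measure: str = "cosine") -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(), measure=measure)


@dataclass
class TripletSet:
    """Ordered triplet constraints as integer indices into ``ids``."""

    ids: list[str]
    triples: np.ndarray  # (m, 3) int: anchor, positive, negative
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.triples = np.asarray(self.triples, dtype=int).reshape(-1, 3)
        if len(self.triples):
            t = self.triples
            if (
                (t[:, 0] == t[:, 1]) | (t[:, 0] == t[:, 2]) | (t[:, 1] == t[:, 2])
            ).any():
                raise ValueError("triplet members must be pairwise distinct")
            if t.min() < 0 or t.max() >= len(self.ids):
                raise ValueError("triplet index out of range")

    def __len__(self) -> int:
        return len(self.triples)

    def as_keys(self) -> list[tuple[str, str, str]]:
        return [
            (self.ids[a], self.ids[p], self.ids[n]) for a, p, n in self.triples
        ]

    def subset(self, idx: np.ndarray) -> "TripletSet":
        return TripletSet(
            ids=list(self.ids), triples=self.triples[idx], provenance=dict(self.provenance)
        )

    def to_csv(self, path: str | Path) -> None:
        rows = self.as_keys()
        pd.DataFrame(rows, columns=["anchor", "positive", "negative"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, ids: Sequence[str] | None = None) -> "TripletSet":
        df = pd.read_csv(path, dtype=str)
        if ids is None:
            ids = sorted(set(df.to_numpy().ravel().tolist()))
        ids = [str(i) for i in ids]
        pos = {k: i for i, k in enumerate(ids)}
        triples = np.array(
            [[pos[a], pos[p], pos[n]] for a, p, n in df.itertuples(index=False)],
            dtype=int,
        ).reshape(-1, 3)
        return cls(ids=list(ids), triples=triples)


@dataclass
class SplitPlan:
    """Train/validation/test partitions for repeated evaluation runs."""

    splits: list[dict]  # each: {"train": idx, "val": idx, "test": idx}
    unit: str = "triplet"  # or "molecule"
    seed: int = 0

    @property
    def n_splits(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)


def cosine_dissimilarity(profiles: DescriptorProfiles) -> DissimilarityMatrix:
    """Pairwise dissimilarity 1 - cos(y_i, y_j) between descriptor profiles.

    The cosine of two nonnegative rating vectors lies in [0, 1], so the
    dissimilarity does too.  An all-zero profile has no direction and is an
    error naming the molecule.
    """
    Y = profiles.Y
    norms = np.linalg.norm(Y, axis=1)
    zero = np.where(norms == 0)[0]
    if len(zero):
        raise ValueError(
            "cosine dissimilarity undefined for all-zero profiles: "
            f"{[profiles.ids[i] for i in zero]}"
        )
    D = squareform(pdist(Y, metric="cosine"))
    D = np.clip(D, 0.0, 1.0)
    return DissimilarityMatrix(ids=list(profiles.ids), values=D, measure="cosine")


def jaccard_dissimilarity(profiles: DescriptorProfiles) -> DissimilarityMatrix:
    """Jaccard distance 1 - |S_i ∩ S_j| / |S_i ∪ S_j| between binary profiles.

    Two empty descriptor sets are treated as maximally similar (distance 0):
    both molecules are odorless under the vocabulary.
    """
    if profiles.mode != "binary":
        raise ValueError("jaccard dissimilarity requires binary profiles")
    B = profiles.Y.astype(bool)
    inter = (B[:, None, :] & B[None, :, :]).sum(axis=2).astype(float)
    union = (B[:, None, :] | B[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(ids=list(profiles.ids), values=D, measure="jaccard")


def exhaustive_triplet_count(n: int) -> int:
    """Number of triplets over n molecules with all-distinct dissimilarities.

    Each anchor contributes one orientation per unordered pair of the other
    n-1 molecules: n * C(n-1, 2).
    """
    return n * math.comb(n - 1, 2)


def build_triplets(
    matrix: DissimilarityMatrix,
    tie_tolerance: float = 1e-9,
    cap: int | None = 500_000,
    seed: int = 0,
) -> TripletSet:
    """Construct the exhaustive triplet set {(i,j,k) : d_ik - d_ij > tol}.

    The exhaustive set is O(n^3); with ``cap`` set, a seeded uniform
    subsample of size ``min(cap, total)`` is returned instead.  Ties (within
    ``tie_tolerance``) are never emitted.
    """
    n = matrix.n
    if n < 3:
        raise ValueError("triplet construction needs at least 3 molecules")
    if tie_tolerance < 0:
        raise ValueError("tie_tolerance must be >= 0")
    D = matrix.values
    rng = np.random.default_rng(seed)

    # per-anchor boolean plane: valid (j, k) iff d_ik - d_ij > tol, j,k != i
    counts = np.empty(n, dtype=np.int64)
    planes: list[np.ndarray] = []
    for i in range(n):
        plane = (D[i][None, :] - D[i][:, None]) > tie_tolerance  # [j, k]
        plane[i, :] = False
        plane[:, i] = False
        np.fill_diagonal(plane, False)
        planes.append(plane)
        counts[i] = plane.sum()
    total = int(counts.sum())

    if cap is not None and cap <= 0:
        cap = None
    if cap is not None and total > cap:
        chosen = np.sort(rng.choice(total, size=cap, replace=False))
    else:
        chosen = np.arange(total)

    triples = np.empty((len(chosen), 3), dtype=int)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    out = 0
    for i in range(n):
        lo, hi = offsets[i], offsets[i + 1]
        sel = chosen[(chosen >= lo) & (chosen < hi)] - lo
        if len(sel) == 0:
            continue
        jj, kk = np.nonzero(planes[i])
        triples[out : out + len(sel), 0] = i
        triples[out : out + len(sel), 1] = jj[sel]
        triples[out : out + len(sel), 2] = kk[sel]
        out += len(sel)
    assert out == len(chosen)

    return TripletSet(
        ids=list(matrix.ids),
        triples=triples,
        provenance={
            "measure": matrix.measure,
            "tie_tolerance": tie_tolerance,
            "cap": cap,
            "seed": seed,
            "total_exhaustive": total,
        },
    )


def _partition_sizes(m: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n_val = int(round(f_val * m))
    n_test = int(round(f_test * m))
    n_train = m - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"too few items ({m}) to honor fractions {fractions}")
    return n_train, n_val, n_test


def make_splits(
    triplets: TripletSet,
    n_splits: int = 10,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    unit: str = "triplet",
    seed: int = 0,
) -> SplitPlan:
    """Create repeated random train/val/test partitions.

    ``unit="triplet"`` shuffles and partitions the triplet list directly
    (appropriate for the transductive MDS evaluation).  ``unit="molecule"``
    partitions molecules and keeps a triplet only when all three members fall
    in the same partition, discarding cross-partition triplets (the honest
    out-of-sample protocol for the parametric learners).
    """
    if unit not in ("triplet", "molecule"):
        raise ValueError(f"unknown split unit {unit!r}")
    rng = np.random.default_rng(seed)
    splits: list[dict] = []
    m = len(triplets)
    if m == 0:
        raise ValueError("cannot split an empty triplet set")

    if unit == "triplet":
        n_train, n_val, n_test = _partition_sizes(m, fractions)
        for _ in range(n_splits):
            perm = rng.permutation(m)
            splits.append(
                {
                    "train": perm[:n_train],
                    "val": perm[n_train : n_train + n_val],
                    "test": perm[n_train + n_val :],
                }
            )
        return SplitPlan(splits=splits, unit=unit, seed=seed)

    mols = np.unique(triplets.triples)
    n_train, n_val, n_test = _partition_sizes(len(mols), fractions)
    for _ in range(n_splits):
        perm = rng.permutation(mols)
        part = {}
        part_of = {}
        bounds = {"train": (0, n_train), "val": (n_train, n_train + n_val),
                  "test": (n_train + n_val, len(mols))}
        for name, (lo, hi) in bounds.items():
            part[name] = set(perm[lo:hi].tolist())
            for mstar in perm[lo:hi]:
                part_of[int(mstar)] = name
        split = {"train": [], "val": [], "test": []}
        discarded = 0
        for t_idx, (a, p, ng) in enumerate(triplets.triples):
            pa, pp, pn = part_of[int(a)], part_of[int(p)], part_of[int(ng)]
            if pa == pp == pn:
                split[pa].append(t_idx)
            else:
                discarded += 1
        if any(len(v) == 0 for v in split.values()):
            raise ValueError(
                "molecule-level split left an empty partition "
                f"(discarded {discarded}/{m} cross-partition triplets)"
            )
        splits.append(
            {
                "train": np.array(split["train"], dtype=int),
                "val": np.array(split["val"], dtype=int),
                "test": np.array(split["test"], dtype=int),
                "discarded": discarded,
                "molecules": {k: sorted(v) for k, v in part.items()},
            }
        )
    return SplitPlan(splits=splits, unit=unit, seed=seed)


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (raw, canonical) descriptor synonym CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("synonym map needs two columns: raw, canonical")
    return {
        str(r): str(c) for r, c in zip(df.iloc[:, 0], df.iloc[:, 1])
    }
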