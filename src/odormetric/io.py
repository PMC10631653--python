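"""Reading, validation and preprocessing of feature and descriptor-rating tables.

Feature tables hold one row of numeric physicochemical descriptors per
molecule (the ``x_i`` fed to every metric learner).  Ratings tables hold
per-subject analog-scale ratings (0-100) of verbal odor descriptors, which
are averaged or binarized into per-molecule descriptor profiles (the ``y_i``
from which perceptual dissimilarities and triplet constraints are derived).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA, TruncatedSVD

logger = logging.getLogger(__name__)

#: Column names expected in a ratings CSV (D1 dialect).
RATINGS_COLUMNS = ("cid", "concentration", "subject", "descriptor", "rating")

#: The 20 non-hedonic descriptors rated on the 0-100 analog scale, plus the
#: hedonic descriptor "pleasant" handled separately by ``include_pleasant``.
KELLER_DESCRIPTORS = (
    "edible", "bakery", "sweet", "fruit", "fish", "garlic", "spices",
    "cold", "sour", "burnt", "acid", "warm", "musky", "sweaty",
    "ammonia/urinous", "decayed", "wood", "grass", "flower", "chemical",
)
HEDONIC_DESCRIPTOR = "pleasant"

CONCENTRATIONS = ("high", "low")


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class FeatureTable:
    """Molecules x structural-feature matrix.

    Parameters
    ----------
    ids : ordered molecule keys (opaque strings, e.g. PubChem CIDs).
    X : dense float matrix, one row per molecule.
    feature_names : column labels, length ``X.shape[1]``.
    provenance : free-text tag, e.g. ``"keller"`` or ``"mordred-pca"``.
    transform : optional fitted reducer retained by :func:`reduce_features`
        so held-out molecules can be projected with the same map.
    """

    ids: list[str]
    X: np.ndarray
    feature_names: list[str]
    provenance: str = ""
    transform: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.ids = [str(i) for i in self.ids]
        if self.X.ndim != 2:
            raise DataValidationError("feature matrix must be 2-D")
        n, d = self.X.shape
        if len(self.ids) != n:
            raise DataValidationError(
                f"{len(self.ids)} ids for {n} feature rows"
            )
        if d < 1:
            raise DataValidationError("feature table needs at least one column")
        if len(self.feature_names) != d:
            raise DataValidationError("feature_names length != n columns")
        dupes = _duplicates(self.ids)
        if dupes:
            raise DataValidationError(f"duplicate molecule ids: {sorted(dupes)}")
        if any(not i for i in self.ids):
            raise DataValidationError("empty molecule id")
        if not np.all(np.isfinite(self.X)):
            bad = [self.ids[r] for r in np.where(~np.isfinite(self.X).all(axis=1))[0]]
            raise DataValidationError(f"non-finite feature values for: {bad}")

    @property
    def n_molecules(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def index_of(self, keys: Sequence[str]) -> np.ndarray:
        lookup = {k: i for i, k in enumerate(self.ids)}
        try:
            return np.array([lookup[k] for k in keys], dtype=int)
        except KeyError as e:  # pragma: no cover - message clarity
            raise KeyError(f"molecule {e.args[0]!r} not in feature table") from None

    def subset(self, keys: Sequence[str]) -> "FeatureTable":
        idx = self.index_of(keys)
        return FeatureTable(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            feature_names=list(self.feature_names),
            provenance=self.provenance,
            transform=self.transform,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "cid", self.ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DescriptorProfiles:
    """A set of per-molecule descriptor profiles over a shared vocabulary."""

    ids: list[str]
    Y: np.ndarray
    vocabulary: list[str]
    mode: str = "continuous"  # or "binary"

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.ids = [str(i) for i in self.ids]
        if self.Y.shape != (len(self.ids), len(self.vocabulary)):
            raise DataValidationError("profile matrix shape mismatch")
        if self.mode not in ("continuous", "binary"):
            raise DataValidationError(f"unknown profile mode {self.mode!r}")
        if not np.all(np.isfinite(self.Y)):
            raise DataValidationError("non-finite profile entries")
        if self.mode == "continuous":
            if self.Y.min() < 0 or self.Y.max() > 100:
                raise DataValidationError("continuous ratings must lie in [0, 100]")
        else:
            if not np.isin(self.Y, (0.0, 1.0)).all():
                raise DataValidationError("binary profiles must contain only 0/1")

    @property
    def n_molecules(self) -> int:
        return self.Y.shape[0]

    def vector(self, key: str) -> np.ndarray:
        return self.Y[self.ids.index(str(key))]

    def descriptor_set(self, key: str) -> set[str]:
        """Descriptor names present (nonzero) for one molecule."""
        v = self.vector(key)
        return {d for d, x in zip(self.vocabulary, v) if x > 0}


def _duplicates(seq: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for s in seq:
        if s in seen:
            dup.add(s)
        seen.add(s)
    return dup


def read_feature_table(path: str | Path, format: str = "csv") -> FeatureTable:
    """Read a molecular feature table from CSV.

    The first column (named ``cid``) carries molecule ids; all remaining
    columns must be numeric.  Rows containing non-finite values are reported
    via logging and rejected (never imputed).
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DataValidationError("feature CSV needs an id column plus >=1 feature")
    id_col = df.columns[0]
    ids = df[id_col].astype(str).tolist()
    dupes = _duplicates(ids)
    if dupes:
        raise DataValidationError(
            f"duplicate molecule ids in {path.name}: {sorted(dupes)}"
        )
    feat = df.drop(columns=[id_col])
    try:
        X = feat.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise DataValidationError(f"non-numeric feature cell in {path.name}: {e}")
    finite = np.isfinite(X).all(axis=1)
    if not finite.all():
        bad = [ids[i] for i in np.where(~finite)[0]]
        logger.warning(
            "rejecting %d molecules with non-finite features: %s", len(bad), bad
        )
        X = X[finite]
        ids = [i for i, ok in zip(ids, finite) if ok]
    return FeatureTable(
        ids=ids, X=X, feature_names=list(feat.columns), provenance=path.stem
    )


def read_ratings_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format descriptor-ratings CSV.

    Columns: ``cid, concentration, subject, descriptor, rating`` with ratings
    on the 0-100 analog scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(RATINGS_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"ratings table missing columns: {sorted(missing)}")
    df = df.copy()
    df["cid"] = df["cid"].astype(str)
    r = df["rating"].to_numpy(dtype=float)
    if not np.isfinite(r).all() or r.min() < 0 or r.max() > 100:
        raise DataValidationError("ratings must be finite and within [0, 100]")
    return df


def read_expert_table(path: str | Path) -> DescriptorProfiles:
    """Read a binary expert-descriptor CSV of (cid, semicolon-joined descriptors)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DataValidationError("expert CSV needs cid + descriptor-list columns")
    ids = df.iloc[:, 0].astype(str).tolist()
    sets = [
        {d.strip() for d in str(cell).split(";") if d.strip()}
        if not pd.isna(cell)
        else set()
        for cell in df.iloc[:, 1]
    ]
    vocab = sorted(set().union(*sets)) if sets else []
    Y = np.zeros((len(ids), len(vocab)))
    pos = {d: j for j, d in enumerate(vocab)}
    for i, s in enumerate(sets):
        for d in s:
            Y[i, pos[d]] = 1.0
    return DescriptorProfiles(ids=ids, Y=Y, vocabulary=vocab, mode="binary")


def apply_synonym_map(
    profiles: DescriptorProfiles, mapping: dict[str, str]
) -> DescriptorProfiles:
    """Merge equivalent descriptors (e.g. 'fruity' -> 'fruit') in binary profiles.

    The mapping sends raw descriptor names to canonical ones; a merged
    descriptor is present if any of its synonyms was present.
    """
    canonical = [mapping.get(d, d) for d in profiles.vocabulary]
    vocab = sorted(set(canonical))
    pos = {d: j for j, d in enumerate(vocab)}
    Y = np.zeros((profiles.n_molecules, len(vocab)))
    for src, dst in zip(range(len(canonical)), (pos[c] for c in canonical)):
        Y[:, dst] = np.maximum(Y[:, dst], profiles.Y[:, src])
    return DescriptorProfiles(
        ids=list(profiles.ids), Y=Y, vocabulary=vocab, mode="binary"
    )


def _pivot_ratings(
    ratings: pd.DataFrame, concentration: str
) -> tuple[pd.DataFrame, list[str]]:
    if concentration not in set(ratings["concentration"].unique()):
        raise ValueError(
            f"unknown concentration {concentration!r}; "
            f"available: {sorted(ratings['concentration'].unique())}"
        )
    sub = ratings[ratings["concentration"] == concentration]
    if sub.empty:
        raise ValueError(f"no ratings at concentration {concentration!r}")
    return sub, sorted(sub["cid"].unique())


def average_profiles(
    ratings: pd.DataFrame,
    concentration: str = "high",
    include_pleasant: bool = False,
    vocabulary: Sequence[str] | None = None,
) -> DescriptorProfiles:
    """Average subject ratings into one continuous profile per molecule.

    Each profile entry is the arithmetic mean over subjects of that
    descriptor's rating.  The hedonic descriptor "pleasant" is excluded
    unless ``include_pleasant`` is set, matching the two triplet dialects
    (20- vs 21-descriptor profiles).
    """
    sub, cids = _pivot_ratings(ratings, concentration)
    if vocabulary is None:
        vocab = sorted(sub["descriptor"].unique())
        # keep the canonical ordering when the data uses the standard names
        known = [d for d in (*KELLER_DESCRIPTORS, HEDONIC_DESCRIPTOR) if d in set(vocab)]
        if set(known) == set(vocab):
            vocab = known
    else:
        vocab = list(vocabulary)
    if not include_pleasant:
        vocab = [d for d in vocab if d != HEDONIC_DESCRIPTOR]
    means = (
        sub[sub["descriptor"].isin(vocab)]
        .groupby(["cid", "descriptor"], sort=False)["rating"]
        .mean()
        .unstack("descriptor")
    )
    if means.isna().any().any():
        missing = means.index[means.isna().any(axis=1)].tolist()
        raise DataValidationError(
            f"molecules with missing descriptor ratings: {missing}"
        )
    means = means.reindex(index=cids, columns=vocab)
    if means.isna().any().any():
        raise DataValidationError("molecule with zero ratings for a descriptor")
    return DescriptorProfiles(
        ids=cids, Y=means.to_numpy(), vocabulary=vocab, mode="continuous"
    )


def binarize_profiles(
    ratings: pd.DataFrame,
    concentration: str = "high",
    min_subject_fraction: float = 0.25,
    include_pleasant: bool = False,
) -> DescriptorProfiles:
    """Binarize ratings: a descriptor is present for a molecule iff at least
    ``min_subject_fraction`` of subjects rated it strictly above zero.

    A subject "uses" a descriptor when their rating is > 0 (the analog
    scale's 0 anchor means absence).  The threshold is inclusive (>=), so
    1 of 4 subjects at threshold 0.25 counts as present.
    """
    if not (0 < min_subject_fraction <= 1):
        raise ValueError("min_subject_fraction must lie in (0, 1]")
    sub, cids = _pivot_ratings(ratings, concentration)
    vocab = sorted(sub["descriptor"].unique())
    if not include_pleasant:
        vocab = [d for d in vocab if d != HEDONIC_DESCRIPTOR]
        sub = sub[sub["descriptor"].isin(vocab)]
    used = (
        sub.assign(used=sub["rating"] > 0)
        .groupby(["cid", "descriptor"], sort=False)["used"]
        .mean()  # fraction of subjects using the descriptor, per molecule
        .unstack("descriptor")
        .reindex(index=cids, columns=vocab)
        .fillna(0.0)
    )
    Y = (used.to_numpy() >= min_subject_fraction).astype(float)
    return DescriptorProfiles(ids=cids, Y=Y, vocabulary=vocab, mode="binary")


def restrict_vocabulary(
    profiles: DescriptorProfiles, vocabulary: Sequence[str]
) -> DescriptorProfiles:
    """Project profiles onto a given descriptor vocabulary, in that order.

    Descriptors absent from the source vocabulary become 0 (used for the
    expert-alignment protocol on the descriptors shared by both datasets).
    """
    vocab = list(vocabulary)
    if not vocab:
        raise ValueError("vocabulary must be nonempty")
    pos = {d: j for j, d in enumerate(profiles.vocabulary)}
    Y = np.zeros((profiles.n_molecules, len(vocab)))
    for j, d in enumerate(vocab):
        if d in pos:
            Y[:, j] = profiles.Y[:, pos[d]]
    return DescriptorProfiles(
        ids=list(profiles.ids), Y=Y, vocabulary=vocab, mode=profiles.mode
    )


def reduce_features(
    table: FeatureTable,
    method: str = "pca",
    n_components: int = 379,
    seed: int = 0,
) -> FeatureTable:
    """Standardize feature columns and reduce dimension by PCA or truncated SVD.

    Columns are z-scored first (constant columns are dropped with a warning);
    the fitted (center, scale, reducer) triple is retained on the returned
    table's ``transform`` so held-out molecules can be projected identically.
    """
    if method not in ("pca", "svd"):
        raise ValueError(f"unknown reduction method {method!r}")
    X = table.X
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(table.feature_names, keep) if not k]
        logger.warning("dropping %d constant feature columns: %s",
                       len(dropped), dropped[:10])
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    bound = min(Z.shape)
    if not (1 <= n_components <= bound):
        raise ValueError(
            f"n_components={n_components} exceeds rank bound {bound}"
        )
    if method == "pca":
        reducer = PCA(n_components=n_components, random_state=seed)
    else:
        if n_components == bound:
            raise ValueError("truncated SVD requires n_components < min(n, d)")
        reducer = TruncatedSVD(n_components=n_components, random_state=seed)
    Xr = reducer.fit_transform(Z)

    names = [f"{method}_{i}" for i in range(n_components)]
    out = FeatureTable(
        ids=list(table.ids),
        X=Xr,
        feature_names=names,
        provenance=f"{table.provenance}-{method}" if table.provenance else method,
    )
    out.transform = _FittedReducer(mu[keep], sd[keep], keep, reducer)
    return out


def rescale_features(X) -> np.ndarray:
    """Scale a feature matrix so the median squared pairwise distance is ~1.

    The exponential triplet loss of the parametric learners operates on raw
    squared distances, so its gradients are informative only when margins are
    O(1); apply this (or an equivalent standardization) before fitting them.
    """
    from scipy.spatial.distance import pdist

    if isinstance(X, FeatureTable):
        X = X.X
    X = np.asarray(X, dtype=float)
    sample = X if len(X) <= 500 else X[:: len(X) // 500]
    med = np.median(pdist(sample, metric="sqeuclidean"))
    return X / np.sqrt(max(med, 1e-12))


@dataclass
class _FittedReducer:
    """Standardization + reduction map fit on a training table."""

    center: np.ndarray
    scale: np.ndarray
    keep: np.ndarray
    reducer: object

    def __call__(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float)[:, self.keep] - self.center) / self.scale
        return self.reducer.transform(Z)
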