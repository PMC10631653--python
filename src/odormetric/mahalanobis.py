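"""Global linear (Mahalanobis) metric learning from triplet constraints.

The metric is d_M(x_i, x_j) = (x_i - x_j)^T M (x_i - x_j) with M = W^T W
positive semidefinite by construction; equivalently the squared Euclidean
distance after the linear map x -> W x.  W is trained to widen the margin
d_M(x_i, x_k) - d_M(x_i, x_j) on each triplet (i, j, k) by minimizing the
exponential margin loss sum exp(-(d_M(i,k) - d_M(i,j))) with seeded
mini-batch Adam — the same loss family as the deep learner, so the two
differ only in the embedding function.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from ._optim import Adam
from .io import FeatureTable
from .triplets import TripletSet

# exp argument clipped here to keep the loss finite on extreme margins
_MARGIN_CLIP = 500.0


def _as_matrix_and_triples(features, triplets):
    if isinstance(features, FeatureTable):
        X = features.X
        ids = features.ids
    else:
        X = np.asarray(features, dtype=float)
        ids = None
    if isinstance(triplets, TripletSet):
        if ids is not None:
            idx = {k: i for i, k in enumerate(ids)}
            try:
                rows = np.array(
                    [[idx[a], idx[p], idx[n]] for a, p, n in triplets.as_keys()],
                    dtype=int,
                ).reshape(-1, 3)
            except KeyError as e:
                raise KeyError(f"triplet references unknown molecule {e.args[0]!r}")
        else:
            rows = triplets.triples
    else:
        rows = np.asarray(triplets, dtype=int).reshape(-1, 3)
        if len(rows) and rows.max() >= len(X):
            raise KeyError("triplet index exceeds feature table size")
    return X, rows


class MahalanobisTripletMetric(BaseEstimator, TransformerMixin):
    """Learn W (and M = W^T W) from relative similarity comparisons.

    Parameters
    ----------
    n_components : output dimension d-hat of the linear map (default 25).
    epochs, lr, batch_size : Adam mini-batch schedule; defaults mirror the
        deep learner (lr 0.001, batch 200).
    random_state : seeds initialization noise-free batch shuffling.

    Attributes
    ----------
    W_ : (n_components, d) learned linear map, initialized at the
        identity-padded matrix so training starts from the Euclidean baseline.
    M_ : implied PSD metric W^T W.
    loss_trace_ : mean per-triplet training loss per epoch.
    """

    def __init__(
        self,
        n_components: int = 25,
        epochs: int = 100,
        lr: float = 1e-3,
        batch_size: int = 200,
        random_state: int | None = 0,
    ) -> None:
        self.n_components = n_components
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.random_state = random_state

    @staticmethod
    def _init_W(d_out: int, d_in: int) -> np.ndarray:
        W = np.zeros((d_out, d_in))
        r = min(d_out, d_in)
        W[:r, :r] = np.eye(r)
        return W

    def fit(self, X, triplets) -> "MahalanobisTripletMetric":
        """Fit W on a feature matrix/table and a set of triplet constraints."""
        X, rows = _as_matrix_and_triples(X, triplets)
        if len(rows) == 0 and self.epochs > 0:
            raise ValueError("cannot train on an empty triplet set")
        n, d = X.shape
        rng = np.random.default_rng(self.random_state)
        W = self._init_W(self.n_components, d)
        opt = Adam([W], lr=self.lr)
        trace: list[float] = []

        Dij = X[rows[:, 0]] - X[rows[:, 1]]  # anchor-positive differences
        Dik = X[rows[:, 0]] - X[rows[:, 2]]  # anchor-negative differences
        m = len(rows)
        bs = min(self.batch_size, m) if m else 0

        for _ in range(self.epochs):
            perm = rng.permutation(m)
            epoch_loss = 0.0
            for start in range(0, m, bs):
                sel = perm[start : start + bs]
                dij, dik = Dij[sel], Dik[sel]
                u = dik @ W.T  # (b, d_out)
                v = dij @ W.T
                margin = (u**2).sum(axis=1) - (v**2).sum(axis=1)
                w = np.exp(-np.clip(margin, -_MARGIN_CLIP, _MARGIN_CLIP))
                epoch_loss += float(w.sum())
                # dL/dW = sum_b w_b * (-2) (u_b dik_b^T - v_b dij_b^T)
                gW = -2.0 * ((u * w[:, None]).T @ dik - (v * w[:, None]).T @ dij)
                opt.step([gW])
            trace.append(epoch_loss / m)

        self.W_ = W
        self.M_ = W.T @ W
        self.loss_trace_ = np.array(trace)
        self.n_features_in_ = d
        return self

    def transform(self, X) -> np.ndarray:
        """Map features into the learned metric space (x -> W x)."""
        if isinstance(X, FeatureTable):
            X = X.X
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.W_.shape[1]:
            raise ValueError("feature dimension mismatch")
        return X @ self.W_.T

    def distance(self, x_i, x_j) -> float:
        """Squared Mahalanobis distance d_M between two feature vectors."""
        x_i = np.asarray(x_i, dtype=float).ravel()
        x_j = np.asarray(x_j, dtype=float).ravel()
        if x_i.shape != x_j.shape or x_i.shape[0] != self.W_.shape[1]:
            raise ValueError("feature dimension mismatch")
        diff = self.W_ @ (x_i - x_j)
        return float(diff @ diff)

    def pairwise_distance(self, X, X2=None) -> np.ndarray:
        """Squared-distance matrix in the learned metric."""
        Z = self.transform(X)
        if X2 is None:
            return squareform(pdist(Z, metric="sqeuclidean"))
        return cdist(Z, self.transform(X2), metric="sqeuclidean")

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            W=self.W_,
            loss_trace=self.loss_trace_,
            config=np.array(
                [self.n_components, self.epochs, self.lr, self.batch_size,
                 -1 if self.random_state is None else self.random_state],
                dtype=float,
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "MahalanobisTripletMetric":
        data = np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path)
        cfg = data["config"]
        model = cls(
            n_components=int(cfg[0]),
            epochs=int(cfg[1]),
            lr=float(cfg[2]),
            batch_size=int(cfg[3]),
            random_state=None if cfg[4] < 0 else int(cfg[4]),
        )
        model.W_ = data["W"]
        model.M_ = model.W_.T @ model.W_
        model.loss_trace_ = data["loss_trace"]
        model.n_features_in_ = model.W_.shape[1]
        return model


def mahalanobis_distance(model: MahalanobisTripletMetric, x_i, x_j) -> float:
    """Functional form of :meth:`MahalanobisTripletMetric.distance`."""
    return model.distance(x_i, x_j)


def fit_mahalanobis(
    features,
    triplets,
    n_components: int = 25,
    epochs: int = 100,
    lr: float = 1e-3,
    batch: int = 200,
    seed: int = 0,
) -> MahalanobisTripletMetric:
    """Functional wrapper over :class:`MahalanobisTripletMetric`."""
    return MahalanobisTripletMetric(
        n_components=n_components,
        epochs=epochs,
        lr=lr,
        batch_size=batch,
        random_state=seed,
    ).fit(features, triplets)
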