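"""Ordinal (non-metric) multidimensional scaling of perceptual dissimilarities.

Given a pairwise perceptual dissimilarity matrix D, MDS places molecules in a
low-dimensional space so that Euclidean distances between the embedded points
reproduce the observed dissimilarity orderings.  The fit minimizes the
normalized stress

    S = sum_{i<j} (t_ij - d_E(x_i, x_j))^2 / sum_{i<j} t_ij^2

where t_ij is the raw dissimilarity (metric mode) or its monotone disparity
obtained by isotonic regression of the embedding distances onto the
dissimilarity rank order (ordinal mode, Kruskal's non-metric MDS).  MDS is
transductive: it embeds only the molecules it was fit on and cannot score
unseen samples, which is what motivates the parametric learners.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .triplets import DissimilarityMatrix, TripletSet


def stress(
    dissimilarities: np.ndarray,
    coords: np.ndarray,
    disparities: np.ndarray | None = None,
) -> float:
    """Normalized stress of an embedding against observed dissimilarities.

    ``dissimilarities`` may be a square matrix or a condensed (i<j) vector;
    each unordered pair is counted once.  When ``disparities`` (monotone
    fitted targets, condensed) are given they replace the raw values both in
    the numerator and the normalization.
    """
    if isinstance(dissimilarities, DissimilarityMatrix):
        dissimilarities = dissimilarities.values
    d = np.asarray(dissimilarities, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if d.ndim == 2:
        if d.shape[0] != coords.shape[0]:
            raise ValueError("dissimilarity/embedding size mismatch")
        d = squareform(d, checks=False)
    dE = pdist(np.asarray(coords, dtype=float))
    if d.shape != dE.shape:
        raise ValueError("dissimilarity/embedding size mismatch")
    t = d if disparities is None else np.asarray(disparities, dtype=float)
    denom = float((t**2).sum())
    if denom == 0:
        raise ValueError("all dissimilarities are zero; stress undefined")
    return float(((t - dE) ** 2).sum() / denom)


def _torgerson(D: np.ndarray, n_components: int, rng: np.random.Generator) -> np.ndarray:
    """Classical (Torgerson) MDS initialization; Gaussian fallback if defective."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    w_top = w[order]
    if (w_top <= 1e-12).all():
        return rng.normal(scale=1e-2, size=(n, n_components))
    w_top = np.clip(w_top, 0.0, None)
    X = V[:, order] * np.sqrt(w_top)
    # jitter exactly coincident points so gradients are defined
    if n_components > np.count_nonzero(w_top > 1e-12):
        X = X + rng.normal(scale=1e-6, size=X.shape)
    return X


class OrdinalMDS(BaseEstimator):
    """Kruskal-style MDS fit by gradient descent with a monotone safeguard.

    Parameters
    ----------
    n_components : target embedding dimension d-hat (default 25, matching the
        parametric embedders' output width).
    mode : "ordinal" alternates isotonic disparities with gradient steps;
        "metric" fits the raw dissimilarities directly.
    max_iter, tol : stopping rule — stop when the stress improvement of an
        accepted iteration falls below ``tol``.
    random_state : seeds the Gaussian fallback initialization and jitter.

    Attributes
    ----------
    embedding_ : (n, n_components) coordinates.
    stress_ : final stress value.
    stress_trace_ : stress after each accepted iteration (non-increasing).
    converged_ : whether the tolerance was reached within ``max_iter``.
    """

    def __init__(
        self,
        n_components: int = 25,
        mode: str = "ordinal",
        max_iter: int = 300,
        tol: float = 1e-7,
        random_state: int | None = 0,
    ) -> None:
        self.n_components = n_components
        self.mode = mode
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _disparities(self, d_cond: np.ndarray, dE: np.ndarray) -> np.ndarray:
        if self.mode == "metric":
            return d_cond
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        return iso.fit_transform(d_cond, dE)

    def fit(self, D, y=None) -> "OrdinalMDS":
        """Fit the embedding to a square dissimilarity matrix.

        ``D`` may be a :class:`DissimilarityMatrix` or a plain square array.
        """
        if self.mode not in ("ordinal", "metric"):
            raise ValueError(f"unknown MDS mode {self.mode!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if isinstance(D, DissimilarityMatrix):
            self.ids_ = list(D.ids)
            Dm = D.values
        else:
            Dm = np.asarray(D, dtype=float)
            self.ids_ = [str(i) for i in range(Dm.shape[0])]
        if Dm.ndim != 2 or Dm.shape[0] != Dm.shape[1]:
            raise ValueError("D must be a square dissimilarity matrix")
        n = Dm.shape[0]
        rng = np.random.default_rng(self.random_state)
        d_cond = squareform(Dm, checks=False)
        if (d_cond == 0).all():
            raise ValueError("all dissimilarities are zero")

        X = _torgerson(Dm, self.n_components, rng)
        dE = pdist(X)
        t = self._disparities(d_cond, np.maximum(dE, 1e-12))
        s = stress(d_cond, X, t if self.mode == "ordinal" else None)
        trace = [s]
        lr = 0.1
        converged = False

        for _ in range(self.max_iter):
            # gradient of stress w.r.t. coordinates, disparities held fixed
            denom = (t**2).sum()
            dE_safe = np.maximum(dE, 1e-12)
            coef = squareform((dE - t) / dE_safe, checks=False)  # back to square
            # grad_i = (2/denom) * sum_j coef_ij (x_i - x_j)
            row_sums = coef.sum(axis=1, keepdims=True)
            grad = (2.0 / denom) * (row_sums * X - coef @ X)

            accepted = False
            for _halving in range(40):
                X_new = X - lr * grad
                dE_new = pdist(X_new)
                t_new = self._disparities(d_cond, np.maximum(dE_new, 1e-12))
                s_new = stress(
                    d_cond, X_new, t_new if self.mode == "ordinal" else None
                )
                if s_new <= s:
                    accepted = True
                    break
                lr *= 0.5
            if not accepted:
                break
            improvement = s - s_new
            X, dE, t, s = X_new, dE_new, t_new, s_new
            trace.append(s)
            lr *= 1.2
            if improvement < self.tol:
                converged = True
                break

        self.embedding_ = X
        self.stress_ = float(s)
        self.stress_trace_ = np.array(trace)
        self.converged_ = converged
        self.n_iter_ = len(trace) - 1
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        return self.fit(D).embedding_

    def pairwise_distance(self) -> np.ndarray:
        """Euclidean distances between embedded molecules (the learned d_P)."""
        if not hasattr(self, "embedding_"):
            raise RuntimeError("OrdinalMDS instance is not fitted")
        return squareform(pdist(self.embedding_))


def fit_mds(
    matrix: DissimilarityMatrix,
    n_components: int = 25,
    mode: str = "ordinal",
    max_iter: int = 300,
    tolerance: float = 1e-7,
    seed: int = 0,
) -> OrdinalMDS:
    """Functional wrapper over :class:`OrdinalMDS`."""
    return OrdinalMDS(
        n_components=n_components,
        mode=mode,
        max_iter=max_iter,
        tol=tolerance,
        random_state=seed,
    ).fit(matrix)


def dimension_sweep(
    matrix: DissimilarityMatrix,
    dims: list[int],
    test_triplets: TripletSet,
    seed: int = 0,
    mode: str = "ordinal",
    max_iter: int = 300,
) -> "pd.DataFrame":
    """Fit MDS at each dimension and score test triplets.

    Returns a table of (dimension, stress, tga_percent); stress typically
    decreases and triplet generalization accuracy increases with dimension.
    """
    import pandas as pd

    from .evaluation import triplet_generalization_accuracy

    if not dims:
        raise ValueError("dims must be nonempty")
    rows = []
    for d in dims:
        model = fit_mds(
            matrix, n_components=d, mode=mode, max_iter=max_iter, seed=seed
        )
        tga = triplet_generalization_accuracy(model.pairwise_distance(), test_triplets)
        rows.append({"dimension": d, "stress": model.stress_, "tga_percent": tga})
    return pd.DataFrame(rows)
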