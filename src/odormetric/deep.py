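"""Deep triplet metric: a shared-weight three-branch network trained with the
exponential triplet loss.

The embedder phi is a fully connected network (rectifier nonlinearities on
all but the last layer; the last layer is linear with zero bias and plays the
role of the metric matrix W, so the output-space metric is the identity).
The three molecules of a triplet (i, j, k) pass through three replicas of the
network with shared weights, and the loss

    L = sum exp(-(||phi(x_i) - phi(x_k)||^2 - ||phi(x_i) - phi(x_j)||^2))

is minimized with mini-batch Adam.  The perceptual distance of a fitted
model is d_P(x_i, x_j) = ||phi(x_i) - phi(x_j)||^2.

The network and its backward pass are implemented directly on numpy arrays;
at the problem sizes this package targets a CPU matmul is all that's needed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from ._optim import Adam
from .io import FeatureTable
from .mahalanobis import _MARGIN_CLIP, _as_matrix_and_triples


def exp_triplet_loss(anchor, positive, negative) -> float:
    """Exponential triplet loss for a single triple or a batch.

    exp(-(||a - n||^2 - ||a - p||^2)); for 2-D inputs the batch loss is the
    sum over rows.
    """
    a = np.atleast_2d(np.asarray(anchor, dtype=float))
    p = np.atleast_2d(np.asarray(positive, dtype=float))
    n = np.atleast_2d(np.asarray(negative, dtype=float))
    if not (a.shape == p.shape == n.shape):
        raise ValueError("anchor/positive/negative dimension mismatch")
    margin = ((a - n) ** 2).sum(axis=1) - ((a - p) ** 2).sum(axis=1)
    return float(np.exp(-np.clip(margin, -_MARGIN_CLIP, _MARGIN_CLIP)).sum())


def margin_triplet_loss(anchor, positive, negative, margin: float = 1.0) -> float:
    """Hinge-style alternative: sum max(0, m + ||a-p||^2 - ||a-n||^2)."""
    a = np.atleast_2d(np.asarray(anchor, dtype=float))
    p = np.atleast_2d(np.asarray(positive, dtype=float))
    n = np.atleast_2d(np.asarray(negative, dtype=float))
    gap = ((a - p) ** 2).sum(axis=1) - ((a - n) ** 2).sum(axis=1)
    return float(np.maximum(0.0, margin + gap).sum())


@dataclass
class _MLP:
    """Plain fully connected network; last layer linear with zero bias."""

    weights: list[np.ndarray]  # W_l: (out, in)
    biases: list[np.ndarray]  # b_l: (out,); last entry unused (kept zero)

    @classmethod
    def init(cls, dims: list[int], rng: np.random.Generator) -> "_MLP":
        weights, biases = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            # He-style scaling for the rectifier layers
            weights.append(rng.normal(scale=np.sqrt(2.0 / d_in), size=(d_out, d_in)))
            biases.append(np.zeros(d_out))
        return cls(weights, biases)

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return output and the per-layer pre-activation cache for backprop."""
        acts = [X]
        h = X
        L = len(self.weights)
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W.T
            if l < L - 1:
                z = z + b
                h = np.maximum(z, 0.0)
            else:
                h = z  # linear, zero bias
            acts.append(h)
        return h, acts

    def backward(
        self, acts: list[np.ndarray], grad_out: np.ndarray
    ) -> list[np.ndarray]:
        """Gradients of a scalar loss w.r.t. all weights and hidden biases."""
        L = len(self.weights)
        gW = [None] * L
        gb = [None] * L
        g = grad_out
        for l in range(L - 1, -1, -1):
            h_in = acts[l]
            if l < L - 1:
                g = g * (acts[l + 1] > 0)  # rectifier gate
                gb[l] = g.sum(axis=0)
            else:
                gb[l] = np.zeros_like(self.biases[l])  # bias pinned at zero
            gW[l] = g.T @ h_in
            if l > 0:
                g = g @ self.weights[l]
        return gW + gb  # flat list matching params order

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases


class DeepTripletEmbedder(BaseEstimator, TransformerMixin):
    """Non-linear perceptual embedder trained on triplet constraints.

    Parameters
    ----------
    hidden_layer_sizes : widths of the rectifier layers (default (256, 128),
        tapering a 379-dim input toward the output).
    n_components : output embedding width d-hat (default 25).
    lr, epochs, batch_size : Adam schedule (defaults 0.001 / 1000 / 200).
    loss : "exponential" (default) or "margin".
    margin : hinge margin when ``loss="margin"``.
    weight_decay : L2 penalty coefficient (default 0, i.e. none).
    random_state : seeds weight initialization and batch shuffling; a fixed
        seed gives bitwise-reproducible batch order and loss traces.

    Attributes
    ----------
    net_ : the fitted network (best validation-TGA weights when a validation
        set is supplied, else the final weights).
    train_loss_trace_, val_loss_trace_, val_tga_trace_ : per-epoch traces.
    best_epoch_ : epoch whose weights were retained (1-based; 0 = init).
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (256, 128),
        n_components: int = 25,
        lr: float = 1e-3,
        epochs: int = 1000,
        batch_size: int = 200,
        loss: str = "exponential",
        margin: float = 1.0,
        weight_decay: float = 0.0,
        random_state: int | None = 0,
    ) -> None:
        self.hidden_layer_sizes = hidden_layer_sizes
        self.n_components = n_components
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.loss = loss
        self.margin = margin
        self.weight_decay = weight_decay
        self.random_state = random_state

    def _batch_loss_grad(self, out: np.ndarray, b: int):
        """Loss value and gradient w.r.t. the stacked [a; p; n] outputs."""
        a, p, n = out[:b], out[b : 2 * b], out[2 * b :]
        an = a - n
        ap = a - p
        m = (an**2).sum(axis=1) - (ap**2).sum(axis=1)
        if self.loss == "exponential":
            w = np.exp(-np.clip(m, -_MARGIN_CLIP, _MARGIN_CLIP))
            loss = float(w.sum())
            # dL/dm = -w;  dm/da = 2(an - ap); dm/dp = 2 ap; dm/dn = -2 an
            ga = -w[:, None] * 2.0 * (an - ap)
            gp = -w[:, None] * 2.0 * ap
            gn = w[:, None] * 2.0 * an
        elif self.loss == "margin":
            active = (self.margin - m) > 0
            loss = float(np.maximum(0.0, self.margin - m).sum())
            c = -active.astype(float)
            ga = c[:, None] * 2.0 * (an - ap)
            gp = c[:, None] * 2.0 * ap
            gn = -c[:, None] * 2.0 * an
        else:
            raise ValueError(f"unknown loss {self.loss!r}")
        return loss, np.vstack([ga, gp, gn])

    def fit(self, X, triplets, validation_triplets=None) -> "DeepTripletEmbedder":
        """Train on a feature matrix/table and triplet constraints.

        When ``validation_triplets`` is given, per-epoch validation loss and
        triplet generalization accuracy are traced and the weights with the
        best validation TGA are retained.
        """
        from .evaluation import triplet_generalization_accuracy

        features_obj = X
        X, rows = _as_matrix_and_triples(X, triplets)
        if len(rows) == 0 and self.epochs > 0:
            raise ValueError("cannot train on an empty triplet set")
        val_rows = None
        if validation_triplets is not None:
            _, val_rows = _as_matrix_and_triples(features_obj, validation_triplets)
        n, d = X.shape
        dims = [d, *self.hidden_layer_sizes, self.n_components]
        if len(dims) < 3:
            raise ValueError("network needs at least one hidden layer")
        rng = np.random.default_rng(self.random_state)
        net = _MLP.init(dims, rng)
        opt = Adam(net.params, lr=self.lr, weight_decay=self.weight_decay)

        m = len(rows)
        bs = min(self.batch_size, m) if m else 0
        train_trace: list[float] = []
        val_trace: list[float] = []
        tga_trace: list[float] = []
        best = (-np.inf, 0, copy.deepcopy(net))

        for epoch in range(1, self.epochs + 1):
            perm = rng.permutation(m)
            epoch_loss = 0.0
            for start in range(0, m, bs):
                sel = perm[start : start + bs]
                b = len(sel)
                stacked = np.vstack(
                    [X[rows[sel, 0]], X[rows[sel, 1]], X[rows[sel, 2]]]
                )
                out, acts = net.forward(stacked)
                loss, g_out = self._batch_loss_grad(out, b)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "reduce the learning rate or standardize features"
                    )
                epoch_loss += loss
                grads = net.backward(acts, g_out)
                opt.step(grads)
            train_trace.append(epoch_loss / m)

            if val_rows is not None and len(val_rows):
                Z = net.forward(X)[0]
                Dv = squareform(pdist(Z, metric="sqeuclidean"))
                a, p, nn = val_rows.T
                mgn = Dv[a, nn] - Dv[a, p]
                w = np.exp(-np.clip(mgn, -_MARGIN_CLIP, _MARGIN_CLIP))
                val_trace.append(float(w.mean()))
                tga = 100.0 * float((mgn > 0).mean())
                tga_trace.append(tga)
                if tga > best[0]:
                    best = (tga, epoch, copy.deepcopy(net))

        if val_rows is not None and len(val_rows) and self.epochs > 0:
            _, self.best_epoch_, net = best
        else:
            self.best_epoch_ = self.epochs
        self.net_ = net
        self.train_loss_trace_ = np.array(train_trace)
        self.val_loss_trace_ = np.array(val_trace)
        self.val_tga_trace_ = np.array(tga_trace)
        self.n_features_in_ = d
        return self

    def transform(self, X) -> np.ndarray:
        """Embed features with the learned phi (deterministic forward map)."""
        if isinstance(X, FeatureTable):
            X = X.X
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        return self.net_.forward(X)[0]

    def distance(self, x_i, x_j) -> float:
        """Perceptual distance d_P: squared Euclidean between embeddings."""
        zi = self.transform(np.atleast_2d(x_i))
        zj = self.transform(np.atleast_2d(x_j))
        return float(((zi - zj) ** 2).sum())

    def pairwise_distance(self, X, X2=None) -> np.ndarray:
        Z = self.transform(X)
        if X2 is None:
            return squareform(pdist(Z, metric="sqeuclidean"))
        return cdist(Z, self.transform(X2), metric="sqeuclidean")

    def save(self, path: str | Path) -> None:
        arrays = {
            f"W{l}": W for l, W in enumerate(self.net_.weights)
        } | {f"b{l}": b for l, b in enumerate(self.net_.biases)}
        np.savez(
            path,
            n_layers=np.array([len(self.net_.weights)]),
            train_loss=self.train_loss_trace_,
            val_loss=self.val_loss_trace_,
            val_tga=self.val_tga_trace_,
            seed=np.array([-1 if self.random_state is None else self.random_state]),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "DeepTripletEmbedder":
        p = str(path)
        data = np.load(p if p.endswith(".npz") else p + ".npz")
        L = int(data["n_layers"][0])
        weights = [data[f"W{l}"] for l in range(L)]
        biases = [data[f"b{l}"] for l in range(L)]
        seed = int(data["seed"][0])
        model = cls(
            hidden_layer_sizes=tuple(w.shape[0] for w in weights[:-1]),
            n_components=weights[-1].shape[0],
            random_state=None if seed < 0 else seed,
        )
        model.net_ = _MLP(weights, biases)
        model.train_loss_trace_ = data["train_loss"]
        model.val_loss_trace_ = data["val_loss"]
        model.val_tga_trace_ = data["val_tga"]
        model.n_features_in_ = weights[0].shape[1]
        model.best_epoch_ = len(model.train_loss_trace_)
        return model


def fit_deep(features, train, val=None, **config) -> DeepTripletEmbedder:
    """Functional wrapper over :class:`DeepTripletEmbedder`."""
    return DeepTripletEmbedder(**config).fit(features, train, validation_triplets=val)


def embed(model: DeepTripletEmbedder, features) -> np.ndarray:
    """Forward-map a feature table through a fitted embedder."""
    return model.transform(features)


def perceptual_distance(model: DeepTripletEmbedder, x_i, x_j) -> float:
    """d_P(x_i, x_j) = ||phi(x_i) - phi(x_j)||^2 under a fitted model."""
    return model.distance(x_i, x_j)
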