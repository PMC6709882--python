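"""The two trainable deep classifiers: MVCNN and a PointNet-style network.

Both are binary classifiers trained with softmax cross-entropy plus an L2
weight penalty, with one-hot targets ([1, 0] for the positive/caveolae
class, [0, 1] for the negative class) and a best-on-validation checkpoint.

* :class:`MVCNNClassifier` consumes the three-plane projections (3 channels
  of one image) through the conv ladder
  (3->32), (32->64), (64->128), (128->256), (256->512), each followed by a
  3x3 non-overlapping max pool, then fully connected layers 256, 512, 2.
  ReLU on every layer except the final softmax. The ladder and image size
  are configurable so the same model trains at reduced resolution on a CPU.
* :class:`PointNetClassifier` consumes raw point sets: a shared per-point
  dense stack, a symmetric max aggregation (so the output is exactly
  invariant to point order, and to duplicate-padding up to the fixed input
  size), and a dense classifier head. Following the source architecture's
  minimal variant, there is no dropout layer and no input jittering.

Both follow the scikit-learn estimator protocol (fit / predict /
predict_proba / get_params).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn
from .models import ClassificationReport, report_from_predictions

#: One-hot convention: class index 0 <-> positive label 1 ([1, 0]),
#: class index 1 <-> negative label 0 ([0, 1]).
def _label_to_index(y: np.ndarray) -> np.ndarray:
    return (1 - np.asarray(y, dtype=int)).astype(int)


def _index_to_label(idx: np.ndarray) -> np.ndarray:
    return 1 - np.asarray(idx, dtype=int)


class MVCNNClassifier(BaseEstimator, ClassifierMixin):
    """Multi-view CNN over (n, 3, S, S) projection stacks.

    Parameters
    ----------
    image_size_px : int
        Side length S of the input views. Must survive one 3x3 pool per conv
        stage (S // 3**n_stages >= 1).
    channels : tuple of int
        Output channels of the conv ladder. The default is the full-scale
        ladder; pass e.g. ``(8, 16, 32)`` for a reduced-resolution model.
    fc : tuple of int
        Hidden fully connected sizes before the final 2-way layer.
    lr, l2 : float
        Adam step size and L2 weight-penalty coefficient.
    epochs, batch_size, seed : training schedule and RNG seed.
    """

    def __init__(
        self,
        image_size_px: int = 512,
        channels: tuple[int, ...] = (32, 64, 128, 256, 512),
        fc: tuple[int, ...] = (256, 512),
        kernel: int = 3,
        pool: int = 3,
        lr: float = 1e-3,
        l2: float = 1e-4,
        epochs: int = 20,
        batch_size: int = 32,
        seed: int = 0,
    ):
        self.image_size_px = image_size_px
        self.channels = channels
        self.fc = fc
        self.kernel = kernel
        self.pool = pool
        self.lr = lr
        self.l2 = l2
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    def layer_shapes(self) -> list[tuple[str, int, int]]:
        """(stage name, spatial size, channels) after every conv/pool stage.

        Same-padded stride-1 convs preserve the spatial size; each pool
        divides it by the window (floor). Raises if the image is too small
        for the configured ladder.
        """
        size = self.image_size_px
        shapes = []
        in_c = 3
        for i, out_c in enumerate(self.channels, start=1):
            shapes.append((f"conv{i}", size, out_c))
            size = size // self.pool
            if size < 1:
                raise ValueError(
                    f"image_size_px={self.image_size_px} incompatible with "
                    f"{len(self.channels)} pooling stages of window {self.pool}"
                )
            shapes.append((f"pool{i}", size, out_c))
            in_c = out_c
        return shapes

    def _build(self) -> _nn.Sequential:
        rng = np.random.default_rng(self.seed)
        shapes = self.layer_shapes()
        layers: list[_nn.Layer] = []
        in_c = 3
        for out_c in self.channels:
            layers += [_nn.Conv2D(in_c, out_c, rng, kernel=self.kernel), _nn.ReLU(),
                       _nn.MaxPool2D(self.pool)]
            in_c = out_c
        final_size = shapes[-1][1]
        layers.append(_nn.Flatten())
        width = in_c * final_size * final_size
        for h in self.fc:
            layers += [_nn.Dense(width, h, rng), _nn.ReLU()]
            width = h
        layers.append(_nn.Dense(width, 2, rng))
        return _nn.Sequential(layers)

    @staticmethod
    def _check_X(X: np.ndarray, image_size_px: int) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1] != 3 or X.shape[2] != image_size_px or X.shape[3] != image_size_px:
            raise ValueError(
                f"expected (n, 3, {image_size_px}, {image_size_px}) view stack, got {X.shape}"
            )
        return X

    def fit(self, X, y, X_val=None, y_val=None) -> "MVCNNClassifier":
        X = self._check_X(X, self.image_size_px)
        y_idx = _label_to_index(y)
        self.net_ = self._build()
        self.n_parameters_ = self.net_.n_parameters()
        rng = np.random.default_rng(self.seed + 1)
        Xv = self._check_X(X_val, self.image_size_px) if X_val is not None else None
        yv = _label_to_index(y_val) if y_val is not None else None
        self.history_ = _nn.train_loop(
            self.net_, X, y_idx, epochs=self.epochs, batch_size=self.batch_size,
            lr=self.lr, l2=self.l2, rng=rng, X_val=Xv, y_val=yv,
        )
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_X(X, self.image_size_px)
        out = []
        for start in range(0, X.shape[0], 64):
            out.append(_nn.softmax(self.net_.forward(X[start:start + 64])))
        probs = np.concatenate(out)
        # columns ordered as classes_ = [0, 1]: [P(negative), P(positive)]
        return probs[:, ::-1]

    def predict(self, X) -> np.ndarray:
        return _index_to_label(
            np.concatenate(
                [
                    self.net_.forward(self._check_X(X, self.image_size_px)[s:s + 64]).argmax(-1)
                    for s in range(0, np.asarray(X).shape[0], 64)
                ]
            )
        )


def pad_points(points: np.ndarray, size: int) -> np.ndarray:
    """Duplicate-pad a point set to exactly ``size`` points (cyclic repeats).

    Invisible to the max aggregation: duplicates never change an elementwise
    maximum.
    """
    pts = np.asarray(points, dtype=np.float32).reshape(-1, 3)
    n = pts.shape[0]
    if n == 0:
        raise ValueError("cannot pad an empty point set")
    if n > size:
        raise ValueError(f"point set has {n} > {size} points")
    idx = np.arange(size) % n
    return pts[idx]


class PointNetClassifier(BaseEstimator, ClassifierMixin):
    """PointNet-style classifier on raw (centered) point sets.

    Input is a list of (N_i, 3) arrays (or one (n, P, 3) array); each set is
    centered at its centroid and duplicate-padded to ``max_points``. The
    shared per-point dense stack lifts points into ``point_channels[-1]``
    dimensions, a max over the point axis aggregates them into a single
    blob descriptor, and the dense head classifies it. No dropout, no
    jittering.

    ``input_scale_nm`` divides the centered coordinates so a one-sigma blob
    radius (10 nm) maps to unit scale, which conditions the He-initialized
    layers; it is a fixed constant of the architecture, not a per-blob
    normalization, so blob size information is preserved.
    """

    def __init__(
        self,
        point_channels: tuple[int, ...] = (32, 64, 128),
        fc: tuple[int, ...] = (64,),
        max_points: int = 512,
        lr: float = 1e-3,
        l2: float = 1e-4,
        epochs: int = 60,
        batch_size: int = 32,
        seed: int = 0,
        center: bool = True,
        input_scale_nm: float = 10.0,
    ):
        self.point_channels = point_channels
        self.fc = fc
        self.max_points = max_points
        self.lr = lr
        self.l2 = l2
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.center = center
        self.input_scale_nm = input_scale_nm

    def _build(self) -> _nn.Sequential:
        rng = np.random.default_rng(self.seed)
        layers: list[_nn.Layer] = []
        width = 3
        for c in self.point_channels:
            layers += [_nn.Dense(width, c, rng), _nn.ReLU()]
            width = c
        layers.append(_nn.MaxOverPoints())
        for h in self.fc:
            layers += [_nn.Dense(width, h, rng), _nn.ReLU()]
            width = h
        layers.append(_nn.Dense(width, 2, rng))
        return _nn.Sequential(layers)

    def _prepare(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            sets = list(X)
        else:
            sets = list(X)
        out = np.empty((len(sets), self.max_points, 3), dtype=np.float32)
        for i, pts in enumerate(sets):
            pts = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
            if pts.shape[0] == 0:
                raise ValueError(f"point set {i} is empty")
            if self.center:
                # order-independent centroid (sorted summation) so the
                # network output is bitwise invariant to point permutations
                centroid = np.sort(pts, axis=0).sum(axis=0) / pts.shape[0]
                pts = pts - centroid
            out[i] = pad_points(pts / self.input_scale_nm, self.max_points)
        return out

    def fit(self, X, y, X_val=None, y_val=None) -> "PointNetClassifier":
        Xp = self._prepare(X)
        y_idx = _label_to_index(y)
        self.net_ = self._build()
        self.n_parameters_ = self.net_.n_parameters()
        rng = np.random.default_rng(self.seed + 1)
        Xv = self._prepare(X_val) if X_val is not None else None
        yv = _label_to_index(y_val) if y_val is not None else None
        self.history_ = _nn.train_loop(
            self.net_, Xp, y_idx, epochs=self.epochs, batch_size=self.batch_size,
            lr=self.lr, l2=self.l2, rng=rng, X_val=Xv, y_val=yv,
        )
        self.classes_ = np.array([0, 1])
        return self

    def decision_logits(self, X) -> np.ndarray:
        """Raw logits in the one-hot order [positive, negative]."""
        return self.net_.forward(self._prepare(X))

    def predict_proba(self, X) -> np.ndarray:
        probs = _nn.softmax(self.decision_logits(X))
        return probs[:, ::-1]  # columns ordered as classes_ = [0, 1]

    def predict(self, X) -> np.ndarray:
        return _index_to_label(self.decision_logits(X).argmax(axis=-1))


def evaluate_model(model, X_test, y_test) -> ClassificationReport:
    """Argmax predictions -> confusion counts -> the shared metric formulas."""
    y_test = np.asarray(y_test, dtype=int)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X_test)
    return report_from_predictions(y_test, pred)
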