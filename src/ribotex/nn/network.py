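"""Network assembly and training loop (Adam + categorical cross-entropy).

A :class:`Network` is one or more branches of layers applied to the same
input, concatenated, and passed through a shared head ending in a linear
layer whose softmax gives the class probabilities.  Solo models are the
one-branch special case.  Training minimizes the mean categorical
cross-entropy over mini-batches; everything is seeded and reproducible.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Layer, collect_params


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, params: list[Tensor]) -> None:
        self.t += 1
        for p in params:
            if p.grad is None:
                continue
            m, v = self.state.get(id(p), (np.zeros_like(p.data), np.zeros_like(p.data)))
            m = self.beta1 * m + (1 - self.beta1) * p.grad
            v = self.beta2 * v + (1 - self.beta2) * p.grad**2
            self.state[id(p)] = (m, v)
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Network:
    """Branches -> concatenate -> head; the last head layer emits logits."""

    def __init__(self, branches: list[list[Layer]], head: list[Layer]):
        self.branches = branches
        self.head = head

    def forward(self, x: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        xt = Tensor(x)
        outs = []
        for branch in self.branches:
            h = xt
            for layer in branch:
                h = layer(h, train=train, rng=rng)
            outs.append(h)
        h = outs[0] if len(outs) == 1 else ag.concat(outs, axis=-1)
        for layer in self.head:
            h = layer(h, train=train, rng=rng)
        return h

    def parameters(self) -> list[Tensor]:
        params = []
        for branch in self.branches:
            params.extend(collect_params(branch))
        params.extend(collect_params(self.head))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class NeuralNetClassifier:
    """Sklearn-flavoured wrapper: fit / predict / predict_proba.

    Flat feature vectors are presented to the network as a univariate
    sequence of shape (n, n_features, 1) so recurrent and convolutional
    stages can scan the feature axis.
    """

    def __init__(self, build_network, epochs: int = 50, batch_size: int = 64,
                 lr: float = 1e-3, seed: int = 0):
        self.build_network = build_network
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed
        self.net: Network | None = None
        self.classes_: np.ndarray | None = None

    @staticmethod
    def _shape(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X[:, :, None] if X.ndim == 2 else X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NeuralNetClassifier":
        X = self._shape(X)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("training data contains a single class")
        rng = np.random.default_rng(self.seed)
        self.rng_ = rng
        self.net = self.build_network(n_classes)
        onehot = np.eye(n_classes)[y_idx]
        opt = Adam(lr=self.lr)
        n = len(X)
        self.history_: list[float] = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                self.net.zero_grad()
                logits = self.net.forward(X[idx], train=True, rng=rng)
                loss = ag.softmax_cross_entropy(logits, onehot[idx])
                loss.backward()
                opt.step(self.net.parameters())
                epoch_loss += float(loss.data) * len(idx)
            self.history_.append(epoch_loss / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.net is None:
            raise ValueError("classifier is not fitted")
        X = self._shape(X)
        # inference in chunks to bound tape size
        probs = []
        for start in range(0, len(X), 256):
            logits = self.net.forward(X[start:start + 256], train=False,
                                      rng=self.rng_)
            probs.append(ag.softmax(logits.data))
        return np.vstack(probs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
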