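"""Small multilayer perceptron with Gaussian hidden-node activations.

One hidden layer of units with activation ``g(z) = exp(-z^2)`` on the
affine pre-activation, softmax-normalized class outputs, fit by minimizing
multinomial cross-entropy with a small ridge penalty via L-BFGS.  Inputs
are standardized with mean/sd estimated from the training matrix.  Multiple
random restarts are run and the fit with the lowest training loss kept, so
results are deterministic under (seed, restarts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize


@dataclass
class AnnSpec:
    """Architecture and fitting parameters for :class:`GaussianMLP`."""

    predictors: tuple[str, ...] = ()
    hidden_nodes: int = 5
    ridge: float = 1e-3
    restarts: int = 2
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


class GaussianMLP:
    """Multiclass MLP classifier with exp(-z^2) hidden activations."""

    def __init__(
        self,
        hidden_nodes: int = 5,
        ridge: float = 1e-3,
        restarts: int = 2,
        max_iter: int = 300,
        seed: int = 0,
    ) -> None:
        if hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")
        if restarts < 1:
            raise ValueError("restarts must be >= 1")
        self.hidden_nodes = hidden_nodes
        self.ridge = ridge
        self.restarts = restarts
        self.max_iter = max_iter
        self.seed = seed
        self.classes_: Optional[np.ndarray] = None

    # -- parameter packing ------------------------------------------------
    def _shapes(self, p: int, c: int):
        h = self.hidden_nodes
        return [(p, h), (h,), (h, c), (c,)]

    def _unpack(self, theta: np.ndarray, p: int, c: int):
        out = []
        offset = 0
        for shape in self._shapes(p, c):
            size = int(np.prod(shape))
            out.append(theta[offset:offset + size].reshape(shape))
            offset += size
        return out

    def _loss_grad(self, theta, Xs, Y):
        n, p = Xs.shape
        c = Y.shape[1]
        W1, b1, W2, b2 = self._unpack(theta, p, c)
        Z1 = Xs @ W1 + b1
        H = np.exp(-Z1 * Z1)
        logits = H @ W2 + b2
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        P = expl / expl.sum(axis=1, keepdims=True)
        eps = 1e-12
        ce = -np.mean(np.sum(Y * np.log(P + eps), axis=1))
        reg = self.ridge * (np.sum(W1 * W1) + np.sum(W2 * W2))
        loss = ce + reg

        dlogits = (P - Y) / n
        dW2 = H.T @ dlogits + 2 * self.ridge * W2
        db2 = dlogits.sum(axis=0)
        dH = dlogits @ W2.T
        dZ1 = dH * (-2.0 * Z1 * H)
        dW1 = Xs.T @ dZ1 + 2 * self.ridge * W1
        db1 = dZ1.sum(axis=0)
        grad = np.concatenate([a.ravel() for a in (dW1, db1, dW2, db2)])
        return loss, grad

    # -- scikit-learn-ish interface ---------------------------------------
    def fit(self, X, y) -> "GaussianMLP":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-d")
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in X")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - self._mean) / self._sd
        class_index = {cls: i for i, cls in enumerate(self.classes_)}
        Y = np.zeros((len(y), len(self.classes_)))
        for i, label in enumerate(y):
            Y[i, class_index[label]] = 1.0

        p, c = Xs.shape[1], Y.shape[1]
        n_params = sum(int(np.prod(s)) for s in self._shapes(p, c))
        rng = np.random.default_rng(self.seed)
        best_loss = np.inf
        best_theta = None
        for _ in range(self.restarts):
            theta0 = rng.normal(0.0, 0.5, size=n_params)
            res = minimize(
                self._loss_grad,
                theta0,
                args=(Xs, Y),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.max_iter},
            )
            if res.fun < best_loss:
                best_loss = float(res.fun)
                best_theta = res.x
        self._theta = best_theta
        self.train_loss_ = best_loss
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = (X - self._mean) / self._sd
        p, c = Xs.shape[1], len(self.classes_)
        W1, b1, W2, b2 = self._unpack(self._theta, p, c)
        H = np.exp(-((Xs @ W1 + b1) ** 2))
        logits = H @ W2 + b2
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        return expl / expl.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def train_ann(X, y, spec: AnnSpec) -> GaussianMLP:
    """Fit a :class:`GaussianMLP` according to an :class:`AnnSpec`."""
    model = GaussianMLP(
        hidden_nodes=spec.hidden_nodes,
        ridge=spec.ridge,
        restarts=spec.restarts,
        max_iter=spec.max_iter,
        seed=spec.seed,
    )
    return model.fit(X, y)
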