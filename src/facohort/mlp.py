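"""Feed-forward classifier trained with the value-hot focal loss.

A numpy implementation with manual backpropagation: each hidden layer is
affine -> batch normalisation -> ReLU -> dropout, the output layer is affine
-> softmax over the three attendance classes.  Training is mini-batch Adam on
the value-hot focal loss plus optional L1/L2 weight penalties, with early
stopping on a held-out validation split.  All stochastic pieces
(initialisation, batch shuffling, dropout masks, validation split) draw from
one generator seeded by ``random_state``, so fits are reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .loss import softmax, value_hot_focal_grad_logits, value_hot_focal_loss

__all__ = ["ValueHotFocalMLP", "TrainingDivergedError"]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class _BatchNorm:
    def __init__(self, dim, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        n = dout.shape[0]
        xhat = self._xhat
        self.dgamma = (dout * xhat).sum(axis=0)
        self.dbeta = dout.sum(axis=0)
        dxhat = dout * self.gamma
        return (
            dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)
        ) / self._std


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ValueHotFocalMLP(BaseEstimator, ClassifierMixin):
    """Multi-layer perceptron with batch norm, ReLU, dropout and the
    value-hot focal loss.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Widths of the hidden layers; an empty tuple yields softmax
        regression.
    dropout : float
        Dropout rate applied after each hidden activation during training.
    l1, l2 : float
        L1/L2 penalty strengths on the affine weights (not biases or batch
        norm parameters).
    gamma : float
        Focusing parameter of the focal term; 0 disables it.
    learning_rate, batch_size, max_epochs : training loop controls.
    validation_fraction : float
        Share of the training data held out for early stopping; 0 disables
        early stopping.
    patience : int
        Epochs without validation improvement before stopping.
    """

    def __init__(
        self,
        hidden_layer_sizes=(64, 32),
        dropout=0.2,
        l1=0.0,
        l2=1e-4,
        gamma=2.0,
        learning_rate=1e-3,
        batch_size=256,
        max_epochs=200,
        validation_fraction=0.1,
        patience=20,
        random_state=0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.dropout = dropout
        self.l1 = l1
        self.l2 = l2
        self.gamma = gamma
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _init_net(self, n_features, n_classes, rng):
        sizes = [n_features, *self.hidden_layer_sizes, n_classes]
        self.weights_ = []
        self.biases_ = []
        self.batchnorms_ = []
        for i in range(len(sizes) - 1):
            fan_in, fan_out = sizes[i], sizes[i + 1]
            # He initialisation for the ReLU layers
            self.weights_.append(rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.biases_.append(np.zeros(fan_out))
            if i < len(sizes) - 2:
                self.batchnorms_.append(_BatchNorm(fan_out))

    def _forward(self, x, training, rng=None):
        cache = []
        h = x
        for i, (w, b) in enumerate(zip(self.weights_[:-1], self.biases_[:-1])):
            a = h @ w + b
            bn_out = self.batchnorms_[i].forward(a, training)
            relu_mask = bn_out > 0
            r = bn_out * relu_mask
            if training and self.dropout > 0:
                drop_mask = rng.random(r.shape) >= self.dropout
                r = r * drop_mask / (1.0 - self.dropout)
            else:
                drop_mask = None
            cache.append((h, relu_mask, drop_mask))
            h = r
        logits = h @ self.weights_[-1] + self.biases_[-1]
        cache.append(h)
        return logits, cache

    def _backward(self, dlogits, cache):
        grads_w = [None] * len(self.weights_)
        grads_b = [None] * len(self.biases_)
        h_last = cache[-1]
        grads_w[-1] = h_last.T @ dlogits
        grads_b[-1] = dlogits.sum(axis=0)
        dh = dlogits @ self.weights_[-1].T
        for i in range(len(self.weights_) - 2, -1, -1):
            h_in, relu_mask, drop_mask = cache[i]
            if drop_mask is not None:
                dh = dh * drop_mask / (1.0 - self.dropout)
            dh = dh * relu_mask
            dh = self.batchnorms_[i].backward(dh)
            grads_w[i] = h_in.T @ dh
            grads_b[i] = dh.sum(axis=0)
            dh = dh @ self.weights_[i].T
        # weight penalties
        for i, w in enumerate(self.weights_):
            if self.l2:
                grads_w[i] = grads_w[i] + self.l2 * w
            if self.l1:
                grads_w[i] = grads_w[i] + self.l1 * np.sign(w)
        return grads_w, grads_b

    def _penalty(self):
        p = 0.0
        for w in self.weights_:
            if self.l2:
                p += 0.5 * self.l2 * float((w**2).sum())
            if self.l1:
                p += self.l1 * float(np.abs(w).sum())
        return p

    def _data_loss(self, x, y, values):
        logits, _ = self._forward(x, training=False)
        return value_hot_focal_loss(
            softmax(logits), y, values, gamma=self.gamma, normaliser=self._normaliser_
        )

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, sample_values=None):
        """Fit the network.

        ``sample_values`` are the per-sample ground-truth magnitudes
        (attendance counts) used by the value-hot weighting; ``None`` trains
        with unit weights.
        """
        x = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        class_index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_index[c] for c in y])
        values = None if sample_values is None else np.asarray(sample_values, dtype=float)
        self._normaliser_ = 1.0 if values is None else float(values.mean())

        rng = np.random.default_rng(self.random_state)
        n, d = x.shape
        self.n_features_in_ = d
        self._init_net(d, len(self.classes_), rng)

        # validation split for early stopping
        idx = rng.permutation(n)
        n_val = int(n * self.validation_fraction)
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        xv, yv = x[val_idx], yi[val_idx]
        vv = None if values is None else values[val_idx]
        xt, yt = x[tr_idx], yi[tr_idx]
        vt = None if values is None else values[tr_idx]

        params = self.weights_ + self.biases_
        for bn in self.batchnorms_:
            params += [bn.gamma, bn.beta]
        opt = _Adam(params, self.learning_rate)

        best_val = np.inf
        best_state = None
        stall = 0
        self.loss_curve_ = []
        n_tr = len(xt)
        batch = min(self.batch_size, n_tr)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n_tr)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n_tr, batch):
                sel = order[start: start + batch]
                if len(sel) < 2:
                    continue  # batch norm needs at least two rows
                xb, yb = xt[sel], yt[sel]
                vb = None if vt is None else vt[sel]
                logits, cache = self._forward(xb, training=True, rng=rng)
                loss, dlogits = value_hot_focal_grad_logits(
                    logits, yb, vb, gamma=self.gamma, normaliser=self._normaliser_
                )
                loss += self._penalty()
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}: learning rate "
                        f"{self.learning_rate}, batch size {batch}"
                    )
                grads_w, grads_b = self._backward(dlogits, cache)
                grads = grads_w + grads_b
                for bn in self.batchnorms_:
                    grads += [bn.dgamma, bn.dbeta]
                opt.step(params, grads)
                epoch_loss += loss
                n_batches += 1
            self.loss_curve_.append(epoch_loss / max(n_batches, 1))

            if n_val:
                val_loss = self._data_loss(xv, yv, vv)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = self._snapshot()
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if best_state is not None:
            self._restore(best_state)
        self.n_iter_ = len(self.loss_curve_)
        return self

    def _snapshot(self):
        return (
            [w.copy() for w in self.weights_],
            [b.copy() for b in self.biases_],
            [
                (bn.gamma.copy(), bn.beta.copy(), bn.running_mean.copy(), bn.running_var.copy())
                for bn in self.batchnorms_
            ],
        )

    def _restore(self, state):
        ws, bs, bns = state
        for w, wc in zip(self.weights_, ws):
            w[...] = wc
        for b, bc in zip(self.biases_, bs):
            b[...] = bc
        for bn, (g, be, rm, rv) in zip(self.batchnorms_, bns):
            bn.gamma[...] = g
            bn.beta[...] = be
            bn.running_mean[...] = rm
            bn.running_var[...] = rv

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        logits, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return logits

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def training_loss(self, X, y, sample_values=None):
        """Data loss (no penalties) of the fitted network on (X, y)."""
        check_is_fitted(self, "weights_")
        yi = np.searchsorted(self.classes_, np.asarray(y))
        return self._data_loss(np.asarray(X, dtype=float), yi, sample_values)
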