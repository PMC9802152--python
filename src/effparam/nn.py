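"""Minimal neural-network stack: reverse-mode autodiff, MLPs, Adam.

The conformal autoencoder's loss penalizes inner products of *input
gradients* of the latent coordinates, so the training graph must contain the
encoder's input-Jacobian.  Here the Jacobian is propagated layer-by-layer
with ordinary tensor primitives (matmul, tanh', elementwise products), which
makes it a first-class node of the computation graph: a single reverse-mode
sweep then differentiates the penalty with respect to the weights, and no
second-order machinery is needed.

The engine operates on numpy arrays with full broadcasting; only the
operations required by the package's architectures are implemented.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "MLP", "Adam", "MLPRegressor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, prev=(), requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._backward = None
        self._prev = prev
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    def __pow__(self, p: int):
        out = Tensor(self.data**p, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * p * self.data ** (p - 1)
        )
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1.0 - t * t))
        return out

    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def expand_dims(self, axis):
        out = Tensor(np.expand_dims(self.data, axis), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.shape)
        )
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        out._backward = bw
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad and t.grad is not None:
                t._backward(t.grad)


class MLP:
    """Fully connected tanh network with a linear output layer."""

    def __init__(self, sizes, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.sizes = tuple(sizes)
        self.params = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            W = Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)
            b = Tensor(np.zeros(fan_out), requires_grad=True)
            self.params += [W, b]

    def __call__(self, x: Tensor) -> Tensor:
        a = x
        n_layers = len(self.params) // 2
        for i in range(n_layers):
            W, b = self.params[2 * i], self.params[2 * i + 1]
            z = a @ W + b
            a = z.tanh() if i < n_layers - 1 else z
        return a

    def forward_with_jacobian(self, x: Tensor):
        """Return (output, J) where J[i] = d out_i / d in_i, shape (n, d_out, d_in).

        The Jacobian is built from the same graph nodes as the output, so
        losses on J backpropagate into the weights in one reverse sweep.
        """
        n, d = x.shape
        a = x
        J = Tensor(np.broadcast_to(np.eye(d), (n, d, d)).copy())
        n_layers = len(self.params) // 2
        for i in range(n_layers):
            W, b = self.params[2 * i], self.params[2 * i + 1]
            z = a @ W + b
            # dz/dx = W^T @ da/dx  (W^T broadcast over the batch)
            WT = Tensor(W.data.T, (W,))

            def bw(g, W=W):
                if W.requires_grad:
                    W._accum(np.swapaxes(_unbroadcast(g, W.data.T.shape), -1, -2))

            WT._backward = bw
            J = WT @ J
            if i < n_layers - 1:
                a = z.tanh()
                J = (1.0 - a * a).expand_dims(2) * J
            else:
                a = z
        return a, J

    def numpy_call(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        n_layers = len(self.params) // 2
        for i in range(n_layers):
            W, b = self.params[2 * i].data, self.params[2 * i + 1].data
            z = a @ W + b
            a = np.tanh(z) if i < n_layers - 1 else z
        return a

    def numpy_jacobian(self, X: np.ndarray) -> np.ndarray:
        """Input-Jacobian without graph building (for inference-time scores)."""
        a = np.asarray(X, dtype=float)
        n, d = a.shape
        J = np.broadcast_to(np.eye(d), (n, d, d)).copy()
        n_layers = len(self.params) // 2
        for i in range(n_layers):
            W, b = self.params[2 * i].data, self.params[2 * i + 1].data
            z = a @ W + b
            J = W.T @ J
            if i < n_layers - 1:
                a = np.tanh(z)
                J = (1.0 - a * a)[:, :, None] * J
            else:
                a = z
        return J

    def state(self):
        return [p.data.copy() for p in self.params]

    def load_state(self, state):
        for p, s in zip(self.params, state):
            p.data = s.copy()


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            p.data -= self.lr * (self.m[i] / c1) / (np.sqrt(self.v[i] / c2) + self.eps)


class MLPRegressor:
    """Tanh MLP regression with Adam, input standardization, early stopping.

    Inputs are standardized internally; outputs are fit on their raw scale so
    the reported mean-squared error is in the target's own units.
    """

    def __init__(self, hidden=(30, 30, 30, 30, 30), lr=1e-3, batch_size=None,
                 epochs=2000, seed=0, patience=200, val_fraction=0.1,
                 lr_decay=0.1, lr_milestones=(0.6, 0.85)):
        self.hidden = tuple(hidden)
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.patience = patience
        self.val_fraction = val_fraction
        self.lr_decay = lr_decay
        self.lr_milestones = tuple(lr_milestones)
        self.net = None
        self.history = []

    def fit(self, X, Y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        self.x_mean, self.x_std = X.mean(0), np.where(X.std(0) > 0, X.std(0), 1.0)
        Xs = (X - self.x_mean) / self.x_std
        rng = np.random.default_rng(self.seed)
        n = Xs.shape[0]
        n_val = max(1, int(self.val_fraction * n))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, Ytr, Xval, Yval = Xs[tr_idx], Y[tr_idx], Xs[val_idx], Y[val_idx]
        self.net = MLP((Xs.shape[1], *self.hidden, Y.shape[1]), seed=self.seed)
        opt = Adam(self.net.params, lr=self.lr)
        best_val, best_state, since_best = np.inf, self.net.state(), 0
        bs = self.batch_size or Xtr.shape[0]
        milestones = {int(m * self.epochs) for m in self.lr_milestones}
        for epoch in range(self.epochs):
            if epoch in milestones:
                opt.lr *= self.lr_decay
            order = rng.permutation(Xtr.shape[0])
            for start in range(0, Xtr.shape[0], bs):
                idx = order[start : start + bs]
                xb, yb = Tensor(Xtr[idx]), Tensor(Ytr[idx])
                pred = self.net(xb)
                loss = ((pred - yb) ** 2).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
            val_mse = float(np.mean((self.net.numpy_call(Xval) - Yval) ** 2))
            self.history.append(val_mse)
            if val_mse < best_val:
                best_val, best_state, since_best = val_mse, self.net.state(), 0
            else:
                since_best += 1
                if since_best > self.patience:
                    break
        self.net.load_state(best_state)
        self.val_mse_ = best_val
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.net.numpy_call((X - self.x_mean) / self.x_std)

    def mse(self, X, Y):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        return float(np.mean((self.predict(X) - Y) ** 2))
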