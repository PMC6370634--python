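"""NumPy multilayer perceptron with hard parameter sharing.

A shared fully connected trunk (ReLU) feeds one or more task branches,
each ending in a single sigmoid unit.  Training uses minibatch Adam on a
task-weighted sum of binary cross-entropies, inverted dropout on the input
and every hidden activation, normal (He-scaled) kernel initialization, and
early stopping on a held-out stratified split of the training data with
best-checkpoint restoration.  A single NumPy Generator drives all
randomness, so runs are bit-reproducible per seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split

_EPS = 1e-7


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _bce(p, y):
    p = np.clip(p, _EPS, 1 - _EPS)
    return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MLP:
    """Shared-trunk multilayer perceptron with ``n_tasks`` sigmoid heads.

    ``shared_layers`` and ``task_layers`` are unit counts for the trunk and
    for each task branch's hidden layers (the final 1-unit sigmoid output
    of each branch is implicit).
    """

    def __init__(self, n_features, shared_layers, task_layers, n_tasks=1,
                 dropout_rate=0.3, task_weights=None, seed=0):
        if n_tasks < 1:
            raise ValueError("n_tasks must be >= 1")
        self.n_features = n_features
        self.shared_layers = list(shared_layers)
        self.task_layers = list(task_layers)
        self.n_tasks = n_tasks
        self.dropout_rate = float(dropout_rate)
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        tw = np.ones(n_tasks) if task_weights is None else \
            np.asarray(task_weights, dtype=float)
        if tw.shape != (n_tasks,) or (tw < 0).any() or tw.sum() == 0:
            raise ValueError("task_weights must be n_tasks non-negative "
                             "reals, not all zero")
        self.task_weights = tw
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self._init_params()
        self.history: dict[str, list[float]] = {}
        self.n_epochs_run = 0

    def _dense_init(self, fan_in, fan_out):
        # normal kernel initializer; He scaling keeps deep ReLU nets trainable
        w = self.rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
        return w, np.zeros(fan_out)

    def _init_params(self):
        self.trunk = []
        fan = self.n_features
        for units in self.shared_layers:
            self.trunk.append(self._dense_init(fan, units))
            fan = units
        self.branches = []
        for _ in range(self.n_tasks):
            branch = []
            bfan = fan
            for units in self.task_layers:
                branch.append(self._dense_init(bfan, units))
                bfan = units
            branch.append(self._dense_init(bfan, 1))  # sigmoid head
            self.branches.append(branch)

    # -- parameter bookkeeping -------------------------------------------
    def _params(self):
        out = []
        for w, b in self.trunk:
            out += [w, b]
        for branch in self.branches:
            for w, b in branch:
                out += [w, b]
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self._params())

    def get_weights(self):
        return [p.copy() for p in self._params()]

    def set_weights(self, weights):
        for p, w in zip(self._params(), weights):
            p[...] = w

    # -- forward / backward ----------------------------------------------
    def _dropout_mask(self, shape):
        keep = 1.0 - self.dropout_rate
        return (self.rng.random(shape) < keep) / keep

    def _forward(self, X, train):
        """Returns (probs, cache); dropout active only when train=True."""
        cache = {"a": [], "z": [], "masks": []}
        a = X
        if train and self.dropout_rate > 0:
            m = self._dropout_mask(a.shape)
            a = a * m
            cache["input_mask"] = m
        else:
            cache["input_mask"] = None
        cache["a0"] = a
        trunk_a, trunk_z, trunk_m = [], [], []
        for w, b in self.trunk:
            z = a @ w + b
            h = np.maximum(z, 0.0)
            if train and self.dropout_rate > 0:
                m = self._dropout_mask(h.shape)
                h = h * m
            else:
                m = None
            trunk_z.append(z)
            trunk_m.append(m)
            trunk_a.append(h)
            a = h
        cache["trunk"] = (trunk_a, trunk_z, trunk_m)
        cache["trunk_out"] = a
        probs = np.empty((X.shape[0], self.n_tasks))
        branch_caches = []
        for t, branch in enumerate(self.branches):
            bt_a, bt_z, bt_m = [], [], []
            ab = a
            for w, b in branch[:-1]:
                z = ab @ w + b
                h = np.maximum(z, 0.0)
                if train and self.dropout_rate > 0:
                    m = self._dropout_mask(h.shape)
                    h = h * m
                else:
                    m = None
                bt_z.append(z)
                bt_m.append(m)
                bt_a.append(h)
                ab = h
            w, b = branch[-1]
            logit = ab @ w + b
            probs[:, t] = _sigmoid(logit)[:, 0]
            branch_caches.append((bt_a, bt_z, bt_m, ab))
        cache["branches"] = branch_caches
        return probs, cache

    def _backward(self, X, Y, probs, cache):
        B = X.shape[0]
        grads_trunk = [(np.zeros_like(w), np.zeros_like(b))
                       for w, b in self.trunk]
        grads_branches = []
        d_trunk_out = np.zeros_like(cache["trunk_out"])
        for t, branch in enumerate(self.branches):
            bt_a, bt_z, bt_m, ab = cache["branches"][t]
            # d(bce)/dlogit for sigmoid + BCE, averaged over batch
            dlogit = (self.task_weights[t] *
                      (probs[:, t] - Y[:, t]) / B)[:, None]
            w, b = branch[-1]
            gw = ab.T @ dlogit
            gb = dlogit.sum(axis=0)
            da = dlogit @ w.T
            bgrads = [(gw, gb)]
            for i in range(len(branch) - 2, -1, -1):
                w, b = branch[i]
                if bt_m[i] is not None:
                    da = da * bt_m[i]
                dz = da * (bt_z[i] > 0)
                a_prev = cache["trunk_out"] if i == 0 else bt_a[i - 1]
                bgrads.append((a_prev.T @ dz, dz.sum(axis=0)))
                da = dz @ w.T
            bgrads.reverse()
            grads_branches.append(bgrads)
            d_trunk_out += da
        da = d_trunk_out
        trunk_a, trunk_z, trunk_m = cache["trunk"]
        for i in range(len(self.trunk) - 1, -1, -1):
            w, b = self.trunk[i]
            if trunk_m[i] is not None:
                da = da * trunk_m[i]
            dz = da * (trunk_z[i] > 0)
            a_prev = cache["a0"] if i == 0 else trunk_a[i - 1]
            grads_trunk[i] = (a_prev.T @ dz, dz.sum(axis=0))
            da = dz @ w.T
        flat = []
        for gw, gb in grads_trunk:
            flat += [gw, gb]
        for bgrads in grads_branches:
            for gw, gb in bgrads:
                flat += [gw, gb]
        return flat

    def _loss(self, probs, Y):
        return float(sum(self.task_weights[t] * _bce(probs[:, t], Y[:, t])
                         for t in range(self.n_tasks)))

    # -- training ---------------------------------------------------------
    def fit(self, X, Y, batch_size=64, max_epochs=200, patience=10,
            learning_rate=1e-3, val_fraction=0.1):
        """Minibatch Adam with early stopping.

        Stops when the validation loss (10% stratified split by default)
        has not improved for ``patience`` epochs and restores the best
        checkpoint, so the returned model is never worse than the best one
        seen.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[1] != self.n_tasks:
            raise ValueError("label matrix width != n_tasks")
        strat = Y[:, 0] if self.n_tasks == 1 else Y.max(axis=1)
        try:
            X_tr, X_val, Y_tr, Y_val = train_test_split(
                X, Y, test_size=val_fraction, stratify=strat,
                random_state=int(self.rng.integers(0, 2**31 - 1)))
        except ValueError:  # a class too small to stratify
            X_tr, X_val, Y_tr, Y_val = train_test_split(
                X, Y, test_size=val_fraction,
                random_state=int(self.rng.integers(0, 2**31 - 1)))
        opt = _Adam(self._params(), learning_rate)
        best_loss = np.inf
        best_weights = self.get_weights()
        wait = 0
        hist_tr, hist_val = [], []
        n = X_tr.shape[0]
        for epoch in range(max_epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = X_tr[idx], Y_tr[idx]
                probs, cache = self._forward(xb, train=True)
                grads = self._backward(xb, yb, probs, cache)
                opt.step(self._params(), grads)
                epoch_loss += self._loss(probs, yb)
                n_batches += 1
            probs_val, _ = self._forward(X_val, train=False)
            val_loss = self._loss(probs_val, Y_val)
            if not np.isfinite(val_loss):
                raise FloatingPointError(
                    f"non-finite validation loss at epoch {epoch}: "
                    f"{val_loss}")
            hist_tr.append(epoch_loss / max(n_batches, 1))
            hist_val.append(val_loss)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_weights = self.get_weights()
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
        self.set_weights(best_weights)
        self.history = {"train_loss": hist_tr, "val_loss": hist_val,
                        "best_val_loss": best_loss}
        self.n_epochs_run = len(hist_tr)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """(n_samples, n_tasks) sigmoid probabilities; dropout disabled."""
        probs, _ = self._forward(np.asarray(X, dtype=float), train=False)
        return probs
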