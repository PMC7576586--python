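"""A small stacked-GRU sequence classifier in pure numpy.

Architecture: optional temporal mean-pooling of the input, one or more GRU
layers (optionally bidirectional; each direction has its own parameters),
temporal mean-pooling of the last layer's states, and a dense softmax
readout.  Trained with Adam on cross-entropy, full backpropagation through
time, and early stopping on a held-out slice of the training data.

The gate equations are the standard GRU:

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
    g_t = tanh(x_t Wh + (r_t * h_{t-1}) Uh + bh)
    h_t = (1 - z_t) * h_{t-1} + z_t * g_t

Gradients are derived by hand and verified against finite differences in
the test suite.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["GRUClassifier"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _GRULayer:
    """One GRU direction: processes [B, T, D] -> [B, T, H]."""

    PARAM_NAMES = ("Wz", "Wr", "Wh", "Uz", "Ur", "Uh", "bz", "br", "bh")

    def __init__(self, d_in: int, width: int, rng: np.random.Generator):
        s_in = 1.0 / math.sqrt(d_in)
        s_h = 1.0 / math.sqrt(width)
        self.params: Dict[str, np.ndarray] = {}
        for name in ("Wz", "Wr", "Wh"):
            self.params[name] = rng.uniform(-s_in, s_in, (d_in, width))
        for name in ("Uz", "Ur", "Uh"):
            self.params[name] = rng.uniform(-s_h, s_h, (width, width))
        for name in ("bz", "br", "bh"):
            self.params[name] = np.zeros(width)
        self.width = width
        self.d_in = d_in

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def forward(self, X: np.ndarray) -> Tuple[np.ndarray, dict]:
        B, T, _ = X.shape
        p = self.params
        H = np.zeros((B, T, self.width))
        cache = {"X": X, "z": [], "r": [], "g": [], "h_prev": []}
        h = np.zeros((B, self.width))
        for t in range(T):
            x = X[:, t, :]
            z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
            g = np.tanh(x @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
            cache["h_prev"].append(h)
            cache["z"].append(z)
            cache["r"].append(r)
            cache["g"].append(g)
            h = (1.0 - z) * h + z * g
            H[:, t, :] = h
        return H, cache

    def backward(
        self, dH: np.ndarray, cache: dict
    ) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
        p = self.params
        X = cache["X"]
        B, T, _ = X.shape
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, self.width))
        for t in range(T - 1, -1, -1):
            dh = dH[:, t, :] + dh_next
            z, r, g = cache["z"][t], cache["r"][t], cache["g"][t]
            h_prev = cache["h_prev"][t]
            x = X[:, t, :]

            dz = dh * (g - h_prev)
            dg = dh * z
            dh_prev = dh * (1.0 - z)

            dg_pre = dg * (1.0 - g * g)
            grads["Wh"] += x.T @ dg_pre
            grads["Uh"] += (r * h_prev).T @ dg_pre
            grads["bh"] += dg_pre.sum(axis=0)
            d_rh = dg_pre @ p["Uh"].T
            dr = d_rh * h_prev
            dh_prev += d_rh * r

            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            grads["Wz"] += x.T @ dz_pre
            grads["Uz"] += h_prev.T @ dz_pre
            grads["bz"] += dz_pre.sum(axis=0)
            grads["Wr"] += x.T @ dr_pre
            grads["Ur"] += h_prev.T @ dr_pre
            grads["br"] += dr_pre.sum(axis=0)

            dX[:, t, :] = dg_pre @ p["Wh"].T + dz_pre @ p["Wz"].T + dr_pre @ p["Wr"].T
            dh_next = dh_prev + dz_pre @ p["Uz"].T + dr_pre @ p["Ur"].T
        return dX, grads


class GRUClassifier:
    """Stacked (bi)directional GRU classifier trained by BPTT + Adam.

    Parameters
    ----------
    n_layers, width
        Number of recurrent layers and hidden units per direction.
    bidirectional
        If True each layer runs a forward and a backward pass with separate
        parameters; their state sequences are concatenated featurewise.
    pool
        Temporal mean-pooling factor applied to the input before the
        recurrent stack ("auto": chosen so <= ``target_steps`` steps remain).
    val_fraction, patience
        Early stopping: fraction of the training set held out for
        validation and number of non-improving epochs tolerated.
    """

    def __init__(
        self,
        n_layers: int = 2,
        width: int = 64,
        bidirectional: bool = False,
        pool: int | str = "auto",
        target_steps: int = 25,
        lr: float = 1e-2,
        max_epochs: int = 40,
        batch_size: int = 32,
        val_fraction: float = 0.1,
        patience: int = 8,
        seed: int = 0,
    ):
        self.n_layers = n_layers
        self.width = width
        self.bidirectional = bidirectional
        self.pool = pool
        self.target_steps = target_steps
        self.lr = lr
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed
        self.layers_: List[List[_GRULayer]] = []
        self.classes_: Optional[np.ndarray] = None

    # -- construction --------------------------------------------------

    def _build(self, d_in: int, n_classes: int) -> None:
        rng = np.random.default_rng(self.seed)
        self.layers_ = []
        d = d_in
        n_dir = 2 if self.bidirectional else 1
        for _ in range(self.n_layers):
            self.layers_.append([_GRULayer(d, self.width, rng) for _ in range(n_dir)])
            d = self.width * n_dir
        s = 1.0 / math.sqrt(d)
        self.Wout = rng.uniform(-s, s, (d, n_classes))
        self.bout = np.zeros(n_classes)

    @property
    def n_recurrent_params(self) -> int:
        """Total parameter count of the recurrent layers (doubles when
        bidirectional)."""
        return sum(l.n_params for group in self.layers_ for l in group)

    def _all_params(self):
        for group in self.layers_:
            for layer in group:
                for name in layer.PARAM_NAMES:
                    yield layer.params, name
        yield self.__dict__, "Wout"
        yield self.__dict__, "bout"

    # -- forward/backward ----------------------------------------------

    def _pool_input(self, X: np.ndarray) -> np.ndarray:
        T = X.shape[1]
        k = getattr(self, "_pool_k", None)
        if k is None:
            k = self.pool
            if k == "auto":
                k = max(1, int(math.ceil(T / self.target_steps)))
            self._pool_k = k
        if k <= 1:
            return X
        T2 = T // k
        return X[:, : T2 * k, :].reshape(X.shape[0], T2, k, X.shape[2]).mean(axis=2)

    def _forward(self, Xp: np.ndarray):
        caches = []
        H = Xp
        for group in self.layers_:
            outs, group_cache = [], []
            for d, layer in enumerate(group):
                inp = H if d == 0 else H[:, ::-1, :]
                out, cache = layer.forward(inp)
                if d == 1:
                    out = out[:, ::-1, :]
                outs.append(out)
                group_cache.append(cache)
            H = np.concatenate(outs, axis=2) if len(outs) > 1 else outs[0]
            caches.append(group_cache)
        pooled = H.mean(axis=1)
        logits = pooled @ self.Wout + self.bout
        return logits, pooled, H, caches

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grads(self, Xp: np.ndarray, y_idx: np.ndarray):
        """Cross-entropy loss and analytic gradients on pooled input Xp."""
        B, T = Xp.shape[0], Xp.shape[1]
        logits, pooled, H, caches = self._forward(Xp)
        probs = self._softmax(logits)
        loss = -float(np.mean(np.log(probs[np.arange(B), y_idx] + 1e-12)))

        dlogits = probs.copy()
        dlogits[np.arange(B), y_idx] -= 1.0
        dlogits /= B
        grads: Dict[int, list] = {}
        gWout = pooled.T @ dlogits
        gbout = dlogits.sum(axis=0)
        dH = np.repeat((dlogits @ self.Wout.T)[:, None, :], H.shape[1], axis=1) / H.shape[1]

        layer_grads: List[List[Dict[str, np.ndarray]]] = []
        for li in range(len(self.layers_) - 1, -1, -1):
            group = self.layers_[li]
            if len(group) == 2:
                dH_f, dH_b = np.split(dH, 2, axis=2)
                dX_f, g_f = group[0].backward(dH_f, caches[li][0])
                dX_b, g_b = group[1].backward(dH_b[:, ::-1, :], caches[li][1])
                dH = dX_f + dX_b[:, ::-1, :]
                layer_grads.append([g_f, g_b])
            else:
                dX, g = group[0].backward(dH, caches[li][0])
                dH = dX
                layer_grads.append([g])
        layer_grads.reverse()
        return loss, layer_grads, gWout, gbout

    # -- training -------------------------------------------------------

    def fit(self, X: np.ndarray, y: Sequence) -> "GRUClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be [n_windows, n_samples, n_channels]")
        self.classes_ = np.unique(y)
        y_idx = np.searchsorted(self.classes_, y)
        Xp = self._pool_input(X)
        self._build(Xp.shape[2], len(self.classes_))

        rng = np.random.default_rng(self.seed + 1)
        n = len(Xp)
        n_val = int(round(self.val_fraction * n)) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        # Adam state
        mstate = [np.zeros_like(p[name]) for p, name in self._all_params()]
        vstate = [np.zeros_like(p[name]) for p, name in self._all_params()]
        step = 0
        b1, b2, eps = 0.9, 0.999, 1e-8

        best_val = np.inf
        best_params = None
        bad_epochs = 0
        for _epoch in range(self.max_epochs):
            order = rng.permutation(tr_idx)
            for lo in range(0, len(order), self.batch_size):
                idx = order[lo : lo + self.batch_size]
                if len(idx) == 0:
                    continue
                loss, layer_grads, gWout, gbout = self.loss_and_grads(
                    Xp[idx], y_idx[idx]
                )
                flat: List[np.ndarray] = []
                for gi, group in enumerate(self.layers_):
                    for di, layer in enumerate(group):
                        for name in layer.PARAM_NAMES:
                            flat.append(layer_grads[gi][di][name])
                flat.append(gWout)
                flat.append(gbout)
                step += 1
                for (holder, name), g, m, v in zip(
                    self._all_params(), flat, mstate, vstate
                ):
                    m *= b1
                    m += (1 - b1) * g
                    v *= b2
                    v += (1 - b2) * g * g
                    mhat = m / (1 - b1**step)
                    vhat = v / (1 - b2**step)
                    holder[name] = holder[name] - self.lr * mhat / (np.sqrt(vhat) + eps)
            if n_val:
                logits, *_ = self._forward(Xp[val_idx])
                probs = self._softmax(logits)
                vloss = -float(
                    np.mean(np.log(probs[np.arange(n_val), y_idx[val_idx]] + 1e-12))
                )
                if vloss < best_val - 1e-5:
                    best_val = vloss
                    best_params = [
                        (holder, name, holder[name].copy())
                        for holder, name in self._all_params()
                    ]
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs >= self.patience:
                        break
        if best_params is not None:
            for holder, name, val in best_params:
                holder[name] = val
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xp = self._pool_input(np.asarray(X, dtype=float))
        logits, *_ = self._forward(Xp)
        return self._softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise RuntimeError("model is not fitted")
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
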