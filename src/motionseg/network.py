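"""A small bidirectional-GRU per-timestep sequence labeler, in pure numpy.

Architecture (per input window of L feature vectors):

    time-distributed dense(48) -> batch norm -> ELU -> dropout
    -> bidirectional GRU(48)   -> batch norm -> dropout
    -> bidirectional GRU(32)   -> batch norm -> dropout
    -> time-distributed dense(K) -> softmax          (one row per frame)

Bidirectional outputs are concatenated (widths 96 and 64).  Batch
normalization sits before the activation on the dense layer and on the
recurrent-layer outputs; dropout is applied to every layer except the
output.  Training uses Adam on a class-weighted categorical
cross-entropy.  Forward, backward and the optimizer are implemented
here directly; gradients are exercised against finite differences in
the test suite.

All randomness (initialization, dropout, shuffling) flows from a single
seeded Generator, so training is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["GruNet", "Adam", "softmax", "weighted_cce", "cce_grad_logits"]

_LOG_FLOOR = 1e-12
_BN_EPS = 1e-5


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cce(y_true: np.ndarray, y_pred: np.ndarray, alpha: np.ndarray) -> float:
    """Mean over samples of -sum_i alpha_i * y_i * log(p_i).

    ``y_true`` is one-hot (..., K), ``y_pred`` rows are probability
    vectors, ``alpha`` is a per-class weight vector.  The log is clamped
    at a small floor for numerical safety.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    logp = np.log(np.maximum(y_pred, _LOG_FLOOR))
    per_sample = -(np.asarray(alpha) * y_true * logp).sum(axis=-1)
    return float(per_sample.mean())


def cce_grad_logits(y_true: np.ndarray, probs: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gradient of :func:`weighted_cce` w.r.t. the softmax logits."""
    n = int(np.prod(y_true.shape[:-1]))
    a = (y_true * alpha).sum(axis=-1, keepdims=True)  # alpha of the true class
    return a * (probs - y_true) / n


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k, g in grads.items():
            m = self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            v = self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            self.params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# layer primitives (functional, with explicit caches)
# ---------------------------------------------------------------------------


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, y + 1.0)


@dataclass
class _BnCache:
    xhat: np.ndarray
    inv_std: np.ndarray


class _BatchNorm:
    """Per-feature batch normalization over all (batch, time) positions."""

    def __init__(self, dim: int, prefix: str, momentum: float = 0.9):
        self.prefix = prefix
        self.momentum = momentum
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.run_mean = np.zeros(dim)
        self.run_var = np.ones(dim)

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.prefix}.gamma": self.gamma, f"{self.prefix}.beta": self.beta}

    def state(self) -> dict[str, np.ndarray]:
        return {f"{self.prefix}.run_mean": self.run_mean, f"{self.prefix}.run_var": self.run_var}

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, _BnCache | None]:
        flat = x.reshape(-1, x.shape[-1])
        if training:
            mu = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu) * inv_std
        out = self.gamma * xhat + self.beta
        cache = _BnCache(xhat, inv_std) if training else None
        return out, cache

    def backward(self, dy: np.ndarray, cache: _BnCache,
                 grads: dict[str, np.ndarray]) -> np.ndarray:
        xhat, inv_std = cache.xhat, cache.inv_std
        axes = tuple(range(dy.ndim - 1))
        n = int(np.prod(dy.shape[:-1]))
        grads[f"{self.prefix}.gamma"] = (dy * xhat).sum(axis=axes)
        grads[f"{self.prefix}.beta"] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = inv_std * (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes) / n
        )
        return dx


class _Gru:
    """One GRU direction.  h_t = (1-z)*n + z*h_{t-1}."""

    def __init__(self, in_dim: int, units: int, prefix: str, rng: np.random.Generator):
        self.prefix = prefix
        self.units = units
        lim = math.sqrt(6.0 / (in_dim + units))
        def w():
            return rng.uniform(-lim, lim, size=(in_dim, units))
        def u():
            # orthogonal recurrent init
            q, _ = np.linalg.qr(rng.standard_normal((units, units)))
            return q
        self.Wz, self.Wr, self.Wn = w(), w(), w()
        self.Uz, self.Ur, self.Un = u(), u(), u()
        self.bz = np.zeros(units)
        self.br = np.zeros(units)
        self.bn = np.zeros(units)

    def params(self) -> dict[str, np.ndarray]:
        p = self.prefix
        return {
            f"{p}.Wz": self.Wz, f"{p}.Wr": self.Wr, f"{p}.Wn": self.Wn,
            f"{p}.Uz": self.Uz, f"{p}.Ur": self.Ur, f"{p}.Un": self.Un,
            f"{p}.bz": self.bz, f"{p}.br": self.br, f"{p}.bn": self.bn,
        }

    def forward(self, x: np.ndarray, need_cache: bool) -> tuple[np.ndarray, dict | None]:
        B, L, _ = x.shape
        H = self.units
        h = np.zeros((B, H))
        hs = np.empty((L + 1, B, H))
        hs[0] = h
        zs = np.empty((L, B, H))
        rs = np.empty((L, B, H))
        ns = np.empty((L, B, H))
        # hoist the input projections out of the time loop
        xz = x @ self.Wz + self.bz
        xr = x @ self.Wr + self.br
        xn = x @ self.Wn + self.bn
        for t in range(L):
            z = _sigmoid(xz[:, t] + h @ self.Uz)
            r = _sigmoid(xr[:, t] + h @ self.Ur)
            n = np.tanh(xn[:, t] + (r * h) @ self.Un)
            h = (1 - z) * n + z * h
            zs[t], rs[t], ns[t], hs[t + 1] = z, r, n, h
        out = hs[1:].transpose(1, 0, 2)  # (B, L, H)
        cache = {"x": x, "hs": hs, "zs": zs, "rs": rs, "ns": ns} if need_cache else None
        return out, cache

    def backward(self, dout: np.ndarray, cache: dict,
                 grads: dict[str, np.ndarray]) -> np.ndarray:
        x, hs, zs, rs, ns = cache["x"], cache["hs"], cache["zs"], cache["rs"], cache["ns"]
        B, L, _ = x.shape
        H = self.units
        p = self.prefix
        # the time loop carries only the recurrence; all weight gradients
        # and dx are batched afterwards from the stored pre-activations
        dzr_all = np.empty((L, B, H))
        drr_all = np.empty((L, B, H))
        dnr_all = np.empty((L, B, H))
        dh = np.zeros((B, H))
        UnT, UzT, UrT = self.Un.T, self.Uz.T, self.Ur.T
        for t in range(L - 1, -1, -1):
            g = dh + dout[:, t]
            z, r, n, h_prev = zs[t], rs[t], ns[t], hs[t]
            dnr = (g * (1 - z)) * (1 - n * n)
            drh = dnr @ UnT
            dzr = (g * (h_prev - n)) * z * (1 - z)
            drr = (drh * h_prev) * r * (1 - r)
            dh = g * z + drh * r + dzr @ UzT + drr @ UrT
            dzr_all[t], drr_all[t], dnr_all[t] = dzr, drr, dnr
        xf = x.transpose(1, 0, 2).reshape(L * B, -1)          # (L*B, I)
        hp = hs[:-1].reshape(L * B, H)                        # h_{t-1}
        rh = (rs * hs[:-1]).reshape(L * B, H)                 # r * h_{t-1}
        dzf = dzr_all.reshape(L * B, H)
        drf = drr_all.reshape(L * B, H)
        dnf = dnr_all.reshape(L * B, H)
        grads.update({
            f"{p}.Wz": xf.T @ dzf, f"{p}.Wr": xf.T @ drf, f"{p}.Wn": xf.T @ dnf,
            f"{p}.Uz": hp.T @ dzf, f"{p}.Ur": hp.T @ drf, f"{p}.Un": rh.T @ dnf,
            f"{p}.bz": dzf.sum(0), f"{p}.br": drf.sum(0), f"{p}.bn": dnf.sum(0),
        })
        dx = (dzf @ self.Wz.T + drf @ self.Wr.T + dnf @ self.Wn.T)
        return dx.reshape(L, B, -1).transpose(1, 0, 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _BiGru:
    def __init__(self, in_dim: int, units: int, prefix: str, rng: np.random.Generator):
        self.fwd = _Gru(in_dim, units, f"{prefix}.fwd", rng)
        self.bwd = _Gru(in_dim, units, f"{prefix}.bwd", rng)
        self.units = units

    def params(self) -> dict[str, np.ndarray]:
        return {**self.fwd.params(), **self.bwd.params()}

    def forward(self, x: np.ndarray, need_cache: bool) -> tuple[np.ndarray, dict | None]:
        yf, cf = self.fwd.forward(x, need_cache)
        yb, cb = self.bwd.forward(x[:, ::-1], need_cache)
        out = np.concatenate([yf, yb[:, ::-1]], axis=-1)
        return out, ({"f": cf, "b": cb} if need_cache else None)

    def backward(self, dout: np.ndarray, cache: dict,
                 grads: dict[str, np.ndarray]) -> np.ndarray:
        H = self.units
        dxf = self.fwd.backward(dout[..., :H], cache["f"], grads)
        dxb = self.bwd.backward(dout[..., H:][:, ::-1], cache["b"], grads)
        return dxf + dxb[:, ::-1]


class GruNet:
    """The full sequence labeler: features (B, L, 11) -> probabilities (B, L, K)."""

    def __init__(self, feature_dim: int = 11, num_classes: int = 12,
                 dense_units: int = 48, gru_units: tuple[int, int] = (48, 32),
                 dropout_rate: float = 0.2, seed: int = 0):
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0 <= dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.feature_dim = feature_dim
        self.num_classes = num_classes
        self.dense_units = dense_units
        self.gru_units = tuple(gru_units)
        self.dropout_rate = dropout_rate
        rng = np.random.default_rng(seed)

        lim = math.sqrt(6.0 / (feature_dim + dense_units))
        self.W0 = rng.uniform(-lim, lim, size=(feature_dim, dense_units))
        self.b0 = np.zeros(dense_units)
        self.bn0 = _BatchNorm(dense_units, "bn0")
        self.gru1 = _BiGru(dense_units, self.gru_units[0], "gru1", rng)
        self.bn1 = _BatchNorm(2 * self.gru_units[0], "bn1")
        self.gru2 = _BiGru(2 * self.gru_units[0], self.gru_units[1], "gru2", rng)
        self.bn2 = _BatchNorm(2 * self.gru_units[1], "bn2")
        lim = math.sqrt(6.0 / (2 * self.gru_units[1] + num_classes))
        self.Wout = rng.uniform(-lim, lim, size=(2 * self.gru_units[1], num_classes))
        self.bout = np.zeros(num_classes)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

    # -- parameter access ---------------------------------------------------

    def params(self) -> dict[str, np.ndarray]:
        return {
            "W0": self.W0, "b0": self.b0,
            **self.bn0.params(), **self.gru1.params(), **self.bn1.params(),
            **self.gru2.params(), **self.bn2.params(),
            "Wout": self.Wout, "bout": self.bout,
        }

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        own = self.params()
        for k, v in params.items():
            own[k][...] = v

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Trainable parameters plus batch-norm running statistics."""
        return {**self.params(), **self.bn0.state(), **self.bn1.state(), **self.bn2.state()}

    def n_params(self) -> int:
        return sum(v.size for v in self.params().values())

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False):
        """Return (probs, cache); cache is None outside training."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[-1] != self.feature_dim:
            raise ValueError(f"expected feature dim {self.feature_dim}, got {x.shape[-1]}")
        cache: dict = {"x": x}

        pre0 = x @ self.W0 + self.b0
        bn0_out, cache["bn0"] = self.bn0.forward(pre0, training)
        act0 = _elu(bn0_out)
        h0, cache["drop0"] = self._dropout(act0, training)

        g1, cache["gru1"] = self.gru1.forward(h0, training)
        bn1_out, cache["bn1"] = self.bn1.forward(g1, training)
        h1, cache["drop1"] = self._dropout(bn1_out, training)

        g2, cache["gru2"] = self.gru2.forward(h1, training)
        bn2_out, cache["bn2"] = self.bn2.forward(g2, training)
        h2, cache["drop2"] = self._dropout(bn2_out, training)

        logits = h2 @ self.Wout + self.bout
        probs = softmax(logits)
        if training:
            cache.update({"pre0": pre0, "bn0_out": bn0_out, "h0": h0,
                          "h1": h1, "h2": h2, "probs": probs})
            return probs, cache
        return probs, None

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        h2 = cache["h2"]
        grads["Wout"] = h2.reshape(-1, h2.shape[-1]).T @ dlogits.reshape(-1, dlogits.shape[-1])
        grads["bout"] = dlogits.sum(axis=(0, 1))
        dh2 = dlogits @ self.Wout.T
        dh2 = self._dropout_back(dh2, cache["drop2"])
        dg2 = self.bn2.backward(dh2, cache["bn2"], grads)
        dh1 = self.gru2.backward(dg2, cache["gru2"], grads)
        dh1 = self._dropout_back(dh1, cache["drop1"])
        dg1 = self.bn1.backward(dh1, cache["bn1"], grads)
        dh0 = self.gru1.backward(dg1, cache["gru1"], grads)
        dh0 = self._dropout_back(dh0, cache["drop0"])
        dact0 = dh0 * _elu_grad(cache["bn0_out"], _elu(cache["bn0_out"]))
        dpre0 = self.bn0.backward(dact0, cache["bn0"], grads)
        x = cache["x"]
        grads["W0"] = x.reshape(-1, x.shape[-1]).T @ dpre0.reshape(-1, dpre0.shape[-1])
        grads["b0"] = dpre0.sum(axis=(0, 1))
        return grads

    def _dropout(self, x: np.ndarray, training: bool):
        if not training or self.dropout_rate == 0:
            return x, None
        keep = 1.0 - self.dropout_rate
        mask = (self._dropout_rng.random(x.shape) < keep) / keep
        return x * mask, mask

    @staticmethod
    def _dropout_back(dy: np.ndarray, mask):
        return dy if mask is None else dy * mask

    # -- inference ----------------------------------------------------------

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Probabilities in inference mode (running BN stats, no dropout)."""
        probs, _ = self.forward(x, training=False)
        return probs
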