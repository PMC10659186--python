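"""Minimal numpy neural-network kernels: forward/backward layers + Adam.

Everything runs in float32 on the CPU. Layers cache what their backward pass
needs on ``self``; a layer instance therefore handles one forward/backward
pair at a time (fine for plain minibatch SGD loops).
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    """Base layer; subclasses fill ``params``/``grads`` with matching keys."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1-D convolution with ReLU, input (B, T, C_in)."""

    def __init__(self, c_in: int, filters: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        self.pad_lo = (kernel - 1) // 2
        self.pad_hi = kernel - 1 - self.pad_lo
        self.params["W"] = glorot_uniform(rng, (kernel, c_in, filters), kernel * c_in, filters)
        self.params["b"] = np.zeros(filters, dtype=F32)

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        B, T, _ = x.shape
        W, b = self.params["W"], self.params["b"]
        xp = np.pad(x, ((0, 0), (self.pad_lo, self.pad_hi), (0, 0)))
        out = np.broadcast_to(b, (B, T, W.shape[2])).copy()
        for k in range(self.kernel):
            out += xp[:, k : k + T, :] @ W[k]
        self.x_padded = xp
        self.pre_relu_mask = out > 0
        return np.maximum(out, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout * self.pre_relu_mask
        B, T, _ = dout.shape
        W = self.params["W"]
        xp = self.x_padded
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        flat_dout = dout.reshape(B * T, -1)
        for k in range(self.kernel):
            seg = xp[:, k : k + T, :].reshape(B * T, -1)
            dW[k] = seg.T @ flat_dout
            dxp[:, k : k + T, :] += dout @ W[k].T
        self.grads["W"] = dW
        self.grads["b"] = dout.sum(axis=(0, 1))
        return dxp[:, self.pad_lo : self.pad_lo + T, :]


class MaxPool1D(Layer):
    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        B, T, C = x.shape
        t_out = T // self.pool
        xr = x[:, : t_out * self.pool, :].reshape(B, t_out, self.pool, C)
        out = xr.max(axis=2)
        self.mask = xr == out[:, :, None, :]
        self.in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, C = self.in_shape
        t_out = T // self.pool
        dx = np.zeros(self.in_shape, dtype=dout.dtype)
        # route gradient to (all) argmax positions; ties are rare with floats
        expanded = self.mask * dout[:, :, None, :]
        dx[:, : t_out * self.pool, :] = expanded.reshape(B, t_out * self.pool, C)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (rng.random(x.shape) < keep).astype(x.dtype) / F32(keep)
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.mask is None:
            return dout
        return dout * self.mask


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class _LSTMDirection:
    """One direction of an LSTM returning the final hidden state."""

    def __init__(self, c_in: int, units: int, rng: np.random.Generator) -> None:
        H = units
        self.units = H
        self.Wx = glorot_uniform(rng, (c_in, 4 * H), c_in, 4 * H)
        self.Wh = glorot_uniform(rng, (H, 4 * H), H, 4 * H)
        self.b = np.zeros(4 * H, dtype=F32)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self._buf_shape: tuple[int, int] | None = None

    def _ensure_buffers(self, B: int, T: int) -> None:
        # reallocating tens of MB per minibatch is dominated by page-fault
        # cost on some kernels; cache capacity-sized activations and hand
        # out views so alternating batch sizes do not thrash the allocator
        if self._buf_shape is not None and self._buf_shape[1] == T and self._buf_shape[0] >= B:
            cap = self._buf_shape[0]
        else:
            cap = max(B, self._buf_shape[0] if self._buf_shape else 0)
            H = self.units
            self._gates_buf = np.empty((T, cap, 4 * H), dtype=F32)
            self._cs_buf = np.empty((T + 1, cap, H), dtype=F32)
            self._hs_buf = np.empty((T + 1, cap, H), dtype=F32)
            self._dz_buf = np.empty((T, cap, 4 * H), dtype=F32)
            self._buf_shape = (cap, T)
        self.gates = self._gates_buf[:, :B]
        self.cs = self._cs_buf[:, :B]
        self.hs = self._hs_buf[:, :B]
        self._dz_all = self._dz_buf[:, :B]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.units
        self._ensure_buffers(B, T)
        xproj = x.reshape(B * T, -1) @ self.Wx
        xproj = xproj.reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        self.x = x
        self.cs[0] = c
        self.hs[0] = h
        for t in range(T):
            z = xproj[:, t, :] + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            self.gates[t, :, :H] = i
            self.gates[t, :, H : 2 * H] = f
            self.gates[t, :, 2 * H : 3 * H] = g
            self.gates[t, :, 3 * H :] = o
            self.cs[t + 1] = c
            self.hs[t + 1] = h
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        B, T, _ = self.x.shape
        H = self.units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.empty_like(self.x)
        dh = dh_last.astype(F32)
        dc = np.zeros((B, H), dtype=F32)
        dz_all = self._dz_all
        for t in range(T - 1, -1, -1):
            i = self.gates[t, :, :H]
            f = self.gates[t, :, H : 2 * H]
            g = self.gates[t, :, 2 * H : 3 * H]
            o = self.gates[t, :, 3 * H :]
            c = self.cs[t + 1]
            c_prev = self.cs[t]
            tc = np.tanh(c)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = dz_all[t]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            dWh += self.hs[t].T @ dz
            dh = dz @ self.Wh.T
            dc = dc * f
        # input-side gradients in two big matmuls
        dz_flat = dz_all.transpose(1, 0, 2).reshape(B * T, 4 * H)
        x_flat = self.x.reshape(B * T, -1)
        dWx[:] = x_flat.T @ dz_flat
        db[:] = dz_flat.sum(axis=0)
        dx[:] = (dz_flat @ self.Wx.T).reshape(B, T, -1)
        self.dWx, self.dWh, self.db = dWx, dWh, db
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM over the feature axis, concatenated final states."""

    def __init__(self, c_in: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.fwd = _LSTMDirection(c_in, units, rng)
        self.bwd = _LSTMDirection(c_in, units, rng)
        for tag, d in (("f", self.fwd), ("b", self.bwd)):
            self.params[f"Wx_{tag}"] = d.Wx
            self.params[f"Wh_{tag}"] = d.Wh
            self.params[f"b_{tag}"] = d.b

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        h_f = self.fwd.forward(x)
        h_b = self.bwd.forward(x[:, ::-1, :])
        return np.concatenate([h_f, h_b], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.fwd.units
        dx_f = self.fwd.backward(dout[:, :H])
        dx_b = self.bwd.backward(dout[:, H:])[:, ::-1, :]
        for tag, d in (("f", self.fwd), ("b", self.bwd)):
            self.grads[f"Wx_{tag}"] = d.dWx
            self.grads[f"Wh_{tag}"] = d.dWh
            self.grads[f"b_{tag}"] = d.db
        return dx_f + dx_b


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, relu: bool) -> None:
        super().__init__()
        self.relu = relu
        self.params["W"] = glorot_uniform(rng, (c_in, c_out), c_in, c_out)
        self.params["b"] = np.zeros(c_out, dtype=F32)

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        self.x = x
        out = x @ self.params["W"] + self.params["b"]
        if self.relu:
            self.mask = out > 0
            out = np.maximum(out, 0.0)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * self.mask
        self.grads["W"] = self.x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(
    probs: np.ndarray, labels: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    n = len(labels)
    eps = 1e-12
    logp = -np.log(probs[np.arange(n), labels] + eps)
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    if sample_weight is not None:
        logp = logp * sample_weight
        dlogits *= sample_weight[:, None]
    loss = float(np.mean(logp))
    return loss, (dlogits / n).astype(F32)


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lyr.params.items()} for lyr in layers]
        self.v = [{k: np.zeros_like(v) for k, v in lyr.params.items()} for lyr in layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for lyr, m, v in zip(self.layers, self.m, self.v):
            for key, param in lyr.params.items():
                g = lyr.grads[key]
                m[key] = b1 * m[key] + (1.0 - b1) * g
                v[key] = b2 * v[key] + (1.0 - b2) * g * g
                update = self.lr * (m[key] / corr1) / (np.sqrt(v[key] / corr2) + self.eps)
                param -= update.astype(param.dtype)
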