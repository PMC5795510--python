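"""Gated recurrent layers (GRU, LSTM) with backpropagation through time.

Standard formulations:

GRU (update gate z, reset gate r, candidate n)::

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
    n_t = tanh(x_t Wn + r_t * (h_{t-1} Un) + bn)
    h_t = (1 - z_t) * h_{t-1} + z_t * n_t

LSTM (input i, forget f, cell candidate g, output o; forget bias init 1)::

    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

Input projections for all timesteps are computed as one matrix product;
only the hidden-to-hidden recurrences loop over time.  Both layers return
the full hidden sequence ``(N, T, H)``; the classification/regression heads
read its last step.
"""

from __future__ import annotations

import numpy as np

from imu2seg.networks.layers import F32, Layer

__all__ = ["GRULayer", "LSTMLayer", "recurrent_forward"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return (q * np.sign(np.diag(r))).astype(F32)


class GRULayer(Layer):
    no_decay = ("b",)

    def __init__(self, c_in: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        H = units
        scale = np.sqrt(1.0 / c_in)
        Wh = np.concatenate([_orthogonal(rng, H) for _ in range(3)], axis=1)
        self.params = {
            "Wx": rng.normal(0.0, scale, size=(c_in, 3 * H)).astype(F32),
            "Wh": Wh,
            "b": np.zeros(3 * H, dtype=F32),
        }
        self.units = H
        self._cache = None

    def forward(self, x, training=False, rng=None, **kw):
        n, t, _ = x.shape
        H = self.units
        dt = x.dtype
        Wh = self.params["Wh"]
        xp = x @ self.params["Wx"] + self.params["b"]
        h = np.zeros((n, H), dtype=dt)
        Hs = np.empty((n, t, H), dtype=dt)
        zs, rs, ns, ms, hp = (np.empty((n, t, H), dtype=dt) for _ in range(5))
        for i in range(t):
            hp[:, i] = h
            rec = h @ Wh                      # (N, 3H)
            z = _sigmoid(xp[:, i, :H] + rec[:, :H])
            r = _sigmoid(xp[:, i, H:2 * H] + rec[:, H:2 * H])
            m = rec[:, 2 * H:]
            nn = np.tanh(xp[:, i, 2 * H:] + r * m)
            h = (1.0 - z) * h + z * nn
            zs[:, i], rs[:, i], ns[:, i], ms[:, i] = z, r, nn, m
            Hs[:, i] = h
        self._cache = (x, xp.shape, zs, rs, ns, ms, hp)
        return Hs

    def backward(self, dH):
        x, xp_shape, zs, rs, ns, ms, hp = self._cache
        n, t, H = dH.shape
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dt = dH.dtype
        dxp = np.zeros(xp_shape, dtype=dt)
        dWh = np.zeros_like(Wh, dtype=dt)
        dh = np.zeros((n, H), dtype=dt)
        for i in range(t - 1, -1, -1):
            dh_tot = dH[:, i] + dh
            z, r, nn, m, h_prev = zs[:, i], rs[:, i], ns[:, i], ms[:, i], hp[:, i]
            dz = dh_tot * (nn - h_prev)
            dn = dh_tot * z
            dh = dh_tot * (1.0 - z)
            dan = dn * (1.0 - nn * nn)
            dr = dan * m
            dm = dan * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            dxp[:, i, :H] = daz
            dxp[:, i, H:2 * H] = dar
            dxp[:, i, 2 * H:] = dan
            da = np.concatenate([daz, dar, dm], axis=1)
            dWh += h_prev.T @ da
            dh += da @ Wh.T
        dxp2 = dxp.reshape(-1, 3 * H)
        self.grads["Wx"] = x.reshape(-1, x.shape[2]).T @ dxp2
        self.grads["Wh"] = dWh
        self.grads["b"] = dxp2.sum(axis=0)
        return dxp @ Wx.T


class LSTMLayer(Layer):
    no_decay = ("b",)

    def __init__(self, c_in: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        H = units
        scale = np.sqrt(1.0 / c_in)
        Wh = np.concatenate([_orthogonal(rng, H) for _ in range(4)], axis=1)
        b = np.zeros(4 * H, dtype=F32)
        b[H:2 * H] = 1.0  # forget-gate bias
        self.params = {
            "Wx": rng.normal(0.0, scale, size=(c_in, 4 * H)).astype(F32),
            "Wh": Wh,
            "b": b,
        }
        self.units = H
        self._cache = None

    def forward(self, x, training=False, rng=None, **kw):
        n, t, _ = x.shape
        H = self.units
        Wh = self.params["Wh"]
        xp = x @ self.params["Wx"] + self.params["b"]
        dt = x.dtype
        h = np.zeros((n, H), dtype=dt)
        c = np.zeros((n, H), dtype=dt)
        Hs = np.empty((n, t, H), dtype=dt)
        gates = np.empty((n, t, 4 * H), dtype=dt)
        cp = np.empty((n, t, H), dtype=dt)
        hp = np.empty((n, t, H), dtype=dt)
        tc = np.empty((n, t, H), dtype=dt)
        for idx in range(t):
            hp[:, idx], cp[:, idx] = h, c
            a = xp[:, idx] + h @ Wh
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c = f * c + i * g
            tch = np.tanh(c)
            h = o * tch
            gates[:, idx] = np.concatenate([i, f, g, o], axis=1)
            tc[:, idx] = tch
            Hs[:, idx] = h
        self._cache = (x, xp.shape, gates, cp, hp, tc)
        return Hs

    def backward(self, dH):
        x, xp_shape, gates, cp, hp, tc = self._cache
        n, t, H = dH.shape
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dt = dH.dtype
        dxp = np.zeros(xp_shape, dtype=dt)
        dWh = np.zeros_like(Wh, dtype=dt)
        dh = np.zeros((n, H), dtype=dt)
        dc = np.zeros((n, H), dtype=dt)
        for idx in range(t - 1, -1, -1):
            i = gates[:, idx, :H]
            f = gates[:, idx, H:2 * H]
            g = gates[:, idx, 2 * H:3 * H]
            o = gates[:, idx, 3 * H:]
            tch = tc[:, idx]
            dh_tot = dH[:, idx] + dh
            do = dh_tot * tch
            dc = dc + dh_tot * o * (1.0 - tch * tch)
            di = dc * g
            df = dc * cp[:, idx]
            dg = dc * i
            da = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            dxp[:, idx] = da
            dWh += hp[:, idx].T @ da
            dh = da @ Wh.T
            dc = dc * f
        dxp2 = dxp.reshape(-1, 4 * H)
        self.grads["Wx"] = x.reshape(-1, x.shape[2]).T @ dxp2
        self.grads["Wh"] = dWh
        self.grads["b"] = dxp2.sum(axis=0)
        return dxp @ Wx.T


def recurrent_forward(x: np.ndarray, kind: str, weights: dict) -> np.ndarray:
    """Run a single recurrent layer from explicit weights.

    ``weights`` holds ``Wx`` (C, G*H), ``Wh`` (H, G*H) and ``b`` (G*H) with
    G = 3 for ``kind='gru'`` and G = 4 for ``kind='lstm'``.  Returns the
    hidden sequence (N, T, H).  Useful for step-by-step oracle checks.
    """
    kind = kind.lower()
    gates = {"gru": 3, "lstm": 4}[kind]
    H = weights["Wh"].shape[0]
    cls = GRULayer if kind == "gru" else LSTMLayer
    layer = cls.__new__(cls)
    Layer.__init__(layer)
    layer.params = {k: np.asarray(v) for k, v in weights.items()}
    if layer.params["Wx"].shape[1] != gates * H:
        raise ValueError("weight shapes inconsistent with the cell type")
    layer.units = H
    layer._cache = None
    return layer.forward(np.asarray(x))
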