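"""Multi-layer LSTM with step-level forward/backward.

The step API (``init_state`` / ``step`` / ``step_backward``) exists so that
callers can unroll the recurrence themselves — the learned-optimizer network
carries state across update iterations and backpropagates through a stored
unroll.  ``forward_seq`` / ``backward_seq`` wrap the common whole-sequence
case used by the motion predictor.

Gate order inside the packed weight matrices is (input, forget, cell, output).
Forget-gate biases are initialised to 1.
"""
from __future__ import annotations

import numpy as np

from .layers import Layer


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    def __init__(self, input_size: int, hidden_size: int, num_layers: int, rng,
                 dtype=np.float32):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.dtype = dtype
        h = hidden_size
        bound = 1.0 / np.sqrt(h)
        arrays = {}
        for l in range(num_layers):
            d = input_size if l == 0 else h
            arrays[f"Wx{l}"] = rng.uniform(-bound, bound, (d, 4 * h)).astype(dtype)
            arrays[f"Wh{l}"] = rng.uniform(-bound, bound, (h, 4 * h)).astype(dtype)
            b = np.zeros(4 * h, dtype=dtype)
            b[h : 2 * h] = 1.0  # forget gate
            arrays[f"b{l}"] = b
        self._register(**arrays)

    def init_state(self, n: int):
        h = self.hidden_size
        return [(np.zeros((n, h), dtype=self.dtype), np.zeros((n, h), dtype=self.dtype))
                for _ in range(self.num_layers)]

    def step(self, x: np.ndarray, state):
        """One time step.  x: (N, input_size).  Returns (h_top, new_state, cache)."""
        hs = self.hidden_size
        new_state, caches = [], []
        inp = x
        for l in range(self.num_layers):
            h_prev, c_prev = state[l]
            z = inp @ self.params[f"Wx{l}"] + h_prev @ self.params[f"Wh{l}"] + self.params[f"b{l}"]
            i = _sigmoid(z[:, :hs])
            f = _sigmoid(z[:, hs : 2 * hs])
            g = np.tanh(z[:, 2 * hs : 3 * hs])
            o = _sigmoid(z[:, 3 * hs :])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            hout = o * tc
            caches.append((inp, h_prev, c_prev, i, f, g, o, tc))
            new_state.append((hout, c))
            inp = hout
        return inp, new_state, caches

    def step_backward(self, dh_top, dstate, caches):
        """Backward through one step.

        dh_top: gradient w.r.t. the top layer's output at this step.
        dstate: list of (dh, dc) flowing back from the next step (may be None).
        Returns (dx, dstate_prev); parameter gradients are accumulated.
        """
        hs = self.hidden_size
        if dstate is None:
            dstate = [(None, None)] * self.num_layers
        dstate_prev = [None] * self.num_layers
        d_from_above = dh_top
        for l in reversed(range(self.num_layers)):
            inp, h_prev, c_prev, i, f, g, o, tc = caches[l]
            dh_next, dc_next = dstate[l]
            dh = d_from_above if dh_next is None else d_from_above + dh_next
            dc = dh * o * (1.0 - tc**2)
            if dc_next is not None:
                dc = dc + dc_next
            do = dh * tc
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.grads[f"Wx{l}"] += inp.T @ dz
            self.grads[f"Wh{l}"] += h_prev.T @ dz
            self.grads[f"b{l}"] += dz.sum(axis=0)
            dstate_prev[l] = (dz @ self.params[f"Wh{l}"].T, dc * f)
            d_from_above = dz @ self.params[f"Wx{l}"].T
        return d_from_above, dstate_prev

    # -- whole-sequence convenience -------------------------------------
    def forward_seq(self, x: np.ndarray):
        """x: (N, T, input_size) → outputs (N, T, hidden) of the top layer."""
        n, t, _ = x.shape
        state = self.init_state(n)
        outs = np.empty((n, t, self.hidden_size), dtype=self.dtype)
        self._seq_caches = []
        for k in range(t):
            h_top, state, caches = self.step(x[:, k, :], state)
            outs[:, k, :] = h_top
            self._seq_caches.append(caches)
        return outs

    def backward_seq(self, douts: np.ndarray):
        """douts: (N, T, hidden) gradients w.r.t. every top output."""
        n, t, _ = douts.shape
        dx = np.empty((n, t, self.input_size), dtype=self.dtype)
        dstate = None
        for k in reversed(range(t)):
            dxk, dstate = self.step_backward(douts[:, k, :], dstate, self._seq_caches[k])
            dx[:, k, :] = dxk
        return dx
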