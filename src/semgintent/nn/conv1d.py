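"""FFT-based 1-D convolution layers for long temporal kernels.

The Single-Kernel stages use kernels of length 105/55/30 on 96–200-sample
windows; direct im2col would re-read the input once per tap, so all three
passes (forward, gradient w.r.t. input, gradient w.r.t. weight) are computed
in the frequency domain: a real FFT along time, one batched complex matrix
product per frequency bin to contract the channel axis, and an inverse FFT.
Because the time axis is zero-padded to at least the full linear
convolution length, the circular products equal the linear ones.

Layouts match the 2-D layers: activations (N, C, H, T) — H is the untouched
muscle axis — and weights (C_out, C_in, kw) / (C_in, C_out, kw).
"""
from __future__ import annotations

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from .layers import Layer, kaiming_uniform


def _freq_contract(af: np.ndarray, bf: np.ndarray) -> np.ndarray:
    """Per-frequency GEMM: (N, A, H, F) × (A, B, F) → (N, B, H, F)."""
    n, a, h, f = af.shape
    ab = np.ascontiguousarray(af.transpose(3, 0, 2, 1)).reshape(f, n * h, a)
    bb = np.ascontiguousarray(bf.transpose(2, 0, 1))  # (F, A, B)
    out = ab @ bb  # (F, N*H, B)
    return out.reshape(f, n, h, -1).transpose(1, 3, 2, 0)


def _freq_weight_grad(xf: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Per-frequency GEMM over the batch: (N, A, H, F) × (N, B, H, F) → (A, B, F)."""
    n, a, h, f = xf.shape
    xb = np.ascontiguousarray(xf.transpose(3, 1, 0, 2)).reshape(f, a, n * h)
    db = np.ascontiguousarray(df.transpose(3, 0, 2, 1)).reshape(f, n * h, -1)
    return (xb @ db).transpose(1, 2, 0)  # (A, B, F)


class Conv1D(Layer):
    """Valid temporal cross-correlation: (N, C_in, H, T) → (N, C_out, H, T−kw+1)."""

    def __init__(self, in_ch, out_ch, kw, rng, dtype=np.float32):
        super().__init__()
        self.kw = kw
        self._register(
            weight=kaiming_uniform(rng, (out_ch, in_ch, kw), in_ch * kw, dtype),
            bias=np.zeros(out_ch, dtype=dtype),
        )

    def forward(self, x):
        t = x.shape[-1]
        length = next_fast_len(t)
        xf = rfft(x, length, axis=-1)
        wf = rfft(self.params["weight"], length, axis=-1)  # (O, C, F)
        # correlation: multiply by the conjugate spectrum
        out = irfft(_freq_contract(xf, np.conj(wf).transpose(1, 0, 2)), length, axis=-1)
        out = out[..., : t - self.kw + 1]
        self._cache = (xf, t, length)
        return np.ascontiguousarray(out) + self.params["bias"][None, :, None, None]

    def backward(self, dout):
        xf, t, length = self._cache
        w = self.params["weight"]
        df = rfft(dout, length, axis=-1)
        # dx: full convolution of dout with w (contract the output channels)
        dx = irfft(_freq_contract(df, rfft(w, length, axis=-1)), length, axis=-1)[..., :t]
        # dw[o, c, j] = Σ x[c, t+j] dout[o, t]  → corr(x, dout)
        dwf = _freq_weight_grad(xf, np.conj(df))
        dw = irfft(dwf, length, axis=-1)[..., : self.kw]  # (C, O, kw)
        self.grads["weight"] += dw.transpose(1, 0, 2)
        self.grads["bias"] += dout.sum(axis=(0, 2, 3))
        return np.ascontiguousarray(dx)


class ConvTranspose1D(Layer):
    """Temporal transposed convolution: (N, C_in, H, T) → (N, C_out, H, T+kw−1)."""

    def __init__(self, in_ch, out_ch, kw, rng, dtype=np.float32):
        super().__init__()
        self.kw = kw
        self._register(
            weight=kaiming_uniform(rng, (in_ch, out_ch, kw), in_ch * kw, dtype),
            bias=np.zeros(out_ch, dtype=dtype),
        )

    def forward(self, x):
        t = x.shape[-1]
        t_out = t + self.kw - 1
        length = next_fast_len(t_out)
        xf = rfft(x, length, axis=-1)
        wf = rfft(self.params["weight"], length, axis=-1)  # (C_in, C_out, F)
        out = irfft(_freq_contract(xf, wf), length, axis=-1)[..., :t_out]
        self._cache = (xf, t, length)
        return np.ascontiguousarray(out) + self.params["bias"][None, :, None, None]

    def backward(self, dout):
        xf, t, length = self._cache
        w = self.params["weight"]
        df = rfft(dout, length, axis=-1)
        wf = rfft(w, length, axis=-1)
        # dx: valid correlation of dout with w (contract output channels)
        dx = irfft(_freq_contract(df, np.conj(wf).transpose(1, 0, 2)), length, axis=-1)[..., :t]
        # dw[c, o, j] = Σ x[c, t] dout[o, t+j] → corr(dout, x)
        dwf = _freq_weight_grad(np.conj(xf), df)
        self.grads["weight"] += irfft(dwf, length, axis=-1)[..., : self.kw]
        self.grads["bias"] += dout.sum(axis=(0, 2, 3))
        return np.ascontiguousarray(dx)
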