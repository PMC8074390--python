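"""Low-level array operations for the neural layers.

All convolutions are "valid" (padding 0) with stride 1, which is the only
configuration the networks in this package use.  Batches are laid out as
``(N, C, H, W)``.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Extract sliding kernel patches.

    Parameters
    ----------
    x : (N, C, H, W)
    kh, kw : kernel height and width.

    Returns
    -------
    (N, H_out, W_out, C * kh * kw) view-backed array with
    ``H_out = H - kh + 1`` and ``W_out = W - kw + 1``.
    """
    # windows: (N, C, H_out, W_out, kh, kw)
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))
    n, c, ho, wo = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho, wo, c * kh * kw)


def col2im(dcols: np.ndarray, c: int, h: int, w: int, kh: int, kw: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back onto an image.

    dcols : (N, H_out, W_out, C * kh * kw)
    Returns (N, C, H, W).
    """
    n, ho, wo = dcols.shape[:3]
    d = dcols.reshape(n, ho, wo, c, kh, kw)
    out = np.zeros((n, c, h, w), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + ho, j : j + wo] += d[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return out


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """Valid cross-correlation.  weight: (C_out, C_in, kh, kw).

    Returns (out, cols) where cols is the im2col cache for the backward pass.
    """
    c_out, c_in, kh, kw = weight.shape
    cols = im2col(x, kh, kw)  # (N, Ho, Wo, C_in*kh*kw)
    n, ho, wo, _ = cols.shape
    out = cols.reshape(-1, c_in * kh * kw) @ weight.reshape(c_out, -1).T
    out = out.reshape(n, ho, wo, c_out).transpose(0, 3, 1, 2)
    if bias is not None:
        out += bias[None, :, None, None]
    return out, cols


def conv2d_backward(dout: np.ndarray, cols: np.ndarray, weight: np.ndarray, x_shape):
    """Gradients of :func:`conv2d` w.r.t. input, weight and bias."""
    c_out, c_in, kh, kw = weight.shape
    n, _, ho, wo = dout.shape
    dmat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)  # (N*Ho*Wo, C_out)
    dw = (dmat.T @ cols.reshape(-1, c_in * kh * kw)).reshape(weight.shape)
    db = dmat.sum(axis=0)
    dcols = (dmat @ weight.reshape(c_out, -1)).reshape(n, ho, wo, c_in * kh * kw)
    dx = col2im(dcols, c_in, x_shape[2], x_shape[3], kh, kw)
    return dx, dw, db


def conv_transpose2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """Transposed valid convolution (the adjoint of conv2d's forward map).

    weight: (C_in, C_out, kh, kw); output spatial size grows by k - 1.
    """
    c_in, c_out, kh, kw = weight.shape
    n, _, h, w = x.shape
    flat = x.transpose(0, 2, 3, 1).reshape(-1, c_in)  # (N*H*W, C_in)
    contrib = flat @ weight.reshape(c_in, -1)  # (N*H*W, C_out*kh*kw)
    dcols = contrib.reshape(n, h, w, c_out * kh * kw)
    out = col2im(dcols, c_out, h + kh - 1, w + kw - 1, kh, kw)
    if bias is not None:
        out += bias[None, :, None, None]
    return out, flat


def conv_transpose2d_backward(dout: np.ndarray, x_flat: np.ndarray, weight: np.ndarray, x_shape):
    """Gradients of :func:`conv_transpose2d`."""
    c_in, c_out, kh, kw = weight.shape
    n, _, h, w = x_shape
    cols = im2col(dout, kh, kw).reshape(-1, c_out * kh * kw)  # (N*H*W, C_out*kh*kw)
    dw = (x_flat.T @ cols).reshape(weight.shape)
    db = dout.sum(axis=(0, 2, 3))
    dx = (cols @ weight.reshape(c_in, -1).T).reshape(n, h, w, c_in).transpose(0, 3, 1, 2)
    return dx, dw, db
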