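"""Muscle-synergy estimation and synergy-guided channel rearrangement.

Muscle synergies model multi-muscle activation as a low-rank non-negative
factorization V ≈ W·H, where V (samples × muscles) holds rectified,
low-pass-filtered sEMG envelopes, W the synergy activation time-courses and
H the per-muscle synergy weights.  The factorization drives a channel
re-ordering inside the autoencoder: each of the five feature-map groups gets
the muscle axis permuted so that one synergy's cooperating muscles sit
adjacently, within reach of a single 4×4 kernel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import linear_sum_assignment

DEFAULT_R = 5
_EPS = 1e-12


@dataclass
class SynergyModel:
    """NMF factors of an envelope matrix: V (n×m) ≈ W (n×r) · H (r×m)."""

    W: np.ndarray
    H: np.ndarray
    recon_error: float  # Frobenius residual ‖V − WH‖_F
    history: list = None  # per-iteration Frobenius error of the kept run

    @property
    def r(self) -> int:
        return self.H.shape[0]


@dataclass
class ChannelOrders:
    """One channel permutation per feature-map group (5 groups of 16 maps)."""

    perms: np.ndarray  # (n_groups, n_channels) integer permutations

    def __post_init__(self):
        for p in self.perms:
            if sorted(p) != list(range(len(p))):
                raise ValueError("each group order must be a permutation of the channels")

    @property
    def n_groups(self) -> int:
        return self.perms.shape[0]

    def inverse(self) -> "ChannelOrders":
        inv = np.empty_like(self.perms)
        for g, p in enumerate(self.perms):
            inv[g, p] = np.arange(len(p))
        return ChannelOrders(inv)


def envelope(semg: np.ndarray, rate: float, cutoff: float = 4.0) -> np.ndarray:
    """Rectify and low-pass filter (4 Hz Butterworth) raw sEMG.

    NMF requires a non-negative input; the linear envelope is the standard
    non-negative activation estimate.  semg: (channels, samples).
    """
    sos = signal.butter(4, cutoff, btype="low", fs=rate, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(semg), axis=-1)
    return np.clip(env, 0.0, None)


def _mu_nmf(v: np.ndarray, r: int, rng: np.random.Generator, tol: float,
            max_iter: int) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One multiplicative-update (Frobenius) NMF run from a random start."""
    n, m = v.shape
    scale = np.sqrt(v.mean() / r) + _EPS
    w = scale * rng.random((n, r)) + _EPS
    h = scale * rng.random((r, m)) + _EPS
    history = [float(np.linalg.norm(v - w @ h))]
    for _ in range(max_iter):
        h *= (w.T @ v) / (w.T @ w @ h + _EPS)
        w *= (v @ h.T) / (w @ (h @ h.T) + _EPS)
        err = float(np.linalg.norm(v - w @ h))
        stop = history[-1] - err <= tol * max(history[-1], _EPS)
        history.append(err)
        if stop:
            break
    return w, h, history


def fit_nmf(v: np.ndarray, r: int = DEFAULT_R, *, seed: int = 0, tol: float = 1e-6,
            max_iter: int = 500, n_restarts: int = 5) -> SynergyModel:
    """Multiplicative-update NMF of a non-negative matrix, best of restarts.

    The Frobenius objective is non-increasing under the updates; iteration
    stops when the relative decrease falls below ``tol`` or at ``max_iter``.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("NMF input must be non-negative")
    if r > min(v.shape):
        raise ValueError("rank r exceeds matrix dimensions")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        w, h, hist = _mu_nmf(v, r, rng, tol, max_iter)
        if best is None or hist[-1] < best[2][-1]:
            best = (w, h, hist)
    return SynergyModel(W=best[0], H=best[1], recon_error=best[2][-1], history=best[2])


def derive_channel_orders(h: np.ndarray) -> ChannelOrders:
    """Per-synergy channel permutation: descending synergy weight.

    Group g's permutation lists the channel indices sorted by descending
    H[g, :], ties broken by original index, so each synergy's dominant
    (cooperating) muscles become adjacent leading rows.
    """
    h = np.asarray(h)
    if np.any(h < 0):
        raise ValueError("synergy weights must be non-negative")
    # stable sort on -h keeps original index order within ties
    perms = np.argsort(-h, axis=1, kind="stable")
    return ChannelOrders(perms)


def rearrange(feature_maps: np.ndarray, orders: ChannelOrders) -> np.ndarray:
    """Permute the channel (height) axis of grouped feature maps.

    feature_maps: (..., n_maps, n_channels, time); maps are split into
    ``orders.n_groups`` equal groups and group g's channel axis is reordered
    by ``orders.perms[g]``.  Values are only moved, never altered.
    """
    n_maps = feature_maps.shape[-3]
    g = orders.n_groups
    if n_maps % g:
        raise ValueError(f"{n_maps} maps not divisible into {g} groups")
    per = n_maps // g
    out = np.empty_like(feature_maps)
    for k in range(g):
        sl = slice(k * per, (k + 1) * per)
        out[..., sl, :, :] = feature_maps[..., sl, orders.perms[k], :]
    return out


def synergy_similarity(h_a: np.ndarray, h_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cosine similarity between best-matched synergy weight vectors.

    Rows of ``h_b`` are matched one-to-one to rows of ``h_a`` by maximising
    total cosine similarity (Hungarian assignment).  Returns the full r×r
    cosine matrix (rows of a vs columns re-ordered b) and the matched
    diagonal similarities.  Zero rows have similarity 0 by convention.
    """
    h_a = np.asarray(h_a, dtype=float)
    h_b = np.asarray(h_b, dtype=float)
    if h_a.shape != h_b.shape:
        raise ValueError("synergy weight matrices must have identical shapes")
    na = np.linalg.norm(h_a, axis=1)
    nb = np.linalg.norm(h_b, axis=1)
    cos = (h_a @ h_b.T) / (np.outer(na, nb) + _EPS)
    cos[na == 0, :] = 0.0
    cos[:, nb == 0] = 0.0
    rows, cols = linear_sum_assignment(-cos)
    matched = cos[rows, cols]
    return cos[:, cols], matched
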