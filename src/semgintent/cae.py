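"""Convolutional autoencoder for sEMG feature compression.

Encoder (five valid, stride-1 convolutions):

    1×9×200 ─1×105→ 20@9×96 ─1×55→ 40@9×42 ─1×30→ 80@9×13   (Single-Kernel)
            ─[synergy rearrange]─ 4×4 → 40@6×10 ─4×4→ 40@3×7  (Multi-Kernels)

The Single-Kernel stage compresses each muscle's time axis independently;
the synergy-derived permutation then re-orders the muscle axis per group of
16 feature maps before the two 4×4 layers mix muscles and time.  The 40@3×7
output is the compressed feature (reshaped time-major to 7×120 for the
predictor).  The decoder mirrors the chain with transposed convolutions and
its own parameters, undoing the rearrangement so the 9×200 reconstruction is
in original channel order.  ReLU follows every layer except the feature
output and the reconstruction output, which stay linear because raw sEMG is
signed.

Reconstruction fidelity is reported as total variance accounted for,
tVAF = 1 − ‖EMG − EMG_rec‖² / ‖EMG‖², per image.
"""
from __future__ import annotations

import numpy as np

from .nn import SGD, Adam, Conv2D, ConvTranspose2D, ReLU, mse_loss
from .nn.conv1d import Conv1D, ConvTranspose1D
from .synergy import ChannelOrders, rearrange

#: (kernel_h, kernel_w, out_channels) of the encoder stack, in order.
ENCODER_STACK = [(1, 105, 20), (1, 55, 40), (1, 30, 80), (4, 4, 40), (4, 4, 40)]


def identity_orders(n_groups: int = 5, n_channels: int = 9) -> ChannelOrders:
    return ChannelOrders(np.tile(np.arange(n_channels), (n_groups, 1)))


class Encoder:
    """Single-Kernel + Multi-Kernels convolutional encoder."""

    def __init__(self, orders: ChannelOrders, rng, dtype=np.float32):
        self.orders = orders
        self.convs = []
        in_ch = 1
        for kh, kw, out_ch in ENCODER_STACK:
            if kh == 1:  # temporal-only kernel: FFT implementation
                self.convs.append(Conv1D(in_ch, out_ch, kw, rng, dtype))
            else:
                self.convs.append(Conv2D(in_ch, out_ch, kh, kw, rng, dtype))
            in_ch = out_ch
        self.relus = [ReLU() for _ in range(4)]  # feature output stays linear

    @property
    def layers(self):
        return self.convs

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, 9, 200) → feature maps (N, 40, 3, 7)."""
        h = x
        for i in range(3):  # Single-Kernel part
            h = self.relus[i].forward(self.convs[i].forward(h))
        h = rearrange(h, self.orders)
        h = self.relus[3].forward(self.convs[3].forward(h))
        return self.convs[4].forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.convs[4].backward(dout)
        d = self.convs[3].backward(self.relus[3].backward(d))
        d = rearrange(d, self.orders.inverse())
        for i in reversed(range(3)):
            d = self.convs[i].backward(self.relus[i].backward(d))
        return d


class Decoder:
    """Mirror of the encoder with transposed convolutions, own parameters."""

    def __init__(self, orders: ChannelOrders, rng, dtype=np.float32):
        self.orders = orders
        self.convs = []
        stack = list(reversed(ENCODER_STACK))  # kernel sizes mirrored
        in_ch = 40
        out_chain = [40, 80, 40, 20, 1]
        for (kh, kw, _), out_ch in zip(stack, out_chain):
            if kh == 1:
                self.convs.append(ConvTranspose1D(in_ch, out_ch, kw, rng, dtype))
            else:
                self.convs.append(ConvTranspose2D(in_ch, out_ch, kh, kw, rng, dtype))
            in_ch = out_ch
        self.relus = [ReLU() for _ in range(4)]

    @property
    def layers(self):
        return self.convs

    def forward(self, feat: np.ndarray) -> np.ndarray:
        """feat: (N, 40, 3, 7) → reconstruction (N, 1, 9, 200)."""
        h = self.relus[0].forward(self.convs[0].forward(feat))  # 40@6×10
        h = self.relus[1].forward(self.convs[1].forward(h))  # 80@9×13
        h = rearrange(h, self.orders.inverse())  # back to anatomical order
        h = self.relus[2].forward(self.convs[2].forward(h))  # 40@9×42
        h = self.relus[3].forward(self.convs[3].forward(h))  # 20@9×96
        return self.convs[4].forward(h)  # 1@9×200, linear

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.convs[4].backward(dout)
        d = self.convs[3].backward(self.relus[3].backward(d))
        d = self.convs[2].backward(self.relus[2].backward(d))
        d = rearrange(d, self.orders)
        d = self.convs[1].backward(self.relus[1].backward(d))
        return self.convs[0].backward(self.relus[0].backward(d))


class CAE:
    """Autoencoder pairing an :class:`Encoder` and :class:`Decoder`."""

    def __init__(self, orders: ChannelOrders | None = None, seed: int = 0,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.orders = orders if orders is not None else identity_orders()
        self.encoder = Encoder(self.orders, rng, dtype)
        self.decoder = Decoder(self.orders, rng, dtype)
        self.trained = False  # set by train_cae; later stages depend on it
        #: images are divided by this scale (training-set RMS) before the
        #: encoder and the reconstruction is multiplied back, so training is
        #: well-conditioned regardless of the physical units of the sEMG.
        self.input_scale = 1.0

    @property
    def layers(self):
        return self.encoder.layers + self.decoder.layers

    @property
    def adaptable_conv(self) -> Conv2D:
        """Encoder layer 4 (80→40, 4×4), the online-adapted layer."""
        return self.encoder.convs[3]

    def encode(self, images: np.ndarray) -> np.ndarray:
        """images: (N, 9, 200) → features (N, 40, 3, 7)."""
        x = (images / self.input_scale).astype(np.float32)
        return self.encoder.forward(x[:, None, :, :])

    def decode(self, feat: np.ndarray) -> np.ndarray:
        return self.decoder.forward(feat)[:, 0, :, :] * self.input_scale

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(images))

    def loss_and_grad(self, images: np.ndarray) -> float:
        """Reconstruction MSE of a batch (in normalised units); accumulates
        parameter gradients."""
        if images.shape[0] == 0:
            raise ValueError("empty batch")
        x = (images / self.input_scale).astype(np.float32)
        recon = self.decoder.forward(self.encoder.forward(x[:, None, :, :]))[:, 0]
        loss, dpred = mse_loss(recon, x)
        d = self.decoder.backward(dpred[:, None, :, :].astype(recon.dtype))
        self.encoder.backward(d)
        return loss


def feature_matrix(feat: np.ndarray) -> np.ndarray:
    """Reshape (N, 40, 3, 7) feature maps into time-major (N, 7, 120).

    Column 40·row + map of time step t holds maps[map, row, t]; the layout is
    fixed so the predictor always sees features in the same order.
    """
    n = feat.shape[0]
    return np.ascontiguousarray(feat.transpose(0, 3, 2, 1)).reshape(n, 7, 120)


def tvaf(emg: np.ndarray, recon: np.ndarray) -> float:
    """Total variance accounted for: 1 − SSE/SST over one image (or batch)."""
    emg = np.asarray(emg, dtype=np.float64)
    recon = np.asarray(recon, dtype=np.float64)
    if emg.shape != recon.shape:
        raise ValueError("shape mismatch")
    sst = np.sum(emg**2)
    if sst == 0:
        raise ValueError("tVAF undefined for all-zero sEMG")
    return float(1.0 - np.sum((emg - recon) ** 2) / sst)


def tvaf_batch(images: np.ndarray, recons: np.ndarray) -> np.ndarray:
    """Per-image tVAF for a batch (N, 9, 200)."""
    sse = np.sum((images.astype(np.float64) - recons) ** 2, axis=(1, 2))
    sst = np.sum(images.astype(np.float64) ** 2, axis=(1, 2))
    if np.any(sst == 0):
        raise ValueError("tVAF undefined for all-zero sEMG")
    return 1.0 - sse / sst


def reconstruction_loss(cae: CAE, images: np.ndarray) -> float:
    """Mean squared reconstruction error of a batch (no gradients)."""
    if images.shape[0] == 0:
        raise ValueError("empty batch")
    recon = cae.reconstruct(images)
    return float(np.mean((recon.astype(np.float64) - images) ** 2))


def make_optimizer(name: str, layers, lr: float, clip_norm: float | None):
    """"sgd" (the reference schedule) or "adam" (desk-scale schedules)."""
    if name == "sgd":
        return SGD(layers, lr, clip_norm=clip_norm)
    if name == "adam":
        return Adam(layers, lr, clip_norm=clip_norm)
    raise ValueError(f"unknown optimizer {name!r}")


def train_cae(cae: CAE, images: np.ndarray, *, epochs: int = 40, batch_size: int = 100,
              lr: float = 0.01, lr_decay: float = 0.8, decay_every: int = 40,
              seed: int = 0, clip_norm: float = 10.0,
              optimizer: str = "sgd") -> list[float]:
    """Minibatch training of the autoencoder; returns per-epoch mean loss.

    The reference schedule is batch 100, lr 0.01 multiplied by 0.8 whenever
    the epoch index is divisible by 40.  Before training, the network's
    ``input_scale`` is set to the training-set RMS so the optimisation sees
    unit-scale inputs.
    """
    rms = float(np.sqrt(np.mean(np.asarray(images, dtype=np.float64) ** 2)))
    if rms > 0:
        cae.input_scale = rms
    rng = np.random.default_rng(seed)
    opt = make_optimizer(optimizer, cae.layers, lr, clip_norm)
    history = []
    n = images.shape[0]
    for epoch in range(epochs):
        if epoch > 0 and epoch % decay_every == 0:
            opt.lr *= lr_decay
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            batch = images[order[start : start + batch_size]]
            opt.zero_grad()
            losses.append(cae.loss_and_grad(batch))
            opt.step()
        history.append(float(np.mean(losses)))
    cae.trained = True
    return history
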