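"""LSTM motion-prediction network.

Maps one (motion sequence, compressed sEMG feature) pair to a scalar: a
future knee angle (degrees) at a fixed horizon, or the time to the next
heel strike (ms).  Per time step the 120-dim sEMG feature is squeezed to a
single value by FC1 (120→100, ReLU) and FC2 (100→1, linear — a ReLU on a
single squeezed scalar can die permanently during training); that value is
concatenated with the 5 motion features, the 7×6 sequence runs through
three 200-unit LSTM layers, and FC3 (200→100, ReLU) then FC4 (100→1) read
the last step's hidden state.

The feature extractor is detached: predictor training consumes encoder
features as fixed inputs, so its loss never propagates into the CAE.

Each prediction task (four angle horizons, one event) is an independently
trained instance of the same architecture.
"""
from __future__ import annotations

import numpy as np

from .nn import LSTM, Dense, ReLU, mse_loss
from .cae import make_optimizer

LSTM_UNITS = 200
LSTM_LAYERS = 3
SEQ_LEN = 7
FEATURE_DIM = 120
MOTION_DIM = 5


class Predictor:
    def __init__(self, seed: int = 0, dtype=np.float32, residual: bool = False,
                 log_target: bool = False):
        if residual and log_target:
            raise ValueError("residual and log_target are mutually exclusive")
        rng = np.random.default_rng(seed)
        self.fc1 = Dense(FEATURE_DIM, 100, rng, dtype)
        self.fc2 = Dense(100, 1, rng, dtype)
        self.lstm = LSTM(1 + MOTION_DIM, LSTM_UNITS, LSTM_LAYERS, rng, dtype)
        self.fc3 = Dense(LSTM_UNITS, 100, rng, dtype)
        self.fc4 = Dense(100, 1, rng, dtype)
        self.r1, self.r3 = ReLU(), ReLU()
        self.dtype = dtype
        # residual mode: the target is the change from the current angle
        # (motion[:, -1, 0]); the current value is added back at predict time.
        # Used for the angle horizons, where it removes the large shared
        # component that every horizon could trivially copy.
        self.residual = residual
        # log mode: regress log1p of a non-negative target (time-to-event),
        # giving uniform relative rather than absolute precision
        self.log_target = log_target
        # input/target standardisation (z-scores from the training set);
        # raw angles (~70°) and angular rates would saturate the LSTM gates
        self.motion_mean = np.zeros(MOTION_DIM, dtype=dtype)
        self.motion_std = np.ones(MOTION_DIM, dtype=dtype)
        self.target_mean = 0.0
        self.target_std = 1.0
        self.trained = False  # set by train_predictor

    @property
    def layers(self):
        return [self.fc1, self.fc2, self.lstm, self.fc3, self.fc4]

    def forward(self, motion: np.ndarray, feat: np.ndarray) -> np.ndarray:
        """motion: (N, 7, 5); feat: (N, 7, 120) → standardised output (N,)."""
        if motion.shape[1:] != (SEQ_LEN, MOTION_DIM) or feat.shape[1:] != (SEQ_LEN, FEATURE_DIM):
            raise ValueError("expected (N,7,5) motion and (N,7,120) features")
        s = self.fc2.forward(self.r1.forward(self.fc1.forward(feat)))
        m = (motion - self.motion_mean) / self.motion_std
        x = np.concatenate([s, m], axis=2).astype(self.dtype)  # (N,7,6)
        h = self.lstm.forward_seq(x)  # (N,7,200)
        self._h_shape = h.shape
        out = self.fc4.forward(self.r3.forward(self.fc3.forward(h[:, -1, :])))
        return out[:, 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backprop a gradient w.r.t. the scalar outputs; returns dfeat."""
        d = self.fc3.backward(self.r3.backward(self.fc4.backward(dout[:, None])))
        douts = np.zeros(self._h_shape, dtype=self.dtype)
        douts[:, -1, :] = d
        dx = self.lstm.backward_seq(douts)
        ds, _dmotion = dx[:, :, :1], dx[:, :, 1:]
        return self.fc1.backward(self.r1.backward(self.fc2.backward(ds)))

    def effective_targets(self, motion: np.ndarray, targets: np.ndarray) -> np.ndarray:
        """Raw regression targets: the change from the current angle in
        residual mode, the target itself otherwise."""
        if self.residual:
            return targets - motion[:, -1, 0]
        if self.log_target:
            return np.log1p(np.maximum(targets, 0.0))
        return targets

    def predict(self, motion: np.ndarray, feat: np.ndarray) -> np.ndarray:
        """Prediction in physical units (degrees or ms)."""
        out = self.forward(motion, feat) * self.target_std + self.target_mean
        if self.residual:
            out = out + motion[:, -1, 0]
        elif self.log_target:
            out = np.expm1(out)
        return out

    def loss_and_grad(self, motion, feat, targets_std) -> float:
        """MSE on standardised targets; accumulates parameter gradients."""
        out = self.forward(motion, feat)
        loss, dout = mse_loss(out, targets_std)
        self.backward(dout.astype(self.dtype))
        return loss


def prediction_loss(pred: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared prediction error."""
    pred = np.asarray(pred, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if pred.shape != targets.shape:
        raise ValueError("length mismatch")
    if pred.size == 0:
        raise ValueError("empty batch")
    return float(np.mean((pred - targets) ** 2))


def train_predictor(pred: Predictor, motion: np.ndarray, feat: np.ndarray,
                    targets: np.ndarray, *, epochs: int = 40, batch_size: int = 100,
                    lr: float = 0.1, lr_decay: float = 0.5, decay_every: int = 40,
                    seed: int = 0, clip_norm: float = 5.0,
                    optimizer: str = "sgd") -> list[float]:
    """SGD training; returns per-epoch mean loss (standardised units).

    The reference schedule is batch 100, lr 0.1 halved whenever the epoch
    index is divisible by 40.  Targets are z-scored from the training set for
    conditioning; predictions are un-standardised at report time.
    """
    pred.motion_mean = motion.reshape(-1, motion.shape[-1]).mean(axis=0).astype(pred.dtype)
    pred.motion_std = (motion.reshape(-1, motion.shape[-1]).std(axis=0).astype(pred.dtype)
                       + np.asarray(1e-6, dtype=pred.dtype))
    targets = pred.effective_targets(motion, targets)
    pred.target_mean = float(np.mean(targets))
    pred.target_std = float(np.std(targets)) or 1.0
    t_std = ((targets - pred.target_mean) / pred.target_std).astype(np.float64)
    rng = np.random.default_rng(seed)
    opt = make_optimizer(optimizer, pred.layers, lr, clip_norm)
    n = motion.shape[0]
    history = []
    for epoch in range(epochs):
        if epoch > 0 and epoch % decay_every == 0:
            opt.lr *= lr_decay
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            opt.zero_grad()
            losses.append(pred.loss_and_grad(motion[idx], feat[idx], t_std[idx]))
            opt.step()
        history.append(float(np.mean(losses)))
    pred.trained = True
    return history


def max_stride_error(pred_series: np.ndarray, label_series: np.ndarray,
                     stride_ids: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximum absolute prediction error within each complete gait cycle.

    ``stride_ids`` assigns every sample to a cycle (as from
    :meth:`Dataset.stride_ids`); samples before the first or after the last
    heel strike (negative or maximal ids) do not form complete strides and
    are ignored.  Returns (per-stride maxima, their mean).
    """
    pred_series = np.asarray(pred_series, dtype=float)
    label_series = np.asarray(label_series, dtype=float)
    stride_ids = np.asarray(stride_ids)
    err = np.abs(pred_series - label_series)
    valid = stride_ids >= 0
    ids = stride_ids[valid]
    if ids.size == 0:
        raise ValueError("no complete stride in the series")
    maxima = []
    for sid in np.unique(ids):
        maxima.append(err[valid][ids == sid].max())
    maxima = np.asarray(maxima)
    return maxima, float(maxima.mean())
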