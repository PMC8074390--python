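"""Learned-optimizer online adaptation.

When the sEMG distribution drifts (fatigue, a new wearer), the trained
feature extractor and predictor degrade.  Rather than retraining, a small
coordinatewise recurrent "optimizer network" g maps each tuned parameter and
its preprocessed gradient to a parameter increment:

    θ_{t+1} = θ_t + g(∇f(θ_t), φ)

Only two parameter subsets are tuned online: half of the predictor's FC3
layer (the even rows of its 200×100 weight matrix plus all 100 biases,
10,100 values) and about a quarter of the encoder's fourth convolution layer
(every fourth input-channel slice of its 80×40×4×4 weights plus all 40
biases, 12,840 values).  The optimizer network is shared across coordinates
but keeps per-coordinate recurrent state; gradients are log-magnitude/sign
preprocessed so inputs of wildly different scales land in a common range.

Meta-training unrolls the optimizer over a window of update steps on
training-population batches and backpropagates the summed post-update loss
into φ, treating the gradient inputs as constants (the standard first-order
approximation for learned optimizers).  The CAE and predictor are adapted
independently: reconstruction error drives the encoder subset, prediction
error drives the FC3 subset.
"""
from __future__ import annotations

import numpy as np

from .cae import CAE, feature_matrix, make_optimizer
from .nn import LSTM, SGD, Dense
from .predictor import Predictor


# ---------------------------------------------------------------------------
# tuned-parameter selection
# ---------------------------------------------------------------------------

class TunedParamSpec:
    """A flat view onto a selected subset of one layer's parameters.

    ``segments`` is an ordered list of ``(param_name, flat_indices)`` pairs;
    gather/scatter concatenate the indexed values in that order, so a
    round trip restores every selected value exactly and never touches the
    complement.
    """

    def __init__(self, layer, segments):
        self.layer = layer
        self.segments = [(name, np.asarray(idx, dtype=np.intp)) for name, idx in segments]
        self.count = int(sum(len(idx) for _, idx in self.segments))

    def gather(self) -> np.ndarray:
        return np.concatenate(
            [self.layer.params[name].ravel()[idx] for name, idx in self.segments]
        ).astype(np.float64)

    def gather_grads(self) -> np.ndarray:
        return np.concatenate(
            [self.layer.grads[name].ravel()[idx] for name, idx in self.segments]
        ).astype(np.float64)

    def scatter(self, vec: np.ndarray) -> None:
        if vec.shape != (self.count,):
            raise ValueError(f"expected a {self.count}-vector")
        pos = 0
        for name, idx in self.segments:
            p = self.layer.params[name]
            flat = p.reshape(-1)
            flat[idx] = vec[pos : pos + len(idx)].astype(p.dtype)
            pos += len(idx)


def fc3_even_rows_spec(fc3: Dense) -> TunedParamSpec:
    """Even rows (1-based: 2, 4, …, 200) of FC3's 200×100 weights + all biases.

    Per output node i the selection is the 101-vector
    [w_{2,i}, w_{4,i}, …, w_{200,i}, b_i]; nodes are concatenated in order.
    """
    n_in, n_out = fc3.params["weight"].shape
    rows = np.arange(1, n_in, 2)  # 0-based odd == 1-based even
    segments = []
    for i in range(n_out):
        segments.append(("weight", rows * n_out + i))
        segments.append(("bias", np.array([i])))
    return TunedParamSpec(fc3, segments)


def fc3_all_spec(fc3: Dense) -> TunedParamSpec:
    """Comparative variant: every FC3 weight and bias."""
    n_in, n_out = fc3.params["weight"].shape
    segments = []
    for i in range(n_out):
        segments.append(("weight", np.arange(n_in) * n_out + i))
        segments.append(("bias", np.array([i])))
    return TunedParamSpec(fc3, segments)


def fc4_all_spec(fc4: Dense) -> TunedParamSpec:
    """Comparative variant: every FC4 weight and bias."""
    n_in, n_out = fc4.params["weight"].shape
    segments = [("weight", np.arange(n_in * n_out)), ("bias", np.arange(n_out))]
    return TunedParamSpec(fc4, segments)


def conv4_quarter_spec(conv4) -> TunedParamSpec:
    """Input-channel slices with 1-based index divisible by 4 + all biases.

    The layer's weights are 80×40×4×4 in (input, output, kernel) layout;
    selecting input channels 4, 8, …, 80 gives 20 slices of 40·4·4 weights,
    plus the 40 biases.  Weights here are stored (out, in, kh, kw), so the
    selected flat indices are computed for that memory order.
    """
    out_ch, in_ch, kh, kw = conv4.params["weight"].shape
    k = kh * kw
    sel_in = np.arange(3, in_ch, 4)  # 0-based: 1-based multiples of 4
    segments = []
    o_idx = np.arange(out_ch)[:, None] * (in_ch * k)
    k_idx = np.arange(k)[None, :]
    for c in sel_in:
        segments.append(("weight", (o_idx + c * k + k_idx).ravel()))
    segments.append(("bias", np.arange(out_ch)))
    return TunedParamSpec(conv4, segments)


# ---------------------------------------------------------------------------
# gradient preprocessing
# ---------------------------------------------------------------------------

def preprocess_gradient(g: np.ndarray, p: float = 10.0) -> np.ndarray:
    """Log-magnitude / sign preprocessing of a gradient vector.

    Coordinates with |g| ≥ e^(−p) map to (log|g| / p, sign g); smaller ones
    to (−1, e^p · g).  The two branches agree at the threshold, and the first
    component is bounded in [−1, log(max|g|)/p].
    """
    g = np.asarray(g, dtype=np.float64)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite gradient")
    absg = np.abs(g)
    big = absg >= np.exp(-p)
    out = np.empty((g.size, 2))
    with np.errstate(divide="ignore"):
        out[:, 0] = np.where(big, np.log(np.maximum(absg, 1e-300)) / p, -1.0)
    out[:, 1] = np.where(big, np.sign(g), np.exp(p) * g)
    return out


# ---------------------------------------------------------------------------
# the optimizer network
# ---------------------------------------------------------------------------

class OptimizerNetwork:
    """Coordinatewise FC(3→40)+Tanh → 3×40-unit LSTM → FC(40→1).

    The same weights φ are applied to every tuned coordinate; the LSTM state
    is per-coordinate, so the "batch" axis is the coordinate axis.  Input per
    coordinate: (θ_i, preprocessed-gradient pair).
    """

    INPUT_DIM = 3
    UNITS = 40

    def __init__(self, seed: int = 0, p: float = 10.0, output_scale: float = 0.1,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.fc_in = Dense(self.INPUT_DIM, self.UNITS, rng, dtype)
        self.lstm = LSTM(self.UNITS, self.UNITS, 3, rng, dtype)
        self.fc_out = Dense(self.UNITS, 1, rng, dtype)
        # zero output init: the untrained optimizer is a no-op, so meta-training
        # only moves it away from identity where the meta-loss provides signal
        self.fc_out.params["weight"][:] = 0.0
        self.fc_out.params["bias"][:] = 0.0
        self.p = p
        self.output_scale = output_scale
        self.dtype = dtype

    @property
    def layers(self):
        return [self.fc_in, self.lstm, self.fc_out]

    def init_state(self, n_coords: int):
        return self.lstm.init_state(n_coords)

    def step(self, theta: np.ndarray, grad: np.ndarray, state):
        """One adaptation step: returns (Δθ, new_state, cache)."""
        pg = preprocess_gradient(grad, self.p)
        x = np.column_stack([theta, pg]).astype(self.dtype)  # (n, 3)
        z = x @ self.fc_in.params["weight"] + self.fc_in.params["bias"]
        a = np.tanh(z)
        h, new_state, lstm_caches = self.lstm.step(a, state)
        delta = (h @ self.fc_out.params["weight"] + self.fc_out.params["bias"])[:, 0]
        cache = (x, a, h, lstm_caches)
        return self.output_scale * delta.astype(np.float64), new_state, cache

    def step_backward(self, ddelta: np.ndarray, dstate, cache):
        """Backprop one step; accumulates φ gradients, returns dstate_prev."""
        x, a, h, lstm_caches = cache
        dd = (self.output_scale * ddelta)[:, None].astype(self.dtype)
        self.fc_out.grads["weight"] += h.T @ dd
        self.fc_out.grads["bias"] += dd.sum(axis=0)
        dh = dd @ self.fc_out.params["weight"].T
        da, dstate_prev = self.lstm.step_backward(dh, dstate, lstm_caches)
        dz = da * (1.0 - a**2)
        self.fc_in.grads["weight"] += x.T @ dz
        self.fc_in.grads["bias"] += dz.sum(axis=0)
        return dstate_prev


def optimizer_step(theta: np.ndarray, grads: np.ndarray, state,
                   net: OptimizerNetwork):
    """Functional wrapper: (θ, ∇, state) → (θ + Δθ, new_state)."""
    if theta.shape != grads.shape:
        raise ValueError("θ / gradient length mismatch")
    delta, new_state, _ = net.step(theta, grads, state)
    return theta + delta, new_state


# ---------------------------------------------------------------------------
# adaptation objectives (frozen base networks + tuned subset)
# ---------------------------------------------------------------------------

class CAEObjective:
    """Reconstruction loss of the CAE as a function of its tuned subset."""

    def __init__(self, cae: CAE, spec: TunedParamSpec | None = None):
        self.cae = cae
        self.spec = spec if spec is not None else conv4_quarter_spec(cae.adaptable_conv)

    @property
    def base_trained(self) -> bool:
        return bool(getattr(self.cae, "trained", False))

    def gather(self):
        return self.spec.gather()

    def scatter(self, vec):
        self.spec.scatter(vec)

    def loss_grad(self, images: np.ndarray):
        for l in self.cae.layers:
            l.zero_grad()
        loss = self.cae.loss_and_grad(images)
        return loss, self.spec.gather_grads()


class PredictorObjective:
    """Prediction loss (standardised units) as a function of the FC3 subset.

    Features are consumed as fixed arrays, so this objective can never
    propagate gradients into the CAE.
    """

    def __init__(self, predictor: Predictor, spec: TunedParamSpec | None = None):
        self.predictor = predictor
        self.spec = spec if spec is not None else fc3_even_rows_spec(predictor.fc3)

    @property
    def base_trained(self) -> bool:
        return bool(getattr(self.predictor, "trained", False))

    def gather(self):
        return self.spec.gather()

    def scatter(self, vec):
        self.spec.scatter(vec)

    def loss_grad(self, batch):
        motion, feat, targets = batch
        p = self.predictor
        for l in p.layers:
            l.zero_grad()
        t_std = (p.effective_targets(motion, targets) - p.target_mean) / p.target_std
        return p.loss_and_grad(motion, feat, t_std), self.spec.gather_grads()


# ---------------------------------------------------------------------------
# meta-training and online adaptation
# ---------------------------------------------------------------------------

def train_optimizer(net: OptimizerNetwork, objective, batch_sampler, *,
                    epochs: int = 50, unroll: int = 10, lr: float = 0.01,
                    lr_decay: float = 0.5, decay_every: int = 100,
                    reset_every: int = 10, clip_norm: float = 1.0,
                    optimizer: str = "sgd") -> list[float]:
    """Meta-train the optimizer network φ on a frozen base network.

    ``batch_sampler(epoch)`` yields a list of per-step batches (one subject's
    shuffled data per epoch).  Each epoch unrolls ``unroll`` optimizer steps,
    sums the post-update losses as the meta-objective, and backpropagates it
    through the stored unroll into φ only (gradient inputs are treated as
    constants).  The tuned parameters are reset to their trained values every
    ``reset_every`` epochs.  Returns the per-epoch meta-loss history.

    Training order is enforced: the base network must already be trained
    (meta-training around a random base would learn updates for the wrong
    loss landscape).
    """
    if not getattr(objective, "base_trained", True):
        raise RuntimeError("optimizer meta-training requires a trained base network")
    theta0 = objective.gather()
    meta_opt = make_optimizer(optimizer, net.layers, lr, clip_norm)
    history = []
    for epoch in range(epochs):
        if epoch > 0 and epoch % decay_every == 0:
            meta_opt.lr *= lr_decay
        if epoch % reset_every == 0:
            objective.scatter(theta0)
        batches = batch_sampler(epoch)
        theta = objective.gather()
        state = net.init_state(theta.size)
        meta_opt.zero_grad()
        _, g = objective.loss_grad(batches[0])
        caches, g_hist = [], []
        meta_loss = 0.0
        steps = min(unroll, len(batches))
        for t in range(steps):
            delta, state, cache = net.step(theta, g, state)
            theta = theta + delta
            objective.scatter(theta)
            loss, g = objective.loss_grad(batches[min(t + 1, len(batches) - 1)])
            meta_loss += loss
            caches.append(cache)
            g_hist.append(g)
        # dL/dΔθ_t = Σ_{s ≥ t} ∇loss(θ_{s+1}) — θ_{s+1} shifts by every earlier Δθ
        dstate = None
        running = np.zeros_like(theta)
        for t in reversed(range(steps)):
            running = running + g_hist[t]
            dstate = net.step_backward(running, dstate, caches[t])
        meta_opt.step()
        if not np.isfinite(meta_loss):
            raise FloatingPointError("meta-loss diverged")
        history.append(meta_loss / steps)
    objective.scatter(theta0)
    return history


def adapt_online(objective, net: OptimizerNetwork, update_batches,
                 n_iterations: int = 1) -> list[float]:
    """Run online adaptation iterations; returns the loss trace.

    One iteration is one pass over ``update_batches`` (the update half of the
    new-condition stream), taking one optimizer-network step per batch with
    the recurrent state carried across batches.  The base network's tuned
    subset is updated in place.
    """
    if len(update_batches) == 0:
        raise ValueError("empty update stream")
    theta = objective.gather()
    state = net.init_state(theta.size)
    trace = []
    for _ in range(n_iterations):
        for batch in update_batches:
            loss, g = objective.loss_grad(batch)
            theta, state = optimizer_step(theta, g, state, net)
            objective.scatter(theta)
            trace.append(loss)
    return trace


def relative_growth_rate(adapted: float, shifted: float, intra: float) -> float:
    """Fraction of the shift-induced accuracy drop recovered by adaptation:
    (Acc_adapted − Acc_shifted) / (Acc_intra − Acc_shifted)."""
    denom = intra - shifted
    if denom == 0:
        raise ZeroDivisionError("no accuracy drop to recover")
    return (adapted - shifted) / denom
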