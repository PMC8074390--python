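"""Experiment protocols: training schedules, intra/inter-subject testing,
online-adaptation evaluation and metric aggregation.

The reference protocol is leave-one-subject-out: group A (the training
population) trains the feature extractor, then the predictors, then the
adaptation optimizers, in that order; the held-out group-B subject probes
distribution shift.  Intra-subject metrics come from held-out segments of
group A; inter-subject metrics from group B before adaptation; adapted
metrics from group B after online tuning on half of its stream, evaluated
on the other half.

Two scales are provided: the full reference schedule (340/340/550 epochs)
and a desk scale with shorter schedules and subsampled data for quick,
CPU-only runs; both use the same code paths.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import synthetic
from .adaptation import (
    CAEObjective,
    OptimizerNetwork,
    PredictorObjective,
    adapt_online,
    fc3_all_spec,
    fc3_even_rows_spec,
    fc4_all_spec,
    relative_growth_rate,
    train_optimizer,
)
from .cae import CAE, feature_matrix, train_cae, tvaf_batch
from .predictor import Predictor, max_stride_error, train_predictor
from .preprocessing import IMU_INTERVAL_MS, Dataset, build_dataset
from .synergy import derive_channel_orders, envelope, fit_nmf

HORIZON_MS = {1: 6.75, 5: 33.75, 10: 67.5, 15: 101.25}


def lr_schedule(lr0: float, decay: float, every: int, epoch: int) -> float:
    """Step learning-rate schedule: lr0 · decay^(epoch // every)."""
    return lr0 * decay ** (epoch // every)


@dataclass
class TrainConfig:
    """Schedules and problem sizes for one experiment run.

    Defaults are the full reference schedule; :meth:`desk_scale` shrinks the
    run to a few CPU-minutes while keeping every pipeline stage.
    """

    #: "sgd" is the reference schedule; the desk scale uses "adam" because
    #: plain SGD cannot cross the CAE's ill-conditioned loss surface within
    #: the reduced step budget.
    optimizer: str = "sgd"
    batch_size: int = 100
    cae_epochs: int = 340
    cae_lr: float = 0.01
    cae_decay: float = 0.8
    cae_decay_every: int = 40
    pred_epochs: int = 340
    pred_lr: float = 0.1
    pred_decay: float = 0.5
    pred_decay_every: int = 40
    pred_batch_size: int = 100
    #: the event head converges slower than the residual angle heads;
    #: None means "same as pred_epochs"
    event_pred_epochs: int | None = None
    adapt_epochs: int = 550
    #: meta-epochs for the predictor-side optimizer (None = adapt_epochs);
    #: its role is a small correction on top of the extractor adaptation
    pred_adapt_epochs: int | None = None
    adapt_lr: float = 0.01
    adapt_decay: float = 0.5
    adapt_decay_every: int = 100
    adapt_reset_every: int = 10
    adapt_unroll: int = 10
    adapt_batch: int = 100
    n_adapt_iterations: int = 1
    # synthetic study population
    n_train_subjects: int = 9
    subject_duration: float = 40.0  # seconds of walking per subject
    #: extra electrode gain on the held-out subject (scalar or per-channel)
    inter_gain: float | tuple = 1.5
    inter_compression: float = 0.8  # carrier-band compression (fatigue-like)
    inter_channel_swap: tuple = ()  # electrode-placement remapping
    #: meta-train the adaptation optimizers on pseudo-shifted group-A batches
    augment_meta_shifts: bool = False
    # data subsampling caps (None = use everything)
    max_cae_images: int | None = None
    max_pred_samples: int | None = None
    max_meta_samples: int | None = None  # per-subject pool for meta-training
    test_fraction: float = 0.2
    seed: int = 0

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "TrainConfig":
        return cls(
            optimizer="adam",
            batch_size=25,
            cae_epochs=10,
            cae_lr=1e-3,
            pred_epochs=32,
            pred_lr=5e-3,
            pred_decay=0.5,
            pred_decay_every=12,
            pred_batch_size=100,
            event_pred_epochs=28,
            adapt_epochs=24,
            pred_adapt_epochs=8,
            adapt_lr=5e-3,
            adapt_unroll=16,
            adapt_batch=25,
            n_train_subjects=8,
            subject_duration=10.0,
            inter_gain=(2.0, 0.5, 1.6, 0.6, 1.4, 0.7, 1.8, 0.5, 1.2),
            inter_compression=1.0,
            inter_channel_swap=((0, 4), (2, 6)),
            augment_meta_shifts=True,
            max_cae_images=2500,
            max_pred_samples=1500,
            max_meta_samples=300,
            seed=seed,
        )


@dataclass
class SubjectData:
    dataset: Dataset
    semg: np.ndarray  # raw recording channels × samples, for synergy fitting
    train_idx: np.ndarray
    test_idx: np.ndarray  # contiguous tail segment (complete strides)


def _split_indices(n: int, test_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    cut = int(round(n * (1.0 - test_fraction)))
    return np.arange(cut), np.arange(cut, n)


def make_population(config: TrainConfig):
    """Generate group A subjects and the shifted group-B subject."""
    group_a = []
    for s in range(config.n_train_subjects):
        params, shift = synthetic.make_subject_params(
            s, config.seed, duration=config.subject_duration
        )
        rec = synthetic.generate_recording(params, shift)
        ds = build_dataset(rec)
        tr, te = _split_indices(len(ds), config.test_fraction)
        group_a.append(SubjectData(ds, rec.semg, tr, te))
    params_b, shift_b = synthetic.make_subject_params(
        config.n_train_subjects, config.seed, duration=config.subject_duration
    )
    shift_b = synthetic.ShiftParams(
        amplitude_gain=np.asarray(shift_b.amplitude_gain) * np.asarray(config.inter_gain),
        spectral_compression=config.inter_compression,
        envelope_jitter=0.05,
        channel_swap=tuple(config.inter_channel_swap),
    )
    rec_b = synthetic.generate_recording(params_b, shift_b)
    ds_b = build_dataset(rec_b)
    group_b = SubjectData(ds_b, rec_b.semg, *_split_indices(len(ds_b), 0.5))
    return group_a, group_b


def fit_synergies(group_a: list[SubjectData], rate: float = synthetic.SEMG_RATE,
                  r: int = 5, seed: int = 0):
    """Pooled group-A envelope NMF → frozen synergy model + channel orders."""
    envs = [envelope(s.semg, rate)[:, ::20] for s in group_a]
    v = np.concatenate(envs, axis=1).T  # (time, channels)
    model = fit_nmf(v, r, seed=seed)
    return model, derive_channel_orders(model.H)


def encode_features(cae: CAE, images: np.ndarray, batch: int = 200, *,
                    require_trained: bool = True) -> np.ndarray:
    """Encoder features as (N, 7, 120) matrices, computed in batches.

    By default refuses an untrained encoder: every downstream consumer
    (predictor training, adaptation) must see post-training features.
    """
    if require_trained and not getattr(cae, "trained", False):
        raise RuntimeError("feature extraction requires a trained CAE")
    out = []
    for s in range(0, images.shape[0], batch):
        out.append(feature_matrix(cae.encode(images[s : s + batch])))
    return np.concatenate(out) if out else np.empty((0, 7, 120), dtype=np.float32)


def _subsample(rng, n, cap):
    if cap is None or n <= cap:
        return np.arange(n)
    return np.sort(rng.choice(n, size=cap, replace=False))


def pseudo_shift(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one synthetic nonstationarity and apply it to an image batch.

    Draws from the same family as the held-out subject's shift — an
    electrode-pair swap plus per-channel gains — so that meta-training sees
    the kind of input change the adaptation optimizers must learn to repair.
    """
    i, j = rng.choice(images.shape[1], size=2, replace=False)
    out = images.copy()
    out[:, [i, j]] = out[:, [j, i]]
    gains = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=images.shape[1]))
    return (out * gains[None, :, None]).astype(images.dtype)


@dataclass
class PipelineArtifacts:
    """Everything trained by :func:`run_experiment`."""

    cae: CAE
    predictors: dict  # horizon (IMU samples) or "event" → Predictor
    synergy_model: object
    orders: object
    cae_optimizer: OptimizerNetwork
    pred_optimizer: OptimizerNetwork
    group_a: list[SubjectData]
    group_b: SubjectData
    config: TrainConfig
    report: dict = field(default_factory=dict)


def train_pipeline(config: TrainConfig) -> PipelineArtifacts:
    """Train CAE → predictors → adaptation optimizers, in the stated order."""
    rng = np.random.default_rng(config.seed)
    group_a, group_b = make_population(config)

    syn_model, orders = fit_synergies(group_a, seed=config.seed)

    train_images = np.concatenate([s.dataset.images[s.train_idx] for s in group_a])
    idx = _subsample(rng, train_images.shape[0], config.max_cae_images)
    cae = CAE(orders, seed=config.seed)
    train_cae(cae, train_images[idx], epochs=config.cae_epochs,
              batch_size=config.batch_size, lr=config.cae_lr,
              lr_decay=config.cae_decay, decay_every=config.cae_decay_every,
              seed=config.seed, optimizer=config.optimizer)

    # predictor training set (pooled over group A)
    motion = np.concatenate([s.dataset.motion[s.train_idx] for s in group_a])
    tti = np.concatenate([s.dataset.time_to_ic[s.train_idx] for s in group_a])
    angles = np.concatenate([s.dataset.future_angles[s.train_idx] for s in group_a])
    pidx = _subsample(rng, motion.shape[0], config.max_pred_samples)
    feats = encode_features(cae, train_images[pidx])

    # one shared seed across horizons: per-horizon difficulty then shows up
    # as a clean ordering instead of being masked by initialisation noise
    predictors: dict = {}
    horizons = group_a[0].dataset.horizons
    for col, h in enumerate(horizons):
        p = Predictor(seed=config.seed + 10, residual=True)
        train_predictor(p, motion[pidx], feats, angles[pidx, col],
                        epochs=config.pred_epochs, batch_size=config.pred_batch_size,
                        lr=config.pred_lr, lr_decay=config.pred_decay,
                        decay_every=config.pred_decay_every, seed=config.seed + 10,
                        optimizer=config.optimizer)
        predictors[h] = p
    p_event = Predictor(seed=config.seed + 10, log_target=True)
    train_predictor(p_event, motion[pidx], feats, tti[pidx],
                    epochs=config.event_pred_epochs or config.pred_epochs,
                    batch_size=config.pred_batch_size,
                    lr=config.pred_lr, lr_decay=config.pred_decay,
                    decay_every=config.pred_decay_every, seed=config.seed + 10,
                    optimizer=config.optimizer)
    predictors["event"] = p_event

    # ---- meta-train the two adaptation optimizers on group A ------------
    h_max = horizons[-1]
    cae_obj = CAEObjective(cae)
    pred_obj = PredictorObjective(predictors[h_max])
    meta_idx = {
        s_id: s.train_idx[_subsample(rng, len(s.train_idx), config.max_meta_samples)]
        for s_id, s in enumerate(group_a)
    }
    per_subject_feats = {
        s_id: encode_features(cae, s.dataset.images[meta_idx[s_id]])
        for s_id, s in enumerate(group_a)
    }

    need = (config.adapt_unroll + 1) * config.adapt_batch

    def cae_sampler(epoch):
        s_id = epoch % len(group_a)
        s = group_a[s_id]
        srng = np.random.default_rng((config.seed, 1, epoch))
        order = np.resize(srng.permutation(len(meta_idx[s_id])), need)  # cycles if short
        imgs = s.dataset.images[meta_idx[s_id]]
        if config.augment_meta_shifts:
            imgs = pseudo_shift(imgs, srng)  # one consistent shift per epoch
        return [
            imgs[order[k * config.adapt_batch : (k + 1) * config.adapt_batch]]
            for k in range(config.adapt_unroll + 1)
        ]

    def pred_sampler(epoch):
        s_id = epoch % len(group_a)
        s = group_a[s_id]
        srng = np.random.default_rng((config.seed, 2, epoch))
        order = np.resize(srng.permutation(len(meta_idx[s_id])), need)
        col = list(horizons).index(h_max)
        if config.augment_meta_shifts:
            # features of the pseudo-shifted images: what the predictor will
            # actually see when the extractor runs on a shifted subject
            imgs = pseudo_shift(s.dataset.images[meta_idx[s_id]], srng)
            feats_e = encode_features(cae, imgs)
        else:
            feats_e = per_subject_feats[s_id]
        out = []
        for k in range(config.adapt_unroll + 1):
            b = order[k * config.adapt_batch : (k + 1) * config.adapt_batch]
            out.append((s.dataset.motion[meta_idx[s_id]][b],
                        feats_e[b],
                        s.dataset.future_angles[meta_idx[s_id]][b, col]))
        return out

    cae_opt = OptimizerNetwork(seed=config.seed + 201)
    pred_opt = OptimizerNetwork(seed=config.seed + 202)
    train_optimizer(cae_opt, cae_obj, cae_sampler, epochs=config.adapt_epochs,
                    unroll=config.adapt_unroll, lr=config.adapt_lr,
                    lr_decay=config.adapt_decay, decay_every=config.adapt_decay_every,
                    reset_every=config.adapt_reset_every, optimizer=config.optimizer)
    train_optimizer(pred_opt, pred_obj, pred_sampler,
                    epochs=config.pred_adapt_epochs or config.adapt_epochs,
                    unroll=config.adapt_unroll, lr=config.adapt_lr,
                    lr_decay=config.adapt_decay, decay_every=config.adapt_decay_every,
                    reset_every=config.adapt_reset_every, optimizer=config.optimizer)

    return PipelineArtifacts(cae, predictors, syn_model, orders, cae_opt,
                             pred_opt, group_a, group_b, config)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mean_tvaf(cae: CAE, images: np.ndarray, batch: int = 200) -> np.ndarray:
    vals = []
    for s in range(0, images.shape[0], batch):
        b = images[s : s + batch]
        vals.append(tvaf_batch(b, cae.reconstruct(b)))
    return np.concatenate(vals)


def angle_errors(art: PipelineArtifacts, subject: SubjectData, idx: np.ndarray,
                 feats: np.ndarray | None = None,
                 horizons: tuple | None = None) -> dict[float, float]:
    """Mean max-stride angle error (degrees) per horizon on one segment.

    ``horizons`` restricts the evaluation to a subset (default: all).
    """
    ds = subject.dataset
    if feats is None:
        feats = encode_features(art.cae, ds.images[idx])
    sids = ds.stride_ids()[idx]
    out = {}
    for h in (ds.horizons if horizons is None else horizons):
        col = list(ds.horizons).index(h)
        pred = art.predictors[h].predict(ds.motion[idx], feats)
        _, mean_err = max_stride_error(pred, ds.future_angles[idx, col], sids)
        out[HORIZON_MS[h]] = mean_err
    return out


def event_advance(pred_series: np.ndarray, label_series: np.ndarray,
                  stride_ids: np.ndarray, tol_ms: float = 6.0) -> tuple[np.ndarray, float, float]:
    """How far before initial contact the event prediction is trustworthy.

    Per stride: the largest true time-to-IC value T such that every sample
    with label ≤ T has |prediction − label| ≤ tol_ms.  Returns (per-stride
    advances, mean, sd); a stride whose closest-to-IC sample already fails
    the tolerance contributes 0.
    """
    err = np.abs(np.asarray(pred_series, dtype=float) - label_series)
    advances = []
    for sid in np.unique(stride_ids[stride_ids >= 0]):
        m = stride_ids == sid
        labels, errors = label_series[m], err[m]
        order = np.argsort(labels)  # ascending time-to-IC
        labels, errors = labels[order], errors[order]
        ok = errors <= tol_ms
        if ok.all():
            advances.append(labels[-1])
        else:
            first_bad = int(np.argmin(ok))
            advances.append(labels[first_bad - 1] if first_bad > 0 else 0.0)
    advances = np.asarray(advances)
    if advances.size == 0:
        raise ValueError("no complete stride")
    return advances, float(advances.mean()), float(advances.std())


def event_phase_errors(pred_series: np.ndarray, label_series: np.ndarray,
                       stride_ids: np.ndarray, heel_strikes: np.ndarray,
                       near: float = 0.2, far: float = 0.8) -> tuple[float, float]:
    """Mean |time-to-IC error| close to vs. far from initial contact.

    Each sample's position in its stride is its time-to-IC label divided by
    the stride duration; "near" averages samples in the last ``near`` fraction
    before the strike, "far" those earlier than the ``far`` fraction.
    """
    strikes = np.asarray(heel_strikes)
    durations_ms = np.diff(strikes) * IMU_INTERVAL_MS
    err = np.abs(np.asarray(pred_series, dtype=float) - label_series)
    near_errs, far_errs = [], []
    for sid in np.unique(stride_ids[stride_ids >= 0]):
        if sid >= len(durations_ms):
            continue  # after the last strike: no complete stride
        m = stride_ids == sid
        frac = label_series[m] / durations_ms[sid]  # 0 at IC, 1 a stride early
        near_errs.append(err[m][frac <= near])
        far_errs.append(err[m][frac >= far])
    near_all = np.concatenate(near_errs) if near_errs else np.empty(0)
    far_all = np.concatenate(far_errs) if far_errs else np.empty(0)
    if near_all.size == 0 or far_all.size == 0:
        raise ValueError("no samples in the near/far stride-phase windows")
    return float(near_all.mean()), float(far_all.mean())


def run_experiment(config: TrainConfig | None = None) -> PipelineArtifacts:
    """Full protocol: train, test intra/inter, adapt online, aggregate.

    Returns the artifacts with ``report`` populated.  The report contains
    reconstruction fidelity (tVAF) and per-horizon mean max-stride angle
    errors for the intra-subject, inter-subject (shifted, unadapted) and
    adapted conditions, plus event-prediction statistics.
    """
    config = config or TrainConfig.desk_scale()
    art = train_pipeline(config)
    group_a, b = art.group_a, art.group_b
    horizons = group_a[0].dataset.horizons
    h_max = horizons[-1]
    col_max = len(horizons) - 1

    # ---- intra-subject: held-out segments of group A --------------------
    tvaf_intra_subj, angle_intra, intra_feats = [], [], []
    for s in group_a:
        imgs = s.dataset.images[s.test_idx]
        tvaf_intra_subj.append(mean_tvaf(art.cae, imgs).mean())
        feats_s = encode_features(art.cae, imgs)
        intra_feats.append(feats_s)
        angle_intra.append(angle_errors(art, s, s.test_idx, feats=feats_s))
    tvaf_intra = float(np.mean(tvaf_intra_subj))
    intra_by_h = {ms: float(np.mean([a[ms] for a in angle_intra]))
                  for ms in HORIZON_MS.values()}

    # ---- event prediction on intra test data ----------------------------
    all_adv, nears, fars = [], [], []
    for s, feats_s in zip(group_a, intra_feats):
        ev_pred = art.predictors["event"].predict(s.dataset.motion[s.test_idx], feats_s)
        ev_label = s.dataset.time_to_ic[s.test_idx]
        sids_s = s.dataset.stride_ids()[s.test_idx]
        adv, _, _ = event_advance(ev_pred, ev_label, sids_s)
        all_adv.append(adv)
        n_err, f_err = event_phase_errors(ev_pred, ev_label, sids_s,
                                          s.dataset.heel_strikes)
        nears.append(n_err)
        fars.append(f_err)
    all_adv = np.concatenate(all_adv)
    adv_mean, adv_sd = float(all_adv.mean()), float(all_adv.std())
    ev_err_near = float(np.mean(nears))
    ev_err_far = float(np.mean(fars))

    # ---- inter-subject: group B before adaptation -----------------------
    test_imgs = b.dataset.images[b.test_idx]
    tvaf_inter = float(mean_tvaf(art.cae, test_imgs).mean())
    inter_errs = angle_errors(art, b, b.test_idx, horizons=(h_max,))
    angle_inter = inter_errs[HORIZON_MS[h_max]]

    # ---- online adaptation on group B -----------------------------------
    cae_obj = CAEObjective(art.cae)
    pred_obj = PredictorObjective(art.predictors[h_max])
    theta_cae0, theta_pred0 = cae_obj.gather(), pred_obj.gather()

    upd = b.train_idx  # first half of the shifted stream updates parameters
    cae_batches = [b.dataset.images[upd[k : k + config.adapt_batch]]
                   for k in range(0, len(upd), config.adapt_batch)]
    adapt_online(cae_obj, art.cae_optimizer, cae_batches,
                 n_iterations=config.n_adapt_iterations)
    # the predictor adapts to the features it will actually receive online:
    # those produced by the already-adapted extractor
    upd_feats = encode_features(art.cae, b.dataset.images[upd])
    pred_batches = [(b.dataset.motion[upd[k : k + config.adapt_batch]],
                     upd_feats[k : k + config.adapt_batch],
                     b.dataset.future_angles[upd[k : k + config.adapt_batch], col_max])
                    for k in range(0, len(upd), config.adapt_batch)]
    adapt_online(pred_obj, art.pred_optimizer, pred_batches,
                 n_iterations=config.n_adapt_iterations)

    tvaf_adapted = float(mean_tvaf(art.cae, test_imgs).mean())
    adapted_errs = angle_errors(art, b, b.test_idx, horizons=(h_max,))
    angle_adapted = adapted_errs[HORIZON_MS[h_max]]

    # restore trained parameters so the artifacts stay reusable
    cae_obj.scatter(theta_cae0)
    pred_obj.scatter(theta_pred0)

    art.report = {
        "tvaf_intra": tvaf_intra,
        "tvaf_intra_sd": float(np.std(tvaf_intra_subj)),
        "tvaf_inter": tvaf_inter,
        "tvaf_adapted": tvaf_adapted,
        "tvaf_recovery": relative_growth_rate(tvaf_adapted, tvaf_inter, tvaf_intra)
        if tvaf_intra != tvaf_inter else float("nan"),
        "angle_max_err_intra_by_horizon_ms": intra_by_h,
        "angle_max_err_inter": float(angle_inter),
        "angle_max_err_adapted": float(angle_adapted),
        "event_advance_ms": adv_mean,
        "event_advance_sd_ms": adv_sd,
        "event_err_near_ic_ms": ev_err_near,
        "event_err_far_ic_ms": ev_err_far,
        "n_train_windows": int(sum(len(s.train_idx) for s in group_a)),
    }
    return art


def comparative_adaptation(art: PipelineArtifacts, variants=("fc3_even", "fc3_all", "fc4_all"),
                           n_iterations: int = 3, meta_epochs: int = 8) -> dict:
    """Per-iteration max angle error curves for different tuned subsets.

    Each variant meta-trains its own optimizer (short schedule) for the
    chosen predictor subset, then adapts on the shifted subject's update half
    and logs the max-stride angle error on the test half after each
    iteration.
    """
    config = art.config
    b = art.group_b
    horizons = b.dataset.horizons
    h_max, col_max = horizons[-1], len(horizons) - 1
    predictor = art.predictors[h_max]
    spec_fns = {
        "fc3_even": lambda: fc3_even_rows_spec(predictor.fc3),
        "fc3_all": lambda: fc3_all_spec(predictor.fc3),
        "fc4_all": lambda: fc4_all_spec(predictor.fc4),
    }
    group_a = art.group_a
    feats_by_subject = {
        s_id: encode_features(art.cae, s.dataset.images[s.train_idx])
        for s_id, s in enumerate(group_a)
    }
    upd = b.train_idx
    upd_feats = encode_features(art.cae, b.dataset.images[upd])
    test_feats = encode_features(art.cae, b.dataset.images[b.test_idx])
    sids = b.dataset.stride_ids()[b.test_idx]

    curves = {}
    for name in variants:
        if name not in spec_fns:
            raise ValueError(f"unknown variant {name!r}")
        obj = PredictorObjective(predictor, spec_fns[name]())
        theta0 = obj.gather()

        def sampler(epoch):
            s_id = epoch % len(group_a)
            s = group_a[s_id]
            srng = np.random.default_rng((config.seed, 3, epoch))
            order = np.resize(srng.permutation(len(s.train_idx)),
                              (config.adapt_unroll + 1) * config.adapt_batch)
            return [(s.dataset.motion[s.train_idx][bidx],
                     feats_by_subject[s_id][bidx],
                     s.dataset.future_angles[s.train_idx][bidx, col_max])
                    for bidx in (order[k * config.adapt_batch : (k + 1) * config.adapt_batch]
                                 for k in range(config.adapt_unroll + 1))]

        net = OptimizerNetwork(seed=config.seed + 300 + hash(name) % 97)
        train_optimizer(net, obj, sampler, epochs=meta_epochs,
                        unroll=config.adapt_unroll, lr=config.adapt_lr,
                        reset_every=config.adapt_reset_every)
        batches = [(b.dataset.motion[upd[k : k + config.adapt_batch]],
                    upd_feats[k : k + config.adapt_batch],
                    b.dataset.future_angles[upd[k : k + config.adapt_batch], col_max])
                   for k in range(0, len(upd), config.adapt_batch)]
        errs = []
        theta = obj.gather()
        state = net.init_state(theta.size)
        _, g = obj.loss_grad(batches[0])
        for t in range(n_iterations):
            delta, state, _ = net.step(theta, g, state)
            theta = theta + delta
            obj.scatter(theta)
            _, g = obj.loss_grad(batches[(t + 1) % len(batches)])
            pred = predictor.predict(b.dataset.motion[b.test_idx], test_feats)
            _, mean_err = max_stride_error(pred, b.dataset.future_angles[b.test_idx, col_max], sids)
            errs.append(mean_err)
        obj.scatter(theta0)
        curves[name] = errs
    return curves
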