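"""Windowing, multi-rate alignment and labelling of gait recordings.

The sEMG stream is cut into 9×200 "images" (180 ms) advanced by 15 samples
(13.5 ms); the motion streams are cut into 13-sample blocks (87.75 ms)
advanced by 2 IMU samples (also 13.5 ms), then decimated to 7 rows.  Because
both strides span 13.5 ms — the least common multiple of the 0.9 ms and
6.75 ms sampling intervals — the two sequences advance in lockstep and can
be paired one-to-one.

Labels: for every IMU sample, the time to the next heel strike (ms) and the
knee angle 1, 5, 10 and 15 IMU intervals (6.75–101.25 ms) into the future.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synthetic import Recording

IMU_INTERVAL_MS = 6.75
SEMG_WINDOW = 200
SEMG_STRIDE = 15
MOTION_LENGTH = 13
MOTION_STRIDE = 2
DEFAULT_HORIZONS = (1, 5, 10, 15)  # IMU intervals → 6.75, 33.75, 67.5, 101.25 ms

#: IMU samples between a motion block's end and the paired sEMG image's end.
#: Image i ends at sEMG sample 15·i + 200, i.e. 13.5·i + 180 ms; the first IMU
#: sample boundary at or after that instant is 2·i + 27, so the paired block
#: covers IMU samples [2·i + 14, 2·i + 27) and the block ends within one IMU
#: interval (2.25 ms) of the image end.
ALIGN_END = 27


def segment_semg(recording: Recording, window: int = SEMG_WINDOW,
                 stride: int = SEMG_STRIDE) -> tuple[np.ndarray, np.ndarray]:
    """Sliding sEMG windows anchored at the stream start.

    Returns ``(images, ends)`` where ``images`` is (n, channels, window) and
    ``ends[i]`` is the exclusive end sample index ``i·stride + window``.
    A too-short stream yields zero windows, not an error.
    """
    n_samples = recording.semg.shape[1]
    if n_samples < window:
        return (np.empty((0, recording.semg.shape[0], window)), np.empty(0, dtype=int))
    win = sliding_window_view(recording.semg, window, axis=1)  # (C, n-w+1, w)
    starts = np.arange(0, n_samples - window + 1, stride)
    return win[:, starts, :].transpose(1, 0, 2), starts + window


def segment_motion(recording: Recording, length: int = MOTION_LENGTH,
                   stride: int = MOTION_STRIDE) -> tuple[np.ndarray, np.ndarray]:
    """Sliding motion blocks, (n, length, 5), plus exclusive end indices."""
    motion = recording.motion_matrix()
    n = motion.shape[0]
    if n < length:
        return np.empty((0, length, 5)), np.empty(0, dtype=int)
    win = sliding_window_view(motion, length, axis=0)  # (n-l+1, 5, l)
    starts = np.arange(0, n - length + 1, stride)
    return win[starts].transpose(0, 2, 1), starts + length


def downsample_to_7(blocks: np.ndarray) -> np.ndarray:
    """Decimate 13-row motion blocks to 7 rows (every other sample),
    preserving the 87.75 ms span and its endpoints."""
    if blocks.shape[1] != MOTION_LENGTH:
        raise ValueError(f"expected {MOTION_LENGTH}-row blocks, got {blocks.shape[1]}")
    return blocks[:, ::2, :]


def label_time_to_ic(recording: Recording) -> np.ndarray:
    """Time to the next heel strike, in ms, for every IMU sample.

    Samples after the last heel strike have no future event and are marked
    NaN (callers drop them).
    """
    n = recording.n_imu_samples
    idx = np.arange(n)
    strikes = np.asarray(recording.heel_strikes)
    pos = np.searchsorted(strikes, idx, side="left")
    out = np.full(n, np.nan)
    valid = pos < len(strikes)
    out[valid] = (strikes[pos[valid]] - idx[valid]) * IMU_INTERVAL_MS
    return out


def label_future_angle(recording: Recording, horizon_samples: int) -> np.ndarray:
    """Knee angle ``horizon_samples`` IMU intervals ahead of each sample.

    Trailing samples whose future index falls off the recording are NaN.
    """
    n = recording.n_imu_samples
    out = np.full(n, np.nan)
    if horizon_samples == 0:
        return recording.angle.copy()
    out[: n - horizon_samples] = recording.angle[horizon_samples:]
    return out


def trim_recording(recording: Recording, head: float = 60.0, tail: float = 60.0) -> Recording:
    """Discard the first/last ``head``/``tail`` seconds of every stream."""
    dur = recording.n_imu_samples / recording.imu_rate
    if dur <= head + tail:
        raise ValueError("recording shorter than head + tail trim")
    s0 = round(head * recording.semg_rate)
    s1 = recording.n_semg_samples - round(tail * recording.semg_rate)
    i0 = round(head * recording.imu_rate)
    i1 = recording.n_imu_samples - round(tail * recording.imu_rate)
    strikes = recording.heel_strikes
    strikes = strikes[(strikes >= i0) & (strikes < i1)] - i0
    return replace(
        recording,
        semg=recording.semg[:, s0:s1],
        angle=recording.angle[i0:i1],
        thigh_omega=recording.thigh_omega[i0:i1],
        shank_omega=recording.shank_omega[i0:i1],
        thigh_acc=recording.thigh_acc[i0:i1],
        shank_acc=recording.shank_acc[i0:i1],
        heel_strikes=strikes,
    )


@dataclass
class Dataset:
    """Aligned, labelled (sEMG image, motion sequence, targets) triples."""

    images: np.ndarray  # (n, 9, 200) float32
    motion: np.ndarray  # (n, 7, 5) float32
    time_to_ic: np.ndarray  # (n,) ms
    future_angles: np.ndarray  # (n, len(horizons)) degrees
    anchors: np.ndarray  # (n,) IMU index of each sample's "current" instant
    heel_strikes: np.ndarray  # IMU indices, for stride separation
    horizons: tuple[int, ...] = DEFAULT_HORIZONS

    def __len__(self) -> int:
        return self.images.shape[0]

    def stride_ids(self) -> np.ndarray:
        """Index of the gait cycle each sample's anchor falls in."""
        return np.searchsorted(self.heel_strikes, self.anchors, side="right") - 1

    def subset(self, idx) -> "Dataset":
        return Dataset(self.images[idx], self.motion[idx], self.time_to_ic[idx],
                       self.future_angles[idx], self.anchors[idx],
                       self.heel_strikes, self.horizons)


def build_dataset(recording: Recording, horizons=DEFAULT_HORIZONS) -> Dataset:
    """Pair each sEMG image with its end-aligned motion sequence and labels.

    Image i (ending 13.5·i + 180 ms) is paired with the 13-sample motion
    block ending at IMU sample 2·i + 27 and decimated to 7 rows; labels are
    taken at the block's last sample (the "current" instant).  Samples whose
    motion block or any label would leave the recording are dropped.
    """
    images, _ = segment_semg(recording)
    n_imu = recording.n_imu_samples
    tti = label_time_to_ic(recording)
    future = np.column_stack([label_future_angle(recording, h) for h in horizons])

    motion = recording.motion_matrix().astype(np.float32)
    keep_img, keep_motion, keep_anchor = [], [], []
    for i in range(images.shape[0]):
        end = MOTION_STRIDE * i + ALIGN_END
        anchor = end - 1
        if end > n_imu or end < MOTION_LENGTH:
            continue
        if np.isnan(tti[anchor]) or np.any(np.isnan(future[anchor])):
            continue
        keep_img.append(i)
        keep_motion.append(motion[end - MOTION_LENGTH : end : 2])
        keep_anchor.append(anchor)
    idx = np.asarray(keep_img, dtype=int)
    anchors = np.asarray(keep_anchor, dtype=int)
    return Dataset(
        images=images[idx].astype(np.float32),
        motion=np.asarray(keep_motion, dtype=np.float32).reshape(-1, 7, 5),
        time_to_ic=tti[anchors],
        future_angles=future[anchors],
        anchors=anchors,
        heel_strikes=np.asarray(recording.heel_strikes),
        horizons=tuple(horizons),
    )


def concat_datasets(datasets: list[Dataset]) -> Dataset:
    """Concatenate datasets (e.g. several subjects) for pooled training.

    Stride bookkeeping is per-source, so the concatenated set keeps only the
    fields needed for training; use per-subject datasets for stride metrics.
    """
    if not datasets:
        raise ValueError("no datasets to concatenate")
    return Dataset(
        images=np.concatenate([d.images for d in datasets]),
        motion=np.concatenate([d.motion for d in datasets]),
        time_to_ic=np.concatenate([d.time_to_ic for d in datasets]),
        future_angles=np.concatenate([d.future_angles for d in datasets]),
        anchors=np.concatenate([d.anchors for d in datasets]),
        heel_strikes=datasets[0].heel_strikes,
        horizons=datasets[0].horizons,
    )
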