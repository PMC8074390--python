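"""Synthetic treadmill-gait recordings with synergy-structured sEMG.

The generator emulates the statistical structure the downstream pipeline
assumes: nine muscle channels whose amplitude envelopes are a non-negative
rank-``r`` combination of gait-phase-locked synergy activations, multiplied
by band-limited zero-mean stochastic carriers; a smooth two-peak periodic
knee-angle trajectory phase-locked to heel strikes; and sagittal-plane thigh
and shank angular velocity / acceleration channels derived from smooth
periodic segment templates.  Distribution-shift knobs (per-channel amplitude
gain, carrier spectral compression, envelope jitter) stand in for muscle
fatigue and inter-subject anatomical difference: fatigue raises sEMG
amplitude and lowers its frequency content.

Sampling rates are the exact rationals 10000/9 Hz (sEMG, 0.9 ms interval)
and 4000/27 Hz (IMU/footswitch, 6.75 ms interval); 15 sEMG samples and
2 IMU samples both span 13.5 ms, the least common multiple of the two
sampling intervals.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

SEMG_RATE = 10000.0 / 9.0  # 1111.111... Hz
IMU_RATE = 4000.0 / 27.0  # 148.148... Hz

CHANNEL_NAMES = ["RF", "VM", "VL", "TA", "SOL", "SEM", "BF", "MG", "LG"]

#: gait-phase centres and widths of the five synergy activation bursts
_SYNERGY_CENTERS = np.array([0.05, 0.25, 0.50, 0.70, 0.90])
_SYNERGY_WIDTHS = np.array([0.06, 0.09, 0.10, 0.07, 0.06])
_TONIC_LEVEL = 0.05  # baseline activation shared by every synergy time-course


@dataclass(frozen=True)
class GaitParams:
    """Configuration of one synthetic walking recording."""

    n_channels: int = 9
    semg_rate: float = SEMG_RATE
    imu_rate: float = IMU_RATE
    cycle_period_mean: float = 1.1  # seconds per gait cycle
    cycle_period_cv: float = 0.03  # lognormal multiplicative jitter
    n_synergies: int = 5
    duration: float = 30.0  # seconds
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.semg_rate <= 0 or self.imu_rate <= 0:
            raise ValueError("duration and sampling rates must be positive")
        if self.duration < 3 * self.cycle_period_mean:
            raise ValueError("duration must cover at least 3 gait cycles")
        if self.n_synergies > self.n_channels:
            raise ValueError("n_synergies cannot exceed n_channels")


@dataclass(frozen=True)
class ShiftParams:
    """Distribution-shift knobs applied on top of a base recording.

    ``amplitude_gain`` scales each channel (scalar or per-channel vector);
    ``spectral_compression`` in (0, 1] scales the carrier band edges downward,
    emulating the spectral slowing of fatigue; ``envelope_jitter`` adds
    per-cycle lognormal variability to each synergy's burst amplitude;
    ``channel_swap`` exchanges the listed channel pairs, emulating an
    electrode-placement (muscle-to-channel mapping) change.
    """

    amplitude_gain: float | np.ndarray = 1.0
    spectral_compression: float = 1.0
    envelope_jitter: float = 0.0
    channel_swap: tuple = ()

    def __post_init__(self):
        if np.any(np.asarray(self.amplitude_gain) <= 0):
            raise ValueError("amplitude gains must be positive")
        if not (0.0 < self.spectral_compression <= 1.0):
            raise ValueError("spectral_compression must lie in (0, 1]")
        flat = [c for pair in self.channel_swap for c in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("channel_swap pairs must be disjoint")


@dataclass
class Recording:
    """Synchronised multi-rate gait streams.

    ``semg`` is (channels, n_semg) in mV; the five motion channels are at IMU
    rate; ``heel_strikes`` are strictly increasing IMU sample indices.
    """

    semg: np.ndarray
    angle: np.ndarray  # knee flexion, degrees
    thigh_omega: np.ndarray  # deg/s
    shank_omega: np.ndarray  # deg/s
    thigh_acc: np.ndarray  # m/s^2
    shank_acc: np.ndarray  # m/s^2
    heel_strikes: np.ndarray  # IMU sample indices
    semg_rate: float = SEMG_RATE
    imu_rate: float = IMU_RATE
    channel_names: list[str] = field(default_factory=lambda: list(CHANNEL_NAMES))

    @property
    def n_semg_samples(self) -> int:
        return self.semg.shape[1]

    @property
    def n_imu_samples(self) -> int:
        return self.angle.shape[0]

    def motion_matrix(self) -> np.ndarray:
        """(n_imu, 5) matrix: [angle, thigh w, shank w, thigh a, shank a]."""
        return np.column_stack(
            [self.angle, self.thigh_omega, self.shank_omega, self.thigh_acc, self.shank_acc]
        )


@dataclass
class SynergyTruth:
    """Ground-truth factors used to build the envelopes: V ≈ W · H."""

    W: np.ndarray  # (n_samples, r) synergy activations over time
    H: np.ndarray  # (r, n_channels) synergy weights


def _cycle_onsets(rng: np.random.Generator, params: GaitParams) -> np.ndarray:
    """Heel-strike instants (seconds), first at t = 0, covering the duration."""
    sigma = np.sqrt(np.log(1.0 + params.cycle_period_cv**2))
    onsets = [0.0]
    while onsets[-1] <= params.duration:
        period = params.cycle_period_mean * rng.lognormal(-0.5 * sigma**2, sigma)
        onsets.append(onsets[-1] + period)
    return np.asarray(onsets)


def _phase(t: np.ndarray, onsets: np.ndarray):
    """Fractional gait phase in [0, 1) and cycle index for each time."""
    idx = np.searchsorted(onsets, t, side="right") - 1
    idx = np.clip(idx, 0, len(onsets) - 2)
    periods = np.diff(onsets)
    phase = (t - onsets[idx]) / periods[idx]
    return np.clip(phase, 0.0, 1.0 - 1e-9), idx


def _ground_truth_weights(rng: np.random.Generator, params: GaitParams) -> np.ndarray:
    """Non-negative synergy-weight matrix H (r × m) with distinct dominant muscles."""
    r, m = params.n_synergies, params.n_channels
    h = 0.08 * rng.random((r, m))
    for k in range(r):
        dominant = [(2 * k) % m, (2 * k + 1) % m]
        h[k, dominant] += 1.0 + 0.3 * rng.random(len(dominant))
    return h


def _activation_curves(phase: np.ndarray, cycle_idx: np.ndarray, r: int,
                       jitter: np.ndarray | None) -> np.ndarray:
    """Synergy activation time-courses W (n × r): tonic level + phase bump."""
    w = np.empty((phase.shape[0], r))
    for k in range(r):
        d = phase - _SYNERGY_CENTERS[k]
        d -= np.round(d)  # circular distance in phase
        burst = np.exp(-0.5 * (d / _SYNERGY_WIDTHS[k]) ** 2)
        if jitter is not None:
            burst = burst * jitter[k][cycle_idx]
        w[:, k] = _TONIC_LEVEL + burst
    return w


def _bandlimited_carrier(rng: np.random.Generator, n_channels: int, n: int,
                         rate: float, compression: float) -> np.ndarray:
    """Unit-RMS zero-mean noise band-passed to (20, 450) Hz × compression."""
    lo, hi = 20.0 * compression, 450.0 * compression
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    white = rng.standard_normal((n_channels, n))
    x = signal.sosfilt(sos, white, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / rms


def _knee_angle_template(phase: np.ndarray) -> np.ndarray:
    """Two-peak knee flexion profile (degrees): stance bump + swing peak."""
    out = np.full_like(phase, 4.0)
    for center, width, amp in [(0.15, 0.10, 16.0), (0.72, 0.09, 56.0)]:
        d = phase - center
        d -= np.round(d)
        out += amp * np.exp(-0.5 * (d / width) ** 2)
    return out


def _segment_templates(phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal thigh and shank angle profiles (degrees)."""
    tau = 2 * np.pi * phase
    thigh = 20.0 * np.cos(tau - 0.3) + 5.0
    shank = 30.0 * np.cos(tau - 1.1) - 8.0 * np.cos(2 * tau - 0.4)
    return thigh, shank


def generate_recording(params: GaitParams, shift: ShiftParams | None = None) -> Recording:
    """Generate one synthetic gait recording.

    Identical ``params`` (including the seed) produce bit-identical output;
    ``shift`` never alters the random draws, so shifted and unshifted
    recordings from the same seed share carriers and gait timing.
    """
    shift = shift or ShiftParams()
    rng = np.random.default_rng(params.seed)
    h_true = _ground_truth_weights(rng, params)
    onsets = _cycle_onsets(rng, params)

    n_semg = round(params.duration * params.semg_rate)
    n_imu = round(params.duration * params.imu_rate)
    t_semg = np.arange(n_semg) / params.semg_rate
    t_imu = np.arange(n_imu) / params.imu_rate

    phase_s, cyc_s = _phase(t_semg, onsets)
    jitter = None
    if shift.envelope_jitter > 0:
        sig = np.sqrt(np.log(1.0 + shift.envelope_jitter**2))
        jitter = rng.lognormal(-0.5 * sig**2, sig, size=(params.n_synergies, len(onsets)))
    else:
        # keep the stream position identical whether or not jitter is on
        rng.lognormal(0.0, 1.0, size=(params.n_synergies, len(onsets)))
    w_acts = _activation_curves(phase_s, cyc_s, params.n_synergies, jitter)
    envelopes = (w_acts @ h_true).T  # (channels, n_semg), non-negative rank ≤ r

    carrier = _bandlimited_carrier(rng, params.n_channels, n_semg, params.semg_rate,
                                   shift.spectral_compression)
    gain = np.broadcast_to(np.atleast_1d(np.asarray(shift.amplitude_gain, dtype=float)),
                           (params.n_channels,))
    semg = 0.5 * envelopes * carrier  # ~mV scale
    for i, j in shift.channel_swap:  # electrode remapping, then electrode gains
        semg[[i, j]] = semg[[j, i]]
    semg = gain[:, None] * semg

    phase_i, _ = _phase(t_imu, onsets)
    angle = _knee_angle_template(phase_i) + 0.2 * rng.standard_normal(n_imu)
    thigh, shank = _segment_templates(phase_i)
    dt = 1.0 / params.imu_rate
    thigh_omega = np.gradient(thigh, dt) + 2.0 * rng.standard_normal(n_imu)
    shank_omega = np.gradient(shank, dt) + 2.0 * rng.standard_normal(n_imu)
    # segment accelerations from the angle templates (pendulum-like scaling)
    thigh_acc = 0.01 * np.gradient(np.gradient(thigh, dt), dt) + 0.2 * rng.standard_normal(n_imu)
    shank_acc = 0.012 * np.gradient(np.gradient(shank, dt), dt) + 0.2 * rng.standard_normal(n_imu)

    strikes = np.round(onsets * params.imu_rate).astype(int)
    strikes = strikes[(strikes >= 0) & (strikes < n_imu)]

    return Recording(
        semg=semg,
        angle=angle,
        thigh_omega=thigh_omega,
        shank_omega=shank_omega,
        thigh_acc=thigh_acc,
        shank_acc=shank_acc,
        heel_strikes=strikes,
        semg_rate=params.semg_rate,
        imu_rate=params.imu_rate,
    )


def true_synergies(params: GaitParams) -> SynergyTruth:
    """Ground-truth factors (W, H) behind :func:`generate_recording` envelopes."""
    rng = np.random.default_rng(params.seed)
    h_true = _ground_truth_weights(rng, params)
    onsets = _cycle_onsets(rng, params)
    n_semg = round(params.duration * params.semg_rate)
    t_semg = np.arange(n_semg) / params.semg_rate
    phase_s, cyc_s = _phase(t_semg, onsets)
    w_acts = _activation_curves(phase_s, cyc_s, params.n_synergies, None)
    return SynergyTruth(W=w_acts, H=h_true)


# ---------------------------------------------------------------------------
# plain-text round trip
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, directory: str | Path) -> None:
    """Write a recording as one TSV per stream plus a JSON metadata file."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "semg.tsv", rec.semg.T, delimiter="\t",
               header="\t".join(rec.channel_names), comments="")
    motion = rec.motion_matrix()
    np.savetxt(d / "motion.tsv", motion, delimiter="\t",
               header="angle\tthigh_omega\tshank_omega\tthigh_acc\tshank_acc", comments="")
    np.savetxt(d / "heel_strikes.tsv", rec.heel_strikes[:, None], fmt="%d",
               header="imu_index", comments="")
    meta = {
        "semg_rate": rec.semg_rate,
        "imu_rate": rec.imu_rate,
        "channel_names": rec.channel_names,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def read_recording(directory: str | Path) -> Recording:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    semg = np.loadtxt(d / "semg.tsv", delimiter="\t", skiprows=1).T
    motion = np.loadtxt(d / "motion.tsv", delimiter="\t", skiprows=1)
    strikes = np.loadtxt(d / "heel_strikes.tsv", dtype=int, skiprows=1).reshape(-1)
    return Recording(
        semg=semg,
        angle=motion[:, 0],
        thigh_omega=motion[:, 1],
        shank_omega=motion[:, 2],
        thigh_acc=motion[:, 3],
        shank_acc=motion[:, 4],
        heel_strikes=strikes,
        semg_rate=meta["semg_rate"],
        imu_rate=meta["imu_rate"],
        channel_names=list(meta["channel_names"]),
    )


def make_subject_params(subject: int, base_seed: int, duration: float = 30.0,
                        **overrides) -> tuple[GaitParams, ShiftParams]:
    """Study-population helper: per-subject gait statistics and channel gains.

    Each synthetic subject differs in cycle period, per-channel electrode
    gains and envelope variability — the between-subject factors that make
    inter-subject generalisation hard for sEMG models.
    """
    rng = np.random.default_rng(np.uint32(base_seed * 1013 + subject * 7919))
    params = GaitParams(
        cycle_period_mean=float(rng.uniform(1.0, 1.2)),
        cycle_period_cv=0.03,
        duration=duration,
        seed=int(rng.integers(0, 2**31 - 1)),
        **overrides,
    )
    gains = rng.lognormal(0.0, 0.15, size=params.n_channels)
    shift = ShiftParams(amplitude_gain=gains)
    return params, shift
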