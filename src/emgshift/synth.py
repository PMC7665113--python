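"""Synthetic bracelet-sEMG generator.

Emulates the statistical structure the recognition method relies on,
without claiming biophysical realism:

* each gesture has a characteristic *spatial* energy distribution over
  the 8 pods, modelled as a circular Gaussian gain centred on the
  gesture's anatomical locus;
* within a 5 s repetition the activity is one smooth burst (trapezoid
  with raised-cosine ramps) flanked by rest, mirroring recordings that
  start and end in the relax position;
* the carrier is band-limited (20-90 Hz) zero-mean Gaussian noise —
  a standard amplitude-modulated-noise surrogate for surface EMG at a
  200 Hz sampling rate;
* baseline sensor noise is added at a configurable SNR, and a donning
  rotation is a circular shift of the channel rows.

Ground truth is the interval where the envelope exceeds 10% of its
peak, which makes the otherwise-manual segmentation reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .types import (
    CANONICAL_LENGTH,
    N_PODS,
    SAMPLE_RATE,
    CLASS_ORDER,
    EmgRecording,
    GestureClass,
    wrap_pod,
)

log = logging.getLogger(__name__)

#: admissible simulated donning rotations (45-degree steps, half turn each way)
ROTATION_OFFSETS: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3, 4)

#: default signal-to-noise ratio of the synthetic sensor, dB
DEFAULT_SNR_DB = 15.0

#: reference amplitude used to scale the baseline noise floor so rest
#: segments look alike across classes (including the relax class)
_NOISE_REF_AMPLITUDE = 0.6

_CARRIER_BAND_HZ = (20.0, 90.0)


@dataclass(frozen=True)
class GestureProfile:
    """Spatial/temporal signature of one gesture class."""

    gesture: GestureClass
    center_pod: int
    spread: float  # circular-Gaussian width, in pods
    amplitude: float  # peak normalized amplitude, (0, 1]; 0 for relax
    duration_s: float  # active-burst length, seconds

    def __post_init__(self) -> None:
        if not 1 <= self.center_pod <= N_PODS:
            raise ValueError(f"center_pod must be in 1..8, got {self.center_pod}")
        if self.amplitude < 0 or self.amplitude > 1:
            raise ValueError(f"amplitude must be in [0, 1], got {self.amplitude}")
        if self.spread <= 0:
            raise ValueError("spread must be positive")

    def pod_gains(self) -> np.ndarray:
        """Circular-Gaussian gain per pod, peak 1 at ``center_pod``."""
        pods = np.arange(1, N_PODS + 1)
        d = np.abs(pods - self.center_pod)
        d = np.minimum(d, N_PODS - d)  # circular distance, 0..4
        return np.exp(-(d**2) / (2 * self.spread**2))


#: Default gesture profiles.  Loci are distinct so the spatial pattern
#: carries class information; waveOut (the synchronization gesture) has
#: the sharpest, strongest locus so its peak pod dominates the energy
#: at that pod over every other profile.
DEFAULT_PROFILES: dict[GestureClass, GestureProfile] = {
    GestureClass.WAVE_OUT: GestureProfile(GestureClass.WAVE_OUT, 4, 0.8, 0.90, 2.5),
    GestureClass.WAVE_IN: GestureProfile(GestureClass.WAVE_IN, 8, 1.0, 0.70, 2.5),
    GestureClass.FIST: GestureProfile(GestureClass.FIST, 2, 1.6, 0.60, 2.5),
    GestureClass.OPEN: GestureProfile(GestureClass.OPEN, 6, 2.0, 0.60, 2.5),
    GestureClass.PINCH: GestureProfile(GestureClass.PINCH, 7, 1.2, 0.45, 2.5),
    GestureClass.NO_GESTURE: GestureProfile(GestureClass.NO_GESTURE, 1, 1.0, 0.0, 0.0),
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _bandlimited_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to the sEMG band (20-90 Hz)."""
    white = rng.standard_normal(shape)
    lo, hi = _CARRIER_BAND_HZ
    b, a = butter(4, [lo, hi], btype="band", fs=SAMPLE_RATE)
    shaped = filtfilt(b, a, white, axis=-1)
    rms = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    return shaped / np.maximum(rms, 1e-30)


def _burst_envelope(n: int, duration_s: float, center_s: float, ramp_s: float = 0.3) -> np.ndarray:
    """Trapezoidal envelope with raised-cosine ramps, peak 1."""
    if duration_s <= 0:
        return np.zeros(n)
    t = np.arange(n) / SAMPLE_RATE
    start = center_s - duration_s / 2
    stop = center_s + duration_s / 2
    ramp = min(ramp_s, duration_s / 2)
    env = np.zeros(n)
    rising = (t >= start) & (t < start + ramp)
    env[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - start) / ramp))
    env[(t >= start + ramp) & (t <= stop - ramp)] = 1.0
    falling = (t > stop - ramp) & (t <= stop)
    env[falling] = 0.5 * (1 - np.cos(np.pi * (stop - t[falling]) / ramp))
    return env


def generate_repetition(
    profile: GestureProfile,
    noise_snr_db: float = DEFAULT_SNR_DB,
    seed: int | np.random.Generator = 0,
    user_id: str = "user1",
    repetition_id: str = "rep1",
    n_samples: int = CANONICAL_LENGTH,
    gain: float = 1.0,
) -> EmgRecording:
    """One 5 s, 8-channel synthetic repetition of ``profile``'s gesture.

    ``gain`` is a multiplicative amplitude factor used to emulate
    inter-user and inter-repetition variability.
    """
    if 10 ** (noise_snr_db / 20) <= 0:
        raise ValueError("SNR must be positive in linear scale")
    rng = _as_rng(seed)
    amp = profile.amplitude * gain
    center_s = n_samples / SAMPLE_RATE / 2 + rng.uniform(-0.15, 0.15)
    env = _burst_envelope(n_samples, profile.duration_s, center_s)
    carrier = _bandlimited_noise(rng, (N_PODS, n_samples))
    gains = profile.pod_gains()
    signal = amp * gains[:, None] * env[None, :] * carrier
    noise_std = _NOISE_REF_AMPLITUDE * 10 ** (-noise_snr_db / 20)
    noise = noise_std * _bandlimited_noise(rng, (N_PODS, n_samples))
    samples = np.clip(signal + noise, -1.0, 1.0)

    active = env > 0.1 * env.max() if env.max() > 0 else np.zeros(n_samples, bool)
    if active.any():
        idx = np.flatnonzero(active)
        ground_truth = (int(idx[0]), int(idx[-1]) + 1)
    else:
        ground_truth = (0, 0)
    return EmgRecording(
        samples=samples,
        label=profile.gesture,
        ground_truth=ground_truth,
        user_id=user_id,
        repetition_id=repetition_id,
    )


def draw_rotation_offset(seed: int | np.random.Generator) -> int:
    """Uniform draw from the 8 simulated donning rotations."""
    rng = _as_rng(seed)
    return int(rng.choice(ROTATION_OFFSETS))


def apply_simulated_rotation(rec: EmgRecording, r: int) -> EmgRecording:
    """Circularly shift the channel rows to simulate a donning rotation.

    Output channel ``i`` carries input pod ``wrap(i + r)``; the label
    and ground truth are untouched (rotation moves electrodes, not the
    gesture).
    """
    if r not in ROTATION_OFFSETS:
        raise ValueError(f"rotation offset must be in {ROTATION_OFFSETS}, got {r}")
    rows = np.array([wrap_pod(i + r) - 1 for i in range(1, N_PODS + 1)])
    return replace(rec, samples=rec.samples[rows].copy())


def generate_user_dataset(
    n_users: int,
    reps_per_gesture: int,
    seed: int = 0,
    noise_snr_db: float = DEFAULT_SNR_DB,
    profiles: dict[GestureClass, GestureProfile] | None = None,
    user_gain_sigma: float = 0.15,
    rep_gain_sigma: float = 0.05,
) -> dict[str, list[EmgRecording]]:
    """Per-user synthetic datasets: 6 classes x ``reps_per_gesture`` each.

    Each user gets an independent random stream spawned from ``seed``,
    so user k's recordings do not depend on ``n_users``.  Inter-user
    variability is a log-normal per-user amplitude gain; repetitions
    add a smaller per-repetition gain jitter.
    """
    if n_users < 1 or reps_per_gesture < 1:
        raise ValueError("n_users and reps_per_gesture must be >= 1")
    profiles = profiles or DEFAULT_PROFILES
    streams = np.random.SeedSequence(seed).spawn(n_users)
    out: dict[str, list[EmgRecording]] = {}
    for u, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        user_id = f"user{u:03d}"
        user_gain = float(np.exp(rng.normal(0.0, user_gain_sigma)))
        recs: list[EmgRecording] = []
        for gesture in CLASS_ORDER:
            prof = profiles[gesture]
            for p in range(1, reps_per_gesture + 1):
                rep_gain = user_gain * float(np.exp(rng.normal(0.0, rep_gain_sigma)))
                recs.append(
                    generate_repetition(
                        prof,
                        noise_snr_db=noise_snr_db,
                        seed=rng,
                        user_id=user_id,
                        repetition_id=f"{gesture.value}-{p:03d}",
                        gain=min(rep_gain, 1.0 / max(prof.amplitude, 1e-9)),
                    )
                )
        out[user_id] = recs
    log.info("generated %d users x %d recordings", n_users, 6 * reps_per_gesture)
    return out


def generate_sync_repetitions(
    T: int,
    seed: int | np.random.Generator,
    user_id: str = "user1",
    noise_snr_db: float = DEFAULT_SNR_DB,
    profiles: dict[GestureClass, GestureProfile] | None = None,
    gain: float = 1.0,
) -> list[EmgRecording]:
    """T waveOut repetitions to be used as synchronization signals."""
    profiles = profiles or DEFAULT_PROFILES
    rng = _as_rng(seed)
    prof = profiles[GestureClass.WAVE_OUT]
    return [
        generate_repetition(
            prof,
            noise_snr_db=noise_snr_db,
            seed=rng,
            user_id=user_id,
            repetition_id=f"sync-{j:02d}",
            gain=gain,
        )
        for j in range(1, T + 1)
    ]
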