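"""Maximum-energy-channel (MEC) orientation calibration.

Bracelet sEMG sensors can be donned at any rotation, which circularly
permutes which muscle each pod sees and destroys a classifier trained
at a different rotation.  The correction calibrates at donning time:
the user performs the synchronization gesture (waveOut) T times; the
per-pod signal energy of a 200-sample active window is averaged over
the T repetitions; the pod with the maximum mean energy anchors a new
circular channel order that starts there.  Training and testing both
operate on the rearranged channels, so the pipeline becomes invariant
to the donning rotation (up to the pod resolution of 45 degrees).

Calibration also fixes the two window-gating thresholds: the
rearranged pods are split into ``group_high`` (new positions 1-4, the
pods the synchronization gesture activates) and ``group_low``
(positions 5-8); each threshold is ``energy_fraction`` (default 17%)
of the group's mean calibration energy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import channel_energies, signal_energy
from .types import N_PODS, EmgRecording, GestureClass, PodOrder, wrap_pod

log = logging.getLogger(__name__)

SYNC_GESTURE = GestureClass.WAVE_OUT
SYNC_WINDOW_LEN = 200


class DegenerateCalibrationError(ValueError):
    """All calibration energies are zero: no identifiable MEC."""


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one donning-time calibration."""

    sx: int
    pod_order: PodOrder
    mean_energies: np.ndarray  # per pod, original order
    th_high: float
    th_low: float
    T: int

    def to_dict(self) -> dict:
        return {
            "sx": self.sx,
            "pod_order": list(self.pod_order.order),
            "mean_energies": [float(e) for e in self.mean_energies],
            "th_high": self.th_high,
            "th_low": self.th_low,
            "T": self.T,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationResult":
        d = json.loads(Path(path).read_text())
        return cls(
            sx=d["sx"],
            pod_order=PodOrder(tuple(d["pod_order"])),
            mean_energies=np.asarray(d["mean_energies"], dtype=float),
            th_high=d["th_high"],
            th_low=d["th_low"],
            T=d["T"],
        )


def channel_energy(x: np.ndarray) -> float:
    """Energy of one channel (shared with the feature stage)."""
    return signal_energy(x)


def sync_window(rec: EmgRecording, window_len: int = SYNC_WINDOW_LEN) -> np.ndarray:
    """The 200-sample calibration window of a synchronization repetition.

    Taken at the ground-truth onset (clipped so the window fits), which
    places it on the muscle burst deterministically.
    """
    on = rec.ground_truth[0]
    start = min(on, rec.n_samples - window_len)
    if start < 0:
        raise ValueError(f"recording too short for a {window_len}-sample sync window")
    return rec.samples[:, start : start + window_len]


def mean_sync_energies(sync_reps: Sequence[EmgRecording]) -> np.ndarray:
    """Mean per-pod energy over the T synchronization repetitions."""
    T = len(sync_reps)
    if not 1 <= T <= 4:
        raise ValueError(f"sync repetition count must be in [1, 4], got {T}")
    return np.mean([channel_energies(sync_window(r)) for r in sync_reps], axis=0)


def mean_sync_energy(sync_reps: Sequence[EmgRecording], pod: int) -> float:
    """Mean energy of a single pod over the sync repetitions."""
    if not 1 <= pod <= N_PODS:
        raise ValueError(f"pod index must be in 1..8, got {pod}")
    return float(mean_sync_energies(sync_reps)[pod - 1])


def find_max_energy_channel(mean_energies: np.ndarray) -> int:
    """Pod index of the maximum mean energy; ties break to the lowest pod."""
    e = np.asarray(mean_energies, dtype=float)
    if e.shape != (N_PODS,):
        raise ValueError(f"expected {N_PODS} energies, got shape {e.shape}")
    if np.any(np.isnan(e)):
        raise ValueError("mean energies contain NaN")
    return int(np.argmax(e)) + 1  # argmax returns the first (lowest) index on ties


def rearrange_channels(sx: int) -> PodOrder:
    """Circular pod order starting at the maximum-energy channel."""
    return PodOrder.starting_at(sx)


def calibrate(
    sync_reps: Sequence[EmgRecording],
    energy_fraction: float = 0.17,
    rearrange: bool = True,
) -> CalibrationResult:
    """Full donning-time calibration from T waveOut repetitions.

    With ``rearrange=False`` the pod order is left as the identity
    (used by pipelines that gate on energy but skip orientation
    correction); the gating thresholds are then computed over the
    un-rearranged pod grouping.
    """
    energies = mean_sync_energies(sync_reps)
    if np.all(energies == 0):
        raise DegenerateCalibrationError("all-zero sync energies: no identifiable MEC")
    sx = find_max_energy_channel(energies)
    order = rearrange_channels(sx) if rearrange else PodOrder.identity()
    arranged = energies[order.as_row_index()]
    th_high = energy_fraction * float(np.mean(arranged[:4]))
    th_low = energy_fraction * float(np.mean(arranged[4:]))
    log.info(
        "calibration: T=%d sx=%d order=%s th_high=%.4g th_low=%.4g",
        len(sync_reps), sx, order.order, th_high, th_low,
    )
    return CalibrationResult(
        sx=sx,
        pod_order=order,
        mean_energies=energies,
        th_high=th_high,
        th_low=th_low,
        T=len(sync_reps),
    )
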