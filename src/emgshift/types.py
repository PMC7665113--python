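"""Domain types for bracelet sEMG gesture recognition.

The recording model follows the structure of commercial 8-pod EMG
bracelets: 8 differential channels sampled at 200 Hz, 5 s per gesture
repetition, amplitudes normalized to [-1, 1].  Channels ("pods") are
indexed 1..8 around the forearm, so channel arithmetic is circular.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

N_PODS = 8
SAMPLE_RATE = 200
CANONICAL_LENGTH = 1000  # 5 s at 200 Hz


class GestureClass(str, enum.Enum):
    """The six gesture classes; ``noGesture`` is the relax / reject class."""

    WAVE_IN = "waveIn"
    WAVE_OUT = "waveOut"
    FIST = "fist"
    OPEN = "open"
    PINCH = "pinch"
    NO_GESTURE = "noGesture"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical class order used for confusion matrices and reports.
CLASS_ORDER: tuple[GestureClass, ...] = (
    GestureClass.WAVE_IN,
    GestureClass.WAVE_OUT,
    GestureClass.FIST,
    GestureClass.OPEN,
    GestureClass.PINCH,
    GestureClass.NO_GESTURE,
)

#: The five active gesture classes (everything except the relax state).
ACTIVE_CLASSES: tuple[GestureClass, ...] = tuple(
    c for c in CLASS_ORDER if c is not GestureClass.NO_GESTURE
)


def wrap_pod(p: int) -> int:
    """Map any integer onto the circular 1-based pod index range 1..8."""
    return (int(p) - 1) % N_PODS + 1


@dataclass(frozen=True)
class PodOrder:
    """A circular permutation of the 8 pod indices.

    A pod order is fully determined by its starting pod: position ``i``
    holds ``wrap(start + i)``.  Rearranging a recording by a pod order
    makes the starting pod the new channel 1.
    """

    order: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.order) != N_PODS or sorted(self.order) != list(range(1, N_PODS + 1)):
            raise ValueError(f"pod order must be a permutation of 1..8, got {self.order}")
        for i in range(N_PODS - 1):
            if self.order[i + 1] != wrap_pod(self.order[i] + 1):
                raise ValueError(f"pod order must be circular, got {self.order}")

    @classmethod
    def identity(cls) -> "PodOrder":
        return cls(tuple(range(1, N_PODS + 1)))

    @classmethod
    def starting_at(cls, sx: int) -> "PodOrder":
        if not 1 <= sx <= N_PODS:
            raise ValueError(f"start pod must be in 1..8, got {sx}")
        return cls(tuple(wrap_pod(sx + i) for i in range(N_PODS)))

    @property
    def start(self) -> int:
        return self.order[0]

    def as_row_index(self) -> np.ndarray:
        """0-based row index that rearranges an 8 x L sample matrix."""
        return np.asarray(self.order, dtype=int) - 1


@dataclass
class EmgRecording:
    """One 5 s, 8-channel gesture repetition.

    ``ground_truth`` is the half-open sample interval ``[on, off)`` of
    muscle activity (0-based); it is empty (``on == off``) exactly for
    the relax class.
    """

    samples: np.ndarray
    label: GestureClass
    ground_truth: tuple[int, int]
    user_id: str
    repetition_id: str
    rate: int = SAMPLE_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.label = GestureClass(self.label)
        self.ground_truth = (int(self.ground_truth[0]), int(self.ground_truth[1]))
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[0] != N_PODS:
            raise ValueError(
                f"samples must be 8 x L, got shape {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.samples.min() < -1.0 or self.samples.max() > 1.0:
            raise ValueError("samples must lie in [-1, 1]")
        on, off = self.ground_truth
        if not (0 <= on <= off <= self.n_samples):
            raise ValueError(f"ground truth {self.ground_truth} outside [0, {self.n_samples}]")
        empty = on == off
        if empty != (self.label is GestureClass.NO_GESTURE):
            raise ValueError(
                "ground truth must be empty exactly for the relax class "
                f"(label={self.label.value}, interval={self.ground_truth})"
            )

    # -- convenience --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def gt_empty(self) -> bool:
        return self.ground_truth[0] == self.ground_truth[1]

    def gt_mask(self) -> np.ndarray:
        """Boolean activity mask of length L derived from the interval."""
        mask = np.zeros(self.n_samples, dtype=bool)
        on, off = self.ground_truth
        mask[on:off] = True
        return mask

    def rearranged(self, order: PodOrder) -> "EmgRecording":
        """Return a copy whose channel ``i`` is pod ``order[i]`` of ``self``."""
        return replace(self, samples=self.samples[order.as_row_index()].copy())


@dataclass(frozen=True)
class LabeledWindow:
    """A 200-sample analysis window cut from a recording."""

    start: int
    window: np.ndarray  # 8 x window_len view
    label: GestureClass

    @property
    def length(self) -> int:
        return self.window.shape[1]

    @property
    def stop(self) -> int:
        return self.start + self.length
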