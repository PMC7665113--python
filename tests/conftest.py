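"""Shared fixtures: small seeded synthetic objects used across modules."""

from __future__ import annotations

import numpy as np
import pytest

from emgshift import (
    CalibrationResult,
    EmgRecording,
    GestureClass,
    PipelineConfig,
    calibrate,
    generate_repetition,
    generate_sync_repetitions,
)
from emgshift.synth import DEFAULT_PROFILES


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def sync_reps() -> list[EmgRecording]:
    """Four seeded waveOut synchronization repetitions."""
    return generate_sync_repetitions(4, seed=7, noise_snr_db=15)


@pytest.fixture(scope="session")
def calibration(sync_reps) -> CalibrationResult:
    return calibrate(sync_reps)


@pytest.fixture(scope="session")
def fist_recording() -> EmgRecording:
    return generate_repetition(DEFAULT_PROFILES[GestureClass.FIST], 15, seed=99)


@pytest.fixture(scope="session")
def relax_recording() -> EmgRecording:
    return generate_repetition(DEFAULT_PROFILES[GestureClass.NO_GESTURE], 15, seed=11)


def make_recording(
    samples: np.ndarray,
    label: GestureClass = GestureClass.WAVE_OUT,
    ground_truth: tuple[int, int] | None = None,
    user_id: str = "u1",
    repetition_id: str = "r1",
) -> EmgRecording:
    """Hand-built recording with a sensible default ground truth."""
    if ground_truth is None:
        n = samples.shape[1]
        ground_truth = (0, 0) if label is GestureClass.NO_GESTURE else (0, min(200, n))
    return EmgRecording(
        samples=samples,
        label=label,
        ground_truth=ground_truth,
        user_id=user_id,
        repetition_id=repetition_id,
    )
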