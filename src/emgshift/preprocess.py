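"""Sliding-window extraction and per-group energy gating.

Training uses 7 windows of 200 samples at stride 25 anchored at the
ground-truth onset (recording start for the relax class), so the
windows sit on the muscle burst.  Testing slides a 200-sample window
at stride 20 from sample 0 (41 windows over a 5 s repetition).

Before classification every window must pass an energy gate: its mean
channel energy over the rearranged ``group_high`` pods (positions 1-4)
or over ``group_low`` (positions 5-8) must reach the calibrated
threshold for that group.  Windows that fail are assigned the relax
label without being classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .features import channel_energies
from .orientation import CalibrationResult
from .types import EmgRecording, GestureClass, LabeledWindow


@dataclass(frozen=True)
class GateDecision:
    passed: bool
    e_high: float
    e_low: float


def slide_windows(
    rec: EmgRecording,
    window_len: int = 200,
    stride: int = 20,
    anchor: int = 0,
    count: int | None = None,
) -> list[LabeledWindow]:
    """Windows of ``window_len`` samples at ``stride``, starting at ``anchor``.

    With ``count`` given, at most that many windows are produced; the
    sequence always stops before a window would cross the recording
    end (no partial windows).
    """
    L = rec.n_samples
    if anchor < 0 or anchor + window_len > L:
        raise ValueError(f"anchor {anchor} leaves no room for a {window_len}-sample window")
    n_fit = (L - window_len - anchor) // stride + 1
    n = n_fit if count is None else min(count, n_fit)
    return [
        LabeledWindow(
            start=anchor + k * stride,
            window=rec.samples[:, anchor + k * stride : anchor + k * stride + window_len],
            label=rec.label,
        )
        for k in range(n)
    ]


def training_windows(rec: EmgRecording, cfg: PipelineConfig) -> list[LabeledWindow]:
    """The 7 training windows of a repetition, anchored on the activity.

    The anchor is the ground-truth onset (0 for the relax class),
    pulled back if needed so all 7 windows fit in the recording.
    """
    span = (cfg.windows_per_rep - 1) * cfg.train_stride + cfg.window_len
    anchor = 0 if rec.gt_empty else rec.ground_truth[0]
    anchor = max(0, min(anchor, rec.n_samples - span))
    return slide_windows(
        rec, cfg.window_len, cfg.train_stride, anchor=anchor, count=cfg.windows_per_rep
    )


def evaluation_windows(rec: EmgRecording, cfg: PipelineConfig) -> list[LabeledWindow]:
    """All stride-20 windows of a repetition (41 for a 5 s recording)."""
    return slide_windows(rec, cfg.window_len, cfg.test_stride, anchor=0)


def gate_window(
    win: LabeledWindow, cal: CalibrationResult, group_energy: str = "mean"
) -> GateDecision:
    """Energy gate over the two rearranged pod groups (OR-combined).

    The window must already be rearranged by ``cal.pod_order``.  Group
    statistics are the mean (default) or sum of the four per-channel
    energies; the calibrated thresholds scale accordingly.
    """
    e = channel_energies(win.window)
    if group_energy == "sum":
        e_high, e_low = float(e[:4].sum()), float(e[4:].sum())
        th_high, th_low = 4 * cal.th_high, 4 * cal.th_low
    else:
        e_high, e_low = float(e[:4].mean()), float(e[4:].mean())
        th_high, th_low = cal.th_high, cal.th_low
    return GateDecision(passed=(e_high >= th_high) or (e_low >= th_low), e_high=e_high, e_low=e_low)
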