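"""Post-processing and the strict recognition decision.

Classification asks only *which* gesture a repetition contains;
recognition additionally asks *when*.  The per-window labels (test
stride 20) are smoothed with a mode filter over blocks of four, mapped
onto the sample axis (each window claims its 200-sample span), and the
predicted point set B* is compared against the ground-truth set A*
with the overlap factor

    rho = 2 |A* ∩ B*| / (|A*| + |B*|)

(a Dice coefficient).  A prediction timeline is *valid* only when it
contains exactly one contiguous run of non-relax labels, all with the
same label; a repetition is correctly recognized when the timeline is
valid, the label matches, and rho >= 0.25.  Relax-class repetitions
are correctly recognized exactly when no non-relax segment is
predicted.  Recognition is therefore never easier than classification.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classify import TrainedModel, score_windows, validate_scores
from .config import PipelineConfig
from .features import featurize_matrix
from .orientation import CalibrationResult
from .preprocess import evaluation_windows, gate_window
from .types import EmgRecording, GestureClass

log = logging.getLogger(__name__)


def _block_mode(block: Sequence[GestureClass]) -> GestureClass:
    counts = Counter(block)
    top = max(counts.values())
    tied = {lbl for lbl, c in counts.items() if c == top}
    if len(tied) == 1:
        return next(iter(tied))
    if GestureClass.NO_GESTURE in tied:
        return GestureClass.NO_GESTURE
    for lbl in reversed(list(block)):  # most recent among tied labels
        if lbl in tied:
            return lbl
    raise AssertionError("unreachable")


def mode_filter(
    labels: Sequence[GestureClass], block: int = 4, stride: str = "sliding"
) -> list[GestureClass]:
    """Mode of every ``block`` labels; removes isolated spurious labels.

    ``sliding`` (default) takes the mode over a trailing window ending
    at each position (prefix positions use the partial window), which
    keeps one output label per input window.  ``block`` mode instead
    replaces each non-overlapping block of four by its mode.
    Ties break toward the relax label, then toward the most recent.
    """
    labels = list(labels)
    if not labels:
        return []
    if block < 1:
        raise ValueError("block must be >= 1")
    if stride == "sliding":
        return [_block_mode(labels[max(0, i - block + 1) : i + 1]) for i in range(len(labels))]
    out: list[GestureClass] = []
    for i in range(0, len(labels), block):
        chunk = labels[i : i + block]
        out.extend([_block_mode(chunk)] * len(chunk))
    return out


@dataclass
class LabelTimeline:
    """Per-window labels and their footprint on the sample axis."""

    raw_labels: list[GestureClass]
    filtered_labels: list[GestureClass]
    window_starts: list[int]
    window_len: int
    n_samples: int

    def predicted_mask(self) -> np.ndarray:
        """Boolean mask B*: samples covered by non-relax filtered windows."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for lbl, start in zip(self.filtered_labels, self.window_starts):
            if lbl is not GestureClass.NO_GESTURE:
                mask[start : start + self.window_len] = True
        return mask


def build_label_timeline(
    window_labels: Sequence[GestureClass],
    window_starts: Sequence[int],
    window_len: int = 200,
    n_samples: int | None = None,
    mode_block: int = 4,
    mode_stride: str = "sliding",
) -> LabelTimeline:
    if len(window_labels) != len(window_starts):
        raise ValueError("labels and starts must align")
    starts = [int(s) for s in window_starts]
    if n_samples is None:
        n_samples = (max(starts) + window_len) if starts else 0
    return LabelTimeline(
        raw_labels=list(window_labels),
        filtered_labels=mode_filter(window_labels, mode_block, mode_stride),
        window_starts=starts,
        window_len=window_len,
        n_samples=n_samples,
    )


def _runs(labels: Sequence[GestureClass]) -> list[tuple[int, int]]:
    """Maximal runs [i, j) of consecutive non-relax labels."""
    runs, start = [], None
    for i, lbl in enumerate(labels):
        if lbl is not GestureClass.NO_GESTURE:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(labels)))
    return runs


def is_valid_prediction_vector(tl: LabelTimeline) -> tuple[bool, GestureClass]:
    """Single-segment validity rule and the predicted class.

    Valid iff the filtered labels contain exactly one maximal run of
    non-relax labels and that run is single-labeled (an all-relax
    timeline is valid with the relax prediction).  The returned class
    is the majority non-relax label (used for classification even when
    the timeline is invalid), or the relax class when there is none.
    """
    labels = tl.filtered_labels
    runs = _runs(labels)
    active = [lbl for lbl in labels if lbl is not GestureClass.NO_GESTURE]
    if not active:
        return True, GestureClass.NO_GESTURE
    counts = Counter(active)
    top = max(counts.values())
    predicted = next(lbl for lbl in active if counts[lbl] == top)  # ties: earliest
    valid = len(runs) == 1 and len({labels[i] for i in range(*runs[0])}) == 1
    return valid, predicted


def overlap_factor(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A ∩ B| / (|A| + |B|) between two sample sets."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def recognition_decision(
    valid: bool,
    predicted: GestureClass,
    target: GestureClass,
    rho: float,
    rho_threshold: float = 0.25,
) -> bool:
    """The strict per-repetition recognition rule.

    Gesture targets require a valid single-segment timeline, a label
    match, and an overlap factor reaching the threshold (inclusive).
    Relax targets are correct exactly when nothing non-relax was
    predicted (by construction ``rho`` is 1.0 then, 0.0 otherwise).
    """
    if target is GestureClass.NO_GESTURE:
        return predicted is GestureClass.NO_GESTURE and rho >= 1.0
    return valid and predicted is target and rho >= rho_threshold


@dataclass
class RecognitionResult:
    valid: bool
    predicted: GestureClass
    rho: float
    correct_classification: bool
    correct_recognition: bool
    timeline: LabelTimeline | None = None


def recognize(
    rec: EmgRecording,
    model: TrainedModel,
    cal: CalibrationResult,
    cfg: PipelineConfig,
    keep_timeline: bool = False,
) -> RecognitionResult:
    """Full chain: rearrange, window, gate, featurize, score, validate,
    mode-filter, timeline, validity and overlap."""
    arranged = rec.rearranged(cal.pod_order)
    wins = evaluation_windows(arranged, cfg)
    labels: list[GestureClass | None] = [None] * len(wins)
    feats, idx = [], []
    for i, win in enumerate(wins):
        if gate_window(win, cal, cfg.group_energy).passed:
            feats.append(featurize_matrix(win.window, cfg.ae_reduce))
            idx.append(i)
        else:
            labels[i] = GestureClass.NO_GESTURE
    if feats:
        for i, sv in zip(idx, score_windows(model, np.vstack(feats))):
            labels[i] = validate_scores(sv, cfg.ps_threshold)
    tl = build_label_timeline(
        labels, [w.start for w in wins], cfg.window_len,
        n_samples=rec.n_samples, mode_block=cfg.mode_block, mode_stride=cfg.mode_stride,
    )
    valid, predicted = is_valid_prediction_vector(tl)
    b_mask = tl.predicted_mask()
    a_mask = rec.gt_mask()
    if rec.label is GestureClass.NO_GESTURE:
        rho = 1.0 if not b_mask.any() else 0.0
    else:
        rho = overlap_factor(a_mask, b_mask)
    correct_rec = recognition_decision(valid, predicted, rec.label, rho, cfg.rho_threshold)
    correct_cls = predicted is rec.label
    return RecognitionResult(
        valid=valid,
        predicted=predicted,
        rho=rho,
        correct_classification=correct_cls,
        correct_recognition=correct_rec,
        timeline=tl if keep_timeline else None,
    )
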