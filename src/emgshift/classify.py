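"""Training-matrix assembly, the one-vs-one margin classifier, and
score validation.

The classifier is a support vector machine with a third-order
polynomial kernel, box constraint 1, standardized features and
one-vs-one coding: n(n-1)/2 = 15 pairwise classifiers for the 6
classes.  At prediction time each class receives a non-positive score
(the negated mean hinge loss over its 5 pairwise margins); the nominal
prediction is the class whose score is nearest zero.  A prediction is
only accepted when its normalized score margin

    Ps = max(1 - |scores| / max|scores|)

reaches the validation threshold (default 0.9); otherwise the window
falls back to the relax label.  The Ps margin measures how much closer
to zero the best score is than the runner-up, so near-ambiguous
windows are rejected rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import PipelineConfig
from .features import VECTOR_LENGTH, featurize_matrix
from .orientation import CalibrationResult
from .preprocess import gate_window, training_windows
from .types import CLASS_ORDER, EmgRecording, GestureClass

log = logging.getLogger(__name__)

N_CLASSES = len(CLASS_ORDER)
N_PAIRWISE = N_CLASSES * (N_CLASSES - 1) // 2  # 15


@dataclass
class TrainingMatrix:
    features: np.ndarray  # N x 40
    labels: np.ndarray  # N gesture-class values (str)
    provenance: list[tuple[str, str, str, int]]  # (user, gesture, repetition, window_start)

    def __post_init__(self) -> None:
        if self.features.ndim != 2 or self.features.shape[1] != VECTOR_LENGTH:
            raise ValueError(f"features must be N x {VECTOR_LENGTH}")
        if len(self.labels) != len(self.features) != len(self.provenance):
            raise ValueError("features, labels and provenance must align")


def assemble_training_matrix(
    recordings_by_user: Mapping[str, Sequence[EmgRecording]],
    calibrations: Mapping[str, CalibrationResult],
    cfg: PipelineConfig,
    reps_per_gesture: int | None = None,
) -> TrainingMatrix:
    """Gated, rearranged training windows for one or many users.

    Each user's recordings are rearranged by that user's calibration
    before windowing.  Up to ``reps_per_gesture`` repetitions (default
    ``cfg.reps_per_gesture``) per class per user contribute 7 windows
    each.  Gesture windows that fail the energy gate are dropped
    (logged); relax-class windows are kept regardless, since a failed
    gate *is* the relax label.
    """
    P = reps_per_gesture or cfg.reps_per_gesture
    rows: list[np.ndarray] = []
    labels: list[str] = []
    prov: list[tuple[str, str, str, int]] = []
    n_dropped = 0
    for user_id in sorted(recordings_by_user):
        cal = calibrations[user_id]
        by_class: dict[GestureClass, list[EmgRecording]] = {c: [] for c in CLASS_ORDER}
        for rec in recordings_by_user[user_id]:
            by_class[rec.label].append(rec)
        missing = [c.value for c in CLASS_ORDER if not by_class[c]]
        if missing:
            raise ValueError(f"user {user_id} is missing classes: {missing}")
        for gesture in CLASS_ORDER:
            reps = sorted(by_class[gesture], key=lambda r: r.repetition_id)[:P]
            for rec in reps:
                arranged = rec.rearranged(cal.pod_order)
                for win in training_windows(arranged, cfg):
                    gate = gate_window(win, cal, cfg.group_energy)
                    if not gate.passed and gesture is not GestureClass.NO_GESTURE:
                        n_dropped += 1
                        continue
                    rows.append(featurize_matrix(win.window, cfg.ae_reduce))
                    labels.append(gesture.value)
                    prov.append((user_id, gesture.value, rec.repetition_id, win.start))
    if n_dropped:
        log.info("training assembly dropped %d gated-out gesture windows", n_dropped)
    if not rows:
        raise ValueError("no training windows survived assembly")
    return TrainingMatrix(np.vstack(rows), np.asarray(labels), prov)


@dataclass
class TrainedModel:
    """Standardization statistics plus the 15 pairwise classifiers."""

    scaler: StandardScaler
    svc: SVC
    classes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_pairwise(self) -> int:
        n = len(self.classes)
        return n * (n - 1) // 2

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        return joblib.load(path)


def train_model(tm: TrainingMatrix, cfg: PipelineConfig | None = None) -> TrainedModel:
    """Fit the standardizer and the one-vs-one polynomial-kernel SVM."""
    classes = np.unique(tm.labels)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if len(tm.features) < VECTOR_LENGTH:
        raise ValueError("too few training rows")
    scaler = StandardScaler().fit(tm.features)
    X = scaler.transform(tm.features)
    # polynomial kernel (1 + <x, y>)^3, box constraint 1
    svc = SVC(
        kernel="poly", degree=3, gamma=1.0, coef0=1.0, C=1.0,
        decision_function_shape="ovo", random_state=0,
    ).fit(X, tm.labels)
    log.info("trained on %d rows, %d classes, %d pairwise classifiers",
             len(X), len(classes), len(classes) * (len(classes) - 1) // 2)
    return TrainedModel(scaler=scaler, svc=svc, classes=tuple(svc.classes_))


@dataclass(frozen=True)
class ScoreVector:
    """Per-class non-positive scores for one window."""

    scores: np.ndarray  # aligned with CLASS_ORDER
    predicted: GestureClass
    ps: float


def _class_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """N x 6 non-positive class scores from the pairwise decision values.

    For the pair (i, j) a positive decision value favours class i.  A
    class's score is the negated mean hinge loss max(0, 1 - margin)
    over its 5 pairwise margins, so 0 is a perfect, unanimous margin.
    """
    d = model.svc.decision_function(X)
    if d.ndim == 1:
        d = d[:, None]
    classes = list(model.classes)
    loss = np.zeros((X.shape[0], len(classes)))
    counts = np.zeros(len(classes))
    for k, (i, j) in enumerate(combinations(range(len(classes)), 2)):
        loss[:, i] += np.maximum(0.0, 1.0 - d[:, k])
        loss[:, j] += np.maximum(0.0, 1.0 + d[:, k])
        counts[i] += 1
        counts[j] += 1
    scores = -loss / counts
    # re-order columns to the canonical class order
    col = [classes.index(c.value) for c in CLASS_ORDER]
    return scores[:, col]


def _ps_values(scores: np.ndarray) -> np.ndarray:
    """Normalized score margin Ps per row; all-zero rows give Ps = 1."""
    a = np.abs(scores)
    m = a.max(axis=1)
    safe = np.where(m == 0, 1.0, m)
    ps = (1.0 - a / safe[:, None]).max(axis=1)
    return np.where(m == 0, 1.0, ps)


def _nominal_predictions(scores: np.ndarray) -> list[GestureClass]:
    """Class nearest zero per row; exact ties fall back to the relax class."""
    out: list[GestureClass] = []
    best = scores.max(axis=1)
    for row, b in zip(scores, best):
        tied = np.flatnonzero(row == b)
        if len(tied) > 1:
            out.append(GestureClass.NO_GESTURE)
        else:
            out.append(CLASS_ORDER[tied[0]])
    return out


def score_windows(model: TrainedModel, features: np.ndarray) -> list[ScoreVector]:
    """Score a batch of 40-value feature rows."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != VECTOR_LENGTH:
        raise ValueError(f"expected {VECTOR_LENGTH} features, got {features.shape[1]}")
    X = model.scaler.transform(features)
    scores = _class_scores(model, X)
    ps = _ps_values(scores)
    preds = _nominal_predictions(scores)
    return [ScoreVector(s, p, float(v)) for s, p, v in zip(scores, preds, ps)]


def score_window(model: TrainedModel, features: np.ndarray) -> ScoreVector:
    """Score a single window's 40-value feature vector."""
    return score_windows(model, np.asarray(features, dtype=float)[None, :])[0]


def score_vector_from_scores(scores: Sequence[float]) -> ScoreVector:
    """Build a ScoreVector from six raw non-positive scores.

    Useful for inspecting the validation rule in isolation from a
    trained model.
    """
    s = np.asarray(scores, dtype=float)[None, :]
    if s.shape[1] != N_CLASSES:
        raise ValueError(f"expected {N_CLASSES} scores")
    if np.any(s > 0):
        raise ValueError("scores must be non-positive")
    return ScoreVector(s[0], _nominal_predictions(s)[0], float(_ps_values(s)[0]))


def validate_scores(sv: ScoreVector, ps_threshold: float = 0.9) -> GestureClass:
    """Accept the nominal prediction only when Ps reaches the threshold."""
    return sv.predicted if sv.ps >= ps_threshold else GestureClass.NO_GESTURE
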