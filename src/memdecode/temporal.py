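"""Frame-wise decoding over the decision epoch and temporal generalization.

Epochs are the first seven MR frames after image onset taken from the
residual dataset (execution-phase activity removed): the whole 8 s delay
plus one frame into the execution phase. Each frame is decoded
independently (SVM, C = 1, ANOVA selection k = 50), either between
subjects (leave-one-subject-out) or within subject (k = 7 run-grouped
folds). Temporal generalization trains at frame i and tests at frame j for
all 49 (i, j) pairs; its diagonal equals the frame-wise time course under
the same folds. Significance is a one-sample t against 50% with a
Bonferroni factor of frames x ROIs (time courses) or 49 x ROIs (matrices).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decode_core import (
    CvScheme,
    LabeledPatterns,
    anova_select,
    fit_linear_classifier,
)
from .glm import ResidualDataset
from .study_design import TrialSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "EpochTensor",
    "extract_epochs",
    "TimecourseResult",
    "temporal_decode",
    "GeneralizationResult",
    "temporal_generalization",
    "find_peaks",
]


@dataclass
class EpochTensor:
    """Trials x frames x ROI-voxels activity around image onset."""

    data: np.ndarray
    frame_times_s: np.ndarray  # per frame, seconds from image onset (mean over trials)
    meta: pd.DataFrame
    subject_id: object = None

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def extract_epochs(
    residual: ResidualDataset,
    schedule: TrialSchedule,
    roi_voxels: np.ndarray,
    n_frames: int = 7,
) -> EpochTensor:
    """Cut per-trial frame epochs from the residual dataset.

    Frame 0 is the first acquisition at or after image onset; trials whose
    epoch would run past the end of their run are dropped with a log
    entry. Frame times are reported in seconds from image onset.
    """
    roi_voxels = np.asarray(roi_voxels, dtype=int)
    tr = residual.tr_s
    frame = schedule.frame.reset_index(drop=True)
    runs = schedule.runs
    epochs, kept, offsets = [], [], []
    for i, row in frame.iterrows():
        sl = residual.run_slices[runs.index(row["run"])]
        m = sl.stop - sl.start
        f0 = int(np.ceil(row["onset"] / tr - 1e-9))
        if f0 + n_frames > m:
            logger.info("dropping trial %d: epoch exceeds run end", i)
            continue
        epochs.append(residual.data[sl][f0 : f0 + n_frames][:, roi_voxels])
        offsets.append(f0 * tr - row["onset"])
        kept.append(i)
    if not epochs:
        raise ValueError("no trial has a complete epoch")
    data = np.stack(epochs)
    t0 = float(np.mean(offsets))
    frame_times = t0 + tr * np.arange(n_frames)
    return EpochTensor(data, frame_times, frame.iloc[kept].reset_index(drop=True))


def _epoch_patterns(epochs: EpochTensor, labels: np.ndarray, subject_ids: np.ndarray) -> LabeledPatterns:
    """Wrap an epoch tensor for decoding; features = frames x voxels kept 3D."""
    return LabeledPatterns(
        epochs.data.reshape(epochs.data.shape[0], -1), labels, subject_ids, epochs.meta
    )


def _folds(patterns: LabeledPatterns, scheme: CvScheme):
    from .decode_core import _loso_folds, _within_folds

    if scheme.kind == "leave_one_subject_out":
        yield from _loso_folds(patterns)
    else:
        yield from _within_folds(patterns, scheme.k)


def _normalize_frame(X: np.ndarray) -> np.ndarray:
    """Per-sample spatial z-score of one frame's maps, degenerate-safe."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


@dataclass
class TimecourseResult:
    accuracies: np.ndarray  # folds x frames
    fold_ids: list
    frame_times_s: np.ndarray
    p: np.ndarray  # per frame, uncorrected
    p_corrected: np.ndarray
    significant: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)


def _fit_test_matrix(
    tensor: np.ndarray,
    labels: np.ndarray,
    folds: list,
    k_select: int | None,
    C: float,
    pairs: str,
) -> tuple[np.ndarray, list]:
    """Shared engine: train at frame i, test at frame j.

    ``pairs`` is "diag" (frame-wise time course) or "all" (the full
    generalization matrix). Feature selection and fitting always use the
    training fold at the training frame only.
    """
    n_frames = tensor.shape[1]
    frames_norm = [_normalize_frame(tensor[:, f, :]) for f in range(n_frames)]
    out = np.full((len(folds), n_frames, n_frames), np.nan)
    ids = []
    for fi, (fold_id, train, test) in enumerate(folds):
        ids.append(fold_id)
        for i in range(n_frames):
            Xtr = frames_norm[i][train]
            ytr = labels[train]
            if k_select is not None:
                sel = anova_select(Xtr, ytr, min(k_select, Xtr.shape[1]))
                Xtr_s = Xtr[:, sel]
            else:
                sel = slice(None)
                Xtr_s = Xtr
            clf = fit_linear_classifier(Xtr_s, ytr, C=C)
            js = [i] if pairs == "diag" else range(n_frames)
            for j in js:
                Xte = frames_norm[j][test][:, sel]
                out[fi, i, j] = float(np.mean(clf.predict(Xte) == labels[test]))
    return out, ids


def temporal_decode(
    epochs: EpochTensor,
    labels: np.ndarray,
    subject_ids: np.ndarray,
    scheme: CvScheme | None = None,
    k_select: int = 50,
    C: float = 1.0,
    n_rois: int = 1,
    alpha: float = 0.05,
) -> TimecourseResult:
    """Decode each epoch frame independently; Bonferroni over frames x ROIs."""
    scheme = scheme or CvScheme("leave_one_subject_out")
    patterns = _epoch_patterns(epochs, labels, subject_ids)
    folds = list(_folds(patterns, scheme))
    cube, ids = _fit_test_matrix(epochs.data, patterns.y, folds, k_select, C, "diag")
    acc = np.stack([np.diag(cube[f]) for f in range(len(folds))])
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_1samp(acc, 0.5, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    m = epochs.n_frames * n_rois
    p_corr = np.minimum(1.0, p * m)
    return TimecourseResult(acc, ids, epochs.frame_times_s, p, p_corr, p_corr < alpha)


@dataclass
class GeneralizationResult:
    matrix: np.ndarray  # train-frame x test-frame mean accuracy
    accuracies: np.ndarray  # folds x train x test
    fold_ids: list
    frame_times_s: np.ndarray
    p: np.ndarray
    p_corrected: np.ndarray
    significant: np.ndarray


def temporal_generalization(
    epochs: EpochTensor,
    labels: np.ndarray,
    subject_ids: np.ndarray,
    scheme: CvScheme | None = None,
    k_select: int = 50,
    C: float = 1.0,
    n_rois: int = 1,
    alpha: float = 0.05,
) -> GeneralizationResult:
    """Train at frame i, test at frame j, for every cell of the matrix.

    The diagonal reproduces ``temporal_decode`` exactly under the same
    folds; significance uses a Bonferroni factor of cells (n_frames^2,
    49 for the 7-frame epoch) times ROIs.
    """
    scheme = scheme or CvScheme("leave_one_subject_out")
    patterns = _epoch_patterns(epochs, labels, subject_ids)
    folds = list(_folds(patterns, scheme))
    cube, ids = _fit_test_matrix(epochs.data, patterns.y, folds, k_select, C, "all")
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_1samp(cube, 0.5, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    m = epochs.n_frames**2 * n_rois
    p_corr = np.minimum(1.0, p * m)
    return GeneralizationResult(
        cube.mean(axis=0), cube, ids, epochs.frame_times_s, p, p_corr, p_corr < alpha
    )


def find_peaks(timecourse: np.ndarray) -> np.ndarray:
    """Local maxima by comparison with neighboring values.

    A peak strictly exceeds its nearest differing neighbors on both sides;
    a flat plateau reports its first index; endpoints never count.
    """
    x = np.asarray(timecourse, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("timecourse must be 1-D with at least three samples")
    from scipy.signal import find_peaks as _scipy_find_peaks

    _, props = _scipy_find_peaks(x, plateau_size=1)
    return props["left_edges"].astype(int)
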