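"""Hemodynamic modeling: gamma-family HRF, condition-level design matrices,
execution-phase residualization and single-trial (beta-series) estimation.

Event regressors are built on the MR-frame grid: onsets are rounded to the
nearest frame, a rectangle of the event's duration is sampled at the TR and
convolved with the HRF kernel. The condition GLM crosses memory status x
evidence x accuracy for the decision phase (12 regressors, time-locked to
image onset) and motor response x accuracy for the execution phase (4
regressors at the go-signal), plus per-run intercept and linear drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_design import TrialSchedule, TrialTiming

__all__ = [
    "Hrf",
    "make_hrf",
    "event_regressor",
    "DesignMatrix",
    "build_condition_design",
    "fit_glm",
    "GlmFit",
    "residualize_execution",
    "ResidualDataset",
    "single_trial_betas",
    "BetaSeries",
]


@dataclass(frozen=True)
class Hrf:
    """Gamma-family hemodynamic response function.

    h(t) = ((t - delta)/tau)^(n-1) exp(-(t - delta)/tau) for t >= delta,
    zero before, normalized to unit peak. The analytic mode sits at
    ``delta + (n - 1) * tau`` (4.5 s for the defaults).
    """

    n: int = 3
    tau_s: float = 1.25
    delta_s: float = 2.0

    def kernel(self, dt_s: float, support_s: float = 32.0) -> np.ndarray:
        return make_hrf(self, dt_s, support_s)


def make_hrf(params: Hrf | None = None, dt_s: float = 1.914, support_s: float = 32.0) -> np.ndarray:
    """Sample the HRF on a regular grid of step ``dt_s``; unit peak."""
    params = params or Hrf()
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if params.tau_s <= 0:
        raise ValueError("tau_s must be positive")
    t = np.arange(0.0, support_s, dt_s)
    s = (t - params.delta_s) / params.tau_s
    h = np.where(s > 0, np.power(np.clip(s, 0, None), params.n - 1) * np.exp(-np.clip(s, 0, None)), 0.0)
    peak = h.max()
    if peak <= 0:
        raise ValueError("HRF support too short: kernel is identically zero")
    return h / peak


def event_regressor(
    onsets_s: np.ndarray,
    duration_s: float,
    n_frames: int,
    tr_s: float,
    hrf_kernel: np.ndarray,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at the TR.

    Each onset is rounded to the nearest frame; the boxcar covers every
    frame within ``duration_s`` of the rounded onset. This same routine
    drives both the simulator's forward model and the GLM designs, so a
    noiseless simulation is exactly representable by its design matrix.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    if amplitudes is None:
        amplitudes = np.ones(len(onsets_s))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    box = np.zeros(n_frames)
    n_box = max(1, int(np.ceil(duration_s / tr_s - 1e-9)))
    for onset, amp in zip(onsets_s, amplitudes):
        start = int(np.rint(onset / tr_s))
        for j in range(start, min(start + n_box, n_frames)):
            if j >= 0:
                box[j] += amp
    return np.convolve(box, hrf_kernel)[:n_frames]


@dataclass
class DesignMatrix:
    """Frames x regressors matrix with labeled columns and roles.

    ``roles`` maps each column name to one of {"decision", "execution",
    "trial", "nuisance"}; run-wise nuisance columns are zero outside their
    run.
    """

    matrix: np.ndarray
    names: list[str]
    roles: dict[str, str]
    run_slices: list[slice] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("regressor names must be unique")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix width must match the number of names")

    def columns(self, role: str) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.names) if self.roles[n] == role], dtype=int)


def _nuisance_columns(run_slices: list[slice], n_frames: int) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for r, sl in enumerate(run_slices):
        m = sl.stop - sl.start
        const = np.zeros(n_frames)
        const[sl] = 1.0
        drift = np.zeros(n_frames)
        drift[sl] = np.linspace(-1.0, 1.0, m)
        cols += [const, drift]
        names += [f"run{r}_intercept", f"run{r}_drift"]
    return np.column_stack(cols), names


def _run_layout(schedule: TrialSchedule) -> tuple[list[slice], int]:
    slices, start = [], 0
    for r in schedule.runs:
        m = schedule.run_frames(r)
        slices.append(slice(start, start + m))
        start += m
    return slices, start


def build_condition_design(
    schedule: TrialSchedule,
    hrf: Hrf | None = None,
    tr_s: float | None = None,
) -> DesignMatrix:
    """Condition-level GLM design for a retrieval schedule with choices.

    Decision regressors: status x evidence x accuracy (up to 12), a 1.5 s
    rectangle at image onset. Execution regressors: response x accuracy (up
    to 4), a 1 s rectangle at the go-signal. Cells absent from the schedule
    are dropped with a warning. Runs are concatenated in time; each run
    contributes an intercept and a linear drift.
    """
    frame = schedule.frame
    if "onset" not in frame.columns:
        raise ValueError("schedule has no onsets")
    for col in ("choice", "correct", "response"):
        if col not in frame.columns:
            raise ValueError("schedule lacks observer choices; run simulate_observer first")
    tr = tr_s or schedule.tr_s
    timing = schedule.timing or TrialTiming(tr_s=tr)
    kern = (hrf or Hrf()).kernel(tr)
    run_slices, n_frames = _run_layout(schedule)
    run_index = {r: i for i, r in enumerate(schedule.runs)}

    cols, names, roles = [], [], {}

    def add_event_column(name, role, sub, offset_s, duration_s):
        if len(sub) == 0:
            warnings.warn(f"empty design cell dropped: {name}")
            return
        col = np.zeros(n_frames)
        for r, g in sub.groupby("run"):
            sl = run_slices[run_index[r]]
            col[sl] += event_regressor(
                g["onset"].to_numpy() + offset_s, duration_s, sl.stop - sl.start, tr, kern
            )
        cols.append(col)
        names.append(name)
        roles[name] = role

    acc_label = {True: "correct", False: "incorrect"}
    for status in ("old", "new"):
        for ev in ("low", "middle", "high"):
            for acc in (True, False):
                sub = frame[
                    (frame["memory_status"] == status)
                    & (frame["evidence"] == ev)
                    & (frame["correct"] == acc)
                ]
                add_event_column(
                    f"dec_{status}_{ev}_{acc_label[acc]}", "decision", sub, 0.0, timing.image_s
                )
    for resp in ("eye", "hand"):
        for acc in (True, False):
            sub = frame[(frame["response"] == resp) & (frame["correct"] == acc)]
            add_event_column(
                f"exe_{resp}_{acc_label[acc]}", "execution", sub,
                timing.go_onset_offset_s, timing.go_s,
            )

    nuis, nuis_names = _nuisance_columns(run_slices, n_frames)
    matrix = np.column_stack(cols + [nuis]) if cols else nuis
    names = names + nuis_names
    roles.update({n: "nuisance" for n in nuis_names})
    return DesignMatrix(matrix, names, roles, run_slices)


@dataclass
class GlmFit:
    betas: np.ndarray  # regressors x voxels
    names: list[str]
    residual_variance: np.ndarray  # per voxel
    dof: int

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.names.index(name)]


def fit_glm(data: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares fit of ``data`` (frames x voxels)."""
    X = design.matrix
    if data.shape[0] != X.shape[0]:
        raise ValueError("data frames do not match design frames")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Name the offending columns via the QR diagonal.
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or 'unidentified'}"
        )
    betas, _, _, _ = np.linalg.lstsq(X, data, rcond=None)
    resid = data - X @ betas
    dof = X.shape[0] - X.shape[1]
    rv = (resid**2).sum(axis=0) / max(dof, 1)
    return GlmFit(betas, list(design.names), rv, dof)


@dataclass
class ResidualDataset:
    """BOLD with execution-phase and nuisance contributions projected out.

    ``data`` is frames x in-mask voxels over concatenated runs; the
    decision-phase activity (modeled or not) is retained, and the result is
    orthogonal to the execution and nuisance regressors.
    """

    data: np.ndarray
    run_slices: list[slice]
    tr_s: float


def residualize_execution(
    data: np.ndarray, design: DesignMatrix, tr_s: float | None = None
) -> ResidualDataset:
    """Project execution + nuisance regressors out of the data.

    The removed subspace is spanned by the execution-phase and nuisance
    columns only, so the residual is exactly orthogonal to them and the
    projection is idempotent.
    """
    exe = design.columns("execution")
    if exe.size == 0:
        raise ValueError("design has no execution-phase columns")
    keep = np.concatenate([exe, design.columns("nuisance")])
    X = design.matrix[:, keep]
    Q, _ = np.linalg.qr(X)
    resid = data - Q @ (Q.T @ data)
    return ResidualDataset(resid, list(design.run_slices), tr_s or 1.914)


@dataclass
class BetaSeries:
    """Single-trial amplitude estimates, trials x in-mask voxels."""

    data: np.ndarray
    meta: pd.DataFrame  # one row per trial, aligned with data rows

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def single_trial_betas(
    data: np.ndarray,
    schedule: TrialSchedule,
    hrf: Hrf | None = None,
    tr_s: float | None = None,
    method: str = "lsa",
) -> BetaSeries:
    """Estimate one beta per trial per voxel (beta series).

    ``lsa`` (least-squares-all, the default) gives every trial its own
    1.5 s-rectangle ⊗ HRF regressor and fits all of them per run jointly,
    with the execution regressors and run nuisance as covariates. ``lss``
    (least-squares-separate) fits one trial at a time against the summed
    remainder, trading variance for robustness at short ITIs.
    """
    if method not in ("lsa", "lss"):
        raise ValueError("method must be 'lsa' or 'lss'")
    frame = schedule.frame.reset_index(drop=True)
    tr = tr_s or schedule.tr_s
    timing = schedule.timing or TrialTiming(tr_s=tr)
    kern = (hrf or Hrf()).kernel(tr)
    run_slices, n_frames = _run_layout(schedule)
    if data.shape[0] != n_frames:
        raise ValueError(
            f"data has {data.shape[0]} frames but the schedule implies {n_frames}"
        )
    run_index = {r: i for i, r in enumerate(schedule.runs)}

    betas = np.empty((len(frame), data.shape[1]))
    acc_label = {True: "correct", False: "incorrect"}
    for r, g in frame.groupby("run"):
        sl = run_slices[run_index[r]]
        m = sl.stop - sl.start
        trial_cols = [
            event_regressor(np.array([t]), timing.image_s, m, tr, kern)
            for t in g["onset"].to_numpy()
        ]
        exe_cols, exe_names = [], []
        for resp in ("eye", "hand"):
            for acc in (True, False):
                sub = g[(g["response"] == resp) & (g["correct"] == acc)]
                if len(sub):
                    exe_cols.append(
                        event_regressor(
                            sub["onset"].to_numpy() + timing.go_onset_offset_s,
                            timing.go_s, m, tr, kern,
                        )
                    )
                    exe_names.append(f"exe_{resp}_{acc_label[acc]}")
        const = np.ones(m)
        drift = np.linspace(-1.0, 1.0, m)
        cov = np.column_stack(exe_cols + [const, drift]) if exe_cols else np.column_stack([const, drift])
        Y = data[sl]
        if method == "lsa":
            X = np.column_stack(trial_cols + [cov])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise np.linalg.LinAlgError(
                    f"single-trial design for run {r} is rank deficient "
                    "(trials too close together); consider method='lss' or a "
                    "ridge-regularized fit"
                )
            b, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
            betas[g.index.to_numpy(), :] = b[: len(trial_cols)]
        else:
            allsum = np.sum(trial_cols, axis=0)
            for k, (row_i, col) in enumerate(zip(g.index.to_numpy(), trial_cols)):
                X = np.column_stack([col, allsum - col, cov])
                b, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
                betas[row_i, :] = b[0]
    return BetaSeries(betas, frame.reset_index(drop=True))
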