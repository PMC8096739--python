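"""Run-level GLM: exemplar-wise regressors, FD nuisance, OLS pattern estimates.

Each condition present in a run is modeled by its own regressor (a boxcar
of its trials convolved with a canonical double-gamma hemodynamic response
function), question trials are pooled into a single nuisance regressor,
null trials stay unmodeled as implicit baseline, and framewise displacement
(FD) — the per-timepoint sum of absolute temporal derivatives of the six
rigid-body motion parameters, rotations converted to arc length — enters
as a motion nuisance.  Ordinary least squares yields the condition × voxel
beta patterns and the residuals from which the voxel noise covariance is
later estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .design import TrialTimeline

#: default TR of the acquisition protocol (seconds)
DEFAULT_TR = 2.0
#: microtime resolution for event convolution (seconds); fine enough that
#: 2 s events are not aliased
MICROTIME_DT = 0.1


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF in the SPM convention.

    Response gamma peaking at ``peak_delay`` s minus an undershoot gamma
    peaking at ``undershoot_delay`` s scaled by ``ratio``.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 1.0 / 6.0
    window: float = 32.0


def hrf_kernel(params: Optional[HRFParams] = None,
               dt: float = MICROTIME_DT) -> np.ndarray:
    """Canonical double-gamma kernel sampled every ``dt`` s over the window.

    Normalized to unit peak; vanishes at t = 0 and has a single positive
    lobe followed by an undershoot.
    """
    params = params or HRFParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.window <= 0:
        raise ValueError("nonpositive HRF window")
    t = np.arange(0.0, params.window + dt / 2, dt)
    peak = stats.gamma.pdf(t, params.peak_delay / params.peak_dispersion,
                           scale=params.peak_dispersion)
    under = stats.gamma.pdf(t, params.undershoot_delay / params.undershoot_dispersion,
                            scale=params.undershoot_dispersion)
    h = peak - params.ratio * under
    return h / h.max()


def framewise_displacement(motion: np.ndarray,
                           rotation_radius_mm: float = 50.0) -> np.ndarray:
    """FD series: sum of absolute temporal derivatives of the six motion
    parameters, rotations (radians) converted to mm of arc at the given
    radius.  FD[0] = 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise ValueError("motion must be (timepoints >= 2) x 6")
    d = np.abs(np.diff(motion, axis=0))
    d[:, 3:] *= rotation_radius_mm
    fd = np.concatenate([[0.0], d.sum(axis=1)])
    return fd


@dataclass
class DesignMatrix:
    """Timepoint × regressor matrix with labels.

    Condition columns are HRF-convolved indicators sampled at TR midpoints;
    nuisance columns (pooled question trials, FD) and the intercept follow.
    """

    matrix: np.ndarray
    labels: list
    condition_names: list
    tr: float

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    def condition_columns(self) -> np.ndarray:
        idx = [self.labels.index(c) for c in self.condition_names]
        return self.matrix[:, idx]


def n_volumes_for(timeline: TrialTimeline, tr: float = DEFAULT_TR,
                  post_rest: float = 16.0) -> int:
    """Volume count covering the timeline plus a rest tail for the HRF."""
    return int(np.ceil((timeline.duration + post_rest) / tr))


def _convolve_events(onsets, durations, hrf, dt, volume_times, t_max):
    grid = np.zeros(int(np.ceil(t_max / dt)) + len(hrf) + 1)
    for onset, dur in zip(onsets, durations):
        a = int(round(onset / dt))
        b = int(round((onset + dur) / dt))
        grid[a:b] += 1.0
    conv = np.convolve(grid, hrf)[:len(grid)]
    idx = np.clip((volume_times / dt).astype(int), 0, len(conv) - 1)
    return conv[idx]


def build_design_matrix(timeline: TrialTimeline,
                        tr: float = DEFAULT_TR,
                        n_volumes: Optional[int] = None,
                        hrf_params: Optional[HRFParams] = None,
                        motion: Optional[np.ndarray] = None,
                        conditions: Optional[Sequence] = None,
                        rotation_radius_mm: float = 50.0) -> DesignMatrix:
    """Design matrix of one run.

    One column per condition (by default, the conditions present in the
    timeline), a pooled question-trial nuisance, an FD nuisance when motion
    is supplied and non-constant, and an intercept.  A condition with zero
    trials raises (its column would be identically zero).
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    if not timeline.trials:
        raise ValueError("empty timeline")
    if n_volumes is None:
        n_volumes = n_volumes_for(timeline, tr)
    if motion is not None and len(motion) != n_volumes:
        raise ValueError("motion length does not match volume count")

    if conditions is None:
        seen = []
        for cond in timeline.experimental_conditions():
            if cond not in seen:
                seen.append(cond)
        conditions = seen
    cond_names = [c.name for c in conditions]

    hrf = hrf_kernel(hrf_params, MICROTIME_DT)
    volume_times = (np.arange(n_volumes) + 0.5) * tr
    t_max = n_volumes * tr

    events_by_cond = {c: ([], []) for c in conditions}
    question_events = ([], [])
    for onset, dur, kind, cond in timeline.trials:
        if kind == "experimental" and cond in events_by_cond:
            events_by_cond[cond][0].append(onset)
            events_by_cond[cond][1].append(dur)
        elif kind == "question":
            question_events[0].append(onset)
            question_events[1].append(dur)

    cols, labels = [], []
    for cond in conditions:
        onsets, durs = events_by_cond[cond]
        if not onsets:
            raise np.linalg.LinAlgError(
                f"condition {cond.name!r} has zero trials: zero column is "
                "rank-deficient")
        cols.append(_convolve_events(onsets, durs, hrf, MICROTIME_DT,
                                     volume_times, t_max))
        labels.append(cond.name)
    if question_events[0]:
        cols.append(_convolve_events(*question_events, hrf, MICROTIME_DT,
                                     volume_times, t_max))
        labels.append("question")
    if motion is not None:
        fd = framewise_displacement(np.asarray(motion), rotation_radius_mm)
        if np.ptp(fd) > 0:  # constant motion => all-zero FD => guarded out
            cols.append(fd)
            labels.append("fd")
    cols.append(np.ones(n_volumes))
    labels.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), labels=labels,
                        condition_names=cond_names, tr=tr)


@dataclass
class GLMResult:
    """OLS estimates of one run: betas, residuals and residual dof."""

    betas: np.ndarray            # regressor x voxel
    labels: list
    condition_names: list
    residuals: np.ndarray        # timepoint x voxel
    dof: int

    def condition_patterns(self) -> np.ndarray:
        """Condition × voxel beta patterns (the u vectors of the RDM stage)."""
        idx = [self.labels.index(c) for c in self.condition_names]
        return self.betas[idx]


def fit_glm(run_data: np.ndarray, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares fit of one run.

    Raises on rank deficiency or row-count mismatch; residual dof is
    timepoints minus design rank.
    """
    y = np.asarray(run_data, dtype=float)
    x = design.matrix
    if y.ndim != 2 or y.shape[0] != x.shape[0]:
        raise ValueError("data rows must match design rows")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    betas, *_ = np.linalg.lstsq(x, y, rcond=None)
    residuals = y - x @ betas
    return GLMResult(betas=betas, labels=list(design.labels),
                     condition_names=list(design.condition_names),
                     residuals=residuals, dof=y.shape[0] - rank)
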