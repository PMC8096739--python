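"""Cross-validated Mahalanobis (crossnobis) distances and noise normalization.

The dissimilarity between the activity patterns ``u_i``, ``u_j`` of two
conditions, estimated independently in ``M`` run partitions, is

    d_ij = sum_{l != m} (u_i^m - u_j^m)' (u_i^l - u_j^l) / (M (M - 1))

i.e. the pattern difference measured in one run is validated against the
difference measured in every other run.  Because run noise is independent
across partitions the estimator is unbiased: a condition pair with no true
pattern difference has expected distance zero (a meaningful zero point),
and individual estimates may be negative.  Applied to patterns prewhitened
by the inverse square root of the voxel noise covariance, ``d`` estimates
the squared Mahalanobis distance between the true patterns.

Noise covariances are estimated from GLM residuals with shrinkage toward
the diagonal of sample variances (Schaefer–Strimmer-style analytic weight),
guaranteeing a positive-definite matrix even when voxels outnumber
timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd


@dataclass
class PatternSet:
    """Run-indexed condition × voxel activity estimates of one subject/region.

    ``patterns`` has shape (n_runs, n_conditions, n_voxels); all runs share
    the same condition ordering.
    """

    patterns: np.ndarray
    condition_names: list
    subject_id: Optional[str] = None
    region: Optional[str] = None

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 3:
            raise ValueError("patterns must be (n_runs, n_conditions, n_voxels)")
        if self.patterns.shape[1] != len(self.condition_names):
            raise ValueError("condition_names length mismatch")

    @property
    def n_runs(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[2]


@dataclass
class NoiseCovariance:
    """Shrunk voxel × voxel noise covariance with its provenance."""

    cov: np.ndarray
    shrinkage: float
    dof: int

    def __post_init__(self):
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.ndim != 2 or self.cov.shape[0] != self.cov.shape[1]:
            raise ValueError("covariance must be square")

    @property
    def n_voxels(self) -> int:
        return self.cov.shape[0]


@dataclass
class RDM:
    """Condition × condition crossnobis distance matrix.

    Symmetric with an exactly zero diagonal; off-diagonal entries may be
    negative (cross-validation allows it).
    """

    matrix: np.ndarray
    condition_names: list
    subject_id: Optional[str] = None
    region: Optional[str] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.condition_names)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match condition count")

    def value(self, i: int, j: int) -> float:
        return float(self.matrix[i, j])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form table (subject, region, condition_i, condition_j, distance)."""
        rows = []
        n = len(self.condition_names)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "subject": self.subject_id,
                    "region": self.region,
                    "condition_i": self.condition_names[i],
                    "condition_j": self.condition_names[j],
                    "distance": self.matrix[i, j],
                })
        return pd.DataFrame(rows)

    def write_long_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)


def _shrinkage_weight(residuals: np.ndarray, sample_cov: np.ndarray) -> float:
    """Analytic shrinkage weight toward the diagonal target.

    Closed-form estimate of the weight minimizing expected squared error of
    the shrunk off-diagonal entries (Schaefer & Strimmer 2005, target D =
    diag of sample variances)."""
    t, p = residuals.shape
    x = residuals - residuals.mean(axis=0, keepdims=True)
    # Var of each off-diagonal covariance entry
    w = np.einsum("ti,tj->tij", x, x)
    w_bar = w.mean(axis=0)
    var_s = (t / (t - 1.0) ** 3) * ((w - w_bar) ** 2).sum(axis=0)
    off = ~np.eye(p, dtype=bool)
    denom = (sample_cov[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    lam = var_s[off].sum() / denom
    return float(np.clip(lam, 0.0, 1.0))


def estimate_noise_cov(residuals: np.ndarray,
                       shrinkage: Union[str, float] = "auto",
                       dof: Optional[int] = None) -> NoiseCovariance:
    """Shrunk sample covariance of one run's residual time series.

    ``residuals`` is timepoints × voxels.  When ``dof`` is given (residual
    degrees of freedom of the GLM) the residuals are treated as zero-mean
    and the covariance uses that divisor; otherwise the series is centered
    and ``dof = T - 1``.  ``shrinkage`` is "auto" for the analytic weight or
    a fixed value in [0, 1]; the result is shrunk toward the diagonal of
    sample variances and is positive definite for any positive weight.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2 or residuals.shape[0] < 2:
        raise ValueError("residuals must be (timepoints >= 2) x voxels")
    if dof is None:
        residuals = residuals - residuals.mean(axis=0, keepdims=True)
        dof = residuals.shape[0] - 1
    if dof < 1:
        raise ValueError("residual dof must be >= 1")
    sample = residuals.T @ residuals / dof

    if shrinkage == "auto":
        lam = _shrinkage_weight(residuals, sample)
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("fixed shrinkage must lie in [0, 1]")
    diag = np.diag(np.diag(sample))
    if lam > 0 and np.any(np.diag(sample) <= 0):
        raise ValueError("zero-variance voxel: diagonal target not PD")
    if lam == 0 and np.any(np.diag(sample) <= 0):
        raise ValueError("zero-variance voxel with shrinkage 0")
    cov = (1.0 - lam) * sample + lam * diag
    return NoiseCovariance(cov=cov, shrinkage=lam, dof=int(dof))


def estimate_noise_cov_by_run(residuals_by_run: Sequence[np.ndarray],
                              shrinkage: Union[str, float] = "auto",
                              dofs: Optional[Sequence[int]] = None) -> list:
    """Per-run noise covariances (the paper's "separately for each run")."""
    dofs = dofs if dofs is not None else [None] * len(residuals_by_run)
    return [estimate_noise_cov(r, shrinkage=shrinkage, dof=d)
            for r, d in zip(residuals_by_run, dofs)]


def pool_noise_cov(covs: Sequence[NoiseCovariance]) -> NoiseCovariance:
    """Dof-weighted average of run covariances (pooled mode; more stable
    when individual runs are short)."""
    if not covs:
        raise ValueError("no covariances to pool")
    total_dof = sum(c.dof for c in covs)
    cov = sum(c.cov * c.dof for c in covs) / total_dof
    lam = float(np.mean([c.shrinkage for c in covs]))
    return NoiseCovariance(cov=cov, shrinkage=lam, dof=total_dof)


def inverse_sqrt(cov: np.ndarray, eig_floor: float = 1e-10) -> np.ndarray:
    """Symmetric inverse matrix square root with an eigenvalue floor."""
    cov = np.asarray(cov, dtype=float)
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    if vals[-1] <= 0:
        raise np.linalg.LinAlgError("covariance is not positive definite")
    floor = eig_floor * vals[-1]
    if vals[0] <= 0:
        raise np.linalg.LinAlgError("covariance is not positive definite")
    vals = np.maximum(vals, floor)
    return (vecs / np.sqrt(vals)) @ vecs.T


def prewhiten(patterns, noise_cov: NoiseCovariance,
              bias_correction: bool = False):
    """Multivariate noise normalization: transform patterns by Sigma^{-1/2}.

    Euclidean distances between whitened patterns equal Mahalanobis
    distances under ``noise_cov`` between the originals.  With
    ``bias_correction`` the covariance is inflated by dof/(dof - P - 1)
    before inversion, making the implied precision matrix unbiased for the
    true inverse covariance (Wishart correction; requires dof > P + 1).
    """
    cov = noise_cov.cov
    if bias_correction:
        p = noise_cov.n_voxels
        if noise_cov.dof <= p + 1:
            raise ValueError("bias correction requires dof > n_voxels + 1")
        cov = cov * (noise_cov.dof / (noise_cov.dof - p - 1.0))
    w = inverse_sqrt(cov)
    if isinstance(patterns, PatternSet):
        return PatternSet(patterns=patterns.patterns @ w.T,
                          condition_names=list(patterns.condition_names),
                          subject_id=patterns.subject_id,
                          region=patterns.region)
    arr = np.asarray(patterns, dtype=float)
    return arr @ w.T


def prewhiten_by_run(pattern_set: PatternSet,
                     covs: Sequence[NoiseCovariance],
                     bias_correction: bool = False) -> PatternSet:
    """Whiten each run's patterns with that run's own covariance."""
    if len(covs) != pattern_set.n_runs:
        raise ValueError("need one covariance per run")
    runs = [prewhiten(pattern_set.patterns[m], covs[m],
                      bias_correction=bias_correction)
            for m in range(pattern_set.n_runs)]
    return PatternSet(patterns=np.stack(runs),
                      condition_names=list(pattern_set.condition_names),
                      subject_id=pattern_set.subject_id,
                      region=pattern_set.region)


def crossnobis_rdm(pattern_set: PatternSet,
                   normalize_voxels: bool = False) -> RDM:
    """Crossnobis RDM of an (already prewhitened) pattern set.

    Sums the cross-run inner products of pattern differences over all
    ordered run pairs (l, m), l != m, and divides by M(M-1).  No division
    by voxel count by default; ``normalize_voxels`` enables the d/P
    convention for cross-region comparability.
    """
    u = pattern_set.patterns
    m = pattern_set.n_runs
    if m < 2:
        raise ValueError("crossnobis requires at least 2 run partitions")
    s = u.sum(axis=0)                      # condition x voxel
    a = s @ s.T                            # sum over all (l, m)
    b = np.einsum("mij,mkj->ik", u, u)     # sum over l == m
    c = a - b
    diag = np.diag(c)
    d = (diag[:, None] + diag[None, :] - c - c.T) / (m * (m - 1))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    if normalize_voxels:
        d = d / pattern_set.n_voxels
    return RDM(matrix=d, condition_names=list(pattern_set.condition_names),
               subject_id=pattern_set.subject_id, region=pattern_set.region)


def crossnobis_from_runs(pattern_set: PatternSet,
                         residuals_by_run: Optional[Sequence[np.ndarray]] = None,
                         dofs: Optional[Sequence[int]] = None,
                         shrinkage: Union[str, float] = "auto",
                         noise_mode: str = "pooled",
                         bias_correction: bool = False,
                         normalize_voxels: bool = False) -> RDM:
    """Noise-normalize patterns from residuals, then compute the RDM.

    ``noise_mode`` is "pooled" (default; dof-weighted average covariance
    shared by all runs) or "per_run" (each run whitened by its own
    covariance).  With ``residuals_by_run=None`` patterns are used as-is
    (identity noise covariance).
    """
    if residuals_by_run is None:
        white = pattern_set
    else:
        covs = estimate_noise_cov_by_run(residuals_by_run,
                                         shrinkage=shrinkage, dofs=dofs)
        if noise_mode == "pooled":
            pooled = pool_noise_cov(covs)
            white = prewhiten(pattern_set, pooled,
                              bias_correction=bias_correction)
        elif noise_mode == "per_run":
            white = prewhiten_by_run(pattern_set, covs,
                                     bias_correction=bias_correction)
        else:
            raise ValueError(f"unknown noise_mode {noise_mode!r}")
    return crossnobis_rdm(white, normalize_voxels=normalize_voxels)
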