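"""Synthetic multi-voxel data with known representational geometry.

Ground-truth condition × voxel mean patterns are built as sums of seeded
random unit-norm component vectors — one shared vector per category, per
domain, per quadrant, and one per individual condition — scaled by the
matching named effect sizes.  The true squared Mahalanobis distance between
any two conditions is then available in closed form, so the full analysis
chain (GLM → prewhitening → crossnobis → inference) can be validated by
parameter recovery and null calibration without any real data.

Two generation levels are provided: beta-level run patterns (true pattern
plus spatially correlated Gaussian noise per run, bypassing the GLM) and
full BOLD time series (HRF-convolved design × true patterns plus AR(1)
temporally and spatially correlated noise, with simulated head motion).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import glm as _glm
from .crossnobis import PatternSet, inverse_sqrt
from .design import TrialTimeline


@dataclass(frozen=True)
class EffectSpec:
    """Named nonnegative effect sizes (pattern units) of the factorial
    structure: separation along category, domain, quadrant and individual
    item axes."""

    category_separation: float = 0.0
    domain_separation: float = 0.0
    quadrant_separation: float = 0.0
    item_separation: float = 0.0

    def __post_init__(self):
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"negative effect size {name}={value}")


@dataclass(frozen=True)
class NoiseSpec:
    """Voxel noise model: scale ``sigma``, exchangeable spatial correlation
    ``rho`` and lag-1 temporal autocorrelation ``temporal_ar`` (time-series
    mode only).  The implied voxel covariance
    sigma^2 [(1-rho) I + rho J] is positive definite for
    -1/(P-1) < rho < 1."""

    sigma: float = 1.0
    spatial_correlation: float = 0.0
    temporal_ar: float = 0.0

    def covariance(self, n_voxels: int) -> np.ndarray:
        rho = self.spatial_correlation
        if not -1.0 / max(n_voxels - 1, 1) < rho < 1.0:
            raise ValueError("spatial correlation makes covariance non-PD")
        cov = np.full((n_voxels, n_voxels), rho)
        np.fill_diagonal(cov, 1.0)
        return self.sigma ** 2 * cov

    def chol(self, n_voxels: int) -> np.ndarray:
        if self.sigma == 0:
            return np.zeros((n_voxels, n_voxels))
        return np.linalg.cholesky(self.covariance(n_voxels))


#: default study noise: exchangeable rho strong enough that prewhitening
#: demonstrably matters, AR(1) temporal autocorrelation
DEFAULT_NOISE = NoiseSpec(sigma=1.0, spatial_correlation=0.3, temporal_ar=0.4)


@dataclass
class GroundTruthGeometry:
    """Known condition × voxel mean patterns and the effect sizes that
    built them."""

    conditions: list
    true_patterns: np.ndarray
    effect_spec: EffectSpec

    def __post_init__(self):
        self.true_patterns = np.asarray(self.true_patterns, dtype=float)
        if self.true_patterns.shape[0] != len(self.conditions):
            raise ValueError("pattern rows must match condition count")

    @property
    def n_voxels(self) -> int:
        return self.true_patterns.shape[1]

    def true_rdm(self, noise_cov: Optional[np.ndarray] = None) -> np.ndarray:
        """Closed-form squared Mahalanobis distances between true patterns
        (Euclidean if ``noise_cov`` is None)."""
        u = self.true_patterns
        if noise_cov is not None:
            u = u @ inverse_sqrt(noise_cov).T
        sq = (u ** 2).sum(axis=1)
        d = sq[:, None] + sq[None, :] - 2.0 * u @ u.T
        np.fill_diagonal(d, 0.0)
        return np.maximum(d, 0.0)


def _unit_vector(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal(n)
    return v / np.linalg.norm(v)


def make_geometry(conditions: Sequence, effect_spec: EffectSpec,
                  n_voxels: int, seed) -> GroundTruthGeometry:
    """Ground-truth geometry encoding the factorial condition structure.

    Each condition mean is the sum of the random unit vectors of its
    category, domain, quadrant (when defined) and of the condition itself,
    scaled by the corresponding effect sizes.
    """
    if n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    rng = np.random.default_rng(seed)
    cats = {c.item.category for c in conditions}
    doms = {c.domain for c in conditions}
    quads = {c.item.quadrant for c in conditions if c.item.quadrant}
    cat_v = {k: _unit_vector(rng, n_voxels) for k in sorted(cats)}
    dom_v = {k: _unit_vector(rng, n_voxels) for k in sorted(doms)}
    quad_v = {k: _unit_vector(rng, n_voxels) for k in sorted(quads)}
    patterns = np.zeros((len(conditions), n_voxels))
    for i, c in enumerate(conditions):
        p = (effect_spec.category_separation * cat_v[c.item.category]
             + effect_spec.domain_separation * dom_v[c.domain]
             + effect_spec.item_separation * _unit_vector(rng, n_voxels))
        if c.item.quadrant is not None:
            p = p + effect_spec.quadrant_separation * quad_v[c.item.quadrant]
        patterns[i] = p
    return GroundTruthGeometry(conditions=list(conditions),
                               true_patterns=patterns,
                               effect_spec=effect_spec)


def perturb_geometry(geometry: GroundTruthGeometry, scale: float,
                     seed) -> GroundTruthGeometry:
    """Per-subject variant: seeded Gaussian perturbation of the true
    patterns (scale in pattern units), giving group analyses realistic
    between-subject variance."""
    rng = np.random.default_rng(seed)
    noise = scale * rng.standard_normal(geometry.true_patterns.shape)
    return GroundTruthGeometry(conditions=list(geometry.conditions),
                               true_patterns=geometry.true_patterns + noise,
                               effect_spec=geometry.effect_spec)


def simulate_run_patterns(geometry: GroundTruthGeometry, n_runs: int,
                          noise_spec: NoiseSpec, seed,
                          subject_id: Optional[str] = None,
                          region: Optional[str] = None) -> PatternSet:
    """Beta-level shortcut: per run, true patterns plus an independent
    spatially correlated Gaussian noise draw."""
    if n_runs < 2:
        raise ValueError("crossnobis needs n_runs >= 2")
    rng = np.random.default_rng(seed)
    c, v = geometry.true_patterns.shape
    chol = noise_spec.chol(v)
    noise = rng.standard_normal((n_runs, c, v)) @ chol.T
    return PatternSet(patterns=geometry.true_patterns[None] + noise,
                      condition_names=[c_.name for c_ in geometry.conditions],
                      subject_id=subject_id, region=region)


def simulate_motion(n_timepoints: int, motion_amplitude: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Six rigid-body parameters as a seeded random walk (mm / radians)."""
    steps = rng.standard_normal((n_timepoints, 6))
    steps[:, 3:] /= 50.0  # rotations an order of magnitude smaller
    walk = np.cumsum(motion_amplitude * steps, axis=0)
    walk[0] = 0.0
    return walk


def simulate_timeseries(timeline: TrialTimeline,
                        geometry: GroundTruthGeometry,
                        noise_spec: NoiseSpec = DEFAULT_NOISE,
                        hrf_params: Optional[_glm.HRFParams] = None,
                        motion_amplitude: float = 0.0,
                        tr: float = _glm.DEFAULT_TR,
                        seed=0):
    """Forward BOLD model of one run.

    Signal is the HRF-convolved condition design times the true patterns;
    noise is AR(1) in time with the specified stationary voxel covariance;
    motion is a seeded random walk (it does not corrupt the signal — FD is
    exercised as a nuisance regressor, not as an artifact model).

    Returns ``(data, motion, design)`` where data is timepoints × voxels.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    rng = np.random.default_rng(seed)
    conditions = geometry.conditions
    design = _glm.build_design_matrix(timeline, tr=tr, hrf_params=hrf_params,
                                      conditions=conditions)
    t = design.n_timepoints
    v = geometry.n_voxels
    signal = design.condition_columns() @ geometry.true_patterns

    chol = noise_spec.chol(v)
    phi = noise_spec.temporal_ar
    innov = rng.standard_normal((t, v)) @ chol.T
    noise = np.empty_like(innov)
    noise[0] = innov[0]
    scale = np.sqrt(1.0 - phi ** 2)
    for i in range(1, t):
        noise[i] = phi * noise[i - 1] + scale * innov[i]

    motion = simulate_motion(t, motion_amplitude, rng)
    return signal + noise, motion, design
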