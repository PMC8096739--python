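"""End-to-end synthetic studies and calibration experiments.

``simulate_study`` runs the whole chain for one experiment — ground-truth
geometry per region, per-subject data (beta-level patterns or full BOLD
time series through the GLM), noise normalization, crossnobis RDMs,
selection averaging with outlier exclusion — and returns the tidy
per-subject distance table that the question framework consumes.

The calibration helpers quantify the statistical behaviour of the
estimator and of the gated inference on known ground truth: null-mean
unbiasedness, full-pipeline parameter recovery, gate type-I rate and
power at a pre-registered effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import glm as _glm
from .crossnobis import PatternSet, crossnobis_from_runs, crossnobis_rdm
from .design import (Condition, StimulusItem, TrialTimeline, EVENT_DURATION_S,
                     FIXATION_GAP_S, N_RUNS, carryover_sequence,
                     make_stimulus_set)
from .inference import (GateSpec, QuestionSpec, QuestionAnalysis,
                        bonferroni_alpha, REGIONS_8)
from .questions import subject_distances
from .simulate import (EffectSpec, GroundTruthGeometry, NoiseSpec,
                       make_geometry, perturb_geometry, simulate_run_patterns,
                       simulate_timeseries)
from .study import EXPERIMENT_SELECTIONS, SELECTIONS

#: named effect profiles for whole-study simulations: region -> EffectSpec
EFFECT_PROFILES = {
    # no signal anywhere: for type-I / null checks
    "null": lambda region: EffectSpec(),
    # scene regions carry category, quadrant and item structure; others
    # only weak item structure
    "scene_spatial": lambda region: (
        EffectSpec(category_separation=1.2, domain_separation=1.0,
                   quadrant_separation=0.8, item_separation=0.8)
        if region.split("_")[0] in ("OPA", "PPA", "RSC")
        else EffectSpec(domain_separation=0.6, item_separation=0.3)),
    # everything everywhere: smoke-test profile
    "distributed": lambda region: EffectSpec(
        category_separation=1.0, domain_separation=1.0,
        quadrant_separation=0.6, item_separation=0.6),
}


def two_condition_set(n_voxels_hint: int = 0) -> list:
    """A minimal two-condition stimulus set for calibration studies."""
    items = [StimulusItem(item_id=f"building:cal_{i}", label=f"cal_{i}",
                          category="building", quadrant=None, experiment=3)
             for i in range(2)]
    return [Condition(item=i, domain="imagery") for i in items]


def make_custom_timeline(conditions: Sequence, reps: int, run_id: int,
                         seed) -> TrialTimeline:
    """A small carry-over timeline over arbitrary conditions (calibration
    runs that do not need the full published designs)."""
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(99, run_id)))
    order = carryover_sequence(len(conditions), reps * len(conditions), rng)
    timeline = TrialTimeline(experiment=0, run_id=run_id)
    t = 0.0
    for idx in order:
        timeline.trials.append((t, EVENT_DURATION_S, "experimental",
                                conditions[idx]))
        t += EVENT_DURATION_S + FIXATION_GAP_S
    return timeline


@dataclass
class StudyData:
    """Simulated study: per-subject RDMs and the tidy distance table."""

    experiment: int
    conditions: list
    rdms: dict                   # (subject, region) -> RDM
    distances: pd.DataFrame      # subject, region, selection, value, ...
    effect_profile: str = ""


def simulate_study(experiment: int, n_subjects: int, seed,
                   regions: Sequence[str] = REGIONS_8,
                   effect_profile: str = "scene_spatial",
                   noise: Optional[NoiseSpec] = None,
                   n_voxels: int = 40, n_runs: Optional[int] = None,
                   subject_scale: float = 0.3,
                   mode: str = "patterns",
                   selections: Optional[Sequence[str]] = None,
                   exclude_k: Optional[float] = 2.0) -> StudyData:
    """Simulate one experiment's subjects and compute their distance table.

    ``mode`` "patterns" draws beta-level run patterns directly (fast);
    "timeseries" generates BOLD runs, fits the GLM and noise-normalizes
    with the pooled shrunk residual covariance (the full chain).
    ``subject_scale`` perturbs each subject's true patterns so group tests
    see realistic between-subject variance.
    """
    noise = noise if noise is not None else NoiseSpec(
        sigma=1.0, spatial_correlation=0.3, temporal_ar=0.4)
    n_runs = n_runs if n_runs is not None else N_RUNS[experiment]
    conditions = make_stimulus_set(experiment)
    labels = list(selections if selections is not None
                  else EXPERIMENT_SELECTIONS[experiment])
    profile = EFFECT_PROFILES[effect_profile]

    rdms = {}
    for r_i, region in enumerate(regions):
        base = make_geometry(conditions, profile(region), n_voxels,
                             np.random.SeedSequence(entropy=int(seed),
                                                    spawn_key=(experiment, r_i)))
        for s_i in range(n_subjects):
            subject = f"sub-{s_i + 1:02d}"
            sseq = np.random.SeedSequence(entropy=int(seed),
                                          spawn_key=(experiment, r_i, s_i))
            geo = perturb_geometry(base, subject_scale, sseq)
            child = sseq.spawn(n_runs + 1)
            if mode == "patterns":
                ps = simulate_run_patterns(geo, n_runs, noise, child[0],
                                           subject_id=subject, region=region)
                rdm = crossnobis_rdm(ps)
            elif mode == "timeseries":
                runs, resids, dofs = [], [], []
                for m in range(n_runs):
                    timeline = make_custom_timeline(conditions, 2, m + 1,
                                                    int(seed) + r_i)
                    data, motion, design = simulate_timeseries(
                        timeline, geo, noise_spec=noise,
                        motion_amplitude=0.05, seed=child[m])
                    dm = _glm.build_design_matrix(
                        timeline, n_volumes=data.shape[0], motion=motion,
                        conditions=conditions)
                    fit = _glm.fit_glm(data, dm)
                    runs.append(fit.condition_patterns())
                    resids.append(fit.residuals)
                    dofs.append(fit.dof)
                ps = PatternSet(patterns=np.stack(runs),
                                condition_names=[c.name for c in conditions],
                                subject_id=subject, region=region)
                rdm = crossnobis_from_runs(ps, resids, dofs=dofs)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            rdms[(subject, region)] = rdm

    frames = []
    for region in regions:
        region_rdms = [rdms[(f"sub-{s + 1:02d}", region)]
                       for s in range(n_subjects)]
        for label in labels:
            frames.append(subject_distances(region_rdms, conditions,
                                            SELECTIONS[label],
                                            exclude_k=exclude_k))
    distances = pd.concat(frames, ignore_index=True)
    return StudyData(experiment=experiment, conditions=conditions, rdms=rdms,
                     distances=distances, effect_profile=effect_profile)


# ---------------------------------------------------------------------------
# calibration experiments


def null_distance_mean(n_replicates: int = 1000, n_conditions: int = 2,
                       n_voxels: int = 100, n_runs: int = 5,
                       sigma: float = 1.0, seed=0) -> dict:
    """Mean crossnobis distance under a null geometry (identical true
    patterns), with its Monte-Carlo standard error.

    The estimator's meaningful zero point: the mean over replicates should
    sit within ~3 SEs of zero.
    """
    items = [StimulusItem(item_id=f"building:null_{i}", label=f"null_{i}",
                          category="building", quadrant=None, experiment=3)
             for i in range(n_conditions)]
    conds = [Condition(item=i, domain="imagery") for i in items]
    geo = GroundTruthGeometry(conditions=conds,
                              true_patterns=np.zeros((n_conditions, n_voxels)),
                              effect_spec=EffectSpec())
    noise = NoiseSpec(sigma=sigma)
    rng = np.random.SeedSequence(entropy=int(seed), spawn_key=(41,))
    children = rng.spawn(n_replicates)
    vals = np.empty(n_replicates)
    for i in range(n_replicates):
        ps = simulate_run_patterns(geo, n_runs, noise, children[i])
        vals[i] = crossnobis_rdm(ps).matrix[0, 1]
    return {"mean": float(vals.mean()),
            "mc_se": float(vals.std(ddof=1) / np.sqrt(n_replicates)),
            "n_replicates": n_replicates}


def recovery_experiment(n_replicates: int = 200, true_distance: float = 4.0,
                        n_voxels: int = 12, n_runs: int = 4,
                        reps_per_condition: int = 8,
                        rho: float = 0.3, sigma: float = 1.0,
                        seed=0) -> dict:
    """Full-pipeline parameter recovery.

    Simulates BOLD runs of a two-condition design with a known true
    squared Mahalanobis distance, fits the GLM, noise-normalizes with the
    pooled residual covariance (shrinkage 0, Wishart-corrected inverse so
    the implied precision is unbiased) and averages the crossnobis
    estimates over replicates.  Returns the mean estimate, the truth, and
    the Monte-Carlo SE.
    """
    conds = two_condition_set()
    noise = NoiseSpec(sigma=sigma, spatial_correlation=rho, temporal_ar=0.0)
    cov = noise.covariance(n_voxels)
    # mean difference along the first eigvector scaled for the target
    # Mahalanobis distance: delta' Sigma^-1 delta = true_distance
    delta_dir = np.ones(n_voxels) / np.sqrt(n_voxels)
    maha_unit = float(delta_dir @ np.linalg.solve(cov, delta_dir))
    delta = delta_dir * np.sqrt(true_distance / maha_unit)
    patterns = np.stack([np.zeros(n_voxels), delta])
    geo = GroundTruthGeometry(conditions=conds, true_patterns=patterns,
                              effect_spec=EffectSpec())

    root = np.random.SeedSequence(entropy=int(seed), spawn_key=(42,))
    children = root.spawn(n_replicates)
    est = np.empty(n_replicates)
    timelines = [make_custom_timeline(conds, reps_per_condition, m + 1, seed)
                 for m in range(n_runs)]
    for i in range(n_replicates):
        run_seeds = children[i].spawn(n_runs)
        runs, resids, dofs = [], [], []
        for m in range(n_runs):
            data, motion, design = simulate_timeseries(
                timelines[m], geo, noise_spec=noise, motion_amplitude=0.02,
                seed=run_seeds[m])
            dm = _glm.build_design_matrix(timelines[m],
                                          n_volumes=data.shape[0],
                                          motion=motion, conditions=conds)
            fit = _glm.fit_glm(data, dm)
            runs.append(fit.condition_patterns())
            resids.append(fit.residuals)
            dofs.append(fit.dof)
        ps = PatternSet(patterns=np.stack(runs),
                        condition_names=[c.name for c in conds])
        rdm = crossnobis_from_runs(ps, resids, dofs=dofs, shrinkage=0.0,
                                   noise_mode="pooled", bias_correction=True)
        est[i] = rdm.matrix[0, 1]
    return {"mean_estimate": float(est.mean()),
            "true_distance": float(true_distance),
            "mc_se": float(est.std(ddof=1) / np.sqrt(n_replicates)),
            "n_replicates": n_replicates}


def calibrate_effect_size(n_subjects: int = 16, n_voxels: int = 100,
                          n_runs: int = 5, sigma: float = 1.0,
                          subject_scale: float = 0.25,
                          alpha: float = bonferroni_alpha(0.05, 8),
                          target_power: float = 0.95) -> float:
    """Pre-registered effect size for the power study: the true squared
    distance D whose analytic gate power reaches the target.

    Uses the crossnobis replicate variance under white pattern noise
    (difference noise tau^2 = 2 sigma^2 per voxel),
    Var(d) ~= 4 D tau^2 / M + 2 P tau^4 / (M (M-1)), plus between-subject
    variance from the per-subject signal gain g_s ~ N(1, subject_scale^2)
    (true distance g_s^2 D), in a noncentral-t power calculation.
    """
    tau2 = 2.0 * sigma ** 2
    s2 = subject_scale ** 2
    df = n_subjects - 1
    t_crit = stats.t.isf(alpha, df)

    def power(d):
        var_within = 4.0 * d * tau2 / n_runs + \
            2.0 * n_voxels * tau2 ** 2 / (n_runs * (n_runs - 1))
        var_between = (4.0 * s2 + 2.0 * s2 ** 2) * d ** 2
        sd = np.sqrt(var_within + var_between)
        ncp = (1.0 + s2) * d / (sd / np.sqrt(n_subjects))
        return stats.nct.sf(t_crit, df, ncp)

    lo, hi = 0.0, 1.0
    while power(hi) < target_power:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("no attainable effect size")
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if power(mid) < target_power:
            lo = mid
        else:
            hi = mid
    return hi


def gate_calibration(n_replicates: int = 500, n_subjects: int = 16,
                     regions: Sequence[str] = REGIONS_8,
                     signal_region: Optional[str] = None,
                     true_distance: float = 0.0,
                     n_voxels: int = 100, n_runs: int = 5,
                     sigma: float = 1.0, subject_scale: float = 0.25,
                     seed=0) -> dict:
    """Gate rejection rates over seeded replicate studies.

    Each replicate simulates ``n_subjects`` subjects' two-condition
    patterns per region (true squared distance ``true_distance`` in
    ``signal_region``, exactly zero elsewhere), computes per-subject
    crossnobis distances and runs the one-sample gate through the question
    framework at alpha = 0.05 / n_regions.  Between-subject variability is
    a multiplicative gain g_s ~ N(1, subject_scale^2) on the signal
    pattern difference, so null regions remain exactly null.  Returns
    rejection rates for null and signal regions with binomial SEs.
    """
    conds = two_condition_set()
    spec = QuestionSpec(question_id="calibration", regions=tuple(regions),
                        gates=(GateSpec("pair"),))
    noise = NoiseSpec(sigma=sigma)
    delta = np.zeros(n_voxels)
    delta[0] = np.sqrt(true_distance)
    root = np.random.SeedSequence(entropy=int(seed), spawn_key=(43,))
    reps = root.spawn(n_replicates)

    null_hits, null_n = 0, 0
    sig_hits, sig_n = 0, 0
    for i in range(n_replicates):
        rows = []
        region_seeds = reps[i].spawn(len(regions))
        for r_i, region in enumerate(regions):
            base = delta if region == signal_region else np.zeros(n_voxels)
            subj_seeds = region_seeds[r_i].spawn(n_subjects)
            for s_i in range(n_subjects):
                srng = np.random.default_rng(subj_seeds[s_i])
                gain = 1.0 + subject_scale * srng.standard_normal()
                geo = GroundTruthGeometry(
                    conditions=conds,
                    true_patterns=np.stack([np.zeros(n_voxels), gain * base]),
                    effect_spec=EffectSpec())
                ps = simulate_run_patterns(geo, n_runs, noise, srng)
                rows.append({"subject": f"s{s_i}", "region": region,
                             "selection": "pair",
                             "value": crossnobis_rdm(ps).matrix[0, 1]})
        results = QuestionAnalysis(spec, pd.DataFrame(rows)).fit()
        for g in results.gate_results:
            if g.region == signal_region:
                sig_hits += g.significant
                sig_n += 1
            else:
                null_hits += g.significant
                null_n += 1

    out = {"alpha": spec.gate_alpha,
           "null_rate": null_hits / null_n if null_n else np.nan,
           "null_se": float(np.sqrt(spec.gate_alpha * (1 - spec.gate_alpha)
                                    / null_n)) if null_n else np.nan,
           "n_null_tests": null_n}
    if signal_region is not None:
        out.update({"power": sig_hits / sig_n if sig_n else np.nan,
                    "n_signal_tests": sig_n,
                    "true_distance": true_distance})
    return out
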