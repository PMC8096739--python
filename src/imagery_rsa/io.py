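"""Real-data ingestion and container I/O.

Users with their own GLM output can enter the pipeline at the RDM stage
by supplying per-run beta volumes (4-D NIfTI, one volume per condition),
a binary ROI mask NIfTI, and a condition-label table; the loaders below
turn those into the same :class:`PatternSet` the simulator produces.
Matrix containers are plain TSV for portability.
"""

from __future__ import annotations

import pathlib
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .crossnobis import PatternSet


def load_roi_mask(path) -> np.ndarray:
    """Boolean voxel mask from a NIfTI volume (non-zero = inside)."""
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) != 0
    if mask.ndim != 3:
        raise ValueError("ROI mask must be a 3-D volume")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return mask


def load_beta_patterns(beta_paths: Sequence, mask,
                       condition_names: Sequence[str],
                       subject_id: Optional[str] = None,
                       region: Optional[str] = None) -> PatternSet:
    """PatternSet from per-run 4-D beta NIfTIs restricted to an ROI.

    ``beta_paths`` holds one file per run; each file's 4th axis must
    carry the conditions in the order of ``condition_names``.  ``mask``
    is a boolean volume or a path to one.
    """
    if not isinstance(mask, np.ndarray):
        mask = load_roi_mask(mask)
    runs = []
    for path in beta_paths:
        vol = np.asarray(nib.load(str(path)).dataobj)
        if vol.ndim != 4:
            raise ValueError(f"{path}: beta image must be 4-D")
        if vol.shape[3] != len(condition_names):
            raise ValueError(
                f"{path}: {vol.shape[3]} volumes != "
                f"{len(condition_names)} conditions")
        if vol.shape[:3] != mask.shape:
            raise ValueError(f"{path}: grid does not match the mask")
        runs.append(vol[mask].T)  # condition x voxel
    return PatternSet(patterns=np.stack(runs),
                      condition_names=list(condition_names),
                      subject_id=subject_id, region=region)


def export_beta_nifti(patterns: PatternSet, mask: np.ndarray,
                      out_dir, affine: Optional[np.ndarray] = None) -> list:
    """Write each run's condition × voxel patterns back into 4-D volumes
    (with the ROI mask as a sidecar), the inverse of the loader — mainly
    for round-tripping simulated data through real-data tooling."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = affine if affine is not None else np.eye(4)
    if int(mask.sum()) != patterns.n_voxels:
        raise ValueError("mask voxel count does not match the patterns")
    paths = []
    for m in range(patterns.n_runs):
        vol = np.zeros(mask.shape + (patterns.n_conditions,), dtype=float)
        vol[mask] = patterns.patterns[m].T
        path = out_dir / f"run-{m + 1:02d}_betas.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), str(path))
        paths.append(path)
    mask_path = out_dir / "roi_mask.nii.gz"
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(mask_path))
    return paths + [mask_path]


def write_pattern_tsv(patterns: PatternSet, path) -> None:
    """Long-form TSV container (run, condition, voxel, value) with the
    condition labels inline."""
    m, c, v = patterns.patterns.shape
    run_idx, cond_idx, vox_idx = np.meshgrid(
        np.arange(m), np.arange(c), np.arange(v), indexing="ij")
    pd.DataFrame({
        "run": run_idx.ravel() + 1,
        "condition": np.asarray(patterns.condition_names)[cond_idx.ravel()],
        "voxel": vox_idx.ravel(),
        "value": patterns.patterns.ravel(),
    }).to_csv(path, sep="\t", index=False)


def read_pattern_tsv(path, subject_id: Optional[str] = None,
                     region: Optional[str] = None) -> PatternSet:
    frame = pd.read_csv(path, sep="\t")
    runs = sorted(frame["run"].unique())
    conditions = list(dict.fromkeys(frame["condition"]))
    n_vox = frame["voxel"].max() + 1
    patterns = np.empty((len(runs), len(conditions), n_vox))
    lookup = {c: i for i, c in enumerate(conditions)}
    for (run, cond), sub in frame.groupby(["run", "condition"], sort=False):
        patterns[runs.index(run), lookup[cond], sub["voxel"]] = sub["value"]
    return PatternSet(patterns=patterns, condition_names=conditions,
                      subject_id=subject_id, region=region)
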