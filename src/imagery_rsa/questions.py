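"""From per-subject RDMs to per-question averaged distances.

RDM cells are selected by a predicate over the three condition factors —
same/different category, domain and spatial quadrant — optionally
restricted to particular categories or domains, then averaged within
subject.  Before averaging, cell values more than two standard deviations
from the group mean (pooled across subjects and stimulus pairs of the same
selection, per region) are excluded.  Subjects who took part in two
experiments contribute a single merged (averaged) value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .crossnobis import RDM

_FACTORS = ("category", "domain", "quadrant")
_MODES = ("same", "different", "ignore")


@dataclass(frozen=True)
class CellSelection:
    """Predicate over unordered condition pairs.

    ``predicate`` maps factor name -> "same" | "different" | "ignore";
    ``restrict`` optionally limits the levels both pair members may take,
    e.g. {"category": ("building",), "domain": ("perception",)}.
    Diagonal (self) cells are never selected.
    """

    label: str
    predicate: dict = field(default_factory=dict)
    restrict: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.predicate.items():
            if k not in _FACTORS:
                raise ValueError(f"unknown factor {k!r}")
            if v not in _MODES:
                raise ValueError(f"unknown predicate mode {v!r}")
        for k in self.restrict:
            if k not in _FACTORS:
                raise ValueError(f"unknown factor {k!r}")


def _condition_factors(condition) -> dict:
    """Factor levels of a Condition (or of a mapping with those keys)."""
    if isinstance(condition, dict):
        return {f: condition.get(f) for f in _FACTORS}
    return {"category": condition.item.category,
            "domain": condition.domain,
            "quadrant": condition.item.quadrant}


def select_pairs(conditions: Sequence, selection: CellSelection) -> list:
    """Unordered index pairs (i < j) satisfying every predicate clause.

    Raises if the predicate or restriction references a factor that is
    absent from the condition labels (e.g. quadrant in Experiment 3).
    """
    factors = [_condition_factors(c) for c in conditions]
    referenced = ([k for k, v in selection.predicate.items() if v != "ignore"]
                  + list(selection.restrict))
    for f in referenced:
        if any(fac[f] is None for fac in factors):
            raise ValueError(
                f"predicate references factor {f!r} absent from the labels")
    pairs = []
    for i, j in combinations(range(len(conditions)), 2):
        fi, fj = factors[i], factors[j]
        ok = True
        for f, mode in selection.predicate.items():
            if mode == "same" and fi[f] != fj[f]:
                ok = False
            elif mode == "different" and fi[f] == fj[f]:
                ok = False
        for f, levels in selection.restrict.items():
            levels = (levels,) if isinstance(levels, str) else tuple(levels)
            if fi[f] not in levels or fj[f] not in levels:
                ok = False
        if ok:
            pairs.append((i, j))
    return pairs


def exclude_outliers(values: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Inclusion mask over a subject × pair value matrix.

    Mean and SD are pooled over all entries of the group (subjects and
    stimulus pairs together); entries strictly beyond mean ± k·SD are
    masked out.  A value exactly at the boundary is retained.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("outlier group needs at least 2 values")
    mean = np.nanmean(values)
    sd = np.nanstd(values, ddof=1)
    keep = np.abs(values - mean) <= k * sd
    keep &= ~np.isnan(values)
    return keep


@dataclass
class SubjectDistance:
    """One subject's averaged distance for one selection in one region."""

    subject_id: str
    region_id: str
    selection: str
    value: Optional[float]
    n_cells: int
    n_excluded: int


def average_cells(rdm: RDM, pairs: Sequence,
                  mask: Optional[np.ndarray] = None) -> SubjectDistance:
    """Arithmetic mean of the selected, non-excluded RDM cells.

    ``mask`` is a per-pair inclusion vector; if every cell is excluded the
    value is absent (None)."""
    if not len(pairs):
        raise ValueError("no pairs selected")
    cells = np.array([rdm.matrix[i, j] for i, j in pairs])
    if mask is None:
        mask = np.ones(len(cells), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n_excluded = int((~mask).sum())
    value = float(cells[mask].mean()) if mask.any() else None
    return SubjectDistance(subject_id=str(rdm.subject_id),
                           region_id=str(rdm.region),
                           selection="", value=value,
                           n_cells=len(cells), n_excluded=n_excluded)


def subject_distances(rdms: Sequence[RDM], conditions: Sequence,
                      selection: CellSelection,
                      exclude_k: Optional[float] = 2.0) -> pd.DataFrame:
    """Per-subject averaged distances for one selection in one region.

    ``rdms`` are the subjects' RDMs of a single region, sharing the
    condition ordering of ``conditions``.  The ±k SD exclusion pools cell
    values across subjects and stimulus pairs of this selection (masking
    happens before averaging); pass ``exclude_k=None`` to disable.
    Returns a tidy frame (subject, region, selection, value, n_cells,
    n_excluded).
    """
    pairs = select_pairs(conditions, selection)
    if not pairs:
        raise ValueError(f"selection {selection.label!r} matches no pairs")
    cells = np.array([[r.matrix[i, j] for i, j in pairs] for r in rdms])
    if exclude_k is not None:
        mask = exclude_outliers(cells, k=exclude_k)
    else:
        mask = np.ones_like(cells, dtype=bool)
    rows = []
    for s, rdm in enumerate(rdms):
        sd = average_cells(rdm, pairs, mask[s])
        rows.append({"subject": rdm.subject_id, "region": rdm.region,
                     "selection": selection.label, "value": sd.value,
                     "n_cells": sd.n_cells, "n_excluded": sd.n_excluded})
    return pd.DataFrame(rows)


def merge_repeat_subjects(frames_by_experiment: dict,
                          overlap_ids: Sequence) -> pd.DataFrame:
    """Merge per-subject value tables across experiments.

    Subjects in ``overlap_ids`` (participants of both experiments)
    contribute a single row per (region, selection) holding the arithmetic
    mean of their two values; all other subjects pass through unchanged.
    A subject id occurring twice within one experiment's table (per
    region/selection) raises.
    """
    keys = ["subject", "region", "selection"]
    frames = []
    for exp, frame in frames_by_experiment.items():
        if frame.duplicated(subset=keys).any():
            raise ValueError(f"duplicate subject rows within experiment {exp}")
        frames.append(frame.assign(_experiment=exp))
    stacked = pd.concat(frames, ignore_index=True)
    overlap = set(overlap_ids)
    n_exps = stacked.groupby("subject")["_experiment"].nunique()
    missing = [s for s in overlap if n_exps.get(s, 0) < 2]
    if missing:
        raise ValueError(f"overlap ids absent from the tables: {missing}")
    merged = (stacked.groupby(keys, as_index=False)
              .agg(value=("value", "mean"),
                   n_cells=("n_cells", "sum"),
                   n_excluded=("n_excluded", "sum"),
                   n_experiments=("_experiment", "nunique")))
    bad = merged[(merged["n_experiments"] > 1)
                 & ~merged["subject"].isin(overlap)]
    if not bad.empty:
        raise ValueError(
            f"subjects present in several experiments but not declared as "
            f"overlapping: {sorted(bad['subject'].unique())}")
    return merged.drop(columns="n_experiments")
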