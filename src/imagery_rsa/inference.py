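"""Two-stage, region-gated statistical testing of averaged RDM distances.

Stage 1 ("gate"): per region, one-tailed one-sample t-tests ask whether the
averaged crossnobis distance of each selection is higher than zero, i.e.
whether the region discriminates the selected stimulus pairs at all, at a
Bonferroni level of 0.05 divided by the number of seed regions in the
analysis (0.00625 for the eight hemisphere-resolved scene regions + HC,
0.00416 when the four face-selective regions join).

Stage 2: only in regions whose required gates all passed, directional
paired / two-sample t-tests or one-way ANOVAs compare categories or
domains, again Bonferroni-corrected by the number of regions entering the
comparison.

The framework is exposed statsmodels-style: a :class:`QuestionAnalysis`
model is built from a tidy per-subject distance table and a declarative
:class:`QuestionSpec`; ``fit()`` returns :class:`QuestionResults` carrying
every test with its statistic, dof, p-value, the alpha it was held to, and
an audit trail of which regions entered stage 2 and why.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BASE_ALPHA = 0.05

SCENE_REGIONS = ("OPA", "PPA", "RSC")
FACE_REGIONS = ("FFA", "OFA")
HEMIS = ("LH", "RH")

#: the eight hemisphere-resolved seed regions of the quadrant/building
#: analyses (scene-selective + hippocampus)
REGIONS_8 = tuple(f"{r}_{h}" for r in SCENE_REGIONS + ("HC",) for h in HEMIS)
#: the twelve seeds when face-selective regions are included
REGIONS_12 = tuple(f"{r}_{h}"
                   for r in SCENE_REGIONS + FACE_REGIONS + ("HC",)
                   for h in HEMIS)
FACE_REGIONS_4 = tuple(f"{r}_{h}" for r in FACE_REGIONS for h in HEMIS)
SCENE_REGIONS_6 = tuple(f"{r}_{h}" for r in SCENE_REGIONS for h in HEMIS)


@dataclass
class TestResult:
    """One statistical test: statistic, dof, p, tail and significance."""

    region: Optional[str]
    test: str
    statistic: float
    df: tuple
    p: float
    tail: str
    alpha_used: Optional[float] = None
    significant: Optional[bool] = None
    note: Optional[str] = None

    def judge(self, alpha: float) -> "TestResult":
        self.alpha_used = alpha
        self.significant = bool(self.p < alpha)  # strict, matching "p < a"
        return self


def one_tailed_p(t: float, df: float) -> float:
    """Upper-tail p of Student's t — the printed (t, df) -> p conversion."""
    return float(stats.t.sf(t, df))


def _tail_p(t: float, df: float, tail: str) -> float:
    if tail == "greater":
        return float(stats.t.sf(t, df))
    if tail == "less":
        return float(stats.t.cdf(t, df))
    if tail == "two_sided":
        return float(2.0 * stats.t.sf(abs(t), df))
    raise ValueError(f"unknown tail {tail!r}")


def one_sample_t(values, tail: str = "greater", popmean: float = 0.0,
                 region: Optional[str] = None) -> TestResult:
    """t = mean / (sd / sqrt(n)) against ``popmean``, df = n - 1.

    One-tailed upper p by default (distances higher than zero).  Zero
    sample variance with a nonzero mean yields p = 0 (or 1), flagged in
    ``note``.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValueError("one-sample t-test needs n >= 2")
    mean = x.mean() - popmean
    sd = x.std(ddof=1)
    if sd == 0:
        t = 0.0 if mean == 0 else np.inf * np.sign(mean)
        p = _tail_p(t, n - 1, tail) if np.isfinite(t) else (
            0.0 if (tail != "less") == (mean > 0) else 1.0)
        return TestResult(region=region, test="one_sample_t", statistic=t,
                          df=(n - 1,), p=p, tail=tail, note="zero variance")
    t = mean / (sd / np.sqrt(n))
    return TestResult(region=region, test="one_sample_t", statistic=float(t),
                      df=(n - 1,), p=_tail_p(t, n - 1, tail), tail=tail)


def paired_t(values_a, values_b, tail: str = "greater",
             region: Optional[str] = None) -> TestResult:
    """One-sample t on within-subject differences a - b."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    res = one_sample_t(a - b, tail=tail, region=region)
    res.test = "paired_t"
    return res


def two_sample_t(values_a, values_b, tail: str = "greater",
                 variance: str = "pooled",
                 region: Optional[str] = None) -> TestResult:
    """Independent-samples t; pooled variance with df = n_a + n_b - 2 by
    default, Welch as an option."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    alternative = {"greater": "greater", "less": "less",
                   "two_sided": "two-sided"}[tail]
    if variance == "pooled":
        t, p = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
        df = a.size + b.size - 2
    elif variance == "welch":
        r = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        t, p, df = r.statistic, r.pvalue, r.df
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    return TestResult(region=region, test="two_sample_t",
                      statistic=float(t), df=(float(df),), p=float(p),
                      tail=tail)


def one_way_anova(groups: Sequence, region: Optional[str] = None) -> TestResult:
    """One-way between-groups ANOVA; F = MSbetween / MSwithin."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 groups with n >= 2 each")
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return TestResult(region=region, test="one_way_anova",
                      statistic=float(f), df=(k - 1, n - k), p=float(p),
                      tail="upper")


def bonferroni_alpha(base_alpha: float, n_regions: int) -> float:
    """Seed-level correction: per-test alpha = base / number of regions."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    return base_alpha / n_regions


# ---------------------------------------------------------------------------
# declarative question specs and the model/results pair


@dataclass(frozen=True)
class GateSpec:
    """One stage-1 selection tested against zero in every region."""

    selection: str
    tail: str = "greater"


@dataclass(frozen=True)
class FollowupSpec:
    """One stage-2 comparison.

    ``requires`` lists the gate selections that must all be significant in
    a region for it to enter this comparison (default: every gate);
    ``region_subset`` additionally restricts the candidate regions (e.g.
    face-selective areas only).  ``alpha`` fixes the threshold explicitly;
    if None it is base_alpha / (number of regions actually tested).
    """

    label: str
    kind: str  # paired_t | two_sample_t | anova
    selections: tuple
    tail: str = "greater"
    requires: Optional[tuple] = None
    region_subset: Optional[tuple] = None
    alpha: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("paired_t", "two_sample_t", "anova"):
            raise ValueError(f"unknown followup kind {self.kind!r}")
        if self.kind != "anova" and len(self.selections) != 2:
            raise ValueError("t-test followups compare exactly 2 selections")


@dataclass(frozen=True)
class QuestionSpec:
    """Declarative description of one Q-style analysis."""

    question_id: str
    regions: tuple
    gates: tuple
    followups: tuple = ()
    base_alpha: float = BASE_ALPHA
    gate_divisor: Optional[int] = None  # default: number of regions

    @property
    def gate_alpha(self) -> float:
        return bonferroni_alpha(self.base_alpha,
                                self.gate_divisor or len(self.regions))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QuestionSpec":
        gates = tuple(GateSpec(**g) for g in d["gates"])
        fups = tuple(FollowupSpec(**{**f, "selections": tuple(f["selections"]),
                                     "requires": tuple(f["requires"]) if f.get("requires") else None,
                                     "region_subset": tuple(f["region_subset"]) if f.get("region_subset") else None})
                     for f in d.get("followups", ()))
        return cls(question_id=d["question_id"], regions=tuple(d["regions"]),
                   gates=gates, followups=fups,
                   base_alpha=d.get("base_alpha", BASE_ALPHA),
                   gate_divisor=d.get("gate_divisor"))


class QuestionResults:
    """Fitted results of one question: gate and follow-up tests, eligible
    regions, and an audit trail."""

    def __init__(self, spec: QuestionSpec, gate_results: list,
                 followup_results: dict, eligible: dict, audit: dict):
        self.spec = spec
        self.gate_results = gate_results
        self.followup_results = followup_results
        self.eligible = eligible
        self.audit = audit
        self._check_gate_discipline()

    def _check_gate_discipline(self):
        for label, results in self.followup_results.items():
            allowed = set(self.eligible[label])
            for r in results:
                if r.region not in allowed:
                    raise AssertionError(
                        f"stage-2 result for ineligible region {r.region}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.gate_results:
            rows.append({"question": self.spec.question_id, "stage": 1,
                         "comparison": g.note or "", **_result_row(g)})
        for label, results in self.followup_results.items():
            for r in results:
                rows.append({"question": self.spec.question_id, "stage": 2,
                             "comparison": label, **_result_row(r)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        spec = self.spec
        lines = [f"Question {spec.question_id}",
                 f"  regions: {len(spec.regions)}  "
                 f"gate alpha: {spec.gate_alpha:.6g} "
                 f"(= {spec.base_alpha}/{spec.gate_divisor or len(spec.regions)})",
                 "  Stage 1 (one-sample gates, distance > 0):"]
        for g in self.gate_results:
            mark = "*" if g.significant else " "
            lines.append(
                f"   {mark} {g.region:>8s}  {self.audit['gate_selection'][id(g)]:<34s}"
                f" t({g.df[0]}) = {g.statistic: 7.2f}  p = {g.p:.3g}")
        for fup in spec.followups:
            tested = self.eligible[fup.label]
            lines.append(f"  Stage 2 [{fup.label}] ({fup.kind}, "
                         f"alpha = {self.audit['followup_alpha'][fup.label]:.6g}; "
                         f"{len(tested)} eligible region(s)):")
            if not tested:
                lines.append("      no region passed the required gates")
            for r in self.followup_results[fup.label]:
                mark = "*" if r.significant else " "
                dfs = ", ".join(f"{d:g}" for d in r.df)
                lines.append(f"   {mark} {r.region:>8s}  "
                             f"stat({dfs}) = {r.statistic: 7.2f}  p = {r.p:.3g}")
        return "\n".join(lines)


def _result_row(r: TestResult) -> dict:
    return {"region": r.region, "test": r.test, "statistic": r.statistic,
            "df1": r.df[0], "df2": r.df[1] if len(r.df) > 1 else np.nan,
            "p": r.p, "alpha": r.alpha_used, "significant": r.significant,
            "tail": r.tail}


class QuestionAnalysis:
    """Model object: one question spec applied to a tidy distance table.

    ``distances`` needs columns (subject, region, selection, value); rows
    with absent values (all cells excluded) are dropped listwise per
    comparison, which the audit trail records.
    """

    def __init__(self, spec: QuestionSpec, distances: pd.DataFrame):
        needed = {"subject", "region", "selection", "value"}
        if not needed.issubset(distances.columns):
            raise ValueError(f"distance table must have columns {sorted(needed)}")
        self.spec = spec
        self.distances = distances
        known = set(distances["selection"].unique())
        wanted = {g.selection for g in spec.gates}
        for f in spec.followups:
            wanted.update(f.selections)
        missing = wanted - known
        if missing:
            raise ValueError(f"distance table lacks selections {sorted(missing)}")

    @classmethod
    def from_distances(cls, spec: QuestionSpec,
                       distances: pd.DataFrame) -> "QuestionAnalysis":
        return cls(spec, distances)

    def _values(self, region: str, selection: str) -> pd.DataFrame:
        d = self.distances
        sub = d[(d["region"] == region) & (d["selection"] == selection)]
        return sub.dropna(subset=["value"])

    def fit(self) -> QuestionResults:
        spec = self.spec
        gate_alpha = spec.gate_alpha
        gate_results, gate_sig = [], {}
        gate_selection_of = {}
        for region in spec.regions:
            for gate in spec.gates:
                vals = self._values(region, gate.selection)["value"]
                res = one_sample_t(vals, tail=gate.tail, region=region)
                res.judge(gate_alpha)
                res.note = gate.selection
                gate_results.append(res)
                gate_sig[(region, gate.selection)] = res.significant
                gate_selection_of[id(res)] = gate.selection

        followup_results, eligible, fup_alpha = {}, {}, {}
        dropped_subjects = {}
        for fup in spec.followups:
            required = fup.requires or tuple(g.selection for g in spec.gates)
            candidates = [r for r in spec.regions
                          if fup.region_subset is None or r in fup.region_subset]
            regions = [r for r in candidates
                       if all(gate_sig.get((r, s), False) for s in required)]
            eligible[fup.label] = regions
            alpha = fup.alpha if fup.alpha is not None else (
                bonferroni_alpha(spec.base_alpha, len(regions)) if regions
                else None)
            fup_alpha[fup.label] = alpha if alpha is not None else np.nan
            results = []
            for region in regions:
                if fup.kind == "paired_t":
                    a = self._values(region, fup.selections[0])
                    b = self._values(region, fup.selections[1])
                    merged = a.merge(b, on="subject", suffixes=("_a", "_b"))
                    n_drop = max(len(a), len(b)) - len(merged)
                    if n_drop:
                        dropped_subjects[(fup.label, region)] = n_drop
                    res = paired_t(merged["value_a"], merged["value_b"],
                                   tail=fup.tail, region=region)
                elif fup.kind == "two_sample_t":
                    res = two_sample_t(
                        self._values(region, fup.selections[0])["value"],
                        self._values(region, fup.selections[1])["value"],
                        tail=fup.tail, region=region)
                else:
                    groups = [self._values(region, s)["value"]
                              for s in fup.selections]
                    res = one_way_anova(groups, region=region)
                results.append(res.judge(alpha))
            followup_results[fup.label] = results

        audit = {"gate_alpha": gate_alpha,
                 "gate_selection": gate_selection_of,
                 "followup_alpha": fup_alpha,
                 "eligible": eligible,
                 "dropped_subjects": dropped_subjects}
        return QuestionResults(spec, gate_results, followup_results,
                               eligible, audit)


def run_question(spec: QuestionSpec, distances: pd.DataFrame) -> QuestionResults:
    """Convenience wrapper: build the model and fit it."""
    return QuestionAnalysis(spec, distances).fit()
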