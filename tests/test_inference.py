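"""Statistical tests, Bonferroni policy, the gated question framework."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imagery_rsa import (FollowupSpec, GateSpec, QuestionAnalysis,
                         QuestionSpec, bonferroni_alpha, one_sample_t,
                         one_tailed_p, one_way_anova, paired_t, run_question,
                         two_sample_t)
from imagery_rsa.inference import REGIONS_8, REGIONS_12
from imagery_rsa.study import build_question_specs, load_question_specs, \
    save_question_specs


class TestOneSampleT:
    def test_closed_form_example(self):
        res = one_sample_t([1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3)),
                                              rel=1e-6)
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == (2,)

    def test_symmetric_values_give_half_p(self):
        res = one_sample_t([-2.0, -1.0, 1.0, 2.0])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.5)

    @pytest.mark.parametrize("t, df, expected", [
        (2.49, 18, 1.12e-2),   # left OFA, cross-domain gate
        (6.28, 18, 3.21e-6),   # left FFA, perception > imagery
        (1.94, 18, 3.41e-2),   # left OPA, perceived > imagined buildings
    ])
    def test_printed_t_to_p_conversions(self, t, df, expected):
        """The published (t, p) pairs confirm the one-tailed convention."""
        assert one_tailed_p(t, df) == pytest.approx(expected, rel=0.02)

    def test_zero_variance_flagged(self):
        res = one_sample_t([2.0, 2.0, 2.0])
        assert res.p == 0.0
        assert res.note == "zero variance"

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0])

    def test_matches_numerical_integration_oracle(self):
        """One-tailed p equals numerical integration of the t density."""
        from scipy.integrate import quad
        for t, df in [(1.5, 7), (2.49, 18), (4.0, 28)]:
            num, _ = quad(lambda x: stats.t.pdf(x, df), t, np.inf)
            assert one_tailed_p(t, df) == pytest.approx(num, rel=1e-6)


class TestOtherTests:
    def test_paired_identical_zero(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_paired_matches_one_sample_on_differences(self):
        a, b = [3.0, 5.0, 4.0, 6.0], [1.0, 2.0, 2.5, 3.0]
        res = paired_t(a, b)
        ref = one_sample_t(np.subtract(a, b))
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.p)

    def test_two_sample_pooled_hand_example(self):
        res = two_sample_t([0.0, 1.0], [2.0, 3.0], tail="two_sided")
        assert res.statistic == pytest.approx(-2.828, abs=1e-3)
        assert res.df == (2,)

    def test_two_sample_antisymmetry(self):
        a, b = [0.0, 1.0, 0.5], [2.0, 3.0, 2.5]
        assert two_sample_t(a, b, tail="two_sided").statistic == \
            pytest.approx(-two_sample_t(b, a, tail="two_sided").statistic)

    def test_two_sample_welch_option(self):
        res = two_sample_t([0.0, 1.0, 2.0], [10.0, 30.0], variance="welch",
                           tail="two_sided")
        assert res.df[0] != 3  # Welch dof is not n_a + n_b - 2

    def test_anova_hand_example(self):
        res = one_way_anova([[0.0, 1.0], [2.0, 3.0]])
        assert res.statistic == pytest.approx(8.0)
        assert res.df == (1, 2)

    def test_anova_equal_means_near_zero(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [2.0, 1.0, 3.0]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_group_anova_is_squared_t(self):
        a, b = [0.0, 1.0, 0.5, 2.0], [2.0, 3.0, 2.5, 1.0]
        f = one_way_anova([a, b]).statistic
        t = two_sample_t(a, b, tail="two_sided").statistic
        assert f == pytest.approx(t ** 2)

    def test_group_size_errors(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])


class TestBonferroni:
    @pytest.mark.parametrize("n, expected", [
        (8, 0.00625), (12, 0.05 / 12), (4, 0.0125), (1, 0.05),
    ])
    def test_seed_level_thresholds(self, n, expected):
        assert bonferroni_alpha(0.05, n) == pytest.approx(expected)

    def test_twelve_region_threshold_prints_as_00416(self):
        assert f"{bonferroni_alpha(0.05, 12):.5f}" == "0.00417"
        assert bonferroni_alpha(0.05, 12) == pytest.approx(0.0041667,
                                                           abs=1e-6)

    def test_strictly_decreasing_in_regions(self):
        alphas = [bonferroni_alpha(0.05, n) for n in range(1, 20)]
        assert all(a > b for a, b in zip(alphas, alphas[1:]))

    def test_invalid_region_count(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


def _distances(regions, selections, effects, n_subjects=16, noise_sd=1.0,
               seed=0):
    """Tidy table with per-(region, selection) mean shifts from ``effects``."""
    rng = np.random.default_rng(seed)
    rows = []
    for region in regions:
        for sel in selections:
            mu = effects.get((region, sel), 0.0)
            for s in range(n_subjects):
                rows.append({"subject": f"s{s}", "region": region,
                             "selection": sel,
                             "value": mu + noise_sd * rng.standard_normal()})
    return pd.DataFrame(rows)


class TestQuestionFramework:
    def _spec(self):
        return QuestionSpec(
            question_id="demo", regions=REGIONS_8,
            gates=(GateSpec("a"), GateSpec("b")),
            followups=(FollowupSpec(label="a_gt_b", kind="paired_t",
                                    selections=("a", "b")),))

    def test_signal_region_gated_in_null_regions_out(self):
        effects = {("OPA_LH", "a"): 3.0, ("OPA_LH", "b"): 2.0}
        dist = _distances(REGIONS_8, ["a", "b"], effects, seed=1)
        res = run_question(self._spec(), dist)
        assert res.eligible["a_gt_b"] == ["OPA_LH"]
        sig_regions = {g.region for g in res.gate_results if g.significant}
        assert sig_regions == {"OPA_LH"}

    def test_no_gate_passes_empty_stage_two(self):
        dist = _distances(REGIONS_8, ["a", "b"], {}, seed=2)
        res = run_question(self._spec(), dist)
        assert res.eligible["a_gt_b"] == []
        assert res.followup_results["a_gt_b"] == []
        assert "no region passed" in res.summary()

    def test_gate_discipline_no_stage2_for_ineligible(self):
        effects = {("OPA_LH", "a"): 3.0, ("OPA_LH", "b"): 2.0,
                   ("PPA_RH", "a"): 3.0}  # PPA_RH passes only one gate
        dist = _distances(REGIONS_8, ["a", "b"], effects, seed=3)
        res = run_question(self._spec(), dist)
        assert {r.region for r in res.followup_results["a_gt_b"]} == {"OPA_LH"}

    def test_gate_alpha_uses_region_count(self):
        dist = _distances(REGIONS_8, ["a", "b"], {}, seed=4)
        res = run_question(self._spec(), dist)
        assert res.audit["gate_alpha"] == pytest.approx(0.00625)
        assert all(g.alpha_used == pytest.approx(0.00625)
                   for g in res.gate_results)

    def test_q1a_structure_two_gates_per_region(self):
        spec = build_question_specs()["Q1a"]
        sels = [g.selection for g in spec.gates]
        dist = _distances(REGIONS_12, sels, {}, seed=5)
        res = run_question(spec, dist)
        assert len(res.gate_results) == 2 * len(REGIONS_12)
        assert spec.gate_alpha == pytest.approx(0.05 / 12)

    def test_followup_alpha_data_driven_when_unset(self):
        effects = {(r, s): 3.0 for r in ("OPA_LH", "PPA_RH")
                   for s in ("a", "b")}
        dist = _distances(REGIONS_8, ["a", "b"], effects, seed=6)
        res = run_question(self._spec(), dist)
        assert res.audit["followup_alpha"]["a_gt_b"] == pytest.approx(0.025)

    def test_published_second_level_alphas(self):
        specs = build_question_specs()
        q1b = {f.label: f.alpha for f in specs["Q1b"].followups}
        assert q1b["faces_gt_buildings"] == pytest.approx(0.0125)
        assert q1b["buildings_gt_faces"] == pytest.approx(0.05 / 6)
        assert specs["Q1a"].followups[0].alpha == pytest.approx(0.0056)
        assert specs["Q2a"].followups[0].alpha == pytest.approx(0.025)
        assert specs["Q2b"].followups[1].alpha == pytest.approx(0.05 / 3)
        assert specs["Q2a"].gate_alpha == pytest.approx(0.00625)
        assert specs["Q3c"].gate_alpha == pytest.approx(0.05 / 12)

    def test_missing_selection_rejected(self):
        dist = _distances(REGIONS_8, ["a"], {}, seed=7)
        with pytest.raises(ValueError):
            QuestionAnalysis(self._spec(), dist)

    def test_results_frame_and_summary(self):
        effects = {("OPA_LH", "a"): 3.0, ("OPA_LH", "b"): 1.0}
        dist = _distances(REGIONS_8, ["a", "b"], effects, seed=8)
        res = run_question(self._spec(), dist)
        frame = res.to_frame()
        assert set(frame["stage"]) <= {1, 2}
        assert {"region", "statistic", "p", "alpha",
                "significant"} <= set(frame.columns)
        assert "Question demo" in res.summary()

    def test_yaml_round_trip(self, tmp_path):
        specs = build_question_specs()
        path = tmp_path / "questions.yaml"
        save_question_specs(specs, path)
        back = load_question_specs(path)
        assert set(back) == set(specs)
        for k in specs:
            assert back[k] == specs[k]
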