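"""Built-in cell selections and question specs of the imagery RSA study.

The seven subquestions interrogate averaged crossnobis distances:

* Q1a — cross-category (face vs building) distances per domain; follow-up:
  perception > imagery (paired).
* Q1b — cross-domain (imagery vs perception) distances per category;
  follow-ups: faces > buildings in face-selective areas, buildings > faces
  in scene-selective areas.
* Q2a — same- vs different-quadrant distances of imagined cities, hours
  and buildings; follow-ups: different > same for cities (paired), ANOVA
  across categories.
* Q2b — quadrant distances of perceived buildings; follow-ups:
  different > same (paired), perception > imagery (two-sample; the groups
  are different experiments' participants).
* Q3a — within-category item distances of the three imagined categories;
  follow-ups: buildings > cities (two-sample), ANOVA.
* Q3b — item distances of perceived vs imagined buildings (two-sample).
* Q3c — item distances of buildings and faces per domain; follow-ups:
  perceived > imagined buildings, perceived buildings > perceived faces.

Q1 and Q3c run on the twelve hemisphere-resolved seeds (scene- and
face-selective + HC) with gate alpha 0.05/12; the others on the eight
scene + HC seeds with 0.05/8.  Published second-level thresholds are kept
as explicit fixtures where the paper prints them.
"""

from __future__ import annotations

from typing import Optional

import yaml

from .inference import (FACE_REGIONS_4, GateSpec, FollowupSpec, QuestionSpec,
                        REGIONS_8, REGIONS_12, SCENE_REGIONS_6)
from .questions import CellSelection

SELECTIONS = {s.label: s for s in [
    # Q1 / Q3c (Experiment 3)
    CellSelection("cross_category_perception",
                  predicate={"category": "different"},
                  restrict={"domain": "perception"}),
    CellSelection("cross_category_imagery",
                  predicate={"category": "different"},
                  restrict={"domain": "imagery"}),
    CellSelection("cross_domain_building",
                  predicate={"domain": "different"},
                  restrict={"category": "building"}),
    CellSelection("cross_domain_face",
                  predicate={"domain": "different"},
                  restrict={"category": "face"}),
    CellSelection("e3_items_building_perception",
                  restrict={"category": "building", "domain": "perception"}),
    CellSelection("e3_items_building_imagery",
                  restrict={"category": "building", "domain": "imagery"}),
    CellSelection("e3_items_face_perception",
                  restrict={"category": "face", "domain": "perception"}),
    CellSelection("e3_items_face_imagery",
                  restrict={"category": "face", "domain": "imagery"}),
    # Q2 / Q3a-b (Experiments 1-2); quadrant predicates are within-category
    *[CellSelection(f"{mode}_quadrant_{cat}_{dom}",
                    predicate={"quadrant": "same" if mode == "same" else "different"},
                    restrict={"category": cat, "domain": dom})
      for cat, dom in (("city", "imagery"), ("hour", "imagery"),
                       ("building", "imagery"), ("building", "perception"))
      for mode in ("same", "diff")],
    *[CellSelection(f"items_{cat}_{dom}",
                    restrict={"category": cat, "domain": dom})
      for cat, dom in (("city", "imagery"), ("hour", "imagery"),
                       ("building", "imagery"), ("building", "perception"))],
]}

#: selections computable from each experiment's condition set
EXPERIMENT_SELECTIONS = {
    1: ["same_quadrant_city_imagery", "diff_quadrant_city_imagery",
        "same_quadrant_hour_imagery", "diff_quadrant_hour_imagery",
        "same_quadrant_building_imagery", "diff_quadrant_building_imagery",
        "items_city_imagery", "items_hour_imagery", "items_building_imagery"],
    2: ["same_quadrant_building_imagery", "diff_quadrant_building_imagery",
        "same_quadrant_building_perception", "diff_quadrant_building_perception",
        "items_building_imagery", "items_building_perception"],
    3: ["cross_category_perception", "cross_category_imagery",
        "cross_domain_building", "cross_domain_face",
        "e3_items_building_perception", "e3_items_building_imagery",
        "e3_items_face_perception", "e3_items_face_imagery"],
}


def build_question_specs() -> dict:
    """The seven published question specs, keyed Q1a..Q3c."""
    specs = {}
    specs["Q1a"] = QuestionSpec(
        question_id="Q1a", regions=REGIONS_12,
        gates=(GateSpec("cross_category_perception"),
               GateSpec("cross_category_imagery")),
        followups=(FollowupSpec(
            label="perception_gt_imagery", kind="paired_t",
            selections=("cross_category_perception", "cross_category_imagery"),
            alpha=0.0056),))  # published threshold, divisor left explicit
    specs["Q1b"] = QuestionSpec(
        question_id="Q1b", regions=REGIONS_12,
        gates=(GateSpec("cross_domain_building"),
               GateSpec("cross_domain_face")),
        followups=(
            FollowupSpec(label="faces_gt_buildings", kind="paired_t",
                         selections=("cross_domain_face",
                                     "cross_domain_building"),
                         region_subset=FACE_REGIONS_4, alpha=0.05 / 4),
            FollowupSpec(label="buildings_gt_faces", kind="paired_t",
                         selections=("cross_domain_building",
                                     "cross_domain_face"),
                         region_subset=SCENE_REGIONS_6, alpha=0.05 / 6)))
    specs["Q2a"] = QuestionSpec(
        question_id="Q2a", regions=REGIONS_8,
        gates=tuple(GateSpec(f"{m}_quadrant_{c}_imagery")
                    for c in ("city", "hour", "building")
                    for m in ("same", "diff")),
        followups=(
            FollowupSpec(label="city_diff_gt_same", kind="paired_t",
                         selections=("diff_quadrant_city_imagery",
                                     "same_quadrant_city_imagery"),
                         requires=("same_quadrant_city_imagery",
                                   "diff_quadrant_city_imagery"),
                         alpha=0.05 / 2),
            FollowupSpec(label="categories_diff_quadrant", kind="anova",
                         selections=("diff_quadrant_city_imagery",
                                     "diff_quadrant_hour_imagery",
                                     "diff_quadrant_building_imagery"),
                         requires=("diff_quadrant_city_imagery",
                                   "diff_quadrant_hour_imagery",
                                   "diff_quadrant_building_imagery"),
                         alpha=0.05 / 2)))
    specs["Q2b"] = QuestionSpec(
        question_id="Q2b", regions=REGIONS_8,
        gates=(GateSpec("same_quadrant_building_perception"),
               GateSpec("diff_quadrant_building_perception"),
               GateSpec("diff_quadrant_building_imagery")),
        followups=(
            FollowupSpec(label="perc_diff_gt_same", kind="paired_t",
                         selections=("diff_quadrant_building_perception",
                                     "same_quadrant_building_perception"),
                         requires=("same_quadrant_building_perception",
                                   "diff_quadrant_building_perception"),
                         alpha=0.05 / 2),
            FollowupSpec(label="perception_gt_imagery_diff_quadrant",
                         kind="two_sample_t",
                         selections=("diff_quadrant_building_perception",
                                     "diff_quadrant_building_imagery"),
                         requires=("diff_quadrant_building_perception",
                                   "diff_quadrant_building_imagery"),
                         alpha=0.05 / 3)))
    specs["Q3a"] = QuestionSpec(
        question_id="Q3a", regions=REGIONS_8,
        gates=(GateSpec("items_building_imagery"),
               GateSpec("items_city_imagery"),
               GateSpec("items_hour_imagery")),
        followups=(
            FollowupSpec(label="buildings_gt_cities", kind="two_sample_t",
                         selections=("items_building_imagery",
                                     "items_city_imagery"),
                         requires=("items_building_imagery",
                                   "items_city_imagery")),
            FollowupSpec(label="categories", kind="anova",
                         selections=("items_building_imagery",
                                     "items_city_imagery",
                                     "items_hour_imagery"))))
    specs["Q3b"] = QuestionSpec(
        question_id="Q3b", regions=REGIONS_8,
        gates=(GateSpec("items_building_perception"),
               GateSpec("items_building_imagery")),
        followups=(FollowupSpec(
            label="perception_gt_imagery", kind="two_sample_t",
            selections=("items_building_perception",
                        "items_building_imagery"),
            alpha=0.05 / 3),))
    specs["Q3c"] = QuestionSpec(
        question_id="Q3c", regions=REGIONS_12,
        gates=(GateSpec("e3_items_building_perception"),
               GateSpec("e3_items_building_imagery"),
               GateSpec("e3_items_face_perception"),
               GateSpec("e3_items_face_imagery")),
        followups=(
            FollowupSpec(label="perceived_gt_imagined_buildings",
                         kind="paired_t",
                         selections=("e3_items_building_perception",
                                     "e3_items_building_imagery"),
                         requires=("e3_items_building_perception",
                                   "e3_items_building_imagery")),
            FollowupSpec(label="perceived_buildings_gt_faces",
                         kind="paired_t",
                         selections=("e3_items_building_perception",
                                     "e3_items_face_perception"),
                         requires=("e3_items_building_perception",
                                   "e3_items_face_perception"),
                         alpha=0.05 / 2)))
    return specs


def save_question_specs(specs: dict, path) -> None:
    """Question specs as a plain-text YAML config."""
    with open(path, "w") as fh:
        yaml.safe_dump({k: v.to_dict() for k, v in specs.items()}, fh,
                       sort_keys=False)


def load_question_specs(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: QuestionSpec.from_dict(v) for k, v in raw.items()}
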