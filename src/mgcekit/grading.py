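"""Ordinal 0-3 severity grading of the eight MG-CE exam items.

Each item maps to {0 normal, 1 mild, 2 moderate, 3 severe} using the
published boundaries. Printed intervals are inclusive ("11-60 s" means
11 <= t <= 60); where consecutive rows leave an integer seam uncovered
(e.g. arm drift "no drift >120 s" vs "drift at 90-119 s" says nothing
about exactly 120 s), the milder grade is assigned — the seams and their
resolutions:

* diplopia onset exactly 61 s -> 0 (and above-60 generally); onset 0 is
  "immediate" -> 3, while sub-second onsets in (0, 1) take the milder 2;
* counting-to-50 dysarthria onset exactly 50 -> 0 ("no dysarthria at 50");
* arm drift onset exactly 120 s -> 0.

Purely visual categories (cheek-puff "transverse pucker", sit-to-stand
"need to use hands", ptosis lid-vs-pupil category) are accepted as
annotations; automated metrics ride along as supporting evidence only. A
helper converts a measured lid-to-pupil distance into the ptosis category
with a configurable "at the pupil" tolerance (default 1 px).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

from .errors import GradingUnavailable, InputError, ValidationError


class ExamItem(str, Enum):
    PTOSIS = "ptosis"
    DIPLOPIA = "diplopia"
    CHEEK_PUFF = "cheek_puff"
    TONGUE_TO_CHEEK = "tongue_to_cheek"
    COUNT50 = "count50"
    ARM_STRENGTH = "arm_strength"
    SINGLE_BREATH = "single_breath"
    SIT_TO_STAND = "sit_to_stand"


ALL_ITEMS = tuple(ExamItem)

GRADE_LABELS = {0: "normal", 1: "mild", 2: "moderate", 3: "severe"}


@dataclass(frozen=True)
class GradeResult:
    item: ExamItem
    grade: int
    basis: str                  # metric/annotation the grade rests on
    note: str = ""

    def __post_init__(self):
        if self.grade not in (0, 1, 2, 3):
            raise ValidationError(f"grade {self.grade} outside 0..3")


PTOSIS_CATEGORIES = {"none": 0, "above_pupil": 1, "at_pupil": 2,
                     "below_pupil": 3}
CHEEK_PUFF_CATEGORIES = {"normal_seal": 0, "transverse_pucker": 1,
                         "air_escapes": 2, "cannot_perform": 3}
TONGUE_CATEGORIES = {"full_deformity": 0, "partial_deformity": 1,
                     "no_deformity": 2, "cannot_perform": 3}
SIT_TO_STAND_CATEGORIES = {"no_difficulty": 0, "slow_no_hands": 1,
                           "need_hands": 2, "unable": 3}


def ptosis_category_from_distance(d_lid_pupil: float,
                                  baseline_d: float | None = None,
                                  at_pupil_tol: float = 1.0,
                                  droop_fraction: float = 0.25) -> str:
    """Suggest a ptosis category from the lid-to-pupil distance (px).

    ``d_lid_pupil`` > 0 means the lid sits above the pupil center. Within
    ``at_pupil_tol`` of zero the lid is "at the pupil"; below, "below the
    pupil". A positive distance counts as no ptosis unless a baseline is
    supplied and the lid has descended by more than ``droop_fraction`` of
    it. Supporting evidence only — the clinical category is an annotation.
    """
    if d_lid_pupil < -at_pupil_tol:
        return "below_pupil"
    if abs(d_lid_pupil) <= at_pupil_tol:
        return "at_pupil"
    if baseline_d is not None and d_lid_pupil < (1 - droop_fraction) * baseline_d:
        return "above_pupil"
    return "none" if baseline_d is not None else "above_pupil"


def _grade_onset(onset: float | None,
                 thresholds: list[tuple[float, int]],
                 floor_grade: int) -> int:
    """Grade an onset time/count by descending thresholds.

    ``thresholds`` lists (cutoff, grade) from mildest down: the first rule
    whose cutoff the onset strictly exceeds wins, so values falling in an
    uncovered seam between printed integer intervals take the milder
    grade. ``onset=None`` (event never occurred) takes the mildest grade.
    """
    if onset is None:
        return thresholds[0][1]
    for cutoff, g in thresholds:
        if onset > cutoff:
            return g
    return floor_grade


def grade_item(item: ExamItem | str, inputs: dict[str, Any]) -> GradeResult:
    """Grade one exam item from its required inputs.

    Numeric items take ``onset_s`` / ``count`` / ``onset_count`` keys (and
    optional ``exercise_duration_s`` for consistency validation);
    categorical items take ``category``. Missing inputs raise
    :class:`GradingUnavailable` naming what is needed.
    """
    item = ExamItem(item)
    dur = inputs.get("exercise_duration_s")

    def _check_onset(onset):
        if onset is not None and dur is not None and onset > dur:
            raise ValidationError(
                f"{item.value}: onset {onset}s beyond exercise "
                f"duration {dur}s")

    if item is ExamItem.DIPLOPIA:
        if "onset_s" not in inputs:
            raise GradingUnavailable(
                "diplopia grading needs 'onset_s' (seconds to double "
                "vision, or None)")
        onset = inputs["onset_s"]
        _check_onset(onset)
        # 0: no diplopia at 61 s | 1: 11-60 s | 2: 1-10 s | 3: immediate
        grade = _grade_onset(onset, [(60, 0), (10, 1), (0, 2)],
                             floor_grade=3)
        return GradeResult(item, grade, basis=f"onset_s={onset}")

    if item is ExamItem.ARM_STRENGTH:
        if "onset_s" not in inputs:
            raise GradingUnavailable(
                "arm grading needs 'onset_s' (drift onset, or None)")
        onset = inputs["onset_s"]
        _check_onset(onset)
        # 0: no drift >120 s | 1: 90-119 s | 2: 10-89 s | 3: 0-9 s
        grade = _grade_onset(onset, [(119, 0), (89, 1), (9, 2)],
                             floor_grade=3)
        return GradeResult(item, grade, basis=f"onset_s={onset}")

    if item is ExamItem.COUNT50:
        if "onset_count" not in inputs:
            raise GradingUnavailable(
                "counting grading needs 'onset_count' (count at which "
                "dysarthria appeared, or None)")
        onset = inputs["onset_count"]
        if onset is not None and not 1 <= onset <= 50:
            raise ValidationError(
                f"dysarthria onset count {onset} outside 1..50")
        # 0: none at 50 | 1: 30-49 | 2: 10-29 | 3: 1-9
        grade = _grade_onset(onset, [(49, 0), (29, 1), (9, 2)],
                             floor_grade=3)
        return GradeResult(item, grade, basis=f"onset_count={onset}")

    if item is ExamItem.SINGLE_BREATH:
        if "count" not in inputs:
            raise GradingUnavailable(
                "single-breath grading needs 'count' (highest number "
                "reached)")
        count = inputs["count"]
        if count < 0:
            raise ValidationError(f"negative count {count}")
        if count >= 30:
            grade = 0
        elif count >= 25:
            grade = 1
        elif count >= 20:
            grade = 2
        else:
            grade = 3
        return GradeResult(item, grade, basis=f"count={count}")

    if item is ExamItem.PTOSIS:
        cat = inputs.get("category")
        if cat is None and "d_lid_pupil" in inputs:
            cat = ptosis_category_from_distance(
                inputs["d_lid_pupil"], inputs.get("baseline_d"),
                inputs.get("at_pupil_tol", 1.0))
        if cat is None:
            raise GradingUnavailable(
                "ptosis grading needs 'category' (none/above_pupil/"
                "at_pupil/below_pupil) or 'd_lid_pupil'")
        if cat not in PTOSIS_CATEGORIES:
            raise ValidationError(f"unknown ptosis category {cat!r}")
        return GradeResult(item, PTOSIS_CATEGORIES[cat],
                           basis=f"category={cat}")

    table = {ExamItem.CHEEK_PUFF: CHEEK_PUFF_CATEGORIES,
             ExamItem.TONGUE_TO_CHEEK: TONGUE_CATEGORIES,
             ExamItem.SIT_TO_STAND: SIT_TO_STAND_CATEGORIES}[item]
    cat = inputs.get("category")
    if cat is None:
        raise GradingUnavailable(
            f"{item.value} grading needs 'category' "
            f"(one of {sorted(table)})")
    if cat not in table:
        raise ValidationError(f"unknown {item.value} category {cat!r}")
    note = ""
    if "evidence" in inputs:
        note = f"supporting evidence: {inputs['evidence']}"
    return GradeResult(item, table[cat], basis=f"category={cat}", note=note)


@dataclass
class SessionGrades:
    """Grades for a whole session, with per-item failure reasons."""

    results: list[GradeResult] = field(default_factory=list)
    ungradable: dict[str, str] = field(default_factory=dict)


def grade_session(bundle: dict[str, dict[str, Any]]) -> SessionGrades:
    """Grade every exam item present in the bundle.

    ``bundle`` maps item ids to their input dicts. Items missing their
    required inputs are reported in ``ungradable`` with the reason; an
    empty bundle is an error.
    """
    if not bundle:
        raise InputError("empty metrics bundle: nothing to grade")
    out = SessionGrades()
    for item in ALL_ITEMS:
        inputs = bundle.get(item.value)
        if inputs is None:
            out.ungradable[item.value] = "no inputs provided"
            continue
        try:
            out.results.append(grade_item(item, inputs))
        except GradingUnavailable as e:
            out.ungradable[item.value] = str(e)
    return out
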