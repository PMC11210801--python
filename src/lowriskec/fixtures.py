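"""Packaged count tables from the published study and their expansion into
a patient-level reference cohort.

The study's raw data is not machine-readable, but its printed summary
tables are: the 4x5 preoperative-group x postoperative-class table and the
per-group postoperative invasion, grade and stage panels.  Those panels are
jointly consistent, so a pseudo-cohort of 251 records can be reconstructed
that reproduces every panel exactly; all published concordance statistics
recompute from it bit-for-bit.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .cohort import (
    Grade,
    InconsistentRecordError,
    MICategory,
    PatientRecord,
    PostopClass,
    RiskGroup,
    Stage,
    classify_postop,
    make_pseudo_record,
)

__all__ = [
    "class_by_group",
    "mi_by_group",
    "grade_by_group",
    "stage_by_group",
    "table1_marginals",
    "reference_cohort",
]

GROUP_LABELS = ["group1", "group2", "group3", "group4"]
CLASS_LABELS = ["group1", "group2", "group3", "group4", "higher"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("lowriskec.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, index_col=0)


def class_by_group() -> pd.DataFrame:
    """4x5 counts: preoperative group (rows) x postoperative class (columns)."""
    return _load("postop_class_by_group.csv")


def mi_by_group() -> pd.DataFrame:
    """Postoperative invasion category counts within each preoperative group."""
    return _load("postop_mi_by_group.csv")


def grade_by_group() -> pd.DataFrame:
    """Postoperative grade counts within each preoperative group."""
    return _load("postop_grade_by_group.csv")


def stage_by_group() -> pd.DataFrame:
    """Postoperative FIGO 2009 stage counts within each preoperative group."""
    return _load("postop_stage_by_group.csv")


def table1_marginals() -> dict[str, float]:
    """Published cohort-level marginals (group sizes, covariate moments)."""
    df = _load("cohort_marginals.csv")
    return {k: float(v) for k, v in df["value"].items()} if "value" in df else {
        k: float(v) for k, v in df.iloc[:, 0].items()
    }


_GRADE_COLS = [Grade.G1, Grade.G2, Grade.G3, Grade.INADEQUATE]
_MI_COLS = [MICategory.NONE, MICategory.LT_HALF, MICategory.GE_HALF]
_STAGE_COLS = [Stage.IA, Stage.IB, Stage.II, Stage.IIIA, Stage.IIIB, Stage.IIIC, Stage.IV]


def _reconstruct_group(
    group: RiskGroup,
    class_counts: np.ndarray,
    mi_counts: np.ndarray,
    grade_counts: np.ndarray,
    stage_counts: np.ndarray,
    start_index: int,
) -> list[PatientRecord]:
    """Build records for one preoperative group that jointly satisfy its
    class, invasion, grade and stage panels.

    Records in classes 1-4 have their postoperative findings fixed by
    definition (stage IA, the class's invasion/grade pair).  The residual
    counts then pin down the composition of the HIGHER class: deep invasion
    goes to stage IB first (FIGO 2009 forces it), stage-IA escalations
    absorb exactly the grade-3 and inadequate-grade residuals, and the
    remaining invasion and grade counts distribute over the other
    advanced-stage slots.
    """
    records: list[PatientRecord] = []
    k = start_index

    mi_left = {c: int(n) for c, n in zip(_MI_COLS, mi_counts)}
    grade_left = {c: int(n) for c, n in zip(_GRADE_COLS, grade_counts)}
    stage_left = {c: int(n) for c, n in zip(_STAGE_COLS, stage_counts)}

    class_templates = {
        PostopClass.GROUP1: (MICategory.NONE, Grade.G1),
        PostopClass.GROUP2: (MICategory.NONE, Grade.G2),
        PostopClass.GROUP3: (MICategory.LT_HALF, Grade.G1),
        PostopClass.GROUP4: (MICategory.LT_HALF, Grade.G2),
    }
    for cls, (mi, grade) in class_templates.items():
        n = int(class_counts[int(cls) - 1])
        for _ in range(n):
            k += 1
            records.append(make_pseudo_record(group, mi, grade, Stage.IA, f"R{k:04d}"))
        mi_left[mi] -= n
        grade_left[grade] -= n
        stage_left[Stage.IA] -= n

    n_higher = int(class_counts[4])
    if any(v < 0 for v in (*mi_left.values(), *grade_left.values(), *stage_left.values())):
        raise InconsistentRecordError(f"{group.name}: panels are mutually inconsistent")
    if sum(mi_left.values()) != n_higher or sum(grade_left.values()) != n_higher:
        raise InconsistentRecordError(f"{group.name}: higher-class residuals do not balance")

    # Stage slots for the HIGHER records; advanced stages first, then the
    # stage-IA escalations (grade 3 / inadequate grade).
    slots: list[Stage] = []
    for st in (Stage.IB, Stage.II, Stage.IIIA, Stage.IIIB, Stage.IIIC, Stage.IV):
        slots.extend([st] * stage_left[st])
    n_ia_higher = stage_left[Stage.IA]
    if n_ia_higher != grade_left[Grade.G3] + grade_left[Grade.INADEQUATE]:
        raise InconsistentRecordError(
            f"{group.name}: stage-IA escalations must carry grade 3 or an inadequate grade"
        )
    slots.extend([Stage.IA] * n_ia_higher)
    if len(slots) != n_higher:
        raise InconsistentRecordError(f"{group.name}: higher-class stage slots do not balance")

    # Invasion per slot: deep invasion covers stage IB first, any remainder
    # goes to other advanced stages; stage-IA slots take none/<1/2 only.
    mi_per_slot: list[MICategory] = []
    for st in slots:
        if st == Stage.IB:
            if mi_left[MICategory.GE_HALF] <= 0:
                raise InconsistentRecordError(f"{group.name}: stage IB requires deep invasion")
            mi_left[MICategory.GE_HALF] -= 1
            mi_per_slot.append(MICategory.GE_HALF)
        else:
            mi_per_slot.append(None)  # fill below
    shallow_pool = [MICategory.NONE] * mi_left[MICategory.NONE] + [
        MICategory.LT_HALF
    ] * mi_left[MICategory.LT_HALF]
    deep_spare = mi_left[MICategory.GE_HALF]
    for i, st in enumerate(slots):
        if mi_per_slot[i] is not None:
            continue
        if st > Stage.IA and deep_spare > 0:
            mi_per_slot[i] = MICategory.GE_HALF
            deep_spare -= 1
        else:
            mi_per_slot[i] = shallow_pool.pop(0)
    if deep_spare or shallow_pool:
        raise InconsistentRecordError(f"{group.name}: invasion residuals do not balance")

    # Grade per slot: stage-IA escalations take grade 3 then inadequate;
    # advanced stages draw from what remains.
    grade_per_slot: list[Grade] = [None] * len(slots)
    for i, st in enumerate(slots):
        if st == Stage.IA:
            if grade_left[Grade.G3] > 0:
                grade_left[Grade.G3] -= 1
                grade_per_slot[i] = Grade.G3
            else:
                grade_left[Grade.INADEQUATE] -= 1
                grade_per_slot[i] = Grade.INADEQUATE
    rest_pool = []
    for g in _GRADE_COLS:
        rest_pool.extend([g] * grade_left[g])
    for i, st in enumerate(slots):
        if grade_per_slot[i] is None:
            grade_per_slot[i] = rest_pool.pop(0)

    for st, mi, grade in zip(slots, mi_per_slot, grade_per_slot):
        k += 1
        records.append(make_pseudo_record(group, mi, grade, st, f"R{k:04d}"))
    return records


def reference_cohort() -> list[PatientRecord]:
    """Expand the packaged panels into 251 pseudo patient records.

    The output reproduces, for every preoperative group, the published
    postoperative class, invasion, grade and stage counts simultaneously,
    so group-level and variable-level agreement statistics all recompute
    exactly.  Covariates are deterministic placeholders.
    """
    cls = class_by_group().to_numpy()
    mi = mi_by_group().to_numpy()
    grade = grade_by_group().to_numpy()
    stage = stage_by_group().to_numpy()

    records: list[PatientRecord] = []
    for gi, group in enumerate(RiskGroup):
        records.extend(
            _reconstruct_group(group, cls[gi], mi[gi], grade[gi], stage[gi], len(records))
        )

    # Internal consistency: every record classifies into the class column
    # its construction intended.
    counts = np.zeros((4, 5), dtype=int)
    for r in records:
        counts[int(r.preop_group) - 1, int(classify_postop(r)) - 1] += 1
    if not np.array_equal(counts, cls):
        raise InconsistentRecordError("reconstructed cohort does not reproduce the class table")
    return records
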