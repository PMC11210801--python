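"""Domain model for the low-risk endometrial cancer staging cohort.

A cohort is a list of :class:`PatientRecord` objects, one per surgically
staged patient.  Each record pairs the preoperative work-up (MRI myometrial
invasion category, biopsy grade, tumor size, CA125) with the postoperative
final pathology (FIGO 2009 stage, invasion depth, grade, nodal status).

Eligibility mirrors the study design: no deep invasion on MRI
(``preop_mi`` is NONE or LT_HALF), biopsy grade 1 or 2, endometrioid
histology on biopsy, and serum CA125 below 35 U/mL.  Eligible patients fall
into four preoperative risk groups formed by crossing MRI invasion with
biopsy grade; the postoperative pathology is re-expressed on the same scale
with a fifth, strictly worse, "higher stages" class.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "MICategory",
    "Grade",
    "Stage",
    "BiopsyMethod",
    "SurgeryMethod",
    "RiskGroup",
    "PostopClass",
    "PatientRecord",
    "IneligibleRecordError",
    "InconsistentRecordError",
    "assign_preop_group",
    "group_definition",
    "classify_postop",
    "read_cohort",
    "write_cohort",
    "expand_contingency",
    "CohortReadResult",
]

CA125_INCLUSION_LIMIT = 35.0


class MICategory(enum.IntEnum):
    """Depth of myometrial invasion. The integer value is the depth code
    (0 = none, 1 = less than half, 2 = half or more)."""

    NONE = 0
    LT_HALF = 1
    GE_HALF = 2


class Grade(enum.Enum):
    """Histologic grade of endometrioid adenocarcinoma."""

    G1 = "1"
    G2 = "2"
    G3 = "3"
    INADEQUATE = "inadequate"


class Stage(enum.IntEnum):
    """FIGO 2009 surgical stage, totally ordered."""

    IA = 1
    IB = 2
    II = 3
    IIIA = 4
    IIIB = 5
    IIIC = 6
    IV = 7


class BiopsyMethod(enum.Enum):
    D_AND_C = "d_and_c"
    HYSTEROSCOPY = "hysteroscopy"
    PIPELLE = "pipelle"


class SurgeryMethod(enum.Enum):
    MIS = "mis"  # laparoscopic or robotic
    LAPAROTOMY = "laparotomy"


class RiskGroup(enum.IntEnum):
    """Preoperative risk stratum: (MI, grade) = (no, 1), (no, 2),
    (<1/2, 1), (<1/2, 2)."""

    GROUP1 = 1
    GROUP2 = 2
    GROUP3 = 3
    GROUP4 = 4


class PostopClass(enum.IntEnum):
    """Postoperative re-classification on the preoperative scale plus a
    strictly worse HIGHER class (stage IA with grade 3 or an inadequate
    grade, stage IB, stage II, stage IIIC and beyond)."""

    GROUP1 = 1
    GROUP2 = 2
    GROUP3 = 3
    GROUP4 = 4
    HIGHER = 5


class IneligibleRecordError(ValueError):
    """The record violates an inclusion criterion."""


class InconsistentRecordError(ValueError):
    """The postoperative fields contradict each other (e.g. deep invasion
    reported at stage IA, which FIGO 2009 rules out)."""


_GROUP_BY_MI_GRADE = {
    (MICategory.NONE, Grade.G1): RiskGroup.GROUP1,
    (MICategory.NONE, Grade.G2): RiskGroup.GROUP2,
    (MICategory.LT_HALF, Grade.G1): RiskGroup.GROUP3,
    (MICategory.LT_HALF, Grade.G2): RiskGroup.GROUP4,
}
_MI_GRADE_BY_GROUP = {g: mg for mg, g in _GROUP_BY_MI_GRADE.items()}


def assign_preop_group(preop_mi: MICategory, preop_grade: Grade) -> RiskGroup:
    """Map the preoperative (MRI invasion, biopsy grade) pair to its risk group.

    Raises :class:`IneligibleRecordError` for deep invasion, grade 3 or an
    inadequate biopsy grade, none of which occur in the eligible cohort.
    """
    key = (MICategory(preop_mi), Grade(preop_grade))
    try:
        return _GROUP_BY_MI_GRADE[key]
    except KeyError:
        raise IneligibleRecordError(
            f"ineligible preoperative assessment: MI={key[0].name}, grade={key[1].name}"
        ) from None


def group_definition(group: RiskGroup) -> tuple[MICategory, Grade]:
    """Inverse of :func:`assign_preop_group`."""
    return _MI_GRADE_BY_GROUP[RiskGroup(group)]


@dataclass(frozen=True)
class PatientRecord:
    """One subject: preoperative assessment, covariates and final pathology.

    ``preop_tumor_size_cm`` may be None (missing on about a third of MRIs);
    all other fields are mandatory.  ``calibrated_mi`` is a derived slot
    filled by the calibration stage and is never read from disk.
    """

    id: str
    age: float
    menopause: bool
    biopsy_method: BiopsyMethod
    preop_grade: Grade
    preop_mi: MICategory
    preop_tumor_size_cm: Optional[float]
    ca125: float
    surgery_method: SurgeryMethod
    postop_mi: MICategory
    postop_grade: Grade
    postop_stage: Stage
    postop_tumor_size_cm: float
    lvsi: bool
    histology_endometrioid: bool
    pelvic_node_met: bool
    calibrated_mi: Optional[float] = field(default=None, compare=True)

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"record {self.id}: non-positive age {self.age}")
        if not 0 < self.ca125 < CA125_INCLUSION_LIMIT:
            raise IneligibleRecordError(
                f"record {self.id}: inclusion criterion violated (CA125 = {self.ca125})"
            )
        if self.preop_mi not in (MICategory.NONE, MICategory.LT_HALF):
            raise IneligibleRecordError(
                f"record {self.id}: deep invasion on MRI is ineligible"
            )
        if self.preop_grade not in (Grade.G1, Grade.G2):
            raise IneligibleRecordError(
                f"record {self.id}: biopsy grade must be 1 or 2"
            )
        if self.preop_tumor_size_cm is not None and not self.preop_tumor_size_cm > 0:
            raise ValueError(f"record {self.id}: non-positive preoperative tumor size")
        if not self.postop_tumor_size_cm > 0:
            raise ValueError(f"record {self.id}: non-positive postoperative tumor size")

    @property
    def preop_group(self) -> RiskGroup:
        return assign_preop_group(self.preop_mi, self.preop_grade)


def classify_postop(record: PatientRecord) -> PostopClass:
    """Re-express the final pathology on the preoperative group scale.

    Escalation is evaluated first: any stage above IA, a grade-3 tumor, or a
    specimen whose grade was inadequate for interpretation is HIGHER — an
    inadequate grade cannot confirm membership in any low-risk group, and the
    study's published group tallies count those patients among the higher
    stages.  Otherwise the (invasion, grade) pair maps through the same
    bijection that defines the preoperative groups.
    """
    if record.postop_stage == Stage.IA and record.postop_mi == MICategory.GE_HALF:
        raise InconsistentRecordError(
            f"record {record.id}: MI >= 1/2 entails stage IB or above under FIGO 2009"
        )
    if (
        record.postop_stage > Stage.IA
        or record.postop_grade is Grade.G3
        or record.postop_grade is Grade.INADEQUATE
    ):
        return PostopClass.HIGHER
    return PostopClass(
        int(_GROUP_BY_MI_GRADE[(record.postop_mi, record.postop_grade)])
    )


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "id",
    "age",
    "menopause",
    "biopsy_method",
    "preop_grade",
    "preop_mi",
    "preop_tumor_size_cm",
    "ca125",
    "surgery_method",
    "postop_mi",
    "postop_grade",
    "postop_stage",
    "postop_tumor_size_cm",
    "lvsi",
    "histology_endometrioid",
    "pelvic_node_met",
]

_MI_TOKENS = {"none": MICategory.NONE, "lt_half": MICategory.LT_HALF, "ge_half": MICategory.GE_HALF}
_GRADE_TOKENS = {g.value: g for g in Grade}
_STAGE_TOKENS = {s.name.lower(): s for s in Stage}
_BIOPSY_TOKENS = {b.value: b for b in BiopsyMethod}
_SURGERY_TOKENS = {s.value: s for s in SurgeryMethod}
_BOOL_TOKENS = {"1": True, "0": False, "true": True, "false": False}


def _parse_bool(token: str, col: str) -> bool:
    try:
        return _BOOL_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown boolean token {token!r} in column {col!r}") from None


def _parse_enum(token: str, table: dict, col: str):
    try:
        return table[token.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown category label {token!r} in column {col!r}") from None


def _record_from_row(row: dict[str, str]) -> PatientRecord:
    size = row["preop_tumor_size_cm"].strip()
    return PatientRecord(
        id=row["id"],
        age=float(row["age"]),
        menopause=_parse_bool(row["menopause"], "menopause"),
        biopsy_method=_parse_enum(row["biopsy_method"], _BIOPSY_TOKENS, "biopsy_method"),
        preop_grade=_parse_enum(row["preop_grade"], _GRADE_TOKENS, "preop_grade"),
        preop_mi=_parse_enum(row["preop_mi"], _MI_TOKENS, "preop_mi"),
        preop_tumor_size_cm=float(size) if size else None,
        ca125=float(row["ca125"]),
        surgery_method=_parse_enum(row["surgery_method"], _SURGERY_TOKENS, "surgery_method"),
        postop_mi=_parse_enum(row["postop_mi"], _MI_TOKENS, "postop_mi"),
        postop_grade=_parse_enum(row["postop_grade"], _GRADE_TOKENS, "postop_grade"),
        postop_stage=_parse_enum(row["postop_stage"], _STAGE_TOKENS, "postop_stage"),
        postop_tumor_size_cm=float(row["postop_tumor_size_cm"]),
        lvsi=_parse_bool(row["lvsi"], "lvsi"),
        histology_endometrioid=_parse_bool(row["histology_endometrioid"], "histology_endometrioid"),
        pelvic_node_met=_parse_bool(row["pelvic_node_met"], "pelvic_node_met"),
    )


@dataclass
class CohortReadResult:
    """Validated records plus the 1-based file rows that were rejected."""

    records: list[PatientRecord]
    rejected: list[tuple[int, str]]


def read_cohort(path: Union[str, Path], strict: bool = False) -> CohortReadResult:
    """Read a cohort CSV, validating every row.

    Rows violating an inclusion criterion or carrying malformed values are
    collected in ``rejected`` as ``(file_row, reason)`` pairs; with
    ``strict=True`` the first bad row raises instead.
    """
    records: list[PatientRecord] = []
    rejected: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header required")
        missing = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(_record_from_row(row))
            except (ValueError, KeyError) as exc:
                if strict:
                    raise
                rejected.append((i, str(exc)))
    return CohortReadResult(records=records, rejected=rejected)


def _row_from_record(r: PatientRecord) -> list[str]:
    return [
        r.id,
        repr(float(r.age)),
        "1" if r.menopause else "0",
        r.biopsy_method.value,
        r.preop_grade.value,
        r.preop_mi.name.lower(),
        "" if r.preop_tumor_size_cm is None else repr(float(r.preop_tumor_size_cm)),
        repr(float(r.ca125)),
        r.surgery_method.value,
        r.postop_mi.name.lower(),
        r.postop_grade.value,
        r.postop_stage.name.lower(),
        repr(float(r.postop_tumor_size_cm)),
        "1" if r.lvsi else "0",
        "1" if r.histology_endometrioid else "0",
        "1" if r.pelvic_node_met else "0",
    ]


def write_cohort(records: Iterable[PatientRecord], path: Union[str, Path]) -> None:
    """Write records as CSV; floats use ``repr`` so a round trip is lossless."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(_row_from_record(r))


# ---------------------------------------------------------------------------
# Contingency-table expansion
# ---------------------------------------------------------------------------

# Representative postoperative findings for each class.  The HIGHER choice
# (stage IB with deep invasion) is one of the combinations the class covers.
_POSTOP_TEMPLATE = {
    PostopClass.GROUP1: (MICategory.NONE, Grade.G1, Stage.IA),
    PostopClass.GROUP2: (MICategory.NONE, Grade.G2, Stage.IA),
    PostopClass.GROUP3: (MICategory.LT_HALF, Grade.G1, Stage.IA),
    PostopClass.GROUP4: (MICategory.LT_HALF, Grade.G2, Stage.IA),
    PostopClass.HIGHER: (MICategory.GE_HALF, Grade.G1, Stage.IB),
}

_PLACEHOLDER = dict(
    age=52.8,
    menopause=False,
    biopsy_method=BiopsyMethod.D_AND_C,
    ca125=19.2,
    surgery_method=SurgeryMethod.MIS,
    lvsi=False,
    histology_endometrioid=True,
)

_SIZE_BY_POSTOP_MI = {MICategory.NONE: 1.41, MICategory.LT_HALF: 2.45, MICategory.GE_HALF: 2.95}


def make_pseudo_record(
    group: RiskGroup,
    postop_mi: MICategory,
    postop_grade: Grade,
    postop_stage: Stage,
    ident: str,
) -> PatientRecord:
    """Build a record with the given preop group and postop findings and
    deterministic placeholder covariates."""
    mi, grade = group_definition(group)
    size = _SIZE_BY_POSTOP_MI[postop_mi]
    return PatientRecord(
        id=ident,
        preop_grade=grade,
        preop_mi=mi,
        preop_tumor_size_cm=size,
        postop_mi=postop_mi,
        postop_grade=postop_grade,
        postop_stage=postop_stage,
        postop_tumor_size_cm=size,
        pelvic_node_met=postop_stage == Stage.IIIC,
        **_PLACEHOLDER,
    )


def expand_contingency(counts) -> list[PatientRecord]:
    """Materialize a 4 preop-group x 5 postop-class count table as pseudo
    patient records whose cross-tabulation reproduces the table exactly.

    Covariates are deterministic placeholders; the postoperative fields for
    each class are one fixed combination consistent with it, so statistics
    computed on the group/class level are exact while per-variable (MI,
    grade) agreement panels are not meaningful on the output — use
    :func:`lowriskec.fixtures.reference_cohort` for those.
    """
    import numpy as np

    table = np.asarray(counts)
    if table.shape != (4, 5):
        raise ValueError(f"expected a 4x5 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("negative counts")
    if not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)):
            raise ValueError("counts must be integers")
        table = np.round(table).astype(int)

    records: list[PatientRecord] = []
    k = 0
    for gi, group in enumerate(RiskGroup):
        for ci, cls in enumerate(PostopClass):
            mi, grade, stage = _POSTOP_TEMPLATE[cls]
            for _ in range(int(table[gi, ci])):
                k += 1
                records.append(make_pseudo_record(group, mi, grade, stage, f"X{k:04d}"))
    return records
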