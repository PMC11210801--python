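"""Seed-reproducible synthetic cohorts with the study's joint structure.

The generator draws each patient's preoperative risk group from the
published group frequencies and the postoperative class from the published
class-given-group conditional table, then fills in postoperative findings
consistent with the class and covariates around the published marginals:
truncated-normal age, right-skewed gamma CA125 rejected at the inclusion
limit, log-normal tumor sizes around invasion-stratum means, and a missing
preoperative size indicator.  A ``signal_strength`` dial shifts covariate
locations with the postoperative class so that classifiers have learnable
signal beyond the preoperative categories; at zero the covariates are
independent of the outcome.

``exact`` mode rounds the joint group x class distribution to integers by
largest remainder, so the default specification at n = 251 reproduces the
published table cell for cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cohort import (
    BiopsyMethod,
    Grade,
    MICategory,
    PatientRecord,
    PostopClass,
    RiskGroup,
    Stage,
    SurgeryMethod,
    group_definition,
)

__all__ = ["CohortSpec", "generate_cohort", "write_cohort", "largest_remainder", "null_spec"]

# Published composition: group sizes and postoperative class counts per group.
_DEFAULT_GROUP_COUNTS = np.array([106, 41, 74, 30], dtype=float)
_DEFAULT_CLASS_COUNTS = np.array(
    [
        [46, 6, 38, 5, 11],
        [4, 6, 11, 10, 10],
        [14, 0, 45, 9, 6],
        [3, 2, 4, 13, 8],
    ],
    dtype=float,
)

# Composition of the HIGHER class over the whole cohort: stage IA + grade 3,
# stage IA + inadequate grade, stage IB, stage II, stage IIIC (counts
# 5/6/12/6/6 of 35).
_HIGHER_KINDS = ("ia_g3", "ia_inadequate", "ib", "ii", "iiic")
_DEFAULT_HIGHER_PROBS = np.array([5, 6, 12, 6, 6], dtype=float) / 35.0


def largest_remainder(probs: np.ndarray, n: int) -> np.ndarray:
    """Round ``probs * n`` to integers summing to ``n``: floors first, then
    one extra unit per cell in decreasing order of fractional remainder
    (ties broken by cell index)."""
    probs = np.asarray(probs, dtype=float)
    raw = probs * n
    base = np.floor(raw).astype(int)
    short = int(round(n - base.sum()))
    if short:
        order = np.lexsort((np.arange(probs.size), -(raw - base)))
        base[order[:short]] += 1
    return base


@dataclass
class CohortSpec:
    """Generator parameters; the defaults are the published study conditions."""

    n: int = 251
    group_probs: np.ndarray = field(
        default_factory=lambda: _DEFAULT_GROUP_COUNTS / _DEFAULT_GROUP_COUNTS.sum()
    )
    postop_class_given_group: np.ndarray = field(
        default_factory=lambda: _DEFAULT_CLASS_COUNTS
        / _DEFAULT_CLASS_COUNTS.sum(axis=1, keepdims=True)
    )
    higher_probs: np.ndarray = field(default_factory=lambda: _DEFAULT_HIGHER_PROBS.copy())
    age_mean: float = 52.8
    age_sd: float = 9.6
    age_bounds: tuple[float, float] = (20.0, 90.0)
    menopause_prob: float = 0.606
    biopsy_method_probs: np.ndarray = field(
        default_factory=lambda: np.array([0.908, 0.024, 0.068])
    )
    size_missing_prob: float = 0.355
    ca125_mean: float = 19.2
    ca125_sd: float = 10.1
    postop_size_mean_by_mi: np.ndarray = field(
        default_factory=lambda: np.array([1.41, 2.45, 2.95])
    )
    size_log_sd: float = 0.75
    mis_prob: float = 0.861
    lvsi_prob: float = 0.05
    lvsi_prob_higher: float = 0.3
    endometrioid_prob: float = 0.988
    signal_strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.group_probs = np.asarray(self.group_probs, dtype=float)
        self.postop_class_given_group = np.asarray(self.postop_class_given_group, dtype=float)
        self.higher_probs = np.asarray(self.higher_probs, dtype=float)
        self.biopsy_method_probs = np.asarray(self.biopsy_method_probs, dtype=float)
        self.postop_size_mean_by_mi = np.asarray(self.postop_size_mean_by_mi, dtype=float)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        tol = 1e-12
        if abs(self.group_probs.sum() - 1) > tol:
            raise ValueError("group_probs must sum to 1")
        if np.abs(self.postop_class_given_group.sum(axis=1) - 1).max() > tol:
            raise ValueError("postop_class_given_group rows must sum to 1")
        if abs(self.higher_probs.sum() - 1) > tol or abs(self.biopsy_method_probs.sum() - 1) > tol:
            raise ValueError("probability vectors must sum to 1")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")

    @property
    def joint_probs(self) -> np.ndarray:
        return self.group_probs[:, None] * self.postop_class_given_group


def null_spec(n: int = 2000, seed: int = 0) -> CohortSpec:
    """The no-association null: the postoperative class is independent of
    the preoperative group and of every covariate (identical conditional
    rows, zero covariate signal, a single tumor-size stratum mean)."""
    marginal = _DEFAULT_CLASS_COUNTS.sum(axis=0) / _DEFAULT_CLASS_COUNTS.sum()
    return CohortSpec(
        n=n,
        postop_class_given_group=np.tile(marginal, (4, 1)),
        postop_size_mean_by_mi=np.array([2.0, 2.0, 2.0]),
        signal_strength=0.0,
        seed=seed,
    )


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def _gamma_below(rng, mean, sd, limit) -> float:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    for _ in range(1000):
        v = rng.gamma(shape, scale)
        if 0 < v < limit:
            return float(v)
    return float(limit * 0.5)


def _postop_findings(rng, cls: PostopClass, higher_probs: np.ndarray):
    """Draw (mi, grade, stage, node_met) consistent with a postoperative class."""
    if cls is not PostopClass.HIGHER:
        mi, grade = group_definition(RiskGroup(int(cls)))
        return mi, grade, Stage.IA, False
    kind = _HIGHER_KINDS[rng.choice(len(_HIGHER_KINDS), p=higher_probs)]
    shallow = MICategory.NONE if rng.random() < 0.5 else MICategory.LT_HALF
    low_grade = Grade.G1 if rng.random() < 0.7 else Grade.G2
    if kind == "ia_g3":
        return shallow, Grade.G3, Stage.IA, False
    if kind == "ia_inadequate":
        return shallow, Grade.INADEQUATE, Stage.IA, False
    if kind == "ib":
        return MICategory.GE_HALF, low_grade, Stage.IB, False
    if kind == "ii":
        return shallow, low_grade, Stage.II, False
    return shallow, low_grade, Stage.IIIC, True


def _make_record(rng, spec: CohortSpec, group: RiskGroup, cls: PostopClass, ident: str) -> PatientRecord:
    preop_mi, preop_grade = group_definition(group)
    mi, grade, stage, node_met = _postop_findings(rng, cls, spec.higher_probs)

    # Covariate-to-outcome signal: location shifts monotone in the class.
    shift = spec.signal_strength * (int(cls) - 3)
    age = _truncated_normal(rng, spec.age_mean + 1.0 * shift, spec.age_sd, *spec.age_bounds)
    ca_mean = max(5.0, spec.ca125_mean * (1 + 0.03 * shift))
    ca125 = _gamma_below(rng, ca_mean, spec.ca125_sd, 35.0)

    size_mean = spec.postop_size_mean_by_mi[int(mi)] * np.exp(0.05 * shift)
    mu = np.log(size_mean) - spec.size_log_sd**2 / 2
    postop_size = float(np.exp(rng.normal(mu, spec.size_log_sd)))
    if rng.random() < spec.size_missing_prob:
        preop_size = None
    else:
        preop_size = float(np.exp(rng.normal(mu, spec.size_log_sd)))

    lvsi_p = spec.lvsi_prob_higher if cls is PostopClass.HIGHER else spec.lvsi_prob
    return PatientRecord(
        id=ident,
        age=age,
        menopause=bool(rng.random() < spec.menopause_prob),
        biopsy_method=list(BiopsyMethod)[rng.choice(3, p=spec.biopsy_method_probs)],
        preop_grade=preop_grade,
        preop_mi=preop_mi,
        preop_tumor_size_cm=preop_size,
        ca125=ca125,
        surgery_method=SurgeryMethod.MIS if rng.random() < spec.mis_prob else SurgeryMethod.LAPAROTOMY,
        postop_mi=mi,
        postop_grade=grade,
        postop_stage=stage,
        postop_tumor_size_cm=postop_size,
        lvsi=bool(rng.random() < lvsi_p),
        histology_endometrioid=bool(rng.random() < spec.endometrioid_prob),
        pelvic_node_met=node_met,
    )


def generate_cohort(spec: CohortSpec, mode: str = "sample") -> list[PatientRecord]:
    """Generate ``spec.n`` patient records.

    ``mode='exact'`` rounds the joint group x class distribution to integer
    cell counts by largest remainder (the default specification at n = 251
    reproduces the published composition exactly); ``mode='sample'`` draws
    the cell counts multinomially.  Covariates are random in both modes.
    Identical specs produce identical cohorts.
    """
    if mode not in ("sample", "exact"):
        raise ValueError(f"mode must be 'sample' or 'exact', got {mode!r}")
    rng = np.random.default_rng(spec.seed)
    joint = spec.joint_probs.ravel()
    if mode == "exact":
        n_cells = int((joint > 0).sum())
        if spec.n < n_cells:
            raise ValueError(f"exact mode needs n >= {n_cells} (number of nonzero cells)")
        counts = largest_remainder(joint, spec.n)
    else:
        counts = rng.multinomial(spec.n, joint)
    counts = counts.reshape(4, 5)

    records: list[PatientRecord] = []
    k = 0
    for gi, group in enumerate(RiskGroup):
        for ci, cls in enumerate(PostopClass):
            for _ in range(int(counts[gi, ci])):
                k += 1
                records.append(_make_record(rng, spec, group, cls, f"P{k:05d}"))
    return records


def write_cohort(records, path) -> None:
    """Write a cohort to CSV (lossless round trip with ``read_cohort``)."""
    from .cohort import write_cohort as _write

    _write(records, path)
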