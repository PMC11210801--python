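"""Agreement between preoperative assessment and final pathology.

Cross-tabulation of the four preoperative risk groups against the five
postoperative classes, matching/upstaging/downstaging rates, per-variable
(invasion, grade) agreement, one-vs-rest 2x2 diagnostic metrics, Cohen's
kappa, and percentile bootstrap confidence intervals.

For a dichotomous predictor the rank AUC collapses to the mean of
sensitivity and specificity; :func:`diagnostic_profile` uses that closed
form, which matches the published conventional-analysis AUCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .cohort import MICategory, Grade, PatientRecord, PostopClass, RiskGroup, classify_postop

__all__ = [
    "CrossTab",
    "TwoByTwo",
    "DiagnosticProfile",
    "crosstab",
    "matching_rate",
    "shift_rates",
    "mi_grade_matching",
    "two_by_two",
    "diagnostic_profile",
    "cohen_kappa",
    "kappa_band",
    "bootstrap_ci",
    "group_kappa",
    "kappa_ci",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrossTab:
    """4 preoperative groups x 5 postoperative classes count matrix."""

    counts: np.ndarray  # shape (4, 5), non-negative ints

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (4, 5) or (c < 0).any():
            raise ValueError("CrossTab requires a non-negative 4x5 integer table")
        object.__setattr__(self, "counts", c)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.counts,
            index=[g.name.lower() for g in RiskGroup],
            columns=[c.name.lower() for c in PostopClass],
        )


@dataclass(frozen=True)
class TwoByTwo:
    """One-vs-rest table for a target group: preoperative indicator (test)
    against postoperative indicator (truth)."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticProfile:
    """Proportions are in [0, 1]; ``None`` marks an undefined metric
    (zero denominator), rendered as "N/A" in reports."""

    npv: Optional[float]
    ppv: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    auc: Optional[float]

    def as_percent(self) -> dict[str, str]:
        out = {}
        for name in ("npv", "ppv", "sensitivity", "specificity"):
            v = getattr(self, name)
            out[name] = "N/A" if v is None else f"{100 * v:.1f}"
        out["auc"] = "N/A" if self.auc is None else f"{self.auc:.3f}"
        return out


def crosstab(records: Sequence[PatientRecord]) -> CrossTab:
    """Count patients by (preoperative group, postoperative class)."""
    counts = np.zeros((4, 5), dtype=int)
    for r in records:
        counts[int(r.preop_group) - 1, int(classify_postop(r)) - 1] += 1
    return CrossTab(counts)


def matching_rate(tab: CrossTab, group: RiskGroup) -> float:
    """Fraction of the preoperative group confirmed on final pathology
    (the diagonal cell over the preoperative group size)."""
    i = int(group) - 1
    denom = tab.row_totals[i]
    if denom == 0:
        raise ZeroDivisionError(f"empty preoperative group {group.name}")
    return tab.counts[i, i] / denom


def shift_rates(tab: CrossTab, group: RiskGroup) -> tuple[float, float]:
    """(upstaged, downstaged) fractions of a preoperative group, under the
    ordering group1 < group2 < group3 < group4 < higher."""
    i = int(group) - 1
    denom = tab.row_totals[i]
    if denom == 0:
        raise ZeroDivisionError(f"empty preoperative group {group.name}")
    up = tab.counts[i, i + 1 :].sum() / denom
    down = tab.counts[i, :i].sum() / denom
    return float(up), float(down)


def mi_grade_matching(records: Sequence[PatientRecord]) -> dict:
    """Per-category agreement of invasion depth and grade between the
    preoperative assessment and final pathology, overall and by group.

    Returns a dict with keys ``mi``, ``grade`` (category -> proportion) and
    ``mi_by_group``, ``grade_by_group`` ((group, category) -> proportion).
    Empty strata raise ``ZeroDivisionError``.
    """

    def agree(pairs: list[tuple[int, int]], pre_value) -> float:
        sel = [(a, b) for a, b in pairs if a == pre_value]
        if not sel:
            raise ZeroDivisionError(f"empty preoperative stratum {pre_value}")
        return sum(a == b for a, b in sel) / len(sel)

    mi_pairs = [(r.preop_mi, r.postop_mi) for r in records]
    gr_pairs = [(r.preop_grade, r.postop_grade) for r in records]
    out = {
        "mi": {c: agree(mi_pairs, c) for c in (MICategory.NONE, MICategory.LT_HALF)},
        "grade": {g: agree(gr_pairs, g) for g in (Grade.G1, Grade.G2)},
        "mi_by_group": {},
        "grade_by_group": {},
    }
    for g in RiskGroup:
        sub = [r for r in records if r.preop_group == g]
        mi_cat, grade_cat = sub[0].preop_mi if sub else None, sub[0].preop_grade if sub else None
        if sub:
            out["mi_by_group"][g] = agree([(r.preop_mi, r.postop_mi) for r in sub], mi_cat)
            out["grade_by_group"][g] = agree(
                [(r.preop_grade, r.postop_grade) for r in sub], grade_cat
            )
    return out


def two_by_two(tab: CrossTab, group: RiskGroup) -> TwoByTwo:
    """Binarize the cross-tab one-vs-rest for the target group."""
    i = int(group) - 1
    tp = int(tab.counts[i, i])
    fp = int(tab.row_totals[i] - tp)
    fn = int(tab.col_totals[i] - tp)
    tn = int(tab.n - tp - fp - fn)
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, denom: int) -> Optional[float]:
    return None if denom == 0 else num / denom


def diagnostic_profile(t: TwoByTwo) -> DiagnosticProfile:
    """NPV/PPV/sensitivity/specificity and the binary-predictor rank AUC,
    (sensitivity + specificity) / 2.  Zero denominators yield ``None``."""
    sens = _ratio(t.tp, t.tp + t.fn)
    spec = _ratio(t.tn, t.tn + t.fp)
    return DiagnosticProfile(
        npv=_ratio(t.tn, t.tn + t.fn),
        ppv=_ratio(t.tp, t.tp + t.fp),
        sensitivity=sens,
        specificity=spec,
        auc=None if sens is None or spec is None else (sens + spec) / 2,
    )


def cohen_kappa(t: TwoByTwo) -> Optional[float]:
    """Unweighted Cohen's kappa of the 2x2 agreement table; ``None`` when
    the chance-agreement probability is 1 (degenerate margins)."""
    n = t.n
    if n == 0:
        raise ZeroDivisionError("empty table")
    p_o = (t.tp + t.tn) / n
    p_e = ((t.tp + t.fp) * (t.tp + t.fn) + (t.tn + t.fn) * (t.tn + t.fp)) / n**2
    if p_e == 1.0:
        logger.warning("degenerate 2x2 table: chance agreement is 1, kappa undefined")
        return None
    return (p_o - p_e) / (1 - p_e)


_KAPPA_BANDS = [(0.2, "poor"), (0.4, "fair"), (0.6, "moderate"), (0.8, "substantial")]


def kappa_band(k: float) -> str:
    """Qualitative agreement band; upper bounds are inclusive."""
    for bound, label in _KAPPA_BANDS:
        if k <= bound:
            return label
    return "good"


def group_kappa(records: Sequence[PatientRecord], group: RiskGroup) -> Optional[float]:
    """Cohen's kappa for the one-vs-rest agreement on a target group."""
    return cohen_kappa(two_by_two(crosstab(records), group))


def bootstrap_ci(
    data,
    statistic: Callable,
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap interval over ``B`` patient-level resamples.

    ``data`` is a sequence (list of records or an array of per-patient
    rows); ``statistic`` maps a resample of the same size to a float.  A
    resample on which the statistic is undefined (``None``/NaN) is redrawn;
    the number of redraws is logged.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(data)
    if n == 0:
        raise ValueError("empty data")
    rng = np.random.default_rng(seed)
    is_array = isinstance(data, np.ndarray)
    values = np.empty(B)
    redraws = 0
    for b in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            sample = data[idx] if is_array else [data[i] for i in idx]
            v = statistic(sample)
            if v is not None and np.isfinite(v):
                values[b] = v
                break
            redraws += 1
        else:
            raise RuntimeError("statistic undefined on every redraw of a resample")
    if redraws:
        logger.info("bootstrap: redrew %d resamples with undefined statistic", redraws)
    alpha = (1 - level) / 2
    return float(np.quantile(values, alpha)), float(np.quantile(values, 1 - alpha))


def kappa_ci(
    records: Sequence[PatientRecord],
    group: RiskGroup,
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bootstrap CI for the one-vs-rest kappa, vectorized over patients."""
    pre = np.array([int(r.preop_group) == int(group) for r in records], dtype=int)
    post = np.array([int(classify_postop(r)) == int(group) for r in records], dtype=int)
    pairs = np.column_stack([pre, post])

    def stat(sample: np.ndarray) -> Optional[float]:
        a, b = sample[:, 0], sample[:, 1]
        t = TwoByTwo(
            tp=int((a & b).sum()),
            fp=int((a & (1 - b)).sum()),
            fn=int(((1 - a) & b).sum()),
            tn=int(((1 - a) & (1 - b)).sum()),
        )
        return cohen_kappa(t)

    return bootstrap_ci(pairs, stat, B=B, seed=seed, level=level)


def auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bootstrap CI for the rank AUC of continuous scores."""
    from sklearn.metrics import roc_auc_score

    data = np.column_stack([np.asarray(scores, dtype=float), np.asarray(labels, dtype=float)])

    def stat(sample: np.ndarray) -> Optional[float]:
        y = sample[:, 1]
        if y.min() == y.max():
            return None
        return float(roc_auc_score(y, sample[:, 0]))

    return bootstrap_ci(data, stat, B=B, seed=seed, level=level)
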