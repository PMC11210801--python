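"""Depth-of-invasion calibration and tumor-size preprocessing.

The preoperative MRI invasion category disagrees with final pathology in a
third to a half of patients, so before classification the invasion code is
*calibrated*: a chained-equation imputation treats the postoperative depth
(0 = none, 1 = <1/2, 2 = >= 1/2) as the value observed on training records
and predicts a continuous depth for every record from the model variables.
Variant NPM1 keeps the raw preoperative code among the predictors, so its
calibrated values cluster around the two preoperative levels; variant NPM2
drops it and produces smoothly varying soft values — a label-smoothing
effect on the ordinal depth.

Missing preoperative tumor sizes are imputed with stratum means of the
postoperative size.  On training data the strata are keyed on the
postoperative invasion category (as in the source protocol); at prediction
time the postoperative category is unknown, so the frozen training means
are keyed on the preoperative category instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cohort import BiopsyMethod, Grade, MICategory, PatientRecord

__all__ = [
    "DEFAULT_SIZE_BY_MI",
    "ChainedEquationImputer",
    "CalibrationModel",
    "fit_size_strata",
    "impute_tumor_size",
    "build_features",
    "fit_mi_calibrator",
    "calibrate_mi",
    "mi_mse",
    "cross_fitted_calibration",
]

logger = logging.getLogger(__name__)

# Study-level mean postoperative tumor size (cm) by postoperative invasion
# category: none, <1/2, >=1/2.
DEFAULT_SIZE_BY_MI = {0: 1.41, 1: 2.45, 2: 2.95}

COVARIATE_NAMES = [
    "age",
    "menopause",
    "biopsy_grade",
    "biopsy_hysteroscopy",
    "biopsy_pipelle",
    "preop_tumor_size_cm",
    "ca125",
]


# ---------------------------------------------------------------------------
# Tumor-size imputation
# ---------------------------------------------------------------------------

def fit_size_strata(records: Sequence[PatientRecord]) -> dict[int, float]:
    """Mean postoperative tumor size per postoperative invasion category."""
    strata: dict[int, list[float]] = {}
    for r in records:
        strata.setdefault(int(r.postop_mi), []).append(r.postop_tumor_size_cm)
    return {k: float(np.mean(v)) for k, v in sorted(strata.items())}


def impute_tumor_size(
    records: Sequence[PatientRecord],
    strata_means: Optional[dict[int, float]] = None,
    key_on: str = "postop_mi",
) -> list[PatientRecord]:
    """Fill missing preoperative tumor sizes with invasion-stratum means.

    When ``strata_means`` is omitted they are estimated from these records'
    postoperative sizes (training use).  ``key_on`` selects whether a
    record's stratum is its postoperative or preoperative invasion category
    — the latter is the leakage-free choice for held-out records.  A missing
    stratum with no supplied mean raises ``KeyError``.
    """
    if key_on not in ("postop_mi", "preop_mi"):
        raise ValueError(f"key_on must be 'postop_mi' or 'preop_mi', got {key_on!r}")
    means = fit_size_strata(records) if strata_means is None else dict(strata_means)
    out = []
    for r in records:
        if r.preop_tumor_size_cm is None:
            stratum = int(getattr(r, key_on))
            if stratum not in means:
                raise KeyError(
                    f"record {r.id}: no size stratum mean for invasion category {stratum}"
                )
            out.append(replace(r, preop_tumor_size_cm=means[stratum]))
        else:
            out.append(r)
    return out


def build_features(records: Sequence[PatientRecord]) -> np.ndarray:
    """Design matrix of the six clinical covariates (seven columns: the
    biopsy method contributes two dummies against a curettage baseline).
    Requires tumor sizes to be already imputed."""
    rows = []
    for r in records:
        if r.preop_tumor_size_cm is None:
            raise ValueError(f"record {r.id}: tumor size missing; run impute_tumor_size first")
        rows.append(
            [
                r.age,
                1.0 if r.menopause else 0.0,
                float(r.preop_grade.value),
                1.0 if r.biopsy_method is BiopsyMethod.HYSTEROSCOPY else 0.0,
                1.0 if r.biopsy_method is BiopsyMethod.PIPELLE else 0.0,
                r.preop_tumor_size_cm,
                r.ca125,
            ]
        )
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# Chained-equation imputer
# ---------------------------------------------------------------------------

class ChainedEquationImputer:
    """Iterative imputation by chained linear regressions.

    Each column listed in ``impute_cols`` (or any column with missing
    entries at fit time) is regressed on all other columns using the rows
    where it is observed; missing entries are replaced by the fitted
    predictions, and the sweep repeats until the imputed values move less
    than ``tol`` or ``max_iter`` sweeps have run.  With a single incomplete
    column the procedure reduces to one ordinary least-squares regression.

    Rank-deficient designs fall back to a small ridge penalty (logged).
    """

    def __init__(
        self,
        impute_cols: Optional[Sequence[int]] = None,
        max_iter: int = 10,
        tol: float = 1e-8,
        ridge: float = 1e-6,
    ):
        self.impute_cols = None if impute_cols is None else list(impute_cols)
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge
        self.models_: dict[int, tuple[np.ndarray, float]] = {}
        self.col_means_: Optional[np.ndarray] = None

    def _solve(self, A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
        X = np.column_stack([np.ones(len(A)), A])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            logger.warning("rank-deficient design; falling back to ridge regression")
            XtX = X.T @ X + self.ridge * np.eye(X.shape[1])
            beta = np.linalg.solve(XtX, X.T @ y)
        else:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta[1:], float(beta[0])

    def fit(self, X: np.ndarray) -> "ChainedEquationImputer":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        cols = self.impute_cols
        if cols is None:
            cols = [j for j in range(p) if np.isnan(X[:, j]).any()]
        self.col_means_ = np.nanmean(X, axis=0)
        work = X.copy()
        for j in cols:
            miss = np.isnan(work[:, j])
            work[miss, j] = self.col_means_[j]

        for _ in range(max(1, self.max_iter)):
            max_change = 0.0
            for j in cols:
                others = [k for k in range(p) if k != j]
                obs = ~np.isnan(X[:, j])
                if not obs.any():
                    raise ValueError(f"column {j} has no observed values to fit on")
                coef, intercept = self._solve(work[np.ix_(obs, others)], X[obs, j])
                self.models_[j] = (coef, intercept)
                miss = ~obs
                if miss.any():
                    pred = work[np.ix_(miss, others)] @ coef + intercept
                    max_change = max(max_change, float(np.abs(pred - work[miss, j]).max()))
                    work[miss, j] = pred
            if max_change < self.tol:
                break
        self.fit_cols_ = cols
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.col_means_ is None:
            raise RuntimeError("imputer is not fitted")
        X = np.asarray(X, dtype=float)
        work = X.copy()
        p = X.shape[1]
        for j in self.fit_cols_:
            miss = np.isnan(work[:, j])
            work[miss, j] = self.col_means_[j]
        for _ in range(max(1, self.max_iter)):
            max_change = 0.0
            for j in self.fit_cols_:
                miss = np.isnan(X[:, j])
                if not miss.any():
                    continue
                others = [k for k in range(p) if k != j]
                coef, intercept = self.models_[j]
                pred = work[np.ix_(miss, others)] @ coef + intercept
                max_change = max(max_change, float(np.abs(pred - work[miss, j]).max()))
                work[miss, j] = pred
            if max_change < self.tol:
                break
        return work


# ---------------------------------------------------------------------------
# MI-depth calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """Fitted depth-of-invasion calibrator.

    ``variant`` NPM1 includes the preoperative invasion code among the
    predictors; NPM2 excludes it.  ``size_strata`` are the frozen
    training-fold tumor-size means.  Predictions are clipped to the depth
    coding range [0, 2].
    """

    variant: str
    imputer: ChainedEquationImputer
    size_strata: dict[int, float]
    clip: tuple[float, float] = (0.0, 2.0)
    feature_names: list[str] = field(default_factory=list)

    @property
    def coef(self) -> np.ndarray:
        return self.imputer.models_[self._target_col][0]

    @property
    def intercept(self) -> float:
        return self.imputer.models_[self._target_col][1]

    @property
    def _target_col(self) -> int:
        return self.imputer.fit_cols_[0]


def _calibration_matrix(
    records: Sequence[PatientRecord], variant: str, target: Optional[np.ndarray]
) -> np.ndarray:
    X = build_features(records)
    if variant == "NPM1":
        X = np.column_stack([X, [float(int(r.preop_mi)) for r in records]])
    t = np.full(len(records), np.nan) if target is None else target
    return np.column_stack([X, t])


def fit_mi_calibrator(
    train_records: Sequence[PatientRecord],
    variant: str = "NPM2",
    size_strata: Optional[dict[int, float]] = None,
) -> CalibrationModel:
    """Fit the depth calibrator on training records.

    The chained-equation matrix holds the model covariates (plus the
    preoperative code for NPM1) and a depth column observed as the
    postoperative category on the training rows; that column is the single
    imputable column, so the fit reduces to a least-squares regression of
    the postoperative depth on the predictors.
    """
    variant = variant.upper()
    if variant not in ("NPM1", "NPM2"):
        raise ValueError(f"variant must be 'NPM1' or 'NPM2', got {variant!r}")
    if size_strata is None:
        size_strata = fit_size_strata(train_records)
    train = impute_tumor_size(train_records, size_strata, key_on="postop_mi")
    target = np.array([float(int(r.postop_mi)) for r in train])
    M = _calibration_matrix(train, variant, target)
    imputer = ChainedEquationImputer(impute_cols=[M.shape[1] - 1]).fit(M)
    names = list(COVARIATE_NAMES) + (["preop_mi"] if variant == "NPM1" else [])
    return CalibrationModel(
        variant=variant, imputer=imputer, size_strata=size_strata, feature_names=names
    )


def calibrate_mi(
    records: Sequence[PatientRecord],
    model: CalibrationModel,
    size_key: str = "preop_mi",
) -> list[PatientRecord]:
    """Attach the calibrated continuous depth to each record.

    The original categorical fields are retained; predictions are clipped
    to the depth range.  ``size_key`` chooses the stratum key for any
    missing tumor sizes (preoperative for held-out records).
    """
    if not records:
        return []
    recs = impute_tumor_size(records, model.size_strata, key_on=size_key)
    M = _calibration_matrix(recs, model.variant, target=None)
    completed = model.imputer.transform(M)
    values = np.clip(completed[:, -1], *model.clip)
    return [replace(r, calibrated_mi=float(v)) for r, v in zip(recs, values)]


def mi_mse(calibrated: Sequence[float], postop_codes: Sequence[int]) -> float:
    """Mean squared difference between calibrated and postoperative depth."""
    y_hat = np.asarray(calibrated, dtype=float)
    y = np.asarray(postop_codes, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean((y - y_hat) ** 2))


def cross_fitted_calibration(
    records: Sequence[PatientRecord],
    variant: str,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """K-fold cross-fitted calibrated depths and their out-of-fold MSE
    against the postoperative category."""
    from sklearn.model_selection import KFold

    records = list(records)
    values = np.empty(len(records))
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(records):
        train = [records[i] for i in train_idx]
        test = [records[i] for i in test_idx]
        model = fit_mi_calibrator(train, variant)
        for i, r in zip(test_idx, calibrate_mi(test, model, size_key="preop_mi")):
            values[i] = r.calibrated_mi
    mse = mi_mse(values, [int(r.postop_mi) for r in records])
    return values, mse
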