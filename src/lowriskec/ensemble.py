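"""Class-balanced sub-dataset ensembles and baseline classifiers.

One binary task per target group: does the final pathology confirm the
preoperative risk group?  Positives (the target class) are the minority,
so each outer training fold is rebalanced by keeping every minority record
and splitting the shuffled majority into near-equal disjoint chunks; each
chunk plus the full minority set forms a sub-dataset.  Inner 5-fold
cross-validation trains one weak classifier per fold of each sub-dataset,
and the member with the highest validation selection score

    (TP + TN) - (FP + FN)

is kept per sub-dataset.  The ensemble predicts with the mean member
probability.  The two model variants differ only in the depth calibrator
they use (NPM1 keeps the preoperative invasion code among the calibration
predictors, NPM2 drops it).  Baselines (logistic regression, gradient
boosted trees, RBF-kernel SVM) share the outer folds and tumor-size
imputation but see the raw invasion code and no rebalancing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import (
    build_features,
    calibrate_mi,
    fit_mi_calibrator,
    fit_size_strata,
    impute_tumor_size,
)
from .cohort import PatientRecord, PostopClass, RiskGroup, classify_postop
from .concordance import DiagnosticProfile, TwoByTwo, auc_ci, diagnostic_profile

__all__ = [
    "NPMConfig",
    "SubDataset",
    "WeakClassifier",
    "EnsembleModel",
    "EvaluationResult",
    "outer_split",
    "build_subdatasets",
    "train_weak_classifiers",
    "select_models",
    "selection_score",
    "run_npm",
    "run_baseline",
    "evaluate_methods",
]

logger = logging.getLogger(__name__)


def derive_seed(seed: int, *keys: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class NPMConfig:
    outer_k: int = 5
    inner_k: int = 5
    learner: str = "logistic"  # or "tree"
    top_m: int = 1
    combine: str = "mean"  # or "vote"
    threshold: float = 0.5
    bootstrap_b: int = 2000


@dataclass(frozen=True)
class SubDataset:
    """All minority (target-class) training indices plus one disjoint chunk
    of the shuffled majority."""

    index: int
    minority_idx: np.ndarray
    majority_idx: np.ndarray

    @property
    def indices(self) -> np.ndarray:
        return np.concatenate([self.minority_idx, self.majority_idx])


@dataclass
class WeakClassifier:
    model: object
    subdataset_id: int
    fold_id: int
    score: int  # (TP+TN)-(FP+FN) on the inner validation fold
    counts: TwoByTwo


@dataclass
class EnsembleModel:
    members: list[WeakClassifier]
    combine: str = "mean"
    threshold: float = 0.5

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs = np.column_stack([_proba(m.model, X) for m in self.members])
        if self.combine == "vote":
            return (probs >= self.threshold).mean(axis=1)
        return probs.mean(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)


@dataclass
class EvaluationResult:
    """Pooled outer-fold test predictions for one method on one target."""

    method: str
    target: RiskGroup
    variant: Optional[str]
    per_fold: list[TwoByTwo]
    pooled: TwoByTwo
    profile: DiagnosticProfile
    auc: Optional[float]
    auc_ci: Optional[tuple[float, float]]
    scores: np.ndarray
    labels: np.ndarray
    seed: int
    config: NPMConfig = field(default_factory=NPMConfig)

    def to_dict(self) -> dict:
        prof = self.profile.as_percent()
        return {
            "method": self.method,
            "target": self.target.name.lower(),
            "npv": prof["npv"],
            "ppv": prof["ppv"],
            "sensitivity": prof["sensitivity"],
            "specificity": prof["specificity"],
            "auc": "N/A" if self.auc is None else f"{self.auc:.3f}",
            "auc_ci": None if self.auc_ci is None else [round(v, 3) for v in self.auc_ci],
            "pooled_counts": {
                "tp": self.pooled.tp,
                "fp": self.pooled.fp,
                "fn": self.pooled.fn,
                "tn": self.pooled.tn,
            },
            "seed": self.seed,
        }


def _proba(model, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


def _labels(records: Sequence[PatientRecord], target: RiskGroup) -> np.ndarray:
    return np.array([int(classify_postop(r)) == int(target) for r in records], dtype=int)


def outer_split(
    records: Sequence[PatientRecord],
    target: RiskGroup,
    k: int = 5,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified K-fold partition on the binary postoperative label."""
    from sklearn.model_selection import StratifiedKFold

    y = _labels(records, target)
    n_min = int(min(np.bincount(y, minlength=2)))
    if n_min == 0:
        raise ValueError(f"target {target.name}: both classes must be present")
    eff_k = min(k, n_min)
    if eff_k < k:
        logger.warning(
            "target %s: minority class has %d members; using %d folds", target.name, n_min, eff_k
        )
    if eff_k < 2:
        raise ValueError(f"target {target.name}: minority class too small to split")
    skf = StratifiedKFold(n_splits=eff_k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def build_subdatasets(y_train: np.ndarray, seed: int = 0) -> list[SubDataset]:
    """Split the shuffled majority into r = max(1, round(n_maj / n_min))
    disjoint near-equal chunks; each chunk plus the whole minority set is
    one sub-dataset."""
    y_train = np.asarray(y_train, dtype=int)
    minority_idx = np.flatnonzero(y_train == 1)
    majority_idx = np.flatnonzero(y_train == 0)
    if minority_idx.size == 0:
        raise ValueError("minority class is empty")
    if minority_idx.size > majority_idx.size:
        minority_idx, majority_idx = majority_idx, minority_idx
    r = max(1, int(np.floor(majority_idx.size / minority_idx.size + 0.5)))
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(majority_idx)
    chunks = np.array_split(shuffled, r)
    return [
        SubDataset(index=i, minority_idx=minority_idx, majority_idx=np.sort(chunk))
        for i, chunk in enumerate(chunks)
    ]


def make_learner(kind: str, seed: int):
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.tree import DecisionTreeClassifier

    if kind == "logistic":
        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    if kind == "tree":
        return DecisionTreeClassifier(max_depth=3, random_state=seed)
    raise ValueError(f"unknown learner kind {kind!r}")


def selection_score(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, TwoByTwo]:
    """(TP+TN) - (FP+FN) on a validation fold."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    t = TwoByTwo(
        tp=int(((y_pred == 1) & (y_true == 1)).sum()),
        fp=int(((y_pred == 1) & (y_true == 0)).sum()),
        fn=int(((y_pred == 0) & (y_true == 1)).sum()),
        tn=int(((y_pred == 0) & (y_true == 0)).sum()),
    )
    return (t.tp + t.tn) - (t.fp + t.fn), t


def train_weak_classifiers(
    X: np.ndarray,
    y: np.ndarray,
    subdataset: SubDataset,
    inner_k: int = 5,
    learner: str = "logistic",
    seed: int = 0,
) -> list[WeakClassifier]:
    """Plain inner K-fold on one sub-dataset: fit a weak classifier on each
    K-1 folds, score it by the selection criterion on its held-out fold.
    Folds whose training part is single-class are skipped (logged)."""
    from sklearn.model_selection import KFold

    idx = subdataset.indices
    Xs, ys = X[idx], y[idx]
    out: list[WeakClassifier] = []
    kf = KFold(n_splits=inner_k, shuffle=True, random_state=seed)
    for fold_id, (tr, va) in enumerate(kf.split(Xs)):
        if len(np.unique(ys[tr])) < 2:
            logger.warning(
                "sub-dataset %d fold %d: single-class training fold skipped",
                subdataset.index,
                fold_id,
            )
            continue
        model = make_learner(learner, derive_seed(seed, subdataset.index, fold_id))
        model.fit(Xs[tr], ys[tr])
        score, counts = selection_score(ys[va], model.predict(Xs[va]))
        out.append(
            WeakClassifier(
                model=model,
                subdataset_id=subdataset.index,
                fold_id=fold_id,
                score=score,
                counts=counts,
            )
        )
    return out


def select_models(
    classifier_groups: Sequence[Sequence[WeakClassifier]],
    top_m: int = 1,
    combine: str = "mean",
    threshold: float = 0.5,
) -> EnsembleModel:
    """Keep the top-scoring classifier(s) of each sub-dataset (ties broken
    by lowest inner-fold index); sub-datasets whose classifiers were all
    skipped are dropped (logged)."""
    members: list[WeakClassifier] = []
    for i, group in enumerate(classifier_groups):
        if not group:
            logger.warning("sub-dataset %d: no trainable classifiers, dropped", i)
            continue
        ranked = sorted(group, key=lambda c: (-c.score, c.fold_id))
        members.extend(ranked[:top_m])
    if not members:
        raise ValueError("no classifiers available for the ensemble")
    return EnsembleModel(members=members, combine=combine, threshold=threshold)


# ---------------------------------------------------------------------------
# Full pipelines
# ---------------------------------------------------------------------------

def _features_calibrated(records: Sequence[PatientRecord]) -> np.ndarray:
    X = build_features(records)
    cal = np.array([r.calibrated_mi for r in records], dtype=float)
    if np.isnan(cal).any():
        raise ValueError("records are not calibrated")
    return np.column_stack([X, cal])


def _features_raw_mi(records: Sequence[PatientRecord]) -> np.ndarray:
    X = build_features(records)
    return np.column_stack([X, [float(int(r.preop_mi)) for r in records]])


def _pooled_result(
    method: str,
    target: RiskGroup,
    variant: Optional[str],
    per_fold: list[TwoByTwo],
    scores: np.ndarray,
    labels: np.ndarray,
    preds: np.ndarray,
    seed: int,
    config: NPMConfig,
) -> EvaluationResult:
    from sklearn.metrics import roc_auc_score

    pooled = TwoByTwo(
        tp=int(((preds == 1) & (labels == 1)).sum()),
        fp=int(((preds == 1) & (labels == 0)).sum()),
        fn=int(((preds == 0) & (labels == 1)).sum()),
        tn=int(((preds == 0) & (labels == 0)).sum()),
    )
    prof = diagnostic_profile(pooled)
    if labels.min() == labels.max():
        auc, ci = None, None
    else:
        auc = float(roc_auc_score(labels, scores))
        ci = auc_ci(scores, labels, B=config.bootstrap_b, seed=derive_seed(seed, 999))
    # Replace the binary-predictor AUC with the rank AUC of the scores.
    profile = DiagnosticProfile(
        npv=prof.npv, ppv=prof.ppv, sensitivity=prof.sensitivity,
        specificity=prof.specificity, auc=auc,
    )
    return EvaluationResult(
        method=method,
        target=target,
        variant=variant,
        per_fold=per_fold,
        pooled=pooled,
        profile=profile,
        auc=auc,
        auc_ci=ci,
        scores=scores,
        labels=labels,
        seed=seed,
        config=config,
    )


def run_npm(
    cohort: Sequence[PatientRecord],
    target: RiskGroup,
    variant: str = "NPM2",
    config: Optional[NPMConfig] = None,
    seed: int = 0,
) -> EvaluationResult:
    """Leakage-free outer evaluation of one NPM variant on one target.

    Per outer fold, the tumor-size strata, the depth calibrator and every
    weak classifier are fitted on the training side only; the held-out side
    is calibrated with the frozen model (size strata keyed on the
    preoperative category) and scored by the selected ensemble.  Test
    predictions are pooled over folds into a single 2x2 table and a rank
    AUC with a percentile bootstrap CI.
    """
    config = config or NPMConfig()
    cohort = list(cohort)
    y = _labels(cohort, target)
    folds = outer_split(cohort, target, k=config.outer_k, seed=derive_seed(seed, 1))

    scores = np.empty(len(cohort))
    preds = np.empty(len(cohort), dtype=int)
    per_fold: list[TwoByTwo] = []
    for f, (tr, te) in enumerate(folds):
        train = [cohort[i] for i in tr]
        test = [cohort[i] for i in te]
        strata = fit_size_strata(train)
        calibrator = fit_mi_calibrator(train, variant, size_strata=strata)
        train_c = calibrate_mi(train, calibrator, size_key="postop_mi")
        test_c = calibrate_mi(test, calibrator, size_key="preop_mi")
        X_train = _features_calibrated(train_c)
        X_test = _features_calibrated(test_c)

        subs = build_subdatasets(y[tr], seed=derive_seed(seed, 2, f))
        groups = [
            train_weak_classifiers(
                X_train,
                y[tr],
                sub,
                inner_k=config.inner_k,
                learner=config.learner,
                seed=derive_seed(seed, 3, f, sub.index),
            )
            for sub in subs
        ]
        ensemble = select_models(
            groups, top_m=config.top_m, combine=config.combine, threshold=config.threshold
        )
        p = ensemble.predict_proba(X_test)
        scores[te] = p
        preds[te] = (p >= config.threshold).astype(int)
        _, fold_counts = selection_score(y[te], preds[te])
        per_fold.append(fold_counts)

    return _pooled_result(
        f"npm_{variant.lower()}", target, variant, per_fold, scores, y, preds, seed, config
    )


def _baseline_model(algo: str, seed: int):
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if algo == "logistic":
        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    if algo == "boosted_trees":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100,
            max_depth=3,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    if algo == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf"))
    raise ValueError(f"unknown baseline {algo!r}")


def run_baseline(
    cohort: Sequence[PatientRecord],
    target: RiskGroup,
    algo: str = "logistic",
    config: Optional[NPMConfig] = None,
    seed: int = 0,
) -> EvaluationResult:
    """Comparison classifier on the same outer folds and preprocessing as
    the NPMs, but with the raw preoperative invasion code as a feature and
    a single model per fold on the imbalanced training data.  SVM decision
    values serve as ranking scores."""
    config = config or NPMConfig()
    cohort = list(cohort)
    y = _labels(cohort, target)
    folds = outer_split(cohort, target, k=config.outer_k, seed=derive_seed(seed, 1))

    scores = np.empty(len(cohort))
    preds = np.empty(len(cohort), dtype=int)
    per_fold: list[TwoByTwo] = []
    for f, (tr, te) in enumerate(folds):
        train = [cohort[i] for i in tr]
        test = [cohort[i] for i in te]
        strata = fit_size_strata(train)
        train_i = impute_tumor_size(train, strata, key_on="postop_mi")
        test_i = impute_tumor_size(test, strata, key_on="preop_mi")
        X_train = _features_raw_mi(train_i)
        X_test = _features_raw_mi(test_i)

        model = _baseline_model(algo, derive_seed(seed, 4, f))
        model.fit(X_train, y[tr])
        if hasattr(model, "predict_proba"):
            s = model.predict_proba(X_test)[:, 1]
            p = (s >= config.threshold).astype(int)
        else:  # SVM: decision values rank, sign classifies
            s = model.decision_function(X_test)
            p = model.predict(X_test).astype(int)
        scores[te] = s
        preds[te] = p
        _, fold_counts = selection_score(y[te], preds[te])
        per_fold.append(fold_counts)

    return _pooled_result(algo, target, None, per_fold, scores, y, preds, seed, config)


BASELINES = ("logistic", "boosted_trees", "svm")


def evaluate_methods(
    cohort: Sequence[PatientRecord],
    targets: Sequence[RiskGroup] = tuple(RiskGroup),
    methods: Sequence[str] = ("logistic", "boosted_trees", "svm", "npm1", "npm2"),
    config: Optional[NPMConfig] = None,
    seed: int = 0,
) -> dict[RiskGroup, dict[str, EvaluationResult]]:
    """Run every requested method on every target group."""
    config = config or NPMConfig()
    out: dict[RiskGroup, dict[str, EvaluationResult]] = {}
    for target in targets:
        out[target] = {}
        for method in methods:
            if method in ("npm1", "npm2"):
                res = run_npm(cohort, target, method.upper(), config=config, seed=seed)
            else:
                res = run_baseline(cohort, target, method, config=config, seed=seed)
            out[target][method] = res
    return out
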