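"""Tumor-size imputation and the chained-equation depth calibrator."""

from dataclasses import replace

import numpy as np
import pytest

from lowriskec.calibration import (
    DEFAULT_SIZE_BY_MI,
    ChainedEquationImputer,
    build_features,
    calibrate_mi,
    cross_fitted_calibration,
    fit_mi_calibrator,
    fit_size_strata,
    impute_tumor_size,
    mi_mse,
)
from lowriskec.cohort import (
    BiopsyMethod,
    Grade,
    MICategory,
    PatientRecord,
    RiskGroup,
    Stage,
    SurgeryMethod,
    make_pseudo_record,
)
from lowriskec.synthetic import CohortSpec, generate_cohort


def _rec(i, *, ca125=19.0, preop_size=2.0, postop_size=2.0, postop_mi=MICategory.NONE,
         age=52.0, grade=Grade.G1, method=BiopsyMethod.D_AND_C, preop_mi=MICategory.NONE,
         menopause=False):
    stage = Stage.IB if postop_mi == MICategory.GE_HALF else Stage.IA
    return PatientRecord(
        id=f"c{i}", age=age, menopause=menopause, biopsy_method=method,
        preop_grade=grade, preop_mi=preop_mi, preop_tumor_size_cm=preop_size,
        ca125=ca125, surgery_method=SurgeryMethod.MIS, postop_mi=postop_mi,
        postop_grade=grade, postop_stage=stage, postop_tumor_size_cm=postop_size,
        lvsi=False, histology_endometrioid=True, pelvic_node_met=False,
    )


# ---------------------------------------------------------------------------
# Tumor-size imputation
# ---------------------------------------------------------------------------

def test_impute_with_study_defaults_and_noop_on_observed():
    missing = _rec(0, preop_size=None, postop_mi=MICategory.NONE)
    observed = _rec(1, preop_size=3.0)
    out = impute_tumor_size([missing, observed], DEFAULT_SIZE_BY_MI)
    assert out[0].preop_tumor_size_cm == 1.41
    assert out[1].preop_tumor_size_cm == 3.0


def test_impute_uses_training_stratum_means():
    train = [_rec(0, postop_size=1.0), _rec(1, postop_size=2.0),
             _rec(2, postop_size=5.0, postop_mi=MICategory.LT_HALF)]
    strata = fit_size_strata(train)
    assert strata == {0: 1.5, 1: 5.0}
    out = impute_tumor_size([_rec(3, preop_size=None)], strata)
    assert out[0].preop_tumor_size_cm == 1.5


def test_impute_missing_stratum_raises_and_preop_key():
    with pytest.raises(KeyError):
        impute_tumor_size([_rec(0, preop_size=None, postop_mi=MICategory.LT_HALF)], {0: 1.5})
    out = impute_tumor_size(
        [_rec(0, preop_size=None, postop_mi=MICategory.LT_HALF)], {0: 1.5, 1: 9.9},
        key_on="preop_mi",
    )
    assert out[0].preop_tumor_size_cm == 1.5  # keyed on the preoperative category
    assert all(r.preop_tumor_size_cm is not None for r in out)


# ---------------------------------------------------------------------------
# Chained-equation imputer
# ---------------------------------------------------------------------------

def test_single_missing_column_reduces_to_least_squares():
    """With one incomplete column the chained-equation fit must equal the
    ordinary least-squares regression of that column on the others."""
    rng = np.random.default_rng(0)
    for trial in range(20):
        n, p = rng.integers(15, 40), rng.integers(2, 5)
        X = rng.normal(size=(n, p))
        miss = rng.random(n) < 0.3
        if miss.all() or (~miss).sum() <= p:
            continue
        Xm = X.copy()
        Xm[miss, -1] = np.nan
        imp = ChainedEquationImputer().fit(Xm)
        filled = imp.transform(Xm)
        A = np.column_stack([np.ones((~miss).sum()), X[~miss, :-1]])
        beta, *_ = np.linalg.lstsq(A, X[~miss, -1], rcond=None)
        expected = np.column_stack([np.ones(miss.sum()), X[miss, :-1]]) @ beta
        np.testing.assert_allclose(filled[miss, -1], expected, atol=1e-10)


def test_chained_imputer_matches_sklearn_iterative_imputer():
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    from sklearn.linear_model import LinearRegression

    rng = np.random.default_rng(1)
    X = rng.normal(size=(60, 4))
    Xm = X.copy()
    Xm[rng.random(60) < 0.25, 2] = np.nan
    ours = ChainedEquationImputer().fit(Xm).transform(Xm)
    theirs = IterativeImputer(estimator=LinearRegression(), max_iter=10).fit_transform(Xm)
    np.testing.assert_allclose(ours, theirs, atol=1e-8)


def test_two_point_closed_form_line():
    M = np.array([[0.0, 1.0], [2.0, 5.0], [1.0, np.nan]])
    imp = ChainedEquationImputer().fit(M)
    coef, intercept = imp.models_[1]
    assert coef[0] == pytest.approx(2.0)
    assert intercept == pytest.approx(1.0)
    assert imp.transform(M)[2, 1] == pytest.approx(3.0)


def test_rank_deficient_design_falls_back_to_ridge(caplog):
    M = np.column_stack([np.ones(10), np.ones(10), np.arange(10.0)])
    M[5:, 2] = np.nan
    with caplog.at_level("WARNING"):
        ChainedEquationImputer().fit(M)
    assert any("rank-deficient" in m for m in caplog.messages)


# ---------------------------------------------------------------------------
# Depth calibration
# ---------------------------------------------------------------------------

def _varied_cohort(n, seed=0):
    return generate_cohort(CohortSpec(n=n, seed=seed), mode="sample")


def test_perfect_concordance_limit():
    """If final pathology always confirms the MRI category, the NPM1
    calibrator reproduces the codes exactly and the error is zero."""
    base = _varied_cohort(300, seed=2)
    perfect = [
        replace(r, postop_mi=r.preop_mi, postop_stage=Stage.IA,
                postop_grade=r.preop_grade)
        for r in base
    ]
    model = fit_mi_calibrator(perfect, "NPM1")
    cal = calibrate_mi(perfect, model, size_key="postop_mi")
    values = np.array([r.calibrated_mi for r in cal])
    codes = np.array([int(r.postop_mi) for r in perfect])
    np.testing.assert_allclose(values, codes, atol=1e-8)
    assert mi_mse(values, codes) == pytest.approx(0.0, abs=1e-12)


def test_npm2_has_no_preop_mi_predictor():
    cohort = _varied_cohort(300, seed=3)
    m1 = fit_mi_calibrator(cohort, "NPM1")
    m2 = fit_mi_calibrator(cohort, "NPM2")
    assert "preop_mi" in m1.feature_names
    assert "preop_mi" not in m2.feature_names
    assert len(m1.coef) == len(m2.coef) + 1


def test_calibration_clips_and_is_idempotent():
    cohort = _varied_cohort(200, seed=4)
    model = fit_mi_calibrator(cohort[:150], "NPM2")
    out1 = calibrate_mi(cohort[150:], model)
    out2 = calibrate_mi(out1, model)
    v1 = [r.calibrated_mi for r in out1]
    assert all(0.0 <= v <= 2.0 for v in v1)
    assert v1 == [r.calibrated_mi for r in out2]
    # original categories retained alongside
    assert [r.preop_mi for r in out1] == [r.preop_mi for r in cohort[150:]]


def test_npm1_concentrates_on_preop_codes_npm2_smooth():
    """NPM1's calibrated depths split into clusters at the two preoperative
    levels; NPM2's vary smoothly, so the preoperative category explains far
    less of their variance."""
    cohort = _varied_cohort(2000, seed=5)
    pre = np.array([int(r.preop_mi) for r in cohort])

    def between_share(variant):
        model = fit_mi_calibrator(cohort, variant)
        v = np.array([r.calibrated_mi for r in calibrate_mi(cohort, model, size_key="postop_mi")])
        within = np.mean([v[pre == c].var() for c in (0, 1)])
        return 1 - within / v.var()

    assert between_share("NPM1") > between_share("NPM2") + 0.1


def test_npm2_recovers_linear_trend_in_ca125():
    """When the postoperative depth follows a linear trend in CA125, the
    NPM2 calibrated values recover it (R^2 > 0.9 against the trend)."""
    rng = np.random.default_rng(6)
    recs = []
    for i in range(2000):
        ca = float(np.clip(rng.gamma(3.6, 5.3), 1.0, 34.9))
        p = np.clip(0.05 + 0.025 * ca, 0.0, 1.0)
        code = int(rng.random() < p) + int(rng.random() < max(0.0, p - 0.5))
        recs.append(_rec(i, ca125=ca, postop_mi=MICategory(min(code, 2)),
                         age=float(rng.normal(52, 9)),
                         menopause=bool(rng.integers(2)),
                         grade=Grade.G1 if rng.random() < 0.7 else Grade.G2,
                         method=list(BiopsyMethod)[rng.integers(3)],
                         preop_size=float(rng.lognormal(0.7, 0.4)),
                         postop_size=float(rng.lognormal(0.7, 0.4))))
    model = fit_mi_calibrator(recs, "NPM2")
    cal = np.array([r.calibrated_mi for r in calibrate_mi(recs, model, size_key="postop_mi")])
    ca = np.array([r.ca125 for r in recs])
    trend = np.polyval(np.polyfit(ca, cal, 1), ca)
    ss_res = ((cal - trend) ** 2).sum()
    ss_tot = ((cal - cal.mean()) ** 2).sum()
    assert 1 - ss_res / ss_tot > 0.9


def test_mi_mse_arithmetic_and_errors():
    assert mi_mse([0, 1, 2], [0, 1, 2]) == 0.0
    assert mi_mse([0, 1, 1], [0, 1, 2]) == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        mi_mse([], [])
    with pytest.raises(ValueError):
        mi_mse([1.0], [1, 2])


def test_cross_fitted_calibration_is_out_of_sample():
    cohort = _varied_cohort(400, seed=7)
    values, mse = cross_fitted_calibration(cohort, "NPM2", seed=1)
    assert values.shape == (400,)
    assert np.isfinite(mse) and mse > 0
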