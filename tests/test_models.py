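"""BA model zoo, stacking data-flow, overfit contrast, importance, metrics."""

import numpy as np
import pandas as pd
import pytest

from bioagestack.metrics import pearson_ci, regression_metrics
from bioagestack.models import (
    BaseModelSpec,
    BoostedBioAge,
    OverfitSearchError,
    SplitSpec,
    StackedBioAge,
    StackingSpec,
    aggregate_importance,
    audit_no_leakage,
    ba_range_expansion,
    default_base_specs,
    fit_base_models,
    make_base_model,
    _SplineAdditiveRegressor,
)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_metrics_match_brute_force_reference():
    """RMSE/MAE/R²/r recomputed with explicit loops agree to 1e-9."""
    rng = np.random.default_rng(0)
    y = rng.normal(60, 8, 20)
    yhat = y + rng.normal(0, 3, 20)
    m = regression_metrics(y, yhat, "t", "test")
    n = len(y)
    mae = sum(abs(a - b) for a, b in zip(yhat, y)) / n
    rmse = (sum((a - b) ** 2 for a, b in zip(yhat, y)) / n) ** 0.5
    ybar = sum(y) / n
    r2 = 1 - sum((a - b) ** 2 for a, b in zip(yhat, y)) / sum((v - ybar) ** 2 for v in y)
    sx = (sum((v - ybar) ** 2 for v in y) / n) ** 0.5
    phat = sum(yhat) / n
    sy = (sum((v - phat) ** 2 for v in yhat) / n) ** 0.5
    r = sum((a - ybar) * (b - phat) for a, b in zip(y, yhat)) / (n * sx * sy)
    assert m.mae == pytest.approx(mae, abs=1e-9)
    assert m.rmse == pytest.approx(rmse, abs=1e-9)
    assert m.r2 == pytest.approx(r2, abs=1e-9)
    assert m.pearson_r == pytest.approx(r, abs=1e-9)
    assert m.rmse >= m.mae
    assert m.r_ci_low <= m.pearson_r <= m.r_ci_high


def test_pearson_ci_shrinks_with_n():
    lo1, hi1 = pearson_ci(0.6, 100)
    lo2, hi2 = pearson_ci(0.6, 10_000)
    assert lo1 < 0.6 < hi1
    assert (hi2 - lo2) < (hi1 - lo1)
    # width scales roughly as 1/sqrt(n) on the z scale
    assert (hi1 - lo1) / (hi2 - lo2) == pytest.approx(10, rel=0.15)


def test_constant_target_is_degenerate_not_fatal():
    y = np.full(30, 65.0)
    m = regression_metrics(y, y, "t", "train")
    assert m.rmse == 0.0
    assert np.isnan(m.pearson_r)


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

def _identity_data(n=300, seed=0):
    """Cohort-like frame whose single feature IS chronological age."""
    rng = np.random.default_rng(seed)
    ca = rng.uniform(45, 90, n)
    return pd.DataFrame({"participant_id": np.arange(n),
                         "chronological_age": ca, "oracle_feature": ca})


def test_perfect_base_model_reproduces_age():
    """A linear base model on a feature equal to CA, fused by a linear
    meta-model, returns BA == CA with zero error in both partitions."""
    data = _identity_data()
    stk = StackedBioAge(
        data, features=["oracle_feature"],
        stacking=StackingSpec(base_models=(BaseModelSpec("mlr"),),
                              meta_family="linear"),
        split=SplitSpec(stacking_folds=5, seed=1))
    res = stk.fit()
    assert res.metrics["train"].rmse == pytest.approx(0.0, abs=1e-8)
    assert res.metrics["test"].rmse == pytest.approx(0.0, abs=1e-8)
    np.testing.assert_allclose(res.ba, data["chronological_age"], atol=1e-8)


def test_constant_base_model_propagates_to_level2():
    """A base model fitted on a constant feature predicts the fold-training
    mean everywhere, so the level-2 feature column is (nearly) constant."""
    data = _identity_data(seed=2)
    data["flat"] = 1.0
    stk = StackedBioAge(
        data, features=["flat"],
        stacking=StackingSpec(base_models=(BaseModelSpec("mlr"),),
                              meta_family="linear"),
        split=SplitSpec(stacking_folds=5, seed=1))
    res = stk.fit()
    # fold means differ only by resampling noise of the response
    assert res.level2_train.std() < 1.0
    assert res.level2_test.std() < 1e-8  # mean of fold predictions, constant input


def test_no_leakage_audit_passes_and_is_exhaustive(mid_cohort):
    stk = StackedBioAge(mid_cohort.iloc[:800],
                        split=SplitSpec(stacking_folds=5, seed=3))
    res = stk.fit()
    audit = audit_no_leakage(res)
    assert len(audit) == len(res.train_idx)
    assert not audit["leaked"].any()
    assert set(audit["source_fold"]) == set(range(5))


def test_audit_detects_planted_leak(mid_cohort):
    stk = StackedBioAge(mid_cohort.iloc[:600],
                        split=SplitSpec(stacking_folds=4, seed=3))
    res = stk.fit()
    # corrupt the provenance: claim a row was predicted by a fold that
    # trained on it
    victim = res.train_idx[0]
    for f, rows in res.fold_train_rows.items():
        if victim in rows:
            res.oof_source_fold[victim] = f
            break
    with pytest.raises(AssertionError, match="trained on it"):
        audit_no_leakage(res)


def test_extra_trees_shows_the_overfit_signature(mid_cohort):
    """Unbounded extremely-randomized trees memorize the training set
    (train r ~ 1) while test r stays materially lower."""
    data = mid_cohort.iloc[:1200]
    split = SplitSpec(seed=5)
    tr_mask, te_idx = split.split(len(data))
    fitted, metrics = fit_base_models(
        data[tr_mask], data.iloc[te_idx],
        [BaseModelSpec("extra_trees", params={"n_estimators": 50}),
         BaseModelSpec("mlr")], seed=5)
    et = metrics[metrics["model_tag"] == "extra_trees"].set_index("partition")
    assert et.loc["train", "pearson_r"] > 0.999
    assert et.loc["train", "pearson_r"] > et.loc["test", "pearson_r"] + 0.1
    # ranking: rows come ordered by test pearson r
    test_rows = metrics[metrics["partition"] == "test"]
    rs = test_rows["pearson_r"].to_numpy()
    assert (np.diff(rs) <= 1e-12).all()


def test_nan_design_is_rejected(mid_cohort):
    data = mid_cohort.iloc[:100].copy()
    data.loc[data.index[0], "sbp"] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        StackedBioAge(data)


def test_spline_meta_is_safe_outside_training_range():
    rng = np.random.default_rng(7)
    X = rng.uniform(50, 80, size=(300, 2))
    y = X.sum(axis=1) + rng.normal(0, 2, 300)
    gam = _SplineAdditiveRegressor().fit(X, y)
    wild = np.array([[0.0, 200.0], [55.0, 60.0]])
    pred = gam.predict(wild)
    assert np.isfinite(pred).all()
    # clipped evaluation equals the prediction at the clipped point
    assert pred[0] == pytest.approx(
        gam.predict(np.array([[50.0, 80.0]]))[0], abs=1e-9)


# ---------------------------------------------------------------------------
# boosted contrast
# ---------------------------------------------------------------------------

def test_overfit_search_reports_failure_with_log(mid_cohort):
    """A grid that cannot amplify the training fit raises, carrying the
    search log rather than silently accepting a config."""
    data = mid_cohort.iloc[:600]
    model = BoostedBioAge(
        data, mode="overfit", split=SplitSpec(seed=1),
        overfit_grid=[{"n_estimators": 5, "max_depth": 1, "learning_rate": 0.01}])
    with pytest.raises(OverfitSearchError) as exc:
        model.fit()
    assert len(exc.value.log) == 1
    assert not exc.value.log["accepted"].any()


def test_moderate_mode_trains_on_train_predicts_full(mid_cohort):
    data = mid_cohort.iloc[:800]
    res = BoostedBioAge(data, mode="moderate", split=SplitSpec(seed=2)).fit()
    assert res.tag == "boost_moderate"
    assert len(res.predictions) == len(data)
    assert set(res.predictions["partition"]) == {"train", "test"}
    assert res.metrics["train"].pearson_r > res.metrics["test"].pearson_r


# ---------------------------------------------------------------------------
# importance aggregation and range bookkeeping
# ---------------------------------------------------------------------------

def test_importance_aggregation_properties():
    feats = ["a", "b", "c"]
    w = np.array([0.5, 0.3, 0.2])
    table = aggregate_importance({"m1": w, "m2": w}, feats)
    np.testing.assert_allclose(table["aggregate"], sorted(w, reverse=True))
    np.testing.assert_allclose(table["m1"].sum(), 1.0)
    # permuting features permutes the table identically
    perm = aggregate_importance({"m1": w[::-1], "m2": w[::-1]}, feats[::-1])
    pd.testing.assert_frame_equal(
        table.sort_values("feature").reset_index(drop=True),
        perm.sort_values("feature").reset_index(drop=True))
    with pytest.raises(ValueError, match="all-zero"):
        aggregate_importance({"m": np.zeros(3)}, feats)
    with pytest.raises(ValueError, match="nonnegative"):
        aggregate_importance({"m": np.array([0.5, -0.1, 0.6])}, feats)


def test_single_signal_feature_ranks_first():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(500, 4))
    y = 3 * X[:, 2] + rng.normal(0, 0.1, 500)
    model = make_base_model(BaseModelSpec("xgb", params={"n_estimators": 50}), 0)
    model.fit(X, y)
    from bioagestack.models import _model_importance
    imp = _model_importance(model, X, y)
    table = aggregate_importance({"xgb": imp}, ["f0", "f1", "f2", "f3"])
    assert table["feature"].iloc[0] == "f2"


@pytest.mark.parametrize("stk, other, expected", [
    ((43.59, 88.57), (35.37, 99.66), 42.9),   # printed summary endpoints
    ((0.0, 10.0), (0.0, 10.0), 0.0),
    ((0.0, 10.0), (0.0, 20.0), 100.0),
])
def test_ba_range_expansion(stk, other, expected):
    got = ba_range_expansion(np.array(stk), np.array(other))
    assert got == pytest.approx(expected, abs=0.05)


def test_ba_range_expansion_zero_reference():
    with pytest.raises(ValueError):
        ba_range_expansion(np.array([1.0, 1.0]), np.array([0.0, 2.0]))


def test_default_specs_cover_five_families():
    specs = default_base_specs()
    assert len(specs) == 5
    assert len({s.name for s in specs}) == 5
    for s in specs:
        make_base_model(s, 0)  # constructible
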