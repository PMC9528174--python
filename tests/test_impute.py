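"""Imputer semantics and masked-entry scoring."""

import numpy as np
import pandas as pd
import pytest

from bioagestack.benchmark import score_imputation
from bioagestack.impute import (
    IMPUTER_METHODS,
    ImputerConfig,
    MaskedAutoencoder,
    StandardizationStats,
    impute,
)

FAST = {"epochs": 20, "m": 2, "iterations": 3}


def _fast_config(method, **kw):
    base = {k: v for k, v in FAST.items()}
    base.update(kw)
    return ImputerConfig(method, **base)


@pytest.fixture(scope="module")
def stats_small(gapped_small_module):
    table, mask, truth = gapped_small_module
    return StandardizationStats.from_table(truth, list(mask.columns))


@pytest.fixture(scope="module")
def gapped_small_module():
    from bioagestack.cohort import (MissingnessProfile, default_cohort_spec,
                                    drop_oracle_columns, generate_cohort,
                                    inject_missing)
    truth = drop_oracle_columns(generate_cohort(default_cohort_spec(400, seed=7)))
    gapped, mask = inject_missing(
        truth, MissingnessProfile("MCAR", global_rate=0.10), seed=3)
    return gapped, mask, truth


@pytest.mark.parametrize("method", IMPUTER_METHODS)
def test_no_gaps_is_identity(method, gapped_small_module, stats_small):
    """With an all-false mask every method returns the input unchanged."""
    _, mask, truth = gapped_small_module
    empty_mask = mask & False
    out = impute(truth, empty_mask, _fast_config(method), stats_small)
    pd.testing.assert_frame_equal(out, truth, check_dtype=False)


@pytest.mark.parametrize("method", IMPUTER_METHODS)
def test_observed_cells_preserved_and_gaps_filled(method, gapped_small_module,
                                                  stats_small):
    gapped, mask, truth = gapped_small_module
    out = impute(gapped, mask, _fast_config(method), stats_small)
    cols = list(mask.columns)
    assert not out[cols].isna().any().any()
    obs = ~mask.to_numpy()
    np.testing.assert_array_equal(
        out[cols].to_numpy()[obs], truth[cols].to_numpy()[obs])


@pytest.mark.parametrize("method", IMPUTER_METHODS)
def test_binary_fills_are_binary(method, gapped_small_module, stats_small):
    gapped, mask, truth = gapped_small_module
    out = impute(gapped, mask, _fast_config(method), stats_small)
    for c in ("urine_protein", "urine_sugar"):
        assert set(np.unique(out[c])) <= {0.0, 1.0}


def test_binary_threshold_is_strict_at_half():
    """A predicted value of exactly 0.5 maps to 0 (only values above 0.5
    become 1)."""
    n = 40
    table = pd.DataFrame({
        "x": np.linspace(-1, 1, n),
        "urine_protein": np.array([0.0, 1.0] * (n // 2)),  # mean exactly 0.5
    })
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    mask.iloc[0, 1] = True
    gapped = table.copy()
    gapped.iloc[0, 1] = np.nan
    stats = StandardizationStats.from_table(table, ["x", "urine_protein"])
    out = impute(gapped, mask, ImputerConfig("mean"), stats)
    assert out.iloc[0, 1] == 0.0


def test_round_robin_recovers_collinear_column():
    """y = 2x exactly: round-robin regression reconstructs masked y from x;
    the un-damped fit matches the closed-form regression on complete rows."""
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 300)
    table = pd.DataFrame({"x": x, "y": 2 * x})
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    mask.iloc[:30, 1] = True
    gapped = table.copy()
    gapped.loc[mask["y"], "y"] = np.nan
    stats = StandardizationStats.from_table(table, ["x", "y"])
    # oracle: slope from complete rows is exactly 2
    comp = table.iloc[30:]
    slope = np.polyfit(comp["x"], comp["y"], 1)[0]
    assert abs(slope - 2.0) < 1e-10
    out = impute(gapped, mask, ImputerConfig("round_robin_regression",
                                             ridge_alpha=1e-8), stats)
    np.testing.assert_allclose(out.loc[mask["y"], "y"],
                               2 * x[:30], atol=1e-3)
    # the default (damped) configuration is close but softly shrunk
    out_damped = impute(gapped, mask, ImputerConfig("round_robin_regression"),
                        stats)
    assert np.abs(out_damped.loc[mask["y"], "y"] - 2 * x[:30]).max() < 0.5


def test_fully_missing_column_rejected():
    table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [np.nan] * 3})
    mask = pd.DataFrame({"a": [False] * 3, "b": [True] * 3})
    stats = StandardizationStats(mean=pd.Series({"a": 2.0, "b": 0.0}),
                                 var=pd.Series({"a": 1.0, "b": 1.0}))
    with pytest.raises(ValueError, match="entirely missing"):
        impute(table, mask, ImputerConfig("mean"), stats)


class TestScoring:
    def _setup(self):
        truth = pd.DataFrame({"a": [1.0, 0.0, -1.0, 5.0]})
        mask = pd.DataFrame({"a": [True, True, True, False]})
        stats = StandardizationStats(mean=pd.Series({"a": 0.0}),
                                     var=pd.Series({"a": 1.0}))
        return truth, mask, stats

    def test_perfect_imputation(self):
        truth, mask, stats = self._setup()
        mse, r2 = score_imputation(truth, truth, mask, stats)
        assert mse == 0.0
        assert r2 == 1.0

    def test_masked_mean_prediction_gives_zero_r2(self):
        truth, mask, stats = self._setup()
        completed = truth.copy()
        completed.loc[mask["a"], "a"] = truth.loc[mask["a"], "a"].mean()
        mse, r2 = score_imputation(completed, truth, mask, stats)
        assert abs(r2) < 1e-12

    def test_hand_computed_mse(self):
        """truth (1, 0, -1) imputed as (0, 0, 0): MSE = (1+0+1)/3 = 2/3."""
        truth, mask, stats = self._setup()
        completed = truth.copy()
        completed.loc[mask["a"], "a"] = 0.0
        mse, r2 = score_imputation(completed, truth, mask, stats)
        assert abs(mse - 2.0 / 3.0) < 1e-12

    def test_empty_mask_is_an_error(self):
        truth, mask, stats = self._setup()
        with pytest.raises(ValueError, match="empty"):
            score_imputation(truth, truth, mask & False, stats)


def test_chained_multiple_averaging_stabilizes_with_m():
    """Averaging m stochastic completions: the across-seed variance of the
    combined imputation shrinks as m grows."""
    rng = np.random.default_rng(1)
    z = rng.multivariate_normal([0, 0, 0], [[1, .6, .6], [.6, 1, .6], [.6, .6, 1]], 250)
    truth = pd.DataFrame(z, columns=["a", "b", "c"])
    mask = pd.DataFrame(False, index=truth.index, columns=truth.columns)
    mask.iloc[:40, 0] = True
    gapped = truth.copy()
    gapped.loc[mask["a"], "a"] = np.nan
    stats = StandardizationStats.from_table(truth)
    spread = {}
    for m in (2, 10):
        draws = [impute(gapped, mask, ImputerConfig(
            "chained_multiple", m=m, iterations=3, seed=s), stats)
            .loc[mask["a"], "a"].to_numpy() for s in range(5)]
        spread[m] = np.stack(draws).std(axis=0).mean()
    assert spread[10] < spread[2]


def test_autoencoder_learns_correlated_structure():
    """On a strongly correlated Gaussian block the denoising AE beats the
    column-mean fill on masked cells."""
    rng = np.random.default_rng(2)
    p, rho = 6, 0.7
    cov = np.full((p, p), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(p), cov, 600)
    truth = pd.DataFrame(z, columns=[f"v{i}" for i in range(p)])
    mask = pd.DataFrame(rng.random(z.shape) < 0.15,
                        index=truth.index, columns=truth.columns)
    gapped = truth.where(~mask)
    stats = StandardizationStats.from_table(truth)
    ae_out = impute(gapped, mask, ImputerConfig("autoencoder", epochs=60, seed=0),
                    stats)
    mean_out = impute(gapped, mask, ImputerConfig("mean"), stats)
    ae_mse, _ = score_imputation(ae_out, truth, mask, stats)
    mean_mse, _ = score_imputation(mean_out, truth, mask, stats)
    assert ae_mse < mean_mse


def test_autoencoder_training_is_seeded():
    rng = np.random.default_rng(3)
    z = rng.normal(size=(100, 5))
    obs = rng.random((100, 5)) > 0.1
    rec = []
    for _ in range(2):
        ae = MaskedAutoencoder(5, (4, 2), seed=12)
        ae.fit(np.where(obs, z, 0.0), obs, epochs=5)
        rec.append(ae.reconstruct(np.where(obs, z, 0.0)))
    np.testing.assert_array_equal(rec[0], rec[1])


def test_config_validation():
    with pytest.raises(ValueError):
        ImputerConfig("nope")
    with pytest.raises(ValueError):
        ImputerConfig("knn", k=0)
    with pytest.raises(ValueError):
        ImputerConfig("chained_multiple", m=1)
    with pytest.raises(ValueError):
        ImputerConfig("round_robin_regression", tol=0.0)
    with pytest.raises(ValueError):
        StandardizationStats(mean=pd.Series({"a": 0.0}), var=pd.Series({"a": 0.0}))
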