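"""Split protocol, accuracy metrics, and the six-algorithm regression matrix."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from canagb.errors import (
    InsufficientDataError,
    InvalidArgumentError,
    SchemaError,
)
from canagb.estimation import (
    ALGORITHMS,
    EvalResult,
    ModelSpec,
    SplitSpec,
    evaluate,
    fit_predict,
    make_model,
    run_matrix,
    split,
)
from canagb.selection import FeatureScheme


def _table(n, n_features, rng, stages=("a", "b", "c", "d"), response=None):
    data = {f"x{k}": rng.uniform(size=n) for k in range(n_features)}
    data["stage"] = [stages[i % len(stages)] for i in range(n)]
    data["agb"] = response if response is not None else rng.uniform(500, 12000, n)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n, n_train", [(180, 126), (10, 7), (100, 70)])
def test_split_partition_sizes(rng, n, n_train):
    table = _table(n, 3, rng)
    train, val = split(table, SplitSpec(seed=5))
    assert len(train) == n_train and len(val) == n - n_train
    assert set(train.index).isdisjoint(val.index)
    assert set(train.index) | set(val.index) == set(table.index)


def test_split_is_deterministic(rng):
    table = _table(60, 3, rng)
    a1, _ = split(table, SplitSpec(seed=9))
    a2, _ = split(table, SplitSpec(seed=9))
    b, _ = split(table, SplitSpec(seed=10))
    assert list(a1.index) == list(a2.index)
    assert list(a1.index) != list(b.index)


def test_stratified_split_preserves_stage_proportions(rng):
    table = _table(180, 2, rng)
    train, _ = split(table, SplitSpec(strategy="stratified", seed=3))
    for stage, group in table.groupby("stage"):
        expected = 0.7 * len(group)
        got = (train["stage"] == stage).sum()
        assert abs(got - expected) <= 1


def test_split_rejects_tiny_tables(rng):
    with pytest.raises(InsufficientDataError):
        split(_table(9, 2, rng), SplitSpec())


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_perfect_prediction_metrics():
    r2, rmse, nrmse = evaluate([100.0, 200.0, 300.0], [100.0, 200.0, 300.0])
    assert (r2, rmse, nrmse) == (1.0, 0.0, 0.0)


def test_worked_metric_case():
    r2, rmse, nrmse = evaluate([100.0, 100.0], [90.0, 110.0])
    assert rmse == pytest.approx(10.0)
    assert nrmse == pytest.approx(10.0)
    assert np.isnan(r2)  # zero-variance observations


def test_mean_predictor_has_zero_r2(rng):
    obs = rng.uniform(0, 1, 50)
    r2, _, _ = evaluate(obs, np.full(50, obs.mean()))
    assert r2 == pytest.approx(0.0, abs=1e-12)


def test_nrmse_undefined_for_nonpositive_mean():
    _, _, nrmse = evaluate([-1.0, 1.0], [0.0, 0.0])
    assert np.isnan(nrmse)


def test_r2_invariance_under_common_affine_rescale(rng):
    obs = rng.uniform(100, 1000, 40)
    pred = obs + rng.normal(0, 50, 40)
    r2, _, _ = evaluate(obs, pred)
    r2_scaled, _, _ = evaluate(3.0 * obs + 7.0, 3.0 * pred + 7.0)
    assert r2_scaled == pytest.approx(r2)
    r2_mismatched, _, _ = evaluate(3.0 * obs, pred)
    assert r2_mismatched != pytest.approx(r2)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def test_unknown_algorithm_rejected():
    with pytest.raises(InvalidArgumentError):
        ModelSpec("DeepNet")


def test_easy_linear_problem_is_learned(rng):
    x = rng.uniform(size=200)
    table = _table(200, 1, rng, response=3000.0 + 8000.0 * x)
    table["x0"] = x
    train, val = split(table, SplitSpec(seed=1))
    scheme = FeatureScheme("spectra", ("x0",))
    result = fit_predict(train, val, ModelSpec("RF", seed=1), scheme)
    assert result.r2 > 0.95


def test_uninformative_features_score_near_zero(rng):
    """With the response independent of every feature, no algorithm can beat
    the mean predictor by much on held-out data."""
    scheme = FeatureScheme("spectra", tuple(f"x{k}" for k in range(5)))
    for seed in range(3):
        local = np.random.default_rng(seed)
        table = _table(200, 5, local)
        train, val = split(table, SplitSpec(seed=seed))
        for algorithm in ALGORITHMS:
            result = fit_predict(train, val, ModelSpec(algorithm, seed=seed), scheme)
            assert result.r2 <= 0.2, algorithm


def test_rf_predictions_are_reproducible(rng):
    table = _table(80, 4, rng)
    train, val = split(table, SplitSpec(seed=2))
    scheme = FeatureScheme("spectra", ("x0", "x1", "x2", "x3"))
    a = fit_predict(train, val, ModelSpec("RF", seed=7), scheme)
    b = fit_predict(train, val, ModelSpec("RF", seed=7), scheme)
    assert np.array_equal(a.predicted, b.predicted)


def test_validation_responses_cannot_leak(rng):
    """Permuting validation-set responses leaves trained-model predictions
    bit-identical (hash comparison)."""
    table = _table(80, 4, rng)
    train, val = split(table, SplitSpec(seed=4))
    scheme = FeatureScheme("spectra", ("x0", "x1", "x2", "x3"))
    result = fit_predict(train, val, ModelSpec("GBRT", seed=4), scheme)
    shuffled = val.copy()
    shuffled["agb"] = np.random.default_rng(0).permutation(shuffled["agb"].to_numpy())
    result2 = fit_predict(train, shuffled, ModelSpec("GBRT", seed=4), scheme)
    digest = lambda a: hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()
    assert digest(result.predicted) == digest(result2.predicted)


def test_missing_scheme_column_raises(rng):
    table = _table(40, 2, rng)
    train, val = split(table, SplitSpec(seed=0))
    with pytest.raises(SchemaError):
        fit_predict(train, val, ModelSpec("RF"), FeatureScheme("s", ("ghost",)))


def test_degenerate_response_raises(rng):
    table = _table(40, 2, rng, response=np.full(40, 5000.0))
    train, val = split(table, SplitSpec(seed=0))
    with pytest.raises(InsufficientDataError):
        fit_predict(train, val, ModelSpec("RF"), FeatureScheme("s", ("x0",)))


def test_run_matrix_cell_count(rng):
    table = _table(120, 4, rng)
    table["agb"] = 1000 + 9000 * table["x0"] + rng.normal(0, 300, 120)
    schemes = {
        "spectra": FeatureScheme("spectra", ("x0", "x1")),
        "texture": FeatureScheme("texture", ("x2", "x3")),
        "spectra_texture": FeatureScheme("spectra_texture", ("x0", "x1", "x2", "x3")),
    }
    frame, results = run_matrix(
        table, schemes, algorithms=("RF", "SVR"), split_spec=SplitSpec(seed=1)
    )
    # 3 schemes x 2 algorithms x (4 stages + pooled)
    assert len(frame) == 3 * 2 * 5
    assert (frame["status"] == "ok").all()
    assert {r.stage for r in results} == {"pooled", "a", "b", "c", "d"}
    pooled = frame[(frame["stage"] == "pooled")]
    assert (pooled["n_train"] == 84).all() and (pooled["n_val"] == 36).all()


def test_run_matrix_records_cell_failures(rng):
    table = _table(12, 2, rng)  # stages of 3 samples each cannot split
    schemes = {"spectra": FeatureScheme("spectra", ("x0",))}
    frame, _ = run_matrix(table, schemes, algorithms=("RF",), split_spec=SplitSpec(seed=1))
    assert (frame.loc[frame["stage"] != "pooled", "status"].str.startswith("error")).all()
    assert (frame.loc[frame["stage"] == "pooled", "status"] == "ok").all()
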