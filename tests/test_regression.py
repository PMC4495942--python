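"""Regime dataset construction, regression calibrators, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from poolcal.data import ValidationError
from poolcal.regression import (
    DegenerateTrainingError,
    ModelSpec,
    RegressionCalibration,
    RegressionCalibrationResults,
    apply_calibrator,
    build_regime_datasets,
    combine_sources,
    cross_validate,
    fit_calibrator,
    make_training_pairs,
)

REGIME_CELLS = [
    (tr, te)
    for tr in ("individuals", "combined", "pools")
    for te in ("individuals", "combined", "pools")
]


def _pairs(n, source, snps=("s1", "s2"), f_star=None, prefix=None, rng=None):
    rng = rng or np.random.default_rng(5)
    prefix = prefix or source[0]
    rows = []
    for i in range(n):
        for snp in snps:
            f = rng.uniform(0, 1)
            rows.append(
                {
                    "snp_id": snp,
                    "sample_id": f"{prefix}{i:03d}",
                    "replicate_id": None,
                    "f": f,
                    "f_star": f if f_star is None else f_star,
                    "source": source,
                    "weight": 1,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def individuals():
    df = _pairs(80, "individual")
    df["f_star"] = np.round(df["f"] * 2) / 2  # truths in {0, 1/2, 1}
    return df


@pytest.fixture
def pools():
    return _pairs(10, "pool")


# ---------------------------------------------------------------------------
# combined-set balancing


def test_combined_balancing_equal_proportions():
    ind = _pairs(5, "individual", snps=("s1", "s2"))  # 10 rows
    pool = _pairs(1, "pool", snps=("s1", "s2"))       # 2 rows
    combined = combine_sources(ind, pool)
    pool_w = combined.loc[combined["source"] == "pool", "weight"]
    assert (pool_w == 5).all()
    assert pool_w.sum() == 10


def test_combined_balancing_remainder_distribution():
    # 39521 individual rows vs 901 pool rows: factors 43 and 44 only
    ind = pd.DataFrame(
        {"snp_id": "s", "sample_id": "i", "replicate_id": None,
         "f": 0.5, "f_star": 0.5, "source": "individual",
         "weight": np.ones(39521, dtype=int)}
    )
    pool = pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(901)], "sample_id": "p",
         "replicate_id": None, "f": 0.5, "f_star": 0.5, "source": "pool",
         "weight": np.ones(901, dtype=int)}
    )
    combined = combine_sources(ind, pool)
    w = combined.loc[combined["source"] == "pool", "weight"]
    assert set(w.unique()) == {43, 44}
    assert w.sum() == 39521


# ---------------------------------------------------------------------------
# regime cells


@pytest.mark.parametrize("train_regime,test_regime", REGIME_CELLS)
def test_no_leakage_in_any_cell(individuals, pools, train_regime, test_regime):
    """No (sample, SNP, replicate) triple crosses a fold boundary."""
    datasets = build_regime_datasets(
        individuals, pools, train_regime, test_regime, n_folds=10, seed=3
    )
    for ds in datasets:
        train_keys = set(
            map(tuple, ds.train_pairs[["sample_id", "snp_id", "replicate_id"]].itertuples(index=False))
        )
        test_keys = set(
            map(tuple, ds.test_pairs[["sample_id", "snp_id", "replicate_id"]].itertuples(index=False))
        )
        assert not train_keys & test_keys


@pytest.mark.parametrize("train_regime,test_regime", REGIME_CELLS)
def test_combined_sets_balanced(individuals, pools, train_regime, test_regime):
    """Pool and individual weight totals match within one replication unit."""
    datasets = build_regime_datasets(
        individuals, pools, train_regime, test_regime, n_folds=5, seed=3
    )
    for ds in datasets:
        for part in (ds.train_pairs, ds.test_pairs):
            by_source = part.groupby("source")["weight"].sum()
            n_pool_rows = (part["source"] == "pool").sum()
            if (
                set(by_source.index) == {"individual", "pool"}
                and by_source["individual"] >= n_pool_rows
            ):
                # balancing works by replicating the minority source (pools)
                max_unit = part.loc[part["source"] == "pool", "weight"].max()
                assert abs(by_source["individual"] - by_source["pool"]) <= max_unit


def test_single_fold_cells(individuals, pools):
    """(pools -> individuals) and (individuals -> pools) need no folding."""
    ds = build_regime_datasets(individuals, pools, "pools", "individuals")
    assert len(ds) == 1 and ds[0].fold_index is None
    assert len(ds[0].train_pairs) == len(pools)
    assert len(ds[0].test_pairs) == len(individuals)

    ds = build_regime_datasets(individuals, pools, "individuals", "pools")
    assert len(ds) == 1
    assert len(ds[0].train_pairs) == len(individuals)


def test_folds_partition_test_samples(individuals, pools):
    datasets = build_regime_datasets(
        individuals, pools, "individuals", "individuals", n_folds=10, seed=0
    )
    assert len(datasets) == 10
    test_samples = [set(ds.test_pairs["sample_id"]) for ds in datasets]
    union = set().union(*test_samples)
    assert union == set(individuals["sample_id"])
    for i in range(10):
        for j in range(i + 1, 10):
            assert not test_samples[i] & test_samples[j]


def test_fold_assignment_deterministic(individuals, pools):
    a = build_regime_datasets(individuals, pools, "combined", "combined", seed=7)
    b = build_regime_datasets(individuals, pools, "combined", "combined", seed=7)
    for da, db in zip(a, b):
        pd.testing.assert_frame_equal(da.train_pairs, db.train_pairs)
        pd.testing.assert_frame_equal(da.test_pairs, db.test_pairs)


def test_too_many_folds_rejected(pools, individuals):
    with pytest.raises(ValidationError):
        build_regime_datasets(individuals, pools, "pools", "pools", n_folds=11)


# ---------------------------------------------------------------------------
# calibrator fitting


def test_lr_exact_on_linear_data():
    pairs = _pairs(30, "individual", snps=("s1",))
    pairs["f_star"] = 0.5 * pairs["f"] + 0.25
    model = fit_calibrator(ModelSpec(family="LR"), pairs)
    f = np.array([0.0, 0.3, 1.0])
    np.testing.assert_allclose(
        apply_calibrator(model, f), 0.5 * f + 0.25, atol=1e-8
    )


def test_lr_weight_invariance():
    pairs = _pairs(20, "individual", snps=("s1",))
    pairs["f_star"] = np.round(pairs["f"] * 2) / 2
    doubled = pairs.copy()
    doubled["weight"] = 2
    a = fit_calibrator(ModelSpec(family="LR"), pairs)
    b = fit_calibrator(ModelSpec(family="LR"), doubled)
    f = np.linspace(0, 1, 7)
    np.testing.assert_allclose(
        apply_calibrator(a, f), apply_calibrator(b, f), atol=1e-10
    )


def test_constant_target_predicts_constant():
    pairs = _pairs(25, "individual", snps=("s1",), f_star=0.5)
    for family in ("LR", "SVR"):
        model = fit_calibrator(ModelSpec(family=family), pairs)
        pred = apply_calibrator(model, np.array([0.1, 0.9]))
        np.testing.assert_allclose(pred, 0.5, atol=0.02)


def test_mlp_spec_defaults_reach_estimator():
    pairs = _pairs(30, "individual", snps=("s1",))
    model = fit_calibrator(ModelSpec(family="MLP", seed=4), pairs)
    est = model.estimator
    assert est.hidden_layer_sizes == (2, 2)
    assert est.activation == "logistic"
    assert est.learning_rate_init == 0.1
    assert est.momentum == 0.15


def test_svr_spec_defaults_reach_estimator():
    pairs = _pairs(30, "individual", snps=("s1",))
    model = fit_calibrator(ModelSpec(family="SVR"), pairs)
    assert model.estimator.nu == 0.092
    assert model.estimator.C == 0.027
    assert model.estimator.kernel == "rbf"


def test_mlp_identity_training_near_zero_at_origin():
    pairs = _pairs(120, "individual", snps=("s1",))
    model = fit_calibrator(ModelSpec(family="MLP", seed=2), pairs)
    assert -0.1 <= apply_calibrator(model, 0.0) <= 0.1


def test_degenerate_training_rejected():
    pairs = _pairs(5, "individual", snps=("s1",))
    pairs["f"] = 0.5
    with pytest.raises(DegenerateTrainingError):
        fit_calibrator(ModelSpec(family="LR"), pairs)


def test_unknown_snp_prediction_rejected(individuals):
    results = RegressionCalibration(individuals, ModelSpec(family="LR")).fit()
    with pytest.raises(KeyError):
        results.predict(0.5, "nope")


# ---------------------------------------------------------------------------
# cross-validation


def test_cv_perfect_data_zero_error(individuals, pools):
    ind = individuals.copy()
    ind["f_star"] = ind["f"]  # identity truth, no noise
    report = cross_validate(
        ModelSpec(family="LR"), ind, pools, "individuals", "individuals",
        n_folds=5, seed=1,
    )
    assert report.pooled_mse < 1e-6


def test_cv_deterministic(individuals, pools):
    kwargs = dict(n_folds=5, seed=9)
    a = cross_validate(ModelSpec(family="LR"), individuals, pools,
                       "combined", "pools", **kwargs)
    b = cross_validate(ModelSpec(family="LR"), individuals, pools,
                       "combined", "pools", **kwargs)
    assert a.pooled_mse == b.pooled_mse
    assert a.fold_mse == b.fold_mse


def test_cv_counts_every_test_entry(individuals, pools):
    report = cross_validate(
        ModelSpec(family="LR"), individuals, pools, "pools", "pools",
        n_folds=5, seed=2,
    )
    assert report.n == len(pools)


# ---------------------------------------------------------------------------
# serialization


@pytest.mark.parametrize("family", ["LR", "MLP", "SVR"])
def test_serialized_model_reproduces_predictions(family, tmp_path):
    pairs = _pairs(40, "individual", snps=("s1",), rng=np.random.default_rng(8))
    pairs["f_star"] = np.round(pairs["f"] * 2) / 2
    results = RegressionCalibration(pairs, ModelSpec(family=family, seed=3)).fit()
    f = np.linspace(0, 1, 9)
    direct = results.predict(f, "s1")
    path = tmp_path / "model.json"
    results.to_json(path)
    loaded = RegressionCalibrationResults.from_json(path)
    np.testing.assert_allclose(loaded.predict(f, "s1"), direct, atol=1e-9)


# ---------------------------------------------------------------------------
# pair construction


def test_make_training_pairs_joins_truth(small_panel):
    pairs = make_training_pairs(small_panel.records, small_panel.truth)
    assert set(pairs["source"]) == {"individual", "pool"}
    ind = pairs[pairs["source"] == "individual"]
    assert set(np.unique(ind["f_star"])) <= {0.0, 0.5, 1.0}
    assert (pairs["weight"] == 1).all()
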