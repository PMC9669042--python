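import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hydroadvisor as ha
from hydroadvisor.surrogate import _group_folds
from conftest import FAST_SPACE


# ---------------------------------------------------------------- MAE

def test_mae_hand_computed():
    assert ha.mae([500.0, 600.0], [480.0, 620.0]) == pytest.approx(20.0)


def test_mae_identity_is_zero():
    x = np.linspace(100, 1300, 50)
    assert ha.mae(x, x) == 0.0


def test_mae_matches_elementwise_loop_oracle():
    rng = np.random.default_rng(0)
    a, p = rng.uniform(100, 1300, 1000), rng.uniform(100, 1300, 1000)
    oracle = sum(abs(ai - pi) for ai, pi in zip(a, p)) / len(a)
    assert ha.mae(a, p) == pytest.approx(oracle)


def test_mae_errors():
    with pytest.raises(ValueError):
        ha.mae([1.0, 2.0], [1.0])
    with pytest.raises(ValueError):
        ha.mae([], [])
    with pytest.raises(ValueError):
        ha.mae([1.0, np.nan], [1.0, 2.0])


@given(
    st.lists(st.floats(0, 2000, allow_nan=False), min_size=1, max_size=50),
    st.lists(st.floats(0, 2000, allow_nan=False), min_size=1, max_size=50),
)
@settings(max_examples=50, deadline=None)
def test_mae_symmetric_and_nonnegative(a, b):
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    assert ha.mae(a, b) >= 0
    assert ha.mae(a, b) == pytest.approx(ha.mae(b, a))


# ---------------------------------------------------------- feature ranking

def _known_structure_frame(n=500, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "plain_water": rng.uniform(0, 4000, n),
            "weight": rng.uniform(50, 100, n),
            "noise_a": rng.normal(size=n),
            "noise_b": rng.normal(size=n),
            "noise_c": rng.normal(size=n),
        }
    )
    df["urine_osm"] = 900 - 0.15 * df["plain_water"] + 4.0 * df["weight"] + rng.normal(0, 5, n)
    return df


def test_rank_features_recovers_known_drivers():
    df = _known_structure_frame()
    feats = ["plain_water", "weight", "noise_a", "noise_b", "noise_c"]
    table = ha.rank_features(df, feats, seed=0)
    assert set(table.top(2)) == {"plain_water", "weight"}


def test_rank_features_dominant_single_signal():
    rng = np.random.default_rng(1)
    n = 800
    df = pd.DataFrame({f"noise_{i}": rng.normal(size=n) for i in range(5)})
    df["plain_water"] = rng.uniform(0, 4000, n)
    df["urine_osm"] = 1200 - 0.25 * df["plain_water"] + rng.normal(0, 10, n)
    table = ha.rank_features(df, ["plain_water"] + [f"noise_{i}" for i in range(5)], seed=1)
    row = table.table.set_index("feature")
    assert row.loc["plain_water", "rank"] == 1
    assert row.loc["plain_water", "fractional_gain"] > 0.5


def test_rank_features_duplicate_column_shares_gain():
    df = _known_structure_frame(seed=2)
    solo = ha.rank_features(df, ["plain_water", "weight", "noise_a"], seed=2)
    df_dup = df.assign(water_copy=df["plain_water"])
    dup = ha.rank_features(df_dup, ["plain_water", "water_copy", "weight", "noise_a"], seed=2)
    gain_solo = solo.table.set_index("feature").loc["plain_water", "fractional_gain"]
    pair = dup.table.set_index("feature").loc[["plain_water", "water_copy"], "fractional_gain"].sum()
    assert pair == pytest.approx(gain_solo, rel=0.2)


def test_rank_features_normalization_invariant(small_split):
    feats = ha.DEFAULT_ALLOWED_FEATURES + ["urine_volume", "n_micturitions"]
    table = ha.rank_features(small_split.train_rows, feats, seed=11)
    assert table.table["fractional_gain"].sum() == pytest.approx(1.0, abs=1e-9)
    assert table.table["max_normalized"].max() == pytest.approx(1.0)


def test_rank_features_degenerate_response_errors():
    df = _known_structure_frame(n=50)
    df["urine_osm"] = 500.0
    with pytest.raises(ValueError, match="degenerate"):
        ha.rank_features(df, ["plain_water", "weight"], seed=0)


# ---------------------------------------------------------- feature policy

def test_prune_preserves_allowed_order(small_split):
    feats = ha.DEFAULT_ALLOWED_FEATURES + ["urine_volume", "n_micturitions"]
    table = ha.rank_features(small_split.train_rows, feats, seed=11)
    policy = ha.FeaturePolicy()
    final = ha.prune_features(table, policy)
    assert final == list(policy.allowed_features)
    assert "urine_volume" not in final and "n_micturitions" not in final


def test_prune_configured_23_of_107():
    candidates = [f"var_{i:03d}" for i in range(107)]
    allowed = tuple(candidates[3:49:2])  # 23 names
    assert len(allowed) == 23
    policy = ha.FeaturePolicy(excluded_features=("var_001",), allowed_features=allowed)
    df = _known_structure_frame()
    table = ha.rank_features(df, ["plain_water", "weight", "noise_a"], seed=0)
    assert len(ha.prune_features(table, policy)) == 23


def test_policy_empty_exclusion_is_identity():
    policy = ha.FeaturePolicy(excluded_features=(), allowed_features=("age", "weight"))
    df = _known_structure_frame()
    table = ha.rank_features(df, ["plain_water", "weight"], seed=0)
    assert ha.prune_features(table, policy) == ["age", "weight"]


def test_policy_rejects_urine_feature_in_allowed():
    with pytest.raises(ValueError):
        ha.FeaturePolicy(allowed_features=("age", "urine_volume"))
    with pytest.raises(ValueError):
        ha.FeaturePolicy(allowed_features=("age", "urine_osm"))


# ---------------------------------------------------------- fitting

def test_fit_memorizes_training_rows(small_split):
    rows = small_split.train_rows.head(50)
    model = ha.fit_surrogate(
        rows,
        ha.DEFAULT_ALLOWED_FEATURES,
        "gbt",
        hyperparameter_space={
            "max_depth": (8, 8),
            "learning_rate": (0.3, 0.3),
            "n_estimators": (600, 600),
            "subsample": (1.0, 1.0),
        },
        cv_folds=2,
        n_search=1,
        seed=0,
    )
    assert model.train_mae < 5.0


def test_predictions_finite_with_missing_intake(fitted_model, small_split):
    rows = small_split.test_rows.copy()
    rows.loc[rows.index[:10], "plain_water"] = np.nan
    yhat = fitted_model.predict(rows)
    assert np.all(np.isfinite(yhat))


def test_all_missing_feature_dropped_with_warning(small_split):
    rows = small_split.train_rows.copy()
    rows["plain_water"] = np.nan
    with pytest.warns(UserWarning, match="all-missing"):
        model = ha.fit_surrogate(
            rows, ha.DEFAULT_ALLOWED_FEATURES, "gbt",
            hyperparameter_space=FAST_SPACE, cv_folds=3, n_search=1, seed=0,
        )
    assert "plain_water" not in model.features


def test_grouped_cv_folds_never_leak_participants():
    groups = np.repeat([f"P{i}" for i in range(20)], 3)
    for train_idx, valid_idx in _group_folds(groups, 5):
        assert not set(groups[train_idx]) & set(groups[valid_idx])


def test_noise_free_fit_recovers_forward_model(noisefree_params):
    # parameter-recovery: with zero response noise the surrogate should
    # predict held-out participants far better than the response spread
    spec = ha.CohortSpec(n_participants=800, seed=5, missing_fluid_fraction=0.0)
    cohort = ha.generate_cohort(spec, noisefree_params)
    split = ha.split_by_participant(cohort, 0.75, seed=5)
    model = ha.fit_surrogate(
        split.train_rows, ha.DEFAULT_ALLOWED_FEATURES, "gbt",
        cv_folds=3, n_search=6, seed=5,
    )
    test = split.test_rows
    test_mae = ha.mae(test["urine_osm"].to_numpy(float), model.predict(test))
    assert test_mae < 0.10 * test["urine_osm"].std()


def test_surrogate_slice_monotone_on_monotone_cohort(noisefree_params):
    from hydroadvisor.advisor import response_slice

    spec = ha.CohortSpec(n_participants=300, seed=6, missing_fluid_fraction=0.0)
    cohort = ha.generate_cohort(spec, noisefree_params)
    split = ha.split_by_participant(cohort, 0.75, seed=6)
    model = ha.fit_surrogate(
        split.train_rows, ha.DEFAULT_ALLOWED_FEATURES, "gbt",
        hyperparameter_space=FAST_SPACE, cv_folds=3, n_search=3, seed=6,
    )
    medians = split.train_rows.median(numeric_only=True)
    record = split.train_rows.iloc[0].copy()
    for col in medians.index:
        record[col] = medians[col]
    waters = np.arange(0.0, 4051.0, 150.0)
    slice_vals = response_slice(model, record, waters)
    increases = np.diff(slice_vals)
    # tolerance: one tree-step oscillation relative to the slice's total span
    span = slice_vals.max() - slice_vals.min()
    assert increases.max() <= 0.05 * span


# ---------------------------------------------------------- comparison

TINY_SPACES = {
    "gbt": {"max_depth": (3, 4), "learning_rate": (0.15, 0.25),
            "n_estimators": (80, 120), "subsample": (0.9, 1.0)},
    "rf": {"max_depth": (6, 10), "n_estimators": (50, 80), "max_features": (0.6, 1.0)},
    "gbm": {"max_depth": (3, 4), "learning_rate": (0.15, 0.25),
            "max_iter": (80, 120), "l2_regularization": (0.0, 0.5)},
}


@pytest.fixture(scope="module")
def tiny_split():
    cohort = ha.generate_cohort(ha.CohortSpec(n_participants=60, seed=19))
    filtered, _ = ha.apply_eligibility_filters(cohort)
    return ha.split_by_participant(filtered, 0.75, seed=19)


def test_compare_learners_five_repeat_stability(tiny_split):
    headline, stability = ha.compare_learners(
        tiny_split.train_rows, tiny_split.test_rows,
        learner_kinds=("gbt", "rf", "gbm"), seed=19,
        n_repeats=5, hyperparameter_space=TINY_SPACES, cv_folds=3, n_search=2,
    )
    assert set(headline) == {"gbt", "rf", "gbm"}
    for kind in ("gbt", "rf", "gbm"):
        assert len(stability.maes[kind]) == 5
        assert np.isfinite(stability.mean[kind])
        assert np.isfinite(stability.sd[kind])
    assert stability.sd_defined


def test_compare_learners_single_repeat_sd_undefined(tiny_split):
    _, stability = ha.compare_learners(
        tiny_split.train_rows, tiny_split.test_rows,
        learner_kinds=("gbt",), seed=19,
        n_repeats=1, hyperparameter_space=TINY_SPACES, cv_folds=3, n_search=1,
    )
    assert not stability.sd_defined
    assert np.isnan(stability.sd["gbt"])


def test_shuffled_response_degrades_mae(tiny_split):
    # negative control: destroying the feature-response link cannot help
    train, test = tiny_split.train_rows, tiny_split.test_rows.copy()
    test = test[test["urine_osm"].notna()]
    intact = ha.fit_surrogate(
        train, ha.DEFAULT_ALLOWED_FEATURES, "gbt",
        hyperparameter_space=FAST_SPACE, cv_folds=3, n_search=2, seed=19,
    )
    shuffled_train = train.copy()
    shuffled_train["urine_osm"] = (
        np.random.default_rng(19).permutation(train["urine_osm"].to_numpy())
    )
    broken = ha.fit_surrogate(
        shuffled_train, ha.DEFAULT_ALLOWED_FEATURES, "gbt",
        hyperparameter_space=FAST_SPACE, cv_folds=3, n_search=2, seed=19,
    )
    y = test["urine_osm"].to_numpy(float)
    assert ha.mae(y, broken.predict(test)) >= ha.mae(y, intact.predict(test))


def test_model_persistence_roundtrip(tmp_path, fitted_model, small_split):
    ha.save_model(fitted_model, str(tmp_path / "model"))
    back = ha.load_model(str(tmp_path / "model"))
    test = small_split.test_rows
    np.testing.assert_allclose(back.predict(test), fitted_model.predict(test))
    assert back.features == fitted_model.features
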