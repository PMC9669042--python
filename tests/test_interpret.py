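import numpy as np
import pandas as pd
import pytest

import hydroadvisor as ha
from conftest import AdditiveStub


@pytest.fixture(scope="module")
def interp_rows():
    cohort = ha.generate_cohort(
        ha.CohortSpec(n_participants=80, seed=23, missing_fluid_fraction=0.0)
    )
    return cohort.head(150)


# -------------------------------------------------------------- PDP / ICE

def test_pdp_of_additive_model_has_component_slope(stub_model, interp_rows):
    grid = np.arange(0.0, 4051.0, 150.0)
    res = ha.pdp_ice(stub_model, interp_rows, "plain_water", grid=grid)
    slopes = np.diff(res.pdp) / np.diff(res.grid)
    np.testing.assert_allclose(slopes, -0.1, atol=1e-9)


def test_single_row_pdp_equals_its_ice(stub_model, interp_rows):
    res = ha.pdp_ice(stub_model, interp_rows.head(1), "plain_water",
                     grid=np.linspace(0, 4000, 10))
    np.testing.assert_allclose(res.pdp, res.ice[0])


def test_pdp_matches_brute_force_overwrite_loop(fitted_model, small_split):
    rows = small_split.train_rows.dropna(subset=["plain_water"]).head(120)
    grid = np.arange(0.0, 4051.0, 150.0)  # 28 points
    res = ha.pdp_ice(fitted_model, rows, "plain_water", grid=grid)
    # independent double loop: overwrite one row at a time, one grid value at a time
    oracle = np.zeros((len(rows), len(grid)))
    for i in range(len(rows)):
        for g, value in enumerate(grid):
            row = rows.iloc[[i]].copy()
            row["plain_water"] = value
            oracle[i, g] = fitted_model.predict(row)[0]
    np.testing.assert_allclose(res.ice, oracle, atol=1e-4)
    np.testing.assert_allclose(res.pdp, oracle.mean(axis=0), atol=1e-4)


def test_pdp_mean_identity_and_input_untouched(fitted_model, small_split):
    rows = small_split.train_rows.dropna(subset=["plain_water"]).head(60)
    before = rows.copy()
    res = ha.pdp_ice(fitted_model, rows, "plain_water")
    np.testing.assert_allclose(res.pdp, res.ice.mean(axis=0), atol=1e-9)
    pd.testing.assert_frame_equal(rows, before)


def test_pdp_flags_extrapolation(stub_model, interp_rows):
    with pytest.warns(UserWarning, match="beyond observed"):
        res = ha.pdp_ice(stub_model, interp_rows, "plain_water",
                         grid=np.array([0.0, 10000.0]))
    assert res.extrapolated


def test_pdp_requires_rows(stub_model, interp_rows):
    with pytest.raises(ValueError):
        ha.pdp_ice(stub_model, interp_rows.iloc[0:0], "plain_water")


# ------------------------------------------------------------------- ALE

def test_ale_of_additive_model_is_linear(stub_model, interp_rows):
    res = ha.ale(stub_model, interp_rows, "plain_water", n_bins=10)
    slopes = np.diff(res.effects) / np.diff(res.edges)
    np.testing.assert_allclose(slopes, -0.1, atol=1e-9)


def test_ale_of_ignoring_model_is_zero(interp_rows):
    stub = AdditiveStub(a=0.0)  # no dependence on water
    res = ha.ale(stub, interp_rows, "plain_water", n_bins=8)
    np.testing.assert_allclose(res.effects, 0.0, atol=1e-9)


def test_ale_matches_brute_force_bin_definition(fitted_model, small_split):
    rows = small_split.train_rows.dropna(subset=["plain_water"]).head(150)
    n_bins = 10
    res = ha.ale(fitted_model, rows, "plain_water", n_bins=n_bins)
    # naive oracle built straight from the definition
    x = rows["plain_water"].to_numpy(float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    local, counts = [], []
    for b in range(len(edges) - 1):
        lo, hi = edges[b], edges[b + 1]
        in_bin = (x > lo) & (x <= hi) if b > 0 else (x >= lo) & (x <= hi)
        sub = rows[in_bin]
        counts.append(len(sub))
        deltas = []
        for i in range(len(sub)):
            r_hi = sub.iloc[[i]].copy()
            r_lo = sub.iloc[[i]].copy()
            r_hi["plain_water"] = hi
            r_lo["plain_water"] = lo
            deltas.append(fitted_model.predict(r_hi)[0] - fitted_model.predict(r_lo)[0])
        local.append(np.mean(deltas) if deltas else 0.0)
    acc = np.concatenate([[0.0], np.cumsum(local)])
    mids = 0.5 * (acc[:-1] + acc[1:])
    acc -= np.sum(mids * np.array(counts)) / np.sum(counts)
    np.testing.assert_allclose(res.effects, acc, atol=1e-4)


def test_ale_centering_invariant(fitted_model, small_split):
    rows = small_split.train_rows.dropna(subset=["plain_water"]).head(150)
    res = ha.ale(fitted_model, rows, "plain_water", n_bins=12)
    mids = 0.5 * (res.effects[:-1] + res.effects[1:])
    weighted = np.sum(mids * res.bin_counts) / np.sum(res.bin_counts)
    assert abs(weighted) < 1e-6


def test_ale_and_pdp_differ_on_correlated_features(fitted_model, small_split):
    # plain water and TFI are strongly correlated by construction, so the two
    # curve families need not coincide even after aligning their centers
    rows = small_split.train_rows.dropna(subset=["plain_water"]).head(150)
    pdp = ha.pdp_ice(fitted_model, rows, "plain_water",
                     grid=np.linspace(rows["plain_water"].min(), rows["plain_water"].max(), 15))
    ale_res = ha.ale(fitted_model, rows, "plain_water", n_bins=14)
    pdp_at_edges = np.interp(ale_res.edges, pdp.grid, pdp.pdp)
    pdp_centered = pdp_at_edges - pdp_at_edges.mean()
    ale_centered = ale_res.effects - ale_res.effects.mean()
    assert not np.allclose(pdp_centered, ale_centered, atol=1.0)


def test_ale_requires_enough_distinct_values(stub_model):
    rows = pd.DataFrame({"plain_water": [1000.0] * 30, "weight": 70.0})
    with pytest.raises(ValueError):
        ha.ale(stub_model, rows, "plain_water", n_bins=10)


# ------------------------------------------------------- steepest decrease

def test_largest_drop_enumerated_example():
    res = ha.PdpResult(
        feature="plain_water",
        grid=np.array([0.0, 300.0, 600.0, 900.0]),
        pdp=np.array([800.0, 700.0, 500.0, 450.0]),
        ice=np.array([[800.0, 700.0, 500.0, 450.0]]),
    )
    assert ha.largest_drop_interval(res, 300.0) == (300.0, 600.0)


def test_largest_drop_constant_pdp_reports_no_decrease():
    res = ha.PdpResult(
        feature="plain_water",
        grid=np.array([0.0, 300.0, 600.0]),
        pdp=np.array([500.0, 500.0, 500.0]),
        ice=np.array([[500.0, 500.0, 500.0]]),
    )
    assert ha.largest_drop_interval(res, 300.0) is None


def test_largest_drop_window_must_fit():
    res = ha.PdpResult(
        feature="plain_water",
        grid=np.array([0.0, 100.0]),
        pdp=np.array([500.0, 400.0]),
        ice=np.array([[500.0, 400.0]]),
    )
    with pytest.raises(ValueError):
        ha.largest_drop_interval(res, 500.0)
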