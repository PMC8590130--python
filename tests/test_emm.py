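"""Estimated marginal means of the linear cosinor parameters."""

import numpy as np
import pandas as pd
import pytest

from cosinormixed import (
    EmmSpec,
    ModelSpec,
    SpecificationError,
    fit,
    marginal_cosinor_params,
    marginal_linear_params,
    parse_emm_formula,
    simulate_dataset,
)
from cosinormixed.data import from_dataframe
from cosinormixed.core import TWO_PI

from conftest import make_params, two_group_design


def _aligned(grid):
    """Grid coefficients keyed by level tuple, independent of row order."""
    keys = [tuple(grid.levels.iloc[i]) for i in range(grid.n_cells)]
    return dict(zip(keys, map(tuple, np.round(grid.coef, 10))))


def test_parse_emm_formula():
    spec = parse_emm_formula("~COVID")
    assert spec.means_over == ("COVID",) and spec.conditioned_on == ()
    spec = parse_emm_formula("~bmi_cat|sex")
    assert spec.means_over == ("bmi_cat",) and spec.conditioned_on == ("sex",)
    with pytest.raises(SpecificationError):
        parse_emm_formula("~")
    with pytest.raises(SpecificationError):
        EmmSpec(means_over=("a",), conditioned_on=("a",))


def test_single_binary_factor_direct_coefficient_addition(two_group_data):
    """With one treatment-coded binary factor, the grid is read straight
    off the coefficients: reference cell = base terms, other cell adds
    the factor terms."""
    _, ds, _ = two_group_data
    result = fit(ds, ModelSpec(factors=["grp"]))
    grid = marginal_linear_params(result, parse_emm_formula("~grp"))
    b = result.params
    cells = _aligned(grid)
    assert cells[("a",)] == pytest.approx((b["Intercept"], b["x"], b["z"]), abs=1e-10)
    assert cells[("b",)] == pytest.approx(
        (
            b["Intercept"] + b["grp[b]"],
            b["x"] + b["grp[b]:x"],
            b["z"] + b["grp[b]:z"],
        ),
        abs=1e-10,
    )


def _two_factor_dataset(seed=8, n=48):
    rng = np.random.default_rng(seed)
    subs = [f"s{i}" for i in range(n)]
    sex = rng.choice(["F", "M"], n)
    covid = rng.choice(["neg", "pos"], n)
    rows = []
    for i, s in enumerate(subs):
        for t in rng.uniform(0, 24, 6):
            rows.append(
                {"id": s, "Hour": t, "hrv": rng.normal(60, 8), "sex": sex[i],
                 "covid": covid[i]}
            )
    return from_dataframe(
        pd.DataFrame(rows), subject_col="id", time_col="Hour", response_col="hrv",
        covariate_cols=["sex", "covid"],
    )


def test_equal_weight_averaging_hand_computed():
    """Grid over covid averages sex with weight 1/2 per level: the cell
    value is the hand-built L row applied to the coefficient vector."""
    ds = _two_factor_dataset()
    result = fit(ds, ModelSpec(factors=["sex", "covid"]))
    grid = marginal_linear_params(result, parse_emm_formula("~covid"))
    b = result.params
    cells = _aligned(grid)
    for lev, dummy in [("neg", 0.0), ("pos", 1.0)]:
        expected_m = b["Intercept"] + 0.5 * b["sex[M]"] + dummy * b["covid[pos]"]
        expected_beta = b["x"] + 0.5 * b["sex[M]:x"] + dummy * b["covid[pos]:x"]
        expected_gamma = b["z"] + 0.5 * b["sex[M]:z"] + dummy * b["covid[pos]:z"]
        assert cells[(lev,)] == pytest.approx(
            (expected_m, expected_beta, expected_gamma), abs=1e-10
        )


def test_proportional_weights_sum_to_one():
    ds = _two_factor_dataset()
    result = fit(ds, ModelSpec(factors=["sex", "covid"]))
    grid = marginal_linear_params(
        result, parse_emm_formula("~covid", weights="proportional")
    )
    # L row entries: intercept weight 1, averaged-dummy weight = observed
    # frequency of that level
    freq_m = (ds.records["sex"] == "M").mean()
    j = grid.levels.index[grid.levels["covid"] == "neg"][0]
    base_cols = result.design.base_columns
    row = grid.L[j]
    assert row[base_cols.index("Intercept")] == pytest.approx(1.0)
    assert row[base_cols.index("sex[M]")] == pytest.approx(freq_m)


def test_three_level_grid_cardinality():
    rng = np.random.default_rng(3)
    n = 45
    rows = []
    bmi = rng.choice(["normal", "over", "obese"], n)
    for i in range(n):
        for t in rng.uniform(0, 24, 5):
            rows.append(
                {"id": f"s{i}", "Hour": t, "hrv": rng.normal(60, 8), "bmi": bmi[i]}
            )
    ds = from_dataframe(
        pd.DataFrame(rows), subject_col="id", time_col="Hour", response_col="hrv",
        covariate_cols=["bmi"],
    )
    result = fit(ds, ModelSpec(factors=["bmi"]))
    grid = marginal_linear_params(result, parse_emm_formula("~bmi"))
    assert grid.n_cells == 3
    assert set(grid.levels["bmi"]) == {"normal", "obese", "over"}


def test_coding_invariance_of_grid():
    ds = _two_factor_dataset()
    g1 = marginal_linear_params(
        fit(ds, ModelSpec(factors=["sex", "covid"])), parse_emm_formula("~covid|sex")
    )
    g2 = marginal_linear_params(
        fit(ds, ModelSpec(factors=["sex", "covid"],
                          reference_levels={"sex": "M", "covid": "pos"})),
        parse_emm_formula("~covid|sex"),
    )
    a1, a2 = _aligned(g1), _aligned(g2)
    assert a1.keys() == a2.keys()
    for key in a1:
        assert a1[key] == pytest.approx(a2[key], abs=1e-8)


def test_unknown_factor_rejected(two_group_data):
    _, ds, _ = two_group_data
    result = fit(ds, ModelSpec(factors=["grp"]))
    with pytest.raises(SpecificationError, match="sex"):
        marginal_linear_params(result, parse_emm_formula("~sex"))


def test_marginal_cosinor_params_transform(two_group_data):
    _, ds, truth = two_group_data
    result = fit(ds, ModelSpec(factors=["grp"]))
    grid = marginal_linear_params(result, parse_emm_formula("~grp"))
    table = marginal_cosinor_params(grid)
    assert set(table.columns) >= {"mesor", "amplitude", "acrophase", "peak_time"}
    for i in range(grid.n_cells):
        m, b, g = grid.coef[i]
        assert table.loc[i, "amplitude"] == pytest.approx(np.hypot(b, g), abs=1e-12)
        assert -TWO_PI < table.loc[i, "acrophase"] <= 0.0


def test_rotation_invariance_of_amplitude():
    """Two coefficient pairs related by a rotation have equal amplitude."""
    theta = 1.1
    b1, g1 = 3.0, 4.0
    b2 = np.cos(theta) * b1 - np.sin(theta) * g1
    g2 = np.sin(theta) * b1 + np.cos(theta) * g1
    from cosinormixed import LinearCoefficients, linear_to_cosinor

    p1 = linear_to_cosinor(LinearCoefficients(0.0, b1, g1))
    p2 = linear_to_cosinor(LinearCoefficients(0.0, b2, g2))
    assert p1.amplitude == pytest.approx(p2.amplitude, abs=1e-12)


def test_collapse_property():
    """If one factor's coefficients are identical across its levels
    (synthetically set to zero under treatment coding), the grid over the
    other factor equals the grid from the model without that factor."""
    ds = _two_factor_dataset(seed=21)
    full = fit(ds, ModelSpec(factors=["sex", "covid"]), zero_random_variance=True)
    reduced = fit(ds, ModelSpec(factors=["sex"]), zero_random_variance=True)

    synth = {"Intercept": 50.0, "sex[M]": 3.0, "x": 7.0, "sex[M]:x": -2.0,
             "z": 1.5, "sex[M]:z": 0.5}
    full.params = pd.Series(
        [synth.get(name, 0.0) for name in full.params.index], index=full.params.index
    )
    reduced.params = pd.Series(
        [synth[name] for name in reduced.params.index], index=reduced.params.index
    )
    grid_with = marginal_linear_params(full, parse_emm_formula("~sex"))
    grid_without = marginal_linear_params(reduced, parse_emm_formula("~sex"))
    a_with, a_without = _aligned(grid_with), _aligned(grid_without)
    assert a_with.keys() == a_without.keys()
    for key in a_with:
        assert a_with[key] == pytest.approx(a_without[key], abs=1e-12)


def test_extrapolated_cell_flagged():
    """A never-observed factor combination still gets a model-based cell,
    flagged as extrapolated."""
    rng = np.random.default_rng(5)
    rows = []
    for i in range(40):
        sex = "F" if i % 2 else "M"
        covid = "neg" if sex == "F" else rng.choice(["neg", "pos"])
        for t in rng.uniform(0, 24, 5):
            rows.append({"id": f"s{i}", "Hour": t, "hrv": rng.normal(60, 8),
                         "sex": sex, "covid": covid})
    df = pd.DataFrame(rows)
    assert not ((df["sex"] == "F") & (df["covid"] == "pos")).any()
    ds = from_dataframe(df, subject_col="id", time_col="Hour", response_col="hrv",
                        covariate_cols=["sex", "covid"])
    result = fit(ds, ModelSpec(factors=["sex", "covid"]))
    grid = marginal_linear_params(result, parse_emm_formula("~covid|sex"))
    flags = {tuple(grid.levels.iloc[i]): bool(grid.extrapolated[i])
             for i in range(grid.n_cells)}
    assert flags[("F", "pos")] is True
    assert flags[("M", "neg")] is False
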