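"""Bootstrap CIs, p-values, stars and Wald tests."""

import math

import numpy as np
import pytest
from scipy import stats

from cosinormixed import (
    ModelSpec,
    SpecificationError,
    bootstrap_cosinor,
    bootstrap_p_value,
    contrasts_with_ci,
    fit,
    means_with_ci,
    parse_emm_formula,
    percentile_ci,
    significance_stars,
    simulate_dataset,
    wald_linear_test,
)

from conftest import two_group_design


# ---------------------------------------------------------------- percentile


def test_percentile_ci_type7_oracle():
    """Textbook type-7 quantile: h = (n-1)p + 1, linear interpolation."""
    draws = np.arange(1.0, 101.0)

    def type7(p):
        h = (len(draws) - 1) * p
        lo = int(np.floor(h))
        return draws[lo] + (h - lo) * (draws[min(lo + 1, len(draws) - 1)] - draws[lo])

    lo, hi = percentile_ci(draws, 0.95)
    assert lo == pytest.approx(type7(0.025)) == pytest.approx(3.475)
    assert hi == pytest.approx(type7(0.975)) == pytest.approx(97.525)


def test_percentile_ci_degenerate_and_symmetry():
    assert percentile_ci(np.full(10, 7.0), 0.95) == (7.0, 7.0)
    draws = np.concatenate([-np.arange(1.0, 51.0), np.arange(1.0, 51.0)])
    lo, hi = percentile_ci(draws, 0.5)
    assert lo == pytest.approx(-hi, abs=1e-9)  # symmetric about median 0


def test_percentile_ci_input_validation():
    with pytest.raises(SpecificationError):
        percentile_ci([1.0], 0.95)
    with pytest.raises(SpecificationError):
        percentile_ci([1.0, 2.0], 1.5)


# ------------------------------------------------------------------ p-values


@pytest.mark.parametrize(
    "draws, expected",
    [
        (np.ones(499), 2.0 / 500.0),  # all positive
        (np.array([-2.0, -1.0, 1.0, 2.0]), 1.0),  # symmetric -> capped
        (np.concatenate([-np.ones(250), np.ones(249)]), 1.0),  # 250/499 <= 0
    ],
)
def test_bootstrap_p_value_examples(draws, expected):
    assert bootstrap_p_value(draws) == pytest.approx(expected)


def test_bootstrap_p_value_never_zero():
    assert bootstrap_p_value(np.ones(10_000)) > 0.0


@pytest.mark.parametrize(
    "p, stars",
    [
        (0.0005, "***"), (0.0009, "***"), (0.001, "**"), (0.009, "**"),
        (0.01, "*"), (0.03, "*"), (0.05, "+"), (0.09, "+"), (0.1, ""), (0.9, ""),
    ],
)
def test_significance_stars_thresholds(p, stars):
    assert significance_stars(p) == stars


def test_significance_stars_rejects_invalid():
    with pytest.raises(SpecificationError):
        significance_stars(1.5)


# ---------------------------------------------------------------- Wald tests


def test_wald_single_coefficient_matches_fit(two_group_data):
    _, ds, _ = two_group_data
    result = fit(ds, ModelSpec(factors=["grp"]))
    test = wald_linear_test(result, {"grp[b]:x": 1.0})
    assert test.estimate == pytest.approx(result.params["grp[b]:x"])
    se = math.sqrt(result.vcov.loc["grp[b]:x", "grp[b]:x"])
    assert test.se == pytest.approx(se)
    assert test.p_value == pytest.approx(2 * stats.norm.sf(abs(test.estimate / se)))


def test_wald_quadratic_form_hand_computed(two_group_data):
    """With a synthetic diagonal vcov, se = sqrt(sum w_i^2 sigma_i^2)."""
    import pandas as pd

    _, ds, _ = two_group_data
    result = fit(ds, ModelSpec(factors=["grp"]))
    sigmas = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    result.vcov = pd.DataFrame(
        np.diag(sigmas**2), index=result.params.index, columns=result.params.index
    )
    w = np.array([1.0, -1.0, 0.5, 0.0, 2.0, 0.0])
    test = wald_linear_test(result, w)
    assert test.se == pytest.approx(math.sqrt(np.sum(w**2 * sigmas**2)))
    with pytest.raises(SpecificationError):
        wald_linear_test(result, np.zeros(6))


def test_wald_null_distribution_is_standard_normal():
    """Under the null, z-statistics over repeated simulated datasets are
    approximately N(0, 1) (KS test at alpha = 0.01)."""
    rng = np.random.default_rng(99)
    zs = []
    for rep in range(200):
        design = two_group_design(
            n_subjects=24, obs_per_subject=5, amp=(8.0, 8.0), phase_shift=0.0,
            mesor=(60.0, 60.0), seed=int(rng.integers(2**31)),
        )
        ds, _ = simulate_dataset(design)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = fit(ds, ModelSpec(factors=["grp"]))
        zs.append(wald_linear_test(result, {"grp[b]": 1.0}).z)
    assert stats.kstest(zs, "norm").pvalue > 0.01


# ------------------------------------------------------------- bootstrap core


@pytest.fixture(scope="module")
def small_boot():
    design = two_group_design(n_subjects=30, obs_per_subject=6, seed=7)
    ds, truth = simulate_dataset(design)
    result = fit(ds, ModelSpec(factors=["grp"]))
    boot = bootstrap_cosinor(result, parse_emm_formula("~grp"), n_sim=80, seed=11)
    return truth, result, boot


def test_bootstrap_shapes_and_invariants(small_boot):
    truth, result, boot = small_boot
    assert boot.draws.shape == (boot.n_success, 2, 3)
    assert boot.contrasts.shape == (boot.n_success, 1, 3)
    assert np.all(boot.draws[:, :, 1] >= 0.0)  # amplitudes
    # contrast rows equal cell differences (acrophase wrapped)
    d = boot.draws[:, 0, :] - boot.draws[:, 1, :]
    assert np.allclose(boot.contrasts[:, 0, 0], d[:, 0])
    assert np.allclose(boot.contrasts[:, 0, 1], d[:, 1])
    wrapped = np.mod(boot.contrasts[:, 0, 2] - d[:, 2], 2 * np.pi)
    wrapped = np.minimum(wrapped, 2 * np.pi - wrapped)
    assert np.allclose(wrapped, 0.0, atol=1e-9)
    assert np.all(np.abs(boot.contrasts[:, 0, 2]) <= np.pi + 1e-12)


def test_bootstrap_is_deterministic(small_boot):
    truth, result, _ = small_boot
    b1 = bootstrap_cosinor(result, parse_emm_formula("~grp"), n_sim=25, seed=5)
    b2 = bootstrap_cosinor(result, parse_emm_formula("~grp"), n_sim=25, seed=5)
    assert np.array_equal(b1.draws, b2.draws)
    r1 = contrasts_with_ci(b1)
    r2 = contrasts_with_ci(b2)
    assert r1.equals(r2)


def test_noise_free_bootstrap_collapses():
    """With (near) zero noise every draw equals the truth; CI width -> 0."""
    design = two_group_design(
        n_subjects=10, obs_per_subject=8, re_sd=(0, 0, 0), residual_sd=1e-6, seed=2
    )
    ds, truth = simulate_dataset(design)
    result = fit(ds, ModelSpec(factors=["grp"]), zero_random_variance=True)
    boot = bootstrap_cosinor(result, parse_emm_formula("~grp"), n_sim=30, seed=3)
    table = means_with_ci(boot)
    for _, row in table.iterrows():
        t = truth[truth["grp"] == row["grp"]].iloc[0]
        assert row["mesor_upper"] - row["mesor_lower"] < 1e-4
        assert row["amplitude"] == pytest.approx(t["amplitude"], abs=1e-4)
        assert row["acrophase"] == pytest.approx(t["acrophase"], abs=1e-4)


def test_contrast_report_structure(small_boot):
    truth, result, boot = small_boot
    report = contrasts_with_ci(boot)
    assert set(report["parameter"]) == {
        "mesor", "amplitude", "acrophase", "acrophase_hours"
    }
    assert (report["lower"] <= report["upper"]).all()
    for _, row in report.iterrows():
        assert row["stars"] == significance_stars(row["p_value"])
    # the generating difference: amplitude 10 - 6 = 4 within the CI
    amp = report[report["parameter"] == "amplitude"].iloc[0]
    assert amp["lower"] <= 4.0 + 1.5 and amp["upper"] >= 4.0 - 1.5


def test_means_report_cis_cover_estimates(small_boot):
    truth, result, boot = small_boot
    table = means_with_ci(boot)
    for name in ("mesor", "amplitude"):
        assert (table[f"{name}_lower"] <= table[f"{name}_upper"]).all()
    assert (table["peak_time"] >= 0).all() and (table["peak_time"] < 24).all()


def test_cluster_scheme_runs(small_boot):
    truth, result, _ = small_boot
    boot = bootstrap_cosinor(
        result, parse_emm_formula("~grp"), n_sim=12, seed=4,
        scheme="cluster_nonparametric",
    )
    assert boot.scheme == "cluster_nonparametric"
    assert boot.n_success + boot.n_failed == 12
    assert boot.draws.shape[1] == 2


def test_bootstrap_input_validation(small_boot):
    truth, result, _ = small_boot
    with pytest.raises(SpecificationError):
        bootstrap_cosinor(result, parse_emm_formula("~grp"), n_sim=0, seed=1)
    with pytest.raises(SpecificationError):
        bootstrap_cosinor(result, parse_emm_formula("~grp"), n_sim=5, seed=1,
                          scheme="balanced")
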