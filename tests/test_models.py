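"""Inference machinery: descriptive tests against hand-computed oracles,
mixed-model invariants (ICC identity, reference-level contrasts, OLS limit),
standardized effect sizes, and median-regression properties."""

import numpy as np
import pandas as pd
import pytest

from memtraj.models import (ModelSpec, descriptive_comparisons,
                            effect_size_label, fit_interaction_model,
                            fit_median_regression, fit_stratified_models)
from memtraj.simulate import SimulationConfig, simulate_cohort
from memtraj.studies import truth_analysis_table

from conftest import small_config


@pytest.fixture(scope="module")
def analysis_table():
    cohort = simulate_cohort(small_config(seed=23, n_robust_controls=0,
                                          visits_per_participant=5))
    return truth_analysis_table(cohort)


@pytest.fixture(scope="module")
def fitted(analysis_table):
    return fit_interaction_model(analysis_table, ModelSpec())


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def test_identical_groups_t_zero_p_one():
    df = pd.DataFrame({"sex": ["female"] * 4 + ["male"] * 4,
                       "x": [1.0, 2.0, 3.0, 4.0] * 2})
    out = descriptive_comparisons(df, continuous=["x"])
    assert out["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert out["p"].iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_hand_computed_welch_t():
    """{1,2,3} vs {4,5,6}: t = -3.6742, p = 0.02131 (equal n and variance,
    so Welch and Student agree; frozen from the closed-form t integral)."""
    df = pd.DataFrame({"sex": ["female"] * 3 + ["male"] * 3,
                       "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
    out = descriptive_comparisons(df, continuous=["x"])
    assert abs(out["statistic"].iloc[0]) == pytest.approx(3.6742346, abs=1e-6)
    assert out["p"].iloc[0] == pytest.approx(0.0213116, abs=1e-6)


def test_chi_square_identical_proportions_zero():
    df = pd.DataFrame({"sex": ["female"] * 10 + ["male"] * 10,
                       "carrier": ([0] * 5 + [1] * 5) * 2})
    out = descriptive_comparisons(df, continuous=[], categorical=["carrier"])
    assert out["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_small_cell_skipped_with_nan():
    df = pd.DataFrame({"sex": ["female", "male", "male"],
                       "x": [1.0, 2.0, 3.0]})
    out = descriptive_comparisons(df, continuous=["x"])
    assert np.isnan(out["statistic"].iloc[0])


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def test_icc_identity(fitted):
    assert fitted.icc == pytest.approx(
        fitted.tau00 / (fitted.tau00 + fitted.sigma2), abs=1e-12)
    assert fitted.sigma2 > 0
    assert fitted.tau00 >= 0


def test_cis_bracket_estimates(fitted):
    p = fitted.params
    assert (p["ci_low"] <= p["b"]).all()
    assert (p["b"] <= p["ci_high"]).all()


def test_expected_terms_present(fitted):
    terms = set(fitted.params["term"])
    for t in ["biomarker_change", "sex_male", "group_mci",
              "biomarker_change:sex_male", "biomarker_change:group_mci",
              "sex_male:group_mci", "biomarker_change:sex_male:group_mci",
              "age_c", "educ_c", "apoe_carrier"]:
        assert t in terms


def test_reference_level_swap_contrast_identity(analysis_table):
    """Recoding sex so males are the reference negates the sex main effect
    at group 0 context and maps the interactions by the standard contrast
    identity; implied cell slopes are invariant."""
    res_f = fit_interaction_model(analysis_table,
                                  ModelSpec(standardized=False))
    flipped = analysis_table.copy()
    flipped["sex_male"] = 1 - flipped["sex_male"]
    res_m = fit_interaction_model(flipped, ModelSpec(standardized=False))

    def cell_slopes(res):
        b = {r["term"]: r["b"] for _, r in res.params.iterrows()}
        out = {}
        for male in (0, 1):
            for mci in (0, 1):
                out[(male, mci)] = (b["biomarker_change"]
                                    + b["biomarker_change:sex_male"] * male
                                    + b["biomarker_change:group_mci"] * mci
                                    + b["biomarker_change:sex_male:group_mci"]
                                    * male * mci)
        return out
    s_f = cell_slopes(res_f)
    s_m = cell_slopes(res_m)
    for male in (0, 1):
        for mci in (0, 1):
            assert s_f[(male, mci)] == pytest.approx(s_m[(1 - male, mci)],
                                                     abs=1e-4)
    # the three-way coefficient flips sign under the recoding
    b_f = res_f.coef("biomarker_change:sex_male:group_mci")["b"]
    b_m = res_m.coef("biomarker_change:sex_male:group_mci")["b"]
    assert b_f == pytest.approx(-b_m, abs=1e-4)


def test_lmm_matches_ols_when_no_random_variance():
    """Data with one row per participant: the fallback OLS path engages and
    coefficients equal a plain OLS fit."""
    import statsmodels.formula.api as smf
    cohort = simulate_cohort(small_config(seed=31, n_robust_controls=0,
                                          visits_per_participant=2))
    tab = truth_analysis_table(cohort)   # 1 change row per participant
    res = fit_interaction_model(tab, ModelSpec(standardized=False))
    assert res.method == "ols-fallback"
    ols = smf.ols(res.formula, tab).fit()
    got = {r["term"]: r["b"] for _, r in res.params.iterrows()}
    for term, val in ols.params.items():
        assert got[term] == pytest.approx(val, abs=1e-10)


def test_lmm_near_ols_when_tau_zero():
    import statsmodels.formula.api as smf
    cfg = small_config(seed=37, n_robust_controls=0, random_intercept_sd=0.0,
                       visits_per_participant=4)
    tab = truth_analysis_table(simulate_cohort(cfg))
    res = fit_interaction_model(tab, ModelSpec(standardized=False))
    ols = smf.ols(res.formula, tab).fit()
    got = {r["term"]: r["b"] for _, r in res.params.iterrows()}
    for term, val in ols.params.items():
        # agreement well within sampling uncertainty of the coefficient
        assert abs(got[term] - val) < 0.5 * ols.bse[term], term


def test_stratified_identical_strata_agree():
    cohort = simulate_cohort(small_config(seed=41, n_robust_controls=0,
                                          visits_per_participant=4))
    tab = truth_analysis_table(cohort)
    # duplicate one stratum so both groups carry identical data
    pre = tab[tab["group_mci"] == 0]
    fake_mci = pre.copy()
    fake_mci["group_mci"] = 1
    fake_mci["participant_id"] += 100000
    doubled = pd.concat([pre, fake_mci], ignore_index=True)
    strat = fit_stratified_models(doubled, "group",
                                  ModelSpec(standardized=False))
    b_pre = strat["preclinical"].coef("biomarker_change")["b"]
    b_mci = strat["mci"].coef("biomarker_change")["b"]
    assert b_pre == pytest.approx(b_mci, rel=1e-6)


def test_sex_stratified_emits_group_interaction(analysis_table):
    strat = fit_stratified_models(analysis_table, "sex",
                                  ModelSpec(standardized=False))
    for name in ("female", "male"):
        assert "biomarker_change:group_mci" in set(strat[name].params["term"])


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def test_effect_size_bands():
    assert effect_size_label(0.10) == "small"
    assert effect_size_label(0.19) == "small"
    assert effect_size_label(0.20) == "moderate"
    assert effect_size_label(0.39) == "moderate"
    assert effect_size_label(0.40) == "large"   # boundary inclusive
    assert effect_size_label(-0.55) == "large"


def test_standardized_weights_scale_invariant(analysis_table):
    res1 = fit_interaction_model(analysis_table, ModelSpec())
    scaled = analysis_table.copy()
    scaled["memory_change"] *= 10.0
    res2 = fit_interaction_model(scaled, ModelSpec())
    for term in ("biomarker_change", "biomarker_change:sex_male:group_mci"):
        assert res1.coef(term)["std_b"] == pytest.approx(
            res2.coef(term)["std_b"], abs=1e-6)
        # unstandardized b scales with the outcome
        assert res2.coef(term)["b"] == pytest.approx(
            10 * res1.coef(term)["b"], rel=1e-6)


# ---------------------------------------------------------------------------
# median regression
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def secondary_table():
    cohort = simulate_cohort(small_config(seed=53, n_robust_controls=0,
                                          visits_per_participant=4))
    return truth_analysis_table(cohort, secondary=True)


def test_median_regression_shift_equivariance(secondary_table):
    spec = ModelSpec()
    r1 = fit_median_regression(secondary_table, "trails_b_change", spec,
                               n_boot=20, seed=1)
    shifted = secondary_table.copy()
    shifted["trails_b_change"] += 7.0
    r2 = fit_median_regression(shifted, "trails_b_change", spec,
                               n_boot=20, seed=1)
    assert r2.coef("Intercept")["b"] == pytest.approx(
        r1.coef("Intercept")["b"] + 7.0, abs=1e-6)
    assert r2.coef("biomarker_change")["b"] == pytest.approx(
        r1.coef("biomarker_change")["b"], abs=1e-6)


def test_median_matches_ols_under_symmetric_noise():
    rng = np.random.default_rng(5)
    n = 4000
    x = rng.normal(0, 1, n)
    sex = rng.integers(0, 2, n)
    y = 1.0 + 2.0 * x - 0.5 * sex + rng.normal(0, 1, n)
    tab = pd.DataFrame({"participant_id": np.arange(n), "biomarker_change": x,
                        "sex_male": sex, "y": y})
    spec = ModelSpec(interaction="none", covariates=["sex_male"])
    res = fit_median_regression(tab, "y", spec, n_boot=10, seed=2)
    assert res.coef("biomarker_change")["b"] == pytest.approx(2.0, abs=0.1)
    assert res.coef("sex_male")["b"] == pytest.approx(-0.5, abs=0.12)


def test_median_robust_to_contamination_where_ols_moves():
    import statsmodels.formula.api as smf
    rng = np.random.default_rng(9)
    n = 2000
    x = rng.normal(0, 1, n)
    y = 2.0 * x + rng.normal(0, 0.5, n)
    dirty = y.copy()
    idx = rng.choice(n, n // 20, replace=False)
    dirty[idx] += rng.normal(0, 40, len(idx))   # heavy-tailed 5% contamination
    tab = pd.DataFrame({"participant_id": np.arange(n), "biomarker_change": x,
                        "y": dirty})
    spec = ModelSpec(interaction="none", covariates=[])
    med = fit_median_regression(tab, "y", spec, n_boot=5, seed=3)
    ols = smf.ols("y ~ biomarker_change", tab).fit()
    med_err = abs(med.coef("biomarker_change")["b"] - 2.0)
    ols_err = abs(ols.params["biomarker_change"] - 2.0)
    assert med_err < 0.08
    assert med_err < ols_err
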