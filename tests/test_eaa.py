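"""Anchored EAA: OLS exactness, outlier rule arithmetic, mixed-model adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eaakit.clocks import score_all
from eaakit.eaa import (
    adjust_mixed,
    compute_eaa_table,
    compute_raw_eaa,
    fit_anchor,
    flag_eaad_outliers,
)
from eaakit.simulate import make_fixture_clocks, simulate_cohort
from eaakit.types import EaakitError

from conftest import hn_config


def make_sheet(n, tissue="healthy", sexes=None, dataset="DS00", ages=None, patients=None):
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "patient_id": patients if patients is not None else [f"p{i}" for i in range(n)],
            "dataset_id": dataset,
            "age_years": ages if ages is not None else rng.uniform(30, 80, n),
            "sex": sexes if sexes is not None else ["female", "male"] * (n // 2) + ["female"] * (n % 2),
            "tissue": tissue,
            "platform": "450k",
        },
        index=[f"s{i}" for i in range(n)],
    )


def test_anchor_identity_relation_recovered_exactly():
    sheet = make_sheet(10)
    ea = pd.Series(sheet["age_years"].to_numpy(), index=sheet.index, name="clk")
    m = fit_anchor(ea, sheet, covariates=("age",))
    assert m.coef["intercept"] == pytest.approx(0.0, abs=1e-10)
    assert m.coef["age"] == pytest.approx(1.0, abs=1e-12)
    resid = compute_raw_eaa(ea, sheet, m)
    assert np.abs(resid).max() < 1e-10


def test_anchor_sex_coefficient_exact():
    sheet = make_sheet(12)
    male = (sheet["sex"] == "male").astype(float)
    ea = pd.Series(sheet["age_years"].to_numpy() + 5.0 * male.to_numpy(),
                   index=sheet.index, name="clk")
    m = fit_anchor(ea, sheet, covariates=("age", "sex"))
    assert m.coef["sex"] == pytest.approx(5.0, abs=1e-10)


def test_anchor_matches_normal_equations_oracle():
    rng = np.random.default_rng(3)
    sheet = make_sheet(40)
    ea = pd.Series(rng.normal(60, 10, 40), index=sheet.index, name="clk")
    m = fit_anchor(ea, sheet, covariates=("age", "sex"))
    X = np.column_stack(
        [np.ones(40), sheet["age_years"], (sheet["sex"] == "male").astype(float)]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ ea.to_numpy())  # direct (XᵀX)⁻¹Xᵀy
    np.testing.assert_allclose(
        [m.coef["intercept"], m.coef["age"], m.coef["sex"]], beta, atol=1e-10
    )


def test_anchor_residuals_sum_to_zero_on_anchor_class():
    rng = np.random.default_rng(4)
    sheet = make_sheet(30)
    ea = pd.Series(rng.normal(60, 8, 30), index=sheet.index, name="clk")
    m = fit_anchor(ea, sheet)
    resid = compute_raw_eaa(ea, sheet, m)
    assert abs(resid.mean()) < 1e-8 * max(1.0, abs(ea).max())


def test_anchor_too_few_samples_errors():
    sheet = make_sheet(2)
    ea = pd.Series([50.0, 60.0], index=sheet.index, name="clk")
    with pytest.raises(EaakitError, match=">= 3"):
        fit_anchor(ea, sheet)


def test_anchor_constant_sex_names_covariate():
    sheet = make_sheet(10, sexes=["female"] * 10)
    ea = pd.Series(np.linspace(40, 70, 10), index=sheet.index, name="clk")
    with pytest.raises(EaakitError, match="sex"):
        fit_anchor(ea, sheet, covariates=("age", "sex"))


def test_raw_eaa_covers_non_anchor_classes():
    """Anchors fit on healthy; planted −5y shift shows in normal-sample EAA."""
    cfg = hn_config(seed=9, samples_per_dataset=200)
    beta, sheet, gt = simulate_cohort(cfg)
    ss = score_all(beta, make_fixture_clocks(gt.clock_cpg_ids, gt, kinds=["linear"]))
    m = fit_anchor(ss.scores.iloc[:, 0], sheet)
    eaa = compute_raw_eaa(ss.scores.iloc[:, 0], sheet, m)
    normal_mean = eaa[sheet.index[sheet["tissue"] == "normal"]].mean()
    assert normal_mean == pytest.approx(-5.0, abs=0.5)


def test_identical_sample_gets_identical_eaa():
    sheet = make_sheet(10)
    ea = pd.Series(np.linspace(40, 70, 10), index=sheet.index, name="clk")
    m = fit_anchor(ea, sheet)
    e1 = compute_raw_eaa(ea, sheet, m)
    dup_sheet = sheet.iloc[[0]].rename(index={"s0": "dup"})
    dup_ea = pd.Series([ea.iloc[0]], index=["dup"], name="clk")
    e2 = compute_raw_eaa(dup_ea, dup_sheet, m)
    assert e2["dup"] == pytest.approx(e1["s0"], abs=1e-12)


# ---------------------------------------------------------------------------
# EAAd outliers

def test_outlier_rule_direct_arithmetic():
    """Column of 99 zeros and one 100: mean 1, SD 10 (ddof=1); only the 100
    exceeds mean + 3·SD."""
    col = np.zeros(100)
    col[-1] = 100.0
    eaad = pd.DataFrame({"c1": col}, index=[f"s{i}" for i in range(100)])
    assert eaad["c1"].mean() == pytest.approx(1.0)
    assert eaad["c1"].std(ddof=1) == pytest.approx(10.0)
    assert flag_eaad_outliers(eaad, k_sd=3.0, min_clocks=1) == ["s99"]


def test_outlier_min_clocks_semantics():
    col = np.zeros(100)
    col[-1] = 100.0
    quiet = np.zeros(100)
    eaad = pd.DataFrame({"c1": col, "c2": quiet}, index=[f"s{i}" for i in range(100)])
    assert flag_eaad_outliers(eaad, min_clocks=2) == []  # flagged in 1 clock only
    assert flag_eaad_outliers(eaad, min_clocks=1) == ["s99"]  # classifier mode


def test_outlier_single_sample_errors():
    with pytest.raises(EaakitError, match="SD"):
        flag_eaad_outliers(pd.DataFrame({"c": [1.0]}, index=["s0"]))


@given(scale=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0))
@settings(max_examples=25, deadline=None)
def test_outlier_rule_affine_invariant(scale, shift):
    rng = np.random.default_rng(5)
    base = rng.normal(size=60)
    base[3] = 25.0  # clear outlier
    eaad = pd.DataFrame({"c": base}, index=[f"s{i}" for i in range(60)])
    scaled = eaad * scale + shift
    assert flag_eaad_outliers(eaad, min_clocks=1) == flag_eaad_outliers(
        scaled, min_clocks=1
    )


# ---------------------------------------------------------------------------
# mixed-model adjustment

def balanced_blup_oracle(y: pd.Series, groups: pd.Series):
    """Closed-form REML/BLUP for a balanced one-way random-intercept layout
    (ANOVA estimators coincide with REML when interior)."""
    k = groups.nunique()
    n_per = len(y) // k
    gmean = y.mean()
    means = y.groupby(groups).mean()
    msb = n_per * ((means - gmean) ** 2).sum() / (k - 1)
    mse = sum(
        ((y[groups == g] - means[g]) ** 2).sum() for g in means.index
    ) / (len(y) - k)
    sigma_b2 = max((msb - mse) / n_per, 0.0)
    shrink = sigma_b2 / (sigma_b2 + mse / n_per) if sigma_b2 > 0 else 0.0
    blup = shrink * (means - gmean)
    return y - gmean - groups.map(blup)


def test_adjust_matches_balanced_reml_oracle():
    rng = np.random.default_rng(6)
    k, n_per = 4, 50
    groups = pd.Series(
        np.repeat([f"DS{i}" for i in range(k)], n_per),
        index=[f"s{i}" for i in range(k * n_per)],
    )
    y = pd.Series(
        rng.normal(0, 1, k * n_per) + groups.map({f"DS{i}": b for i, b in
                                                  enumerate([2.0, -1.0, 0.5, -1.5])}),
        index=groups.index, name="clk",
    )
    sheet = pd.DataFrame(
        {
            "patient_id": groups.index,  # all singletons: patient term dropped
            "dataset_id": groups,
            "age_years": 50.0,
            "sex": "female",
            "tissue": "healthy",
            "platform": "450k",
        }
    )
    adj = adjust_mixed(y, sheet)
    oracle = balanced_blup_oracle(y, groups)
    assert np.abs(adj - oracle).max() < 1e-5


def test_adjust_iid_reduces_to_near_centering():
    """No true group variance: adjusted ≈ raw − grand mean (oracle shrinkage
    is itself tiny, and implementation matches it)."""
    rng = np.random.default_rng(7)
    k, n_per = 4, 60
    groups = pd.Series(
        np.repeat([f"DS{i}" for i in range(k)], n_per),
        index=[f"s{i}" for i in range(k * n_per)],
    )
    y = pd.Series(rng.normal(0, 1, k * n_per), index=groups.index, name="clk")
    sheet = pd.DataFrame(
        {"patient_id": groups.index, "dataset_id": groups, "age_years": 50.0,
         "sex": "female", "tissue": "healthy", "platform": "450k"}
    )
    adj = adjust_mixed(y, sheet)
    oracle = balanced_blup_oracle(y, groups)
    assert np.abs(adj - oracle).max() < 1e-5


def test_adjust_single_group_no_repeats_centering_only():
    sheet = make_sheet(10)
    y = pd.Series(np.arange(10, dtype=float), index=sheet.index, name="clk")
    adj = adjust_mixed(y, sheet)
    np.testing.assert_allclose(adj, y - y.mean(), atol=1e-12)


def test_adjust_duplicate_cohort_copies_agree():
    """Duplicating the cohort under new dataset IDs with a +10 offset leaves
    the two copies' conditional residuals nearly identical."""
    rng = np.random.default_rng(8)
    sheet = make_sheet(80, dataset="DS00")
    sheet.loc[sheet.index[40:], "dataset_id"] = "DS01"
    y = pd.Series(rng.normal(0, 2, 80), index=sheet.index, name="clk")
    sheet2 = sheet.copy()
    sheet2.index = [f"{s}_b" for s in sheet.index]
    sheet2["dataset_id"] = sheet2["dataset_id"] + "_b"
    sheet2["patient_id"] = sheet2["patient_id"] + "_b"
    y2 = pd.Series(y.to_numpy() + 10.0, index=sheet2.index, name="clk")
    adj = adjust_mixed(pd.concat([y, y2]), pd.concat([sheet, sheet2]))
    assert np.abs(adj.loc[y.index].to_numpy() - adj.loc[y2.index].to_numpy()).max() < 0.1


def test_adjust_removes_batch_offsets():
    cfg = hn_config(
        seed=13, n_datasets=5, samples_per_dataset=150, batch_sd=3.0,
        group_shift={"healthy": 0.0, "normal": 0.0, "tumour": 0.0, "adenoma": 0.0},
    )
    beta, sheet, gt = simulate_cohort(cfg)
    ss = score_all(beta, make_fixture_clocks(gt.clock_cpg_ids, gt, kinds=["linear"]))
    res = compute_eaa_table(ss, sheet)
    ds_means = res.eaa.iloc[:, 0].groupby(res.sheet["dataset_id"]).mean()
    assert np.abs(ds_means).max() < 0.5
    raw_means = res.eaa_raw.iloc[:, 0].groupby(res.sheet["dataset_id"]).mean()
    assert raw_means.std() > np.abs(ds_means).max()  # adjustment did real work


def test_adjust_with_repeated_patients_shrinks_pairs():
    """Paired tumour/normal samples share a patient intercept; the patient
    term is exercised and the fit stays finite."""
    cfg = hn_config(
        seed=21,
        tissue_proportions={"healthy": 0.4, "normal": 0.3, "tumour": 0.3, "adenoma": 0.0},
        paired_fraction=1.0,
    )
    beta, sheet, gt = simulate_cohort(cfg)
    assert (sheet["patient_id"].value_counts() > 1).any()
    ss = score_all(beta, make_fixture_clocks(gt.clock_cpg_ids, gt, kinds=["linear"]))
    res = compute_eaa_table(ss, sheet)
    assert np.isfinite(res.eaa.to_numpy()).all()


def test_eaa_linearity_under_frozen_anchor():
    """With a frozen anchor, shifting every EA by +c shifts every EAA by +c."""
    sheet = make_sheet(20)
    rng = np.random.default_rng(9)
    ea = pd.Series(rng.normal(60, 10, 20), index=sheet.index, name="clk")
    m = fit_anchor(ea, sheet)
    base = compute_raw_eaa(ea, sheet, m)
    shifted = compute_raw_eaa(ea + 7.5, sheet, m)
    np.testing.assert_allclose(shifted - base, 7.5, atol=1e-10)
    # with a refit anchor the intercept absorbs the shift exactly
    m2 = fit_anchor(ea + 7.5, sheet)
    refit = compute_raw_eaa(ea + 7.5, sheet, m2)
    np.testing.assert_allclose(refit, base, atol=1e-8)
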