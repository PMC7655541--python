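"""ANOVA against a brute-force oracle; Tukey, correlations, diagnostics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from nodulepipe import stats, synth


def _brute_force_ss(table, trait, log=False):
    """Independent sums-of-squares computation from raw loops."""
    y = np.log(table[trait].to_numpy()) if log else table[trait].to_numpy(dtype=float)
    blocks = sorted(table["block"].unique())
    trts = sorted(table["treatment"].unique())
    b, t = len(blocks), len(trts)
    s = len(table) // (b * t)
    grand = y.mean()
    ss = {}
    bm = {blk: y[(table["block"] == blk).to_numpy()].mean() for blk in blocks}
    tm = {trt: y[(table["treatment"] == trt).to_numpy()].mean() for trt in trts}
    pm = {}
    for blk in blocks:
        for trt in trts:
            sel = ((table["block"] == blk) & (table["treatment"] == trt)).to_numpy()
            pm[(blk, trt)] = y[sel].mean()
    ss["blocks"] = t * s * sum((bm[blk] - grand) ** 2 for blk in blocks)
    ss["treatments"] = b * s * sum((tm[trt] - grand) ** 2 for trt in trts)
    ss["experimental_error"] = s * sum(
        (pm[(blk, trt)] - bm[blk] - tm[trt] + grand) ** 2
        for blk in blocks for trt in trts
    )
    resid = 0.0
    for i in range(len(table)):
        key = (table["block"].iloc[i], table["treatment"].iloc[i])
        resid += (y[i] - pm[key]) ** 2
    ss["sampling_error"] = resid
    return ss


@pytest.fixture(scope="module")
def table():
    return synth.generate_phenotypes(synth.DesignSpec(seed=42))


def test_anova_matches_brute_force_oracle(table):
    fit = stats.fit_rcbd_subsampling(table, "trait", log_transform=True)
    oracle = _brute_force_ss(table, "trait", log=True)
    for src in stats.SOURCES:
        assert fit.ss[src] == pytest.approx(oracle[src], rel=1e-8)
        assert fit.ms[src] == pytest.approx(oracle[src] / fit.df[src], rel=1e-8)
    assert fit.df == {
        "blocks": 2, "treatments": 2, "experimental_error": 4,
        "sampling_error": 3 * 3 * 29,
    }


def test_df_and_ss_bookkeeping(table):
    fit = stats.fit_rcbd_subsampling(table, "trait", log_transform=True)
    n = len(table)
    assert sum(fit.df.values()) == n - 1
    y = np.log(table["trait"])
    total_ss = float(((y - y.mean()) ** 2).sum())
    assert sum(fit.ss.values()) == pytest.approx(total_ss, rel=1e-10)


def test_treatment_f_uses_experimental_error_stratum(table):
    fit = stats.fit_rcbd_subsampling(table, "trait", log_transform=True)
    assert fit.f_treatment == pytest.approx(
        fit.ms["treatments"] / fit.ms["experimental_error"], rel=1e-12
    )
    # the (wrong) sampling-error denominator would give a different F
    assert fit.f_treatment != pytest.approx(
        fit.ms["treatments"] / fit.ms["sampling_error"], rel=1e-3
    )


def test_zero_subsample_sd_degenerate_case():
    spec = synth.DesignSpec(subsample_sd=0.0, seed=7)
    tab = synth.generate_phenotypes(spec)
    fit = stats.fit_rcbd_subsampling(tab, "trait", log_transform=True)
    assert fit.ms["sampling_error"] == pytest.approx(0.0, abs=1e-18)
    # other strata still match the brute-force oracle
    oracle = _brute_force_ss(tab, "trait", log=True)
    for src in ("blocks", "treatments", "experimental_error"):
        assert fit.ss[src] == pytest.approx(oracle[src], rel=1e-8)


def test_log_requires_positive_values(table):
    bad = table.copy()
    bad.loc[bad.index[3], "trait"] = -1.0
    with pytest.raises(ValueError, match="offending rows"):
        stats.fit_rcbd_subsampling(bad, "trait", log_transform=True)


def test_unbalanced_design_rejected(table):
    unbal = table.iloc[:-1]
    with pytest.raises(ValueError, match="unbalanced"):
        stats.fit_rcbd_subsampling(unbal, "trait")


def test_scale_equivariance_under_log(table):
    fit1 = stats.fit_rcbd_subsampling(table, "trait", log_transform=True)
    scaled = table.copy()
    scaled["trait"] = scaled["trait"] * 7.3
    fit2 = stats.fit_rcbd_subsampling(scaled, "trait", log_transform=True)
    assert fit2.f_treatment == pytest.approx(fit1.f_treatment, rel=1e-9)
    for src in stats.SOURCES:
        assert fit2.ss[src] == pytest.approx(fit1.ss[src], rel=1e-8, abs=1e-12)


def test_power_increases_with_effect_size():
    rates = []
    for effect in (0.0, 0.4, 0.8):
        hits = 0
        for seed in range(60):
            spec = synth.DesignSpec(
                treatment_effects=(0.0, 0.0, effect),
                block_sd=0.5, plot_sd=0.15, subsample_sd=0.3, seed=1000 + seed,
            )
            tab = synth.generate_phenotypes(spec)
            fit = stats.fit_rcbd_subsampling(tab, "trait", log_transform=True)
            hits += fit.p_treatment < 0.05
        rates.append(hits / 60)
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] > rates[0]


# ---------------------------------------------------------------------------
# Tukey
# ---------------------------------------------------------------------------


def test_tukey_symmetric_unit_diagonal(table):
    fit = stats.fit_rcbd_subsampling(table, "trait", log_transform=True)
    p = stats.tukey_pairwise(fit, table, "trait")
    arr = p.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 1.0)


def test_tukey_identical_means_p_near_one():
    spec = synth.DesignSpec(
        treatment_effects=(0.0, 0.0, 0.0), plot_sd=0.2, subsample_sd=0.3, seed=3,
    )
    tab = synth.generate_phenotypes(spec)
    fit = stats.fit_rcbd_subsampling(tab, "trait", log_transform=True)
    p = stats.tukey_pairwise(fit, tab, "trait")
    assert p.loc["T1", "T2"] > 0.05  # no real differences to find


def test_tukey_detects_large_shift():
    spec = synth.DesignSpec(
        treatment_effects=(0.0, 0.0, 2.0),  # 5+ SD shift for T3
        block_sd=0.5, plot_sd=0.1, subsample_sd=0.3, seed=11,
    )
    tab = synth.generate_phenotypes(spec)
    fit = stats.fit_rcbd_subsampling(tab, "trait", log_transform=True)
    p = stats.tukey_pairwise(fit, tab, "trait")
    assert p.loc["T3", "T1"] < 0.01
    assert p.loc["T3", "T2"] < 0.01
    assert p.loc["T1", "T2"] > 0.05


# ---------------------------------------------------------------------------
# Correlations / stars / weighted fit / diagnostics
# ---------------------------------------------------------------------------


def test_hand_pearson_value():
    tab = pd.DataFrame(
        {
            "treatment": ["T1"] * 5,
            "x": [1.0, 2.0, 3.0, 4.0, 5.0],
            "y": [2.0, 1.0, 4.0, 3.0, 5.0],
        }
    )
    out = stats.treatment_correlations(tab, ["x", "y"])
    assert len(out) == 1
    assert out["r"].iloc[0] == pytest.approx(0.8)


def test_exact_linear_dependence_r_one(table):
    tab = table.copy()
    tab["double"] = 2.0 * tab["trait"]
    out = stats.treatment_correlations(tab, ["trait", "double"])
    assert np.allclose(out["r"], 1.0)
    assert (out["stars"] == "***").all()


def test_constant_trait_reported_missing(table):
    tab = table.copy()
    tab["const"] = 1.0
    out = stats.treatment_correlations(tab, ["trait", "const"])
    assert out["r"].isna().all()
    assert (out["stars"] == "").all()


def test_significance_stars_breakpoints():
    assert stats.significance_stars(0.0005) == "***"
    assert stats.significance_stars(0.005) == "**"
    assert stats.significance_stars(0.04) == "*"
    assert stats.significance_stars(0.2) == ""
    assert stats.significance_stars(float("nan")) == ""


def test_weighted_fit_power_zero_matches_anova(table):
    fit = stats.fit_rcbd_subsampling(table, "trait", log_transform=True)
    wls = stats.fit_plot_means_weighted(
        table, "trait", log_transform=True, variance_power=0.0
    )
    assert wls["f_treatment"] == pytest.approx(fit.f_treatment, rel=1e-9)
    assert wls["p_treatment"] == pytest.approx(fit.p_treatment, rel=1e-9)


def test_diagnostics_residual_identities(table):
    fit = stats.fit_rcbd_subsampling(table, "trait", log_transform=True)
    d = stats.diagnostics(fit, table, "trait")
    # sampling residuals sum to zero within every plot (least squares)
    work = table.copy()
    work["resid"] = d.residuals
    sums = work.groupby(["block", "treatment"])["resid"].sum()
    assert np.allclose(sums, 0.0, atol=1e-9)
    assert len(d.qq_observed) == fit.n_blocks * fit.n_treatments
    assert np.all(np.diff(d.qq_observed) >= 0)
    assert 0.0 <= d.shapiro_p <= 1.0
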