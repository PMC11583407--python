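"""Repeated-measures ANOVA, Tukey HSD, BH FDR, bias summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcompare import SimulationConfig, generate_dataset
from methcompare.array_bias import (fit_array_anova, fit_array_anova_matrix,
                                    tukey_hsd, tukey_hsd_matrix, adjust_fdr,
                                    array_bias_table, summarize_bias,
                                    studentized_range_sf)
from methcompare.pipeline import _primary_beta

# aov(beta ~ array + donor) + TukeyHSD computed in R 4.3.3 on the seeded
# 3-array x 6-donor table below (rng = default_rng(20240501), uniform(0.2, 0.8),
# rounded to 6 decimals)
R_FIXTURE = np.round(np.random.default_rng(20240501)
                     .uniform(0.2, 0.8, size=(3, 6)), 6)
R_F, R_P = 1.464550034259, 0.276795175348
R_TUKEY = {  # (a2 - a1, a3 - a1, a3 - a2): diff, adjusted p
    ("a1", "a2"): (-0.0165806666666666, 0.9841931989337225),
    ("a1", "a3"): (-0.1520168333333333, 0.3062252519326687),
    ("a2", "a3"): (-0.1354361666666667, 0.3821625320371417),
}


def _long(values):
    rows = []
    for ai in range(values.shape[0]):
        for di in range(values.shape[1]):
            rows.append({"beta": values[ai, di], "array": f"a{ai + 1}",
                         "donor": f"d{di + 1}"})
    return pd.DataFrame(rows)


def anova_oracle(values):
    """From-definitions sums-of-squares decomposition (loops, no algebra)."""
    a, n = values.shape
    grand = values.mean()
    ssa = sum(n * (values[i].mean() - grand) ** 2 for i in range(a))
    ssd = sum(a * (values[:, j].mean() - grand) ** 2 for j in range(n))
    sst = ((values - grand) ** 2).sum()
    sse = sst - ssa - ssd
    return (ssa / (a - 1)) / (sse / ((a - 1) * (n - 1)))


def test_identical_arrays_give_null_anova_and_tukey():
    vals = np.tile(np.array([0.2, 0.5, 0.8, 0.4]), (3, 1))
    fit = fit_array_anova(_long(vals))
    assert fit.f_stat == 0.0
    assert fit.p_value == 1.0
    tk = tukey_hsd(fit)
    assert np.allclose(tk["mean_diff"], 0.0)
    assert np.allclose(tk["adj_p"], 1.0)


def test_anova_f_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        vals = rng.uniform(0, 1, size=(3, 3))
        fit = fit_array_anova(_long(vals))
        assert fit.f_stat == pytest.approx(anova_oracle(vals), rel=1e-10)


def test_anova_and_tukey_match_frozen_r_oracle():
    fit = fit_array_anova(_long(R_FIXTURE))
    assert fit.f_stat == pytest.approx(R_F, abs=1e-9)
    assert fit.p_value == pytest.approx(R_P, abs=1e-9)
    tk = tukey_hsd(fit).set_index(["array_a", "array_b"])
    for pair, (diff, adj_p) in R_TUKEY.items():
        assert tk.loc[pair, "mean_diff"] == pytest.approx(diff, abs=1e-9)
        assert tk.loc[pair, "adj_p"] == pytest.approx(adj_p, abs=1e-6)


def test_two_array_tukey_reduces_to_paired_t():
    rng = np.random.default_rng(17)
    vals = rng.uniform(0.2, 0.8, size=(2, 12))
    fit = fit_array_anova(_long(vals))
    tk = tukey_hsd(fit)
    d = vals[0] - vals[1]
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    p_paired = 2 * stats.t.sf(abs(t), len(d) - 1)
    assert tk["adj_p"].iloc[0] == pytest.approx(p_paired, abs=1e-6)
    # studentized range statistic is sqrt(2) * |t|
    q = abs(tk["mean_diff"].iloc[0]) / np.sqrt(fit.mse / fit.n_per_group)
    assert q == pytest.approx(np.sqrt(2) * abs(t), rel=1e-10)


def test_unbalanced_design_falls_back_with_warning():
    df = _long(np.random.default_rng(2).uniform(0, 1, size=(3, 5)))
    df = df.iloc[:-1]  # drop one cell
    with pytest.warns(UserWarning, match="type-II"):
        fit = fit_array_anova(df)
    assert np.isfinite(fit.f_stat) and 0 < fit.p_value <= 1
    assert not fit.balanced


def test_matrix_path_agrees_with_per_probe_fit():
    rng = np.random.default_rng(9)
    cube = rng.uniform(0, 1, size=(15, 3, 6))
    mat = fit_array_anova_matrix(cube)
    for p in range(15):
        fit = fit_array_anova(_long(cube[p]))
        assert mat["f_stat"].iloc[p] == pytest.approx(fit.f_stat, rel=1e-10)
        assert mat["p_value"].iloc[p] == pytest.approx(fit.p_value, rel=1e-8)


def test_injected_offset_detected_as_noise_vanishes():
    rng = np.random.default_rng(21)
    base = rng.uniform(0.3, 0.7, size=12)
    vals = np.vstack([base, base + 0.05, base])
    vals += rng.normal(0, 1e-4, size=vals.shape)
    fit = fit_array_anova(_long(vals))
    assert fit.p_value < 1e-10


def test_studentized_range_sf_matches_scipy():
    rng = np.random.default_rng(4)
    for k, df in [(2, 5), (3, 58), (4, 20)]:
        q = rng.uniform(0.05, 7.0, size=5)
        mine = studentized_range_sf(q, k, df)
        ref = stats.studentized_range.sf(q, k, df)
        assert np.allclose(mine, ref, atol=1e-6)


class TestAdjustFdr:
    def test_hand_computed_step_up(self):
        assert np.allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_null_cases(self):
        assert adjust_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(ValueError):
                adjust_fdr(bad)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        for _ in range(10):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(3, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(adjust_fdr(p), ref, atol=1e-12)

    def test_preserves_order_monotonicity(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(1e-8, 1, 100)
        q = adjust_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


def test_bias_table_and_summary_on_null_data():
    ds = generate_dataset(SimulationConfig(
        n_cpg=200, seed=6, array_bias_sd=0.0, noise_sd=0.01,
        n_sex_cpgs=0, n_replicate_probes=0))
    betas = {a: _primary_beta(ds, a) for a in ds.betas}
    tab = array_bias_table(betas, ds.samples, probes=ds.truth.shared_probes)
    assert (tab["q_value"] >= tab["p_value"] - 1e-15).all()
    summ = summarize_bias(tab)
    assert summ["n_probes"] == len(ds.truth.shared_probes)
    assert summ["n_big_diff"] == 0
    # under the null very few probes should survive FDR
    assert summ["n_significant"] <= 0.05 * summ["n_probes"]


def test_summarize_bias_zero_difference_table():
    tab = pd.DataFrame({"q_value": [1.0, 1.0], "max_abs_diff": [0.0, 0.0]})
    summ = summarize_bias(tab)
    assert summ["median_pct_diff"] == 0.0
    assert summ["mean_pct_diff"] == 0.0
    assert summ["n_big_diff"] == 0


def test_tukey_matrix_antisymmetry_and_max_abs():
    rng = np.random.default_rng(33)
    cube = rng.uniform(0.2, 0.8, size=(10, 3, 8))
    out = tukey_hsd_matrix(cube, ["x", "y", "z"])
    diffs = out[[c for c in out.columns if c.startswith("diff_")]].to_numpy()
    assert np.allclose(out["max_abs_diff"], np.abs(diffs).max(axis=1))
    # mean_diff(a,b) = -(mean of b minus a): check via recomputation
    means = cube.mean(axis=2)
    assert np.allclose(out["diff_x_y"], means[:, 0] - means[:, 1])
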