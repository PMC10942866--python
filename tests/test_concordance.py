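"""Enrichment coefficients, rmcorr, log-Pearson and repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evascites.concordance import (
    enrichment_coefficient,
    pearson_log,
    rm_anova,
    rm_anova_ec,
    rmcorr,
)
from evascites.deconvolution import relative_contribution


def _contrib_frame(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "cell_type", "mean_intensity", "contribution_pct"]
    )


def _cells_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "cell_type", "proportion"])


TYPES = ("malignant", "fibroblast", "macrophage")


def test_enrichment_identity_and_arithmetic():
    contrib = _contrib_frame(
        [("P1", ct, 1.0, pct) for ct, pct in zip(TYPES, (50.0, 25.0, 25.0))]
    )
    cells = _cells_frame(
        [("P1", ct, pr) for ct, pr in zip(TYPES, (0.25, 0.25, 0.50))]
    )
    res = enrichment_coefficient(contrib, cells)
    lut = {
        (r["patient_id"], r["cell_type"]): r["ec"] for _, r in res.table.iterrows()
    }
    assert lut[("P1", "malignant")] == pytest.approx(2.0)
    assert lut[("P1", "fibroblast")] == pytest.approx(1.0)
    assert lut[("P1", "macrophage")] == pytest.approx(0.5)


def test_enrichment_zero_cells_undefined_and_excluded():
    contrib = _contrib_frame(
        [("P1", ct, 1.0, pct) for ct, pct in zip(TYPES, (50.0, 50.0, 0.0))]
    )
    cells = _cells_frame(
        [("P1", ct, pr) for ct, pr in zip(TYPES, (0.5, 0.5, 0.0))]
    )
    res = enrichment_coefficient(contrib, cells)
    assert res.n_undefined == 1
    assert np.isnan(res.type_means["macrophage"])


def test_enrichment_requires_shared_patients():
    contrib = _contrib_frame([("P1", "malignant", 1.0, 100.0)])
    cells = _cells_frame([("P9", "malignant", 1.0)])
    with pytest.raises(ValueError, match="shared"):
        enrichment_coefficient(contrib, cells)


def test_rmcorr_perfect_common_slopes():
    """y = 2x + subject offset gives r_rm = 1; y = -x gives -1."""
    x = np.tile(np.arange(4.0), 3)
    subject = np.repeat(["a", "b", "c"], 4)
    offsets = np.repeat([0.0, 10.0, -5.0], 4)
    up = rmcorr(x, 2 * x + offsets, subject)
    assert up.r_rm == pytest.approx(1.0)
    down = rmcorr(x, -x + offsets, subject)
    assert down.r_rm == pytest.approx(-1.0)


def test_rmcorr_matches_dummy_regression_oracle(rng):
    """r, df and p agree with the explicit normal-equations ANCOVA to 1e-9."""
    n_sub, n_rep = 6, 5
    subject = np.repeat(np.arange(n_sub), n_rep)
    x = rng.normal(size=n_sub * n_rep)
    y = 0.6 * x + rng.normal(size=n_sub * n_rep) + np.repeat(rng.normal(size=n_sub), n_rep)
    res = rmcorr(x, y, subject)

    dummies = np.eye(n_sub)[subject]
    full = np.column_stack([dummies, x])
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    sse_full = np.sum((y - full @ beta) ** 2)
    beta0, *_ = np.linalg.lstsq(dummies, y, rcond=None)
    sse_red = np.sum((y - dummies @ beta0) ** 2)
    ss_x = sse_red - sse_full
    r_expected = np.sign(beta[-1]) * np.sqrt(ss_x / (ss_x + sse_full))
    df = n_sub * n_rep - n_sub - 1
    t = r_expected * np.sqrt(df / (1 - r_expected**2))
    p_expected = 2 * stats.t.sf(abs(t), df)
    assert res.r_rm == pytest.approx(r_expected, abs=1e-9)
    assert res.df == df
    assert res.p_value == pytest.approx(p_expected, abs=1e-9)


def test_rmcorr_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(42)
    subject = np.repeat(np.arange(7), 4)
    x = rng.normal(size=28) + subject * 0.3
    y = 0.5 * x + rng.normal(size=28) * 0.7 + subject * 1.1
    res = rmcorr(x, y, subject)
    df = pd.DataFrame({"x": x, "y": y, "s": subject})
    ref = pg.rm_corr(data=df, x="x", y="y", subject="s")
    assert res.r_rm == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert res.df == int(ref["dof"].iloc[0])
    assert res.p_value == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-8)


def test_rmcorr_pooled_equals_pearson_with_identical_offsets():
    """Subjects sharing one intercept: r_rm equals pooled Pearson r."""
    rng = np.random.default_rng(11)
    x = rng.normal(size=24)
    y = 0.8 * x + rng.normal(size=24) * 0.4  # no subject offsets at all
    subject = np.repeat(np.arange(6), 4)
    res = rmcorr(x, y, subject)
    # same-slope model with equal intercepts: compare against Pearson of
    # within-subject centered data (the pooled analogue)
    xc = x - np.repeat([x[subject == s].mean() for s in range(6)], 4)
    yc = y - np.repeat([y[subject == s].mean() for s in range(6)], 4)
    r_pooled = np.corrcoef(xc, yc)[0, 1]
    assert res.r_rm == pytest.approx(r_pooled, abs=1e-9)


def test_rmcorr_degenerate_constant_x():
    x = np.repeat([1.0, 2.0], 3)  # constant within each subject
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    subject = np.repeat(["a", "b"], 3)
    res = rmcorr(x, y, subject)
    assert res.degenerate
    assert np.isnan(res.r_rm)


def test_rmcorr_input_validation():
    with pytest.raises(ValueError, match="two subjects"):
        rmcorr([1, 2, 3], [1, 2, 3], ["a", "a", "a"])
    with pytest.raises(ValueError, match="at least two observations"):
        rmcorr([1, 2, 3], [1, 2, 3], ["a", "a", "b"])


def _paired_frames(rng, n_genes=50, n_pat=4):
    genes = [f"G{i}" for i in range(n_genes)]
    pats = [f"P{i}" for i in range(n_pat)]
    u = pd.DataFrame(
        np.exp(rng.normal(10, 1, size=(n_genes, n_pat))), index=genes, columns=pats
    )
    return u, genes, pats


def test_pearson_log_scaling_gives_r_one(rng):
    u, genes, pats = _paired_frames(rng)
    s = u * 7.5  # positive scaling is a log-shift
    res = pearson_log(u, s)
    assert res.r == pytest.approx(1.0)
    assert res.n_pairs == u.size


def test_pearson_log_inverse_relation_gives_minus_one(rng):
    u, genes, pats = _paired_frames(rng)
    s = 1.0 / u
    assert pearson_log(u, s).r == pytest.approx(-1.0)


def test_pearson_log_independent_near_zero():
    rng = np.random.default_rng(0)
    n = 40_000
    u = pd.DataFrame(np.exp(rng.normal(size=(n, 1))), columns=["P1"])
    s = pd.DataFrame(np.exp(rng.normal(size=(n, 1))), columns=["P1"])
    res = pearson_log(u, s)
    assert abs(res.r) < 3 / np.sqrt(n)


def test_pearson_log_excludes_zero_pairs_and_scale_invariance(rng):
    u, genes, pats = _paired_frames(rng, n_genes=30)
    s = u ** 1.3
    u.iloc[0, 0] = 0.0
    s.iloc[1, 1] = 0.0
    res = pearson_log(u, s)
    assert res.n_pairs == u.size - 2
    res_scaled = pearson_log(u * 3.0, s * 0.1)
    assert res_scaled.r == pytest.approx(res.r, abs=1e-12)


def test_pearson_log_too_few_pairs():
    u = pd.DataFrame({"P1": [1.0, 0.0, 2.0]})
    s = pd.DataFrame({"P1": [1.0, 1.0, 0.0]})
    with pytest.raises(ValueError, match="fewer than 3"):
        pearson_log(u, s)


def test_rm_anova_all_equal_gives_f_zero():
    vals = pd.DataFrame(
        {"a": [3.0, 4.0, 5.0], "b": [3.0, 4.0, 5.0], "c": [3.0, 4.0, 5.0]},
        index=["s1", "s2", "s3"],
    )
    res = rm_anova(vals)
    assert res.F == 0.0
    assert res.p_value == 1.0


def test_rm_anova_two_conditions_equals_squared_paired_t(rng):
    vals = pd.DataFrame(
        rng.normal(size=(9, 2)), columns=["a", "b"],
        index=[f"s{i}" for i in range(9)],
    )
    res = rm_anova(vals)
    t, p = stats.ttest_rel(vals["a"], vals["b"])
    assert res.F == pytest.approx(float(t) ** 2, abs=1e-9)
    assert res.p_value == pytest.approx(float(p), abs=1e-9)


def test_rm_anova_matches_ss_oracle(rng):
    data = rng.normal(size=(8, 4))
    vals = pd.DataFrame(data, columns=list("abcd"), index=[f"s{i}" for i in range(8)])
    res = rm_anova(vals)
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * ((data.mean(0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(1) - grand) ** 2).sum()
    ss_err = ((data - grand) ** 2).sum() - ss_cond - ss_subj
    f_expected = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    assert res.F == pytest.approx(f_expected, rel=1e-12)
    assert (res.df1, res.df2) == (k - 1, (k - 1) * (n - 1))


def test_rm_anova_drops_incomplete_subjects(rng):
    vals = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"),
                        index=[f"s{i}" for i in range(5)])
    vals.loc["s0", "b"] = np.nan
    res = rm_anova(vals)
    assert res.dropped_subjects == {"s0"}
    assert res.n_subjects == 4


def test_ec_closed_form_on_noiseless_generator():
    """With noiseless intensities and exact FC proportions, every EC is 1."""
    from evascites.deconvolution import crop_panel
    from evascites.simulate import SyntheticConfig, generate

    cfg = SyntheticConfig(
        seed=3, log_intensity_sigma=0.0, log_intensity_sigma_gene=0.0, fc_noise=0.0
    ).without_dropout()
    ds = generate(cfg)
    panel = crop_panel(ds.panel_raw, k=cfg.k_markers)
    contrib = relative_contribution(ds.intensities, panel, "U")
    res = enrichment_coefficient(contrib, ds.fc_proportions)
    assert np.allclose(res.table["ec"].to_numpy(), 1.0, atol=1e-9)
    anova = rm_anova_ec(res)
    assert anova.F == pytest.approx(0.0, abs=1e-12)
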