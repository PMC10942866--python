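"""Log-rank, univariate Cox (Efron), cutoff scan and marker selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from evascites.containers import MarkerPanel
from evascites.deconvolution import crop_panel
from evascites.simulate import SyntheticConfig, generate, simulate_survival_cohort
from evascites.survival import (
    SurvivalCutoffScan,
    _cox_efron_loglik_derivs,
    cox_univariate_binary,
    cutoff_scan,
    logrank_test,
    select_survival_markers,
)
from conftest import random_matrix


# -- log-rank ----------------------------------------------------------------


def test_logrank_identical_groups_is_null():
    t = np.array([2.0, 5.0, 7.0, 2.0, 5.0, 7.0])
    e = np.ones(6, dtype=bool)
    g = np.array([0, 0, 0, 1, 1, 1])
    chi2, p = logrank_test(t, e, g)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_hand_worked_four_subject_table():
    """times {1,2,3,4}, all events, groups A={1,2}, B={3,4}.

    O-E = (1-.5) + (1-1/3) = 7/6; V = 1/4 + 2/9 = 17/36;
    chi2 = (7/6)^2 / (17/36) = 49/17.
    """
    chi2, p = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 0, 0])
    assert chi2 == pytest.approx(49 / 17, abs=1e-12)
    assert p == pytest.approx(stats.chi2.sf(49 / 17, 1), abs=1e-12)


def test_logrank_invariant_to_group_relabeling(rng):
    t = rng.exponential(10, 20)
    e = rng.random(20) < 0.7
    g = rng.integers(0, 2, 20)
    if not (e & (g == 1)).any() or not (e & (g == 0)).any():
        pytest.skip("degenerate draw")
    chi2_a, p_a = logrank_test(t, e, g)
    chi2_b, p_b = logrank_test(t, e, 1 - g)
    assert chi2_a == pytest.approx(chi2_b, abs=1e-12)
    assert p_a == pytest.approx(p_b, abs=1e-12)


def test_logrank_matches_lifelines_with_ties():
    ll = pytest.importorskip("lifelines.statistics")
    rng = np.random.default_rng(77)
    for _ in range(20):
        n = int(rng.integers(8, 40))
        t = rng.exponential(20, n).round(0) + 1.0  # heavy ties
        g = rng.integers(0, 2, n)
        e = rng.random(n) < 0.8
        if g.sum() in (0, n) or not e.any():
            continue
        chi2, p = logrank_test(t, e, g)
        ref = ll.logrank_test(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-10)
        assert p == pytest.approx(ref.p_value, abs=1e-10)


def test_logrank_requires_events_and_two_groups():
    with pytest.raises(ValueError, match="event"):
        logrank_test([1, 2], [0, 0], [0, 1])
    with pytest.raises(ValueError, match="non-empty"):
        logrank_test([1, 2], [1, 1], [1, 1])


# -- Cox ---------------------------------------------------------------------


def test_cox_exchangeable_groups_hr_one():
    t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    e = np.ones(6, dtype=bool)
    g = np.array([1, 1, 1, 0, 0, 0])
    res = cox_univariate_binary(t, e, g)
    assert res.hr == pytest.approx(1.0, abs=1e-6)


def test_cox_matches_golden_section_of_partial_likelihood(rng):
    """Newton beta equals the 1-D maximizer of the coded Efron partial
    likelihood to 1e-6, with and without ties."""
    for rounded in (False, True):
        for _ in range(10):
            n = int(rng.integers(10, 40))
            t = rng.exponential(15, n)
            if rounded:
                t = t.round(0) + 1.0
            g = rng.integers(0, 2, n)
            e = rng.random(n) < 0.8
            if not (e & (g == 1)).any() or not (e & (g == 0)).any():
                continue
            res = cox_univariate_binary(t, e, g)
            neg = lambda b: -_cox_efron_loglik_derivs(b, t, e, g)[0]
            ref = minimize_scalar(neg, bounds=(-12, 12), method="bounded",
                                  options={"xatol": 1e-10})
            assert res.beta == pytest.approx(ref.x, abs=1e-6)


def test_cox_matches_lifelines_efron():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(5)
    n = 60
    t = rng.exponential(20, n).round(1) + 0.1
    g = rng.integers(0, 2, n)
    e = rng.random(n) < 0.75
    res = cox_univariate_binary(t, e, g)
    cph = lifelines.CoxPHFitter().fit(
        pd.DataFrame({"t": t, "e": e.astype(int), "g": g}), "t", "e"
    )
    assert res.beta == pytest.approx(float(cph.params_["g"]), abs=1e-3)
    assert res.se_log_hr == pytest.approx(float(cph.standard_errors_["g"]), abs=1e-3)


def test_cox_monotone_likelihood_flagged():
    t = np.array([1.0, 2.0, 10.0, 11.0])
    e = np.array([True, True, False, False])
    g = np.array([1, 1, 0, 0])  # all events in the high group
    res = cox_univariate_binary(t, e, g)
    assert res.monotone
    assert res.hr == np.inf
    res_lo = cox_univariate_binary(t, e, 1 - g)
    assert res_lo.monotone and res_lo.hr == 0.0


def test_cox_recovers_planted_hazard_ratio():
    """Planted HR=3 at n=500: estimate within 3 SE of log 3."""
    cohort = simulate_survival_cohort(n=500, hr=3.0, seed=2024)
    res = cox_univariate_binary(
        cohort["os_months"], cohort["event"].astype(bool), cohort["group"]
    )
    assert abs(res.beta - np.log(3.0)) < 3 * res.se_log_hr


def test_cox_sign_recovery_rate():
    """At n=200, HR=3 the direction is recovered in >= 95% of replicates."""
    correct = 0
    reps = 60
    for i in range(reps):
        c = simulate_survival_cohort(n=200, hr=3.0, seed=9000 + i)
        res = cox_univariate_binary(
            c["os_months"], c["event"].astype(bool), c["group"]
        )
        correct += res.beta > 0
    assert correct / reps >= 0.95


# -- cutoff scan -------------------------------------------------------------


def _clin(times, events, patients=None):
    patients = patients or [f"P{i}" for i in range(len(times))]
    return pd.DataFrame(
        {"patient_id": patients, "os_months": times, "event": events}
    )


def test_cutoff_scan_single_admissible_cutoff():
    """Six distinct values with min_group=3 admit only the middle split."""
    values = pd.Series([1.0, 2, 3, 4, 5, 6], index=[f"P{i}" for i in range(6)])
    clin = _clin([5, 8, 12, 20, 25, 30], [1, 1, 1, 0, 1, 0])
    res = cutoff_scan(values, clin, min_group=3, floor=None)
    assert not res.empty
    assert res.cutoff == pytest.approx(3.5)
    assert res.n_high == 3 and res.n_low == 3
    assert res.n_candidates == 1


def test_cutoff_scan_floor_excludes_everything():
    values = pd.Series([10.0, 20, 30, 40, 50, 60], index=[f"P{i}" for i in range(6)])
    clin = _clin([5, 8, 12, 20, 25, 30], [1, 1, 1, 1, 1, 1])
    res = cutoff_scan(values, clin, min_group=3, floor=1e5)
    assert res.empty


def test_cutoff_scan_matches_brute_force_enumeration(rng):
    """Chosen cutoff and p equal exhaustive enumeration over admissible splits."""
    for _ in range(25):
        n = int(rng.integers(8, 14))
        values = pd.Series(
            np.round(rng.exponential(2e5, n), -3), index=[f"P{i}" for i in range(n)]
        )
        clin = _clin(rng.exponential(30, n).round(1) + 0.1,
                     (rng.random(n) < 0.8).astype(int),
                     [f"P{i}" for i in range(n)])
        if clin["event"].sum() == 0:
            continue
        res = cutoff_scan(values, clin, min_group=3, floor=1e5)
        # oracle: enumerate midpoints independently
        v = values.to_numpy()
        distinct = np.unique(v)
        best = None
        for c in (distinct[:-1] + distinct[1:]) / 2:
            if not c > 1e5:
                continue
            g = (v > c).astype(int)
            if g.sum() < 3 or (1 - g).sum() < 3:
                continue
            _, p = logrank_test(clin["os_months"], clin["event"].astype(bool), g)
            if best is None or (p, c) < best:
                best = (p, c)
        if best is None:
            assert res.empty
        else:
            assert not res.empty
            assert res.cutoff == pytest.approx(best[1])
            assert res.logrank_p == pytest.approx(best[0], abs=1e-12)


def test_cutoff_scan_hr_direction_agrees_with_logrank(rng):
    """HR > 1 exactly when the high group fares worse by the O-E sign."""
    for _ in range(10):
        n = 12
        values = pd.Series(rng.exponential(2e5, n) + 1.5e5,
                           index=[f"P{i}" for i in range(n)])
        clin = _clin(rng.exponential(30, n) + 0.5, np.ones(n, dtype=int),
                     [f"P{i}" for i in range(n)])
        res = cutoff_scan(values, clin, min_group=3, floor=1e5)
        if res.empty or res.hr_flag:
            continue
        g = (values.to_numpy() > res.cutoff).astype(int)
        t = clin["os_months"].to_numpy()
        e = clin["event"].to_numpy(dtype=bool)
        o_minus_e = 0.0
        for tj in np.unique(t[e]):
            at_risk = t >= tj
            o_minus_e += ((e & (t == tj)) & (g == 1)).sum() - (
                (e & (t == tj)).sum() * (at_risk & (g == 1)).sum() / at_risk.sum()
            )
        assert (res.hr > 1) == (o_minus_e > 0)


def test_scan_all_features_single_feature_and_empty(rng):
    n = 10
    clin = _clin(rng.exponential(30, n) + 0.5, np.ones(n, dtype=int),
                 [f"P{i}" for i in range(n)])
    vals = rng.exponential(3e5, n) + 1.2e5
    features = pd.DataFrame(
        [vals, np.zeros(n)], index=["good", "undetected"],
        columns=[f"P{i}" for i in range(n)],
    )
    scan = SurvivalCutoffScan(features, clin, floor=1e5).fit()
    single = cutoff_scan(features.loc["good"], clin, floor=1e5, feature_id="good")
    got = scan.results[0]
    assert got.cutoff == pytest.approx(single.cutoff)
    assert got.logrank_p == pytest.approx(single.logrank_p)
    assert scan.results[1].empty
    assert "not type-I-calibrated" in scan.note


def test_permutation_adjustment_exceeds_nominal_on_null(rng):
    """Optimistic minimal-p selection: the permutation-adjusted p is larger
    than the raw selected p on null data."""
    n = 14
    clin = _clin(rng.exponential(30, n) + 0.5, np.ones(n, dtype=int),
                 [f"P{i}" for i in range(n)])
    values = pd.Series(rng.exponential(3e5, n) + 1.2e5,
                       index=[f"P{i}" for i in range(n)])
    res = cutoff_scan(values, clin, min_group=3, floor=1e5,
                      permutations=200, rng=np.random.default_rng(0))
    assert not res.empty
    assert res.p_perm >= res.logrank_p


# -- marker selection --------------------------------------------------------


def test_select_survival_markers_requires_both_methods(study_dataset,
                                                       study_detection,
                                                       study_panel):
    sel = select_survival_markers(study_detection, study_detection, study_panel)
    truth = study_dataset.truth
    expected = [g for g in study_panel.all_genes() if g in truth.markers_detected_both]
    expected += [g for g in ("MRC1", "IDH2", "FAS", "ITGB8") if g not in expected]
    assert sel.genes == expected
    assert len(sel.genes) == 45  # 41 panel markers + 4 panel-external proteins


def test_select_survival_markers_deduplicates_extras(rng):
    m = random_matrix(rng, n_genes=6, n_patients=2, density=1.0)
    d = m.binarize()
    panel = MarkerPanel(markers={"a": ["G000", "G001"]})
    sel = select_survival_markers(d, d, panel, extra=("G000", "G005"))
    assert sel.genes == ["G000", "G001", "G005"]


def test_scan_on_study_dataset_runs_for_all_markers(study_dataset,
                                                    study_detection,
                                                    study_panel):
    sel = select_survival_markers(study_detection, study_detection, study_panel)
    u = study_dataset.intensities.fraction_frame("U")
    features = u.loc[[g for g in sel.genes if g in u.index]]
    scan = SurvivalCutoffScan(features, study_dataset.clinical, floor=1e5).fit()
    df = scan.to_frame()
    assert len(df) == len(sel.genes)
    scanned = df[~df["empty"]]
    assert (scanned["n_high"] >= 3).all() and (scanned["n_low"] >= 3).all()
    assert (scanned["cutoff"] > 1e5).all()
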