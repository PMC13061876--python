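"""Group statistics: log transform, normality gating, two-sample tests,
BH-FDR, signed significance maps, and cohort-design helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ifmicrostate.dynamics import compute_metrics, metrics_frame, \
    transitions_frame
from ifmicrostate.states import StateSequence
from ifmicrostate.stats import (chi_square_2x2, cohens_d,
                                cohens_d_from_summary, compare,
                                compare_cohort, eta_squared_to_d,
                                fdr_correct, log_transform, normality_gate,
                                power_analysis_n, signed_significance_map)
from ifmicrostate.synthetic import sample_markov_chains, sticky_markov


def brute_force_bh(p):
    """Independent step-up implementation of Benjamini-Hochberg."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = min(running_min, 1.0)
    return q


def _moments_exact(rng, n, mean, sd):
    """Samples with exactly the requested mean and (ddof=1) sd."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return x * sd + mean


# -- log transform -----------------------------------------------------------

def test_log_transform_closed_form():
    out, flagged = log_transform([1.0, np.e, np.e**2])
    np.testing.assert_allclose(out, [0.0, 1.0, 2.0])
    assert not flagged.any()


def test_log_transform_floor_rule():
    out, flagged = log_transform([0.0, 0.5], floor=1e-3)
    np.testing.assert_allclose(out, [np.log(1e-3), np.log(0.5)])
    assert flagged.tolist() == [True, False]


def test_log_transform_rejects_nonpositive_without_floor():
    with pytest.raises(ValueError, match=r"\[1\]"):
        log_transform([0.5, -1.0])


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-6, 1e6), min_size=2, max_size=30))
def test_log_transform_preserves_order(values):
    out, _ = log_transform(sorted(values))
    assert np.all(np.diff(out) >= 0)


# -- normality gate ----------------------------------------------------------

def test_gate_nominal_level_under_normality():
    """Both groups normal at the study sizes: the parametric path should
    be chosen in about (1 - 0.05)^2 = 90% of replicates."""
    rng = np.random.default_rng(0)
    chosen = [normality_gate(rng.normal(size=29), rng.normal(size=18))[2]
              for _ in range(1000)]
    rate = np.mean([c == "parametric" for c in chosen])
    assert abs(rate - 0.9025) < 0.03


def test_gate_detects_lognormal_group():
    rng = np.random.default_rng(1)
    chosen = [normality_gate(np.exp(rng.normal(0, 1.5, size=29)),
                             rng.normal(size=18))[2]
              for _ in range(200)]
    assert np.mean([c == "nonparametric" for c in chosen]) > 0.95


def test_gate_degenerate_and_small_groups_warn():
    with pytest.warns(UserWarning, match="constant"):
        _, _, path = normality_gate(np.full(20, 3.0),
                                    np.random.default_rng(0).normal(size=20))
    assert path == "nonparametric"
    with pytest.warns(UserWarning, match="small"):
        _, _, path = normality_gate([1, 2, 3], [4, 5, 6, 7, 8, 9, 10, 11])
    assert path == "nonparametric"


# -- two-sample comparison ---------------------------------------------------

def test_effect_size_matches_study_scale_summaries():
    """Group summaries at the reported dwell-time scale (younger
    0.086 +- 0.018 s, n=29; middle-aged 0.103 +- 0.016 s, n=18) give a
    pooled-SD Cohen's d of 0.98, consistent with the printed 1.02 from
    unrounded data."""
    rng = np.random.default_rng(2)
    younger = _moments_exact(rng, 29, 0.086, 0.018)
    middle = _moments_exact(rng, 18, 0.103, 0.016)
    d = cohens_d(younger, middle)
    assert abs(d - 0.98) < 0.05
    # and from-summary equals from-samples when moments are exact
    assert d == pytest.approx(
        cohens_d_from_summary(0.086, 0.018, 29, 0.103, 0.016, 18), abs=1e-9)
    p, direction, _ = compare(younger, middle, "welch_t")
    assert p < 0.01 and direction == 1


def test_identical_groups_are_null():
    x = np.arange(12, dtype=float)
    p, _, d = compare(x, x.copy(), "mann_whitney_u")
    assert p == pytest.approx(1.0)
    assert d == pytest.approx(0.0)


def test_group_swap_antisymmetry(rng):
    a, b = rng.normal(0, 1, 20), rng.normal(0.8, 1, 25)
    p1, dir1, d1 = compare(a, b, "welch_t")
    p2, dir2, d2 = compare(b, a, "welch_t")
    assert p1 == pytest.approx(p2)
    assert dir1 == -dir2
    assert d1 == pytest.approx(-d2)


def test_welch_equals_student_for_balanced_equal_variance(rng):
    a = rng.normal(0, 1, size=30)
    b = rng.normal(0.5, 1, size=30)
    b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + 0.5
    a = (a - a.mean()) / a.std(ddof=1) * a.std(ddof=1)
    p_w, _, _ = compare(a, b, "welch_t")
    p_s, _, _ = compare(a, b, "student_t")
    assert round(p_w, 3) == round(p_s, 3)


def test_zero_variance_in_both_groups_rejected():
    with pytest.raises(ValueError, match="variance"):
        compare([1.0, 1.0], [1.0, 1.0], "welch_t")


# -- BH-FDR ------------------------------------------------------------------

def test_bh_all_pass_at_stepup_thresholds():
    q = fdr_correct([0.01, 0.02, 0.03, 0.04])
    assert np.all(q < 0.05)


def test_bh_single_p_unchanged():
    np.testing.assert_allclose(fdr_correct([0.03]), [0.03])


def test_bh_tied_p_values():
    q = fdr_correct([0.04, 0.04, 0.04, 0.8])
    np.testing.assert_allclose(q, [0.16 / 3, 0.16 / 3, 0.16 / 3, 0.8])
    assert not np.any(q < 0.05)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        fdr_correct([0.5, 1.2])


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_matches_brute_force_stepup(p_values):
    np.testing.assert_allclose(fdr_correct(p_values),
                               brute_force_bh(p_values), atol=1e-12)


# -- signed significance -----------------------------------------------------

def _fake_results():
    return pd.DataFrame([
        {"metric": "transition", "from_state": 1, "to_state": 1,
         "signed_score": 3.0, "significant": True},
        {"metric": "transition", "from_state": 1, "to_state": 2,
         "signed_score": 0.0, "significant": False},
        {"metric": "dwell", "from_state": np.nan, "to_state": np.nan,
         "signed_score": 2.0, "significant": True},
    ])


def test_signed_map_values_and_mask():
    score, mask = signed_significance_map(_fake_results(), n_states=2)
    assert score[0, 0] == 3.0 and score[0, 1] == 0.0
    assert mask[0, 0] and not mask[0, 1]
    assert np.isnan(score[1, 1])  # not in the family -> missing


def test_signed_score_definition(rng):
    a = rng.normal(0, 1, 25)
    b = rng.normal(1.5, 1, 25)
    p, direction, _ = compare(a, b, "welch_t")
    assert direction * (-np.log10(p)) > 0  # b larger -> positive score


# -- cohort-design helpers ---------------------------------------------------

def test_power_analysis_study_planning_value():
    n, total = power_analysis_n(0.8, alpha=0.05, power=0.80)
    assert (n, total) == (26, 52)


def test_power_analysis_medium_effect():
    assert power_analysis_n(0.5, 0.05, 0.80)[0] == 64


def test_power_monotone_in_effect_size():
    assert power_analysis_n(1.6, 0.05, 0.8)[0] < \
        power_analysis_n(0.8, 0.05, 0.8)[0]


def test_power_matches_statsmodels_solver():
    from statsmodels.stats.power import TTestIndPower
    solver = TTestIndPower()
    for d in (0.5, 0.8, 1.0, 1.3):
        n_cont = solver.solve_power(effect_size=d, alpha=0.05, power=0.8)
        assert power_analysis_n(d)[0] == int(np.ceil(n_cont))


def test_eta_squared_conversion():
    assert eta_squared_to_d(0.2) == pytest.approx(1.0)
    assert eta_squared_to_d(0.3) == pytest.approx(1.309, abs=5e-4)
    assert eta_squared_to_d(0.0) == 0.0
    with pytest.raises(ValueError):
        eta_squared_to_d(1.0)


def test_chi_square_study_sex_table():
    chi2, p = chi_square_2x2([[14, 15], [7, 11]])
    assert chi2 == pytest.approx(0.396, abs=5e-4)
    assert p == pytest.approx(0.529, abs=5e-4)


def test_chi_square_independence_and_symmetry():
    chi2, _ = chi_square_2x2([[10, 10], [5, 5]])
    assert chi2 == pytest.approx(0.0)
    t = [[14, 15], [7, 11]]
    assert chi_square_2x2(t)[0] == pytest.approx(
        chi_square_2x2(np.transpose(t))[0])
    with pytest.raises(ValueError, match="margin"):
        chi_square_2x2([[0, 0], [5, 5]])


# -- cohort comparison pipeline ---------------------------------------------

def _label_metrics(markov_a, markov_b, n_a, n_b, n_samples, seed):
    """Metrics from raw label sequences (no signal synthesis)."""
    mets = []
    for g, (markov, n, name) in enumerate(
            [(markov_a, n_a, "younger"), (markov_b, n_b, "middle_aged")]):
        chains = sample_markov_chains(markov, n_samples, n, seed=seed * 7 + g)
        for i, labels in enumerate(chains):
            seq = StateSequence(labels=labels, fs_hz=200.0,
                                participant_id=f"{name}_{i}", group=name)
            mets.append(compute_metrics(seq, markov.n_states))
    return metrics_frame(mets), transitions_frame(mets)


def test_group_contrast_in_stickiness_is_detected():
    """Self-transition 0.94 vs 0.95 for one state, 26 per group: the
    dwell-time difference for that state reaches q < 0.05 in the majority
    of replicates."""
    A = sticky_markov(5, 0.94)
    B = sticky_markov(5, np.array([0.95, 0.94, 0.94, 0.94, 0.94]))
    hits = 0
    for rep in range(5):
        mf, tf = _label_metrics(A, B, 26, 26, 10_000, seed=rep + 1)
        res = compare_cohort(mf, tf, group_a="younger",
                             group_b="middle_aged")
        row = res[(res["metric"] == "dwell") & (res["state"] == 1)]
        hits += bool(row["significant"].iloc[0]) and \
            int(row["direction"].iloc[0]) == 1
    assert hits >= 3


def test_null_cohort_rarely_yields_findings():
    """Identical transition structure in both groups: within each BH
    family (dwell, occupancy, transitions) a replicate yields any
    q < 0.05 finding with probability about 0.05, so at 20 replicates at
    most a couple of hits per family are expected."""
    M = sticky_markov(5, 0.94)
    hits = {}
    for rep in range(20):
        mf, tf = _label_metrics(M, M, 29, 18, 10_000, seed=100 + rep)
        res = compare_cohort(mf, tf)
        for fam, sub in res.groupby("family"):
            hits[fam] = hits.get(fam, 0) + int(sub["significant"].any())
    assert set(hits) == {"dwell_s", "occupancy", "transition"}
    for fam, n_hit in hits.items():
        # 0.05 + 2 * sqrt(0.05 * 0.95 / 20) ~= 0.147 -> at most 2 of 20
        assert n_hit <= 2, (fam, n_hit)


def test_comparison_table_contract():
    A = sticky_markov(3, 0.9)
    mf, tf = _label_metrics(A, A, 12, 10, 3000, seed=5)
    res = compare_cohort(mf, tf)
    # 3 dwell + 3 occupancy + 9 transitions
    assert len(res) == 15
    assert np.all(res["q_fdr"] >= res["p_raw"] - 1e-12)
    assert set(res["test_used"]) <= {"welch_t", "mann_whitney_u"}
    # group roles follow order of appearance: younger is the reference
    assert res.attrs["group_a"] == "younger"
    assert res.attrs["group_b"] == "middle_aged"
    # signed scores finite and consistent with direction
    sel = res["p_raw"] > 0
    assert np.all(np.isfinite(res.loc[sel, "signed_score"]))
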