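"""Reliability, group tests, presence rates and mixed models."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from voicestroop.config import default_config
from voicestroop.scoring import InsufficientDataError, score_cohort
from voicestroop.stats import (
    effect_presence_rate,
    feature_matrix,
    fit_random_intercept,
    icc_3k,
    welch_t,
)
from voicestroop.synthesize import simulate_cohort


def brute_force_icc_3k(matrix):
    """Independent oracle: explicit loop-based two-way ANOVA decomposition."""
    m = [list(map(float, row)) for row in matrix]
    n, k = len(m), len(m[0])
    grand = sum(sum(row) for row in m) / (n * k)
    row_means = [sum(row) / k for row in m]
    col_means = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((m[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / ms_rows


def test_icc_perfect_consistency_is_one():
    m = np.tile(np.array([[0.5], [0.7], [0.9], [1.1]]), (1, 4))
    assert icc_3k(m).icc_3k == pytest.approx(1.0)


def test_icc_pure_noise_near_zero():
    rng = np.random.default_rng(2)
    m = rng.normal(size=(400, 5))
    assert abs(icc_3k(m).icc_3k) < 0.15


def test_icc_matches_brute_force_on_small_matrix():
    m = np.array([[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2]], dtype=float)
    assert icc_3k(m).icc_3k == pytest.approx(brute_force_icc_3k(m), abs=1e-10)


def test_icc_matches_brute_force_on_random_matrices():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = rng.integers(3, 10)
        k = rng.integers(2, 7)
        m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
        assert icc_3k(m).icc_3k == pytest.approx(brute_force_icc_3k(m), abs=1e-10)


def test_icc_consistency_invariant_to_session_shift():
    rng = np.random.default_rng(4)
    m = rng.normal(size=(20, 5)) + rng.normal(size=(20, 1))
    shifted = m.copy()
    shifted[:, 2] += 0.5  # constant practice shift in one session
    assert icc_3k(shifted).icc_3k == pytest.approx(icc_3k(m).icc_3k, abs=1e-12)


def test_icc_agrees_with_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    m = rng.normal(size=(12, 4)) + 2 * rng.normal(size=(12, 1))
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 4),
            "session": np.tile(np.arange(4), 12),
            "y": m.ravel(),
        }
    )
    ref = pg.intraclass_corr(long, targets="subject", raters="session", ratings="y")
    # McGraw–Wong "consistency, average of k raters" == Shrout–Fleiss ICC(3,k)
    mask = ref["Type"].isin(["ICC3k", "ICC(C,k)"])
    icc3k_ref = float(ref.loc[mask, "ICC"].iloc[0])
    assert icc_3k(m).icc_3k == pytest.approx(icc3k_ref, abs=1e-8)


def test_icc_input_requirements():
    with pytest.raises(InsufficientDataError):
        icc_3k(np.ones((2, 4)))
    with pytest.raises(InsufficientDataError):
        icc_3k(np.ones((5, 1)))
    with pytest.raises(InsufficientDataError):
        icc_3k(np.array([[1.0, np.nan], [2.0, 2.0], [3.0, 3.0]]))


def test_welch_identical_groups():
    t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_welch_hand_computed():
    # means 2 and 3, both sample variances 1, n=3: t = -1/sqrt(2/3), df = 4
    t, df, p = welch_t([1, 2, 3], [2, 3, 4])
    assert t == pytest.approx(-math.sqrt(1.5), abs=1e-12)
    assert df == pytest.approx(4.0, abs=1e-9)
    assert p == pytest.approx(2 * sps.t.sf(math.sqrt(1.5), 4), abs=1e-12)


def test_welch_magnitude_grows_with_shift():
    a = [1.0, 2.0, 3.0, 4.0]
    last = 0.0
    for c in (0.5, 1.0, 2.0):
        t, _, _ = welch_t(a, [v + c for v in a])
        assert abs(t) > last
        last = abs(t)


def test_welch_degenerate_variance_rejected():
    with pytest.raises(InsufficientDataError):
        welch_t([1.0, 1.0], [2.0, 2.0])


def test_presence_rate_basics():
    assert effect_presence_rate([0.1, 0.2, 0.3]) == 1.0
    assert effect_presence_rate([0.01, -0.01]) == 0.5
    assert effect_presence_rate([0.0, 1.0]) == 0.5  # strictly positive


def test_presence_rate_heterogeneous_cohort_matches_gaussian_oracle():
    """With between-participant effect SD, presence ~ Phi(delta / sd_participant)."""
    cfg = default_config(31)
    cfg.n_nonpatients, cfg.n_patients = 113, 0
    cfg.nonpatient = dataclasses.replace(
        cfg.nonpatient, sd_interference_s=0.08, sd_facilitation_s=0.05
    )
    cohort = simulate_cohort(cfg)
    groups = cohort.participants.set_index("participant_id")["group"]
    scores, _ = score_cohort(cohort.schedules_frame(), cohort.events_frame(), groups)
    per_part = scores.groupby("participant_id")["interference_raw_s"].mean()
    rate = effect_presence_rate(per_part)
    # session-mean noise ~ trial_sd*sqrt(1/8+1/16)/sqrt(5) on top of the 0.08 SD
    sigma_p = np.sqrt(0.08**2 + (0.065 * 0.445) ** 2 / 5)
    expected = sps.norm.cdf(cfg.nonpatient.delta_interference_s / sigma_p)
    se = np.sqrt(expected * (1 - expected) / 113)
    assert abs(rate - expected) < 4 * se


def _mlm_frame(beta, n_part=60, k=5, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, 0.07, size=n_part)
    rows = []
    for i in range(n_part):
        for j in range(k):
            x = rng.integers(0, 101)
            y = 0.75 + beta * (x - 50) + u[i] + rng.normal(0, 0.03)
            rows.append({"participant_id": f"p{i}", "session_index": j + 1, "x": x, "y": y})
    return pd.DataFrame(rows)


def test_mlm_null_covariate():
    df = _mlm_frame(beta=0.0, seed=1)
    res = fit_random_intercept(df, "y", ["x"])
    assert abs(res.params["x"]) < 3 * res.bse["x"]
    assert res.chi_square_vs_null < 6.0
    assert res.df == 1


def test_mlm_recovers_generating_slope():
    beta = -0.0004
    df = _mlm_frame(beta=beta, seed=2)
    res = fit_random_intercept(df, "y", ["x"])
    lo = res.params["x"] - 1.96 * res.bse["x"]
    hi = res.params["x"] + 1.96 * res.bse["x"]
    assert lo <= beta <= hi
    assert res.p_value < 0.01  # strong effect: LRT rejects the null
    assert res.random_intercept_var > 0
    assert not res.singular


def test_mlm_interaction_and_singular_flag():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(50):
        ama = i < 25
        for j in range(5):
            days = 20 - 2 * j
            y = 0.8 - 0.002 * days + (0.004 * days if ama else 0.0) + rng.normal(0, 0.02)
            rows.append(
                {"participant_id": f"p{i}", "ama": int(ama), "days": days, "y": y}
            )
    df = pd.DataFrame(rows)
    res = fit_random_intercept(df, "y", ["days", "ama"], interaction=("days", "ama"))
    name = "days:ama"
    assert res.params[name] == pytest.approx(0.004, abs=3 * res.bse[name])
    # no participant variance was generated: the fit must flag the boundary
    assert res.singular


def test_feature_matrix_first_k_complete_case(small_scores):
    scores, _ = small_scores
    sub = scores[scores["group"] == "nonpatient"]
    m = feature_matrix(sub, "mean_rt_overall", k=5)
    assert m.shape[1] == 5
    assert not np.isnan(m).any()
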