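"""Reliability, group comparisons and random-intercept mixed models.

* ICC(3,k): two-way mixed model, consistency, average of the k sessions —
  (MS_subjects - MS_error) / MS_subjects from the subjects x sessions ANOVA
  decomposition.  Insensitive to constant session shifts (consistency, not
  absolute agreement).
* Welch t tests for group contrasts (unequal variances).
* Effect-presence rates on *unclamped* participant-averaged effect scores
  (clamped scores are nonnegative by construction, so their sign carries no
  information).
* Random-intercept linear mixed models fitted by maximum likelihood, with
  grand-mean-centered continuous covariates and a likelihood-ratio chi-square
  against the intercept-only model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .scoring import InsufficientDataError


@dataclass
class ReliabilityResult:
    feature: str
    icc_3k: float
    k: int
    n: int
    icc_3k_excl_first: float | None = None


@dataclass
class MLMResult:
    params: dict
    bse: dict
    tvalues: dict
    pvalues: dict          # normal approximation on t
    random_intercept_var: float
    residual_var: float
    chi_square_vs_null: float
    df: int
    p_value: float
    n_obs: int
    n_groups: int
    converged: bool = True
    singular: bool = False


def _icc_3k_value(matrix: np.ndarray) -> float:
    """ICC(3,k) from the two-way mean squares of a complete n x k matrix."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = m.mean()
    ss_rows = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((m - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0:
        return 0.0
    return float((ms_rows - ms_err) / ms_rows)


def icc_3k(matrix, feature: str = "feature") -> ReliabilityResult:
    """Test-retest reliability of a participants x sessions feature matrix.

    Also reports the ICC recomputed without the first session (a practice-
    effect check); that value is None when only two sessions are available.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (participants x sessions)")
    if np.isnan(m).any():
        raise InsufficientDataError("matrix must be complete (no missing cells)")
    n, k = m.shape
    if n < 3 or k < 2:
        raise InsufficientDataError("ICC(3,k) requires n >= 3 participants and k >= 2 sessions")
    excl = _icc_3k_value(m[:, 1:]) if k >= 3 else None
    return ReliabilityResult(
        feature=feature, icc_3k=_icc_3k_value(m), k=k, n=n, icc_3k_excl_first=excl
    )


def feature_matrix(scores: pd.DataFrame, feature: str, k: int) -> np.ndarray:
    """First-k-sessions participants x sessions matrix for one feature.

    Participants with fewer than k sessions (or a missing value among the
    first k) are dropped, matching a complete-case first-k analysis.
    """
    wide = scores.pivot(index="participant_id", columns="session_index", values=feature)
    cols = [c for c in range(1, k + 1) if c in wide.columns]
    if len(cols) < k:
        raise InsufficientDataError(f"fewer than {k} session columns available")
    sub = wide[cols].dropna()
    return sub.to_numpy()


def reliability_report(scores: pd.DataFrame, features, k: int) -> pd.DataFrame:
    """Mean, SD (of participant session-averaged scores) and ICC(3,k) per feature."""
    rows = []
    for feat in features:
        part_means = scores.groupby("participant_id")[feat].mean()
        try:
            mat = feature_matrix(scores, feat, k)
            res = icc_3k(mat, feature=feat)
            icc, icc_x1, n_icc = res.icc_3k, res.icc_3k_excl_first, res.n
        except InsufficientDataError:
            icc, icc_x1, n_icc = np.nan, np.nan, 0
        rows.append(
            {
                "feature": feat,
                "mean": part_means.mean(),
                "sd": part_means.std(ddof=1),
                "icc_3k": icc,
                "icc_3k_excl_first": icc_x1,
                "n_participants": int(n_icc),
                "k_sessions": k,
            }
        )
    return pd.DataFrame(rows)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t: (statistic, Welch-Satterthwaite df, p)."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise InsufficientDataError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def effect_presence_rate(participant_effects) -> float:
    """Fraction of participants with a strictly positive (unclamped) mean effect."""
    vals = np.asarray(list(participant_effects), dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("no participant effect values")
    return float(np.mean(vals > 0))


def fit_random_intercept(
    data: pd.DataFrame,
    outcome: str,
    covariates,
    group_col: str = "participant_id",
    interaction: tuple[str, str] | None = None,
) -> MLMResult:
    """Random-intercept linear mixed model of a session-level outcome.

    Continuous covariates (more than two distinct values) are centered at the
    grand mean; binary covariates are treated as 0/1 dummies.  ``interaction``
    names a (continuous, binary) pair whose product (after centering the
    continuous member) is added.  Estimation is maximum likelihood so the
    likelihood-ratio chi-square against the intercept-only random-intercept
    model is valid.  Fixed-effect p-values use the normal approximation on t.
    """
    covariates = list(covariates)
    cols = [outcome, group_col] + covariates
    if interaction is not None:
        cols += [c for c in interaction if c not in cols]
    df = data[cols].dropna().copy()
    if df.empty:
        raise InsufficientDataError("no complete rows to fit")

    def centered(col: str) -> pd.Series:
        s = df[col].astype(float)
        if s.nunique() > 2:
            return s - s.mean()
        return s

    exog = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for c in covariates:
        exog[c] = centered(c)
    if interaction is not None:
        cont, binary = interaction
        name = f"{cont}:{binary}"
        exog[name] = centered(cont) * df[binary].astype(float)

    endog = df[outcome].astype(float)
    groups = df[group_col]

    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # boundary chatter from the profile-likelihood steps; real failures are
        # surfaced through the converged/singular flags below
        warnings.simplefilter("ignore", ConvergenceWarning)
        full = sm.MixedLM(endog, exog, groups=groups).fit(reml=False)
        null = sm.MixedLM(endog, exog[["Intercept"]], groups=groups).fit(reml=False)
    k_fixed = exog.shape[1] - 1
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(sps.chi2.sf(chi2, k_fixed)) if k_fixed > 0 else np.nan

    re_var = float(np.asarray(full.cov_re)[0, 0])
    singular = bool(re_var < 1e-10)
    tvals = full.tvalues
    pvals = {name: float(2 * sps.norm.sf(abs(tvals[name]))) for name in exog.columns}
    return MLMResult(
        params={c: float(full.params[c]) for c in exog.columns},
        bse={c: float(full.bse[c]) for c in exog.columns},
        tvalues={c: float(tvals[c]) for c in exog.columns},
        pvalues=pvals,
        random_intercept_var=re_var,
        residual_var=float(full.scale),
        chi_square_vs_null=float(chi2),
        df=int(k_fixed),
        p_value=p,
        n_obs=int(len(df)),
        n_groups=int(groups.nunique()),
        converged=bool(full.converged),
        singular=singular,
    )
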