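"""Group comparison of dynamics metrics, with FDR control.

For every metric (dwell time per state, occupancy per state, each ordered
transition pair) the two groups are compared as follows: values are
log-transformed to reduce skew (zero transition probabilities are floored
at the participant's smallest observable probability, 1/#transitions, and
flagged); normality of the log values is assessed per group with the
D'Agostino-Pearson omnibus test; if both groups pass (p > alpha) a
two-sample t test is used (Welch by default — the groups are unbalanced),
otherwise the Mann-Whitney U test.  Raw p values are corrected with
Benjamini-Hochberg within each family (dwell across the K states,
occupancy across the K states, transitions across the full K x K set) at
q < 0.05.  Effect sizes are pooled-SD Cohen's d on the original scale,
signed so that positive means the second group (middle-aged) is larger;
the signed significance score is sign(difference) * -log10(p).

Cohort-design helpers (a-priori power analysis via the noncentral t
distribution, eta-squared to Cohen's d conversion, and a 2x2 Pearson
chi-square for e.g. sex distributions) live here as well.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log_transform",
    "normality_gate",
    "compare",
    "compare_groups",
    "fdr_correct",
    "compare_cohort",
    "signed_significance_map",
    "cohens_d",
    "cohens_d_from_summary",
    "power_analysis_n",
    "eta_squared_to_d",
    "chi_square_2x2",
]

_NORMALITY_MIN_N = 8  # validity floor of the omnibus test


def log_transform(values, floor: float | np.ndarray | None = None):
    """Natural log, with an optional floor for non-positive entries.

    Returns ``(log_values, floored_mask)``.  Without a floor, any
    non-positive value is an error (their indices are listed).
    """
    v = np.asarray(values, dtype=float)
    nonpos = v <= 0
    if floor is None:
        if nonpos.any():
            raise ValueError(
                "log_transform: non-positive values at indices "
                f"{np.flatnonzero(nonpos).tolist()} (provide a floor)")
        return np.log(v), nonpos
    v = np.where(nonpos, np.broadcast_to(floor, v.shape), v)
    return np.log(v), nonpos


def normality_gate(group_a, group_b, alpha: float = 0.05):
    """D'Agostino-Pearson omnibus test per group; choose the test path.

    Returns ``(p_a, p_b, test)`` where ``test`` is ``"parametric"`` iff
    both groups pass (p > alpha).  Groups smaller than 8 or degenerate
    (constant) fall back to the nonparametric path with a warning.
    """
    ps = []
    for g in (np.asarray(group_a, float), np.asarray(group_b, float)):
        if g.size < _NORMALITY_MIN_N:
            warnings.warn("group too small for the normality test; "
                          "using the nonparametric path", stacklevel=2)
            ps.append(np.nan)
            continue
        if np.ptp(g) == 0:
            warnings.warn("constant group: skew/kurtosis undefined; "
                          "using the nonparametric path", stacklevel=2)
            ps.append(np.nan)
            continue
        ps.append(sps.normaltest(g).pvalue)
    parametric = all(np.isfinite(p) and p > alpha for p in ps)
    return ps[0], ps[1], "parametric" if parametric else "nonparametric"


def cohens_d(group_a, group_b) -> float:
    """Pooled-SD standardized difference, (mean_b - mean_a) / s_pooled."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    return cohens_d_from_summary(a.mean(), a.std(ddof=1), a.size,
                                 b.mean(), b.std(ddof=1), b.size)


def cohens_d_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> float:
    """Cohen's d from group summary statistics ((n-1)-weighted pooled SD)."""
    sp = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2)
                 / (n_a + n_b - 2))
    if sp == 0:
        return float("nan")  # undefined when both groups are constant
    return float((mean_b - mean_a) / sp)


def compare(group_a, group_b, test: str = "welch_t") -> tuple[float, int, float]:
    """Two-sided two-sample comparison.

    ``test``: ``welch_t``, ``student_t`` or ``mann_whitney_u``.  Returns
    ``(p, direction, d)`` with direction = sign(mean_b - mean_a) and d the
    pooled-SD Cohen's d of the inputs as given.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        raise ValueError("zero variance in both groups")
    if test == "welch_t":
        p = sps.ttest_ind(a, b, equal_var=False).pvalue
    elif test == "student_t":
        p = sps.ttest_ind(a, b, equal_var=True).pvalue
    elif test == "mann_whitney_u":
        p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    direction = int(np.sign(b.mean() - a.mean()))
    return float(p), direction, cohens_d(a, b)


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_significance_map(results: pd.DataFrame,
                            n_states: int) -> tuple[np.ndarray, np.ndarray]:
    """K x K matrix of sign(difference) * -log10(p_raw) for the transition
    family, plus the q < 0.05 significance mask."""
    score = np.full((n_states, n_states), np.nan)
    mask = np.zeros((n_states, n_states), dtype=bool)
    trans = results[results["metric"] == "transition"]
    for _, r in trans.iterrows():
        i, j = int(r["from_state"]) - 1, int(r["to_state"]) - 1
        score[i, j] = r["signed_score"]
        mask[i, j] = bool(r["significant"])
    return score, mask


# ---------------------------------------------------------------------------
# cohort-level comparison pipeline

def _compare_one(a_raw, b_raw, floors_a, floors_b, test_mode, alpha):
    """Shared per-comparison path: floor+log, gate, test, effect size."""
    la, fa = log_transform(a_raw, floor=floors_a)
    lb, fb = log_transform(b_raw, floor=floors_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_a, p_b, gate = normality_gate(la, lb, alpha)
    if test_mode == "auto":
        test = "welch_t" if gate == "parametric" else "mann_whitney_u"
    elif test_mode == "student":
        test = "student_t" if gate == "parametric" else "mann_whitney_u"
    else:
        test = test_mode
    p, _, _ = compare(la, lb, test)
    d = cohens_d(a_raw, b_raw)  # original scale, per reporting convention
    direction = int(np.sign(np.mean(b_raw) - np.mean(a_raw)))
    return {
        "group_a_mean": float(np.mean(a_raw)),
        "group_a_sd": float(np.std(a_raw, ddof=1)),
        "group_b_mean": float(np.mean(b_raw)),
        "group_b_sd": float(np.std(b_raw, ddof=1)),
        "n_a": len(a_raw), "n_b": len(b_raw),
        "normality_p_a": p_a, "normality_p_b": p_b,
        "test_used": test, "p_raw": p, "cohens_d": d,
        "direction": direction,
        "n_floored": int(fa.sum() + fb.sum()),
        "signed_score": direction * (-np.log10(p)) if p > 0 else np.inf,
    }


def compare_cohort(metrics_df: pd.DataFrame,
                   transitions_df: pd.DataFrame | None = None,
                   group_a: str | None = None,
                   group_b: str | None = None,
                   test: str = "auto",
                   alpha: float = 0.05,
                   fdr_q: float = 0.05) -> pd.DataFrame:
    """Full family-wise group comparison.

    ``metrics_df`` is the tidy per-state table from
    :func:`ifmicrostate.dynamics.metrics_frame`; ``transitions_df`` the
    matching transition table.  Group A is the reference (younger); a
    positive direction/effect means group B (middle-aged) is larger.
    Families for BH correction: dwell (K states), occupancy (K states),
    transitions (K x K pairs).
    """
    groups = list(dict.fromkeys(metrics_df["group"]))  # order of appearance
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError(f"need exactly 2 groups, found {groups}")
        group_a, group_b = groups
    rows = []
    states = sorted(metrics_df["state"].unique())
    for metric in ("dwell_s", "occupancy"):
        for k in states:
            sub = metrics_df[metrics_df["state"] == k]
            a = sub.loc[sub["group"] == group_a, metric].dropna().to_numpy()
            b = sub.loc[sub["group"] == group_b, metric].dropna().to_numpy()
            a, b = a[a > 0], b[b > 0]
            if len(a) < 2 or len(b) < 2:
                continue
            row = _compare_one(a, b, None, None, test, alpha)
            row.update({"metric": "dwell" if metric == "dwell_s"
                        else "occupancy",
                        "state": k, "from_state": np.nan,
                        "to_state": np.nan, "family": metric})
            rows.append(row)
    if transitions_df is not None:
        for (i, j), sub in transitions_df.groupby(["from_state", "to_state"]):
            sub = sub.dropna(subset=["probability"])
            a_sub = sub[sub["group"] == group_a]
            b_sub = sub[sub["group"] == group_b]
            if len(a_sub) < 2 or len(b_sub) < 2:
                continue
            # smallest observable nonzero probability per participant
            row = _compare_one(
                a_sub["probability"].to_numpy(),
                b_sub["probability"].to_numpy(),
                1.0 / a_sub["n_outgoing"].to_numpy(),
                1.0 / b_sub["n_outgoing"].to_numpy(),
                test, alpha)
            row.update({"metric": "transition", "state": np.nan,
                        "from_state": i, "to_state": j,
                        "family": "transition"})
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_fdr"] = np.nan
    for _, idx in out.groupby("family").groups.items():
        out.loc[idx, "q_fdr"] = fdr_correct(out.loc[idx, "p_raw"])
    out["significant"] = out["q_fdr"] < fdr_q
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    return out


# ---------------------------------------------------------------------------
# cohort-design helpers

def _t_test_power(d: float, n: int, alpha: float) -> float:
    """Power of a two-sided two-sample t test, n per group, effect d."""
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(1 - sps.nct.cdf(tcrit, df, nc)
                 + sps.nct.cdf(-tcrit, df, nc))


def power_analysis_n(d: float, alpha: float = 0.05,
                     power: float = 0.80, n_max: int = 100000) -> tuple[int, int]:
    """Smallest per-group n with noncentral-t power >= target.

    Returns ``(n_per_group, n_total)`` for a two-sided independent-samples
    t test at level ``alpha`` detecting effect size ``d``.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if d == 0:
        raise ValueError("effect size must be nonzero")
    d = abs(d)
    for n in range(2, n_max + 1):
        if _t_test_power(d, n, alpha) >= power:
            return n, 2 * n
    raise ValueError(f"power {power} not attainable with n <= {n_max}")


def eta_squared_to_d(eta2: float) -> float:
    """Convert eta-squared (proportion of variance) to Cohen's d:
    d = 2 * sqrt(eta2 / (1 - eta2))."""
    if not 0 <= eta2 < 1:
        raise ValueError("eta squared must lie in [0, 1)")
    return 2.0 * np.sqrt(eta2 / (1.0 - eta2))


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction, df=1) of a 2x2 table.

    Returns ``(statistic, p)``; zero margins are an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)
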