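"""Responder / non-responder stratification and group statistics.

Treatment response is read out as the fractional reduction in central
subfield thickness (CST): change = (x − y)/x for baseline x and
post-treatment y.  Eyes are ranked by that change and split at the median
into quartiles 1–2 (responders) and 3–4 (non-responders); with an odd
number of eyes the median-ranked eye goes to the non-responder group, so
61 eyes split 30/31.  Groups are then compared variable by variable with
the pooled-variance Student t-test (continuous) or Pearson's chi-square
(categorical), Bonferroni-corrected across the comparisons actually run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RESPONDER = "responder"
NONRESPONDER = "nonresponder"


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    mean_r: float
    sd_r: float
    mean_n: float
    sd_n: float
    n_r: int
    n_n: int
    statistic: float
    p_value: float
    test: str
    bonferroni_alpha: float
    significant: bool


@dataclass(frozen=True)
class ContributionRow:
    variable: str
    responder_mean: float
    nonresponder_mean: float
    mean_difference: float
    percentage_change: float
    status: str


def filter_by_signal(cohort: pd.DataFrame, min_ss: int = 7) -> pd.DataFrame:
    """Keep records whose OCTA signal strength meets the inclusion floor."""
    out = cohort[cohort["signal_strength"] >= min_ss].reset_index(drop=True)
    if out.empty:
        warnings.warn("no records meet the signal-strength threshold")
    return out


def percentage_change_cst(x, y):
    """Fractional CST change (x − y)/x for baseline x, post-treatment y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ValueError("baseline CST must be positive")
    out = (x - y) / x
    return float(out) if out.ndim == 0 else out


def quartile_split(changes, eye_ids=None) -> np.ndarray:
    """Group labels from the quartile rule on fractional CST change.

    Records are ranked with the largest reduction first; the top two
    quartiles (the first floor(n/2) records) are responders, the rest —
    including the median-ranked record when n is odd — non-responders.
    Ties are broken by the original record order (eye-id order), which
    makes the split deterministic.
    """
    changes = np.asarray(changes, dtype=float)
    n = changes.size
    if n < 4:
        raise ValueError("need at least 4 records to form quartiles")
    # stable sort on descending change; ties keep input order
    order = np.argsort(-changes, kind="stable")
    labels = np.full(n, NONRESPONDER, dtype=object)
    labels[order[:n // 2]] = RESPONDER
    return labels


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _pooled_t(a: np.ndarray, b: np.ndarray, welch: bool = False):
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero variance in both groups: t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_groups(cohort: pd.DataFrame, variables: list[str],
                   group_col: str = "group", alpha: float = 0.05,
                   categorical: tuple[str, ...] = ("sex",),
                   welch: bool = False) -> list[GroupComparison]:
    """Two-group comparison of every variable, Bonferroni-corrected.

    Continuous variables get the two-sided pooled-variance Student t-test
    (Welch's correction available by flag); variables named in
    ``categorical`` get Pearson's chi-square on the count table, without
    continuity correction.  The Bonferroni threshold is alpha divided by
    the number of comparisons actually run.
    """
    g = cohort[group_col]
    in_r = (g == RESPONDER).to_numpy()
    in_n = (g == NONRESPONDER).to_numpy()
    if not in_r.any() or not in_n.any():
        raise ValueError("both groups must be nonempty")
    thr = bonferroni_alpha(alpha, len(variables))
    out = []
    for var in variables:
        col = cohort[var]
        if var in categorical or col.dtype == object:
            table = pd.crosstab(col, g).to_numpy()
            res = stats.chi2_contingency(table, correction=False)
            statistic, p = float(res[0]), float(res[1])
            m_r = sd_r = m_n = sd_n = float("nan")
            test = "chi2"
        else:
            a = col[in_r].to_numpy(dtype=float)
            b = col[in_n].to_numpy(dtype=float)
            statistic, p = _pooled_t(a, b, welch=welch)
            m_r, sd_r = float(a.mean()), float(a.std(ddof=1))
            m_n, sd_n = float(b.mean()), float(b.std(ddof=1))
            test = "welch_t" if welch else "student_t"
        out.append(GroupComparison(
            variable=var, mean_r=m_r, sd_r=sd_r, mean_n=m_n, sd_n=sd_n,
            n_r=int(in_r.sum()), n_n=int(in_n.sum()),
            statistic=statistic, p_value=p, test=test,
            bonferroni_alpha=thr, significant=bool(p < thr)))
    return out


def contribution_table(responder_means: dict[str, float],
                       nonresponder_means: dict[str, float],
                       ) -> list[ContributionRow]:
    """Per-variable contribution of the significant factors to CST change.

    For each variable: mean difference = responder − non-responder, and
    percentage change = (non-responder − responder)/responder × 100,
    rounded to 2 decimals; status is Decreased for a negative percentage
    change (the non-responder group's value is lower), Increased otherwise.
    """
    if set(responder_means) != set(nonresponder_means):
        raise ValueError("variable lists must match")
    rows = []
    for var, r in responder_means.items():
        n = nonresponder_means[var]
        if r == 0:
            raise ValueError(f"zero responder mean for {var!r}")
        diff = round(r - n, 2)
        pct = round((n - r) / r * 100.0, 2)
        rows.append(ContributionRow(
            variable=var, responder_mean=r, nonresponder_mean=n,
            mean_difference=diff, percentage_change=pct,
            status="Decreased" if pct < 0 else "Increased"))
    return rows


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


def contribution_frame(rows: list[ContributionRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
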