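"""Group-level statistics: factorial ANOVA, repeated measures, post-hoc corrections.

Covers the statistical battery used on behavioral and excitability tables:

* two-way ANOVA (surgery x housing) with Type-II sums of squares, so
  unbalanced cell counts are handled and the balanced case reduces to the
  classical decomposition;
* mixed repeated-measures ANOVA for time courses (between-subject group,
  within-subject timepoint);
* all-pairwise post-hoc comparisons with Tukey HSD, Holm-Šídák, or the
  Benjamini-Krieger-Yekutieli two-stage FDR;
* unpaired two-sample t-tests (Student pooled-variance by default, so the
  reported df is n_A + n_B - 2; Welch optional).

Factorial model fitting is delegated to statsmodels (OLS / anova_lm); the
mixed repeated-measures partition is computed directly from the classical
weighted-means formulas so that degenerate designs (zero residual variance,
flat time courses) are handled explicitly instead of erroring.  Post-hoc p
adjustment uses statsmodels' multipletests plus the studentized-range
distribution for Tukey.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "AnovaResult",
    "TTestResult",
    "two_way_anova",
    "rm_two_way_anova",
    "posthoc",
    "adjust_pvalues",
    "unpaired_t",
    "POSTHOC_METHODS",
]

POSTHOC_METHODS = ("tukey", "holm_sidak", "bky_fdr")
_EPS = 1e-12


@dataclass
class EffectResult:
    F: float
    df1: float
    df2: float
    p: float


@dataclass
class AnovaResult:
    """Per-effect F tests plus cell means and an optional post-hoc table."""

    effects: dict[str, EffectResult]
    cell_means: pd.DataFrame
    posthoc: Optional[pd.DataFrame] = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "effects": {
                k: {"F": e.F, "df1": e.df1, "df2": e.df2, "p": e.p}
                for k, e in self.effects.items()
            },
            "cell_means": self.cell_means.to_dict(orient="records"),
            "flags": list(self.flags),
        }
        if self.posthoc is not None:
            out["posthoc"] = self.posthoc.to_dict(orient="records")
        return out


def _cell_means(df: pd.DataFrame, outcome: str, by: list[str]) -> pd.DataFrame:
    g = df.groupby(by, observed=True)[outcome]
    tab = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    tab["sem"] = tab["sd"] / np.sqrt(tab["n"])
    return tab


def two_way_anova(
    table: pd.DataFrame,
    outcome: str,
    factor_a: str = "surgery",
    factor_b: str = "housing",
    posthoc_method: Optional[str] = None,
    alpha: float = 0.05,
) -> AnovaResult:
    """Two-way factorial ANOVA with interaction, Type-II sums of squares.

    Requires at least 2 observations in every design cell.  With zero residual
    variance the F statistics are reported as ``inf`` (non-zero effect SS) or
    0, flagged ``zero_residual_variance``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[factor_a, factor_b, outcome]].dropna().copy()
    df = df.rename(columns={outcome: "_y", factor_a: "_a", factor_b: "_b"})
    counts = df.groupby(["_a", "_b"], observed=True).size()
    levels_a = df["_a"].unique()
    levels_b = df["_b"].unique()
    if len(counts) < len(levels_a) * len(levels_b):
        raise ValueError(
            f"empty design cell: {factor_a} x {factor_b} has unobserved combinations"
        )
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"design cells with fewer than 2 observations: {bad}")

    flags: list[str] = []
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on degenerate residuals
        aov = sm.stats.anova_lm(model, typ=2)
    df_resid = float(model.df_resid)
    ss_resid = float(model.ssr)
    effects: dict[str, EffectResult] = {}
    name_map = {"C(_a)": factor_a, "C(_b)": factor_b, "C(_a):C(_b)": "interaction"}
    for row_name, label in name_map.items():
        ss = float(aov.loc[row_name, "sum_sq"])
        d1 = float(aov.loc[row_name, "df"])
        if ss_resid < _EPS:
            if "zero_residual_variance" not in flags:
                flags.append("zero_residual_variance")
            if ss < _EPS:
                F, p = 0.0, 1.0
            else:
                F, p = float("inf"), 0.0
        else:
            F = (ss / d1) / (ss_resid / df_resid)
            p = float(sps.f.sf(F, d1, df_resid))
        effects[label] = EffectResult(F=F, df1=d1, df2=df_resid, p=p)

    cells = _cell_means(df.rename(columns={"_a": factor_a, "_b": factor_b, "_y": outcome}),
                        outcome, [factor_a, factor_b])
    ph = None
    if posthoc_method is not None:
        ph = posthoc(table, outcome, posthoc_method, factor_a, factor_b, alpha=alpha)
    return AnovaResult(effects=effects, cell_means=cells, posthoc=ph, flags=flags)


def _ratio_test(ss_num: float, df_num: float, ss_den: float, df_den: float,
                flags: list[str], label: str) -> EffectResult:
    """F test with explicit handling of vanishing numerator/denominator SS."""
    if ss_den < _EPS:
        flag = f"degenerate_{label}"
        if flag not in flags:
            flags.append(flag)
        if ss_num < _EPS:
            return EffectResult(0.0, df_num, df_den, 1.0)
        return EffectResult(float("inf"), df_num, df_den, 0.0)
    F = (ss_num / df_num) / (ss_den / df_den)
    return EffectResult(F, df_num, df_den, float(sps.f.sf(F, df_num, df_den)))


def rm_two_way_anova(
    table: pd.DataFrame,
    outcome: str,
    subject: str = "animal_id",
    within: str = "timepoint_day",
    between: str = "group",
    gg_correction: bool = False,
) -> AnovaResult:
    """Mixed repeated-measures ANOVA: between-subject group, within-subject time.

    Subjects lacking the complete within-subject series are dropped listwise
    with a warning.  The classical weighted-means partition is used: the
    between-group effect is tested against subjects-within-groups, the time
    and group x time effects against the within-subject residual.  Sphericity
    is not corrected by default (common practice for short time courses);
    ``gg_correction=True`` applies the Greenhouse-Geisser epsilon to the
    within-subject tests.
    """
    df = table[[subject, within, between, outcome]].dropna().copy()
    n_times = df[within].nunique()
    per_subj = df.groupby(subject)[within].nunique()
    complete = per_subj[per_subj == n_times].index
    dropped = sorted(set(df[subject]) - set(complete))
    if dropped:
        warnings.warn(f"subjects without complete time series dropped: {dropped}")
    df = df[df[subject].isin(complete)]
    if df[subject].nunique() < 2 or n_times < 2:
        raise ValueError("mixed ANOVA needs >= 2 complete subjects and >= 2 timepoints")
    if df.duplicated([subject, within]).any():
        raise ValueError("multiple observations per subject x timepoint")

    y = df[outcome].to_numpy(dtype=float)
    grand = float(y.mean())
    subj_mean = df.groupby(subject)[outcome].mean()
    subj_group = df.groupby(subject)[between].first()
    group_mean = subj_mean.groupby(subj_group).mean()
    time_mean = df.groupby(within)[outcome].mean()
    cell_mean = df.groupby([between, within])[outcome].mean()
    n_per_group = subj_group.value_counts()
    n_subj = int(len(subj_mean))
    g = int(len(group_mean))
    t = int(n_times)

    ss_between = t * float(
        sum(n_per_group[gr] * (group_mean[gr] - grand) ** 2 for gr in group_mean.index)
    )
    ss_subj_within = t * float(
        sum((subj_mean[s] - group_mean[subj_group[s]]) ** 2 for s in subj_mean.index)
    )
    ss_time = n_subj * float(sum((time_mean[tt] - grand) ** 2 for tt in time_mean.index))
    ss_int = float(
        sum(
            n_per_group[gr]
            * (cell_mean[(gr, tt)] - group_mean[gr] - time_mean[tt] + grand) ** 2
            for gr in group_mean.index
            for tt in time_mean.index
        )
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = max(ss_total - ss_between - ss_subj_within - ss_time - ss_int, 0.0)

    df_err = (n_subj - g) * (t - 1)
    flags: list[str] = []
    eps = 1.0
    if gg_correction:
        eps = _gg_epsilon(df, subject, within, outcome)
        flags.append(f"greenhouse_geisser_eps={eps:.4f}")
    effects = {
        "between": _ratio_test(ss_between, g - 1, ss_subj_within, n_subj - g,
                               flags, "between"),
        "within": _ratio_test(ss_time, (t - 1) * eps, ss_err, df_err * eps,
                              flags, "within"),
        "interaction": _ratio_test(ss_int, (g - 1) * (t - 1) * eps, ss_err,
                                   df_err * eps, flags, "interaction"),
    }
    cells = _cell_means(df, outcome, [between, within])
    return AnovaResult(effects=effects, cell_means=cells, flags=flags)


def _gg_epsilon(df: pd.DataFrame, subject: str, within: str, outcome: str) -> float:
    """Greenhouse-Geisser epsilon from the within-subject covariance matrix."""
    wide = df.pivot(index=subject, columns=within, values=outcome).to_numpy()
    t = wide.shape[1]
    S = np.cov(wide, rowvar=False, ddof=1)
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    denom = (t - 1) * float(np.sum(Sc**2))
    if denom < _EPS:
        return 1.0
    return float(min(max(np.trace(Sc) ** 2 / denom, 1.0 / (t - 1)), 1.0))


def adjust_pvalues(
    pvals: Sequence[float],
    method: str,
    alpha: float = 0.05,
    clip_at_raw: bool = True,
) -> np.ndarray:
    """Multiple-comparison adjusted p-values.

    ``holm_sidak`` is the step-down Šídák procedure; ``bky_fdr`` is the
    Benjamini-Krieger-Yekutieli two-stage linear step-up FDR.  The adaptive
    BKY stage can legitimately yield corrected values below the raw p; by
    default those are lower-bounded at the raw p (``clip_at_raw``), a
    conservative convention that preserves p_adj >= p.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if method == "holm_sidak":
        adj = multipletests(p, method="holm-sidak")[1]
    elif method == "bky_fdr":
        adj = multipletests(p, alpha=alpha, method="fdr_tsbky")[1]
        if clip_at_raw:
            adj = np.maximum(adj, p)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return np.minimum(adj, 1.0)


def posthoc(
    table: pd.DataFrame,
    outcome: str,
    method: str,
    factor_a: str = "surgery",
    factor_b: str = "housing",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise comparisons of the factorial design cells.

    Comparisons use the pooled residual mean square of the full two-way model
    (cells = factor_a x factor_b combinations).  ``method`` selects the
    adjustment: ``tukey`` (studentized range), ``holm_sidak``, or ``bky_fdr``
    (two-stage FDR, reported values lower-bounded at the raw p).
    """
    if method not in POSTHOC_METHODS:
        raise ValueError(f"unknown post-hoc method {method!r}; choose {POSTHOC_METHODS}")
    df = table[[factor_a, factor_b, outcome]].dropna().copy()
    df["_cell"] = df[factor_a].astype(str) + "-" + df[factor_b].astype(str)
    groups = df.groupby("_cell", observed=True)[outcome]
    means = groups.mean()
    ns = groups.count()
    k = len(means)
    if k < 2:
        raise ValueError("post-hoc comparisons need at least 2 design cells")
    n_total = int(ns.sum())
    df_resid = n_total - k
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for post-hoc tests")
    ss_resid = float(((df[outcome] - df["_cell"].map(means)) ** 2).sum())
    mse = ss_resid / df_resid
    degenerate = mse < _EPS

    labels = list(means.index)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            diff = float(means[a] - means[b])
            if degenerate:
                se = 0.0
                t = 0.0 if abs(diff) < _EPS else float("inf")
                p_raw = 1.0 if abs(diff) < _EPS else 0.0
            else:
                se = float(np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b])))
                t = diff / se
                p_raw = float(2.0 * sps.t.sf(abs(t), df_resid))
            rows.append({"group1": a, "group2": b, "diff": diff, "se": se,
                         "t": t, "p_raw": p_raw})
    out = pd.DataFrame(rows)
    if method == "tukey":
        if degenerate:
            out["p_adj"] = [1.0 if abs(d) < _EPS else 0.0 for d in out["diff"]]
        else:
            out["p_adj"] = [
                float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_resid))
                for t in out["t"]
            ]
            out["p_adj"] = np.minimum(np.maximum(out["p_adj"], out["p_raw"]), 1.0)
    else:
        out["p_adj"] = adjust_pvalues(out["p_raw"].to_numpy(), method, alpha=alpha)
    out["method"] = method
    out["reject"] = out["p_adj"] < alpha
    return out


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    flags: list[str] = field(default_factory=list)


def unpaired_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> TTestResult:
    """Two-sided unpaired t-test (Student pooled by default, Welch optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    var_a, var_b = np.var(a, ddof=1), np.var(b, ddof=1)
    if var_a == 0 and var_b == 0:
        df = float(a.size + b.size - 2)
        if np.mean(a) == np.mean(b):
            return TTestResult(0.0, df, 1.0, ["zero_variance_equal_means"])
        return TTestResult(float("inf") * np.sign(np.mean(a) - np.mean(b)),
                           df, 0.0, ["zero_variance"])
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(a.size + b.size - 2) if equal_var else float(res.df)
    return TTestResult(float(res.statistic), df, float(res.pvalue), [])
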