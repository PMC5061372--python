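"""Univariate and covariate-adjusted group comparisons.

Reproduces the demographic and index comparison machinery of a standard
case-control analysis: Welch two-sample t-tests (computable directly from
printed mean/SD/n summaries), Pearson chi-square tests on 2x2 contingency
tables, tie-corrected Mann-Whitney rank tests with exact small-sample
enumeration, and linear mixed-effects models with a per-subject random
intercept adjusting for age, sex and handedness.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .indices import SubjectRecord, INDEX_NAMES

#: switch from exact Mann-Whitney enumeration to the normal approximation
#: above this pooled sample size
MW_EXACT_MAX_N = 20


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    sd: float
    n: int

    def validate(self) -> "SummaryStat":
        if self.sd < 0 or self.n < 2:
            raise ValueError(f"invalid summary {self}")
        return self


def welch_t_from_summary(a: SummaryStat, b: SummaryStat
                         ) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from group summaries.

    Returns (t, Welch-Satterthwaite df, two-sided p). The sign convention
    is mean(b) - mean(a). Degenerate zero-variance inputs follow the
    convention p = 1 for equal means and p = 0 otherwise.
    """
    a.validate(); b.validate()
    va = a.sd * a.sd / a.n
    vb = b.sd * b.sd / b.n
    if va + vb == 0:
        return (0.0, float(a.n + b.n - 2), 1.0) if a.mean == b.mean else (
            math.inf if b.mean > a.mean else -math.inf,
            float(a.n + b.n - 2), 0.0)
    t = (b.mean - a.mean) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va * va / (a.n - 1) + vb * vb / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch t-test on raw samples, via their sufficient summaries."""
    x = np.asarray(x, float); y = np.asarray(y, float)
    return welch_t_from_summary(
        SummaryStat(float(np.mean(x)), float(np.std(x, ddof=1)), x.size),
        SummaryStat(float(np.mean(y)), float(np.std(y, ddof=1)), y.size))


def chisq_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    tab = np.asarray(table, float)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def _u_statistic(ranks_x: np.ndarray, n_x: int, n_y: int) -> float:
    return float(np.sum(ranks_x)) - n_x * (n_x + 1) / 2.0


def mann_whitney(x: Sequence[float], y: Sequence[float]
                 ) -> tuple[float, float]:
    """Tie-corrected Mann-Whitney U test, two-sided.

    U is the midrank U statistic of the first sample. For pooled sample
    sizes of at most ``MW_EXACT_MAX_N`` the p-value is computed by exact
    enumeration of all label assignments (valid under ties); otherwise the
    tie-corrected normal approximation is used.
    """
    x = np.asarray(x, float); y = np.asarray(y, float)
    n_x, n_y = x.size, y.size
    if n_x == 0 or n_y == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_x], n_x, n_y)
    n = n_x + n_y
    if n <= MW_EXACT_MAX_N:
        mu = n_x * n_y / 2.0
        dev = abs(u_obs - mu)
        hits = total = 0
        offset = n_x * (n_x + 1) / 2.0
        for comb in itertools.combinations(range(n), n_x):
            u = ranks[list(comb)].sum() - offset
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return u_obs, float(res.pvalue)


def _check_full_rank(exog: pd.DataFrame) -> None:
    X = np.asarray(exog, float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a removable covariate column (prefer not to blame the intercept)
        order = sorted(range(X.shape[1]),
                       key=lambda j: exog.columns[j] == "Intercept")
        for j in order:
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(
                    f"singular design: column {exog.columns[j]!r} is collinear")
        raise ValueError("singular design matrix")


def fit_mixed_model(data: pd.DataFrame, value_col: str = "value"
                    ) -> dict[str, float]:
    """Linear mixed model: value ~ group + age + sex + handedness,
    random intercept per subject, fit by REML.

    ``data`` holds one row per trial with columns ``subject_id``, ``group``
    ("PD"/"control"), ``age``, ``sex``, ``handedness`` and the value column.
    Returns the group (PD vs control) fixed effect, its SE and p-value.
    """
    counts = data.groupby("subject_id").size()
    if (counts < 2).any():
        raise ValueError("need >= 2 observations per subject for a random "
                         "intercept model")
    formula = (f"{value_col} ~ C(group, Treatment('control')) + age "
               f"+ C(sex) + C(handedness)")
    model = smf.mixedlm(formula, data=data, groups=data["subject_id"])
    _check_full_rank(model.data.orig_exog)
    # a near-zero between-subject variance can make the REML surface
    # degenerate for some optimizers; fall back before giving up
    fit = None
    last_err: Exception | None = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=True, method=method)
            break
        except (np.linalg.LinAlgError, ValueError) as err:
            last_err = err
    if fit is None:
        raise RuntimeError(f"mixed model failed to fit: {last_err}")
    term = "C(group, Treatment('control'))[T.PD]"
    # statsmodels reports Wald z p-values, which are anticonservative for a
    # between-subject effect at modest cohort sizes; use a t reference with
    # between-subject degrees of freedom instead
    n_subjects = data["subject_id"].nunique()
    df_between = max(n_subjects - model.data.orig_exog.shape[1], 1)
    tval = float(fit.params[term]) / float(fit.bse[term])
    p_t = float(2.0 * stats.t.sf(abs(tval), df_between))
    return {
        "estimate": float(fit.params[term]),
        "se": float(fit.bse[term]),
        "p_value": p_t,
        "df": float(df_between),
        "group_var": float(fit.cov_re.iloc[0, 0]),
        "resid_var": float(fit.scale),
        "converged": bool(fit.converged),
    }


def _iqr(v: np.ndarray) -> float:
    """Single-width IQR Q3 - Q1 with linearly interpolated quartiles."""
    q1, q3 = np.percentile(v, [25, 75])
    return float(q3 - q1)


def comparison_table(records: Sequence[SubjectRecord],
                     holm: bool = False) -> pd.DataFrame:
    """Index comparison table: dominant-hand block plus hand-difference block.

    Dominant-hand rows report mean +/- SD per group with a Welch t-test,
    except SWVI which (as a skewed ratio index) reports median (IQR) with a
    Mann-Whitney test; all dominant/non-dominant difference rows report
    median (IQR) with Mann-Whitney tests. ``holm`` optionally applies a
    Holm step-down adjustment across the 12 rows.
    """
    pd_rec = [r for r in records if r.meta.group == "PD"]
    ct_rec = [r for r in records if r.meta.group == "control"]
    if len(pd_rec) < 2 or len(ct_rec) < 2:
        raise ValueError(
            f"need >= 2 subjects per group, got PD={len(pd_rec)}, "
            f"control={len(ct_rec)}")
    rows = []
    for block, getter in (("dominant", lambda r, n: getattr(r.dom, n)),
                          ("difference", lambda r, n: getattr(r.diff, n))):
        for name in INDEX_NAMES:
            ct = np.array([getter(r, name) for r in ct_rec])
            pdv = np.array([getter(r, name) for r in pd_rec])
            nonparam = block == "difference" or name == "SWVI"
            if nonparam:
                u, p = mann_whitney(ct, pdv)
                rows.append({
                    "block": block, "index": name, "test": "mann_whitney",
                    "control_center": float(np.median(ct)),
                    "control_spread": _iqr(ct),
                    "pd_center": float(np.median(pdv)),
                    "pd_spread": _iqr(pdv),
                    "summary": "median (IQR)",
                    "statistic": u, "p_value": p,
                    "n_control": ct.size, "n_pd": pdv.size,
                })
            else:
                t, _, p = welch_t(ct, pdv)
                rows.append({
                    "block": block, "index": name, "test": "welch_t",
                    "control_center": float(np.mean(ct)),
                    "control_spread": float(np.std(ct, ddof=1)),
                    "pd_center": float(np.mean(pdv)),
                    "pd_spread": float(np.std(pdv, ddof=1)),
                    "summary": "mean +/- SD",
                    "statistic": t, "p_value": p,
                    "n_control": ct.size, "n_pd": pdv.size,
                })
    table = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests
        table["p_holm"] = multipletests(table["p_value"], method="holm")[1]
    return table


def demographics_table(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Demographic comparison: age (Welch t), sex and handedness (chi-square)."""
    pd_rec = [r for r in records if r.meta.group == "PD"]
    ct_rec = [r for r in records if r.meta.group == "control"]
    age_ct = np.array([r.meta.age for r in ct_rec])
    age_pd = np.array([r.meta.age for r in pd_rec])
    t, _, p_age = welch_t(age_ct, age_pd)
    rows = [{"variable": "age", "test": "welch_t",
             "control": f"{np.mean(age_ct):.2f}+/-{np.std(age_ct, ddof=1):.2f}",
             "pd": f"{np.mean(age_pd):.2f}+/-{np.std(age_pd, ddof=1):.2f}",
             "statistic": t, "p_value": p_age}]
    for var, level in (("sex", "F"), ("handedness", "right")):
        ct_yes = sum(getattr(r.meta, var) == level for r in ct_rec)
        pd_yes = sum(getattr(r.meta, var) == level for r in pd_rec)
        tab = [[ct_yes, len(ct_rec) - ct_yes], [pd_yes, len(pd_rec) - pd_yes]]
        try:
            chi2, p = chisq_2x2(tab)
        except ValueError:  # a degenerate margin (e.g. everyone right-handed)
            chi2, p = float("nan"), float("nan")
        rows.append({"variable": var, "test": "chisq",
                     "control": f"{ct_yes} ({100 * ct_yes / len(ct_rec):.0f}%)",
                     "pd": f"{pd_yes} ({100 * pd_yes / len(pd_rec):.0f}%)",
                     "statistic": chi2, "p_value": p})
    return pd.DataFrame(rows)


def anova_by_label(values: Sequence[float], labels: Sequence[str]
                   ) -> tuple[float, float]:
    """One-way ANOVA of an index across >= 2 labeled groups (e.g. motor
    subtype labels carried as optional metadata)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
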