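"""Statistical layer: mixed two-way (split-plot) ANOVA with eta squared
and Fisher LSD post-hocs, exact Mann-Whitney U, unpaired t, Bonferroni.

The mixed ANOVA is computed from explicit sums of squares so every
stratum can be verified by hand: with one between factor (group) and one
within factor (time), and every subject measured at every timepoint,

    SS_total = SS_group + SS_subj(group) + SS_time + SS_group:time + SS_error

where SS_subj(group) is the between-subject error stratum (tests the
group effect) and SS_error the within-subject error stratum (tests time
and the interaction).  Unequal group sizes are handled by the classical
weighted-means decomposition, exact when all subjects share the full
timepoint schedule.  Effect size is classical eta squared,
SS_effect / SS_total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "mixed_anova",
    "eta_squared",
    "lsd_posthoc",
    "mann_whitney_exact",
    "t_test_unpaired",
    "bonferroni",
]


@dataclass
class AnovaResult:
    """Per-effect sums of squares, F and p, plus design bookkeeping."""

    table: pd.DataFrame          # index: effect; columns: ss, df, ms, F, p, eta_sq
    ss_total: float
    design: dict = field(default_factory=dict)

    def p_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]


def _pivot(table: pd.DataFrame, subject, group, time, value):
    df = table[[subject, group, time, value]].dropna()
    wide = df.pivot_table(index=subject, columns=time, values=value, aggfunc="mean")
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"missing cells for subjects {missing}; use listwise deletion")
    gmap = df.groupby(subject)[group].agg(lambda s: s.iloc[0])
    ngroups = df.groupby(subject)[group].nunique()
    if (ngroups > 1).any():
        raise ValueError("a subject appears in more than one group")
    groups = gmap.loc[wide.index]
    return wide, groups


def mixed_anova(
    table: pd.DataFrame,
    subject: str = "subject",
    group: str = "group",
    time: str = "timepoint",
    value: str = "value",
) -> AnovaResult:
    """Split-plot ANOVA: between factor `group`, within factor `time`.

    Requires >= 2 groups, >= 2 timepoints and >= 2 subjects per group,
    with every subject observed at every timepoint.
    """
    wide, groups = _pivot(table, subject, group, time, value)
    y = wide.to_numpy(float)                   # subjects x timepoints
    n_subj, n_time = y.shape
    glabels = groups.to_numpy()
    glevels = pd.unique(glabels)
    n_g = {g: int((glabels == g).sum()) for g in glevels}
    if len(glevels) < 2:
        raise ValueError("need >= 2 groups")
    if n_time < 2:
        raise ValueError("need >= 2 timepoints")
    if min(n_g.values()) < 2:
        raise ValueError("need >= 2 subjects per group")

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = y.mean(axis=1)
    ss_between_subj = n_time * float(((subj_means - grand) ** 2).sum())
    group_means = {g: y[glabels == g].mean() for g in glevels}
    ss_group = n_time * sum(n_g[g] * (group_means[g] - grand) ** 2 for g in glevels)
    ss_subj_within = ss_between_subj - ss_group

    time_means = y.mean(axis=0)
    ss_time = n_subj * float(((time_means - grand) ** 2).sum())
    cell_means = np.stack([y[glabels == g].mean(axis=0) for g in glevels])
    ss_cells = sum(
        n_g[g] * float(((cell_means[i] - grand) ** 2).sum())
        for i, g in enumerate(glevels)
    )
    ss_int = ss_cells - ss_group - ss_time
    ss_error = ss_total - ss_between_subj - ss_time - ss_int

    g = len(glevels)
    df_group = g - 1
    df_sw = n_subj - g
    df_time = n_time - 1
    df_int = df_group * df_time
    df_err = df_sw * df_time

    def row(ss, df, ms_err, df_err_):
        ms = ss / df if df else np.nan
        if ms_err is None or ms_err <= 0 or df_err_ == 0:
            f = np.nan if ms_err is None else (0.0 if ss <= 1e-300 else np.inf)
            p = np.nan if ms_err is None else (1.0 if ss <= 1e-300 else 0.0)
        else:
            f = ms / ms_err
            p = float(sps.f.sf(f, df, df_err_))
        return ss, df, ms, f, p

    ms_sw = ss_subj_within / df_sw if df_sw else np.nan
    ms_err = ss_error / df_err if df_err else np.nan
    rows = {
        "group": row(ss_group, df_group, ms_sw, df_sw),
        "subject(group)": (ss_subj_within, df_sw, ms_sw, np.nan, np.nan),
        "time": row(ss_time, df_time, ms_err, df_err),
        "group:time": row(ss_int, df_int, ms_err, df_err),
        "error": (ss_error, df_err, ms_err, np.nan, np.nan),
    }
    tab = pd.DataFrame(rows, index=["ss", "df", "ms", "F", "p"]).T
    tab["eta_sq"] = tab["ss"] / ss_total
    return AnovaResult(
        table=tab,
        ss_total=ss_total,
        design={
            "groups": {g_: n_g[g_] for g_ in glevels},
            "n_time": n_time,
            "time_levels": list(wide.columns),
            "wide": wide,
            "group_labels": groups,
        },
    )


def eta_squared(result: AnovaResult, effect: str) -> float:
    """Classical eta squared: SS_effect / SS_total."""
    if result.ss_total <= 0:
        raise ValueError("SS_total is zero; eta squared undefined")
    return float(result.table.loc[effect, "ss"] / result.ss_total)


def lsd_posthoc(
    result: AnovaResult,
    effect: str = "group",
    alpha: float = 0.05,
    override: bool = False,
    per_timepoint: bool = False,
) -> pd.DataFrame:
    """Fisher LSD pairwise comparisons after a significant omnibus test.

    For the between factor, group means (over all timepoints) are
    compared with the subject(group) error stratum.  With
    ``per_timepoint=True`` (the partial-interaction follow-up) groups
    are compared separately at each timepoint by one-way LSD on the
    cell data.  P values are unadjusted, as LSD prescribes.
    """
    omni = result.p_value("group:time" if per_timepoint else effect)
    if not override and not (omni < alpha):
        raise ValueError(
            f"omnibus p = {omni:.4g} not significant at alpha = {alpha}; "
            "pass override=True to force the post-hoc"
        )
    wide: pd.DataFrame = result.design["wide"]
    groups: pd.Series = result.design["group_labels"]
    glevels = pd.unique(groups.to_numpy())
    rows = []
    if not per_timepoint:
        n_time = result.design["n_time"]
        ms_sw = float(result.table.loc["subject(group)", "ms"])
        df_sw = int(result.table.loc["subject(group)", "df"])
        subj_means = wide.mean(axis=1)
        for a, b in combinations(glevels, 2):
            ma, mb = subj_means[groups == a], subj_means[groups == b]
            se = np.sqrt(ms_sw / n_time * (1 / len(ma) + 1 / len(mb)))
            tstat = (ma.mean() - mb.mean()) / se
            p = 2 * sps.t.sf(abs(tstat), df_sw)
            rows.append({"level": "all", "a": a, "b": b, "diff": ma.mean() - mb.mean(),
                         "t": float(tstat), "df": df_sw, "p": float(p)})
    else:
        for tp in wide.columns:
            col = wide[tp]
            cells = {g: col[groups == g].to_numpy(float) for g in glevels}
            df_err = sum(len(v) - 1 for v in cells.values())
            mse = sum(((v - v.mean()) ** 2).sum() for v in cells.values()) / df_err
            for a, b in combinations(glevels, 2):
                va, vb = cells[a], cells[b]
                se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
                if se == 0:
                    tstat, p = 0.0, 1.0
                else:
                    tstat = (va.mean() - vb.mean()) / se
                    p = 2 * sps.t.sf(abs(tstat), df_err)
                rows.append({"level": tp, "a": a, "b": b,
                             "diff": va.mean() - vb.mean(),
                             "t": float(tstat), "df": df_err, "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------- Mann-Whitney

@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple:
    """Number of rank arrangements yielding each U value, U = 0..n*m."""
    # dynamic programme over c[n, m, u] = c[n-1, m, u-m] + c[n, m-1, u]
    table = {(0, j): np.array([1.0]) for j in range(m + 1)}
    for i in range(1, n + 1):
        prev_row = table[(i - 1, 0)]
        table[(i, 0)] = np.array([1.0])
        for j in range(1, m + 1):
            a = table[(i - 1, j)]
            b = table[(i, j - 1)]
            out = np.zeros(i * j + 1)
            out[j:] += a if len(a) == i * j + 1 - j else np.pad(a, (0, i * j + 1 - j - len(a)))
            out[: len(b)] += b
            table[(i, j)] = out
    res = table[(n, m)]
    return tuple(res)


def _exact_two_sided_p(u: float, n: int, m: int) -> float:
    counts = np.asarray(_u_counts(n, m))
    total = counts.sum()
    u_int = int(round(u))
    cdf = counts[: u_int + 1].sum() / total
    sf = counts[u_int:].sum() / total
    return float(min(1.0, 2.0 * min(cdf, sf)))


def mann_whitney_exact(a, b, alternative: str = "two-sided") -> dict:
    """Mann-Whitney U test; exact enumeration for n+m <= 20 without ties,
    tie-corrected normal approximation otherwise.

    Returns {'U': U statistic of sample a, 'p': p value, 'method': ...}.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra = ranks[:n].sum()
    u_a = ra - n * (n + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n + m
    if np.all(pooled == pooled[0]):
        return {"U": float(u_a), "p": 1.0, "method": "degenerate (all tied)"}
    if not has_ties and n + m <= 20:
        if alternative == "two-sided":
            p = _exact_two_sided_p(u_a, n, m)
        else:
            counts = np.asarray(_u_counts(n, m))
            total = counts.sum()
            ui = int(round(u_a))
            p = counts[ui:].sum() / total if alternative == "greater" else counts[: ui + 1].sum() / total
        return {"U": float(u_a), "p": float(p), "method": "exact"}
    # tie-corrected normal approximation with continuity correction
    N = n + m
    mu = n * m / 2.0
    tie_counts = np.unique(pooled, return_counts=True)[1]
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return {"U": float(u_a), "p": 1.0, "method": "degenerate"}
    sigma = np.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(u_a - mu) - 0.5) / sigma
        p = 2 * sps.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        p = sps.norm.sf((u_a - mu - 0.5) / sigma)
    else:
        p = sps.norm.cdf((u_a - mu + 0.5) / sigma)
    return {"U": float(u_a), "p": float(min(p, 1.0)), "method": "normal"}


# ------------------------------------------------------------- t / bonf

def t_test_unpaired(a, b) -> dict:
    """Two-sided pooled-variance Student t test."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    n, m = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n + m - 2)
    if sp2 == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": n + m - 2, "p": 1.0}
        return {"t": np.inf, "df": n + m - 2, "p": 0.0}
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n + 1 / m))
    return {"t": float(t), "df": n + m - 2, "p": float(2 * sps.t.sf(abs(t), n + m - 2))}


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p * m, capped at 1."""
    p = np.asarray(pvals, float)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(p * m, 1.0)
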