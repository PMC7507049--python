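"""Group statistics on connectivity time series and window-averaged PLI.

Three stages localize and quantify group differences:

1. :func:`pointwise_ttest` -- an independent two-sample t-test at every
   time sample of the global-connectivity series, one-tailed in a stated
   direction, uncorrected across time; contiguous significant samples form
   the reported time window(s).
2. :func:`window_mean` -- per-subject average of a series (or tensor) over
   a closed ms window; the band defaults in :data:`DEFAULT_WINDOWS_MS`
   are the pooled significant ranges used for window-averaged PLI.
3. :func:`mixed_anova` -- the 2 (group, between) x 2 (intensity, within)
   x 3 (stimulus type, within) split-plot ANOVA with Greenhouse-Geisser
   correction for within effects, partial eta squared per effect, and
   Bonferroni-adjusted pairwise post hocs.

The split-plot ANOVA is computed from orthonormal within-subject contrasts
on the balanced subject x cell table: for each within effect the subject
scores are projected onto a Kronecker-product contrast basis, the effect,
group-interaction and error sums of squares follow from group means of the
projected scores, and the Greenhouse-Geisser epsilon comes from the pooled
within-group covariance of the same projections.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_WINDOWS_MS",
    "GroupComparison",
    "AnovaResult",
    "pointwise_ttest",
    "window_mean",
    "gg_epsilon",
    "mixed_anova",
    "pairwise_posthoc",
]

#: Default band windows (ms, closed) for window-averaged PLI: the pooled
#: ranges over which the groups' global connectivity differed.
DEFAULT_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "theta": (52.0, 348.0),
    "alpha": (108.0, 328.0),
    "beta": (108.0, 240.0),
    "gamma": (0.0, 200.0),
}


@dataclass
class GroupComparison:
    """Pointwise two-sample comparison of two groups' time series."""

    times_ms: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    mask: np.ndarray                       # p <= alpha
    windows_ms: list[tuple[float, float]]  # contiguous significant runs
    tail: str
    alpha: float


@dataclass
class AnovaResult:
    """Mixed-ANOVA effect table plus optional post hoc comparisons.

    ``table`` has one row per effect with columns ``effect, ss, ss_error,
    df1, df2, F, eps, df1_corr, df2_corr, p, eta_p2``; ``p`` is
    Greenhouse-Geisser corrected wherever ``eps < 1`` applies (between
    effects carry ``eps = 1``).
    """

    table: pd.DataFrame
    posthoc: pd.DataFrame | None = None

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect named {name!r}")
        return row.iloc[0]


# ---------------------------------------------------------------------------
# Pointwise comparison
# ---------------------------------------------------------------------------

def _contiguous_windows(times: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return [(float(times[s]), float(times[e])) for s, e in zip(starts, ends)]


def pointwise_ttest(
    series_a: np.ndarray,
    series_b: np.ndarray,
    times_ms: np.ndarray,
    *,
    tail: str = "greater",
    alpha: float = 0.05,
) -> GroupComparison:
    """Independent two-sample t-test at each time point.

    ``series_a`` and ``series_b`` are (subjects, samples) arrays on a
    common time axis.  ``tail='greater'`` tests A > B, ``'less'`` tests
    A < B, ``'two-sided'`` both.  Contiguous samples with ``p <= alpha``
    form the reported windows; no correction across samples is applied.
    """
    a = np.atleast_2d(np.asarray(series_a, float))
    b = np.atleast_2d(np.asarray(series_b, float))
    times = np.asarray(times_ms, float)
    if a.shape[1] != b.shape[1] or a.shape[1] != times.size:
        raise ValueError("time axes of the two groups do not match")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError("tail must be 'greater', 'less' or 'two-sided'")
    t, p = stats.ttest_ind(a, b, axis=0, alternative=tail)
    mask = np.nan_to_num(p, nan=1.0) <= alpha
    return GroupComparison(
        times_ms=times,
        t_values=t,
        p_values=p,
        mask=mask,
        windows_ms=_contiguous_windows(times, mask),
        tail=tail,
        alpha=alpha,
    )


def window_mean(
    values: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
) -> np.ndarray | float:
    """Mean of ``values`` over samples inside the closed ms window.

    ``values`` may be a 1-D series or any array whose *last* axis is time;
    the window must lie within the time axis.  Linear in ``values``.
    """
    times = np.asarray(times_ms, float)
    lo, hi = window_ms
    if lo > hi:
        raise ValueError("window start exceeds window end")
    if lo < times.min() or hi > times.max():
        raise ValueError(
            f"window {window_ms} outside time axis [{times.min():g}, {times.max():g}] ms"
        )
    sel = (times >= lo) & (times <= hi)
    if not sel.any():
        raise ValueError("window contains no samples")
    out = np.asarray(values, float)[..., sel].mean(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Mixed (split-plot) ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts spanning the deviation space
    (Helmert basis, rows orthonormal and orthogonal to the constant)."""
    h = np.zeros((k - 1, k))
    for i in range(1, k):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -float(i)
        h[i - 1] /= np.linalg.norm(h[i - 1])
    return h


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of a d x d contrast-space covariance:
    ``tr(S)^2 / (d * tr(S @ S))``, equal to 1 exactly under sphericity
    (S proportional to the identity) and bounded below by 1/d."""
    s = np.asarray(cov, float)
    d = s.shape[0]
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    if tr2 <= 0:
        return 1.0
    return float(tr**2 / (d * tr2))


def mixed_anova(
    data: pd.DataFrame,
    *,
    dv: str = "value",
    subject: str = "subject",
    between: str = "group",
    within: tuple[str, str] = ("intensity", "stim_type"),
) -> AnovaResult:
    """Three-way mixed ANOVA: one between-subject factor, two
    within-subject factors, balanced design, one observation per cell.

    For each within effect, Greenhouse-Geisser corrected degrees of
    freedom are used for the p-value whenever the effect has more than one
    numerator df (epsilon is 1 by construction for single-df effects).
    Partial eta squared is ``SS_effect / (SS_effect + SS_error)`` with the
    effect's own error term.  Post hoc tables are produced separately via
    :func:`pairwise_posthoc`.

    Raises
    ------
    ValueError
        On missing cells, replicated cells, or unbalanced group sizes.
    """
    w1, w2 = within
    wide = data.pivot_table(
        index=[subject, between], columns=[w1, w2], values=dv, aggfunc="count"
    )
    if wide.isna().any().any():
        raise ValueError("missing cells: design must be complete")
    if (wide != 1).any().any():
        raise ValueError("expected exactly one observation per subject per cell")

    wide = data.pivot_table(index=[subject, between], columns=[w1, w2], values=dv)
    wide = wide.sort_index(axis=1)
    groups_lab = wide.index.get_level_values(between).to_numpy()
    y = wide.to_numpy()                      # (N, b*c)
    levels1 = wide.columns.get_level_values(0).unique()
    levels2 = wide.columns.get_level_values(1).unique()
    b, c = len(levels1), len(levels2)
    glevels = pd.unique(groups_lab)
    a = len(glevels)
    n_total = y.shape[0]
    counts = np.array([(groups_lab == g).sum() for g in glevels])
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per group")
    if len(set(counts)) != 1:
        raise ValueError("groups must be balanced")
    n = counts[0]
    m = b * c

    rows = []

    # --- between-subject stratum ---------------------------------------
    u = y.mean(axis=1)  # subject means over within cells
    grand = u.mean()
    g_means = np.array([u[groups_lab == g].mean() for g in glevels])
    ss_between = m * n * float(((g_means - grand) ** 2).sum())
    g_index = {g: gi for gi, g in enumerate(glevels)}
    resid = u - g_means[[g_index[g] for g in groups_lab]]
    ss_subj = m * float((resid**2).sum())
    df1, df2 = a - 1, n_total - a
    f = (ss_between / df1) / (ss_subj / df2)
    rows.append({
        "effect": between, "ss": ss_between, "ss_error": ss_subj,
        "df1": df1, "df2": df2, "F": f, "eps": 1.0,
        "df1_corr": float(df1), "df2_corr": float(df2),
        "p": float(stats.f.sf(f, df1, df2)),
        "eta_p2": ss_between / (ss_between + ss_subj),
    })

    # --- within-subject strata ------------------------------------------
    c1 = _orthonormal_contrasts(b)
    c2 = _orthonormal_contrasts(c)
    one1 = np.full((1, b), 1.0 / np.sqrt(b))
    one2 = np.full((1, c), 1.0 / np.sqrt(c))
    effects = {
        w1: np.kron(c1, one2),
        w2: np.kron(one1, c2),
        f"{w1} * {w2}": np.kron(c1, c2),
    }
    for ename, mat in effects.items():
        d = mat.shape[0]
        z = y @ mat.T  # (N, d) contrast scores
        zbar = z.mean(axis=0)
        zg = np.vstack([z[groups_lab == g].mean(axis=0) for g in glevels])
        ss_eff = n_total * float(zbar @ zbar)
        ss_int = n * float(((zg - zbar) ** 2).sum())
        centered = z - zg[[g_index[g] for g in groups_lab]]
        ss_err = float((centered**2).sum())
        df_err = d * (n_total - a)
        pooled_cov = centered.T @ centered / (n_total - a)
        eps = gg_epsilon(pooled_cov) if d > 1 else 1.0
        for name, ss, dfe in ((ename, ss_eff, d), (f"{between} * {ename}", ss_int, d * (a - 1))):
            f_stat = (ss / dfe) / (ss_err / df_err)
            p = float(stats.f.sf(f_stat, dfe * eps, df_err * eps))
            rows.append({
                "effect": name, "ss": ss, "ss_error": ss_err,
                "df1": dfe, "df2": df_err, "F": f_stat, "eps": eps,
                "df1_corr": dfe * eps, "df2_corr": df_err * eps,
                "p": p, "eta_p2": ss / (ss + ss_err),
            })

    order = [between, w1, w2, f"{between} * {w1}", f"{between} * {w2}",
             f"{w1} * {w2}", f"{between} * {w1} * {w2}"]
    table = pd.DataFrame(rows)
    table["effect"] = pd.Categorical(table["effect"], categories=order, ordered=True)
    table = table.sort_values("effect").reset_index(drop=True)
    table["effect"] = table["effect"].astype(str)
    return AnovaResult(table=table)


def pairwise_posthoc(
    data: pd.DataFrame,
    factor: str,
    *,
    dv: str = "value",
    subject: str = "subject",
    paired: bool = True,
    adjust: str = "bonferroni",
    by: str | None = None,
) -> pd.DataFrame:
    """All pairwise comparisons between levels of ``factor``, Bonferroni
    adjusted over the family.

    Values are first averaged per subject per level (collapsing other
    factors).  ``paired`` selects paired (within factor) versus
    independent (between factor) t-tests.  ``by`` optionally stratifies
    the comparisons within levels of another factor (e.g. pairwise
    stimulus-type contrasts separately at each intensity), with the
    Bonferroni family spanning all emitted comparisons.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    strata = [(None, data)] if by is None else [
        (lvl, data[data[by] == lvl]) for lvl in pd.unique(data[by])
    ]
    rows = []
    for lvl, chunk in strata:
        means = chunk.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
        for la, lb in itertools.combinations(means.columns, 2):
            xa, xb = means[la], means[lb]
            if paired:
                t, p = stats.ttest_rel(xa, xb)
            else:
                t, p = stats.ttest_ind(xa.dropna(), xb.dropna())
            rows.append({
                "stratum": lvl, "level_a": la, "level_b": lb,
                "mean_a": float(xa.mean()), "mean_b": float(xb.mean()),
                "t": float(t), "p_uncorrected": float(p),
            })
    out = pd.DataFrame(rows)
    k = len(out)
    if adjust == "bonferroni":
        out["p_adjusted"] = np.minimum(out["p_uncorrected"] * k, 1.0)
    else:
        out["p_adjusted"] = out["p_uncorrected"]
    if by is None:
        out = out.drop(columns="stratum")
    return out
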