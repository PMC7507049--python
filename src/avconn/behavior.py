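"""Race-model analysis of redundant-signals reaction times.

The redundant-signals effect is the speed-up of responses to a combined
audio-visual (AV) stimulus over the faster of its unimodal parts.  Whether
the speed-up exceeds what parallel independent channels can produce is
tested against Miller's race-model bound

    P_race(t) = P_A(t) + P_V(t) - P_A(t) * P_V(t),

evaluated on empirical cumulative distribution functions segmented into
10-ms bins.  Exceeding the bound (a significantly positive
``P_AV - P_race`` at a bin) is evidence of audio-visual integration; the
contiguous significant bins form the integration window, and the mean
difference curve yields the peak benefit, its latency, and the positive
area under the curve (AUC, a unitless bin-sum) as summary indices.

Conventions (documented and deliberate):

* RTs below 200 ms or above 1700 ms are excluded; the bounds themselves
  are kept, and no further outlier trimming is applied.
* The CDF grid is the right edges of consecutive 10-ms bins covering
  0-1700 ms (170 points), matching the RT filter ceiling.
* Misses count in the CDF denominator by default (switchable), so a
  subject who never responds has a flat zero CDF rather than no CDF.
* The per-bin violation test is a two-tailed one-sample t-test at
  alpha = .05 with a positive-mean requirement, uncorrected across bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RT_FILTER_MS",
    "default_grid",
    "EmpiricalCDF",
    "RaceModelResult",
    "filter_rts",
    "hit_rate",
    "hit_rates",
    "empirical_cdf",
    "race_model_cdf",
    "race_difference_curves",
    "violation_test",
    "summarize_race",
]

#: Closed interval of admissible reaction times, ms.
RT_FILTER_MS: tuple[float, float] = (200.0, 1700.0)


def default_grid() -> np.ndarray:
    """Right edges of 10-ms bins covering 0-1700 ms: 10, 20, ..., 1700."""
    return np.arange(10.0, 1700.0 + 10.0, 10.0)


@dataclass
class EmpiricalCDF:
    """Cumulative response probability on a fixed ms grid."""

    grid: np.ndarray  # right bin edges, ms
    p: np.ndarray     # P(response and rt <= grid point)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.grid.shape != self.p.shape:
            raise ValueError("grid and p must have the same length")


@dataclass
class RaceModelResult:
    """Group summary of the race-model difference curves."""

    grid: np.ndarray
    diff_curves: np.ndarray        # (subjects, bins)
    mean_diff: np.ndarray          # (bins,)
    peak_benefit: float
    peak_latency_group_ms: float
    peak_latency_individual_ms: np.ndarray  # (subjects,)
    auc: float
    windows_ms: list[tuple[float, float]] | None = None


def filter_rts(table: pd.DataFrame) -> pd.DataFrame:
    """Remove trials with RT outside the closed interval [200, 1700] ms.

    Miss rows (no RT) are retained; no other outlier rule is applied.
    """
    lo, hi = RT_FILTER_MS
    rt = table["rt_ms"]
    keep = rt.isna() | ((rt >= lo) & (rt <= hi))
    return table.loc[keep].reset_index(drop=True)


def hit_rate(table: pd.DataFrame, subject: str, intensity: str, stim_type: str) -> float:
    """Correct responses over total target trials for one
    (subject, intensity, stimulus type) cell."""
    cell = table[
        (table["subject"] == subject)
        & (table["intensity"] == intensity)
        & (table["stim_type"] == stim_type)
        & table["is_target"]
    ]
    if cell.empty:
        raise ValueError(
            f"no target trials for ({subject}, {intensity}, {stim_type})"
        )
    return float(cell["correct"].mean())


def hit_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Hit rate per (subject, group, intensity, stim_type), long format."""
    tgt = table[table["is_target"]]
    out = (
        tgt.groupby(["subject", "group", "intensity", "stim_type"], observed=True)["correct"]
        .mean()
        .rename("hit_rate")
        .reset_index()
    )
    return out


def empirical_cdf(
    rts: np.ndarray | pd.Series,
    grid: np.ndarray | None = None,
    *,
    misses_in_denominator: bool = True,
) -> EmpiricalCDF:
    """Empirical CDF of one cell's target-trial RTs on the common grid.

    ``rts`` is the cell's full RT column: NaN entries are misses.  With
    ``misses_in_denominator`` (default) the denominator is the total number
    of target trials, so the CDF plateaus below 1 when misses occurred.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("no target trials in cell")
    if grid is None:
        grid = default_grid()
    responded = rts[~np.isnan(rts)]
    denom = rts.size if misses_in_denominator else responded.size
    if denom == 0:
        raise ValueError("no responses and misses excluded from denominator")
    counts = (responded[:, None] <= grid[None, :]).sum(axis=0)
    return EmpiricalCDF(grid=np.asarray(grid, float), p=counts / denom)


def race_model_cdf(cdf_a: EmpiricalCDF, cdf_v: EmpiricalCDF) -> EmpiricalCDF:
    """Miller bound ``P_A + P_V - P_A * P_V`` on a shared grid.

    The result dominates both unimodal CDFs pointwise and stays within
    [0, 1] by construction.
    """
    if cdf_a.grid.shape != cdf_v.grid.shape or not np.allclose(cdf_a.grid, cdf_v.grid):
        raise ValueError("CDF grids do not match")
    pa, pv = cdf_a.p, cdf_v.p
    return EmpiricalCDF(grid=cdf_a.grid.copy(), p=pa + pv - pa * pv)


def race_difference_curves(
    table: pd.DataFrame,
    *,
    group: str | None = None,
    intensity: str | None = None,
    grid: np.ndarray | None = None,
    misses_in_denominator: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-subject ``P_AV - P_race`` probability difference curves.

    Filters to one group/intensity (when given), builds each subject's A,
    V and AV CDFs from target trials, and subtracts the race bound from
    the AV CDF.

    Returns
    -------
    grid : ndarray of bin right-edges (ms)
    curves : ndarray (subjects, bins)
    subjects : list of subject ids, row order of ``curves``
    """
    if grid is None:
        grid = default_grid()
    sel = table["is_target"].to_numpy(copy=True)
    if group is not None:
        sel &= (table["group"] == group).to_numpy()
    if intensity is not None:
        sel &= (table["intensity"] == intensity).to_numpy()
    tgt = table[sel]
    curves, subjects = [], []
    for subject, sub in tgt.groupby("subject", sort=True, observed=True):
        cdfs = {}
        for st in ("A", "V", "AV"):
            cell = sub.loc[sub["stim_type"] == st, "rt_ms"]
            if cell.empty:
                raise ValueError(f"subject {subject} has no {st} target trials")
            cdfs[st] = empirical_cdf(
                cell.to_numpy(), grid, misses_in_denominator=misses_in_denominator
            )
        race = race_model_cdf(cdfs["A"], cdfs["V"])
        curves.append(cdfs["AV"].p - race.p)
        subjects.append(subject)
    if not curves:
        raise ValueError("no subjects matched the selection")
    return np.asarray(grid, float), np.vstack(curves), subjects


def _contiguous_windows(grid: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    """Maximal runs of True in ``mask`` as (start, end) grid values (ms).
    Single-bin runs are reported, not suppressed."""
    windows = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return windows
    starts = [idx[0]]
    ends = []
    for prev, cur in zip(idx[:-1], idx[1:]):
        if cur != prev + 1:
            ends.append(prev)
            starts.append(cur)
    ends.append(idx[-1])
    for s, e in zip(starts, ends):
        windows.append((float(grid[s]), float(grid[e])))
    return windows


def violation_test(
    diff_curves: np.ndarray,
    grid: np.ndarray | None = None,
    *,
    alpha: float = 0.05,
) -> tuple[list[tuple[float, float]], np.ndarray, np.ndarray]:
    """Race-model violation (integration) window from subject difference
    curves.

    At each 10-ms bin a one-sample two-tailed t-test compares the subject
    differences against zero; bins with ``p <= alpha`` *and* a positive
    mean are significant ("significantly greater than the race model"),
    and contiguous significant bins form the reported window(s).  Bins
    where every subject's difference is identical (zero variance, t
    undefined) are never significant.  No correction across bins.

    Returns ``(windows_ms, t_values, p_values)``.
    """
    curves = np.asarray(diff_curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need difference curves from at least 2 subjects")
    if grid is None:
        grid = default_grid()
    if curves.shape[1] != len(grid):
        raise ValueError("curves and grid lengths differ")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_1samp(curves, 0.0, axis=0)
    mask = np.nan_to_num(p, nan=1.0) <= alpha
    mask &= curves.mean(axis=0) > 0
    return _contiguous_windows(np.asarray(grid, float), mask), t, p


def summarize_race(
    diff_curves: np.ndarray,
    grid: np.ndarray | None = None,
    *,
    alpha: float = 0.05,
) -> RaceModelResult:
    """Group summary of the difference curves.

    The across-subject mean curve gives the peak benefit (its maximum),
    the group peak latency (time of the maximum) and the positive AUC
    (bin-sum of the positive part, unitless).  Individual peak latencies
    come from each subject's own curve and feed the between-group latency
    comparison.  The violation window is attached for convenience.
    """
    curves = np.asarray(diff_curves, dtype=float)
    if curves.size == 0:
        raise ValueError("empty difference curves")
    if curves.ndim != 2:
        raise ValueError("diff_curves must be (subjects, bins)")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, float)
    mean_diff = curves.mean(axis=0)
    peak_idx = int(np.argmax(mean_diff))
    windows = None
    if curves.shape[0] >= 2:
        windows, _, _ = violation_test(curves, grid, alpha=alpha)
    return RaceModelResult(
        grid=grid,
        diff_curves=curves,
        mean_diff=mean_diff,
        peak_benefit=float(mean_diff[peak_idx]),
        peak_latency_group_ms=float(grid[peak_idx]),
        peak_latency_individual_ms=grid[np.argmax(curves, axis=1)].astype(float),
        auc=float(np.clip(mean_diff, 0.0, None).sum()),
        windows_ms=windows,
    )
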