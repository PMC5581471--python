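"""Expression-stratified survival analysis.

Patients are split into low/high expression groups at an optimum
cutpoint — chosen by scanning a percentile grid and minimising the
two-group log-rank p — and the groups' Kaplan–Meier curves are compared.
This emulates the X-tile style of cutpoint selection; because the
minimal p over a scan is anti-conservative, a Miller–Siegmund corrected
p is reported alongside the raw one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "LogrankResult",
    "CutpointResult",
    "km_estimate",
    "logrank_test",
    "optimal_cutpoint",
    "miller_siegmund_p",
    "plot_km_groups",
]


@dataclass
class LogrankResult:
    statistic: float
    p: float
    reason: str | None = None  # "zero events" when the test is undefined


@dataclass
class CutpointResult:
    component: str
    cutpoint: float
    n_low: int
    n_high: int
    statistic: float
    p: float
    p_corrected: float
    direction: str  # "high_expression_worse" or "low_expression_worse"


def km_estimate(records: pd.DataFrame, label: str = "KM") -> KaplanMeierFitter:
    """Product-limit survival estimate for a clinical table.

    ``records`` needs columns ``time_days`` and ``event``.  Returns the
    fitted lifelines estimator (survival probabilities start at 1 and
    are non-increasing).
    """
    if records.empty:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(records["time_days"], event_observed=records["event"])
    return kmf


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> LogrankResult:
    """Two-group log-rank chi-square (1 df) with upper-tail chi-square p."""
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be nonempty")
    if int(group_a["event"].sum() + group_b["event"].sum()) == 0:
        return LogrankResult(float("nan"), float("nan"), "zero events")
    res = _ll_logrank(
        group_a["time_days"], group_b["time_days"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    return LogrankResult(float(res.test_statistic), float(res.p_value), None)


def _logrank_chi2(time: np.ndarray, event: np.ndarray, in_b: np.ndarray) -> tuple[float, float]:
    """Vectorised two-group log-rank: returns (chi2, O_b − E_b).

    Same hypergeometric observed-minus-expected statistic as the lifelines
    test; implemented directly so a cutpoint scan can evaluate thousands
    of splits cheaply.  Assumes ≥1 event overall.
    """
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order].astype(float), in_b[order].astype(float)
    n = t.size
    uniq, first = np.unique(t, return_index=True)
    # at-risk counts just before each distinct time
    n_at = n - first
    g_cum = np.concatenate(([0.0], np.cumsum(g)))
    nb_at = g_cum[-1] - g_cum[first]
    bounds = np.concatenate((first, [n]))
    d = np.add.reduceat(e, first)  # total deaths at each distinct time
    db = np.add.reduceat(e * g, first)  # deaths in group b
    mask = d > 0
    d, db, n_at, nb_at = d[mask], db[mask], n_at[mask], nb_at[mask]
    frac = nb_at / n_at
    o_minus_e = float(np.sum(db - d * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * frac * (1.0 - frac) * (n_at - d) / (n_at - 1.0)
    v = float(np.nansum(np.where(n_at > 1, v, 0.0)))
    if v <= 0:
        return (0.0, o_minus_e)
    return (o_minus_e * o_minus_e / v, o_minus_e)


def miller_siegmund_p(p_min: float, eps_low: float, eps_high: float) -> float:
    """Miller–Siegmund correction of a minimal log-rank p over a cutpoint scan.

    ``eps_low``/``eps_high`` are the scan's boundary fractions (e.g. 0.10
    and 0.90 for a 10th–90th percentile grid).  The corrected value is
    clipped to [p_min, 1].
    """
    if not (0 < p_min < 1):
        return min(max(p_min, 0.0), 1.0)
    z = stats.norm.isf(p_min / 2.0)
    if z <= 1e-8:
        return 1.0
    phi = stats.norm.pdf(z)
    span = math.log((1 - eps_low) * eps_high / (eps_low * (1 - eps_high)))
    p_adj = phi * (z - 1.0 / z) * span + 4.0 * phi / z
    return float(min(1.0, max(p_min, p_adj)))


def plot_km_groups(
    low: pd.DataFrame,
    high: pd.DataFrame,
    path,
    title: str = "",
) -> None:
    """Write a two-group Kaplan–Meier plot (low vs high expression)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    km_estimate(low, label=f"low (n={len(low)})").plot_survival_function(ax=ax)
    km_estimate(high, label=f"high (n={len(high)})").plot_survival_function(ax=ax)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def optimal_cutpoint(
    expression: pd.Series,
    records: pd.DataFrame,
    component: str | None = None,
    percentiles: tuple[int, int] = (10, 90),
    min_group_frac: float = 0.10,
) -> CutpointResult:
    """Minimum-p log-rank cutpoint over an expression-percentile grid.

    Candidate cutpoints are every integer percentile of the observed
    expression between ``percentiles`` (inclusive); each splits samples
    into low (≤ cutpoint) and high (>) groups, subject to a minimum
    group size of ``min_group_frac`` × n.  The cutpoint with the smallest
    log-rank p wins; exact ties go to the cutpoint nearest the median.
    The minimal p is reported raw and Miller–Siegmund corrected, and the
    direction names the group with the worse (lower) survival curve.
    """
    shared = expression.dropna().index.intersection(records.index)
    if len(shared) < 20:
        raise ValueError(f"need >= 20 shared samples, have {len(shared)}")
    expr = expression.loc[shared].to_numpy(dtype=float)
    time = records.loc[shared, "time_days"].to_numpy(dtype=float)
    event = records.loc[shared, "event"].to_numpy(dtype=float)
    if event.sum() == 0:
        raise ValueError("no events observed")

    n = len(shared)
    min_group = max(1, int(math.ceil(min_group_frac * n)))
    lo, hi = percentiles
    grid = np.unique(np.percentile(expr, np.arange(lo, hi + 1)))
    median = float(np.median(expr))

    best: tuple[float, float] | None = None  # (p, |cut - median|)
    best_state: tuple[float, float, float, int, int] | None = None
    for cut in grid:
        high = expr > cut
        n_high = int(high.sum())
        if n_high < min_group or n - n_high < min_group:
            continue
        chi2, o_minus_e = _logrank_chi2(time, event, high)
        p = float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
        key = (p, abs(float(cut) - median))
        if best is None or key < best:
            best = key
            best_state = (float(cut), chi2, o_minus_e, n - n_high, n_high)
    if best_state is None:
        raise ValueError("no cutpoint satisfies the minimum group-size floor")

    cut, chi2, o_minus_e, n_low, n_high = best_state
    p_min = best[0]
    # positive O−E in the high group = more deaths there than expected
    direction = "high_expression_worse" if o_minus_e > 0 else "low_expression_worse"
    p_corr = miller_siegmund_p(p_min, eps_low=lo / 100.0, eps_high=hi / 100.0)
    return CutpointResult(
        component=component or (expression.name or "component"),
        cutpoint=cut,
        n_low=n_low,
        n_high=n_high,
        statistic=chi2,
        p=p_min,
        p_corrected=p_corr,
        direction=direction,
    )
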