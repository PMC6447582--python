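"""Comparative statistics: pre/post change and during-exertion trends.

Pre/post change is the percent change of the group-mean feature per phase,
with per-phase Wilcoxon signed-rank tests on the per-participant means (n is
tiny, so the exact null distribution is used).  During-exertion fatigue is
described by an ordinary least-squares line over the group-averaged 1-s
windows: Pearson's r, its two-sided P, the slope b per unit normalized time,
and the percent change between the first ("fresh muscle") and last ("tired
muscle") 10% of the hold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "percent_change",
    "average_phase_change",
    "wilcoxon_signed_rank",
    "linear_trend",
    "trend_from_series",
    "TrendResult",
    "PhaseComparison",
    "PrePostComparison",
]

#: above this many non-zero pairs the Wilcoxon p switches to the normal
#: approximation; at or below it the exact sign-assignment distribution is used
WILCOXON_EXACT_MAX_N = 15


def percent_change(pre: float, post: float) -> float:
    """(post - pre) / pre * 100, reported to 2 decimals.  ``pre`` must be
    non-zero."""
    if pre == 0:
        raise ValueError("percent change undefined for pre == 0")
    return round((post - pre) / pre * 100.0, 2)


def average_phase_change(per_phase_changes: tuple[float, float, float] | list[float]) -> float:
    """Arithmetic mean of the three per-phase percent changes, 2 decimals."""
    vals = np.asarray(per_phase_changes, float)
    if vals.size != 3 or not np.isfinite(vals).all():
        raise ValueError("need exactly three finite per-phase changes")
    return round(float(vals.mean()), 2)


def wilcoxon_signed_rank(paired_pre, paired_post) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon convention).  The exact
    sign-assignment distribution is used for up to ``WILCOXON_EXACT_MAX_N``
    non-zero pairs — mandatory at the study's n = 5, where the normal
    approximation is meaningless — and the normal approximation beyond.
    Returns ``(W_plus, p)``.  All-zero differences give p = 1 by contract.
    """
    pre = np.asarray(paired_pre, float)
    post = np.asarray(paired_post, float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if pre.size < 3:
        raise ValueError("need at least three pairs")
    d = post - pre
    d = d[d != 0]
    if d.size == 0:
        log.warning("all paired differences are zero; returning p = 1")
        return 0.0, 1.0
    method = "exact" if d.size <= WILCOXON_EXACT_MAX_N else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns about ties under 'exact'
        res = sps.wilcoxon(d, alternative="two-sided", method=method)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, float(res.pvalue)


@dataclass(frozen=True)
class TrendResult:
    """Linear-trend summary of one channel x metric during the hold."""

    channel: str
    metric: str
    r: float
    p: float
    slope: float
    intercept: float
    pct_change_first_last: float
    degenerate: bool = False


def linear_trend(x, y, channel: str = "", metric: str = "") -> TrendResult:
    """OLS trend of ``y`` against normalized time ``x`` (0-100).

    Computes Pearson's r with its two-sided t-distribution P, the slope and
    intercept, and the percent change between the mean of the first and of
    the last 10% of the time axis.  A constant series has undefined r and is
    returned flagged ``degenerate`` with r = P = NaN and slope 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three (x, y) points")
    span = x.max() - x.min()
    first = y[x <= x.min() + 0.10 * span]
    last = y[x >= x.max() - 0.10 * span]
    if np.allclose(y, y[0]):
        log.warning("constant series for %s/%s; correlation undefined", channel, metric)
        return TrendResult(channel, metric, np.nan, np.nan, 0.0, float(y[0]),
                           0.0, degenerate=True)
    fit = sps.linregress(x, y)
    pct = percent_change(float(first.mean()), float(last.mean()))
    return TrendResult(channel, metric, float(fit.rvalue), float(fit.pvalue),
                       float(fit.slope), float(fit.intercept), pct)


def trend_from_series(grid_df: pd.DataFrame, metric: str,
                      channel: str = "") -> TrendResult:
    """Trend of a group-averaged exertion series (``<metric>_mean`` column,
    or the raw metric column for a single-participant series)."""
    col = f"{metric}_mean" if f"{metric}_mean" in grid_df.columns else metric
    return linear_trend(grid_df["normalized_time"].to_numpy(),
                        grid_df[col].to_numpy(), channel=channel, metric=metric)


@dataclass(frozen=True)
class PhaseComparison:
    """Pre/post comparison of one contraction phase."""

    phase: str
    pre_mean: float
    post_mean: float
    pct_change: float
    wilcoxon_p: float


@dataclass
class PrePostComparison:
    """Pre/post comparison of one channel x metric across the three phases."""

    channel: str
    metric: str
    phases: list[PhaseComparison]
    average_pct_change: float = field(init=False)

    def __post_init__(self) -> None:
        self.average_pct_change = average_phase_change(
            [p.pct_change for p in self.phases])

    @classmethod
    def from_participant_means(cls, channel: str, metric: str,
                               pre: pd.DataFrame, post: pd.DataFrame,
                               phases=("entering", "held", "exiting")
                               ) -> "PrePostComparison":
        """Build from tidy frames with columns (participant, phase, value).

        The group comparison uses the mean over participants; the Wilcoxon
        test pairs the per-participant means.
        """
        rows = []
        for phase in phases:
            a = pre[pre["phase"] == phase].sort_values("participant")["value"].to_numpy()
            b = post[post["phase"] == phase].sort_values("participant")["value"].to_numpy()
            if a.size >= 3:
                _, p = wilcoxon_signed_rank(a, b)
            else:
                log.warning("fewer than three participants; Wilcoxon p undefined")
                p = float("nan")
            rows.append(PhaseComparison(phase, float(a.mean()), float(b.mean()),
                                        percent_change(float(a.mean()), float(b.mean())),
                                        p))
        return cls(channel, metric, rows)
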