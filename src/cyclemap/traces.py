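"""Fate classification of CDK2-activity traces and computational synchronization.

A cell's post-mitotic fate is read directly from its CDK2 activity trace
(cytoplasmic:nuclear sensor ratio): cells whose activity stays at or above
0.5 for every post-anaphase frame are committed to the cycle (CDK2inc);
cells that stay below 0.5 throughout are spontaneously quiescent (CDK2low);
cells that stay low for at least three hours and then show a confirmed
rise re-enter the cycle (CDK2emerge).  Cells with no mitosis during the
movie are prolonged-quiescent if their activity never reaches 0.6, or
nondividing-emerge if a confirmed rise occurs.

The R-point (restriction point) of an emerging trace is the time activity
first begins to rise, found by maximizing a linear score over time points:
long time since mitosis, low current activity, and high activity slope
(slopes taken as the best over forward-looking windows of 6-10 points).

Ensembles of traces are synchronized computationally by shifting each
cell's time axis so its anchor event (last anaphase, or R-point) sits at
t = 0; each cell's endpoint IF value then inherits x = fixation time -
anchor time, reconstructing marker dynamics as a function of
time-since-anaphase without chemical synchronization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNCLASSIFIED = "unclassified"


@dataclass
class ClassifierParams:
    """Thresholds of the trace-classification rules.

    ``inc_threshold`` (0.5) splits post-mitotic high/low activity;
    ``prolonged_threshold`` (0.6) bounds activity of prolonged-quiescent
    nondividing cells; ``emerge_min_low`` (3 h) is the minimum low dwell
    before an emergence counts; a rise is confirmed by ``rise_confirm``
    consecutive frames at or above ``inc_threshold``.  ``grace_period``
    ignores the first hours after anaphase in the all-frames predicates
    (0 = strict rule).  ``smooth_window`` applies a running-median of that
    many frames before evaluating predicates (1 = no smoothing).
    """

    inc_threshold: float = 0.5
    emerge_min_low: float = 3.0  # hours
    prolonged_threshold: float = 0.6
    movie_length: float = 24.0  # hours
    rise_confirm: int = 3  # consecutive frames
    grace_period: float = 0.0  # hours
    smooth_window: int = 1  # frames; odd

    def __post_init__(self) -> None:
        if self.inc_threshold <= 0 or self.prolonged_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.emerge_min_low < 0:
            raise ValueError("emerge_min_low must be >= 0")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")


@dataclass
class RPointParams:
    """Linear-score coefficients for R-point detection.

    score(t) = w_time * t_since_mitosis - |w_activity| * activity(t)
             + w_slope * slope(t), with slope(t) the maximum least-squares
    slope over forward windows of ``slope_windows`` points.  Coefficient
    signs favour long times since mitosis, low activity and high slope.
    """

    slope_windows: tuple[int, ...] = (6, 7, 8, 9, 10)
    w_time: float = 0.02  # per hour
    w_activity: float = 1.0
    w_slope: float = 10.0  # hours
    min_slope: float = 0.05  # activity/h noise floor for "rising at all"

    def __post_init__(self) -> None:
        if any(w < 2 for w in self.slope_windows):
            raise ValueError("slope windows must have >= 2 points")
        if self.w_time < 0 or self.w_slope < 0:
            raise ValueError("w_time and w_slope must be >= 0")


def _smooth(a: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or a.size < window:
        return a
    from scipy.ndimage import median_filter

    return median_filter(a, size=window, mode="nearest")


def _confirmed_rise_start(above: np.ndarray, confirm: int) -> int | None:
    """Index of the first run of >= confirm consecutive True values."""
    if above.size < confirm:
        return None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= confirm:
            return i - confirm + 1
    return None


def classify_trace(
    times: np.ndarray,
    activity: np.ndarray,
    anaphase_time: float | None,
    params: ClassifierParams | None = None,
) -> str:
    """Assign one fate label to a single-cell trace.

    ``times`` are hours (movie clock), ``activity`` the CDK2 activity at
    those times (NaN = missing frame; predicates are evaluated over
    observed frames only).  ``anaphase_time`` is the cell's last anaphase,
    or None for a cell with no mitosis during the movie.  Returns one of
    CDK2inc / CDK2low / CDK2emerge / prolonged_quiescent /
    nondividing_emerge / unclassified.
    """
    p = params or ClassifierParams()
    t = np.asarray(times, dtype=float)
    a = np.asarray(activity, dtype=float)
    ok = np.isfinite(a)
    t, a = t[ok], a[ok]
    if a.size < p.rise_confirm:
        return UNCLASSIFIED
    a = _smooth(a, p.smooth_window)

    if anaphase_time is None:
        # nondividing cell over the whole movie
        if np.nanmax(a) < p.prolonged_threshold:
            return "prolonged_quiescent"
        above = a >= p.inc_threshold
        if _confirmed_rise_start(above, p.rise_confirm) is not None:
            return "nondividing_emerge"
        return UNCLASSIFIED

    post = t >= anaphase_time + p.grace_period
    if not post.any():
        return UNCLASSIFIED
    tp, ap = t[post], a[post]
    if ap.size < p.rise_confirm:
        return UNCLASSIFIED
    if (ap >= p.inc_threshold).all():
        return "CDK2inc"
    if (ap < p.inc_threshold).all():
        return "CDK2low"
    # emerge: low for >= emerge_min_low hours post-anaphase, then a
    # confirmed rise
    above = ap >= p.inc_threshold
    first_above = int(np.argmax(above))  # above.any() is True here
    low_dwell = tp[first_above] - anaphase_time
    if low_dwell >= p.emerge_min_low:
        start = _confirmed_rise_start(above, p.rise_confirm)
        if start is not None and tp[start] - anaphase_time >= p.emerge_min_low:
            return "CDK2emerge"
    return UNCLASSIFIED


def classify_traces(
    trace_df: pd.DataFrame,
    anaphase_times: dict | pd.Series,
    params: ClassifierParams | None = None,
) -> pd.Series:
    """Classify every cell in a long-format trace table.

    ``trace_df`` needs columns cell_id, time_h, cdk2_activity.
    ``anaphase_times`` maps cell_id -> anaphase time in hours (missing or
    NaN = no mitosis observed).
    """
    out = {}
    ana = dict(anaphase_times)
    for cid, grp in trace_df.groupby("cell_id", sort=False):
        at = ana.get(cid, None)
        if at is not None and not np.isfinite(at):
            at = None
        out[cid] = classify_trace(
            grp["time_h"].to_numpy(), grp["cdk2_activity"].to_numpy(), at, params
        )
    return pd.Series(out, name="fate")


def _window_slopes(t: np.ndarray, a: np.ndarray, window: int) -> np.ndarray:
    """Least-squares slope of a over t in forward windows [i, i+window)."""
    n = t.size
    out = np.full(n, -np.inf)
    if n < window:
        return out
    for i in range(n - window + 1):
        ts = t[i:i + window]
        as_ = a[i:i + window]
        tm = ts.mean()
        denom = np.sum((ts - tm) ** 2)
        out[i] = np.sum((ts - tm) * (as_ - as_.mean())) / denom
    return out


def detect_rpoint(
    times: np.ndarray,
    activity: np.ndarray,
    anaphase_time: float = 0.0,
    params: RPointParams | None = None,
) -> float | None:
    """Time (hours, movie clock) at which CDK2 activity first begins to rise.

    Returns None for traces that never rise above the slope noise floor
    (flat traces have no R-point).
    """
    p = params or RPointParams()
    t = np.asarray(times, dtype=float)
    a = np.asarray(activity, dtype=float)
    ok = np.isfinite(a)
    t, a = t[ok], a[ok]
    if t.size < min(p.slope_windows):
        return None
    slopes = np.full(t.size, -np.inf)
    for w in p.slope_windows:
        slopes = np.maximum(slopes, _window_slopes(t, a, w))
    valid = np.isfinite(slopes)
    if not valid.any() or np.nanmax(slopes[valid]) < p.min_slope:
        return None
    score = (
        p.w_time * (t - anaphase_time)
        - abs(p.w_activity) * a
        + p.w_slope * np.where(valid, slopes, -np.inf)
    )
    return float(t[int(np.argmax(score))])


@dataclass
class AlignedEnsemble:
    """Traces on a common time axis anchored at anaphase or the R-point.

    ``aligned`` is long-format (cell_id, time_h, cdk2_activity) with the
    anchor at time 0; ``anchors`` maps cell_id -> anchor time on the movie
    clock; ``endpoint_x`` maps cell_id -> fixation time minus anchor time,
    the x-coordinate its endpoint IF value inherits.
    """

    anchor: str  # "anaphase" | "rpoint"
    aligned: pd.DataFrame
    anchors: pd.Series
    endpoint_x: pd.Series
    fates: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    excluded: list = field(default_factory=list)


def align_ensemble(
    trace_df: pd.DataFrame,
    anchor_times: dict | pd.Series,
    anchor: str = "anaphase",
    movie_length: float = 24.0,
    fates: pd.Series | None = None,
) -> AlignedEnsemble:
    """Shift each cell's time axis so its anchor event sits at t = 0.

    Cells without an anchor time are excluded (listed in ``excluded``).
    The endpoint x-coordinate of each aligned cell is
    ``movie_length - anchor_time`` (time between the anchor and fixation).
    """
    ana = pd.Series(dict(anchor_times), dtype=float)
    ana = ana[np.isfinite(ana)]
    keep = trace_df["cell_id"].isin(ana.index)
    excluded = sorted(set(trace_df.loc[~keep, "cell_id"]))
    df = trace_df.loc[keep].copy()
    df["time_h"] = df["time_h"].to_numpy() - ana.loc[df["cell_id"]].to_numpy()
    endpoint_x = movie_length - ana
    f = fates.loc[fates.index.isin(ana.index)] if fates is not None else pd.Series(dtype=object)
    return AlignedEnsemble(anchor, df, ana, endpoint_x, f, excluded)
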