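"""Protein-dynamics maps: IF signal vs time-since-anchor per fate class.

Endpoint IF intensities of computationally synchronized cells reconstruct
each protein's dynamics as a function of time since the last anaphase (or
since the R-point): every cell contributes one point at x = fixation time
minus anchor time; prolonged-quiescent cells, which have no anaphase, are
plotted at the movie-length mark.  A sliding-window moving average (mean
+/- SD) summarizes each fate class's scatter.  For cross-protein
comparison, the CDK2inc and CDK2low curves of a protein are jointly
min-max normalized to [0, 1], and the protein is assigned to Group 1
(signal "off" in quiescent cells: flat and low CDK2low curve) or Group 2
(signal changing dynamically during quiescence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class NormalizationError(ValueError):
    """Flat curve pair: shared min equals shared max."""


@dataclass
class DynamicsCurve:
    """Binned mean +/- SD of an IF signal vs time since the anchor."""

    protein: str
    fate: str
    anchor: str
    centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class NormalizedCurvePair:
    inc: DynamicsCurve
    low: DynamicsCurve
    shared_min: float
    shared_max: float


def reconstruct_dynamics(endpoint_x: pd.Series, if_values: pd.Series,
                         fates: pd.Series, fate_class: str,
                         movie_length: float = 24.0) -> pd.DataFrame:
    """Scatter of (time-since-anchor, IF value) for one fate class.

    ``endpoint_x`` maps cell id -> fixation time minus anchor time (from
    the aligned ensemble); prolonged-quiescent cells have no anchor and
    are assigned x = ``movie_length``.  Cells with missing IF values are
    dropped.
    """
    sel = fates[fates == fate_class].index
    if fate_class == "prolonged_quiescent":
        x = pd.Series(movie_length, index=sel, dtype=float)
    else:
        x = endpoint_x.reindex(sel)
    y = if_values.reindex(sel)
    out = pd.DataFrame({"time": x, "value": y}).dropna()
    return out.reset_index(names="cell_id")


def moving_average(scatter: pd.DataFrame, window: float = 2.0,
                   step: float = 0.5, min_bin_count: int = 10,
                   protein: str = "", fate: str = "", anchor: str = "anaphase"
                   ) -> DynamicsCurve:
    """Sliding-window mean and SD of ``value`` vs ``time``.

    Bin centers advance by ``step`` hours; each bin averages points
    within +/- window/2.  Bins with fewer than ``min_bin_count`` points
    are suppressed.  An empty scatter yields an empty curve.
    """
    if len(scatter) == 0:
        z = np.empty(0)
        return DynamicsCurve(protein, fate, anchor, z, z.copy(), z.copy(),
                             z.astype(int))
    t = scatter["time"].to_numpy(dtype=float)
    v = scatter["value"].to_numpy(dtype=float)
    lo = np.floor(t.min() / step) * step
    hi = np.ceil(t.max() / step) * step
    centers = np.arange(lo, hi + step / 2, step)
    means, sds, ns = [], [], []
    half = window / 2.0
    for c in centers:
        sel = (t >= c - half) & (t <= c + half)
        n = int(sel.sum())
        if n < min_bin_count:
            continue
        means.append(v[sel].mean())
        sds.append(v[sel].std(ddof=0))
        ns.append(n)
    kept = [c for c in centers
            if ((t >= c - half) & (t <= c + half)).sum() >= min_bin_count]
    return DynamicsCurve(protein, fate, anchor, np.array(kept),
                         np.array(means), np.array(sds),
                         np.array(ns, dtype=int))


def normalize_pair(curve_inc: DynamicsCurve, curve_low: DynamicsCurve
                   ) -> NormalizedCurvePair:
    """Affine-map both curves with the shared min/max to [0, 1].

    The minimum signal across the CDK2inc and CDK2low curves maps to 0
    and the maximum across both maps to 1, so the extremes are attained
    by construction.  Raises :class:`NormalizationError` for a flat pair.
    """
    if len(curve_inc) == 0 or len(curve_low) == 0:
        raise NormalizationError("both curves must be nonempty")
    lo = min(curve_inc.mean.min(), curve_low.mean.min())
    hi = max(curve_inc.mean.max(), curve_low.mean.max())
    if hi <= lo:
        raise NormalizationError("flat curve pair: shared max equals shared min")
    span = hi - lo

    def _norm(c: DynamicsCurve) -> DynamicsCurve:
        return DynamicsCurve(c.protein, c.fate, c.anchor, c.centers.copy(),
                             (c.mean - lo) / span, c.sd / span, c.n.copy())

    return NormalizedCurvePair(_norm(curve_inc), _norm(curve_low),
                               float(lo), float(hi))


def assign_group(curve_low: DynamicsCurve, flat_tolerance: float = 0.2,
                 low_ceiling: float = 0.25) -> str:
    """Group 1 vs Group 2 from the normalized CDK2low curve.

    Group 1 proteins are "off" in quiescent cells: the normalized CDK2low
    curve both spans less than ``flat_tolerance`` of the normalized range
    and stays below ``low_ceiling``.  Everything else -- signals that
    rise or fall the longer a cell is quiescent -- is Group 2.  Curves
    with fewer than 3 bins are unassigned.
    """
    if len(curve_low) < 3:
        return "unassigned"
    rng = float(curve_low.mean.max() - curve_low.mean.min())
    level = float(curve_low.mean.max())
    if rng < flat_tolerance and level < low_ceiling:
        return "Group1"
    return "Group2"


_FATE_COLORS = {"CDK2inc": "tab:blue", "CDK2low": "tab:red",
                "CDK2emerge": "tab:green", "prolonged_quiescent": "purple"}


def plot_dynamics(curves: dict, scatters: dict | None = None,
                  path=None, title: str = "", normalized: bool = False):
    """Scatter + moving-average plot of per-fate dynamics curves.

    ``curves`` maps fate -> DynamicsCurve; ``scatters`` optionally maps
    fate -> DataFrame(time, value) for the underlying points.  Saves to
    ``path`` (PNG/SVG by extension) when given, otherwise returns the
    figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for fate, curve in curves.items():
        color = _FATE_COLORS.get(fate, "gray")
        if scatters and fate in scatters and len(scatters[fate]):
            ax.plot(scatters[fate]["time"], scatters[fate]["value"], ".",
                    ms=2, alpha=0.25, color=color)
        if len(curve):
            ax.errorbar(curve.centers, curve.mean, yerr=curve.sd,
                        color=color, lw=1.5, capsize=2, label=fate)
    ax.set_xlabel("time since anaphase (h)")
    ax.set_ylabel("normalized signal" if normalized else "IF signal (AU)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def s_phase_window_from_edu(edu_curve_inc: DynamicsCurve) -> tuple[float, float]:
    """S-phase interval from the EdU "rainbow": the window where the
    CDK2inc EdU moving average exceeds its half-maximum.  Used to draw
    the G1/S/G2 annotation bars over dynamics maps."""
    if len(edu_curve_inc) == 0:
        raise ValueError("empty EdU curve")
    m = edu_curve_inc.mean
    half = m.min() + 0.5 * (m.max() - m.min())
    above = m > half
    if not above.any():
        raise ValueError("EdU curve never exceeds half-max")
    idx = np.flatnonzero(above)
    return (float(edu_curve_inc.centers[idx[0]]),
            float(edu_curve_inc.centers[idx[-1]]))
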