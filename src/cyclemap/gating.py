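"""Snapshot-mode cell-cycle phase gating from multiplexed IF marker tables.

An asynchronous fixed-cell population co-stained for DNA content
(Hoechst), DNA synthesis (EdU), and either phospho-Rb or phospho-Histone
H3 can be partitioned into seven phases: EdU-negative 2N cells split into
G0 (hypo-phosphorylated Rb) and G1 (hyper-phosphorylated Rb); cells with
intermediate EdU near 2N are early S; high-EdU cells are S; intermediate
EdU near 4N is late S; EdU-negative 4N cells split into M (pHH3-positive)
and G2.  Gates are fitted from the data (DNA-peak normalization, density
valleys of the bimodal phospho-Rb and trimodal log-EdU distributions) and
drawn conservatively; cells outside every box stay unassigned rather than
being forced into a phase.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import gaussian_kde

PHASES = ("G0", "G1", "earlyS", "S", "lateS", "G2", "M")
UNASSIGNED = "unassigned"


class GateError(ValueError):
    """Gate fitting failed (e.g. unimodal input to a bimodal gate)."""


class NormalizationError(ValueError):
    """No detectable DNA peak."""


@dataclass
class GateSet:
    """Fitted thresholds partitioning marker space into phases.

    DNA windows are in normalized units (2N peak at 1.0); EdU thresholds
    are on the measured (linear) scale.  ``prb_threshold`` and
    ``phh3_threshold`` may be NaN when the corresponding marker was not
    fitted; phase calling then degrades to joint G0/G1 or G2/M labels.
    """

    dna_2n_window: tuple[float, float] = (0.8, 1.25)
    dna_4n_window: tuple[float, float] = (1.6, 2.5)
    edu_neg_max: float = np.nan
    edu_high_min: float = np.nan
    prb_threshold: float = np.nan
    phh3_threshold: float = np.nan
    dna_scale: float = 1.0  # raw intensity of the 2N peak

    def __post_init__(self) -> None:
        if not self.dna_2n_window[1] < self.dna_4n_window[0]:
            raise GateError("2N window must lie below the 4N window")
        if np.isfinite(self.edu_neg_max) and np.isfinite(self.edu_high_min):
            if not self.edu_neg_max < self.edu_high_min:
                raise GateError("edu_neg_max must be below edu_high_min")


def normalize_dna(dna_values: np.ndarray, min_cells: int = 100) -> tuple[np.ndarray, float]:
    """Rescale DNA content so the first major histogram mode (2N) is 1.0.

    Returns (rescaled values, raw 2N peak location).  4N cells land near
    2.0.  Raises :class:`NormalizationError` when no peak is detectable.
    """
    v = np.asarray(dna_values, dtype=float)
    if v.size < min_cells:
        raise NormalizationError(f"need >= {min_cells} cells, got {v.size}")
    if np.ptp(v) < 1e-12:
        return v / v[0], float(v[0])  # constant input: single trivial mode
    hist, edges = np.histogram(v, bins=128)
    smooth = signal.savgol_filter(hist.astype(float), 9, 2, mode="nearest")
    smooth = np.concatenate([[0.0], smooth, [0.0]])  # boundary modes count
    peaks, props = signal.find_peaks(smooth, height=0.25 * smooth.max(),
                                     prominence=0.1 * smooth.max())
    peaks = peaks - 1
    if len(peaks) == 0:
        raise NormalizationError("no detectable DNA peak")
    centers = 0.5 * (edges[:-1] + edges[1:])
    # first major mode = lowest-intensity peak with substantial mass
    scale = float(centers[np.clip(peaks[0], 0, len(centers) - 1)])
    if scale <= 0:
        raise NormalizationError("DNA peak at nonpositive intensity")
    return v / scale, scale


def fit_bimodal_gate(values: np.ndarray, min_separation: float = 0.3) -> float:
    """Threshold at the density valley between two modes of log-values.

    ``values`` must already be log-transformed.  The density is estimated
    with a Gaussian KDE; the threshold is the minimum of the density
    between the two dominant modes.  Raises :class:`GateError` when the
    distribution is unimodal.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10 or np.ptp(x) < 1e-12:
        raise GateError("not enough spread to fit a bimodal gate")
    kde = gaussian_kde(x)
    pad = 0.05 * np.ptp(x)
    grid = np.linspace(x.min() - pad, x.max() + pad, 512)
    dens = kde(grid)
    peaks, props = signal.find_peaks(dens, height=0.01 * dens.max())
    if len(peaks) < 2:
        raise GateError("distribution is unimodal; no valley to gate on")
    heights = props["peak_heights"]
    top2 = peaks[np.argsort(heights)[-2:]]
    lo, hi = sorted(top2)
    if grid[hi] - grid[lo] < min_separation:
        raise GateError("modes too close; distribution effectively unimodal")
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    return float(grid[valley])


def fit_trimodal_edu_gates(edu_values: np.ndarray) -> tuple[float, float]:
    """(edu_neg_max, edu_high_min) from the valleys of the log-EdU density.

    The negative / intermediate / high split uses the two deepest valleys
    between the three dominant modes; with only two modes the single
    valley serves as both thresholds' anchor (intermediate band empty).
    """
    x = np.log10(np.asarray(edu_values, dtype=float) + 1.0)
    kde = gaussian_kde(x)
    pad = 0.05 * np.ptp(x)
    grid = np.linspace(x.min() - pad, x.max() + pad, 512)
    dens = kde(grid)
    peaks, props = signal.find_peaks(dens, height=0.01 * dens.max())
    if len(peaks) < 2:
        raise GateError("log-EdU density has fewer than two modes")
    heights = props["peak_heights"]
    keep = peaks[np.argsort(heights)[-3:]]
    keep = np.sort(keep)
    valleys = []
    for a, b in zip(keep[:-1], keep[1:]):
        valleys.append(grid[a + int(np.argmin(dens[a:b + 1]))])
    if len(valleys) == 1:
        valleys = [valleys[0], valleys[0]]
    return float(10 ** valleys[0] - 1.0), float(10 ** valleys[-1] - 1.0)


def fit_gates(records: pd.DataFrame, **overrides) -> GateSet:
    """Fit a full GateSet from a marker table (dna, edu, optional prb/phh3).

    Keyword overrides replace any fitted field (manual gating).
    """
    norm, scale = normalize_dna(records["dna"].to_numpy())
    edu_neg_max, edu_high_min = fit_trimodal_edu_gates(records["edu"].to_numpy())
    prb_thr = np.nan
    if "prb" in records and records["prb"].notna().any():
        try:
            prb_thr = float(
                10 ** fit_bimodal_gate(np.log10(records["prb"].to_numpy() + 1.0))
            ) - 1.0
        except GateError:
            warnings.warn("phospho-Rb not bimodal; G0/G1 split unavailable",
                          stacklevel=2)
    phh3_thr = np.nan
    if "phh3" in records and records["phh3"].notna().any():
        try:
            phh3_thr = float(
                10 ** fit_bimodal_gate(np.log10(records["phh3"].to_numpy() + 1.0))
            ) - 1.0
        except GateError:
            warnings.warn("pHH3 not bimodal; G2/M split unavailable",
                          stacklevel=2)
    gates = dict(
        edu_neg_max=edu_neg_max, edu_high_min=edu_high_min,
        prb_threshold=prb_thr, phh3_threshold=phh3_thr, dna_scale=scale,
    )
    gates.update(overrides)
    return GateSet(**gates)


def call_phase(record, gates: GateSet) -> str:
    """Phase label for one cell's marker record (dict-like with dna, edu,
    and optionally prb / phh3).  ``record['dna']`` must be on the raw
    scale; it is normalized with ``gates.dna_scale``.

    Missing phospho markers downgrade the resolution (joint "G0/G1" or
    "G2/M"); records outside every gate box come back unassigned.
    """
    dna = record["dna"] / gates.dna_scale
    edu = record["edu"]
    in2n = gates.dna_2n_window[0] <= dna <= gates.dna_2n_window[1]
    in4n = gates.dna_4n_window[0] <= dna <= gates.dna_4n_window[1]
    if edu >= gates.edu_high_min:
        return "S"
    if edu <= gates.edu_neg_max:
        if in2n:
            prb = record.get("prb", None)
            if prb is None or not np.isfinite(gates.prb_threshold) or \
                    (prb != prb):
                return "G0/G1"
            return "G0" if prb < gates.prb_threshold else "G1"
        if in4n:
            phh3 = record.get("phh3", None)
            if phh3 is None or not np.isfinite(gates.phh3_threshold) or \
                    (phh3 != phh3):
                return "G2/M"
            return "M" if phh3 > gates.phh3_threshold else "G2"
        return UNASSIGNED
    # intermediate EdU
    if in2n:
        return "earlyS"
    if in4n:
        return "lateS"
    return UNASSIGNED


def call_phases(records: pd.DataFrame, gates: GateSet) -> pd.Series:
    """Vectorized phase calls for a whole marker table."""
    dna = records["dna"].to_numpy(dtype=float) / gates.dna_scale
    edu = records["edu"].to_numpy(dtype=float)
    n = len(records)
    prb = records["prb"].to_numpy(dtype=float) if "prb" in records else np.full(n, np.nan)
    phh3 = records["phh3"].to_numpy(dtype=float) if "phh3" in records else np.full(n, np.nan)
    out = np.full(n, UNASSIGNED, dtype=object)
    in2n = (dna >= gates.dna_2n_window[0]) & (dna <= gates.dna_2n_window[1])
    in4n = (dna >= gates.dna_4n_window[0]) & (dna <= gates.dna_4n_window[1])
    high = edu >= gates.edu_high_min
    neg = edu <= gates.edu_neg_max
    mid = ~high & ~neg
    out[high] = "S"
    have_prb = np.isfinite(prb) & np.isfinite(gates.prb_threshold)
    out[neg & in2n & have_prb & (prb < gates.prb_threshold)] = "G0"
    out[neg & in2n & have_prb & (prb >= gates.prb_threshold)] = "G1"
    out[neg & in2n & ~have_prb] = "G0/G1"
    have_phh3 = np.isfinite(phh3) & np.isfinite(gates.phh3_threshold)
    out[neg & in4n & have_phh3 & (phh3 > gates.phh3_threshold)] = "M"
    out[neg & in4n & have_phh3 & (phh3 <= gates.phh3_threshold)] = "G2"
    out[neg & in4n & ~have_phh3] = "G2/M"
    out[mid & in2n] = "earlyS"
    out[mid & in4n] = "lateS"
    return pd.Series(out, index=records.index, name="phase")


def phase_histograms(records: pd.DataFrame, phases: pd.Series, poi: str = "poi",
                     bins: int = 64):
    """Per-phase probability densities of the protein of interest.

    Returns a dict phase -> (bin_centers, density, n).  Mitotic cells are
    kept but flagged in the output (IF intensities are artificially high
    in rounded-up mitotic cells); empty phases are omitted with a warning.
    The unassigned fraction is reported, never silently dropped.
    """
    vals = records[poi].to_numpy(dtype=float)
    out = {}
    lo, hi = np.nanmin(vals), np.nanmax(vals)
    edges = np.linspace(lo, hi, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for phase in list(PHASES) + [UNASSIGNED, "G0/G1", "G2/M"]:
        sel = (phases == phase).to_numpy()
        if not sel.any():
            if phase in PHASES:
                warnings.warn(f"phase {phase}: no cells; omitted", stacklevel=2)
            continue
        dens, _ = np.histogram(vals[sel], bins=edges, density=True)
        out[phase] = {
            "centers": centers, "density": dens, "n": int(sel.sum()),
            "mitotic_inflation": phase == "M",
        }
    out["unassigned_fraction"] = float((phases == UNASSIGNED).mean())
    return out
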