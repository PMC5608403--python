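"""Synthetic cohorts, movies, and endpoint immunofluorescence with ground truth.

This module generates the inputs the analysis pipeline expects from a
time-lapse + endpoint-IF experiment on an asynchronous epithelial cell
population: a two-channel movie (nuclear H2B + CDK2 translocation sensor,
one frame every 12 minutes for 24 hours), a final fixed-cell IF image set,
and full per-cell ground truth (fate labels, anaphase times, R-point times,
true activity traces, true endpoint marker intensities).

The population model mirrors the proliferation-quiescence bifurcation seen
in unperturbed MCF10A cells: after mitosis a cell either keeps building
CDK2 activity (CDK2inc), stays persistently low (CDK2low, spontaneous
quiescence), or stays low for at least three hours and then re-enters the
cycle (CDK2emerge).  A small fraction never divides during the movie,
either remaining quiescent throughout (prolonged quiescence) or building
up activity without an observed mitosis (nondividing emerge).

Rendered nuclei are hard-edged ellipses whose integrated H2B intensity is
the cell's H2B mass (conserved across frames; split 45-55% between the two
daughters at anaphase).  The sensor channel distributes a fixed per-cell
sensor mass between the nucleus and a perinuclear ring so that the
ring-mean : nuclear-mean ratio equals the cell's true CDK2 activity at
that frame -- the construction identity the quantification module is
tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

FATES = (
    "CDK2inc",
    "CDK2low",
    "CDK2emerge",
    "prolonged_quiescent",
    "nondividing_emerge",
)

#: Default population composition of an unperturbed asynchronous cohort.
#: 95.6% of lineages divide at least once during the 24 h movie.
DEFAULT_COMPOSITION = {
    "CDK2inc": 0.790,
    "CDK2low": 0.088,
    "CDK2emerge": 0.078,
    "prolonged_quiescent": 0.023,
    "nondividing_emerge": 0.021,
}

DIVIDING_FATES = ("CDK2inc", "CDK2low", "CDK2emerge")

#: Cell-cycle phase windows (hours since anaphase) used by the protein
#: profiles and the EdU pulse: G1 = [0, 5), S = [5, 13), G2 = [13, 18].
S_PHASE_WINDOW = (5.0, 13.0)
G2_END = 18.0


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class LayoutError(ValueError):
    """Field too small to place the requested number of cells."""


class PanelError(KeyError):
    """Unknown protein requested from the profile set."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study-condition parameters for a synthetic time-lapse cohort.

    Defaults reproduce the imaging conditions the analysis assumes: frames
    every 12 minutes over 24 hours, binned 10x widefield sampling
    (1 um/px), 5 um nuclear radius, and the default asynchronous population
    composition.  ``field_shape=None`` sizes the field automatically from
    ``n_cells`` (jittered grid, 4.4 nuclear radii spacing) plus an empty
    margin wide enough that a global background mode can still be computed
    after the 50 um mask dilation.
    """

    n_cells: int = 2000
    composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    frame_interval: float = 12.0  # minutes
    duration: float = 24.0  # hours
    pixel_size: float = 1.0  # um / pixel
    field_shape: tuple[int, int] | None = None
    nucleus_radius: float = 5.0  # um
    noise_sd: float = 5.0  # intensity units, per pixel
    background_level: float = 100.0  # intensity units
    jitter_shift: tuple[int, int] | str = "random"
    jitter_radius: int = 10  # px, for jitter_shift="random"
    crowding: float = 0.015  # fraction of cells placed touching a neighbour
    eccentricity: float = 0.10  # max relative deviation of ellipse axes
    trace_noise_sd: float = 0.03  # activity units, per frame
    seed: int = 0

    def __post_init__(self) -> None:
        comp = self.composition
        unknown = set(comp) - set(FATES)
        if unknown:
            raise ConfigurationError(f"unknown fates in composition: {sorted(unknown)}")
        fracs = np.array([comp.get(f, 0.0) for f in FATES], dtype=float)
        if (fracs < 0).any():
            raise ConfigurationError("composition fractions must be nonnegative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"composition fractions must sum to 1 (got {fracs.sum():.12f})"
            )
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        n_frames = self.duration * 60.0 / self.frame_interval
        if abs(n_frames - round(n_frames)) > 1e-9 or round(n_frames) < 2:
            raise ConfigurationError(
                "duration/frame_interval must give an integer frame count >= 2"
            )
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")

    # -- derived quantities -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * 60.0 / self.frame_interval))

    @property
    def frame_hours(self) -> float:
        return self.frame_interval / 60.0

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in hours (t=0 is the first frame)."""
        return np.arange(self.n_frames) * self.frame_hours

    @property
    def radius_px(self) -> float:
        return self.nucleus_radius / self.pixel_size

    @property
    def grid_spacing_px(self) -> float:
        return 4.4 * self.radius_px

    @property
    def margin_px(self) -> int:
        # wide enough that pixels beyond the 50 um dilation remain
        return int(math.ceil(50.0 / self.pixel_size + self.radius_px + 8))

    def resolved_field_shape(self) -> tuple[int, int]:
        if self.field_shape is not None:
            return tuple(self.field_shape)
        side_sites = math.ceil(math.sqrt(self.n_cells))
        side = int(math.ceil(side_sites * self.grid_spacing_px)) + 2 * self.margin_px
        return (side, side)


@dataclass
class TraceModel:
    """Parametric CDK2-activity trace for one lineage's post-anaphase fate.

    ``emerge_delay`` is the low-activity dwell (hours after anaphase, or
    after movie start for nondividing cells) before activity rises; it is
    the ground-truth R-point offset for emerging cells.
    """

    fate: str
    birth_activity: float = 0.7
    rise_rate: float = 0.09  # activity / hour
    low_level: float = 0.3
    emerge_delay: float = 5.0  # hours
    next_division_time: float = np.inf  # hours; beyond the movie by default
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.fate not in FATES:
            raise ConfigurationError(f"unknown fate {self.fate!r}")
        if not self.low_level < 0.5:
            raise ConfigurationError("low_level must be < 0.5")
        if self.fate == "CDK2inc" and self.birth_activity < 0.5:
            raise ConfigurationError("CDK2inc birth_activity must be >= 0.5")
        if self.fate == "CDK2emerge" and self.emerge_delay < 3.0:
            raise ConfigurationError("CDK2emerge emerge_delay must be >= 3 h")


def sample_trace(
    model: TraceModel,
    times: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample a CDK2-activity series on ``times`` (hours since anchor).

    The anchor is anaphase for post-mitotic fates and movie start for
    nondividing fates.  Without ``rng`` (or with ``noise_sd == 0``) the
    series is the noiseless parametric curve: CDK2inc rises linearly from
    ``birth_activity``; CDK2low and prolonged-quiescent cells hold
    ``low_level``; emerging cells hold ``low_level`` for ``emerge_delay``
    hours and then rise at ``rise_rate``.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("times must be 1-D and strictly increasing")
    if model.fate == "CDK2inc":
        a = model.birth_activity + model.rise_rate * t
    elif model.fate in ("CDK2low", "prolonged_quiescent"):
        a = np.full_like(t, model.low_level)
    elif model.fate in ("CDK2emerge", "nondividing_emerge"):
        a = model.low_level + model.rise_rate * np.maximum(0.0, t - model.emerge_delay)
    else:  # pragma: no cover - guarded by TraceModel validation
        raise ConfigurationError(model.fate)
    if rng is not None and model.noise_sd > 0:
        a = a + rng.normal(0.0, model.noise_sd, size=a.shape)
    a = np.maximum(a, 0.0)
    if model.fate == "prolonged_quiescent":
        # hard ground-truth guarantee: quiescent for the whole movie
        a = np.minimum(a, 0.595)
    return a


# ---------------------------------------------------------------------------
# protein profiles
# ---------------------------------------------------------------------------


def _interp_curve(points):
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)

    def f(t):
        return np.interp(np.clip(t, xs[0], xs[-1]), xs, ys)

    return f


class ProteinProfileSet:
    """Expected endpoint IF intensity vs (fate, time-since-anaphase).

    Each protein carries two base curves: ``cycle(t)`` for cells
    progressing through the cycle (t = hours since anaphase for CDK2inc
    cells, or since the R-point for emerging cells) and ``quiescent(t)``
    for cells in the CDK2low state (t = hours spent quiescent).  The
    shapes encode the measured per-protein behaviour: Cyclin A2 rises
    linearly through S and G2 and is at baseline in quiescent cells;
    Cyclin B1 rises supra-linearly from late S; Geminin rises in early S
    and plateaus; Cyclin D1 is U-shaped in cycling cells (moderate in G1,
    low in S, moderate in G2) while rising steadily in quiescent cells to
    levels above anything cycling cells reach; Cyclin E rises in G1 and
    falls at the G1/S transition but keeps rising in quiescence; p21 is
    near-zero in cycling cells and climbs steadily in quiescence; Cdt1 is
    high in G1, degraded in S, re-accumulates in G2, and decays slowly in
    quiescence; c-Myc and phospho-Rb rise through the cycle and are off in
    quiescent cells; EdU marks the S-phase window; p27 is a flat control.
    """

    BASELINE = 10.0

    _S0, _S1 = S_PHASE_WINDOW

    _CYCLE = {
        "CyclinA2": _interp_curve([(0, 10), (_S0, 10), (G2_END, 270)]),
        "CyclinB1": lambda t: 10.0 + 4.0 * np.maximum(0.0, np.clip(t, 0, G2_END) - 10.0) ** 2,
        "CyclinE": _interp_curve([(0, 40), (_S0, 165), (_S0 + 2, 30), (G2_END, 30)]),
        "CyclinD1": _interp_curve(
            [(0, 80), (_S0, 80), (_S0 + 1, 30), (_S1, 30), (_S1 + 1, 80), (G2_END, 80)]
        ),
        "p21": lambda t: np.full_like(np.asarray(t, dtype=float), 8.0),
        "Cdt1": _interp_curve(
            [(0, 120), (_S0, 150), (_S0 + 1, 20), (_S1, 20), (_S1 + 2, 100), (G2_END, 110)]
        ),
        "Geminin": _interp_curve([(0, 10), (_S0, 10), (_S0 + 6, 190), (G2_END, 190)]),
        "cMyc": _interp_curve([(0, 60), (_S0, 60), (G2_END, 216)]),
        "phosphoRb": lambda t: 80.0 + 8.0 * np.clip(t, 0, G2_END),
        "EdU": lambda t: np.where(
            (np.asarray(t, dtype=float) >= ProteinProfileSet._S0)
            & (np.asarray(t, dtype=float) < ProteinProfileSet._S1),
            200.0,
            3.0,
        ),
        "p27": lambda t: np.full_like(np.asarray(t, dtype=float), 50.0),
    }

    _QUIESCENT = {
        "CyclinA2": lambda t: np.full_like(np.asarray(t, dtype=float), 10.0),
        "CyclinB1": lambda t: np.full_like(np.asarray(t, dtype=float), 10.0),
        "CyclinE": lambda t: 60.0 + 5.0 * np.asarray(t, dtype=float),
        "CyclinD1": lambda t: 100.0 + 6.0 * np.asarray(t, dtype=float),
        "p21": lambda t: 60.0 + 6.0 * np.asarray(t, dtype=float),
        "Cdt1": lambda t: np.maximum(15.0, 120.0 - 3.5 * np.asarray(t, dtype=float)),
        "Geminin": lambda t: np.full_like(np.asarray(t, dtype=float), 10.0),
        "cMyc": lambda t: np.full_like(np.asarray(t, dtype=float), 15.0),
        "phosphoRb": lambda t: np.full_like(np.asarray(t, dtype=float), 12.0),
        "EdU": lambda t: np.full_like(np.asarray(t, dtype=float), 3.0),
        "p27": lambda t: np.full_like(np.asarray(t, dtype=float), 50.0),
    }

    PROTEINS = tuple(_CYCLE)

    def expected(self, protein, fate, t_since_anchor, emerge_delay=0.0):
        """Expected intensity for one protein.

        ``t_since_anchor`` is hours since anaphase for dividing fates and
        hours since movie start for nondividing fates.  For emerging
        fates, time before ``emerge_delay`` follows the quiescent curve
        and time after it follows the cycle curve re-anchored at the
        R-point.
        """
        if protein not in self._CYCLE:
            raise PanelError(f"unknown protein {protein!r}")
        t = np.asarray(t_since_anchor, dtype=float)
        cyc, qui = self._CYCLE[protein], self._QUIESCENT[protein]
        if fate == "CDK2inc":
            out = cyc(t)
        elif fate in ("CDK2low", "prolonged_quiescent"):
            out = qui(t)
        elif fate in ("CDK2emerge", "nondividing_emerge"):
            out = np.where(t < emerge_delay, qui(np.minimum(t, emerge_delay)),
                           cyc(t - emerge_delay))
        else:
            raise ConfigurationError(f"unknown fate {fate!r}")
        out = np.asarray(out, dtype=float)
        if (out < 0).any():  # pragma: no cover - profiles are nonnegative
            raise ValueError("protein profile produced negative intensity")
        return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthCohort:
    """Simulated cohort with complete ground truth.

    ``cells`` has one row per rendered entity (initial cell or daughter)
    with its lifetime ``[birth_frame, end_frame)``, geometry and H2B mass.
    ``lineages`` has one row per initial cell with its fate, division and
    R-point times and trace-model parameters.  ``activity`` is the true
    per-frame CDK2 activity of every entity (NaN outside its lifetime).
    """

    config: SimConfig
    cells: pd.DataFrame
    lineages: pd.DataFrame
    activity: np.ndarray  # (n_entities, n_frames)
    models: list[TraceModel]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    def entities_alive_at(self, frame: int) -> pd.DataFrame:
        c = self.cells
        return c[(c.birth_frame <= frame) & (frame < c.end_frame)]

    def endpoint_truth(self, panel, profiles: ProteinProfileSet | None = None
                       ) -> pd.DataFrame:
        """True endpoint IF intensities for entities alive at the last frame."""
        profiles = profiles or ProteinProfileSet()
        last = self.n_frames - 1
        alive = self.entities_alive_at(last)
        lin = self.lineages.set_index("lineage_id")
        rows = {}
        tau = []
        delay = []
        for _, cell in alive.iterrows():
            li = lin.loc[cell.lineage_id]
            if li.division_time == li.division_time and np.isfinite(li.division_time):
                t = self.config.duration - li.division_time
            else:
                t = self.config.duration
            tau.append(t)
            if li.fate == "CDK2emerge":
                delay.append(li.emerge_delay)
            elif li.fate == "nondividing_emerge":
                delay.append(li.emerge_delay)
            else:
                delay.append(0.0)
        out = pd.DataFrame({
            "cell_id": alive.cell_id.to_numpy(),
            "lineage_id": alive.lineage_id.to_numpy(),
            "fate": alive.fate.to_numpy(),
            "time_since_anaphase": np.array(tau),
        })
        fates = out.fate.to_numpy()
        taus = out.time_since_anaphase.to_numpy()
        delays = np.array(delay)
        for protein in panel:
            vals = np.empty(len(out))
            for i in range(len(out)):
                vals[i] = profiles.expected(protein, fates[i], taus[i], delays[i])
            rows[protein] = vals
        for protein, vals in rows.items():
            out[protein] = vals
        return out


def _draw_lineage_model(fate: str, rng: np.random.Generator, cfg: SimConfig):
    """Division time, trace model and mother-peak for one lineage."""
    T = cfg.duration
    division_time = np.nan
    emerge_delay = 0.0
    if fate == "CDK2inc":
        division_time = rng.uniform(1.0, T - 2.0)
        model = TraceModel(
            fate,
            birth_activity=rng.uniform(0.65, 0.85),
            rise_rate=rng.uniform(0.06, 0.11),
            noise_sd=cfg.trace_noise_sd,
        )
    elif fate == "CDK2low":
        division_time = rng.uniform(1.0, T - 2.0)
        model = TraceModel(
            fate,
            low_level=rng.uniform(0.2, 0.35),
            noise_sd=cfg.trace_noise_sd,
        )
    elif fate == "CDK2emerge":
        division_time = rng.uniform(1.0, T - 8.0)
        low = rng.uniform(0.25, 0.35)
        rise = rng.uniform(0.15, 0.30)
        # dwell must leave room for a confirmed crossing before the movie ends
        max_delay = T - division_time - (0.5 - low) / rise - 1.5
        delay = rng.uniform(3.2, max(3.3, min(10.0, max_delay)))
        model = TraceModel(
            fate, low_level=low, rise_rate=rise, emerge_delay=delay,
            noise_sd=cfg.trace_noise_sd,
        )
        emerge_delay = delay
    elif fate == "prolonged_quiescent":
        model = TraceModel(
            fate, low_level=rng.uniform(0.15, 0.45), noise_sd=cfg.trace_noise_sd
        )
    else:  # nondividing_emerge
        low = rng.uniform(0.25, 0.35)
        rise = rng.uniform(0.15, 0.30)
        delay = rng.uniform(6.0, T - (0.6 - low) / rise - 2.0)
        model = TraceModel(
            fate, low_level=low, rise_rate=rise, emerge_delay=delay,
            noise_sd=cfg.trace_noise_sd,
        )
        emerge_delay = delay
    peak = rng.uniform(1.4, 2.2)  # mother's pre-mitotic activity
    return division_time, emerge_delay, model, peak


def simulate_cohort(config: SimConfig) -> GroundTruthCohort:
    """Draw a cohort of lineages with fates, geometry and true traces.

    Deterministic given ``config.seed``.  Each lineage divides at most
    once during the movie (dividing fates carry exactly one anaphase);
    daughters inherit the lineage's post-anaphase trace model and each
    receives 45-55% of the mother's H2B mass.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    fracs = np.array([cfg.composition.get(f, 0.0) for f in FATES])
    fates = rng.choice(len(FATES), size=n, p=fracs)
    shape = cfg.resolved_field_shape()
    r_px = cfg.radius_px
    spacing = cfg.grid_spacing_px
    side_sites = math.ceil(math.sqrt(n))
    usable = (shape[0] - 2 * cfg.margin_px, shape[1] - 2 * cfg.margin_px)
    if side_sites * spacing > max(usable) + spacing * 0.5 and cfg.field_shape is not None:
        raise LayoutError(
            f"field {shape} too small for {n} cells at spacing {spacing:.1f} px"
        )

    # jittered-grid site positions; a `crowding` fraction of cells is
    # instead placed tangent to a host cell to create touching pairs
    n_crowded = int(round(cfg.crowding * n))
    n_sites = n - n_crowded
    sites = []
    for k in range(n_sites):
        gr, gc = divmod(k, side_sites)
        sites.append((
            cfg.margin_px + (gr + 0.5) * spacing + rng.uniform(-0.1, 0.1) * spacing,
            cfg.margin_px + (gc + 0.5) * spacing + rng.uniform(-0.1, 0.1) * spacing,
        ))
    sites = np.array(sites, dtype=float)

    times = cfg.times
    dt = cfg.frame_hours
    n_frames = cfg.n_frames

    cell_rows = []
    lineage_rows = []
    models: list[TraceModel] = []
    activities = []
    next_id = 0
    # occupancy list for division-axis placement: (row, col, radius,
    # birth_frame, end_frame)
    placed: list[tuple[float, float, float, int, int]] = []

    def _division_axis(row, col, off, rad_d, a_frame, self_idx):
        """Division axis maximizing daughters' clearance from neighbours
        alive while the daughters exist (cells divide into free space)."""
        base = rng.uniform(0, 2 * math.pi)
        angles = base + np.arange(12) * (math.pi / 12)
        relevant = [p for p in placed
                    if p[5] != self_idx
                    and p[4] > a_frame  # alive at/after the division
                    and (p[0] - row) ** 2 + (p[1] - col) ** 2 < (6 * r_px) ** 2]
        if not relevant:
            return float(base)
        best_ang, best_gap = float(base), -np.inf
        for ang in angles:
            gap = np.inf
            for sgn in (1.0, -1.0):
                dr = row + sgn * off * math.sin(ang)
                dc = col + sgn * off * math.cos(ang)
                for (pr, pc, prad, pb, pe, pidx) in relevant:
                    d = math.hypot(dr - pr, dc - pc) - rad_d - prad
                    gap = min(gap, d)
            if gap > best_gap:
                best_gap, best_ang = gap, float(ang)
        return best_ang

    def ellipse_axes(scale=1.0):
        e = cfg.eccentricity
        return (
            r_px * scale * rng.uniform(1 - e / 2, 1 + e / 2),
            r_px * scale * rng.uniform(1 - e / 2, 1 + e / 2),
        )

    host_ids = rng.choice(n_sites, size=n_crowded, replace=False) if n_crowded else []

    # all initial positions are fixed up front so that division-axis
    # placement can avoid every neighbour, not only earlier-indexed ones
    positions = []
    for lineage in range(n):
        if lineage < n_sites:
            positions.append(tuple(sites[lineage]))
        else:
            # tangent partner of a host cell (exercises deflection bridging)
            hr, hc = sites[host_ids[lineage - n_sites]]
            ang = rng.uniform(0, 2 * math.pi)
            d = 2 * r_px - 1.0
            positions.append((hr + d * math.sin(ang), hc + d * math.cos(ang)))
    placed = [(p[0], p[1], r_px, 0, n_frames, i)
              for i, p in enumerate(positions)]

    for lineage in range(n):
        fate = FATES[fates[lineage]]
        division_time, emerge_delay, model, peak = _draw_lineage_model(fate, rng, cfg)
        models.append(model)
        row, col = positions[lineage]
        ra, rc = ellipse_axes()
        theta = rng.uniform(0, math.pi)
        h2b_intensity = rng.uniform(500.0, 800.0)
        sensor_scale = rng.uniform(120.0, 160.0)

        if fate in DIVIDING_FATES:
            a_frame = int(math.ceil(division_time / dt - 1e-9))
            a_frame = min(max(a_frame, 1), n_frames - 1)
            frac = rng.uniform(0.47, 0.53)
            # mother trace: activity ramps up toward the pre-mitotic peak
            mother_t = times[:a_frame]
            mother_a = np.maximum(0.3, peak - 0.08 * (division_time - mother_t))
            mother_a = mother_a + rng.normal(0, cfg.trace_noise_sd, mother_a.shape)
            act = np.full(n_frames, np.nan)
            act[:a_frame] = np.maximum(mother_a, 0.0)
            mother_id = next_id
            cell_rows.append(dict(
                cell_id=mother_id, lineage_id=lineage, mother_id=-1, fate=fate,
                birth_frame=0, end_frame=a_frame, division_frame=a_frame,
                row=row, col=col, rad_r=ra, rad_c=rc, theta=theta,
                h2b_intensity=h2b_intensity, sensor_scale=sensor_scale,
                h2b_mass_frac=1.0,
            ))
            activities.append(act)
            next_id += 1
            off = 1.45 * r_px
            rad_d = r_px / math.sqrt(2)
            ax_ang = _division_axis(row, col, off, rad_d, a_frame, lineage)
            post_t = times[a_frame:] - division_time
            for j, (sgn, dfrac) in enumerate(((1.0, frac), (-1.0, 1.0 - frac))):
                dr = row + sgn * off * math.sin(ax_ang)
                dc = col + sgn * off * math.cos(ax_ang)
                dra, drc = ellipse_axes(scale=1 / math.sqrt(2))
                placed.append((dr, dc, max(dra, drc), a_frame, n_frames,
                               lineage))
                d_act = np.full(n_frames, np.nan)
                d_act[a_frame:] = sample_trace(model, post_t, rng)
                cell_rows.append(dict(
                    cell_id=next_id, lineage_id=lineage, mother_id=mother_id,
                    fate=fate, birth_frame=a_frame, end_frame=n_frames,
                    division_frame=-1, row=dr, col=dc, rad_r=dra, rad_c=drc,
                    theta=rng.uniform(0, math.pi),
                    h2b_intensity=h2b_intensity, sensor_scale=sensor_scale,
                    h2b_mass_frac=dfrac,
                ))
                activities.append(d_act)
                next_id += 1
            rpoint = division_time + (emerge_delay if fate == "CDK2emerge" else 0.0)
            if fate == "CDK2low":
                rpoint = np.nan
        else:
            act = sample_trace(model, times, rng)
            cell_rows.append(dict(
                cell_id=next_id, lineage_id=lineage, mother_id=-1, fate=fate,
                birth_frame=0, end_frame=n_frames, division_frame=-1,
                row=row, col=col, rad_r=ra, rad_c=rc, theta=theta,
                h2b_intensity=h2b_intensity, sensor_scale=sensor_scale,
                h2b_mass_frac=1.0,
            ))
            activities.append(act)
            next_id += 1
            a_frame = -1
            frac = np.nan
            rpoint = emerge_delay if fate == "nondividing_emerge" else np.nan

        lineage_rows.append(dict(
            lineage_id=lineage, fate=fate, division_time=division_time,
            anaphase_frame=a_frame, rpoint_time=rpoint,
            birth_activity=model.birth_activity, rise_rate=model.rise_rate,
            low_level=model.low_level, emerge_delay=emerge_delay,
            mother_peak=peak, daughter_frac=frac,
        ))

    cells = pd.DataFrame(cell_rows)
    lineages = pd.DataFrame(lineage_rows)
    activity = np.vstack(activities)
    return GroundTruthCohort(cfg, cells, lineages, activity, models)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

RING_INNER_OFFSET = 1.0  # px between nuclear boundary and ring
RING_WIDTH = 4.0  # px


class _EntityPixels:
    __slots__ = ("nucleus", "ring", "area", "ring_area")

    def __init__(self, nucleus, ring):
        self.nucleus = nucleus
        self.ring = ring
        self.area = nucleus.size
        self.ring_area = ring.size


def _scaled_boundary_distance(rr, cc, cell):
    """Approximate signed distance (px) from pixel centres to the ellipse."""
    dr = rr - cell.row
    dc = cc - cell.col
    ct, st = math.cos(cell.theta), math.sin(cell.theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    m = np.sqrt((u / cell.rad_r) ** 2 + (v / cell.rad_c) ** 2)
    r_mean = math.sqrt(cell.rad_r * cell.rad_c)
    return (m - 1.0) * r_mean


def _build_pixel_lists(cohort: GroundTruthCohort, shape) -> list[_EntityPixels]:
    """Static nucleus and perinuclear-ring pixel lists for every entity.

    Nucleus pixels are claimed first-come (masks disjoint, so integrated
    masses are exact).  Ring pixels are assigned to the entity whose
    boundary is closest (among entities with overlapping lifetimes) and
    exclude all nucleus pixels, matching the quantifier's
    nearest-nucleus ring assignment on isolated and touching cells alike.
    """
    H, W = shape
    cells = cohort.cells
    n_ent = len(cells)
    claim = np.full(shape, -1, dtype=np.int32)
    claim_dist = np.full(H * W, np.inf, dtype=np.float32)
    stolen: dict[int, list[np.ndarray]] = {}
    recs = list(cells.itertuples())
    # spatial neighbour lists via a coarse grid
    from scipy.spatial import cKDTree

    centers = cells[["row", "col"]].to_numpy()
    tree = cKDTree(centers)
    interact = 4.0 * max(r.rad_r for r in recs) + 2 * (RING_INNER_OFFSET + RING_WIDTH)
    pixel_lists: list[_EntityPixels] = [None] * n_ent  # type: ignore

    outer = RING_INNER_OFFSET + RING_WIDTH
    for rec in recs:
        R = max(rec.rad_r, rec.rad_c) + outer + 2
        r0 = max(0, int(rec.row - R)); r1 = min(H, int(rec.row + R) + 2)
        c0 = max(0, int(rec.col - R)); c1 = min(W, int(rec.col + R) + 2)
        if r0 >= r1 or c0 >= c1:
            raise LayoutError("cell outside field")
        rr, cc = np.mgrid[r0:r1, c0:c1]
        rr = rr.astype(float); cc = cc.astype(float)
        dist = _scaled_boundary_distance(rr, cc, rec)
        inside = dist <= 0
        ring_band = (dist > RING_INNER_OFFSET) & (dist <= outer)
        flat = (rr.astype(np.int64) * W + cc.astype(np.int64))

        # nucleus: claim pixels; contested pixels between entities with
        # overlapping lifetimes go to the cell whose boundary is nearest
        # (the bisector), matching how deflection bridging later splits
        # touching nuclei
        nuc_flat = flat[inside]
        nuc_dist = dist[inside].astype(np.float32)
        prev = claim.ravel()[nuc_flat]
        free = prev < 0
        take = free.copy()
        if not free.all():
            contested = prev[~free]
            overlap = np.array([
                (cells.birth_frame.iat[p] < rec.end_frame)
                and (rec.birth_frame < cells.end_frame.iat[p])
                for p in contested
            ])
            closer = nuc_dist[~free] < claim_dist[nuc_flat[~free]]
            # non-overlapping lifetimes: both may keep the pixel
            take[~free] = ~overlap | closer
            steal = np.zeros(nuc_flat.size, dtype=bool)
            steal[~free] = overlap & closer
            for p in np.unique(prev[steal]):
                stolen.setdefault(int(p), []).append(
                    nuc_flat[steal & (prev == p)])
        nuc_flat = nuc_flat[take]
        claim.ravel()[nuc_flat] = rec.cell_id
        claim_dist[nuc_flat] = nuc_dist[take]

        # ring: drop pixels whose nearest (boundary-distance) live
        # neighbour is someone else, or that sit inside any neighbour
        neigh = tree.query_ball_point([rec.row, rec.col], interact)
        ring_rr, ring_cc = rr[ring_band], cc[ring_band]
        ring_flat = flat[ring_band]
        own_d = dist[ring_band]
        keep = np.ones(ring_flat.size, dtype=bool)
        for j in neigh:
            other = recs[j]
            if other.cell_id == rec.cell_id:
                continue
            if not (other.birth_frame < rec.end_frame
                    and rec.birth_frame < other.end_frame):
                continue
            od = _scaled_boundary_distance(ring_rr, ring_cc, other)
            keep &= od > own_d
            keep &= od > 0
        ring_flat = ring_flat[keep]
        pixel_lists[rec.cell_id] = _EntityPixels(nuc_flat, ring_flat)

    # hand stolen contested pixels back to their final owner's ledger
    for cid, chunks in stolen.items():
        gone = np.concatenate(chunks)
        pl = pixel_lists[cid]
        pl.nucleus = np.setdiff1d(pl.nucleus, gone, assume_unique=False)
        pl.area = pl.nucleus.size

    # remove ring pixels that fall on any nucleus pixel
    nucleus_any = claim.ravel() >= 0
    for pl in pixel_lists:
        pl.ring = pl.ring[~nucleus_any[pl.ring]]
        pl.ring_area = pl.ring.size
    return pixel_lists


class MovieRenderer:
    """Frame-by-frame renderer for a simulated cohort.

    Produces the H2B and sensor channels for any frame; channel intensity
    layout is documented in the module docstring.  Use
    :func:`render_movie` for a fully materialised stack.
    """

    def __init__(self, cohort: GroundTruthCohort):
        self.cohort = cohort
        self.shape = cohort.config.resolved_field_shape()
        self.pixels = _build_pixel_lists(cohort, self.shape)
        cells = cohort.cells
        # per-entity H2B pixel value: mass_frac * lineage mass / area
        lin_mass = {}
        for rec in cells.itertuples():
            if rec.mother_id < 0:
                lin_mass[rec.lineage_id] = (
                    rec.h2b_intensity * self.pixels[rec.cell_id].area
                )
        self.h2b_mass = np.array([
            rec.h2b_mass_frac * lin_mass[rec.lineage_id]
            for rec in cells.itertuples()
        ])
        self.h2b_value = self.h2b_mass / np.array(
            [max(pl.area, 1) for pl in self.pixels]
        )

    def true_mask(self, frame: int) -> np.ndarray:
        """Ground-truth label image (cell_id + 1; 0 = background)."""
        lab = np.zeros(self.shape, dtype=np.int32).ravel()
        alive = self.cohort.entities_alive_at(frame)
        for rec in alive.itertuples():
            lab[self.pixels[rec.cell_id].nucleus] = rec.cell_id + 1
        return lab.reshape(self.shape)

    def render_frame(self, frame: int, noisy: bool = True):
        """Return (h2b, sensor) float32 images for one frame."""
        cfg = self.cohort.config
        H, W = self.shape
        h2b = np.full(H * W, cfg.background_level, dtype=np.float32)
        sensor = np.full(H * W, cfg.background_level, dtype=np.float32)
        alive = self.cohort.entities_alive_at(frame)
        act = self.cohort.activity
        for rec in alive.itertuples():
            pl = self.pixels[rec.cell_id]
            a = act[rec.cell_id, frame]
            h2b[pl.nucleus] += self.h2b_value[rec.cell_id]
            # sensor mass is constant; translocation moves it into the ring
            total = rec.sensor_scale * (pl.area + pl.ring_area)
            v_n = total / (pl.area + a * max(pl.ring_area, 1))
            sensor[pl.nucleus] += v_n
            sensor[pl.ring] += a * v_n
        h2b = h2b.reshape(H, W)
        sensor = sensor.reshape(H, W)
        if noisy and cfg.noise_sd > 0:
            rng = np.random.default_rng([cfg.seed, 1000 + frame])
            h2b += rng.normal(0, cfg.noise_sd, h2b.shape).astype(np.float32)
            sensor += rng.normal(0, cfg.noise_sd, sensor.shape).astype(np.float32)
        return np.maximum(h2b, 0.0), np.maximum(sensor, 0.0)


def render_movie(cohort: GroundTruthCohort, config: SimConfig | None = None,
                 noisy: bool = True) -> np.ndarray:
    """Materialise the full movie as (frames, 2, rows, cols) float32.

    Channel 0 is H2B, channel 1 the CDK2 sensor.  For long movies prefer
    :class:`MovieRenderer` and stream frames.
    """
    cfg = config or cohort.config
    if config is not None and config is not cohort.config:
        cohort = replace(cohort, config=config)
    renderer = MovieRenderer(cohort)
    H, W = renderer.shape
    out = np.empty((cfg.n_frames, 2, H, W), dtype=np.float32)
    for f in range(cfg.n_frames):
        h2b, sensor = renderer.render_frame(f, noisy=noisy)
        out[f, 0] = h2b
        out[f, 1] = sensor
    return out


def _rigid_translate(img: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(img, fill)
    H, W = img.shape
    ys0, ys1 = max(0, dy), min(H, H + dy)
    xs0, xs1 = max(0, dx), min(W, W + dx)
    out[ys0:ys1, xs0:xs1] = img[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx]
    return out


def render_endpoint_if(
    cohort: GroundTruthCohort,
    panel: list[str],
    config: SimConfig | None = None,
    renderer: MovieRenderer | None = None,
    profiles: ProteinProfileSet | None = None,
):
    """Render the post-fixation IF image set and return the applied shift.

    Returns ``(stack, channels, shift, truth)`` where ``stack`` is
    (1 + len(panel), rows, cols) float32 with channel 0 a Hoechst-like
    nuclear stain of the final frame, ``shift`` the rigid (dy, dx)
    translation applied to the whole set (the stage jitter the
    registration module must recover), and ``truth`` the per-cell true
    endpoint intensities.
    """
    cfg = config or cohort.config
    profiles = profiles or ProteinProfileSet()
    for p in panel:
        if p not in ProteinProfileSet.PROTEINS:
            raise PanelError(f"unknown protein {p!r}")
    renderer = renderer or MovieRenderer(cohort)
    H, W = renderer.shape
    last = cohort.n_frames - 1
    rng = np.random.default_rng([cfg.seed, 7777])

    if cfg.jitter_shift == "random":
        r = cfg.jitter_radius
        shift = (int(rng.integers(-r, r + 1)), int(rng.integers(-r, r + 1)))
    else:
        shift = (int(cfg.jitter_shift[0]), int(cfg.jitter_shift[1]))

    truth = cohort.endpoint_truth(panel, profiles)
    truth_by_id = truth.set_index("cell_id")
    hoechst = np.full(H * W, cfg.background_level, dtype=np.float32)
    chans = [np.full(H * W, cfg.background_level, dtype=np.float32)
             for _ in panel]
    alive = cohort.entities_alive_at(last)
    noisy_vals = {}
    for rec in alive.itertuples():
        pl = renderer.pixels[rec.cell_id]
        hoechst[pl.nucleus] += renderer.h2b_value[rec.cell_id]
        for k, protein in enumerate(panel):
            base = truth_by_id.loc[rec.cell_id, protein]
            # per-cell multiplicative (staining) noise
            val = base * rng.lognormal(0.0, 0.12) if cfg.noise_sd > 0 else base
            noisy_vals[(rec.cell_id, protein)] = val
            chans[k][pl.nucleus] += val
    stack = np.stack([hoechst.reshape(H, W)] + [c.reshape(H, W) for c in chans])
    shifted = np.stack([
        _rigid_translate(img, shift[0], shift[1], cfg.background_level)
        for img in stack
    ])
    if cfg.noise_sd > 0:
        shifted = shifted + rng.normal(0, cfg.noise_sd, shifted.shape).astype(np.float32)
        shifted = np.maximum(shifted, 0.0)
    channels = ["Hoechst"] + list(panel)
    for protein in panel:
        truth[protein + "_rendered"] = [
            noisy_vals[(cid, protein)] for cid in truth.cell_id
        ]
    return shifted, channels, shift, truth


# ---------------------------------------------------------------------------
# snapshot populations
# ---------------------------------------------------------------------------

PHASES = ("G0", "G1", "earlyS", "S", "lateS", "G2", "M")

DEFAULT_PHASE_FRACTIONS = {
    "G0": 0.15, "G1": 0.30, "earlyS": 0.07, "S": 0.25,
    "lateS": 0.07, "G2": 0.13, "M": 0.03,
}

#: representative time-since-anaphase (h) used to look up the protein of
#: interest for each phase
_PHASE_TIME = {"G0": 12.0, "G1": 2.0, "earlyS": 5.5, "S": 9.0,
               "lateS": 12.5, "G2": 15.0, "M": 17.9}


@dataclass
class SnapshotConfig:
    """Configuration for an asynchronous fixed-cell snapshot population."""

    n_cells: int = 5000
    phase_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_FRACTIONS)
    )
    poi: str = "p21"
    noise_log_sd: float = 0.05  # log-normal measurement noise; 0 = noiseless
    dna_2n: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.array([self.phase_fractions.get(p, 0.0) for p in PHASES])
        if (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
            raise ConfigurationError("phase fractions must be nonnegative and sum to 1")


def snapshot_population(config: SnapshotConfig):
    """Per-cell marker table for an asynchronous snapshot plus true phases.

    DNA content spans 2N-4N, EdU is negative / intermediate / high by
    phase, phospho-Rb is bimodal (hypo in G0 only), and pHH3 marks M;
    the protein of interest follows its phase-representative profile
    value.  Measurement noise is log-normal.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fr = np.array([cfg.phase_fractions.get(p, 0.0) for p in PHASES])
    phase_idx = rng.choice(len(PHASES), size=cfg.n_cells, p=fr)
    phases = np.array(PHASES, dtype=object)[phase_idx]
    D = cfg.dna_2n
    profiles = ProteinProfileSet()

    dna = np.empty(cfg.n_cells)
    edu = np.empty(cfg.n_cells)
    prb = np.empty(cfg.n_cells)
    phh3 = np.empty(cfg.n_cells)
    poi = np.empty(cfg.n_cells)
    for i, ph in enumerate(phases):
        if ph in ("G0", "G1"):
            dna[i] = D * rng.uniform(0.97, 1.08)
        elif ph == "earlyS":
            dna[i] = D * rng.uniform(1.02, 1.2)
        elif ph == "S":
            dna[i] = D * rng.uniform(1.05, 1.95)
        elif ph == "lateS":
            dna[i] = D * rng.uniform(1.8, 1.98)
        else:  # G2, M
            dna[i] = D * rng.uniform(1.92, 2.06)
        if ph == "S":
            edu[i] = 3000.0
        elif ph in ("earlyS", "lateS"):
            edu[i] = 300.0
        else:
            edu[i] = 30.0
        prb[i] = 50.0 if ph == "G0" else 800.0
        phh3[i] = 500.0 if ph == "M" else 20.0
        fate = "CDK2low" if ph == "G0" else "CDK2inc"
        poi[i] = profiles.expected(cfg.poi, fate, _PHASE_TIME[ph])
    if cfg.noise_log_sd > 0:
        for arr in (dna, edu, prb, phh3, poi):
            arr *= rng.lognormal(0.0, cfg.noise_log_sd, size=arr.shape)
    records = pd.DataFrame({
        "dna": dna, "edu": edu, "prb": prb, "phh3": phh3, "poi": poi,
    })
    return records, pd.Series(phases, name="phase")
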