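"""End-to-end orchestration: simulate/segment/quantify/track/classify/map.

The movie pipeline consumes a two-channel time-lapse (H2B + CDK2 sensor)
frame by frame: nuclei are segmented with the LoG detector (full
deflection bridging on the first frame, adaptive bridging afterwards on
objects the tracker flags as putative merges), per-cell intensities and
CDK2 activity are measured, frames are linked by mass-screened nearest
neighbour with anaphase calls, and every lineage is classified into the
proliferation-quiescence fate classes.  Snapshot mode routes IF marker
tables through gate fitting and phase calling instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import find_objects as ndimage_find_objects

from . import dynmap, gating, register, simdata
from .quantify import QuantParams, measure_frame
from .segment import SegmentParams, adaptive_resegment, segment_nuclei
from .track import CellTrace, TrackParams, Tracker, lineage_roots
from .traces import ClassifierParams, align_ensemble, classify_trace

log = logging.getLogger("cyclemap")


@dataclass
class PipelineConfig:
    """Parameter blocks for every stage plus provenance fields."""

    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    segment: SegmentParams | None = None
    quant: QuantParams | None = None
    track: TrackParams | None = None
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    panel: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        r = self.sim.radius_px
        if self.segment is None:
            self.segment = SegmentParams(expected_radius_px=r)
        if self.quant is None:
            self.quant = QuantParams(pixel_size=self.sim.pixel_size)
        if self.track is None:
            self.track = TrackParams(expected_radius_px=r)

    def provenance(self) -> dict:
        blob = json.dumps(
            {k: str(v) for k, v in asdict(self).items()}, sort_keys=True
        )
        return {
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:12],
            "seed": self.sim.seed,
        }


@dataclass
class MovieResult:
    """Everything the movie pipeline produced for one cohort."""

    config: PipelineConfig
    traces: dict[int, CellTrace]
    trace_table: pd.DataFrame  # long format: cell_id, frame, time_h, ...
    lineage_summary: pd.DataFrame  # per frame-0 lineage
    fractions: dict[str, float]
    final_mask: np.ndarray | None = None
    endpoint_if: pd.DataFrame | None = None


def _classify_lineages(traces: dict[int, CellTrace], frame_hours: float,
                       params: ClassifierParams) -> pd.DataFrame:
    """Per-lineage division status and fate label.

    A lineage is every track rooted at frame 0 plus its descendants.  For
    dividing lineages the post-anaphase daughter traces are classified
    and the lineage takes the daughters' (majority) label; nondividing
    lineages are classified on the whole trace.
    """
    rows = []
    roots = lineage_roots(traces)
    for root, members in roots.items():
        divided = any(traces[t].daughter_ids for t in members)
        if divided:
            labels = []
            for t in members:
                tr = traces[t]
                if tr.mother_id < 0 or tr.daughter_ids:
                    continue  # only terminal daughters carry the fate
                obs = tr.observations
                t_h = obs["frame"].to_numpy() * frame_hours
                ana_t = tr.anaphase_frames[0] * frame_hours
                labels.append(classify_trace(
                    t_h, obs["cdk2_activity"].to_numpy(), ana_t, params))
            if labels:
                vals, counts = np.unique(labels, return_counts=True)
                fate = str(vals[np.argmax(counts)])
            else:
                fate = "unclassified"
        else:
            tr = traces[root]
            obs = tr.observations
            t_h = obs["frame"].to_numpy() * frame_hours
            fate = classify_trace(
                t_h, obs["cdk2_activity"].to_numpy(), None, params)
        rows.append(dict(root_id=root, divided=divided, fate=fate,
                         n_tracks=len(members)))
    return pd.DataFrame(rows)


def _population_fractions(summary: pd.DataFrame) -> dict[str, float]:
    n = len(summary)
    if n == 0:
        return {}
    out = {"n_lineages": float(n),
           "pct_divided": 100.0 * summary["divided"].mean()}
    for fate in simdata.FATES + ("unclassified",):
        out["pct_" + fate] = 100.0 * (summary["fate"] == fate).mean()
    nondiv = summary[~summary["divided"]]
    if len(nondiv):
        out["pct_prolonged_among_nondividing"] = (
            100.0 * (nondiv["fate"] == "prolonged_quiescent").mean()
        )
    else:
        out["pct_prolonged_among_nondividing"] = float("nan")
    return out


def analyze_movie_frames(frame_iter, config: PipelineConfig,
                         keep_final_mask: bool = True) -> MovieResult:
    """Run segmentation, quantification, tracking and classification over
    an iterable of ``(frame_index, h2b_image, sensor_image)``.

    Deflection bridging runs on every object of the first frame; later
    frames are re-bridged adaptively when the tracker flags putative
    merged objects ("conservation of mass").
    """
    seg_p, qnt_p, trk_p = config.segment, config.quant, config.track
    state: dict = {"carry": set()}

    def resegment(frame: int, suspect_labels):
        lab = state["mask"]
        # remember where merged objects sat: the same contact usually
        # persists, so later frames pre-split it before measurement
        slices = ndimage_find_objects(lab)
        for s in suspect_labels:
            sl = slices[s - 1]
            state["carry"].add((
                (sl[0].start + sl[0].stop) // 2,
                (sl[1].start + sl[1].stop) // 2,
            ))
        lab2 = adaptive_resegment(lab, suspect_labels, seg_p)
        state["mask"] = lab2
        obs = measure_frame(state["h2b"], state["sensor"], lab2, qnt_p,
                            frame=frame)
        return obs

    tracker = Tracker(trk_p, resegment_callback=resegment)
    frame_hours = config.sim.frame_hours
    last_mask = None
    n_frames_seen = 0
    for frame, h2b, sensor in frame_iter:
        lab = segment_nuclei(h2b, seg_p)
        if frame == 0:
            labels = [int(v) for v in np.unique(lab) if v > 0]
            lab = adaptive_resegment(lab, labels, seg_p)
        elif state["carry"]:
            labels = sorted({
                int(lab[r, c]) for (r, c) in state["carry"]
                if 0 <= r < lab.shape[0] and 0 <= c < lab.shape[1]
                and lab[r, c] > 0
            })
            if labels:
                lab = adaptive_resegment(lab, labels, seg_p)
        state.update(mask=lab, h2b=h2b, sensor=sensor)
        obs = measure_frame(h2b, sensor, lab, qnt_p, frame=frame)
        tracker.advance(frame, obs)
        last_mask = state["mask"]
        n_frames_seen += 1
    traces = tracker.finalize()
    log.info("tracked %d objects into %d traces over %d frames",
             sum(len(t.observations) for t in traces.values()),
             len(traces), n_frames_seen)

    chunks = []
    for tid, tr in traces.items():
        if len(tr.observations) == 0:
            continue
        obs = tr.observations.copy()
        obs["cell_id"] = tid
        obs["time_h"] = obs["frame"] * frame_hours
        chunks.append(obs)
    trace_table = (pd.concat(chunks, ignore_index=True)
                   if chunks else pd.DataFrame())

    summary = _classify_lineages(traces, frame_hours, config.classifier)
    for _, row in summary.iterrows():
        traces[row.root_id].fate = row.fate
    fractions = _population_fractions(summary)
    return MovieResult(config, traces, trace_table, summary, fractions,
                       final_mask=last_mask if keep_final_mask else None)


def analyze_cohort(config: PipelineConfig,
                   cohort: simdata.GroundTruthCohort | None = None,
                   noisy: bool = True) -> MovieResult:
    """Simulate (unless given) and analyze a full synthetic cohort."""
    if cohort is None:
        cohort = simdata.simulate_cohort(config.sim)
    renderer = simdata.MovieRenderer(cohort)

    def frames():
        for f in range(cohort.n_frames):
            h2b, sensor = renderer.render_frame(f, noisy=noisy)
            yield f, h2b, sensor

    result = analyze_movie_frames(frames(), config)
    result._renderer = renderer  # kept for endpoint-IF stages
    result._cohort = cohort
    return result


def attach_endpoint_if(result: MovieResult, panel, search_radius: int = 15):
    """Render the endpoint IF set, correct jitter, and match IF values to
    the tracked cells of a simulated cohort result."""
    cohort = result._cohort
    renderer = result._renderer
    stack, channels, true_shift, truth = simdata.render_endpoint_if(
        cohort, list(panel), renderer=renderer)
    last_frame = cohort.n_frames - 1
    ref_h2b, _ = renderer.render_frame(last_frame, noisy=True)
    est = register.estimate_jitter(ref_h2b, stack[0], search_radius)
    if_images = {name: stack[1 + i] for i, name in enumerate(channels[1:])}
    values = register.match_if_to_traces(
        result.final_mask, if_images, est, result.config.quant)
    # map mask labels at the last frame to track ids
    final_obs = result.trace_table[result.trace_table["frame"] == last_frame]
    lab_to_cell = dict(zip(final_obs["label"], final_obs["cell_id"]))
    values["cell_id"] = [lab_to_cell.get(l, -1) for l in values["label"]]
    for _, row in values.iterrows():
        if row.cell_id >= 0:
            result.traces[int(row.cell_id)].endpoint_if = {
                p: row[p] for p in panel
            }
    result.endpoint_if = values
    return est, true_shift, truth


def build_dynamics(result: MovieResult, protein: str,
                   window: float = 2.0, step: float = 0.5,
                   min_bin_count: int = 10) -> dict[str, dynmap.DynamicsCurve]:
    """Anaphase-aligned dynamics curves per fate class for one protein."""
    frame_hours = result.config.sim.frame_hours
    movie_len = result.config.sim.duration
    anchors, fates, vals = {}, {}, {}
    for tid, tr in result.traces.items():
        if tr.mother_id >= 0 and not tr.daughter_ids and tr.endpoint_if:
            anchors[tid] = tr.anaphase_frames[0] * frame_hours
        if tr.endpoint_if and protein in tr.endpoint_if:
            vals[tid] = tr.endpoint_if[protein]
    # fate of each terminal track comes from its lineage summary
    roots = lineage_roots(result.traces)
    fate_by_root = dict(zip(result.lineage_summary["root_id"],
                            result.lineage_summary["fate"]))
    for root, members in roots.items():
        for t in members:
            tr = result.traces[t]
            if not tr.daughter_ids:
                fates[t] = fate_by_root.get(root, "unclassified")
    fates = pd.Series(fates)
    vals = pd.Series(vals, dtype=float)
    endpoint_x = pd.Series(
        {tid: movie_len - a for tid, a in anchors.items()}, dtype=float)
    curves = {}
    for fate in ("CDK2inc", "CDK2low", "prolonged_quiescent"):
        scatter = dynmap.reconstruct_dynamics(
            endpoint_x, vals, fates, fate, movie_len)
        curves[fate] = dynmap.moving_average(
            scatter, window, step, min_bin_count, protein=protein,
            fate=fate)
    return curves


def analyze_snapshot(records: pd.DataFrame, **gate_overrides):
    """Snapshot-mode: fit gates on a marker table and call phases."""
    gates = gating.fit_gates(records, **gate_overrides)
    phases = gating.call_phases(records, gates)
    return gates, phases
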