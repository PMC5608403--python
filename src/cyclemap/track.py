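"""Frame-to-frame tracking by nearest neighbour screened for mass conservation.

Cells are linked between consecutive frames to their nearest future
neighbour whose total H2B fluorescence is consistent with their own
("conservation of mass").  Mass conservation is further exploited to
detect merges (one object at t+1 carrying the mass of two cells at t;
sent back for adaptive re-segmentation) and splits.  A mitosis is called
at anaphase when the two nearest future neighbours of a cell each carry
between 45% and 55% (inclusive) of its total H2B fluorescence; the mother
track ends and two daughter tracks begin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class TrackParams:
    """``max_displacement`` is in pixels/frame (default three nuclear
    radii); ``h2b_tolerance`` is the relative mass-consistency band for
    links; daughters must each carry a mass fraction in
    [daughter_low, daughter_high] (inclusive) for an anaphase call."""

    expected_radius_px: float = 5.0
    max_displacement: float | None = None  # px / frame
    h2b_tolerance: float = 0.1
    daughter_low: float = 0.45
    daughter_high: float = 0.55
    max_gap: int = 1  # frames a track may go unseen before being closed

    def __post_init__(self) -> None:
        if self.max_displacement is None:
            self.max_displacement = 3.0 * self.expected_radius_px
        if not 0 < self.daughter_low < self.daughter_high < 1:
            raise ValueError("need 0 < daughter_low < daughter_high < 1")
        if self.h2b_tolerance <= 0:
            raise ValueError("h2b_tolerance must be positive")


def _link_arrays(src_xy, src_mass, tgt_xy, tgt_mass, params: TrackParams):
    n_s, n_t = len(src_xy), len(tgt_xy)
    link = np.full(n_s, -1, dtype=int)
    if n_s == 0 or n_t == 0:
        return link
    tree = cKDTree(tgt_xy)
    neighbours = tree.query_ball_point(src_xy, params.max_displacement)
    pairs = []
    for i, cand in enumerate(neighbours):
        for j in cand:
            rel = abs(tgt_mass[j] - src_mass[i]) / max(src_mass[i], 1e-12)
            if rel <= params.h2b_tolerance:
                d = float(np.hypot(*(src_xy[i] - tgt_xy[j])))
                pairs.append((d, rel, i, j))
    pairs.sort()
    used_t = np.zeros(n_t, dtype=bool)
    for d, rel, i, j in pairs:
        if link[i] < 0 and not used_t[j]:
            link[i] = j
            used_t[j] = True
    return link


def _coords(obs: pd.DataFrame) -> np.ndarray:
    return obs[["centroid_row", "centroid_col"]].to_numpy(dtype=float)


def link_frames(obs_t: pd.DataFrame, obs_t1: pd.DataFrame,
                params: TrackParams | None = None) -> np.ndarray:
    """Match cells at t to cells at t+1.

    Returns, for each row of ``obs_t``, the row index in ``obs_t1`` it
    links to, or -1.  A link requires the target to lie within
    ``max_displacement`` and have total H2B within ``h2b_tolerance``
    (relative) of the source; candidate pairs are taken in order of
    distance (ties broken by mass difference) and the matching is
    one-to-one, so mass-consistent assignments beat distance-greedy ones.
    """
    params = params or TrackParams()
    return _link_arrays(
        _coords(obs_t), obs_t["total_h2b"].to_numpy(dtype=float),
        _coords(obs_t1), obs_t1["total_h2b"].to_numpy(dtype=float),
        params,
    )


def call_anaphase(mother_mass: float, daughter_masses,
                  params: TrackParams | None = None) -> bool:
    """True iff both daughter masses lie in the 45-55% band (inclusive)
    of the mother's total H2B fluorescence."""
    params = params or TrackParams()
    if daughter_masses is None or len(daughter_masses) != 2:
        return False
    if mother_mass <= 0:
        return False
    for m in daughter_masses:
        f = m / mother_mass
        if not (params.daughter_low <= f <= params.daughter_high):
            return False
    return True


def _detect_arrays(src_xy, src_mass, tgt_xy, tgt_mass, link,
                   params: TrackParams):
    merge_suspects: set[int] = set()  # target ROW indices
    split_candidates: list[tuple[int, int, int]] = []
    if len(src_xy) == 0 or len(tgt_xy) == 0:
        return merge_suspects, split_candidates
    tol = params.h2b_tolerance
    tree_t = cKDTree(tgt_xy)
    d_near, j_near = tree_t.query(src_xy)
    unmatched_src = np.flatnonzero(link < 0)
    matched_tgt = set(int(j) for j in link[link >= 0])

    by_target: dict[int, list[int]] = {}
    for i in unmatched_src:
        if d_near[i] <= params.max_displacement:
            by_target.setdefault(int(j_near[i]), []).append(int(i))
    for j, sources in by_target.items():
        if len(sources) >= 2:
            pair_mass = sum(sorted((src_mass[s] for s in sources), reverse=True)[:2])
            if abs(tgt_mass[j] - pair_mass) / pair_mass <= tol:
                merge_suspects.add(j)
                continue
        # orphan source whose putative target is much heavier than itself
        if tgt_mass[j] > (1 + tol) * max(src_mass[s] for s in sources):
            merge_suspects.add(j)

    # any unmatched target far heavier than its nearest source is a
    # putative merged object too (mass appeared from nowhere otherwise)
    unmatched_tgt = np.array(
        [j for j in range(len(tgt_xy)) if j not in matched_tgt], dtype=int
    )
    if unmatched_tgt.size:
        tree_s = cKDTree(src_xy)
        ds, is_ = tree_s.query(tgt_xy[unmatched_tgt])
        for k, j in enumerate(unmatched_tgt):
            if ds[k] <= params.max_displacement and \
                    tgt_mass[j] > (1 + tol) * src_mass[int(is_[k])]:
                merge_suspects.add(int(j))
    if unmatched_tgt.size >= 2:
        tree_u = cKDTree(tgt_xy[unmatched_tgt])
        for i in unmatched_src:
            d, jj = tree_u.query(src_xy[i], k=2)
            if np.max(d) > params.max_displacement:
                continue
            ja, jb = unmatched_tgt[jj[0]], unmatched_tgt[jj[1]]
            pair = tgt_mass[ja] + tgt_mass[jb]
            if abs(pair - src_mass[i]) / max(src_mass[i], 1e-12) <= tol:
                split_candidates.append((int(i), int(ja), int(jb)))
    return merge_suspects, split_candidates


def detect_merge_split(obs_t: pd.DataFrame, obs_t1: pd.DataFrame,
                       link: np.ndarray, params: TrackParams | None = None):
    """Mass-based merge and split candidates for one frame transition.

    Returns ``(merge_suspect_labels, split_candidates)``.  Merge suspects
    are object labels at t+1 whose mass matches the summed mass of two
    source cells that both point at them (or that are far heavier than
    their only orphan source); they go to adaptive re-segmentation.
    Split candidates are ``(source_row, target_row_a, target_row_b)``
    tuples of a source whose mass splits across its two nearest unmatched
    future neighbours; they go to the anaphase caller.
    """
    params = params or TrackParams()
    rows, splits = _detect_arrays(
        _coords(obs_t), obs_t["total_h2b"].to_numpy(dtype=float),
        _coords(obs_t1), obs_t1["total_h2b"].to_numpy(dtype=float),
        np.asarray(link), params,
    )
    labels = obs_t1["label"].to_numpy()
    return {int(labels[j]) for j in rows}, splits


# ---------------------------------------------------------------------------
# trace assembly
# ---------------------------------------------------------------------------


@dataclass
class CellTrace:
    """Observations of one tracked cell between birth and disappearance.

    ``anaphase_frames`` holds the frame of the division this cell was
    born at (daughters) and, for mothers, no entry (the division ends the
    mother's track).  ``fate`` and ``endpoint_if`` are filled by the
    classification and registration stages.
    """

    cell_id: int
    observations: pd.DataFrame = field(default_factory=pd.DataFrame)
    anaphase_frames: list[int] = field(default_factory=list)
    mother_id: int = -1
    daughter_ids: list[int] = field(default_factory=list)
    fate: str = ""
    endpoint_if: dict = field(default_factory=dict)

    @property
    def frames(self) -> np.ndarray:
        return self.observations["frame"].to_numpy()

    def validate(self) -> None:
        f = self.frames
        if len(f) and (np.diff(f) <= 0).any():
            raise ValueError("observations must be strictly increasing in frame")
        if self.anaphase_frames != sorted(self.anaphase_frames):
            raise ValueError("anaphase_frames must be increasing")


class Tracker:
    """Incremental tracker over per-frame observation tables.

    Feed frames in order with :meth:`advance`.  If a
    ``resegment_callback(frame, suspect_labels) -> DataFrame | None`` is
    provided, putative merged objects detected during linking trigger
    adaptive re-segmentation and the frame is re-linked on the recovered
    observations before anything is committed.
    """

    def __init__(self, params: TrackParams | None = None,
                 resegment_callback=None):
        self.params = params or TrackParams()
        self.resegment_callback = resegment_callback
        self._frames: dict[int, pd.DataFrame] = {}
        self._assign: dict[int, np.ndarray] = {}  # frame -> row's track id
        self._meta: dict[int, dict] = {}  # tid -> mother_id, anaphase, daughters
        self._next_id = 0
        # active track state (parallel lists)
        self._ids: list[int] = []
        self._xy: list[np.ndarray] = []
        self._mass: list[float] = []
        self._missed: list[int] = []

    def _new_track(self, mother_id: int = -1) -> int:
        tid = self._next_id
        self._next_id += 1
        self._meta[tid] = dict(mother_id=mother_id, anaphase_frames=[],
                               daughter_ids=[])
        return tid

    def advance(self, frame: int, obs: pd.DataFrame) -> None:
        obs = obs.reset_index(drop=True)
        tgt_xy = _coords(obs) if len(obs) else np.empty((0, 2))
        tgt_mass = obs["total_h2b"].to_numpy(dtype=float) if len(obs) else np.empty(0)

        if self._ids:
            src_xy = np.array(self._xy)
            src_mass = np.array(self._mass)
            link = _link_arrays(src_xy, src_mass, tgt_xy, tgt_mass, self.params)
            suspects, splits = _detect_arrays(
                src_xy, src_mass, tgt_xy, tgt_mass, link, self.params
            )
            if suspects and self.resegment_callback is not None:
                labels = sorted(int(obs["label"].iloc[j]) for j in suspects)
                new_obs = self.resegment_callback(frame, labels)
                if new_obs is not None:
                    obs = new_obs.reset_index(drop=True)
                    tgt_xy = _coords(obs)
                    tgt_mass = obs["total_h2b"].to_numpy(dtype=float)
                    link = _link_arrays(src_xy, src_mass, tgt_xy, tgt_mass,
                                        self.params)
                    _, splits = _detect_arrays(
                        src_xy, src_mass, tgt_xy, tgt_mass, link, self.params
                    )
        else:
            link = np.empty(0, dtype=int)
            splits = []

        assign = np.full(len(obs), -1, dtype=int)
        new_ids: list[int] = []
        new_xy: list[np.ndarray] = []
        new_mass: list[float] = []
        new_missed: list[int] = []

        claimed = set(int(j) for j in link[link >= 0])
        anaphases: dict[int, tuple[int, int]] = {}
        for (si, ja, jb) in splits:
            if ja in claimed or jb in claimed or si in anaphases:
                continue
            if call_anaphase(self._mass[si], (tgt_mass[ja], tgt_mass[jb]),
                             self.params):
                anaphases[si] = (ja, jb)
                claimed.update((ja, jb))

        for k, tid in enumerate(self._ids):
            j = int(link[k]) if k < len(link) else -1
            if j >= 0:
                assign[j] = tid
                new_ids.append(tid)
                new_xy.append(tgt_xy[j])
                new_mass.append(float(tgt_mass[j]))
                new_missed.append(0)
            elif k in anaphases:
                ja, jb = anaphases[k]
                for jd in (ja, jb):
                    did = self._new_track(mother_id=tid)
                    self._meta[did]["anaphase_frames"].append(frame)
                    self._meta[tid]["daughter_ids"].append(did)
                    assign[jd] = did
                    new_ids.append(did)
                    new_xy.append(tgt_xy[jd])
                    new_mass.append(float(tgt_mass[jd]))
                    new_missed.append(0)
            elif self._missed[k] < self.params.max_gap:
                new_ids.append(tid)
                new_xy.append(self._xy[k])
                new_mass.append(self._mass[k])
                new_missed.append(self._missed[k] + 1)
            # else: track closed
        for j in range(len(obs)):
            if assign[j] < 0 and j not in claimed:
                tid = self._new_track()
                assign[j] = tid
                new_ids.append(tid)
                new_xy.append(tgt_xy[j])
                new_mass.append(float(tgt_mass[j]))
                new_missed.append(0)

        self._frames[frame] = obs
        self._assign[frame] = assign
        self._ids, self._xy, self._mass, self._missed = (
            new_ids, new_xy, new_mass, new_missed
        )

    def finalize(self) -> dict[int, CellTrace]:
        """Assemble CellTrace objects for every track."""
        chunks = []
        for frame in sorted(self._frames):
            obs = self._frames[frame].copy()
            obs["cell_id"] = self._assign[frame]
            chunks.append(obs[obs["cell_id"] >= 0])
        traces: dict[int, CellTrace] = {}
        for tid, meta in self._meta.items():
            traces[tid] = CellTrace(
                tid, mother_id=meta["mother_id"],
                anaphase_frames=list(meta["anaphase_frames"]),
                daughter_ids=list(meta["daughter_ids"]),
            )
        if chunks:
            long = pd.concat(chunks, ignore_index=True)
            for tid, grp in long.groupby("cell_id", sort=True):
                traces[int(tid)].observations = (
                    grp.sort_values("frame").reset_index(drop=True)
                )
        for tr in traces.values():
            tr.validate()
        return traces


def track_movie(observations_by_frame, params: TrackParams | None = None,
                resegment_callback=None) -> dict[int, CellTrace]:
    """Track a whole movie from (frame_index, observation table) pairs."""
    tracker = Tracker(params, resegment_callback)
    for frame, obs in observations_by_frame:
        tracker.advance(frame, obs)
    return tracker.finalize()


def lineage_roots(traces: dict[int, CellTrace]) -> dict[int, list[int]]:
    """Map each root track (present at frame 0, no mother) to all track
    ids in its lineage."""
    out: dict[int, list[int]] = {}
    for tid, tr in traces.items():
        if tr.mother_id >= 0:
            continue
        if len(tr.observations) == 0 or tr.observations["frame"].iloc[0] != 0:
            continue
        members = [tid]
        stack = list(tr.daughter_ids)
        while stack:
            d = stack.pop()
            members.append(d)
            stack.extend(traces[d].daughter_ids)
        out[tid] = members
    return out
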