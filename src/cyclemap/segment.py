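"""Nuclear segmentation: LoG blob detection plus deflection bridging.

Nuclei are detected on the log-transformed nuclear channel (H2B or
Hoechst) with a rotationally symmetric Laplacian-of-Gaussian filter;
objects are contiguous pixels exceeding a threshold filter score.  The
detected objects seed a mask refined to the nuclear intensity support so
that integrated H2B masses are accurate (see docs/methods.md).

Touching nuclei appear as a single object with concave inflections at the
contact neck.  The deflection-bridging algorithm finds perimeter
concavities whose turning angle exceeds a threshold, connects the best
admissible pair with a straight cut ("bridge"), and recurses until no
admissible pair remains.  Bridging is run on every object in the first
frame and afterwards only adaptively, on objects the tracker flags as
putative merges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, measure
from skimage.filters import threshold_otsu

CONNECTIVITY = 2  # 8-connected labeling throughout


@dataclass
class SegmentParams:
    """Tunables of the nuclear segmentation.

    ``log_sigma`` defaults to expected_radius_px / sqrt(2) (standard
    blob-scale matching); ``response_threshold="auto"`` uses Otsu on the
    LoG response.  Area bounds default to [0.25, 4] x the expected
    nucleus area.  ``concavity_angle_threshold`` is the perimeter turning
    angle (degrees, measured on a smoothed contour) above which an
    inflection counts as concave; ``max_bridge_length`` bounds the cut.
    """

    expected_radius_px: float = 5.0
    log_sigma: float | None = None
    response_threshold: float | str = "auto"
    log_offset: float = 1.0  # added before the log-transform
    min_area: float | None = None
    max_area: float | None = None
    concavity_angle_threshold: float = 25.0  # degrees
    max_bridge_length: float | None = None  # px
    contour_smoothing: int = 5  # vertices
    turn_span: int = 3  # vertices each side for the turning angle
    min_region_area: int = 15  # px; smallest fragment a bridge may produce
    intensity_refine: bool = True

    def __post_init__(self) -> None:
        if self.log_sigma is None:
            self.log_sigma = self.expected_radius_px / math.sqrt(2.0)
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be positive")
        area = math.pi * self.expected_radius_px ** 2
        if self.min_area is None:
            self.min_area = 0.25 * area
        if self.max_area is None:
            self.max_area = 4.0 * area
        if not self.min_area < self.max_area:
            raise ValueError("min_area must be < max_area")
        if self.max_bridge_length is None:
            self.max_bridge_length = 2.5 * self.expected_radius_px


def log_response(image: np.ndarray, params: SegmentParams,
                 logimg: np.ndarray | None = None) -> np.ndarray:
    """Scale-normalized (positive = blob) LoG response of the log image."""
    if logimg is None:
        logimg = np.log(np.asarray(image, dtype=np.float32) + params.log_offset)
    return -params.log_sigma ** 2 * ndimage.gaussian_laplace(
        logimg, params.log_sigma)


def segment_nuclei(image: np.ndarray, params: SegmentParams | None = None
                   ) -> np.ndarray:
    """Detect nuclei in one nuclear-channel frame; returns a label image.

    Labels are contiguous positive integers (8-connected regions,
    0 = background); objects with area outside [min_area, max_area] are
    removed.  A constant image yields an empty mask.
    """
    params = params or SegmentParams()
    logimg = np.log(np.asarray(image, dtype=np.float32) + params.log_offset)
    resp = log_response(image, params, logimg)
    if params.response_threshold == "auto":
        if np.ptp(resp) < 1e-12:
            return np.zeros(image.shape, dtype=np.int32)
        thr = threshold_otsu(resp)
        thr = max(thr, 1e-6)
    else:
        thr = float(params.response_threshold)
    seeds = resp > thr
    if not seeds.any():
        return np.zeros(image.shape, dtype=np.int32)

    if params.intensity_refine:
        support = logimg > threshold_otsu(logimg)
        support = ndimage.binary_fill_holes(support)
        # objects = support components that contain at least one seed pixel
        lab, n = ndimage.label(support, structure=np.ones((3, 3)))
        has_seed = np.zeros(n + 1, dtype=bool)
        has_seed[np.unique(lab[seeds])] = True
        has_seed[0] = False
        mask = has_seed[lab]
    else:
        mask = ndimage.binary_fill_holes(seeds)
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return lab.astype(np.int32)
    areas = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    good = (areas >= params.min_area) & (areas <= params.max_area)
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1:][good] = np.arange(1, good.sum() + 1)
    return remap[lab]


def mask_properties(label_mask: np.ndarray) -> pd.DataFrame:
    """Per-object area and centroid (label, area, centroid_row, centroid_col)."""
    if label_mask.max() == 0:
        return pd.DataFrame(columns=["label", "area", "centroid_row", "centroid_col"])
    props = measure.regionprops_table(
        label_mask, properties=("label", "area", "centroid")
    )
    return pd.DataFrame({
        "label": props["label"],
        "area": props["area"],
        "centroid_row": props["centroid-0"],
        "centroid_col": props["centroid-1"],
    })


# ---------------------------------------------------------------------------
# deflection bridging
# ---------------------------------------------------------------------------


def _smooth_closed(contour: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return contour
    n = contour.shape[0]
    if n <= window:
        return contour
    k = window
    pad = k // 2
    ext = np.vstack([contour[-pad:], contour, contour[:pad]])
    kernel = np.ones(k) / k
    sm = np.column_stack([
        np.convolve(ext[:, 0], kernel, mode="valid"),
        np.convolve(ext[:, 1], kernel, mode="valid"),
    ])
    return sm


def _turning_angles(contour: np.ndarray, span: int) -> np.ndarray:
    """Signed turning angle (deg) at each vertex of a closed contour.

    The sign convention is normalized so that convex turning is positive
    regardless of traversal orientation; concave inflections come out
    negative.
    """
    n = contour.shape[0]
    prev = np.roll(contour, span, axis=0)
    nxt = np.roll(contour, -span, axis=0)
    v1 = contour - prev
    v2 = nxt - contour
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    ang = np.degrees(np.arctan2(cross, dot))
    # orientation: signed area of the polygon
    area2 = np.sum(contour[:, 0] * np.roll(contour[:, 1], -1)
                   - np.roll(contour[:, 0], -1) * contour[:, 1])
    if area2 < 0:
        ang = -ang
    return ang


def _concavity_points(mask: np.ndarray, params: SegmentParams):
    """Deepest vertex of each concave perimeter region: (points, depths)."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.empty((0, 2)), np.empty(0)
    contour = max(contours, key=len) - 1.0  # undo padding
    if contour.shape[0] < 2 * params.turn_span + 2:
        return np.empty((0, 2)), np.empty(0)
    sm = _smooth_closed(contour, params.contour_smoothing)
    ang = _turning_angles(sm, params.turn_span)
    concave = ang < -params.concavity_angle_threshold
    if not concave.any():
        return np.empty((0, 2)), np.empty(0)
    # group consecutive concave vertices (circular) into regions
    idx = np.flatnonzero(concave)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    groups = np.split(idx, breaks + 1)
    if len(groups) > 1 and idx[0] == 0 and idx[-1] == len(ang) - 1:
        groups[0] = np.concatenate([groups[-1], groups[0]])
        groups.pop()
    pts, depths = [], []
    for g in groups:
        deepest = g[np.argmin(ang[g])]
        pts.append(contour[deepest])
        depths.append(-float(ang[deepest]))
    return np.array(pts), np.array(depths)


def _bridge_line(p: np.ndarray, q: np.ndarray):
    """4-connected pixel line from p to q (separates 8-connected regions)."""
    rr, cc = draw.line(int(round(p[0])), int(round(p[1])),
                       int(round(q[0])), int(round(q[1])))
    out_r, out_c = [rr[0]], [cc[0]]
    for i in range(1, len(rr)):
        if rr[i] != out_r[-1] and cc[i] != out_c[-1]:
            out_r.append(rr[i])
            out_c.append(out_c[-1])
        out_r.append(rr[i])
        out_c.append(cc[i])
    return np.array(out_r), np.array(out_c)


def bridge_deflections(object_mask: np.ndarray, params: SegmentParams | None = None,
                       restore_cut: bool = True) -> np.ndarray:
    """Split one connected object along concavity bridges.

    Returns a label image of the same shape whose positive regions
    partition the input object.  Convex objects are returned unchanged as
    a single region.  The best pair of concavities is bridged (shortest
    admissible bridge; ties broken by deeper total concavity) and the
    procedure recurses on the parts.

    With ``restore_cut`` (default) the pixels removed by the bridge cuts
    are reassigned to the nearest resulting region, so the output regions
    partition the input object exactly and integrated intensities are
    conserved; with ``restore_cut=False`` the cut pixels stay background.
    Bridging never creates pixels outside the input object.
    """
    params = params or SegmentParams()
    mask = object_mask.astype(bool)
    out = np.zeros(mask.shape, dtype=np.int32)
    parts = _bridge_recursive(mask, params)
    for i, part in enumerate(parts, start=1):
        out[part] = i
    if restore_cut and len(parts) > 1:
        from skimage.segmentation import expand_labels

        lost = mask & (out == 0)
        while lost.any():
            grown = expand_labels(out, distance=2)
            out[lost] = grown[lost]
            lost = mask & (out == 0)
        out[~mask] = 0
    return out


def _bridge_recursive(mask: np.ndarray, params: SegmentParams) -> list[np.ndarray]:
    # lobes connected only diagonally (a 1-pixel 8-connected pinch) are
    # separate 4-connected components; split them outright -- the
    # marching-squares perimeter sees them as separate contours, so the
    # concavity machinery cannot pair their necks
    lab4, n4 = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 1))
    if n4 >= 2:
        areas4 = ndimage.sum_labels(np.ones_like(lab4), lab4,
                                    index=np.arange(1, n4 + 1))
        big = [k + 1 for k in range(n4) if areas4[k] >= params.min_region_area]
        if len(big) >= 2:
            parts = []
            for k in big:
                parts.extend(_bridge_recursive(lab4 == k, params))
            # fragments below min_region_area are left for the cut-restore
            # step to attach to the nearest region
            return parts
    pts, depths = _concavity_points(mask, params)
    if len(pts) < 2:
        return [mask]
    # admissible pairs sorted by (length, -total depth)
    cand = []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = float(np.hypot(*(pts[i] - pts[j])))
            if d <= params.max_bridge_length:
                cand.append((d, -(depths[i] + depths[j]), i, j))
    cand.sort()
    for d, _, i, j in cand:
        rr, cc = _bridge_line(pts[i], pts[j])
        inb = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
        rr, cc = rr[inb], cc[inb]
        interior = mask[rr, cc]
        # bridge interior (excluding endpoints near the boundary) must lie
        # inside the object
        if len(rr) > 2 and not interior[1:-1].all():
            continue
        cut = mask.copy()
        cut[rr, cc] = False
        lab, n = ndimage.label(cut, structure=np.ones((3, 3)))
        if n < 2:
            continue
        areas = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=np.arange(1, n + 1))
        if np.sort(areas)[-2] < params.min_region_area:
            continue  # degenerate sliver cut; try the next pair
        parts = []
        for k in range(1, n + 1):
            part = lab == k
            if areas[k - 1] >= params.min_region_area:
                parts.extend(_bridge_recursive(part, params))
            else:
                parts.append(part)
        return parts
    return [mask]


def adaptive_resegment(label_mask: np.ndarray, suspect_labels,
                       params: SegmentParams | None = None) -> np.ndarray:
    """Re-run deflection bridging only on the given labels.

    Non-suspect labels are carried over bit-identically; regions split off
    a suspect get fresh labels above the current maximum.
    """
    params = params or SegmentParams()
    suspects = list(suspect_labels)
    present = set(np.unique(label_mask)) - {0}
    unknown = [s for s in suspects if s not in present]
    if unknown:
        raise KeyError(f"labels not in mask: {unknown}")
    out = label_mask.copy()
    next_label = int(label_mask.max()) + 1
    slices = ndimage.find_objects(label_mask)
    for s in suspects:
        sl = slices[s - 1]
        obj_sl = label_mask[sl] == s
        sub = bridge_deflections(obj_sl, params)
        nparts = sub.max()
        if nparts <= 1:
            continue
        region = out[sl]
        region[obj_sl] = 0
        for k in range(1, nparts + 1):
            lbl = s if k == 1 else next_label
            if k > 1:
                next_label += 1
            region[sub == k] = lbl
    return out
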