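"""Jitter correction between the last live frame and the fixed-cell IF images.

After fixation and staining the stage position shifts by a small rigid
translation.  The shift is recovered by exhaustively scoring integer
translations of the IF nuclear image against the last live nuclear frame:
the difference score is the mean absolute difference over the overlapping
region, and the position with the lowest score is the jitter.  The IF
images are then translated back and each cell's endpoint IF intensity is
measured on its final-frame nuclear mask, matching every cell's history
to its IF signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .quantify import (BackgroundError, QuantParams, _histogram_mode,
                       cytoplasmic_ring_mean, local_background_subtract)


class DegenerateImageError(ValueError):
    """Flat image: the difference score cannot identify a shift."""


@dataclass
class Shift:
    dy: int
    dx: int
    score: float

    def as_tuple(self) -> tuple[int, int]:
        return (self.dy, self.dx)


def _difference_score(ref: np.ndarray, moving: np.ndarray, dy: int, dx: int
                      ) -> float:
    H, W = ref.shape
    ys0, ys1 = max(0, dy), min(H, H + dy)
    xs0, xs1 = max(0, dx), min(W, W + dx)
    if ys0 >= ys1 or xs0 >= xs1:
        return np.inf
    a = moving[ys0:ys1, xs0:xs1]
    b = ref[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx]
    # mean (not sum) so large shifts are not penalized by smaller overlap
    return float(np.mean(np.abs(a - b)))


def estimate_jitter(ref_image: np.ndarray, moving_image: np.ndarray,
                    search_radius: int = 20) -> Shift:
    """Exhaustive integer search for the rigid shift of ``moving_image``.

    Scores every (dy, dx) in [-r, r]^2 by the mean absolute difference
    over the overlap and returns the argmin.  The returned shift is the
    translation that was applied to ``moving_image``; translate by its
    negative to align it back onto ``ref_image``.
    """
    ref = np.asarray(ref_image, dtype=float)
    mov = np.asarray(moving_image, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("images must have the same shape")
    if np.ptp(ref) < 1e-12 or np.ptp(mov) < 1e-12:
        raise DegenerateImageError("flat image; cannot estimate jitter")
    best = None
    r = int(search_radius)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            s = _difference_score(ref, mov, dy, dx)
            if best is None or s < best.score:
                best = Shift(dy, dx, s)
    return best


def translate(image: np.ndarray, dy: int, dx: int, fill: float = 0.0
              ) -> np.ndarray:
    """Rigid integer translation, filling uncovered pixels with ``fill``."""
    out = np.full_like(np.asarray(image, dtype=float), fill)
    H, W = image.shape
    ys0, ys1 = max(0, dy), min(H, H + dy)
    xs0, xs1 = max(0, dx), min(W, W + dx)
    if ys0 < ys1 and xs0 < xs1:
        out[ys0:ys1, xs0:xs1] = image[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx]
    return out


def match_if_to_traces(final_mask: np.ndarray, if_images: dict,
                       shift: Shift | tuple[int, int],
                       quant_params: QuantParams | None = None,
                       cytoplasmic: set | None = None) -> pd.DataFrame:
    """Measure per-cell endpoint IF values on the final-frame mask.

    ``if_images`` maps channel name -> image (as acquired, i.e. still
    carrying the stage jitter); each is translated by the negative shift
    before measurement.  Nuclear markers get the local-median-subtracted
    nuclear mean; channels listed in ``cytoplasmic`` get the perinuclear
    ring statistic instead (e.g. cytoplasmic Cyclin B1).  Cells whose
    mask leaves the field after the shift are flagged missing (NaN), not
    zero.
    """
    params = quant_params or QuantParams()
    cytoplasmic = cytoplasmic or set()
    dy, dx = shift.as_tuple() if isinstance(shift, Shift) else tuple(shift)
    lab = np.asarray(final_mask)
    labels = np.unique(lab)
    labels = labels[labels > 0]
    H, W = lab.shape
    # pixels of the reference frame not covered by the shifted IF image
    uncovered = np.ones((H, W), dtype=bool)
    ys0, ys1 = max(0, -dy), min(H, H - dy)
    xs0, xs1 = max(0, -dx), min(W, W - dx)
    if ys0 < ys1 and xs0 < xs1:
        uncovered[ys0:ys1, xs0:xs1] = False

    out = pd.DataFrame({"label": labels})
    for name, img in if_images.items():
        aligned = translate(np.asarray(img, dtype=float), -dy, -dx, np.nan)
        covered = np.isfinite(aligned)
        dist = ndimage.distance_transform_edt(lab == 0)
        far = covered & (dist > params.global_bg_dilate_px)
        if not far.any():
            raise BackgroundError("dilated nuclear mask covers the entire image")
        gbg = _histogram_mode(aligned[far])
        aligned = np.where(covered, aligned, gbg)
        vals = np.full(len(labels), np.nan)
        for i, cell in enumerate(labels):
            obj = lab == cell
            if uncovered[obj].any():
                continue  # left the field; flagged missing
            if name in cytoplasmic:
                vals[i] = cytoplasmic_ring_mean(aligned, lab, int(cell),
                                                params, gbg)
            else:
                vals[i] = local_background_subtract(aligned, lab, int(cell),
                                                    params, gbg)
        out[name] = vals
    return out
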