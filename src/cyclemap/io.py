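"""File formats: multi-page TIFF for images, CSV for tables, JSON for
lineage/gates/shifts.  Every table and JSON artifact carries provenance
(config hash, seed, package version) so runs are reproducible and
attributable."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_movie_tiff(path, stack: np.ndarray) -> None:
    """Write a (frames, channels, rows, cols) stack as frame-major TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     metadata={"axes": "TCYX"})


def read_movie_tiff(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    return arr


def write_mask_tiff(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def write_table(path, df: pd.DataFrame, provenance: dict | None = None) -> None:
    """CSV with a one-line provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write("# " + json.dumps(provenance, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(path, obj, provenance: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if provenance:
        payload["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))
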