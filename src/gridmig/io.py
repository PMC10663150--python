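"""Raster and table I/O.

Annual raster stacks are written as multiband TIFF (one band per year)
with a JSON sidecar carrying the band years, the geotransform and the
nodata value; tables are plain CSV.  The sidecar convention keeps every
artifact a text-or-TIFF pair that round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_raster(
    path: str | Path,
    data: np.ndarray,
    years: list[int] | None = None,
    *,
    transform: tuple[float, ...] = (0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
    nodata: float | None = None,
) -> None:
    """Write a (bands, rows, cols) or (rows, cols) array as multiband TIFF."""
    path = Path(path)
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None]
    tifffile.imwrite(
        path,
        arr.astype(np.float32 if arr.dtype.kind == "f" else np.int32),
        photometric="minisblack",
    )
    meta = {
        "years": list(map(int, years)) if years is not None else None,
        "transform": list(transform),
        "nodata": nodata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multiband TIFF and its JSON sidecar (if present)."""
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return np.asarray(arr), meta


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
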