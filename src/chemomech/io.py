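"""File I/O: track CSV, multi-page TIFF with sidecar metadata, truth JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_tracks_csv(tracks: pd.DataFrame, path: str | Path) -> None:
    tracks.to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_stack(stack: np.ndarray, path: str | Path,
                pixel_size: float | None = None, **metadata) -> None:
    """Write an image stack as multi-page TIFF plus a JSON sidecar.

    The sidecar (``<path>.json``) records the pixel size in µm/pixel and
    any extra metadata; numpy values are converted to plain JSON types.
    """
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    meta = {"pixel_size_um": pixel_size, **metadata}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(_jsonable(meta), indent=2))


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return np.asarray(stack), meta


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(truth), indent=2))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
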