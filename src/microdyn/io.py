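"""File I/O: TIFF stacks, cohort manifests, soma records, ground truth."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segment import SomaRecord, TimeLapse

MANIFEST_COLUMNS = (
    "animal_id", "group", "session", "path_population", "path_timelapse",
    "pixel_size_um_population", "pixel_size_um_timelapse",
)


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-page TIFF as a 2D array."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-page 2D image, got shape {arr.shape}")
    return arr


def read_timelapse(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_min: float = 5.0,
) -> TimeLapse:
    """Read a multi-page TIFF (frame order = time) as a :class:`TimeLapse`.

    The ``binary`` flag is inferred from the pixel values.
    """
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a (t, h, w) stack, got shape {arr.shape}")
    binary = bool(np.isin(np.unique(arr), (0, 1)).all())
    return TimeLapse(
        frames=arr,
        pixel_size_um=pixel_size_um,
        timestamps_min=np.arange(arr.shape[0]) * frame_interval_min,
        binary=binary,
    )


def write_timelapse(path: str | Path, stack: TimeLapse) -> None:
    tifffile.imwrite(path, np.asarray(stack.frames))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV; image paths are resolved relative to it."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    base = path.parent
    for col in ("path_population", "path_timelapse"):
        df[col] = [str(base / p) for p in df[col]]
    return df


def write_soma_records(path: str | Path, records: list[SomaRecord]) -> None:
    """Write soma records as CSV (animal, session, label, x_um, y_um)."""
    pd.concat([r.to_frame() for r in records], ignore_index=True).to_csv(path, index=False)


def read_soma_records(path: str | Path) -> list[SomaRecord]:
    df = pd.read_csv(path)
    return [
        SomaRecord.from_frame(g)
        for _, g in df.groupby(["animal", "session"], sort=False)
    ]


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
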