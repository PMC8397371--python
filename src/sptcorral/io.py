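"""Reading and writing the pipeline's file interfaces.

Movies and masks travel as TIFF, localization/trajectory/intensity tables
as CSV, configuration as YAML or JSON, reports as JSON.  Every writer
records enough metadata (seed, frame interval, pixel size) for a run to be
reproduced from its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import FrameStack
from .tracking import frame_to_tracks, tracks_to_frame


def read_movie(path, dt: float | None = None, pixel_size: float | None = None
               ) -> FrameStack:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = {}
    with tifffile.TiffFile(path) as tf:
        desc = tf.pages[0].description or ""
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    dt = dt if dt is not None else meta.get("frame_interval_s")
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if dt is None or px is None:
        raise ValueError(
            "frame interval and pixel size must come from the config or "
            "the TIFF metadata"
        )
    return FrameStack(data=np.clip(data.astype(float), 0, None),
                      dt=float(dt), pixel_size=float(px))


def write_movie(path, stack: FrameStack, seed: int | None = None) -> None:
    meta = {"frame_interval_s": stack.dt, "pixel_size_um": stack.pixel_size}
    if seed is not None:
        meta["rng_seed"] = seed
    tifffile.imwrite(path, stack.data.astype(np.float32),
                     description=json.dumps(meta))


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image).astype(np.float32))


def write_label_mask(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16))


def read_image(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_localizations(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tracks(path, tracks) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks(path, n_frames: int | None = None):
    return frame_to_tracks(pd.read_csv(path), n_frames=n_frames)


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=float) + "\n")
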