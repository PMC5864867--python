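"""File formats: FIJI Manual-Tracking CSV, observation CSV, TIFF, YAML config.

Track tables use the FIJI Manual Tracking plugin layout — columns
``Track n°, Slice n°, X, Y`` with 1-based slice numbers on disk.  Slices are
converted to 0-based frame indices in memory; the conversion round-trips
bit-exactly.  Missing slots inside a track are simply absent rows and are
restored as ``None`` slots on read.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import Point, Track

__all__ = [
    "read_tracks_csv",
    "write_tracks_csv",
    "read_observations_csv",
    "write_observations_csv",
    "read_image_sequence",
    "write_image_sequence",
    "load_config",
]

_TRACK_COLS = ["Track n°", "Slice n°", "X", "Y"]
# Degree-sign-free aliases accepted on read (some exports mangle the °).
_ALIASES = {
    "track n°": "Track n°", "track no": "Track n°", "track": "Track n°",
    "slice n°": "Slice n°", "slice no": "Slice n°", "slice": "Slice n°",
    "x": "X", "y": "Y",
}


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    ren = {}
    for c in df.columns:
        key = str(c).strip().lower()
        if key in _ALIASES:
            ren[c] = _ALIASES[key]
    df = df.rename(columns=ren)
    missing = [c for c in _TRACK_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    return df


def read_tracks_csv(path) -> list:
    """Read a FIJI-style track table into a list of :class:`Track`.

    Rows of one track need not be contiguous in slices; absent slices inside
    a track's lifespan become missing slots.
    """
    df = _canonical(pd.read_csv(path))
    tracks = []
    for tid, g in df.groupby("Track n°", sort=True):
        frames = g["Slice n°"].to_numpy(dtype=int) - 1  # 1-based on disk
        order = np.argsort(frames)
        frames = frames[order]
        xs = g["X"].to_numpy(dtype=float)[order]
        ys = g["Y"].to_numpy(dtype=float)[order]
        birth = int(frames[0])
        slots = [None] * (int(frames[-1]) - birth + 1)
        for f, x, y in zip(frames, xs, ys):
            slots[int(f) - birth] = Point(x, y)
        tracks.append(Track(id=int(tid), birth_frame=birth, points=slots))
    return tracks


def write_tracks_csv(tracks: Iterable[Track], path) -> None:
    """Write tracks in FIJI Manual-Tracking layout (1-based slices)."""
    rows = []
    for tr in tracks:
        for frame, pt in zip(tr.frames(), tr.points):
            if pt is None:
                continue
            rows.append((tr.id, frame + 1, pt.x, pt.y))
    df = pd.DataFrame(rows, columns=_TRACK_COLS)
    df.to_csv(path, index=False)


def read_observations_csv(path) -> dict:
    """Read per-frame observations from a ``frame, x, y`` CSV.

    Returns a dict mapping 0-based frame index to a list of Points.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(int(row["frame"]), []).append(Point(float(row["x"]), float(row["y"])))
    return out


def write_observations_csv(frames, path) -> None:
    """Write observations as a ``frame, x, y`` CSV.

    ``frames`` is an iterable of FrameObservations (anything with ``.frame``
    and ``.centroids``).
    """
    rows = [(fo.frame, p.x, p.y) for fo in frames for p in fo.centroids]
    pd.DataFrame(rows, columns=["frame", "x", "y"]).to_csv(path, index=False)


def read_image_sequence(path) -> np.ndarray:
    """Read a multi-page TIFF stack or a directory of numbered frames.

    Returns a (T, H, W) uint8 array.
    """
    if os.path.isdir(path):
        names = sorted(
            f for f in os.listdir(path)
            if f.lower().endswith((".tif", ".tiff", ".png"))
        )
        if not names:
            raise ValueError(f"no image frames found in {path}")
        frames = []
        for name in names:
            fp = os.path.join(path, name)
            if name.lower().endswith(".png"):
                from imageio.v3 import imread
                frames.append(np.asarray(imread(fp)))
            else:
                frames.append(tifffile.imread(fp))
        stack = np.stack(frames)
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("expected single-channel grayscale frames")
    return stack.astype(np.uint8, copy=False)


def write_image_sequence(stack: np.ndarray, path) -> None:
    """Write a (T, H, W) uint8 stack as a multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint8), photometric="minisblack")


def load_config(path) -> dict:
    """Load a flat YAML parameter file (empty file → empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
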