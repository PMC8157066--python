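"""File I/O for frame stacks, reference traces, maps and reports.

Video input is accepted as (a) an ``.npz`` frame stack with ``frames``
``(T, H, W, 3)`` and ``fps`` arrays, (b) a directory of numbered PNG
frames with a ``meta.json`` carrying ``fps``, or (c) any container
``imageio`` can decode (AVI/MP4 ...) when the relevant plugin is
available. Channel order is R, G, B everywhere; intensities are on the
8-bit scale. Reference traces are 2-column CSV ``time_s,value`` with a
header. Class/phase maps are PNGs coded 0/128/255 (antiphase /
background / in-phase).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import FrameSequence

__all__ = [
    "save_frames", "load_frames",
    "write_reference_csv", "read_reference_csv",
    "save_map_png", "load_map_png",
    "write_trace_csv", "write_bpm_csv",
]


def save_frames(seq: FrameSequence, path) -> Path:
    """Write a frame stack: ``.npz``, a PNG directory, or a video file."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, frames=seq.frames, fps=np.array(seq.fps))
    elif path.suffix == "":
        import imageio.v3 as iio
        path.mkdir(parents=True, exist_ok=True)
        frames = np.clip(np.rint(seq.frames), 0, 255).astype(np.uint8)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)
        (path / "meta.json").write_text(json.dumps({"fps": seq.fps, "n_frames": len(frames)}))
    else:
        import imageio.v2 as iio
        frames = np.clip(np.rint(seq.frames), 0, 255).astype(np.uint8)
        with iio.get_writer(path, fps=seq.fps) as w:
            for frame in frames:
                w.append_data(frame)
    return path


def load_frames(path) -> FrameSequence:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such video input: {path}")
    if path.is_dir():
        meta = json.loads((path / "meta.json").read_text())
        import imageio.v3 as iio
        files = sorted(path.glob("frame_*.png"))
        frames = np.stack([iio.imread(f) for f in files])
        return FrameSequence(frames=frames, fps=float(meta["fps"]))
    if path.suffix == ".npz":
        with np.load(path) as z:
            return FrameSequence(frames=z["frames"], fps=float(z["fps"]))
    import imageio.v2 as iio
    reader = iio.get_reader(path)
    meta = reader.get_meta_data()
    frames = np.stack([frame[..., :3] for frame in reader])
    reader.close()
    return FrameSequence(frames=frames, fps=float(meta.get("fps", 20.0)))


def write_reference_csv(path, times_s: np.ndarray, values: np.ndarray) -> None:
    pd.DataFrame({"time_s": times_s, "value": values}).to_csv(path, index=False)


def read_reference_csv(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such reference file: {path}")
    df = pd.read_csv(path)
    missing = {"time_s", "value"} - set(df.columns)
    if missing:
        raise ValueError(
            f"reference CSV {path} must have columns time_s,value (missing {sorted(missing)})"
        )
    return df["time_s"].to_numpy(float), df["value"].to_numpy(float)


def read_series_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read any 2-column time/value CSV (``value`` or ``respiration``)."""
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column time_s")
    for col in ("value", "respiration"):
        if col in df.columns:
            return df["time_s"].to_numpy(float), df[col].to_numpy(float)
    raise ValueError(f"{path}: expected a 'value' or 'respiration' column")


_MAP_CODES = {-1: 0, 0: 128, 1: 255}


def save_map_png(path, values: np.ndarray) -> None:
    """Write a class/phase map as PNG: -1 -> 0, 0 -> 128, +1 -> 255."""
    import imageio.v3 as iio
    img = np.zeros(values.shape, dtype=np.uint8)
    for v, code in _MAP_CODES.items():
        img[values == v] = code
    iio.imwrite(Path(path), img)


def load_map_png(path) -> np.ndarray:
    import imageio.v3 as iio
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        img = img[..., 0]
    out = np.zeros(img.shape, dtype=np.int8)
    for v, code in _MAP_CODES.items():
        out[img == code] = v
    return out


def write_trace_csv(path, times_s: np.ndarray, respiration: np.ndarray) -> None:
    pd.DataFrame({"time_s": times_s, "respiration": respiration}).to_csv(path, index=False)


def write_bpm_csv(path, starts_s, bpm_est, bpm_ref=None, status=None) -> None:
    cols = {"window_start_s": starts_s, "bpm_est": bpm_est}
    if bpm_ref is not None:
        cols["bpm_ref"] = bpm_ref
    if status is not None:
        cols["status"] = status
    pd.DataFrame(cols).to_csv(path, index=False)
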