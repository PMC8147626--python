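"""File formats: trajectory CSV, movie TIFF, topography TIFF/text, reports.

Trajectory tables are CSV with columns
``movie_id, traj_id, frame, x_um, y_um[, true_x_um, true_y_um]`` (the
ground-truth columns are optional and only written by the simulator).
Movies are 16-bit multi-page TIFF; topographies are 32-bit float TIFF (nm)
or a whitespace-delimited text matrix whose first line is
``# pixel_size_nm <value>``; label maps are 16-bit TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .afm import DomainLabelMap, Topography
from .diffusion import GroundTruthTrajectory
from .imaging import CameraModel, MovieStack

__all__ = [
    "trajectories_to_table",
    "table_to_trajectories",
    "write_trajectories",
    "read_trajectories",
    "write_movie",
    "read_movie",
    "write_topography",
    "read_topography",
    "write_label_map",
    "read_label_map",
    "write_json",
    "load_yaml",
]

TRAJECTORY_COLUMNS = ["movie_id", "traj_id", "frame", "x_um", "y_um"]
TRUTH_COLUMNS = ["true_x_um", "true_y_um"]


def trajectories_to_table(
    trajectories: Sequence[GroundTruthTrajectory], include_truth: bool = True
) -> pd.DataFrame:
    """Flatten simulated trajectories into the package-wide table schema.

    ``x_um, y_um`` are the observed (noise-corrupted) positions; the true
    positions go into the optional truth columns.
    """
    frames = []
    for t in trajectories:
        df = pd.DataFrame(
            {
                "movie_id": t.movie_id,
                "traj_id": t.traj_id,
                "frame": t.frames,
                "x_um": t.observed_xy[:, 0],
                "y_um": t.observed_xy[:, 1],
            }
        )
        if include_truth:
            df["true_x_um"] = t.true_xy[:, 0]
            df["true_y_um"] = t.true_xy[:, 1]
        frames.append(df)
    if not frames:
        cols = TRAJECTORY_COLUMNS + (TRUTH_COLUMNS if include_truth else [])
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def table_to_trajectories(
    table: pd.DataFrame, frame_interval: float
) -> list[GroundTruthTrajectory]:
    """Rebuild trajectory objects from a table (truth columns optional)."""
    has_truth = all(c in table.columns for c in TRUTH_COLUMNS)
    out = []
    for (movie_id, traj_id), g in table.groupby(["movie_id", "traj_id"], sort=True):
        g = g.sort_values("frame")
        obs = g[["x_um", "y_um"]].to_numpy(float)
        true = g[TRUTH_COLUMNS].to_numpy(float) if has_truth else obs.copy()
        out.append(
            GroundTruthTrajectory(
                traj_id=int(traj_id),
                movie_id=str(movie_id),
                frames=g["frame"].to_numpy(int),
                true_xy=true,
                observed_xy=obs,
                frame_interval=frame_interval,
            )
        )
    return out


def write_trajectories(path: str | Path, table: pd.DataFrame) -> None:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns {missing}")
    table.to_csv(path, index=False)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: trajectory CSV missing columns {missing}")
    return table


def write_movie(path: str | Path, movie: MovieStack) -> None:
    """Write a movie as 16-bit multi-page TIFF (intensities clipped/rounded)."""
    data = np.clip(np.round(movie.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={
            "frame_interval_s": movie.frame_interval,
            "pixel_size_nm": movie.camera.pixel_size,
        },
    )


def read_movie(
    path: str | Path,
    frame_interval: float | None = None,
    camera: CameraModel | None = None,
) -> MovieStack:
    """Read a multi-page TIFF movie; metadata fall back to arguments."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    if frame_interval is None:
        frame_interval = float(meta.get("frame_interval_s", 1.0))
    if camera is None:
        camera = CameraModel(
            pixel_size=float(meta.get("pixel_size_nm", 275.86)),
            image_shape=data.shape[1:],
        )
    return MovieStack(data, frame_interval, camera)


def write_topography(path: str | Path, topo: Topography) -> None:
    """Write heights as float32 TIFF (.tif) or text matrix (.txt) in nm."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            topo.heights.astype(np.float32),
            metadata={"pixel_size_nm": topo.pixel_size},
        )
    else:
        header = f"pixel_size_nm {topo.pixel_size}"
        np.savetxt(path, topo.heights, header=header)


def read_topography(path: str | Path, pixel_size: float | None = None) -> Topography:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            heights = tf.asarray().astype(float)
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if pixel_size is None:
            pixel_size = float(meta.get("pixel_size_nm", 0.0))
    else:
        with open(path) as fh:
            first = fh.readline()
        if pixel_size is None and "pixel_size_nm" in first:
            pixel_size = float(first.split("pixel_size_nm")[1].split()[0])
        heights = np.loadtxt(path)
    if not pixel_size:
        raise ValueError(f"{path}: pixel size neither stored nor supplied")
    return Topography(heights, pixel_size, metadata={"source": str(path)})


def write_label_map(path: str | Path, label_map: DomainLabelMap) -> None:
    if label_map.labels.max() > 65535:
        raise ValueError("too many labels for 16-bit storage")
    tifffile.imwrite(
        path,
        label_map.labels.astype(np.uint16),
        metadata={"pixel_size_nm": label_map.pixel_size},
    )


def read_label_map(path: str | Path, pixel_size: float | None = None) -> DomainLabelMap:
    with tifffile.TiffFile(path) as tf:
        labels = tf.asarray().astype(np.int32)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if pixel_size is None:
        pixel_size = float(meta.get("pixel_size_nm", 1.0))
    return DomainLabelMap(labels, pixel_size)


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return data
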