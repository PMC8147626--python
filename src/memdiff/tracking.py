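"""Spot detection, trajectory linking and length filtering.

A functional re-implementation of the detect–link–filter stage commonly
delegated to ImageJ particle-tracking plugins: band-pass filtering plus
local-maximum detection with iterative centroid refinement, deterministic
greedy nearest-neighbour frame-to-frame linking with optional gap memory,
and the trajectory-length filters used before MSD analysis (≥ 50 frames at
500 fps, ≥ 30 frames at 30 fps).

Localization tables and trajectory tables are pandas DataFrames with the
package-wide schema: movie_id, frame, x_um, y_um [, intensity, traj_id].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians

from .imaging import MovieStack

__all__ = [
    "LinkConfig",
    "detect_spots",
    "locate_movie",
    "link_trajectories",
    "filter_trajectories",
]


@dataclass
class LinkConfig:
    """Linking and filtering parameters.

    max_displacement is the largest allowed jump in µm per frame interval
    (scaled by the gap length when memory bridges missed frames);
    memory_frames is the number of consecutive missed frames a trajectory
    may survive. The two min_frames thresholds are the acquisition-rate
    dependent trajectory-length filters.
    """

    max_displacement: float
    memory_frames: int = 0
    min_frames_500fps: int = 50
    min_frames_30fps: int = 30

    def __post_init__(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be positive")
        if self.memory_frames < 0:
            raise ValueError("memory_frames must be >= 0")


# ---------------------------------------------------------------------------
# detection


def detect_spots(
    frame_image: np.ndarray,
    psf_sigma: float,
    intensity_percentile: float = 99.8,
    refine_iterations: int = 3,
) -> np.ndarray:
    """Detect fluorescent spots in one frame; return (n, 3) [x_px, y_px, mass].

    Candidates are local maxima of a band-passed image (difference of
    Gaussians: low sigma 1 px, high sigma 2·psf_sigma) lying above the given
    intensity percentile of the band-passed image. Each candidate is refined
    to sub-pixel precision by an intensity-weighted centroid in a window of
    half-width 2·psf_sigma, re-centred over a few iterations; weights are
    the band-passed intensities clipped at zero, which removes the uniform
    background without a separate estimate.

    A flat image yields an empty array.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame_image must be 2D")
    if np.any(img < 0):
        raise ValueError("frame_image must be non-negative")
    if img.max() == img.min():
        return np.empty((0, 3))

    sigma_px = max(float(psf_sigma), 0.5)
    bp = difference_of_gaussians(img, low_sigma=1.0, high_sigma=2.0 * sigma_px)
    thr = np.percentile(bp, intensity_percentile)
    if thr <= 0:
        thr = 1e-12
    peaks = peak_local_max(
        bp,
        min_distance=max(2, int(round(2 * sigma_px))),
        threshold_abs=thr,
        exclude_border=False,
    )
    if peaks.size == 0:
        return np.empty((0, 3))

    half = max(2, int(round(2 * sigma_px)))
    weights = np.clip(bp, 0.0, None)
    out = []
    for r, c in peaks:
        cy, cx = float(r) + 0.5, float(c) + 0.5  # pixel-centre convention
        mass = 0.0
        for _ in range(refine_iterations):
            r0 = max(0, int(round(cy - 0.5)) - half)
            r1 = min(img.shape[0], int(round(cy - 0.5)) + half + 1)
            c0 = max(0, int(round(cx - 0.5)) - half)
            c1 = min(img.shape[1], int(round(cx - 0.5)) + half + 1)
            win = weights[r0:r1, c0:c1]
            mass = float(win.sum())
            if mass <= 0:
                break
            rr, cc = np.mgrid[r0:r1, c0:c1]
            cy = float((win * (rr + 0.5)).sum() / mass)
            cx = float((win * (cc + 0.5)).sum() / mass)
        if mass > 0:
            out.append((cx, cy, mass))
    return np.asarray(out) if out else np.empty((0, 3))


def locate_movie(
    movie: MovieStack,
    intensity_percentile: float = 99.8,
    movie_id: str = "movie",
) -> pd.DataFrame:
    """Detect spots in every frame of a movie; return a localization table.

    Columns: movie_id, frame, x_um, y_um, intensity. Positions are converted
    from pixels to µm with the movie's camera pixel size.
    """
    scale = movie.camera.pixel_size / 1000.0
    rows = []
    for f in range(movie.n_frames):
        spots = detect_spots(
            movie.frames[f], movie.camera.psf_sigma_px, intensity_percentile
        )
        for x, y, mass in spots:
            rows.append((movie_id, f, x * scale, y * scale, mass))
    return pd.DataFrame(
        rows, columns=["movie_id", "frame", "x_um", "y_um", "intensity"]
    )


# ---------------------------------------------------------------------------
# linking


def link_trajectories(
    localizations: pd.DataFrame, link_config: LinkConfig
) -> pd.DataFrame:
    """Greedy nearest-neighbour linking of a localization table.

    Frame by frame, candidate (track, detection) pairs within the allowed
    displacement are assigned in order of increasing distance (ties broken
    by lower traj_id). Unmatched detections start new trajectories; a track
    is retired after ``memory_frames`` consecutive misses. The result is the
    input table with a ``traj_id`` column, sorted by (movie_id, traj_id,
    frame). Linking is independent of the input row order: detections are
    canonically ordered by (x, y) within each frame.
    """
    required = {"movie_id", "frame", "x_um", "y_um"}
    if not required.issubset(localizations.columns):
        raise ValueError(f"localization table needs columns {sorted(required)}")
    if localizations.empty:
        out = localizations.copy()
        out["traj_id"] = pd.Series(dtype=int)
        return out

    pieces = []
    next_id = 0
    for movie_id, grp in localizations.groupby("movie_id", sort=True):
        linked, next_id = _link_one_movie(grp, link_config, next_id)
        pieces.append(linked)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["movie_id", "traj_id", "frame"], ignore_index=True)


def _link_one_movie(
    grp: pd.DataFrame, cfg: LinkConfig, next_id: int
) -> tuple[pd.DataFrame, int]:
    grp = grp.sort_values(["frame", "x_um", "y_um"], kind="mergesort")
    frames = grp["frame"].to_numpy()
    xy = grp[["x_um", "y_um"]].to_numpy()
    traj_ids = np.full(len(grp), -1, dtype=int)

    # active tracks: traj_id -> (last_xy, last_frame)
    active: dict[int, tuple[np.ndarray, int]] = {}
    for f in np.unique(frames):
        det_idx = np.nonzero(frames == f)[0]
        cand = []
        for tid, (pos, last_f) in active.items():
            gap = int(f - last_f)
            # gap-1 frames were missed; more than memory_frames ends the track
            if gap < 1 or gap - 1 > cfg.memory_frames:
                continue
            allowed = cfg.max_displacement * gap
            d = np.hypot(xy[det_idx, 0] - pos[0], xy[det_idx, 1] - pos[1])
            for k, dist in zip(det_idx, d):
                if dist <= allowed:
                    cand.append((float(dist), tid, int(k)))
        cand.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, tid, k in cand:
            if tid in used_t or k in used_d:
                continue
            used_t.add(tid)
            used_d.add(k)
            traj_ids[k] = tid
            active[tid] = (xy[k], int(f))
        for k in det_idx:
            if traj_ids[k] < 0:
                traj_ids[k] = next_id
                active[next_id] = (xy[k], int(f))
                next_id += 1
        # retire tracks that have exhausted their memory
        active = {
            tid: (pos, last_f)
            for tid, (pos, last_f) in active.items()
            if f - last_f <= cfg.memory_frames
        }
    out = grp.copy()
    out["traj_id"] = traj_ids
    return out, next_id


# ---------------------------------------------------------------------------
# filtering


def filter_trajectories(
    trajectories: pd.DataFrame,
    frame_rate: float | None = None,
    link_config: LinkConfig | None = None,
    min_frames: int | None = None,
) -> pd.DataFrame:
    """Keep only contiguous trajectories meeting the length threshold.

    The threshold is ``min_frames`` when given explicitly; otherwise it is
    taken from ``link_config`` (or its defaults) for frame_rate 500 (≥ 50
    frames) or 30 (≥ 30 frames). Any other rate without an explicit
    threshold is an error. Trajectories with frame gaps (bridged by linking
    memory) are dropped: the MSD estimator requires contiguous sampling.
    """
    cfg = link_config or LinkConfig(max_displacement=1.0)
    if min_frames is None:
        if frame_rate is None:
            raise ValueError("either frame_rate or min_frames is required")
        if math.isclose(frame_rate, 500.0):
            min_frames = cfg.min_frames_500fps
        elif math.isclose(frame_rate, 30.0):
            min_frames = cfg.min_frames_30fps
        else:
            raise ValueError(
                f"no length threshold defined for frame rate {frame_rate}; "
                "pass min_frames explicitly"
            )
    if trajectories.empty:
        return trajectories.copy()

    def _ok(g: pd.DataFrame) -> bool:
        f = np.sort(g["frame"].to_numpy())
        return len(f) >= min_frames and (f[-1] - f[0] == len(f) - 1)

    keep = trajectories.groupby(["movie_id", "traj_id"]).filter(_ok)
    return keep.reset_index(drop=True)
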