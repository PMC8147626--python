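"""Rendering of single-molecule fluorescence movies.

Each probe is drawn as a pixel-integrated symmetric 2D Gaussian point-spread
function scaled to an expected photon count, on a uniform background.
Per-pixel Poisson shot noise and additive Gaussian read noise then emulate an
EM-CCD acquisition. The default pixel size matches the mirrored recordings
(275.86 nm).

Coordinate convention: a position (x, y) in µm maps to fractional pixel
coordinates p = 1000·(x, y)/pixel_size with x along columns and y along rows;
pixel (r, c) covers the unit square [c, c+1) x [r, r+1), so its centre is at
(c + 0.5, r + 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from ._seeds import split_rng
from .diffusion import GroundTruthTrajectory

__all__ = ["CameraModel", "MovieStack", "render_movie"]


@dataclass
class CameraModel:
    """Acquisition parameters of the rendered camera.

    pixel_size and psf_sigma are in nm; photons_per_spot is the expected
    photon count of one emitter per frame; background is expected counts per
    pixel; read_noise_sigma is the SD of the additive Gaussian read noise.
    """

    pixel_size: float = 275.86
    image_shape: tuple[int, int] = (64, 64)
    psf_sigma: float = 275.86
    photons_per_spot: float = 800.0
    background: float = 20.0
    read_noise_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size

    def um_to_px(self, xy_um: np.ndarray) -> np.ndarray:
        return np.asarray(xy_um, dtype=float) * 1000.0 / self.pixel_size

    @property
    def fov_um(self) -> tuple[float, float]:
        """Field of view (x_extent, y_extent) in µm."""
        h, w = self.image_shape
        return (w * self.pixel_size / 1000.0, h * self.pixel_size / 1000.0)


@dataclass
class MovieStack:
    """A rendered (or loaded) movie: (frame, row, col) intensity raster."""

    frames: np.ndarray
    frame_interval: float
    camera: CameraModel

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (frame, row, col) array")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _add_spot(
    img: np.ndarray, px: float, py: float, sigma: float, photons: float
) -> None:
    """Add a pixel-integrated Gaussian of total weight ``photons`` in place."""
    half = max(3, int(math.ceil(4 * sigma)))
    r0 = max(0, int(math.floor(py)) - half)
    r1 = min(img.shape[0], int(math.floor(py)) + half + 1)
    c0 = max(0, int(math.floor(px)) - half)
    c1 = min(img.shape[1], int(math.floor(px)) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    s = sigma * math.sqrt(2.0)
    edges_r = np.arange(r0, r1 + 1)
    edges_c = np.arange(c0, c1 + 1)
    gr = 0.5 * (erf((edges_r[1:] - py) / s) - erf((edges_r[:-1] - py) / s))
    gc = 0.5 * (erf((edges_c[1:] - px) / s) - erf((edges_c[:-1] - px) / s))
    img[r0:r1, c0:c1] += photons * np.outer(gr, gc)


def render_movie(
    trajectories: list[GroundTruthTrajectory],
    camera: CameraModel,
    seed: int | None = 0,
    n_frames: int | None = None,
    apply_noise: bool = True,
) -> MovieStack:
    """Render trajectories into a movie stack.

    Emitters are drawn at their *true* positions; localization error in the
    downstream tracking then arises from photon statistics, as in a real
    acquisition. An empty trajectory list gives a background-only movie.

    Parameters
    ----------
    n_frames : int, optional
        Number of frames; defaults to 1 + the largest frame index present.
    apply_noise : bool
        When False, the expected-intensity image is returned (no shot or
        read noise) — useful for detection-bias tests.

    Raises
    ------
    ValueError
        If any emitter position falls outside the camera field of view.
    """
    if n_frames is None:
        n_frames = (
            1 + max((int(t.frames.max()) for t in trajectories), default=0)
            if trajectories
            else 1
        )
    h, w = camera.image_shape
    frame_interval = (
        trajectories[0].frame_interval if trajectories else 1.0
    )
    stack = np.full((n_frames, h, w), float(camera.background))

    sigma = camera.psf_sigma_px
    for traj in trajectories:
        px = camera.um_to_px(traj.true_xy)
        if np.any(px < 0) or np.any(px[:, 0] > w) or np.any(px[:, 1] > h):
            raise ValueError(
                f"trajectory {traj.traj_id} leaves the camera field of view"
            )
        for f, (x, y) in zip(traj.frames, px):
            if 0 <= f < n_frames:
                _add_spot(stack[int(f)], x, y, sigma, camera.photons_per_spot)

    if apply_noise:
        rng = split_rng(seed, 7)
        stack = rng.poisson(stack).astype(float)
        if camera.read_noise_sigma > 0:
            stack += rng.normal(0.0, camera.read_noise_sigma, size=stack.shape)
        stack = np.clip(stack, 0.0, None)
    return MovieStack(stack, frame_interval, camera)
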