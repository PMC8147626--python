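"""Monte Carlo simulation of (obstructed) 2D Brownian motion.

Probes perform a Gaussian random walk in a square periodic box containing
non-overlapping circular obstacles. Outside the obstacles each coordinate
receives an independent increment of standard deviation sqrt(2 D_free dt)
per substep; inside, D_inside applies (D_inside = 0 declares the obstacles
impermeable: a proposed step that would end inside a disk is redrawn a
bounded number of times, after which the particle holds its position for
that substep). The recorded per-frame positions are kept *unwrapped* so that
displacement statistics are unaffected by the periodic wrap; obstacle
membership is always evaluated in the wrapped box.

Observed positions add independent Gaussian localization noise per
coordinate, emulating the finite position accuracy of single-particle
tracking (44 nm in the experiments this generator mirrors).

Units: lengths µm, times s, diffusion coefficients µm²/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._seeds import split_rng
from .obstacles import ObstacleField

__all__ = ["DiffusionSimConfig", "GroundTruthTrajectory", "simulate_trajectories"]

#: proposed steps into an impermeable disk are redrawn at most this many times
MAX_STEP_RETRIES = 10

#: substep length is capped so that the RMS substep is at most radius/5
STEP_TO_RADIUS = 1.0 / 5.0


@dataclass
class DiffusionSimConfig:
    """Parameters of one simulated acquisition.

    Parameters
    ----------
    d_free : float
        Diffusion coefficient outside the obstacles, µm²/s (0 freezes the
        dynamics, useful for localization-noise checks).
    frame_interval : float
        Time between recorded frames, s (1/500 or 1/30 in the mirrored
        experiments; any positive value is accepted).
    n_trajectories : int
        Number of probes to simulate.
    n_frames : int
        Trajectory length in frames: the fixed length for
        ``length_dist="fixed"``, the mean for ``length_dist="geometric"``.
    length_dist : {"geometric", "fixed"}
        Geometric lengths emulate single-step photobleaching; ``min_frames``
        is the shortest length ever produced.
    min_frames : int
        Lower bound of the geometric length distribution.
    d_inside : float
        Diffusion coefficient inside obstacles; 0 makes them impermeable.
    substeps_per_frame : int, optional
        Monte Carlo substeps per recorded frame. Default (None) chooses the
        smallest count keeping the RMS substep below one fifth of the
        smallest obstacle radius (1 when the field is empty).
    loc_noise_sigma : float
        Localization noise SD per coordinate, µm (0.044 by default).
    seed : int
        Seed; all sub-streams are split from it deterministically.
    """

    d_free: float
    frame_interval: float
    n_trajectories: int
    n_frames: int = 200
    length_dist: Literal["geometric", "fixed"] = "geometric"
    min_frames: int = 50
    d_inside: float = 0.0
    substeps_per_frame: int | None = None
    loc_noise_sigma: float = 0.044
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_free < 0:
            raise ValueError("d_free must be non-negative")
        if self.d_inside < 0:
            raise ValueError("d_inside must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.loc_noise_sigma < 0:
            raise ValueError("loc_noise_sigma must be non-negative")
        if self.substeps_per_frame is not None and self.substeps_per_frame < 1:
            raise ValueError("substeps_per_frame must be >= 1")
        if self.length_dist not in ("geometric", "fixed"):
            raise ValueError(f"unknown length_dist {self.length_dist!r}")

    def resolve_substeps(self, field_: ObstacleField) -> int:
        if self.substeps_per_frame is not None:
            return int(self.substeps_per_frame)
        if field_.n_disks == 0 or self.d_free == 0:
            return 1
        dt_max = (STEP_TO_RADIUS * field_.min_radius) ** 2 / (2.0 * self.d_free)
        return max(1, math.ceil(self.frame_interval / dt_max))


@dataclass
class GroundTruthTrajectory:
    """One simulated probe: true and noise-corrupted positions per frame."""

    traj_id: int
    movie_id: str
    frames: np.ndarray  # contiguous integer frame indices
    true_xy: np.ndarray  # (n, 2) µm, unwrapped
    observed_xy: np.ndarray  # (n, 2) µm, true + localization noise
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.true_xy = np.asarray(self.true_xy, dtype=float)
        self.observed_xy = np.asarray(self.observed_xy, dtype=float)
        d = np.diff(self.frames)
        if d.size and not np.all(d == 1):
            raise ValueError("frames must be strictly increasing and contiguous")
        if not (len(self.true_xy) == len(self.observed_xy) == len(self.frames)):
            raise ValueError("frames / true_xy / observed_xy lengths differ")

    def __len__(self) -> int:
        return len(self.frames)


def _draw_lengths(config: DiffusionSimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_trajectories
    if config.length_dist == "fixed":
        return np.full(n, config.n_frames, dtype=int)
    mean_excess = max(1.0, float(config.n_frames - config.min_frames))
    p = 1.0 / mean_excess
    lengths = config.min_frames + rng.geometric(p, size=n)
    # cap the tail so one lucky probe cannot dominate memory/runtime
    return np.minimum(lengths, config.min_frames + int(10 * mean_excess))


def _initial_positions(
    field_: ObstacleField, n: int, impermeable: bool, rng: np.random.Generator
) -> np.ndarray:
    pos = rng.uniform(0.0, field_.box_size, size=(n, 2))
    if impermeable and field_.n_disks:
        bad = field_.contains(pos)
        while np.any(bad):
            pos[bad] = rng.uniform(0.0, field_.box_size, size=(int(bad.sum()), 2))
            bad[bad] = field_.contains(pos[bad])
    return pos


def simulate_trajectories(
    field_: ObstacleField, config: DiffusionSimConfig, movie_id: str | None = None
) -> list[GroundTruthTrajectory]:
    """Simulate ``config.n_trajectories`` probes diffusing in ``field_``.

    Returns trajectories with contiguous frames starting at 0. With
    ``d_free`` effectively frozen (no motion) positions stay constant; with
    zero trajectories requested the list is empty.
    """
    if config.n_trajectories == 0:
        return []
    if movie_id is None:
        movie_id = f"sim-{config.seed}"
    rng_len = split_rng(config.seed, 1)
    rng_init = split_rng(config.seed, 2)
    rng_step = split_rng(config.seed, 3)
    rng_loc = split_rng(config.seed, 4)

    impermeable = config.d_inside == 0.0 and field_.n_disks > 0
    slowed = config.d_inside > 0.0 and field_.n_disks > 0
    n_sub = config.resolve_substeps(field_)
    dt_sub = config.frame_interval / n_sub
    sigma_free = math.sqrt(2.0 * config.d_free * dt_sub)
    sigma_in = math.sqrt(2.0 * config.d_inside * dt_sub) if slowed else 0.0

    lengths = _draw_lengths(config, rng_len)
    max_len = int(lengths.max())
    n = config.n_trajectories
    pos = _initial_positions(field_, n, impermeable, rng_init)
    recorded = np.empty((max_len, n, 2))
    recorded[0] = pos

    for f in range(1, max_len):
        for _ in range(n_sub):
            if slowed:
                inside = field_.contains(pos)
                sigma = np.where(inside, sigma_in, sigma_free)[:, None]
                pos = pos + sigma * rng_step.normal(size=(n, 2))
            elif impermeable:
                prop = pos + sigma_free * rng_step.normal(size=(n, 2))
                bad = field_.contains(prop)
                for _retry in range(MAX_STEP_RETRIES):
                    if not np.any(bad):
                        break
                    k = int(bad.sum())
                    prop[bad] = pos[bad] + sigma_free * rng_step.normal(size=(k, 2))
                    bad[bad] = field_.contains(prop[bad])
                prop[bad] = pos[bad]  # exhausted retries: hold this substep
                pos = prop
            else:
                pos = pos + sigma_free * rng_step.normal(size=(n, 2))
        recorded[f] = pos

    out: list[GroundTruthTrajectory] = []
    for j in range(n):
        L = int(lengths[j])
        true_xy = recorded[:L, j, :].copy()
        noise = (
            rng_loc.normal(0.0, config.loc_noise_sigma, size=(L, 2))
            if config.loc_noise_sigma > 0
            else np.zeros((L, 2))
        )
        out.append(
            GroundTruthTrajectory(
                traj_id=j,
                movie_id=movie_id,
                frames=np.arange(L),
                true_xy=true_xy,
                observed_xy=true_xy + noise,
                frame_interval=config.frame_interval,
            )
        )
    return out
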