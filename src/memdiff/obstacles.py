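"""Non-overlapping circular obstacle fields in a periodic box.

The membrane microdomains that obstruct lateral diffusion are modelled as
impermeable circular disks in a square, periodically wrapped simulation box.
Fields are built either by random sequential adsorption (RSA) to a target
area fraction, or deterministically on a square lattice.

All lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from ._seeds import split_rng

__all__ = ["ObstacleField", "build_obstacle_field"]

#: disks smaller than this diameter (µm) are never drawn (truncation point
#: of the diameter distribution; 20 nm)
MIN_DIAMETER = 0.020


@dataclass
class ObstacleField:
    """A set of non-overlapping disks in a square periodic box.

    Attributes
    ----------
    box_size : float
        Side length of the square periodic domain, µm.
    centers : ndarray, shape (n, 2)
        Disk centres, µm, all inside ``[0, box_size)``.
    radii : ndarray, shape (n,)
        Disk radii, µm.
    target_fraction : float
        The area fraction the builder aimed for (0 for hand-built fields).
    seed : int or None
        Seed used to build the field, if any.
    """

    box_size: float
    centers: np.ndarray
    radii: np.ndarray
    target_fraction: float = 0.0
    seed: int | None = None
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _tiled_radii: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = np.empty((0, 2))
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if self.centers.shape[0] != self.radii.shape[0]:
            raise ValueError("centers and radii lengths differ")
        if self.box_size <= 0:
            raise ValueError("box_size must be positive")
        if self.n_disks and (
            self.centers.min() < 0 or self.centers.max() >= self.box_size
        ):
            raise ValueError("all centers must lie inside the box")

    @property
    def n_disks(self) -> int:
        return self.radii.shape[0]

    @property
    def area_fraction(self) -> float:
        """Analytic area fraction: Σ πr² / box²  (disks never overlap)."""
        return float(np.pi * np.sum(self.radii**2) / self.box_size**2)

    @property
    def max_radius(self) -> float:
        return float(self.radii.max()) if self.n_disks else 0.0

    @property
    def min_radius(self) -> float:
        return float(self.radii.min()) if self.n_disks else 0.0

    # -- point membership ---------------------------------------------------

    def _index(self) -> tuple[cKDTree, np.ndarray]:
        """KD-tree over the 3x3 periodic tiling of the disk centres."""
        if self._tree is None:
            shifts = np.array(
                [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=float
            )
            tiled = (self.centers[None, :, :] + shifts[:, None, :] * self.box_size)
            tiled = tiled.reshape(-1, 2)
            self._tree = cKDTree(tiled)
            self._tiled_radii = np.tile(self.radii, 9)
        return self._tree, self._tiled_radii

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points fall inside any disk (periodic wrap).

        ``points`` may be unwrapped; they are reduced modulo the box first.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.n_disks == 0:
            return np.zeros(points.shape[0], dtype=bool)
        tree, tiled_radii = self._index()
        wrapped = np.mod(points, self.box_size)
        # disks are disjoint, so a containing disk is always among the few
        # nearest centres; k=8 is generous for near-monodisperse disks
        k = min(8, tree.n)
        dist, idx = tree.query(wrapped, k=k)
        if k == 1:
            dist = dist[:, None]
            idx = idx[:, None]
        return np.any(dist < tiled_radii[idx], axis=1)

    def pairwise_ok(self) -> bool:
        """Brute-force all-pairs overlap check under the minimum-image rule."""
        n = self.n_disks
        for i in range(n):
            d = self.centers[i + 1 :] - self.centers[i]
            d -= self.box_size * np.round(d / self.box_size)
            if np.any(np.hypot(d[:, 0], d[:, 1]) < self.radii[i + 1 :] + self.radii[i]):
                return False
        return True


def build_obstacle_field(
    box_size: float,
    target_fraction: float,
    diameter_mean: float,
    diameter_sd: float = 0.0,
    seed: int | None = None,
    mode: Literal["random", "lattice"] = "random",
    lattice_spacing: float | None = None,
    max_attempts: int = 50_000,
) -> ObstacleField:
    """Build a non-overlapping disk field.

    Parameters
    ----------
    box_size : float
        Side of the square periodic box, µm.
    target_fraction : float
        Desired obstacle area fraction, in [0, 0.5). RSA of disks jams near
        0.55, so targets at or above 0.5 are rejected outright.
    diameter_mean, diameter_sd : float
        Mean and SD of the disk diameter distribution, µm. Diameters are
        drawn from a normal truncated below at 20 nm; ``diameter_sd=0``
        gives identical disks.
    seed : int, optional
        Seed for the placement stream (random mode).
    mode : {"random", "lattice"}
        ``random``: random sequential adsorption until the analytic area
        fraction reaches the target. ``lattice``: identical disks centred on
        a square grid with pitch ``lattice_spacing`` (``target_fraction`` is
        then ignored).
    lattice_spacing : float
        Grid pitch for lattice mode, µm; must exceed ``diameter_mean``.

    Raises
    ------
    RuntimeError
        If RSA cannot reach the target fraction within ``max_attempts``
        consecutive rejected placements; the message names the achieved
        fraction.
    """
    if diameter_mean <= 0:
        raise ValueError("diameter_mean must be positive")
    if mode == "lattice":
        if lattice_spacing is None:
            raise ValueError("lattice mode requires lattice_spacing")
        if lattice_spacing <= diameter_mean:
            raise ValueError("lattice_spacing must exceed the disk diameter")
        n_side = int(np.floor(box_size / lattice_spacing + 1e-9))
        if n_side < 1:
            raise ValueError("lattice_spacing larger than the box")
        coords = (np.arange(n_side) + 0.5) * lattice_spacing
        xx, yy = np.meshgrid(coords, coords)
        centers = np.column_stack([xx.ravel(), yy.ravel()])
        radii = np.full(centers.shape[0], diameter_mean / 2.0)
        return ObstacleField(box_size, centers, radii, target_fraction, seed)

    if not 0.0 <= target_fraction < 0.5:
        raise ValueError("target_fraction must be in [0, 0.5)")
    if target_fraction == 0.0:
        return ObstacleField(box_size, np.empty((0, 2)), np.empty(0), 0.0, seed)

    rng = split_rng(seed, 0)
    box_area = box_size**2
    centers: list[np.ndarray] = []
    radii: list[float] = []
    area = 0.0
    rejects = 0
    while area / box_area < target_fraction:
        if diameter_sd > 0:
            a = (MIN_DIAMETER - diameter_mean) / diameter_sd
            diam = truncnorm.rvs(
                a, np.inf, loc=diameter_mean, scale=diameter_sd, random_state=rng
            )
        else:
            diam = diameter_mean
        r = diam / 2.0
        c = rng.uniform(0.0, box_size, size=2)
        if centers:
            d = np.asarray(centers) - c
            d -= box_size * np.round(d / box_size)
            if np.any(np.hypot(d[:, 0], d[:, 1]) < np.asarray(radii) + r):
                rejects += 1
                if rejects >= max_attempts:
                    raise RuntimeError(
                        "could not reach target area fraction "
                        f"{target_fraction:.3f}; achieved {area / box_area:.3f} "
                        f"after {max_attempts} consecutive rejected placements"
                    )
                continue
        rejects = 0
        centers.append(c)
        radii.append(r)
        area += np.pi * r * r

    fld = ObstacleField(
        box_size, np.asarray(centers), np.asarray(radii), target_fraction, seed
    )
    if abs(fld.area_fraction - target_fraction) > 0.01:
        raise RuntimeError(
            f"target fraction {target_fraction:.4f} not representable: achieved "
            f"{fld.area_fraction:.4f} (disk area is too coarse for this box)"
        )
    return fld
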