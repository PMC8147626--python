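"""Synthetic AFM topographies and depression-domain morphometry.

Membrane microdomains appear in AFM height images of the bilayer as shallow
circular depressions (≈1.4 nm deep, ≈100 nm across, ≈24% of the area). This
module generates such topographies with realistic raster artifacts (plane
tilt, per-scanline offsets, pixel noise), flattens measured or synthetic
images, segments the depressions by a depth threshold, and reports the
domain statistics (count, mean depth, mean equivalent-circle diameter, area
fraction, number density) plus a geometric estimate of the domain-free
region size.

Heights are in nm (depressions negative after flattening); pixel_size in nm;
rasters are row-major with 0-based pixel-centre coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from ._seeds import split_rng

__all__ = [
    "Topography",
    "TopoSimConfig",
    "DomainLabelMap",
    "DomainStats",
    "FreeSizeEstimate",
    "generate_topography",
    "flatten_topography",
    "segment_domains",
    "compute_domain_stats",
    "domain_free_size",
]


@dataclass
class Topography:
    """An AFM height raster (nm) with its lateral pixel size (nm)."""

    heights: np.ndarray
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D raster")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def image_area_um2(self) -> float:
        return self.heights.size * (self.pixel_size / 1000.0) ** 2


@dataclass
class DomainLabelMap:
    """Integer raster: 0 = background, 1..n = segmented domains."""

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D raster")

    @property
    def n_domains(self) -> int:
        return int(self.labels.max())


@dataclass
class TopoSimConfig:
    """Generator parameters; defaults mirror the measured domain statistics.

    image_size in µm (square image), everything else in nm except the
    dimensionless area fraction. Tilt is the background plane gradient in nm
    per pixel along (row, col); line_offset_sigma is the SD of per-scanline
    height offsets, the classic AFM line artifact.
    """

    image_size: float = 3.0
    pixel_size: float = 5.9
    domain_fraction: float = 0.24
    domain_diameter_mean: float = 101.0
    domain_diameter_sd: float = 7.8
    domain_depth_mean: float = 1.4
    domain_depth_sd: float = 0.3
    noise_sigma: float = 0.15
    tilt: tuple[float, float] = (0.0015, -0.001)
    line_offset_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.domain_fraction < 0.5:
            raise ValueError("domain_fraction must be in [0, 0.5)")
        if self.domain_depth_mean <= 0:
            raise ValueError("domain_depth_mean must be positive")
        if self.pixel_size <= 0 or self.image_size <= 0:
            raise ValueError("image_size and pixel_size must be positive")


@dataclass
class DomainStats:
    """Aggregate morphometry of the segmented depressions.

    ``depths`` and ``diameters`` keep the per-domain values (nm) so that
    multi-image studies can average over all domains.
    """

    n_domains: int
    mean_depth: float  # nm, NaN when n_domains == 0
    mean_equiv_diameter: float  # nm, NaN when n_domains == 0
    area_fraction: float
    number_density: float  # µm⁻²
    depths: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    diameters: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def to_dict(self) -> dict:
        return {
            "n_domains": self.n_domains,
            "mean_depth_nm": None if np.isnan(self.mean_depth) else float(self.mean_depth),
            "mean_equiv_diameter_nm": None
            if np.isnan(self.mean_equiv_diameter)
            else float(self.mean_equiv_diameter),
            "area_fraction": float(self.area_fraction),
            "number_density_per_um2": float(self.number_density),
        }


@dataclass
class FreeSizeEstimate:
    """Domain-free region size (nm) under a named geometric convention."""

    l_free: float
    convention: str


# ---------------------------------------------------------------------------
# generation


def _rsa_disks(
    width_nm: float,
    target_fraction: float,
    diam_mean: float,
    diam_sd: float,
    rng: np.random.Generator,
    min_diameter: float = 20.0,
    max_attempts: int = 50_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Random sequential adsorption of whole disks inside a square, no wrap."""
    area_total = width_nm**2
    centers: list[np.ndarray] = []
    radii: list[float] = []
    area = 0.0
    rejects = 0
    while area / area_total < target_fraction:
        if diam_sd > 0:
            a = (min_diameter - diam_mean) / diam_sd
            diam = truncnorm.rvs(a, np.inf, loc=diam_mean, scale=diam_sd, random_state=rng)
        else:
            diam = diam_mean
        r = diam / 2.0
        c = rng.uniform(r, width_nm - r, size=2)
        if centers:
            d = np.asarray(centers) - c
            if np.any(np.hypot(d[:, 0], d[:, 1]) < np.asarray(radii) + r):
                rejects += 1
                if rejects >= max_attempts:
                    raise RuntimeError(
                        f"could not reach domain fraction {target_fraction:.3f}; "
                        f"achieved {area / area_total:.3f}"
                    )
                continue
        rejects = 0
        centers.append(c)
        radii.append(r)
        area += np.pi * r * r
    if not centers:
        return np.empty((0, 2)), np.empty(0)
    return np.asarray(centers), np.asarray(radii)


def generate_topography(config: TopoSimConfig) -> tuple[Topography, DomainLabelMap]:
    """Generate one synthetic topography plus its ground-truth label map.

    Background at 0 nm, plus a tilt plane and per-scanline offsets;
    non-overlapping circular depressions (RSA placement, truncated-normal
    diameters and depths) are subtracted; Gaussian pixel noise is added
    last. Domains are placed wholly inside the field of view.
    """
    width_nm = config.image_size * 1000.0
    n_px = int(round(width_nm / config.pixel_size))
    rng_place = split_rng(config.seed, 10)
    rng_depth = split_rng(config.seed, 11)
    rng_noise = split_rng(config.seed, 12)

    heights = np.zeros((n_px, n_px))
    labels = np.zeros((n_px, n_px), dtype=np.int32)

    if config.domain_fraction > 0:
        centers, radii = _rsa_disks(
            width_nm,
            config.domain_fraction,
            config.domain_diameter_mean,
            config.domain_diameter_sd,
            rng_place,
        )
        if config.domain_depth_sd > 0:
            a = (0.2 - config.domain_depth_mean) / config.domain_depth_sd
            depths = truncnorm.rvs(
                a,
                np.inf,
                loc=config.domain_depth_mean,
                scale=config.domain_depth_sd,
                size=len(radii),
                random_state=rng_depth,
            )
        else:
            depths = np.full(len(radii), config.domain_depth_mean)
        px = config.pixel_size
        for k, ((cx, cy), r, depth) in enumerate(zip(centers, radii, depths), start=1):
            c0 = max(0, int((cx - r) / px) - 1)
            c1 = min(n_px, int((cx + r) / px) + 2)
            r0 = max(0, int((cy - r) / px) - 1)
            r1 = min(n_px, int((cy + r) / px) + 2)
            rr, cc = np.mgrid[r0:r1, c0:c1]
            # pixel-centre coordinates in nm
            xx = (cc + 0.5) * px
            yy = (rr + 0.5) * px
            inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
            heights[r0:r1, c0:c1][inside] -= depth
            labels[r0:r1, c0:c1][inside] = k

    rows, cols = np.mgrid[0:n_px, 0:n_px]
    heights = heights + config.tilt[0] * rows + config.tilt[1] * cols
    if config.line_offset_sigma > 0:
        heights = heights + rng_noise.normal(0, config.line_offset_sigma, n_px)[:, None]
    if config.noise_sigma > 0:
        heights = heights + rng_noise.normal(0, config.noise_sigma, heights.shape)

    topo = Topography(
        heights,
        config.pixel_size,
        metadata={"generator": "memdiff.afm", "seed": config.seed},
    )
    return topo, DomainLabelMap(labels, config.pixel_size)


# ---------------------------------------------------------------------------
# flattening


def _histogram_mode(values: np.ndarray, bin_width: float = 0.02) -> float:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < bin_width:
        return float(np.median(values))
    bins = int(np.ceil((hi - lo) / bin_width))
    counts, edges = np.histogram(values, bins=bins)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def flatten_topography(
    topography: Topography, expected_depth: float = 1.4
) -> Topography:
    """Remove scanline offsets and background tilt; centre background at 0.

    Steps: (1) subtract each scanline's median; (2) remove a least-squares
    plane fitted to all pixels, so the height histogram is no longer smeared
    by tilt; (3) identify background pixels by thresholding at the
    height-histogram mode minus half the expected depression depth and refit
    the plane on the background only (one coarse-threshold iteration);
    (4) re-identify the background and subtract its per-scanline medians and
    finally its histogram mode, so the background level is 0 nm.
    """
    h = topography.heights.astype(float).copy()
    h -= np.median(h, axis=1, keepdims=True)

    rows, cols = np.mgrid[0 : h.shape[0], 0 : h.shape[1]]

    def _plane(mask: np.ndarray) -> np.ndarray:
        A = np.column_stack(
            [np.ones(mask.sum()), rows[mask].astype(float), cols[mask].astype(float)]
        )
        coef, *_ = np.linalg.lstsq(A, h[mask], rcond=None)
        return coef[0] + coef[1] * rows + coef[2] * cols

    h = h - _plane(np.ones_like(h, dtype=bool))
    thr = _histogram_mode(h.ravel()) - expected_depth / 2.0
    h = h - _plane(h > thr)

    thr = _histogram_mode(h.ravel()) - expected_depth / 2.0
    bg = h > thr
    for i in range(h.shape[0]):
        line_bg = bg[i]
        if line_bg.any():
            h[i] -= np.median(h[i][line_bg])
    h -= _histogram_mode(h[bg])
    meta = dict(topography.metadata, flattened=True)
    return Topography(h, topography.pixel_size, meta)


# ---------------------------------------------------------------------------
# segmentation & statistics


def segment_domains(
    topography: Topography,
    depth_threshold: float = 0.7,
    min_diameter: float = 20.0,
) -> DomainLabelMap:
    """Label depression domains in a flattened topography.

    Pixels below −depth_threshold (nm) are foreground; 8-connected
    components smaller than a disk of ``min_diameter`` are discarded and
    the remaining components are relabelled 1..n.
    """
    if depth_threshold <= 0:
        raise ValueError("depth_threshold must be positive")
    mask = topography.heights < -depth_threshold
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return DomainLabelMap(labels.astype(np.int32), topography.pixel_size)
    min_area_px = np.pi * (min_diameter / 2.0) ** 2 / topography.pixel_size**2
    sizes = np.bincount(labels.ravel())
    keep = np.nonzero(sizes >= max(1.0, min_area_px))[0]
    keep = keep[keep > 0]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    return DomainLabelMap(remap[labels], topography.pixel_size)


def compute_domain_stats(
    topography: Topography, label_map: DomainLabelMap
) -> DomainStats:
    """Morphometry of labelled domains.

    Per-domain depth is the background median height minus the mean height
    inside the domain (positive magnitudes for depressions); equivalent
    diameter is 2·sqrt(area/π); area fraction and number density refer to
    the whole image.
    """
    labels = label_map.labels
    if labels.shape != topography.heights.shape:
        raise ValueError("label map does not align with the topography")
    n = int(labels.max())
    total_px = labels.size
    fg_px = int((labels > 0).sum())
    area_fraction = fg_px / total_px
    area_um2 = topography.image_area_um2
    if n == 0:
        return DomainStats(0, float("nan"), float("nan"), area_fraction, 0.0)
    h = topography.heights
    bg_median = float(np.median(h[labels == 0]))
    sums = ndimage.sum_labels(h, labels, index=np.arange(1, n + 1))
    counts = np.bincount(labels.ravel())[1:]
    depths = bg_median - sums / counts
    px_nm = topography.pixel_size
    diameters = 2.0 * np.sqrt(counts * px_nm**2 / np.pi)
    return DomainStats(
        n_domains=n,
        mean_depth=float(np.mean(depths)),
        mean_equiv_diameter=float(np.mean(diameters)),
        area_fraction=float(area_fraction),
        number_density=n / area_um2,
        depths=np.asarray(depths, dtype=float),
        diameters=np.asarray(diameters, dtype=float),
    )


def domain_free_size(
    stats: DomainStats,
    convention: Literal["equivalent_free_circle", "lattice_gap"] = "equivalent_free_circle",
) -> FreeSizeEstimate:
    """Geometric size of the domain-free region between the microdomains.

    ``equivalent_free_circle``: each domain owns a cell of area
    1/number_density; the free area per cell is (1 − φ)/ρ and the estimate
    is the diameter of the circle with that area, l = 2·sqrt(A_free/π).

    ``lattice_gap``: identical disks of the mean diameter d on a square
    lattice reproducing the area fraction φ have pitch a = d·sqrt(π/(4φ));
    the estimate is twice the nearest-neighbour edge-to-edge gap,
    l = 2·d·(sqrt(π/(4φ)) − 1).

    Both are reported in nm together with the convention used; the published
    analyses use an (unstated) periodic-allocation convention of the same
    family, so all outputs are explicitly labelled.
    """
    if stats.n_domains == 0 or stats.number_density <= 0:
        raise ValueError("free-size estimate requires at least one domain")
    phi = stats.area_fraction
    if not 0.0 < phi < 1.0:
        raise ValueError("area_fraction must lie strictly between 0 and 1")
    if convention == "equivalent_free_circle":
        density_nm2 = stats.number_density / 1.0e6  # µm⁻² -> nm⁻²
        free_area = (1.0 - phi) / density_nm2
        l_free = 2.0 * np.sqrt(free_area / np.pi)
    elif convention == "lattice_gap":
        d = stats.mean_equiv_diameter
        l_free = 2.0 * d * (np.sqrt(np.pi / (4.0 * phi)) - 1.0)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return FreeSizeEstimate(float(l_free), convention)
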