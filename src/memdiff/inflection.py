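"""Inflection points of the D–τ curve and diffusion lengths.

On a log-τ axis an obstructed-diffusion D(τ) curve shows descending segments
that turn flat where the probe has explored a characteristic free-region
size. Each such inflection is located as the intersection of straight lines
fitted to the adjacent descending and flat regions in (log₁₀ τ, D) space
(straight lines on the published log-τ plots are lines in that space).
The corresponding length scale is the mean diffusion distance

    L = sqrt(4 D τ)   (D in µm²/s, τ in s → L in µm),

evaluated at the inflection coordinates.

Two fitting modes are provided: *manual*, with user-supplied τ-ranges for
the segments, and *automatic*, a continuous two-segment piecewise-linear
least-squares fit per transition whose breakpoint is chosen by minimum
residual sum over a grid of candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .msd import DCurve

__all__ = [
    "InflectionPoint",
    "InflectionPair",
    "diffusion_length",
    "fit_segment_line",
    "single_inflection",
    "find_inflection",
    "detect_inflections",
]


@dataclass
class InflectionPoint:
    """One inflection of the D–τ curve: coordinates plus derived length."""

    tau: float  # s
    d: float  # µm²/s
    length: float  # µm, sqrt(4 d tau)

    @property
    def length_nm(self) -> int:
        """Diffusion length rounded to the nearest nanometre for display."""
        return int(round(self.length * 1000.0))


@dataclass
class InflectionPair:
    """The two inflections P₁, P₂ (τ₁ < τ₂) and their lengths L₁ < L₂."""

    p1: InflectionPoint
    p2: InflectionPoint
    fit_segments: tuple  # the τ-ranges (or windows) used

    def __post_init__(self) -> None:
        if not self.p1.tau < self.p2.tau:
            raise ValueError("inflections out of order: require tau1 < tau2")

    @property
    def l1(self) -> float:
        return self.p1.length

    @property
    def l2(self) -> float:
        return self.p2.length

    def to_dict(self) -> dict:
        return {
            "p1": {"tau_s": self.p1.tau, "d_um2_s": round(self.p1.d, 2)},
            "p2": {"tau_s": self.p2.tau, "d_um2_s": round(self.p2.d, 2)},
            "l1_nm": self.p1.length_nm,
            "l2_nm": self.p2.length_nm,
            "segments": [list(map(float, s)) for s in self.fit_segments],
        }


def diffusion_length(d: float, tau: float) -> float:
    """Mean diffusion distance L = sqrt(4·D·τ) in µm.

    Negative inputs are rejected; either argument being zero gives 0.
    """
    if d < 0 or tau < 0:
        raise ValueError("diffusion_length requires d >= 0 and tau >= 0")
    return float(np.sqrt(4.0 * d * tau))


def _select(curve: DCurve, tau_range: tuple[float, float]) -> np.ndarray:
    lo, hi = tau_range
    return (curve.taus >= lo) & (curve.taus <= hi)


def fit_segment_line(
    curve: DCurve,
    tau_range: tuple[float, float],
    logspace: bool = True,
    name: str = "segment",
) -> tuple[float, float]:
    """Least-squares line D = a·x + b over a τ-range; x = log₁₀τ by default.

    Returns (slope, intercept). A segment holding fewer than two points is
    an error naming the segment.
    """
    mask = _select(curve, tau_range)
    if mask.sum() < 2:
        raise ValueError(
            f"{name}: fewer than 2 points in tau range [{tau_range[0]}, {tau_range[1]}]"
        )
    x = np.log10(curve.taus[mask]) if logspace else curve.taus[mask]
    a, b = np.polyfit(x, curve.d_values[mask], 1)
    return float(a), float(b)


def single_inflection(
    curve: DCurve,
    down_range: tuple[float, float],
    flat_range: tuple[float, float],
    logspace: bool = True,
) -> InflectionPoint:
    """Intersection of a descending and a flat fitted line.

    The descending fit must have a strictly negative slope (in the chosen
    abscissa); the flat line is fitted, not forced horizontal, so a gently
    sloping plateau is handled gracefully.
    """
    a1, b1 = fit_segment_line(curve, down_range, logspace, name="downward segment")
    if a1 >= -1e-9:
        raise ValueError(
            f"downward segment has non-negative slope ({a1:.3g}); "
            "no descending region in the given range"
        )
    a2, b2 = fit_segment_line(curve, flat_range, logspace, name="flat segment")
    if a1 == a2:
        raise ValueError("segments are parallel; no intersection")
    x = (b2 - b1) / (a1 - a2)
    d_at = a2 * x + b2
    tau = float(10**x) if logspace else float(x)
    return InflectionPoint(tau, float(d_at), diffusion_length(max(d_at, 0.0), tau))


def _two_segment_fit(x: np.ndarray, y: np.ndarray, bp: float) -> tuple[float, np.ndarray]:
    """Continuous two-segment linear LSQ with fixed breakpoint; returns (rss, coef).

    Basis: [1, x, max(x − bp, 0)] — linear in the coefficients.
    """
    basis = np.column_stack([np.ones_like(x), x, np.clip(x - bp, 0.0, None)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    rss = float(np.sum((basis @ coef - y) ** 2))
    return rss, coef


def _log_decimate(x: np.ndarray, points_per_decade: int) -> np.ndarray:
    """Indices of an approximately log-uniform subsample of sorted ``x``.

    Lag grids are linear in τ, so on a log axis the points crowd at large τ
    and would dominate a least-squares fit; the decimation keeps at most one
    point per 1/points_per_decade-decade bin (always keeping the endpoints).
    """
    bins = np.floor(x * points_per_decade).astype(int)
    keep = np.r_[True, np.diff(bins) != 0]
    keep[-1] = True
    return np.nonzero(keep)[0]


def find_inflection(
    curve: DCurve,
    window: tuple[float, float] | None = None,
    logspace: bool = True,
    n_grid: int = 200,
    points_per_decade: int = 12,
) -> InflectionPoint:
    """Automatic single-transition detection by two-segment piecewise fit.

    Within the τ-window (default: the whole curve) a continuous descending →
    flat piecewise-linear model is fitted for every candidate breakpoint on
    a grid; the breakpoint minimising the residual sum of squares is the
    inflection. The left segment must descend (slope < 0); otherwise the fit
    is rejected. In log space the curve is first resampled to roughly
    ``points_per_decade`` points per decade so that the dense large-τ end of
    a linear lag grid cannot dominate the fit.
    """
    mask = _select(curve, window) if window is not None else np.ones(len(curve), bool)
    if mask.sum() < 5:
        raise ValueError("need at least 5 points for automatic inflection detection")
    x = np.log10(curve.taus[mask]) if logspace else curve.taus[mask]
    y = curve.d_values[mask]
    order = np.argsort(x)
    x, y = x[order], y[order]
    if logspace and points_per_decade:
        idx = _log_decimate(x, points_per_decade)
        if len(idx) >= 5:
            x, y = x[idx], y[idx]
    # breakpoint grid strictly inside the data range, away from the edges so
    # both segments keep >= 2 points
    candidates = np.linspace(x[1], x[-2], n_grid)
    best = None
    for bp in candidates:
        if (x < bp - 1e-12).sum() < 2 or (x > bp + 1e-12).sum() < 2:
            continue
        rss, coef = _two_segment_fit(x, y, bp)
        if best is None or rss < best[0]:
            best = (rss, coef, bp)
    if best is None:
        raise ValueError("no admissible breakpoint in the window")
    _, coef, bp = best
    left_slope = coef[1]
    if left_slope >= -1e-9:
        raise ValueError(
            f"left segment slope is non-negative ({left_slope:.3g}); "
            "curve does not descend before the candidate inflection"
        )
    d_at = float(coef[0] + coef[1] * bp)
    tau = float(10**bp) if logspace else float(bp)
    return InflectionPoint(tau, d_at, diffusion_length(max(d_at, 0.0), tau))


def detect_inflections(
    curve: DCurve,
    segment_ranges: Sequence[tuple[float, float]] | None = None,
    windows: Sequence[tuple[float, float]] | None = None,
    logspace: bool = True,
) -> InflectionPair:
    """Locate the two inflections P₁ and P₂ of a descending D–τ curve.

    Manual mode (``segment_ranges`` = three τ-ranges: first descending
    region, intermediate region, final plateau): P₁ intersects the first
    descending line with the horizontal continuation of the intermediate
    line at its left edge; P₂ intersects the intermediate (descending) line
    with the final plateau line.

    Automatic mode (``windows`` = two τ-windows, one per transition; default
    splits the curve's τ-range at its logarithmic midpoint): each transition
    is found by the continuous two-segment piecewise-linear fit of
    :func:`find_inflection`.
    """
    if segment_ranges is not None:
        if len(segment_ranges) != 3:
            raise ValueError("manual mode requires exactly three tau ranges")
        down1, mid, flat2 = segment_ranges
        a1, b1 = fit_segment_line(curve, down1, logspace, name="downward segment 1")
        if a1 >= 0:
            raise ValueError("downward segment 1 has non-negative slope")
        am, bm = fit_segment_line(curve, mid, logspace, name="intermediate segment")
        left_edge = np.log10(mid[0]) if logspace else mid[0]
        h = am * left_edge + bm  # plateau level implied at the mid segment's left edge
        x1 = (h - b1) / a1
        tau1 = float(10**x1) if logspace else float(x1)
        p1 = InflectionPoint(tau1, float(h), diffusion_length(max(h, 0.0), tau1))
        if am >= 0:
            raise ValueError("intermediate segment has non-negative slope")
        p2 = single_inflection(curve, mid, flat2, logspace)
        return InflectionPair(p1, p2, tuple(segment_ranges))

    if windows is None:
        lo, hi = float(curve.taus.min()), float(curve.taus.max())
        split = 10 ** ((np.log10(lo) + np.log10(hi)) / 2.0)
        windows = [(lo, split), (split, hi)]
    if len(windows) != 2:
        raise ValueError("automatic mode requires exactly two tau windows")
    p1 = find_inflection(curve, windows[0], logspace)
    p2 = find_inflection(curve, windows[1], logspace)
    return InflectionPair(p1, p2, tuple(windows))
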