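"""Mean-square-displacement curves and lag-dependent diffusion coefficients.

For a contiguous trajectory r(iΔt), i = 0..N−1, the MSD at lag τ = nΔt is
the overlapping-window average

    MSD(nΔt) = (1/(N−n)) Σ_{i=0}^{N−n−1} |r((i+n)Δt) − r(iΔt)|² ,

and the ensemble curve pools all trajectories with pair-count weights: the
pooled MSD at lag n is the ratio of the summed squared displacements to the
total number of displacement pairs, each trajectory j contributing N_j − n
pairs. A single trajectory therefore reduces the pooled estimator to the
per-trajectory one.

The lag-dependent diffusion coefficient D(τ = nΔt) is the through-origin
least-squares slope of MSD = 4Dτ fitted over lags 1..n:

    D(nΔt) = Σ_{m=1..n} τ_m MSD_m / (4 Σ_{m=1..n} τ_m²) .

A decrease of D with τ is the signature of obstructed (anomalous) diffusion;
for free Brownian motion D(τ) is flat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MSDCurve",
    "DCurve",
    "msd_single",
    "pooled_msd",
    "pooled_msd_from_trajectories",
    "build_d_curve",
    "merge_d_curves",
    "iter_table_trajectories",
]


@dataclass
class MSDCurve:
    """MSD values and pooled pair counts on the lag grid τ = nΔt, n ≥ 1."""

    taus: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # µm²
    pair_counts: np.ndarray  # displacement pairs pooled at each lag
    frame_interval: float  # s

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if not (len(self.taus) == len(self.msd) == len(self.pair_counts)):
            raise ValueError("taus / msd / pair_counts lengths differ")
        if len(self.taus) and np.any(np.diff(self.taus) <= 0):
            raise ValueError("taus must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")

    def __len__(self) -> int:
        return len(self.taus)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau_s": self.taus, "msd_um2": self.msd, "pair_count": self.pair_counts}
        )


@dataclass
class DCurve:
    """Cumulative-fit diffusion coefficients D(τ).

    ``d_values[i]`` is the through-origin fit of MSD = 4Dτ over lags
    1..n(i). ``rates`` carries the acquisition rate (fps) of each point so
    merged multi-rate curves stay traceable.
    """

    taus: np.ndarray  # s
    d_values: np.ndarray  # µm²/s
    source_rate: float | None = None  # fps, None for mixed/unknown
    rates: np.ndarray | None = None  # per-point fps after a merge

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        self.d_values = np.asarray(self.d_values, dtype=float)
        if len(self.taus) != len(self.d_values):
            raise ValueError("taus and d_values lengths differ")
        if self.rates is not None:
            self.rates = np.asarray(self.rates, dtype=float)
            if len(self.rates) != len(self.taus):
                raise ValueError("rates length differs from taus")

    def __len__(self) -> int:
        return len(self.taus)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"tau_s": self.taus, "d_um2_s": self.d_values})
        if self.rates is not None:
            df["source_fps"] = self.rates
        elif self.source_rate is not None:
            df["source_fps"] = self.source_rate
        return df


def _check_contiguous(frames: np.ndarray | None) -> None:
    if frames is None:
        return
    f = np.asarray(frames)
    if f.size and not np.all(np.diff(f) == 1):
        raise ValueError("trajectory frames are not contiguous")


def msd_single(
    positions: np.ndarray,
    frame_interval: float,
    n_max: int | None = None,
    frames: np.ndarray | None = None,
) -> MSDCurve:
    """Overlapping-window MSD of one contiguous trajectory.

    ``positions`` is an (N, 2) array in µm. If ``n_max`` exceeds N−1 the
    curve is truncated at n = N−1 with a warning. Passing the trajectory's
    ``frames`` enables the contiguity check (non-contiguous input raises).
    """
    _check_contiguous(frames)
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("positions must be (N, 2)")
    n_pts = pos.shape[0]
    if n_pts < 2:
        raise ValueError("need at least 2 positions")
    if n_max is None:
        n_max = n_pts - 1
    if n_max > n_pts - 1:
        warnings.warn(
            f"n_max={n_max} exceeds N-1={n_pts - 1}; curve truncated",
            stacklevel=2,
        )
        n_max = n_pts - 1
    lags = np.arange(1, n_max + 1)
    msd = np.empty(n_max)
    counts = np.empty(n_max, dtype=int)
    for j, n in enumerate(lags):
        d = pos[n:] - pos[:-n]
        msd[j] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
        counts[j] = n_pts - n
    return MSDCurve(lags * frame_interval, msd, counts, frame_interval)


def pooled_msd(
    trajectories: Sequence[np.ndarray],
    frame_interval: float,
    n_max: int,
) -> MSDCurve:
    """Pair-weighted ensemble MSD over many contiguous trajectories.

    Every trajectory with N > n contributes its N − n overlapping squared
    displacements to the lag-n pool; the pooled MSD is total sum over total
    count, i.e. the frame-number-weighted average of the per-trajectory
    curves. Duplicating a trajectory leaves the estimator unchanged in value
    (both sums double).
    """
    trajs = [np.asarray(p, dtype=float) for p in trajectories]
    if not trajs:
        raise ValueError("no trajectories supplied")
    for p in trajs:
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValueError("each trajectory must be (N, 2)")
    sums = np.zeros(n_max)
    counts = np.zeros(n_max, dtype=int)
    for pos in trajs:
        n_pts = pos.shape[0]
        for n in range(1, min(n_max, n_pts - 1) + 1):
            d = pos[n:] - pos[:-n]
            sums[n - 1] += float(np.sum(d[:, 0] ** 2 + d[:, 1] ** 2))
            counts[n - 1] += n_pts - n
    valid = counts > 0
    if not np.all(valid):
        warnings.warn(
            "some lags have no displacement pairs; curve truncated", stacklevel=2
        )
    lags = np.arange(1, n_max + 1)[valid]
    return MSDCurve(
        lags * frame_interval, sums[valid] / counts[valid], counts[valid],
        frame_interval,
    )


def pooled_msd_from_trajectories(
    trajectories: Sequence, n_max: int, use_true: bool = False
) -> MSDCurve:
    """Pooled MSD straight from simulated/linked trajectory objects.

    Objects must expose ``frame_interval`` and ``observed_xy`` (and
    ``true_xy`` when ``use_true``). Mixing frame intervals is an error: the
    pooled estimator is only defined on a common lag grid.
    """
    if not trajectories:
        raise ValueError("no trajectories supplied")
    dts = {float(t.frame_interval) for t in trajectories}
    if len(dts) != 1:
        raise ValueError(f"mixed frame intervals in pool: {sorted(dts)}")
    arrays = [t.true_xy if use_true else t.observed_xy for t in trajectories]
    return pooled_msd(arrays, dts.pop(), n_max)


def build_d_curve(
    curve: MSDCurve, n_max: int | None = None, source_rate: float | None = None
) -> DCurve:
    """Cumulative through-origin fits D(nΔt) for every n ≥ 1.

    D(nΔt) = Σ_{m≤n} τ_m·MSD_m / (4 Σ_{m≤n} τ_m²); n = 1 degenerates to
    MSD(Δt)/(4Δt).
    """
    if len(curve) == 0:
        raise ValueError("empty MSD curve")
    taus = curve.taus if n_max is None else curve.taus[:n_max]
    msd = curve.msd if n_max is None else curve.msd[:n_max]
    num = np.cumsum(taus * msd)
    den = 4.0 * np.cumsum(taus**2)
    if source_rate is None and curve.frame_interval > 0:
        source_rate = 1.0 / curve.frame_interval
    return DCurve(taus.copy(), num / den, source_rate=source_rate)


def merge_d_curves(curve_500fps: DCurve, curve_30fps: DCurve) -> DCurve:
    """Concatenate two D(τ) curves from different acquisition rates.

    Points are sorted by τ; where both curves share a τ, both points are
    retained with the faster-rate point first. A gap of more than one decade
    between the curves' τ-ranges triggers a warning.
    """
    a, b = curve_500fps, curve_30fps
    rate_a = a.source_rate if a.source_rate is not None else np.inf
    rate_b = b.source_rate if b.source_rate is not None else 0.0
    taus = np.concatenate([a.taus, b.taus])
    dvals = np.concatenate([a.d_values, b.d_values])
    rates = np.concatenate(
        [np.full(len(a), rate_a), np.full(len(b), rate_b)]
    )
    # stable sort on tau only: equal taus keep input order (faster rate first)
    order = np.argsort(taus, kind="mergesort")
    lo = max(a.taus.min(), b.taus.min())
    hi = min(a.taus.max(), b.taus.max())
    if hi < lo and lo / hi > 10.0:
        warnings.warn(
            f"tau ranges are disjoint by more than one decade ({hi:g} s .. {lo:g} s)",
            stacklevel=2,
        )
    return DCurve(taus[order], dvals[order], source_rate=None, rates=rates[order])


def iter_table_trajectories(
    table: pd.DataFrame, position_cols: tuple[str, str] = ("x_um", "y_um")
) -> Iterable[tuple[tuple, np.ndarray, np.ndarray]]:
    """Yield ((movie_id, traj_id), frames, positions) from a trajectory table."""
    for key, g in table.groupby(["movie_id", "traj_id"], sort=True):
        g = g.sort_values("frame")
        yield key, g["frame"].to_numpy(), g[list(position_cols)].to_numpy(float)
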