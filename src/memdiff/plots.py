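"""Diagnostic plots: MSD–τ and D–τ curves, AFM topography overview."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .afm import DomainLabelMap, Topography
from .inflection import InflectionPair
from .msd import DCurve, MSDCurve

__all__ = ["plot_msd", "plot_d_curve", "plot_topography"]


def plot_msd(curve: MSDCurve, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(curve.taus, curve.msd, "o-", ms=3)
    ax.set_xlabel(r"$\tau$ (s)")
    ax.set_ylabel(r"MSD ($\mu$m$^2$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_d_curve(
    curve: DCurve, path: str | Path, inflections: InflectionPair | None = None
) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.semilogx(curve.taus, curve.d_values, "o", ms=3)
    if inflections is not None:
        for p, name in ((inflections.p1, "P1"), (inflections.p2, "P2")):
            ax.plot([p.tau], [p.d], "k*", ms=10)
            ax.annotate(
                f"{name}: L={p.length_nm} nm",
                (p.tau, p.d),
                textcoords="offset points",
                xytext=(6, 6),
                fontsize=8,
            )
    ax.set_xlabel(r"$\tau$ (s)")
    ax.set_ylabel(r"$D(\tau)$ ($\mu$m$^2$/s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_topography(
    topo: Topography, path: str | Path, label_map: DomainLabelMap | None = None
) -> None:
    ncols = 2 if label_map is not None else 1
    fig, axes = plt.subplots(1, ncols, figsize=(4.5 * ncols, 4))
    axes = [axes] if ncols == 1 else list(axes)
    extent_um = topo.heights.shape[1] * topo.pixel_size / 1000.0
    im = axes[0].imshow(
        topo.heights, cmap="afmhot", extent=(0, extent_um, extent_um, 0)
    )
    fig.colorbar(im, ax=axes[0], label="height (nm)", shrink=0.8)
    axes[0].set_xlabel(r"x ($\mu$m)")
    if label_map is not None:
        axes[1].imshow(
            label_map.labels > 0, cmap="gray", extent=(0, extent_um, extent_um, 0)
        )
        axes[1].set_title("segmented domains")
        axes[1].set_xlabel(r"x ($\mu$m)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
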