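"""Configuration-driven end-to-end studies.

Two orchestrators tie the modules together:

* :func:`run_spt_study` — simulate (or load) single-particle trajectories,
  optionally render a movie and re-track it, pool MSD curves, fit D(τ),
  locate inflections and report diffusion lengths, with a ground-truth
  comparison in simulation mode.
* :func:`run_afm_study` — generate (or load) AFM topographies, flatten,
  segment, and aggregate domain morphometry across images.

Configurations are plain mappings (typically loaded from YAML); one integer
seed drives every random stage through deterministic stream splitting, so a
study is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import contextlib
from dataclasses import asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from . import io as mio
from .afm import (
    DomainStats,
    TopoSimConfig,
    compute_domain_stats,
    domain_free_size,
    flatten_topography,
    generate_topography,
    segment_domains,
)
from .diffusion import DiffusionSimConfig, simulate_trajectories
from .imaging import CameraModel, render_movie
from .inflection import detect_inflections, diffusion_length, find_inflection
from .msd import build_d_curve, pooled_msd, iter_table_trajectories
from .obstacles import build_obstacle_field
from .plots import plot_d_curve, plot_msd, plot_topography
from .tracking import LinkConfig, filter_trajectories, link_trajectories, locate_movie

__all__ = ["ConfigError", "run_spt_study", "run_afm_study"]

SPT_MODES = {"spt_sim", "spt_from_movie", "spt_from_csv"}
AFM_MODES = {"afm_sim", "afm_from_image"}


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@contextlib.contextmanager
def _stage(name: str) -> Iterator[None]:
    try:
        yield
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc


def _require(config: dict, key: str, context: str = "config") -> object:
    if key not in config:
        raise ConfigError(f"{context}: missing required field '{key}'")
    return config[key]


def _outdir(config: dict) -> Path:
    out = Path(_require(config, "output_dir"))
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# SPT study


def run_spt_study(config: dict) -> dict:
    """Run one single-particle-tracking study; returns the report dict.

    Modes: ``spt_sim`` (simulate, optionally render + re-track),
    ``spt_from_csv`` (trajectory table on disk), ``spt_from_movie``
    (TIFF movie on disk). Artifacts written to ``output_dir``:
    trajectories.csv, msd.csv, dcurve.csv, inflections.json (when
    requested), msd.png, dcurve.png, report.json.
    """
    mode = _require(config, "mode")
    if mode not in SPT_MODES:
        raise ConfigError(f"unknown SPT mode {mode!r}; expected one of {sorted(SPT_MODES)}")
    out = _outdir(config)
    analysis = dict(config.get("analysis", {}))
    report: dict = {"mode": mode}
    truth: dict | None = None

    if mode == "spt_sim":
        seed = int(_require(config, "seed"))
        sim = dict(_require(config, "simulation"))
        with _stage("simulate"):
            frame_rate = float(sim.get("frame_rate", 500.0))
            field = build_obstacle_field(
                box_size=float(sim.get("box_size_um", 5.0)),
                target_fraction=float(sim.get("obstacle_fraction", 0.0)),
                diameter_mean=float(sim.get("obstacle_diameter_um", 0.101)),
                diameter_sd=float(sim.get("obstacle_diameter_sd_um", 0.0078)),
                seed=seed,
            )
            simcfg = DiffusionSimConfig(
                d_free=float(sim.get("d_free", 0.5)),
                d_inside=float(sim.get("d_inside", 0.0)),
                frame_interval=1.0 / frame_rate,
                n_trajectories=int(sim.get("n_trajectories", 200)),
                n_frames=int(sim.get("n_frames", 200)),
                length_dist=sim.get("length_dist", "fixed"),
                min_frames=int(sim.get("min_frames", 50)),
                loc_noise_sigma=float(sim.get("loc_noise_sigma_um", 0.044)),
                substeps_per_frame=sim.get("substeps_per_frame"),
                seed=seed,
            )
            trajs = simulate_trajectories(field, simcfg)
            table = mio.trajectories_to_table(trajs)
            frame_interval = simcfg.frame_interval
            truth = {
                "d_free_um2_s": simcfg.d_free,
                "obstacle_fraction": field.area_fraction,
                "n_obstacles": field.n_disks,
            }
            if field.n_disks:
                density = field.n_disks / field.box_size**2
                free_area_nm2 = (1.0 - field.area_fraction) / density * 1.0e6
                truth["free_region_size_nm"] = float(
                    2.0 * np.sqrt(free_area_nm2 / np.pi)
                )
        if sim.get("render", False):
            with _stage("render+track"):
                cam = CameraModel(**sim.get("camera", {}))
                movie = render_movie(trajs, cam, seed=seed)
                mio.write_movie(out / "movie.tif", movie)
                locs = locate_movie(movie)
                link = LinkConfig(
                    max_displacement=float(
                        sim.get("max_displacement_um",
                                5.0 * np.sqrt(4 * simcfg.d_free * frame_interval))
                    ),
                    memory_frames=int(sim.get("memory_frames", 0)),
                )
                table = link_trajectories(locs, link)
    elif mode == "spt_from_csv":
        inputs = dict(_require(config, "inputs"))
        with _stage("load"):
            table = mio.read_trajectories(_require(inputs, "trajectories_csv", "inputs"))
            frame_interval = float(_require(inputs, "frame_interval_s", "inputs"))
            frame_rate = 1.0 / frame_interval
    else:  # spt_from_movie
        inputs = dict(_require(config, "inputs"))
        with _stage("track"):
            movie = mio.read_movie(
                _require(inputs, "movie_tif", "inputs"),
                frame_interval=inputs.get("frame_interval_s"),
            )
            frame_interval = movie.frame_interval
            frame_rate = 1.0 / frame_interval
            locs = locate_movie(movie)
            track = dict(config.get("tracking", {}))
            link = LinkConfig(
                max_displacement=float(_require(track, "max_displacement_um", "tracking")),
                memory_frames=int(track.get("memory_frames", 0)),
            )
            table = link_trajectories(locs, link)

    with _stage("filter"):
        min_frames = analysis.get("min_frames")
        table = filter_trajectories(
            table,
            frame_rate=frame_rate,
            min_frames=int(min_frames) if min_frames is not None else None,
        )
        mio.write_trajectories(out / "trajectories.csv", table)
        report["n_trajectories"] = int(
            table.groupby(["movie_id", "traj_id"]).ngroups
        )
        if report["n_trajectories"] == 0:
            raise RuntimeError("no trajectories survive the length filter")

    with _stage("msd"):
        n_max = int(analysis.get("n_max", 100))
        positions = [pos for _, _, pos in iter_table_trajectories(table)]
        curve = pooled_msd(positions, frame_interval, n_max)
        curve.to_frame().to_csv(out / "msd.csv", index=False)
        plot_msd(curve, out / "msd.png")

    with _stage("d_curve"):
        dcurve = build_d_curve(curve, source_rate=frame_rate)
        dcurve.to_frame().to_csv(out / "dcurve.csv", index=False)
        d_short = float(dcurve.d_values[min(3, len(dcurve) - 1)])
        d_long = float(dcurve.d_values[-1])
        report["d_short_um2_s"] = d_short
        report["d_long_um2_s"] = d_long

    inflections = None
    infl_cfg = analysis.get("inflection")
    if infl_cfg:
        with _stage("inflections"):
            if infl_cfg.get("segments"):
                inflections = detect_inflections(
                    dcurve, segment_ranges=[tuple(s) for s in infl_cfg["segments"]]
                )
                payload = inflections.to_dict()
            elif infl_cfg.get("windows"):
                inflections = detect_inflections(
                    dcurve, windows=[tuple(w) for w in infl_cfg["windows"]]
                )
                payload = inflections.to_dict()
            else:  # single automatic transition over the whole curve
                p = find_inflection(dcurve, window=infl_cfg.get("window"))
                payload = {
                    "p1": {"tau_s": p.tau, "d_um2_s": round(p.d, 2)},
                    "l1_nm": p.length_nm,
                }
                if truth is not None and "free_region_size_nm" in truth:
                    payload["truth_free_region_size_nm"] = truth["free_region_size_nm"]
            mio.write_json(out / "inflections.json", payload)
            report["inflections"] = payload
    plot_d_curve(dcurve, out / "dcurve.png", inflections)

    if truth is not None:
        report["truth"] = truth
        report["d_short_rel_error"] = abs(d_short - truth["d_free_um2_s"]) / truth[
            "d_free_um2_s"
        ]
    report["frame_rate_fps"] = frame_rate
    mio.write_json(out / "report.json", report)
    _write_text_report(out / "report.txt", report)
    return report


# ---------------------------------------------------------------------------
# AFM study


def _pooled_stats(per_image: list[DomainStats], total_area_um2: float) -> DomainStats:
    """Pool per-image stats into one DomainStats over all domains/images."""
    n_total = sum(s.n_domains for s in per_image)
    depths = np.concatenate([s.depths for s in per_image]) if n_total else np.empty(0)
    diams = np.concatenate([s.diameters for s in per_image]) if n_total else np.empty(0)
    fraction = float(np.mean([s.area_fraction for s in per_image]))
    return DomainStats(
        n_domains=n_total,
        mean_depth=float(np.mean(depths)) if n_total else float("nan"),
        mean_equiv_diameter=float(np.mean(diams)) if n_total else float("nan"),
        area_fraction=fraction,
        number_density=n_total / total_area_um2 if total_area_um2 > 0 else 0.0,
        depths=depths,
        diameters=diams,
    )


def run_afm_study(config: dict) -> dict:
    """Run one AFM morphometry study; returns the report dict.

    Modes: ``afm_sim`` (generate ``afm.n_images`` synthetic topographies)
    and ``afm_from_image`` (flatten + segment files listed under
    ``inputs.topographies``). Per-image and aggregate statistics (mean ± SD
    across images, pooled per-domain means, free-size estimates under both
    conventions) are written to report.json.
    """
    mode = _require(config, "mode")
    if mode not in AFM_MODES:
        raise ConfigError(f"unknown AFM mode {mode!r}; expected one of {sorted(AFM_MODES)}")
    out = _outdir(config)
    afm_cfg = dict(config.get("afm", {}))
    depth_threshold = float(afm_cfg.get("depth_threshold_nm", 0.7))
    expected_depth = float(afm_cfg.get("domain_depth_mean", 1.4))

    topos = []
    if mode == "afm_sim":
        seed = int(_require(config, "seed"))
        n_images = int(afm_cfg.get("n_images", 9))
        base = {
            k: afm_cfg[k]
            for k in (
                "image_size",
                "pixel_size",
                "domain_fraction",
                "domain_diameter_mean",
                "domain_diameter_sd",
                "domain_depth_mean",
                "domain_depth_sd",
                "noise_sigma",
                "line_offset_sigma",
            )
            if k in afm_cfg
        }
        if "tilt" in afm_cfg:
            base["tilt"] = tuple(afm_cfg["tilt"])
        with _stage("generate"):
            for i in range(n_images):
                cfg_i = TopoSimConfig(seed=(seed * 1000 + i) % 2**31, **base)
                topo, gt = generate_topography(cfg_i)
                topos.append(topo)
            if afm_cfg.get("save_images", False):
                for i, topo in enumerate(topos):
                    mio.write_topography(out / f"topo_{i:02d}.tif", topo)
            report_cfg = asdict(TopoSimConfig(seed=seed, **base))
    else:
        inputs = dict(_require(config, "inputs"))
        paths = _require(inputs, "topographies", "inputs")
        if isinstance(paths, (str, Path)):
            paths = [paths]
        with _stage("load"):
            for p in paths:
                topos.append(mio.read_topography(p, inputs.get("pixel_size_nm")))
            report_cfg = {"topographies": [str(p) for p in paths]}

    per_image: list[DomainStats] = []
    with _stage("flatten+segment"):
        for i, topo in enumerate(topos):
            flat = flatten_topography(topo, expected_depth=expected_depth)
            labels = segment_domains(flat, depth_threshold=depth_threshold)
            per_image.append(compute_domain_stats(flat, labels))
            if i == 0:
                plot_topography(flat, out / "topography.png", labels)

    with _stage("aggregate"):
        total_area = sum(t.image_area_um2 for t in topos)
        pooled = _pooled_stats(per_image, total_area)
        fractions = [s.area_fraction for s in per_image]
        img_depths = [s.mean_depth for s in per_image if s.n_domains]
        img_diams = [s.mean_equiv_diameter for s in per_image if s.n_domains]
        aggregate = {
            "n_images": len(topos),
            "n_domains_total": pooled.n_domains,
            "area_fraction_mean": float(np.mean(fractions)),
            "area_fraction_sd": float(np.std(fractions, ddof=1)) if len(fractions) > 1 else 0.0,
            "mean_depth_nm_mean": float(np.mean(img_depths)) if img_depths else None,
            "mean_depth_nm_sd": float(np.std(img_depths, ddof=1)) if len(img_depths) > 1 else 0.0,
            "mean_diameter_nm_mean": float(np.mean(img_diams)) if img_diams else None,
            "mean_diameter_nm_sd": float(np.std(img_diams, ddof=1)) if len(img_diams) > 1 else 0.0,
            "per_domain": {
                "mean_depth_nm": None if pooled.n_domains == 0 else float(pooled.mean_depth),
                "mean_diameter_nm": None if pooled.n_domains == 0 else float(pooled.mean_equiv_diameter),
            },
            "number_density_per_um2": pooled.number_density,
        }
        if pooled.n_domains:
            for conv in ("equivalent_free_circle", "lattice_gap"):
                est = domain_free_size(pooled, convention=conv)
                aggregate[f"free_size_nm_{conv}"] = float(est.l_free)
        report = {
            "mode": mode,
            "config": report_cfg,
            "per_image": [s.to_dict() for s in per_image],
            "aggregate": aggregate,
        }
    mio.write_json(out / "report.json", report)
    _write_text_report(out / "report.txt", report)
    return report


def _write_text_report(path: Path, report: dict, indent: int = 0) -> None:
    lines: list[str] = []

    def walk(obj: object, depth: int) -> None:
        pad = "  " * depth
        if isinstance(obj, dict):
            for k, v in obj.items():
                if isinstance(v, (dict, list)):
                    lines.append(f"{pad}{k}:")
                    walk(v, depth + 1)
                else:
                    lines.append(f"{pad}{k}: {v}")
        elif isinstance(obj, list):
            for i, v in enumerate(obj):
                lines.append(f"{pad}- [{i}]")
                walk(v, depth + 1)
        else:
            lines.append(f"{pad}{obj}")

    walk(report, indent)
    path.write_text("\n".join(lines) + "\n")
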