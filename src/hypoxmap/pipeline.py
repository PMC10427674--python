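"""End-to-end orchestration: simulate/load -> demux -> register -> correct ->
invert -> normalise -> connectivity -> statistics, plus summary figures.

The stage order follows the analysis chain of the imaging protocol:
co-registration, hemodynamic correction of the fluorescence channel,
Beer-Lambert hemodynamic signals, dF/F normalisation, global signal
regression (seed-pixel maps only), ROI extraction and statistics.  Every
run writes a manifest (seed, config hash, per-stage status, artifact
checksums) so a rerun with the same configuration and seed is verifiable
bit for bit on the CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import fluorescence as fluo
from .acquisition import demultiplex, read_acquisition, register_within
from .hemodynamics import (
    OpticalModel,
    beer_lambert_invert,
    make_brain_mask,
    quantify_epoch_dynamics,
)
from .synthetic import ScenarioConfig, simulate_scenario

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_figures"]

STAGES = (
    "acquire",
    "demultiplex",
    "register",
    "hemodynamic_correction",
    "hemodynamic_signals",
    "normalization",
    "connectivity",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``input_path`` points at an acquisition fixture on disk or
    ``scenario`` describes a simulation to run in place of real data.
    Analysis windows are in minutes, mirroring the protocol's phrasing;
    they are converted to half-open frame intervals by flooring
    start*60*fps.  ``transition_margin_s`` trims the manually switched
    gas transitions out of the epoch windows.
    """

    output_dir: str | Path = "hypoxmap_run"
    input_path: str | Path | None = None
    scenario: ScenarioConfig | None = None
    registration: bool = False
    diffeomorphic: bool = False
    gsr_for_maps: bool = True
    hypoxia_window_min: tuple[float, float] = conn.HYPOXIA_WINDOW_MIN
    normoxia_window_min: tuple[float, float] = conn.NORMOXIA_WINDOW_MIN
    epoch_windows_min: dict = field(default_factory=dict)
    transition_margin_s: float = 30.0
    edge_margin_px: int = 5
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_path is None and self.scenario is None:
            self.scenario = ScenarioConfig(rng_seed=self.rng_seed)
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(f"input path {self.input_path} does not exist")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["input_path"] = None if self.input_path is None else str(self.input_path)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        scenario = raw.pop("scenario", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "scenario"})
        if scenario is not None:
            if "epoch_timeline" in scenario:
                scenario["epoch_timeline"] = [tuple(e) for e in scenario["epoch_timeline"]]
            for k in ("image_shape", "fov_mm"):
                if k in scenario:
                    scenario[k] = tuple(scenario[k])
            cfg.scenario = ScenarioConfig(**scenario)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.rng_seed,
        "stages": {},
        "artifacts": {},
    }
    stage = "acquire"
    try:
        truth = None
        if config.input_path is not None:
            stack = read_acquisition(config.input_path)
        else:
            stack, truth = simulate_scenario(config.scenario)
        timeline = stack.metadata.get("epoch_timeline") or [
            [lab, s, e] for lab, s, e in config.scenario.epoch_timeline
        ]
        manifest["stages"][stage] = "complete"

        stage = "demultiplex"
        channels = demultiplex(stack)
        fps = channels["blue"].fps
        manifest["stages"][stage] = "complete"

        stage = "register"
        if config.registration:
            registered = {}
            for name, ch in channels.items():
                reg_ch, reg_res = register_within(ch, diffeomorphic=config.diffeomorphic)
                registered[name] = reg_ch
                reg_res.to_frame().to_csv(out / f"registration_{name}.csv", index=False)
            channels = registered
            manifest["stages"][stage] = "complete"
        else:
            manifest["stages"][stage] = "skipped"

        if truth is not None:
            atlas, regions = truth.atlas, truth.regions
        else:
            import tifffile

            atlas = tifffile.imread(Path(config.input_path) / "atlas.tif")
            regions = pd.read_csv(Path(config.input_path) / "regions.csv")
        brain_mask = make_brain_mask(atlas, edge_margin_px=config.edge_margin_px)

        stage = "hemodynamic_correction"
        reflectance = {k: channels[k] for k in ("green", "amber", "red")}
        corrected, coeffs = fluo.hemodynamic_correction(
            channels["blue"], reflectance, mask=brain_mask
        )
        manifest["stages"][stage] = "complete"

        stage = "hemodynamic_signals"
        optical = OpticalModel()
        baseline_end = next(
            (float(e) for lab, s, e in timeline if lab == "normoxia"), 600.0
        )
        hemo = beer_lambert_invert(
            reflectance, optical, brain_mask=brain_mask,
            baseline_window_s=(0.0, baseline_end),
        )
        hemo_summary = quantify_epoch_dynamics(
            {"s1": hemo.whole_brain_mean("hbr")}, fps,
            windows_min=config.epoch_windows_min or None,
        ) if _windows_fit(config, len(corrected), fps) else None
        with h5py.File(out / "hemo_maps.h5", "w") as f:
            f.create_dataset("hbo", data=hemo.delta_hbo, compression="gzip")
            f.create_dataset("hbr", data=hemo.delta_hbr, compression="gzip")
            f.create_dataset("so2", data=hemo.so2.astype(np.float32), compression="gzip")
            f.create_dataset("mask", data=hemo.brain_mask)
        manifest["stages"][stage] = "complete"

        stage = "normalization"
        fmaps = fluo.compute_dff(corrected, fps, brain_mask=brain_mask)
        manifest["stages"][stage] = "complete"

        stage = "connectivity"
        seeds = conn.extract_seeds(regions, fmaps.brain_mask & hemo.brain_mask)
        results = _connectivity_outputs(config, fmaps, hemo, seeds, fps, out)
        manifest["stages"][stage] = "complete"

        # tidy whole-brain traces
        traces = pd.DataFrame(
            {
                "time_s": np.arange(len(corrected)) / fps,
                "hbo_uM": hemo.whole_brain_mean("hbo"),
                "hbr_uM": hemo.whole_brain_mean("hbr"),
                "hbt_uM": hemo.whole_brain_mean("hbt"),
                "so2": hemo.whole_brain_mean("so2"),
            }
        )
        traces.to_csv(out / "whole_brain_traces.csv", index=False)
        if hemo_summary is not None:
            hemo_summary.per_subject.to_csv(out / "hemo_epoch_summary.csv")

        for f_ in sorted(out.glob("*.csv")):
            manifest["artifacts"][f_.name] = _sha256(f_)
        manifest["windows"] = {
            "hypoxia_min": list(config.hypoxia_window_min),
            "normoxia_min": list(config.normoxia_window_min),
        }
        manifest["n_seeds"] = len(seeds)
        manifest.update(results)
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _windows_fit(config: RunConfig, n_frames: int, fps: float) -> bool:
    last = max(w[1] for w in (
        (4.5, 9.5), (14.5, 19.5), (10.0, 11.0), (20.0, 21.0),
        config.hypoxia_window_min, config.normoxia_window_min,
    ))
    return last * 60.0 * fps <= n_frames


def _connectivity_outputs(config, fmaps, hemo, seeds, fps, out: Path) -> dict:
    """Connectivity matrices for both modalities; GSR-ed seed maps if enabled."""
    results: dict = {}
    n_frames = len(fmaps.dff)
    windows_ok = (
        max(config.hypoxia_window_min[1], config.normoxia_window_min[1]) * 60 * fps <= n_frames
    )
    if not windows_ok:
        logger.warning("analysis windows exceed acquisition; connectivity skipped")
        results["connectivity"] = "skipped (acquisition too short)"
        return results

    rows = []
    for modality, maps in (("gcamp", fmaps.dff), ("hbo", hemo.delta_hbo)):
        for label, window in (
            ("hypoxia", config.hypoxia_window_min),
            ("normoxia", config.normoxia_window_min),
        ):
            cm = conn.connectivity_matrix(maps, seeds, fps, window, modality=modality)
            cm.to_frame().to_csv(out / f"connectivity_{modality}_{label}.csv")
            for i, j in seeds.pairs():
                rows.append(
                    {
                        "modality": modality,
                        "window": label,
                        "seed_a": seeds.names[i],
                        "seed_b": seeds.names[j],
                        "kind": seeds.pair_kind(i, j),
                        "r": cm.r[i, j],
                        "z": cm.z[i, j],
                    }
                )
    pd.DataFrame.from_records(rows).to_csv(out / "seed_pairs.csv", index=False)

    if config.gsr_for_maps:
        import tifffile

        maps_gsr = []
        for seed in list(seeds)[:2]:  # representative seed maps
            m = conn.seed_pixel_correlation_map(
                fmaps.dff, seed, fmaps.brain_mask, fps,
                window_min=config.hypoxia_window_min, gsr=True,
            )
            maps_gsr.append(m.astype(np.float32))
        tifffile.imwrite(out / "seed_correlation_maps_gsr.tif", np.stack(maps_gsr))
    return results


# ---------------------------------------------------------------------------
# figures


def make_figures(manifest: dict, output_dir: str | Path | None = None) -> list[Path]:
    """Render the figure families from a completed run's artifacts.

    Produces whole-brain hemodynamic traces with epoch shading, connectivity
    matrix heatmaps per modality/window, and within/between-cluster Delta-z
    boxplots when the contrast exists.  Missing artifacts skip that family
    with a log message.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir or manifest["config"]["output_dir"])
    made: list[Path] = []

    traces_csv = out / "whole_brain_traces.csv"
    if traces_csv.exists():
        df = pd.read_csv(traces_csv)
        fig, ax = plt.subplots(figsize=(8, 4))
        for col, color in (("hbo_uM", "tab:red"), ("hbr_uM", "tab:blue"), ("hbt_uM", "tab:green")):
            ax.plot(df["time_s"] / 60.0, df[col], label=col.replace("_uM", ""), color=color)
        timeline = manifest["config"].get("scenario", {}) or {}
        for lab, s, e in (timeline.get("epoch_timeline") or []):
            if lab == "hypoxia":
                ax.axvspan(s / 60.0, e / 60.0, color="grey", alpha=0.25)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("concentration change (µM)")
        ax.legend()
        fig.tight_layout()
        p = out / "fig_whole_brain_traces.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    else:
        logger.info("no whole-brain traces; skipping trace figure")

    mats = sorted(out.glob("connectivity_*.csv"))
    if mats:
        fig, axes = plt.subplots(1, len(mats), figsize=(4 * len(mats), 4))
        axes = np.atleast_1d(axes)
        for ax, path in zip(axes, mats):
            m = pd.read_csv(path, index_col=0)
            im = ax.imshow(m.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
            ax.set_title(path.stem.replace("connectivity_", ""))
            ax.set_xticks(range(len(m)), m.columns, rotation=90, fontsize=6)
            ax.set_yticks(range(len(m)), m.index, fontsize=6)
        fig.colorbar(im, ax=axes, shrink=0.7, label="Pearson r")
        p = out / "fig_connectivity_matrices.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    else:
        logger.info("no connectivity matrices; skipping heatmaps")

    maps_tif = out / "seed_correlation_maps_gsr.tif"
    if maps_tif.exists():
        import tifffile

        arr = tifffile.imread(maps_tif)
        arr = np.atleast_3d(arr if arr.ndim == 3 else arr[None])
        fig, axes = plt.subplots(1, len(arr), figsize=(4 * len(arr), 4))
        for ax, m in zip(np.atleast_1d(axes), arr):
            im = ax.imshow(m, vmin=-1, vmax=1, cmap="RdBu_r")
            ax.axis("off")
        fig.colorbar(im, ax=axes, shrink=0.7, label="Pearson r")
        p = out / "fig_seed_correlation_maps.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    return made
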