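"""Run configuration, preset filling, manifests and experiment dispatch.

Configs are plain YAML with units spelled out in the key names
(``delay_ms``, ``mean_pps``, ``dt_ms``) because the model mixes
milliseconds, seconds and pulses per second.  An empty config is valid
and yields the defaults: the LB column pair, K = 0, a 16 s trial.
Every run writes a manifest next to its outputs listing the effective
configuration, the seeds and every file produced, so each result can be
reproduced byte-for-byte from its manifest.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import CouplingSpec, SimulationSpec, integrate
from .experiments import (
    K_PRESETS,
    classify_regions,
    erd_ers_map,
    k_sweep,
    run_trial_protocol,
)
from .model import available_bands
from .stimuli import ModulatingInputSpec, NoiseSpec, StimulusSpec

__all__ = ["ConfigError", "RunConfig", "RunManifest", "load_config", "save_config", "run"]

_EXPERIMENTS = ("simulate", "sweep", "regions", "trial", "map")


class ConfigError(ValueError):
    """Raised for invalid or inconsistent run configurations."""


@dataclass
class RunConfig:
    band: str = "LB"
    experiment: str = "simulate"
    master_seed: int = 0
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    sim: SimulationSpec = field(default_factory=SimulationSpec)
    n_trials: int = 5
    K_grid: list[float] | None = None
    out_dir: str = "callosim-out"
    full: bool = False

    def __post_init__(self) -> None:
        if self.band not in available_bands():
            raise ConfigError(
                f"unknown band label {self.band!r}; expected one of "
                f"{sorted(available_bands())}"
            )
        if self.experiment not in _EXPERIMENTS:
            raise ConfigError(
                f"unknown experiment {self.experiment!r}; expected one of {_EXPERIMENTS}"
            )
        if self.n_trials < 1:
            raise ConfigError("n_trials must be at least 1")


def _config_dict(cfg: RunConfig) -> dict:
    mod = cfg.stimulus.modulation
    return {
        "band": cfg.band,
        "experiment": cfg.experiment,
        "master_seed": cfg.master_seed,
        "out_dir": cfg.out_dir,
        "coupling": {
            "K": cfg.coupling.K,
            "split_p": cfg.coupling.split_p,
            "split_f": cfg.coupling.split_f,
            "delay_ms": round(cfg.coupling.delay_s * 1e3, 9),
        },
        "noise_pyramidal": {
            "mean_pps": cfg.stimulus.noise_p.mean,
            "sd_pps": cfg.stimulus.noise_p.sd,
        },
        "noise_fast": {
            "mean_pps": cfg.stimulus.noise_f.mean,
            "sd_pps": cfg.stimulus.noise_f.sd,
        },
        "modulation": (
            None
            if mod is None
            else {
                "baseline_s": mod.baseline_s,
                "rise_s": mod.rise_s,
                "plateau_s": mod.plateau_s,
                "plateau_amp_pps": mod.plateau_amp,
                "fall_s": mod.fall_s,
                "rest_s": mod.rest_s,
                "target_column": mod.target_column,
            }
        ),
        "simulation": {
            "duration_s": cfg.sim.duration_s,
            "dt_ms": round(cfg.sim.dt_s * 1e3, 9),
            "fs_out_hz": cfg.sim.fs_out,
            "warmup_s": cfg.sim.warmup_s,
            "noise_scaling": cfg.sim.noise_scaling,
        },
        "experiment_options": {
            "n_trials": cfg.n_trials,
            "K_grid": cfg.K_grid,
            "full": cfg.full,
        },
    }


def _from_dict(doc: dict | None) -> RunConfig:
    doc = doc or {}
    try:
        coup = doc.get("coupling", {}) or {}
        coupling = CouplingSpec(
            K=float(coup.get("K", 0.0)),
            split_p=float(coup.get("split_p", 0.3)),
            split_f=float(coup.get("split_f", 0.7)),
            delay_s=float(coup.get("delay_ms", 13.0)) * 1e-3,
        )
        np_doc = doc.get("noise_pyramidal", {}) or {}
        nf_doc = doc.get("noise_fast", {}) or {}
        noise_p = NoiseSpec(
            mean=float(np_doc.get("mean_pps", 40.0)),
            sd=float(np_doc.get("sd_pps", 1.0)),
            target="pyramidal",
        )
        noise_f = NoiseSpec(
            mean=float(nf_doc.get("mean_pps", 3.0)),
            sd=float(nf_doc.get("sd_pps", 1.0)),
            target="fast",
        )
        mod_doc = doc.get("modulation")
        modulation = (
            None
            if mod_doc is None
            else ModulatingInputSpec(
                baseline_s=float(mod_doc.get("baseline_s", 4.0)),
                rise_s=float(mod_doc.get("rise_s", 2.0)),
                plateau_s=float(mod_doc.get("plateau_s", 4.0)),
                plateau_amp=float(mod_doc.get("plateau_amp_pps", 100.0)),
                fall_s=float(mod_doc.get("fall_s", 2.0)),
                rest_s=float(mod_doc.get("rest_s", 4.0)),
                target_column=mod_doc.get("target_column", "left"),
            )
        )
        sim_doc = doc.get("simulation", {}) or {}
        sim = SimulationSpec(
            duration_s=float(sim_doc.get("duration_s", 16.0)),
            dt_s=float(sim_doc.get("dt_ms", 0.1)) * 1e-3,
            fs_out=float(sim_doc.get("fs_out_hz", 100.0)),
            warmup_s=float(sim_doc.get("warmup_s", 2.0)),
            master_seed=int(doc.get("master_seed", 0)),
            noise_scaling=sim_doc.get("noise_scaling", "intensity"),
        )
        opts = doc.get("experiment_options", {}) or {}
        return RunConfig(
            band=doc.get("band", "LB"),
            experiment=doc.get("experiment", "simulate"),
            master_seed=int(doc.get("master_seed", 0)),
            coupling=coupling,
            stimulus=StimulusSpec(noise_p=noise_p, noise_f=noise_f, modulation=modulation),
            sim=sim,
            n_trials=int(opts.get("n_trials", 5)),
            K_grid=opts.get("K_grid"),
            out_dir=doc.get("out_dir", "callosim-out"),
            full=bool(opts.get("full", False)),
        )
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys fall back to the Table-style defaults; validation
    failures raise ``ConfigError`` with a descriptive message.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is not None and not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    return _from_dict(doc)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(cfg), fh, sort_keys=False)


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: list[str]
    seeds: dict
    wall_time_s: float

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "callosim_version": self.version,
                    "wall_time_s": round(self.wall_time_s, 3),
                    "seeds": self.seeds,
                    "outputs": self.outputs,
                    "config": self.config,
                },
                fh,
                sort_keys=False,
            )


def _write_tsv(frame: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def run(cfg: RunConfig) -> RunManifest:
    """Dispatch the configured experiment and write outputs + manifest."""
    t0 = time.perf_counter()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    seeds: dict = {"master_seed": cfg.master_seed}
    band = cfg.band

    if cfg.experiment == "simulate":
        ncols = 2 if cfg.coupling.K > 0 or cfg.stimulus.modulation is not None else 1
        columns = (band, band) if ncols == 2 else band
        tr = integrate(columns, cfg.coupling, cfg.stimulus, cfg.sim)
        names = ["left", "right"][: tr.n_columns]
        frame = pd.DataFrame({"time_s": tr.time})
        for i, nm in enumerate(names):
            frame[f"v_out_{nm}_mv"] = tr.v_out[:, i]
            for rate in ("zp", "ze", "zs", "zf"):
                frame[f"{rate}_{nm}_pps"] = getattr(tr, rate)[:, i]
        path = out / f"trial_{band}_K{cfg.coupling.K:g}.tsv"
        _write_tsv(
            frame,
            path,
            [
                f"band={band} K={cfg.coupling.K:g} seed={cfg.master_seed}",
                f"fs_out={cfg.sim.fs_out:g} Hz duration={cfg.sim.duration_s:g} s",
            ],
        )
        outputs.append(str(path))
        seeds["stream_seeds"] = list(tr.stream_seeds)

    elif cfg.experiment in ("sweep", "regions"):
        if cfg.K_grid is not None:
            grid = np.asarray(cfg.K_grid, dtype=float)
        else:
            grid = np.arange(0.0, 101.0, 1.0 if cfg.full else 2.0)
        n_trials = 20 if cfg.full and cfg.K_grid is None else cfg.n_trials
        sweep = k_sweep(
            band, grid, cfg.sim, n_trials, cfg.coupling, cfg.stimulus
        )
        frame = pd.DataFrame(
            {
                "K": sweep.K_grid,
                "mean_zp_loser_pps": sweep.loser_zp,
                "mean_zp_winner_pps": sweep.winner_zp,
            }
        )
        path = out / f"sweep_{band}.tsv"
        _write_tsv(
            frame,
            path,
            [f"band={band} n_trials={n_trials} master_seed={cfg.master_seed}"],
        )
        outputs.append(str(path))
        if cfg.experiment == "regions":
            reg = classify_regions(sweep)
            rpath = out / f"regions_{band}.yaml"
            with open(rpath, "w") as fh:
                yaml.safe_dump(
                    {
                        "band": reg.band,
                        "k_12": reg.k_12,
                        "k_23": reg.k_23,
                        "open_12": reg.open_12,
                        "open_23": reg.open_23,
                    },
                    fh,
                )
            outputs.append(str(rpath))

    elif cfg.experiment == "trial":
        stim = cfg.stimulus
        if stim.modulation is None:
            stim = StimulusSpec(stim.noise_p, stim.noise_f, ModulatingInputSpec())
        K = cfg.coupling.K if cfg.coupling.K > 0 else K_PRESETS[band][0]
        res = run_trial_protocol(
            band, K, cfg.n_trials, cfg.sim, coupling=cfg.coupling, stimuli=stim
        )
        frame = pd.DataFrame(
            {
                "time_s": res.left.times,
                "erd_ers_left_pct": res.left.percent,
                "erd_ers_right_pct": res.right.percent,
            }
        )
        path = out / f"erd_ers_{band}_K{K:g}.tsv"
        _write_tsv(
            frame,
            path,
            [
                f"band={band} K={K:g} n_trials={cfg.n_trials} "
                f"master_seed={cfg.master_seed}",
                f"band_limits={res.left.band.f_lo:g}-{res.left.band.f_hi:g} Hz "
                f"window=1 s hop=0.01 s",
            ],
        )
        outputs.append(str(path))

    elif cfg.experiment == "map":
        stim = cfg.stimulus
        if stim.modulation is None:
            stim = StimulusSpec(stim.noise_p, stim.noise_f, ModulatingInputSpec())
        grid = (
            np.asarray(cfg.K_grid, dtype=float)
            if cfg.K_grid is not None
            else np.arange(0.0, 29.0, 2.0 if cfg.full else 4.0)
        )
        res = erd_ers_map(
            band, grid, cfg.n_trials, cfg.sim, coupling=cfg.coupling, stimuli=stim
        )
        for i, nm in enumerate(("left", "right")):
            frame = pd.DataFrame(
                res.percent[:, :, i], index=res.K_grid, columns=res.times
            )
            frame.index.name = "K"
            path = out / f"erd_ers_map_{band}_{nm}.tsv"
            with open(path, "w") as fh:
                fh.write(
                    f"# band={band} column={nm} n_trials={cfg.n_trials} "
                    f"master_seed={cfg.master_seed}\n"
                    "# rows: K, columns: window-centre time (s)\n"
                )
                frame.to_csv(fh, sep="\t", float_format="%.6g")
            outputs.append(str(path))

    manifest = RunManifest(
        config=_config_dict(cfg),
        version=__version__,
        outputs=outputs,
        seeds=seeds,
        wall_time_s=time.perf_counter() - t0,
    )
    manifest.write(out / f"manifest_{cfg.experiment}_{band}.yaml")
    return manifest
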