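"""Configuration and headless end-to-end pipeline.

A single config (YAML/JSON-friendly dict) declares the cell geometry, the
constitutive and kinetic parameters, the NMR acquisition settings and every
noise seed; ``run_pipeline`` then chains the stages in dependency order —

    fixtures -> lfc -> fit-hb -> fit-skm      (rheology chain)
    fixtures -> droplet-size                   (PFG sizing chain)
    fixtures -> dt2-map                        (relaxometry chain)

— reading and writing only the CSV/JSON schemas of :mod:`rheonmr.io`, and
emits a manifest recording the config hash and each stage's inputs and
outputs. Every random operation must carry an explicit seed; a noise block
without one is rejected so reruns are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as rio
from .dropletsize import fit_droplet_size, growth_ratio, PFGDecay
from .dt2 import ilt2d
from .flowcurve import fit_hb_global_n
from .kinetics import fit_skm
from .params import CouetteGeometry, HBParams, NoiseSpec, PGSEParams, SKMParams
from .synthetic import (
    couette_forward_solve,
    dt2_signal,
    noisy_profile,
    pfg_decay_lognormal,
    skm_series,
)
from .velocimetry import assemble_lfc, VelocityProfile

#: Known stages in dependency order.
STAGES = ("fixtures", "lfc", "fit-hb", "fit-skm", "droplet-size", "dt2-map")


def default_config() -> dict:
    """A complete seeded configuration emulating a full shear-treatment study."""
    return {
        "geometry": {"inner_radius": 10.0e-3, "outer_radius": 11.0e-3,
                     "height": 40.0e-3},
        "hb": {"consistency": 30.0, "flow_index": 0.47},
        "skm": {"tau00": 80.1, "tau0e": 44.0, "ks": 0.012},
        "applied_rate": 5.0,
        "times_min": [0.0, 20.0, 50.0, 100.0, 200.0, 350.0, 500.0],
        "n_profile_points": 21,
        "profile_noise": {"kind": "additive-gaussian", "sigma_rel": 0.01, "seed": 101},
        "mask_gamma_min": 0.05,
        "droplet": {
            "before": {"d33_um": 3.39, "alpha": 0.20},
            "after": {"d33_um": 4.30, "alpha": 0.40},
            "d_oil": 4e-12,
            "pgse": {"delta": 2e-3, "Delta": 0.211, "g_min": 0.05, "g_max": 3.0,
                     "n_steps": 32},
            "noise": {"kind": "additive-gaussian", "sigma": 0.005, "seed": 202},
        },
        "dt2": {
            "components": [[0.4, 9e-10, 0.15], [0.6, 4e-12, 0.08]],
            "pgse": {"delta": 1e-3, "Delta": 0.2, "g_min": 0.1, "g_max": 6.6,
                     "n_steps": 32},
            "echo_spacing": 2.2e-3,
            "n_echoes": 256,
            "noise": {"kind": "additive-gaussian", "sigma_rel": 0.002, "seed": 303},
            "n_d_grid": 64,
            "n_t2_grid": 64,
            "reg_weight": "auto",
        },
    }


def _check_seeds(node, path="config"):
    if isinstance(node, dict):
        if "sigma" in node or "sigma_rel" in node or "kind" in node:
            if "seed" in node:
                pass
            else:
                raise ValueError(f"{path}: noise block without an explicit seed")
        for key, value in node.items():
            _check_seeds(value, f"{path}.{key}")
    elif isinstance(node, list):
        for i, value in enumerate(node):
            _check_seeds(value, f"{path}[{i}]")


def _pgse_from(block: dict) -> PGSEParams:
    g = np.linspace(block["g_min"], block["g_max"], block["n_steps"])
    return PGSEParams(gradient_strengths=tuple(g),
                      gradient_duration=block["delta"],
                      diffusion_time=block["Delta"])


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration; keeps the raw dict for hashing."""

    raw: dict
    geometry: CouetteGeometry
    skm: SKMParams

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        _check_seeds(raw)
        geo = CouetteGeometry(**raw["geometry"])
        skm = SKMParams(**raw["skm"])
        return cls(raw=raw, geometry=geo, skm=skm)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "stages": self.stages,
            "started": self.started,
            "finished": self.finished,
        }


def _stage_fixtures(cfg: dict, out: Path) -> dict:
    geo = CouetteGeometry(**cfg["geometry"])
    skm = SKMParams(**cfg["skm"])
    times = cfg["times_min"]
    rotor = geo.rotor_rate_for_applied_shear(cfg["applied_rate"])
    noise_cfg = cfg["profile_noise"]
    outputs = []
    torques = []
    for i, t in enumerate(times):
        tau0_t = float(skm.tau0(t))
        hb = HBParams(tau0_t, cfg["hb"]["consistency"], cfg["hb"]["flow_index"])
        sol = couette_forward_solve(geo, hb, rotor, n_points=cfg["n_profile_points"])
        profile = VelocityProfile(r=sol.profile.r, v=sol.profile.v, time_stamp=t,
                                  applied_rate=sol.profile.applied_rate)
        sigma_abs = noise_cfg.get("sigma_rel", 0.0) * np.abs(profile.v).max()
        spec = NoiseSpec(kind=noise_cfg["kind"], sigma=sigma_abs,
                         seed=noise_cfg["seed"] + i)
        profile = noisy_profile(profile, spec)
        path = out / f"profile_{i:02d}.csv"
        rio.write_profile_csv(path, profile)
        outputs.append(str(path))
        torques.append(sol.torque)
    rio.write_torque_csv(out / "torque.csv", times, torques)
    outputs.append(str(out / "torque.csv"))

    # PFG droplet decays, before and after shear treatment
    drop = cfg["droplet"]
    pgse_d = _pgse_from(drop["pgse"])
    for label in ("before", "after"):
        E = pfg_decay_lognormal(drop[label]["d33_um"], drop[label]["alpha"],
                                drop["d_oil"], pgse_d)
        spec = NoiseSpec(kind=drop["noise"]["kind"], sigma=drop["noise"]["sigma"],
                         seed=drop["noise"]["seed"] + (0 if label == "before" else 1))
        E = np.clip(spec.apply(E), 1e-6, None)
        path = out / f"decay_{label}.csv"
        rio.write_decay_csv(path, PFGDecay(pgse_d.g, E))
        outputs.append(str(path))

    # D-T2 surface
    d2 = cfg["dt2"]
    pgse_2 = _pgse_from(d2["pgse"])
    echo_times = d2["echo_spacing"] * np.arange(1, d2["n_echoes"] + 1)
    clean = dt2_signal(d2["components"], pgse_2, echo_times)
    sigma_abs = d2["noise"].get("sigma_rel", 0.0) * clean.signal.max()
    spec = NoiseSpec(kind=d2["noise"]["kind"], sigma=sigma_abs,
                     seed=d2["noise"]["seed"])
    noisy = dt2_signal(d2["components"], pgse_2, echo_times, noise=spec)
    rio.write_dt2_csv(out / "dt2_surface", noisy)
    outputs.append(str(out / "dt2_surface.csv"))
    return {"inputs": [], "outputs": outputs}


def _stage_lfc(cfg: dict, out: Path) -> dict:
    geo = CouetteGeometry(**cfg["geometry"])
    times, torques = rio.read_torque_csv(out / "torque.csv")
    inputs, outputs = [str(out / "torque.csv")], []
    for i, (t, torque) in enumerate(zip(times, torques)):
        ppath = out / f"profile_{i:02d}.csv"
        profile = rio.read_profile_csv(ppath)
        lfc = assemble_lfc(profile, torque, geo, gamma_min=cfg["mask_gamma_min"])
        lpath = out / f"lfc_{i:02d}.csv"
        rio.write_lfc_csv(lpath, lfc)
        inputs.append(str(ppath))
        outputs.append(str(lpath))
    return {"inputs": inputs, "outputs": outputs}


def _stage_fit_hb(cfg: dict, out: Path) -> dict:
    paths = sorted(out.glob("lfc_*.csv"))
    lfcs = [rio.read_lfc_csv(p) for p in paths]
    fits = fit_hb_global_n(lfcs)
    rio.write_hb_fits_json(out / "hb_fits.json", fits)
    rio.write_series_csv(
        out / "tau0_series.csv",
        [f.time_stamp for f in fits],
        [f.params.yield_stress for f in fits],
        [f.stderr.get("tau0", np.nan) for f in fits],
    )
    return {"inputs": [str(p) for p in paths],
            "outputs": [str(out / "hb_fits.json"), str(out / "tau0_series.csv")]}


def _stage_fit_skm(cfg: dict, out: Path) -> dict:
    times, tau0, _err = rio.read_series_csv(out / "tau0_series.csv")
    fit = fit_skm(times, tau0)
    rio.write_skm_json(out / "skm_fit.json", fit, time_unit="min")
    return {"inputs": [str(out / "tau0_series.csv")],
            "outputs": [str(out / "skm_fit.json")]}


def _stage_droplet(cfg: dict, out: Path) -> dict:
    drop = cfg["droplet"]
    pgse = _pgse_from(drop["pgse"])
    before = fit_droplet_size(rio.read_decay_csv(out / "decay_before.csv"), pgse,
                              d_oil=drop["d_oil"])
    after = fit_droplet_size(rio.read_decay_csv(out / "decay_after.csv"), pgse,
                             d_oil=drop["d_oil"])
    rio.write_distribution_json(out / "droplets_before.json", before)
    rio.write_distribution_json(out / "droplets_after.json", after,
                                ratio_vs_baseline=growth_ratio(after, before))
    return {
        "inputs": [str(out / "decay_before.csv"), str(out / "decay_after.csv")],
        "outputs": [str(out / "droplets_before.json"), str(out / "droplets_after.json")],
    }


def _stage_dt2(cfg: dict, out: Path) -> dict:
    d2 = cfg["dt2"]
    pgse = _pgse_from(d2["pgse"])
    dataset = rio.read_dt2_csv(out / "dt2_surface", pgse=pgse)
    from .dt2 import default_d_grid, default_t2_grid

    dt2_map = ilt2d(
        dataset,
        D_grid=default_d_grid(d2["n_d_grid"]),
        T2_grid=default_t2_grid(d2["n_t2_grid"]),
        reg_weight=d2["reg_weight"],
    )
    rio.write_map_csv(out / "dt2_map", dt2_map)
    rio.write_peaks_json(out / "dt2_peaks.json", dt2_map)
    return {"inputs": [str(out / "dt2_surface.csv")],
            "outputs": [str(out / "dt2_map.csv"), str(out / "dt2_peaks.json")]}


_STAGE_FUNCS = {
    "fixtures": _stage_fixtures,
    "lfc": _stage_lfc,
    "fit-hb": _stage_fit_hb,
    "fit-skm": _stage_fit_skm,
    "droplet-size": _stage_droplet,
    "dt2-map": _stage_dt2,
}


def run_pipeline(config, out_dir, stages=None) -> RunManifest:
    """Execute the requested stages in dependency order; emit a manifest.

    ``config`` is a raw dict or :class:`PipelineConfig`. A stage failure is
    recorded in the manifest (status "failed") and aborts the stages that
    would have consumed its outputs.
    """
    from . import __version__

    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; choose from {STAGES}")
    ordered = [s for s in STAGES if s in stages]
    manifest = RunManifest(config_hash=config.config_hash, version=__version__,
                           started=time.time())
    failed = False
    for name in ordered:
        if failed:
            manifest.stages[name] = {"status": "skipped", "inputs": [], "outputs": []}
            continue
        try:
            record = _STAGE_FUNCS[name](config.raw, out)
            record["status"] = "ok"
        except Exception as exc:  # record partial completion
            record = {"status": "failed", "error": f"{type(exc).__name__}: {exc}",
                      "inputs": [], "outputs": []}
            failed = True
        manifest.stages[name] = record
    manifest.finished = time.time()
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return manifest
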