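"""Reproducible end-to-end runs: simulate -> render -> extract -> analyze
and generate -> segment -> stats, with manifests.

A run is fully described by a :class:`RunConfig` (round-trips to YAML) and
a seed; every artifact a run writes is listed in a ``manifest.json`` with
its SHA-256, so any output can be re-derived from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cryofront import __version__, io
from cryofront.front import classify_inversion, track_front
from cryofront.ir import (batch_trace, correct_emissivity, detect_nucleation,
                          line_profile_array, line_trace, vial_trace)
from cryofront.mia import segment_pores
from cryofront.stats import beta_qq, dispersion_stats
from cryofront.synthetic.freezing import (FreezingProtocol, Loading,
                                          NucleationMode, PhysicalProperties,
                                          SimulationSettings,
                                          default_properties, simulate_batch)
from cryofront.synthetic.render import CameraConfig, render_thermal_stack
from cryofront.synthetic.sem import PoreSpec, generate_sem_image

logger = logging.getLogger(__name__)

#: the three nucleation scenarios of the study design
SCENARIOS = ("SPONTANEOUS", "VISF271", "VISF263")


def scenario_protocol(loading: Loading | str, scenario: str,
                      solution: str = "sucrose 5%"):
    """Protocol + simulation settings for one study-design cell.

    Shelf holding temperatures follow the study design (258 K ON-shelf,
    248 K OFF-shelf); the VISF surface-cooling pulse is enabled only for
    the 271 K scenario -- at 263 K nucleation occurs before a surface
    gradient can develop.
    """
    loading = Loading(loading)
    th = 258.0 if loading is Loading.ON_SHELF else 248.0
    settings = SimulationSettings()
    if scenario == "SPONTANEOUS":
        protocol = FreezingProtocol(
            loading=loading, nucleation_mode=NucleationMode.SPONTANEOUS,
            Tn_target=263.0, T_shelf_hold=th)
    elif scenario == "VISF271":
        protocol = FreezingProtocol(
            loading=loading, nucleation_mode=NucleationMode.VISF,
            Tn_target=271.0, T_shelf_hold=th)
    elif scenario == "VISF263":
        protocol = FreezingProtocol(
            loading=loading, nucleation_mode=NucleationMode.VISF,
            Tn_target=263.0, T_shelf_hold=th)
        settings = dataclasses.replace(settings, visf_pulse_enabled=False)
    else:
        raise ValueError(f"unknown scenario {scenario!r}; pick from {SCENARIOS}")
    return protocol, settings


@dataclass
class FreezingRunConfig:
    loading: str = "ON_SHELF"
    scenario: str = "VISF271"
    solution: str = "sucrose 5%"
    n_vials: int = 3
    n_nodes: int = 32
    noise_sd: float = 0.1
    neighbor_humps: bool = False


@dataclass
class PoreRunConfig:
    levels: tuple[str, ...] = ("TOP", "MIDDLE", "BOTTOM")
    images_per_level: int = 3
    image_shape: tuple[int, int] = (512, 544)
    px_size_um: float = 1.0
    n_pores_per_image: int = 150
    diameter_scale_um: float = 150.0
    beta_a: float = 1.2
    beta_b: float = 15.0
    porosity_target: float = 0.12
    score_quantile: float = 0.85


@dataclass
class RunConfig:
    name: str = "run"
    seed: int = 0
    freezing: FreezingRunConfig = field(default_factory=FreezingRunConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    pores: PoreRunConfig = field(default_factory=PoreRunConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("freezing", FreezingRunConfig),
                         ("camera", CameraConfig), ("pores", PoreRunConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        cfg = cls(**d)
        cfg.pores.levels = tuple(cfg.pores.levels)
        cfg.pores.image_shape = tuple(cfg.pores.image_shape)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.load_yaml(path))

    def to_yaml(self, path) -> None:
        io.dump_yaml(json.loads(json.dumps(self.to_dict())), path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, config: RunConfig, artifacts: list[Path],
                    status: str = "complete", extra: dict | None = None) -> dict:
    manifest = {
        "name": config.name,
        "seed": config.seed,
        "package_version": __version__,
        "status": status,
        "config": config.to_dict(),
        "artifacts": [{"path": p.name, "sha256": _sha256(p)} for p in artifacts],
    }
    if extra:
        manifest["extra"] = extra
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True, default=str))
    return manifest


def run_freezing_pipeline(config: RunConfig, out_dir) -> dict:
    """simulate -> render -> extract -> front analysis for one scenario."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fc = config.freezing
    camera = dataclasses.replace(config.camera, noise_sd=fc.noise_sd)
    protocol, settings = scenario_protocol(fc.loading, fc.scenario, fc.solution)
    props = default_properties(protocol.loading)
    artifacts: list[Path] = []
    try:
        histories = simulate_batch(protocol, props, n_vials=fc.n_vials,
                                   n_nodes=fc.n_nodes, seed=config.seed,
                                   settings=settings)
        stack, defs = render_thermal_stack(
            histories, camera, seed=config.seed + 1,
            neighbor_humps=fc.neighbor_humps)

        io.write_stack(stack, out / "stack.tif", out / "timestamps.csv")
        io.write_line_defs(defs, out / "lines.csv")
        artifacts += [out / "stack.tif", out / "timestamps.csv", out / "lines.csv"]

        eps, trefl = camera.emissivity, camera.T_reflected
        line_traces = [line_trace(stack, d, camera.mm_per_pixel, eps, trefl)
                       for d in defs]
        by_vial: dict[str, list] = {}
        for tr in line_traces:
            by_vial.setdefault(tr.vial_id, []).append(tr)
        vial_traces = [vial_trace(trs) for trs in by_vial.values()]
        batch = batch_trace(vial_traces)
        io.write_traces(line_traces + vial_traces + [batch], out / "traces.csv")
        artifacts.append(out / "traces.csv")

        profiles_by_vial = {}
        for d in defs:
            arr = line_profile_array(stack, d, eps, trefl)
            profiles_by_vial.setdefault(d.vial_id, []).append(arr)
        label_rows, front_parts = [], []
        for h, vtr in zip(histories, vial_traces):
            mean_profiles = np.mean(profiles_by_vial[h.vial_id], axis=0)
            t_detected = detect_nucleation(
                stack.time_s, mean_profiles[:, 0],
                jump_K=(4.5 if h.nucleation_mode is NucleationMode.SPONTANEOUS
                        else 1.0))
            label = classify_inversion(
                stack.time_s, mean_profiles, h.t_nucleation_s,
                nucleation_mode=h.nucleation_mode,
                t_pulse_start=h.t_pulse_start_s)
            label_rows.append({
                "type": protocol.loading.value,
                "solution": fc.solution,
                "nucleation": fc.scenario,
                "vial_id": h.vial_id,
                "t_nucleation_true_s": h.t_nucleation_s,
                "t_nucleation_detected_s": t_detected,
                "before": label.before_nucleation.value,
                "after": label.after_nucleation.value,
                "inversion": label.visf_inversion.value,
            })
            if protocol.loading is Loading.ON_SHELF:
                track = track_front(vtr, h.t_nucleation_s, protocol.loading)
                front_parts.append(pd.DataFrame({
                    "vial_id": h.vial_id,
                    "time_s": track.time_s,
                    "z_front_mm": track.z_front_mm,
                    "velocity_mm_per_min": track.velocity_mm_per_min,
                    "phase": [p.value for p in track.phase_labels],
                }))
        pd.DataFrame(label_rows).to_csv(out / "labels.csv", index=False)
        artifacts.append(out / "labels.csv")
        if front_parts:
            pd.concat(front_parts, ignore_index=True).to_csv(
                out / "front_tracks.csv", index=False)
            artifacts.append(out / "front_tracks.csv")
    except Exception:
        logger.exception("freezing pipeline failed; writing partial manifest")
        _write_manifest(out, config, artifacts, status="partial")
        raise
    return _write_manifest(out, config, artifacts)


def run_pore_pipeline(config: RunConfig, out_dir) -> dict:
    """generate -> segment -> stats for a set of SEM images."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pc = config.pores
    artifacts: list[Path] = []
    tables = []
    try:
        for li, level in enumerate(pc.levels):
            for i in range(pc.images_per_level):
                image_id = f"{level.lower()}_{i}"
                spec = PoreSpec(
                    beta_a=pc.beta_a, beta_b=pc.beta_b,
                    diameter_scale_um=pc.diameter_scale_um,
                    n_pores=pc.n_pores_per_image,
                    porosity_target=pc.porosity_target,
                    seed=config.seed * 1000 + li * 100 + i)
                image, truth = generate_sem_image(
                    spec, image_shape=pc.image_shape, px_size_um=pc.px_size_um,
                    cake_level=level, sample_id=image_id)
                io.write_sem_image(image, out / f"{image_id}.png",
                                   out / f"{image_id}.json")
                truth.to_csv(out / f"{image_id}_truth.csv", index=False)
                artifacts += [out / f"{image_id}.png", out / f"{image_id}.json",
                              out / f"{image_id}_truth.csv"]
                _, table = segment_pores(image, score_threshold=pc.score_quantile)
                tables.append(table)
        pore_table = pd.concat(tables, ignore_index=True)
        pore_table.to_csv(out / "poretable.csv", index=False)
        artifacts.append(out / "poretable.csv")

        report = dispersion_stats(pore_table, by=["cake_level"])
        report.to_csv(out / "report.csv", index=False)
        artifacts.append(out / "report.csv")

        qq = beta_qq(pore_table["eq_diameter_um"].to_numpy(),
                     a=pc.beta_a, b=pc.beta_b)
        pd.DataFrame({"theoretical_um": qq.theoretical_q,
                      "empirical_um": qq.empirical_q}).to_csv(
            out / "qq.csv", index=False)
        artifacts.append(out / "qq.csv")
        extra = {"qq_r_squared": qq.r_squared, "qq_scale_um": qq.scale_um}
    except Exception:
        logger.exception("pore pipeline failed; writing partial manifest")
        _write_manifest(out, config, artifacts, status="partial")
        raise
    return _write_manifest(out, config, artifacts, extra=extra)


def run_scenario_matrix(base: RunConfig, out_dir,
                        loadings=("ON_SHELF", "OFF_SHELF"),
                        scenarios=SCENARIOS) -> pd.DataFrame:
    """Run the full loading x nucleation design and collect the label rows."""
    out = Path(out_dir)
    rows = []
    for loading in loadings:
        for scenario in scenarios:
            cfg = dataclasses.replace(
                base,
                name=f"{base.name}_{loading.lower()}_{scenario.lower()}",
                freezing=dataclasses.replace(base.freezing, loading=loading,
                                             scenario=scenario))
            sub = out / cfg.name
            run_freezing_pipeline(cfg, sub)
            labels = pd.read_csv(sub / "labels.csv", keep_default_na=False)
            rows.append(labels)
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(out / "scenario_labels.csv", index=False)
    return table
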