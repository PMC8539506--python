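"""File formats: TIFF stacks, CSV tables, PNG images, YAML configs.

Thermal stacks are written as multi-page 16-bit grayscale TIFF in
centikelvin (``uint16 = round(T_K * 100)``, range 0..655.35 K) with a CSV
of frame timestamps alongside.  Acquisition-line definitions, traces and
pore tables are tidy CSV.  SEM images are 8-bit PNG with a JSON sidecar
carrying pixel size and cake level.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from cryofront.ir import ExtremaTrace, TraceLevel
from cryofront.mia import SEMImage
from cryofront.synthetic.render import AcquisitionLineDef, ThermalStack

CENTIKELVIN = 100.0


def write_stack(stack: ThermalStack, tif_path, times_csv_path) -> None:
    data = np.round(stack.frames * CENTIKELVIN)
    if data.min() < 0 or data.max() > np.iinfo(np.uint16).max:
        raise ValueError("temperatures outside the centikelvin uint16 range")
    tifffile.imwrite(str(tif_path), data.astype(np.uint16))
    pd.DataFrame({"frame": np.arange(stack.time_s.size),
                  "time_s": stack.time_s}).to_csv(times_csv_path, index=False)


def read_stack(tif_path, times_csv_path) -> ThermalStack:
    frames = tifffile.imread(str(tif_path)).astype(float) / CENTIKELVIN
    if frames.ndim == 2:
        frames = frames[None]
    times = pd.read_csv(times_csv_path)["time_s"].to_numpy(dtype=float)
    return ThermalStack(frames=frames, time_s=times)


def write_line_defs(defs: list[AcquisitionLineDef], path) -> None:
    pd.DataFrame([dataclasses.asdict(d) for d in defs]).to_csv(path, index=False)


def read_line_defs(path) -> list[AcquisitionLineDef]:
    df = pd.read_csv(path)
    return [AcquisitionLineDef(vial_id=str(r.vial_id), line_idx=int(r.line_idx),
                               col=int(r.col), row_bottom=int(r.row_bottom),
                               row_top=int(r.row_top))
            for r in df.itertuples()]


def traces_to_frame(traces: list[ExtremaTrace]) -> pd.DataFrame:
    """Tidy long-format table of extrema traces."""
    parts = []
    for tr in traces:
        part = pd.DataFrame({
            "level": tr.level.value,
            "vial_id": tr.vial_id if tr.vial_id is not None else "",
            "line_idx": tr.line_idx if tr.line_idx is not None else -1,
            "time_s": tr.time_s,
            "Tmin_K": tr.Tmin_K,
            "Hmin_mm": tr.Hmin_mm,
            "Tmax_K": tr.Tmax_K,
            "Hmax_mm": tr.Hmax_mm,
            "n_members": tr.n_members,
        })
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def write_traces(traces: list[ExtremaTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path) -> list[ExtremaTrace]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for (level, vial_id, line_idx), grp in df.groupby(
            ["level", "vial_id", "line_idx"], sort=False):
        out.append(ExtremaTrace(
            level=TraceLevel(level),
            time_s=grp["time_s"].to_numpy(dtype=float),
            Tmin_K=grp["Tmin_K"].to_numpy(dtype=float),
            Tmax_K=grp["Tmax_K"].to_numpy(dtype=float),
            Hmin_mm=grp["Hmin_mm"].to_numpy(dtype=float),
            Hmax_mm=grp["Hmax_mm"].to_numpy(dtype=float),
            n_members=int(grp["n_members"].iloc[0]),
            vial_id=vial_id or None,
            line_idx=int(line_idx) if int(line_idx) >= 0 else None,
        ))
    return out


def write_sem_image(image: SEMImage, png_path, sidecar_json_path) -> None:
    iio.imwrite(str(png_path),
                np.clip(np.round(image.intensity), 0, 255).astype(np.uint8))
    Path(sidecar_json_path).write_text(json.dumps({
        "px_size_um": image.px_size_um,
        "cake_level": image.cake_level,
        "sample_id": image.sample_id,
    }, indent=2))


def read_sem_image(png_path, sidecar_json_path) -> SEMImage:
    meta = json.loads(Path(sidecar_json_path).read_text())
    return SEMImage(intensity=iio.imread(str(png_path)).astype(float),
                    px_size_um=float(meta["px_size_um"]),
                    cake_level=str(meta["cake_level"]),
                    sample_id=str(meta["sample_id"]))


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
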