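"""Thermal-stack renderer: the synthetic stand-in for the IR camera.

Each vial's simulated axial field is resampled to pixel-centre heights on
six vertical acquisition lines of 8 pixels (defaults), pushed through the
forward graybody emissivity model, and buried in Gaussian sensor noise.
Optionally a transient "hump" is added to the wall pixels of vials
adjacent to a nucleating neighbour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d

logger = logging.getLogger(__name__)


@dataclass
class CameraConfig:
    """Geometry and radiometry of the synthetic camera."""

    fps: float = 0.1
    pixels_per_line: int = 8
    lines_per_vial: int = 6
    emissivity: float = 0.91
    mm_per_pixel: float = 1.25
    noise_sd: float = 0.0
    T_reflected: float = 293.0

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.pixels_per_line < 2:
            raise ValueError("pixels_per_line must be >= 2")
        if not 0 < self.emissivity <= 1:
            raise ValueError("emissivity must be in (0, 1]")
        if self.mm_per_pixel <= 0 or self.noise_sd < 0:
            raise ValueError("invalid camera geometry/noise")

    @property
    def pixel_heights_mm(self) -> np.ndarray:
        """Pixel-centre heights above the vial bottom."""
        return (np.arange(self.pixels_per_line) + 0.5) * self.mm_per_pixel


@dataclass
class AcquisitionLineDef:
    """One vertical acquisition line in image coordinates.

    Image row 0 is the top of the frame, so ``row_bottom >= row_top`` and
    ``row_bottom`` maps to the vial bottom.
    """

    vial_id: str
    line_idx: int
    col: int
    row_bottom: int
    row_top: int


@dataclass
class ThermalStack:
    """Time-ordered radiometric frames (Kelvin) plus timestamps."""

    frames: np.ndarray   # (n_frames, n_rows, n_cols)
    time_s: np.ndarray   # (n_frames,)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != self.time_s.size:
            raise ValueError("frames must be (n_frames, rows, cols) matching time_s")


def default_layout(vial_ids: list[str], camera: CameraConfig,
                   margin: int = 2) -> list[tuple[str, int]]:
    """Vials side by side in one row; returns ``(vial_id, col0)`` pairs."""
    width = camera.lines_per_vial + 2 * margin
    return [(vid, i * width) for i, vid in enumerate(vial_ids)]


def _line_defs(layout, camera: CameraConfig, margin: int = 2):
    row_top = margin
    row_bottom = margin + camera.pixels_per_line - 1
    defs = []
    for vid, col0 in layout:
        for j in range(camera.lines_per_vial):
            defs.append(AcquisitionLineDef(
                vial_id=vid, line_idx=j, col=col0 + margin + j,
                row_bottom=row_bottom, row_top=row_top,
            ))
    return defs


def render_thermal_stack(
    histories,
    camera: CameraConfig,
    layout: list[tuple[str, int]] | None = None,
    seed: int = 0,
    neighbor_humps: bool = False,
    hump_K: float = 3.5,
    hump_decay_s: float = 60.0,
    background_K: float = 268.0,
    margin: int = 2,
) -> tuple[ThermalStack, list[AcquisitionLineDef]]:
    """Render a batch of vial histories into a thermal stack.

    Every vial's nodal field is linearly interpolated to pixel-centre
    heights and to the camera frame times, converted to apparent
    temperature with the forward graybody model, and Gaussian noise of
    ``camera.noise_sd`` K is added to every pixel.  If the camera frame
    grid does not coincide with the simulation record grid the fields are
    resampled with a logged warning.

    With ``neighbor_humps`` enabled, a decaying ``hump_K`` transient is
    added to the wall (outermost line) pixels of vials adjacent to a
    neighbour from the moment that neighbour nucleates.
    """
    # local import: ir depends on render for the dataclasses
    from cryofront.ir import apparent_temperature

    histories = list(histories)
    if not histories:
        raise ValueError("no histories to render")
    t_grid = histories[0].time_s
    for h in histories[1:]:
        if h.time_s.shape != t_grid.shape or not np.allclose(h.time_s, t_grid):
            raise ValueError("histories must share a time grid (see simulate_batch)")
    if layout is None:
        layout = default_layout([h.vial_id for h in histories], camera, margin)
    if len(layout) != len(histories):
        raise ValueError("layout length must match histories")
    cols0 = sorted(c for _, c in layout)
    width = camera.lines_per_vial + 2 * margin
    if any(b - a < width for a, b in zip(cols0, cols0[1:])):
        raise ValueError("layout has overlapping vials")

    frame_dt = 1.0 / camera.fps
    t_frames = np.arange(t_grid[0], t_grid[-1] + 1e-9, frame_dt)
    if not (np.isclose(frame_dt % (t_grid[1] - t_grid[0]), 0.0)
            or np.isclose((t_grid[1] - t_grid[0]) % frame_dt, 0.0)):
        logger.warning("camera fps incompatible with record grid; resampling")

    n_rows = camera.pixels_per_line + 2 * margin
    n_cols = max(c for _, c in layout) + width
    rng = np.random.default_rng(seed)
    frames = np.full((t_frames.size, n_rows, n_cols), float(background_K))

    px_heights = camera.pixel_heights_mm
    row_top = margin
    row_bottom = margin + camera.pixels_per_line - 1
    rows = np.arange(row_bottom, row_top - 1, -1)   # bottom pixel first

    by_id = {h.vial_id: h for h in histories}
    order = [vid for vid, _ in layout]

    for idx, (vid, col0) in enumerate(layout):
        h = by_id[vid]
        # (n_frames, n_px): interpolate in time, then in height
        f_t = interp1d(h.time_s, h.T_axial, axis=1, assume_sorted=True,
                       bounds_error=False,
                       fill_value=(h.T_axial[:, 0], h.T_axial[:, -1]))
        nodal = f_t(t_frames)                        # (n_nodes, n_frames)
        field = np.empty((t_frames.size, px_heights.size))
        for i in range(t_frames.size):
            field[i] = np.interp(px_heights, h.heights_mm, nodal[:, i])

        hump = np.zeros(t_frames.size)
        if neighbor_humps:
            for nb in (idx - 1, idx + 1):
                if 0 <= nb < len(order):
                    tn = by_id[order[nb]].t_nucleation_s
                    on = t_frames >= tn
                    hump[on] += hump_K * np.exp(-(t_frames[on] - tn) / hump_decay_s)

        for j in range(camera.lines_per_vial):
            col = col0 + margin + j
            vals = field.copy()
            if neighbor_humps and j in (0, camera.lines_per_vial - 1):
                vals = vals + hump[:, None]          # wall pixels only
            frames[:, rows, col] = vals

    frames = apparent_temperature(frames, camera.emissivity, camera.T_reflected)
    if camera.noise_sd > 0:
        frames += rng.normal(0.0, camera.noise_sd, size=frames.shape)

    stack = ThermalStack(frames=frames, time_s=t_frames)
    return stack, _line_defs(layout, camera, margin)
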