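"""IR stack processing: acquisition lines, emissivity, extrema, averaging.

The processing chain is deliberately plain: per-line axial profiles are
extracted with **no smoothing or filtering of any kind**, the per-line
extrema are located by a direct min/max scan, and extremum values *and
positions* are then averaged line -> vial -> batch (extremum-then-average
order, never average-profile-then-extremum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from cryofront.synthetic.render import AcquisitionLineDef, ThermalStack

logger = logging.getLogger(__name__)

_SIGMA = 5.670374419e-8  # Stefan-Boltzmann, W/(m^2 K^4)


class TraceLevel(str, Enum):
    LINE = "LINE"
    VIAL = "VIAL"
    BATCH = "BATCH"


@dataclass
class AxialProfile:
    """One acquisition line in one frame, ordered bottom -> top.

    ``heights_mm`` are pixel-centre heights above the vial bottom.
    """

    heights_mm: np.ndarray
    T_K: np.ndarray
    frame_time_s: float
    vial_id: str
    line_idx: int

    def __post_init__(self):
        self.heights_mm = np.asarray(self.heights_mm, dtype=float)
        self.T_K = np.asarray(self.T_K, dtype=float)
        if self.heights_mm.size != self.T_K.size:
            raise ValueError("heights_mm and T_K must have equal length")
        if self.heights_mm.size and np.any(np.diff(self.heights_mm) <= 0):
            raise ValueError("heights_mm must be strictly increasing")


@dataclass
class ExtremaTrace:
    """Time series of per-profile extrema at LINE, VIAL or BATCH level.

    BATCH traces additionally carry min/max envelopes of the member
    vials' Tmax and Hmax (for shaded-band plots).
    """

    level: TraceLevel
    time_s: np.ndarray
    Tmin_K: np.ndarray
    Tmax_K: np.ndarray
    Hmin_mm: np.ndarray
    Hmax_mm: np.ndarray
    n_members: int = 1
    vial_id: str | None = None
    line_idx: int | None = None
    Tmax_lo: np.ndarray | None = None
    Tmax_hi: np.ndarray | None = None
    Hmax_lo: np.ndarray | None = None
    Hmax_hi: np.ndarray | None = None

    def __post_init__(self):
        self.level = TraceLevel(self.level)
        if np.any(self.Tmin_K > self.Tmax_K + 1e-12):
            raise ValueError("Tmin must not exceed Tmax")


def apparent_temperature(T_true, emissivity: float, T_reflected: float):
    """Forward graybody model: apparent temperature seen by the camera.

    ``sigma * T_app^4 = eps * sigma * T_true^4 + (1 - eps) * sigma * T_refl^4``
    """
    if not 0 < emissivity <= 1:
        raise ValueError("emissivity must be in (0, 1]")
    T_true = np.asarray(T_true, dtype=float)
    rad = emissivity * T_true**4 + (1.0 - emissivity) * float(T_reflected) ** 4
    out = rad**0.25
    return float(out) if np.ndim(T_true) == 0 else out


def correct_emissivity(T_apparent, emissivity: float, T_reflected: float):
    """Invert the graybody radiance balance for the true temperature.

    Monotone in ``T_apparent``; the blackbody case ``eps = 1`` is the
    identity.  Raises for ``eps = 0`` and for the (non-physical) case of a
    negative radicand.
    """
    if not 0 < emissivity <= 1:
        raise ValueError("emissivity must be in (0, 1]")
    T_apparent = np.asarray(T_apparent, dtype=float)
    rad = (T_apparent**4 - (1.0 - emissivity) * float(T_reflected) ** 4) / emissivity
    if np.any(rad < 0):
        raise ValueError("negative radicand: apparent/reflected pair non-physical")
    out = rad**0.25
    return float(out) if np.ndim(T_apparent) == 0 else out


def _line_pixel_rows(d: AcquisitionLineDef) -> np.ndarray:
    """Image rows of a line ordered so index 0 is the vial bottom."""
    if d.row_bottom < d.row_top:
        raise ValueError(
            f"line {d.vial_id}/{d.line_idx}: row_bottom must be the larger "
            "image row (image row 0 is the top)")
    return np.arange(d.row_bottom, d.row_top - 1, -1)


def line_profile_array(
    stack: ThermalStack,
    d: AcquisitionLineDef,
    emissivity: float | None = None,
    T_reflected: float = 293.0,
) -> np.ndarray:
    """All frames of one line as an ``(n_frames, n_pixels)`` array."""
    rows = _line_pixel_rows(d)
    vals = stack.frames[:, rows, d.col]
    if emissivity is not None:
        vals = correct_emissivity(vals, emissivity, T_reflected)
    return vals


def extract_acquisition_lines(
    stack: ThermalStack,
    defs: list[AcquisitionLineDef],
    mm_per_pixel: float = 1.25,
    emissivity: float | None = None,
    T_reflected: float = 293.0,
) -> list[AxialProfile]:
    """One :class:`AxialProfile` per (frame, line), bottom pixel first.

    No smoothing or filtering is applied.  If ``emissivity`` is given the
    graybody correction is applied to every pixel.  Out-of-bounds line
    definitions raise a single error naming every offending line.
    """
    n_frames, n_rows, n_cols = stack.frames.shape
    bad = [
        d for d in defs
        if not (0 <= d.row_top <= d.row_bottom < n_rows and 0 <= d.col < n_cols)
    ]
    if bad:
        names = ", ".join(f"{d.vial_id}/line{d.line_idx}" for d in bad)
        raise ValueError(f"acquisition lines outside frame bounds: {names}")

    profiles: list[AxialProfile] = []
    for d in defs:
        vals = line_profile_array(stack, d, emissivity, T_reflected)
        n_px = vals.shape[1]
        heights = (np.arange(n_px) + 0.5) * mm_per_pixel
        for i in range(n_frames):
            profiles.append(AxialProfile(
                heights_mm=heights,
                T_K=vals[i],
                frame_time_s=float(stack.time_s[i]),
                vial_id=d.vial_id,
                line_idx=d.line_idx,
            ))
    return profiles


def line_extrema(profile: AxialProfile) -> tuple[float, float, float, float]:
    """``(Tmin, Hmin, Tmax, Hmax)`` by a plain extremum scan.

    Ties are broken toward the lowest height (first occurrence from the
    vial bottom).
    """
    T = profile.T_K
    if T.size == 0:
        raise ValueError("empty profile")
    i_min = int(np.argmin(T))
    i_max = int(np.argmax(T))
    return (float(T[i_min]), float(profile.heights_mm[i_min]),
            float(T[i_max]), float(profile.heights_mm[i_max]))


def line_trace(
    stack: ThermalStack,
    d: AcquisitionLineDef,
    mm_per_pixel: float = 1.25,
    emissivity: float | None = None,
    T_reflected: float = 293.0,
) -> ExtremaTrace:
    """LINE-level extrema trace for one acquisition line."""
    vals = line_profile_array(stack, d, emissivity, T_reflected)
    heights = (np.arange(vals.shape[1]) + 0.5) * mm_per_pixel
    i_min = np.argmin(vals, axis=1)
    i_max = np.argmax(vals, axis=1)
    n = vals.shape[0]
    rows = np.arange(n)
    return ExtremaTrace(
        level=TraceLevel.LINE,
        time_s=np.asarray(stack.time_s, dtype=float),
        Tmin_K=vals[rows, i_min],
        Tmax_K=vals[rows, i_max],
        Hmin_mm=heights[i_min].astype(float),
        Hmax_mm=heights[i_max].astype(float),
        n_members=1,
        vial_id=d.vial_id,
        line_idx=d.line_idx,
    )


def _mean_traces(traces: list[ExtremaTrace], level: TraceLevel,
                 vial_id: str | None, envelope: bool) -> ExtremaTrace:
    if not traces:
        raise ValueError("no traces to average")
    t0 = traces[0].time_s
    for tr in traces[1:]:
        if tr.time_s.shape != t0.shape or not np.allclose(tr.time_s, t0):
            raise ValueError("traces must share an aligned time grid")
    fields = {}
    for name in ("Tmin_K", "Tmax_K", "Hmin_mm", "Hmax_mm"):
        stackd = np.stack([getattr(tr, name) for tr in traces])
        n_missing = int(np.isnan(stackd).sum())
        if n_missing:
            logger.info("%s: averaging over available members (%d missing values)",
                        name, n_missing)
        with np.errstate(invalid="ignore"):
            fields[name] = np.nanmean(stackd, axis=0)
    extra = {}
    if envelope:
        tmax = np.stack([tr.Tmax_K for tr in traces])
        hmax = np.stack([tr.Hmax_mm for tr in traces])
        extra = dict(
            Tmax_lo=np.nanmin(tmax, axis=0), Tmax_hi=np.nanmax(tmax, axis=0),
            Hmax_lo=np.nanmin(hmax, axis=0), Hmax_hi=np.nanmax(hmax, axis=0),
        )
    return ExtremaTrace(
        level=level, time_s=t0, n_members=len(traces), vial_id=vial_id,
        **fields, **extra,
    )


def vial_trace(line_traces: list[ExtremaTrace]) -> ExtremaTrace:
    """Average the per-line extremum values and positions into a vial trace.

    The order matters and is extremum-then-average: extrema are located on
    each line first and their values/positions averaged afterwards.  Frames
    where a line is missing (NaN) are averaged over the available lines.
    """
    vial_ids = {tr.vial_id for tr in line_traces}
    vial_id = vial_ids.pop() if len(vial_ids) == 1 else None
    return _mean_traces(line_traces, TraceLevel.VIAL, vial_id, envelope=False)


def batch_trace(vial_traces: list[ExtremaTrace]) -> ExtremaTrace:
    """Average vial traces into the batch mean trace with min/max envelopes."""
    return _mean_traces(vial_traces, TraceLevel.BATCH, None, envelope=True)


def detect_nucleation(
    time_s: np.ndarray,
    T_series: np.ndarray,
    jump_K: float = 2.0,
    window_s: float = 60.0,
) -> float | None:
    """Earliest time at which a forward temperature rise exceeds ``jump_K``.

    Scans forward differences within ``window_s``; returns the time of the
    first frame whose temperature exceeds some earlier in-window frame by
    more than ``jump_K``, or ``None`` on monotone cooling.  A window
    shorter than one frame interval is a configuration error.
    """
    time_s = np.asarray(time_s, dtype=float)
    T = np.asarray(T_series, dtype=float)
    if time_s.size < 2:
        return None
    frame_dt = float(np.median(np.diff(time_s)))
    max_lag = int(window_s // frame_dt)
    if max_lag < 1:
        raise ValueError("window_s shorter than one frame interval")
    best = None
    for lag in range(1, max_lag + 1):
        hits = np.nonzero(T[lag:] - T[:-lag] > jump_K)[0]
        if hits.size:
            j = int(hits[0]) + lag
            if best is None or j < best:
                best = j
    return float(time_s[best]) if best is not None else None
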