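"""Freezing-front quantities derived from extrema traces.

For conduction-dominated (ON-shelf) vials the height of the axial
temperature maximum is a proxy for the freezing-front position; this
module turns extrema traces into front trajectories and velocities, the
frozen-layer temperature gradient, the freezing-interval duration, and a
qualitative gradient-inversion label per vial.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from cryofront.ir import ExtremaTrace
from cryofront.synthetic.freezing import Loading, NucleationMode

logger = logging.getLogger(__name__)


class FrontPhase(str, Enum):
    ASCENT_LINEAR = "ASCENT_LINEAR"
    DECELERATION = "DECELERATION"
    PLATEAU = "PLATEAU"


class GradientPosition(str, Enum):
    LOWEST = "LOWEST"
    HIGHEST = "HIGHEST"
    UNCLEAR = "UNCLEAR"


class InversionLabel(str, Enum):
    YES = "YES"
    NO = "NO"
    UNCLEAR = "UNCLEAR"
    NA = "NA"


@dataclass
class FrontTrack:
    """Inferred front trajectory (ON-shelf only).

    ``z_front_mm`` is the Hmax series restricted to post-nucleation times;
    ``velocity_mm_per_min`` comes from central differences over the
    configured stencil; ``phase_labels`` labels each frame from a
    two-segment piecewise-linear fit.
    """

    time_s: np.ndarray
    z_front_mm: np.ndarray
    velocity_mm_per_min: np.ndarray
    phase_labels: list[FrontPhase]
    breakpoint_idx: int | None
    slopes_mm_per_min: tuple[float, float]


@dataclass
class GradientLabel:
    """Qualitative bottom-pixel classification mirroring a study design
    table: was the bottom the lowest or highest temperature before/after
    nucleation, and did the VISF pulse invert the gradient?"""

    before_nucleation: GradientPosition
    after_nucleation: GradientPosition
    visf_inversion: InversionLabel

    def __post_init__(self):
        self.before_nucleation = GradientPosition(self.before_nucleation)
        self.after_nucleation = GradientPosition(self.after_nucleation)
        self.visf_inversion = InversionLabel(self.visf_inversion)


def _two_segment_fit(t: np.ndarray, z: np.ndarray):
    """Least-squares two-segment linear fit; returns (break_idx, slope1, slope2).

    Segments are fit independently; the breakpoint minimises the total SSE
    over interior candidates (each segment keeps >= 3 points).
    """
    n = t.size
    if n < 6:
        slope = np.polyfit(t, z, 1)[0] if n >= 2 else 0.0
        return None, slope, slope

    def sse(tt, zz):
        coef = np.polyfit(tt, zz, 1)
        resid = zz - np.polyval(coef, tt)
        return float(resid @ resid), coef[0]

    best = None
    for k in range(3, n - 2):
        s1, m1 = sse(t[:k], z[:k])
        s2, m2 = sse(t[k:], z[k:])
        if best is None or s1 + s2 < best[0]:
            best = (s1 + s2, k, m1, m2)
    _, k, m1, m2 = best
    return k, m1, m2


def track_front(
    trace: ExtremaTrace,
    t_nucleation: float,
    loading: Loading | str = Loading.ON_SHELF,
    stencil: int = 5,
    plateau_tol_mm_per_min: float = 0.02,
) -> FrontTrack:
    """Infer the freezing-front trajectory from an Hmax trace.

    Refuses OFF-shelf traces: for suspended vials the temperature maximum
    fluctuates around mid-height and does not follow the front.
    """
    if Loading(loading) is Loading.OFF_SHELF:
        raise ValueError(
            "the temperature-maximum position cannot be used to infer the "
            "freezing front for OFF-shelf (suspended) vials")
    sel = trace.time_s >= t_nucleation
    t = trace.time_s[sel]
    z = trace.Hmax_mm[sel]
    if t.size < 2:
        raise ValueError("fewer than 2 post-nucleation frames")

    half = max(stencil // 2, 1)
    v = np.full(t.size, np.nan)
    for i in range(t.size):
        lo, hi = max(i - half, 0), min(i + half, t.size - 1)
        if hi > lo:
            v[i] = (z[hi] - z[lo]) / (t[hi] - t[lo]) * 60.0

    k, m1, m2 = _two_segment_fit(t, z)
    s1, s2 = m1 * 60.0, m2 * 60.0   # mm/min
    if k is None or (abs(s1) < plateau_tol_mm_per_min
                     and abs(s2) < plateau_tol_mm_per_min):
        overall = np.polyfit(t, z, 1)[0] * 60.0 if t.size >= 2 else 0.0
        lab = (FrontPhase.PLATEAU if abs(overall) < plateau_tol_mm_per_min
               else FrontPhase.ASCENT_LINEAR)
        labels = [lab] * t.size
        return FrontTrack(t, z, v, labels, None, (overall, overall))

    def seg_label(slope, other, first):
        if abs(slope) < plateau_tol_mm_per_min:
            return FrontPhase.PLATEAU
        if not first and slope < other:
            return FrontPhase.DECELERATION
        return FrontPhase.ASCENT_LINEAR

    lab1 = seg_label(s1, s2, first=True)
    lab2 = seg_label(s2, s1, first=False)
    labels = [lab1] * k + [lab2] * (t.size - k)
    return FrontTrack(t, z, v, labels, k, (s1, s2))


def frozen_layer_gradient(Tmax, Tbottom, Hmax_mm, H_bottom_mm=0.0):
    """Frozen-layer temperature gradient ``(Tmax - Tbottom) / Hmax`` in K/mm.

    Sign-preserving (negative if inverted).  When ``Tbottom`` is read from
    the bottom *pixel* rather than the vial bottom, pass its centre height
    as ``H_bottom_mm`` so the gradient spans the right distance.
    ``Hmax <= H_bottom`` is undefined and yields None (scalar) / NaN
    (array) with a warning.
    """
    Tmax = np.asarray(Tmax, dtype=float)
    Tbottom = np.asarray(Tbottom, dtype=float)
    Hmax_mm = np.asarray(Hmax_mm, dtype=float)
    span = Hmax_mm - H_bottom_mm
    scalar = Tmax.ndim == 0 and Hmax_mm.ndim == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        grad = np.where(span > 0, (Tmax - Tbottom) / span, np.nan)
    if np.any(span <= 0):
        warnings.warn("Hmax at/below the bottom reference: gradient undefined",
                      stacklevel=2)
        if scalar:
            return None
    return float(grad) if scalar else grad


def freezing_interval(
    trace: ExtremaTrace,
    t_nucleation: float,
    T_end: float = 263.0,
    sustained_frames: int = 2,
) -> float | None:
    """Seconds from nucleation until the product stays at or below ``T_end``.

    Uses the trace's Tmax series (the warmest reported axial temperature;
    for BATCH traces the upper Tmax envelope when available) and requires
    ``sustained_frames`` consecutive frames at or below ``T_end``.
    Returns None (logged) if the product never gets there.
    """
    tmax = trace.Tmax_hi if trace.Tmax_hi is not None else trace.Tmax_K
    sel = trace.time_s >= t_nucleation
    t = trace.time_s[sel]
    tm = np.asarray(tmax)[sel]
    below = tm <= T_end
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= sustained_frames:
            start = i - sustained_frames + 1
            return float(max(t[start] - t_nucleation, 0.0))
    logger.info("product never reached %.1f K within the trace", T_end)
    return None


def _window_position(profiles: np.ndarray, margin_K: float,
                     frac: float = 0.8) -> GradientPosition:
    """LOWEST/HIGHEST/UNCLEAR for the bottom pixel over a window of profiles."""
    bottom = profiles[:, 0]
    others = profiles[:, 1:]
    low = bottom <= others.min(axis=1) - margin_K
    high = bottom >= others.max(axis=1) + margin_K
    if low.mean() >= frac:
        return GradientPosition.LOWEST
    if high.mean() >= frac:
        return GradientPosition.HIGHEST
    return GradientPosition.UNCLEAR


def classify_inversion(
    time_s: np.ndarray,
    profiles: np.ndarray,
    t_nucleation: float,
    nucleation_mode: NucleationMode | str = NucleationMode.VISF,
    t_pulse_start: float | None = None,
    margin_K: float = 0.2,
    before_window_s: float = 300.0,
    after_window_s: float = 600.0,
    after_settle_s: float = 300.0,
    pulse_eval_s: float = 60.0,
    min_frames: int = 5,
) -> GradientLabel:
    """Classify the bottom-pixel position before/after nucleation and the
    VISF inversion.

    ``profiles`` is ``(n_frames, n_pixels)`` with pixel 0 at the vial
    bottom.  The bottom is LOWEST in a window when it sits at or below
    every other pixel minus ``margin_K`` in >= 80 % of the window frames
    (HIGHEST symmetric, otherwise UNCLEAR).

    * *before* window: ends at the vacuum-pulse start (or at nucleation if
      no pulse time is known);
    * *pulse* window: the last ``pulse_eval_s`` before nucleation;
    * *after* window: ``after_window_s`` starting ``after_settle_s`` past
      nucleation.

    ``visf_inversion`` is YES iff the bottom flips LOWEST -> HIGHEST
    across the pulse, NO if it stays LOWEST, UNCLEAR otherwise, and NA for
    spontaneous nucleation.
    """
    time_s = np.asarray(time_s, dtype=float)
    profiles = np.asarray(profiles, dtype=float)
    t_before_end = t_pulse_start if t_pulse_start is not None else t_nucleation

    def window(lo, hi):
        sel = (time_s >= lo) & (time_s < hi)
        if sel.sum() < min_frames:
            raise ValueError(
                f"window [{lo:.0f}, {hi:.0f}) s has {int(sel.sum())} frames "
                f"(< {min_frames})")
        return profiles[sel]

    before = _window_position(window(t_before_end - before_window_s,
                                     t_before_end), margin_K)
    after = _window_position(window(t_nucleation + after_settle_s,
                                    t_nucleation + after_settle_s + after_window_s),
                             margin_K)
    if NucleationMode(nucleation_mode) is NucleationMode.SPONTANEOUS:
        return GradientLabel(before, after, InversionLabel.NA)

    pulse = _window_position(window(t_nucleation - pulse_eval_s, t_nucleation),
                             margin_K)
    if before is GradientPosition.LOWEST and pulse is GradientPosition.HIGHEST:
        inv = InversionLabel.YES
    elif before is GradientPosition.LOWEST and pulse is GradientPosition.LOWEST:
        inv = InversionLabel.NO
    else:
        inv = InversionLabel.UNCLEAR
    return GradientLabel(before, after, inv)
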