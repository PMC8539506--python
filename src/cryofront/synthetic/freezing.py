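"""1-D vial-freezing simulator.

A nodal enthalpy-marching scheme on a vertical stack of cells spanning the
cake height.  Three phases are simulated per vial:

1. **Liquid cooling** of the solution toward the shelf / gas setpoint
   (explicit conduction; boundary exchange integrated by exact exponential
   relaxation so arbitrarily large contact coefficients stay stable).
2. **Nucleation**: an instantaneous adiabatic jump of the whole nucleated
   column to the equilibrium freezing temperature.  The frozen fraction
   created at each node follows the heat balance implemented by
   :func:`instant_freeze_fraction`.
3. **Front propagation**:

   * ``ON_SHELF`` -- a sharp bottom-up front advanced by a quasi-steady
     energy balance through the growing frozen layer (bottom contact
     coefficient in series with the ice layer).  In the limit of ideal
     shelf contact this converges to the one-sided Stefan solution, which
     is the analytic oracle used in the tests.
   * ``OFF_SHELF`` -- a mushy-zone enthalpy march with heat removed from
     the bottom and top boundaries, emulating the suspended configuration:
     freezing closes in from both ends and the warmest point sits near
     mid-height, so no single front exists.

Units: the public dataclasses use bench units (J/(g K), J/g, g/cm^3, mm);
the integrator converts to SI internally.  The explicit time step is bound
by the conduction stability criterion with a configurable safety factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

logger = logging.getLogger(__name__)


class Loading(str, Enum):
    ON_SHELF = "ON_SHELF"
    OFF_SHELF = "OFF_SHELF"


class NucleationMode(str, Enum):
    SPONTANEOUS = "SPONTANEOUS"
    VISF = "VISF"


@dataclass
class FreezingProtocol:
    """Freezing recipe for one batch.

    ``Tn_target`` is the intended nucleation temperature; ``T_shelf_hold``
    the shelf holding temperature applied after nucleation, followed by a
    ramp at ``ramp_rate`` K/min down to ``T_final``.
    """

    loading: Loading = Loading.ON_SHELF
    nucleation_mode: NucleationMode = NucleationMode.VISF
    Tn_target: float = 271.0
    T_shelf_hold: float = 258.0
    ramp_rate: float = 0.5
    T_final: float = 223.0
    hold_minutes: float = 60.0

    def __post_init__(self):
        self.loading = Loading(self.loading)
        self.nucleation_mode = NucleationMode(self.nucleation_mode)
        if not self.Tn_target < 273.15:
            raise ValueError("Tn_target must be below 273.15 K")
        if self.ramp_rate <= 0:
            raise ValueError("ramp_rate must be positive")
        if not (self.T_final <= self.T_shelf_hold <= self.Tn_target + 10.0):
            raise ValueError("require T_final <= T_shelf_hold <= Tn_target + 10 K")


@dataclass
class PhysicalProperties:
    """Thermophysical properties and effective heat-transfer coefficients.

    ``latent_heat_eq`` is the latent heat of fusion at ``T_eq``; at a
    supercooled nucleation temperature it is corrected by the specific-heat
    difference between liquid and ice (see :func:`instant_freeze_fraction`).
    ``T_eq`` defaults to 273.0 K, a per-solution constant absorbing the
    cryoscopic depression of dilute (~5 % w/w) excipient solutions.

    The ``h_*`` coefficients are *effective* calibration knobs for the
    loading configuration, not measured dryer values.
    """

    cp_liquid: float = 4.18       # J/(g K)
    cp_ice: float = 2.1           # J/(g K)
    latent_heat_eq: float = 334.0  # J/g at T_eq
    T_eq: float = 273.0           # K
    k_ice: float = 2.14           # W/(m K)
    k_liquid: float = 0.6         # W/(m K)
    density: float = 0.95         # g/cm^3
    h_bottom: float = 250.0       # W/(m^2 K)
    h_side: float = 3.0
    h_top: float = 5.0

    def __post_init__(self):
        for name in ("cp_liquid", "cp_ice", "latent_heat_eq", "k_ice",
                     "k_liquid", "density", "h_bottom", "h_side", "h_top"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.k_ice <= self.k_liquid:
            raise ValueError("k_ice must exceed k_liquid")
        if self.T_eq > 273.15:
            raise ValueError("T_eq cannot exceed 273.15 K")


def default_properties(loading: Loading | str) -> PhysicalProperties:
    """Effective properties per loading configuration.

    ON-shelf: conduction-dominated bottom contact, negligible side/top.
    OFF-shelf: weak natural convection + radiation at bottom, side and top;
    the bottom coefficient slightly exceeds the top so that after
    nucleation the bottom boundary ends up coldest, as observed.
    """
    if Loading(loading) is Loading.ON_SHELF:
        return PhysicalProperties(h_bottom=250.0, h_side=3.0, h_top=5.0)
    return PhysicalProperties(h_bottom=22.0, h_side=5.0, h_top=11.0)


@dataclass
class SimulationSettings:
    """Numerical and scenario knobs that are not part of the protocol."""

    cake_height_mm: float = 10.0
    vial_diameter_mm: float = 22.0
    T_initial: float = 278.0
    gas_offset_K: float = 4.0         # chamber gas above shelf setpoint (ON-shelf)
    visf_equil_offset_K: float = 2.0  # shelf below Tn_target while equilibrating
    equil_tolerance_K: float = 0.5
    equil_hold_s: float = 300.0
    visf_pulse_s: float = 120.0
    visf_pulse_rate: float = 0.12     # K/s evaporative cooling rate at the cake top
    visf_pulse_enabled: bool = True
    visf_bottom_decouple: float = 0.05  # h_bottom multiplier at vacuum pressure
    visf_jitter_s: float = 80.0       # max per-vial nucleation delay after the pulse
    spont_rate_per_s: float = 1.0 / 900.0  # exponential nucleation clock rate
    slush_cool_base: float = 1e-3     # K/s uniform slush cooling above the front
    slush_cool_top: float = 5e-3      # K/s extra at the cake top (linear in height)
    slush_grad_K_per_mm: float = 0.15  # quasi-steady slush gradient above the front
    mushy_depression_K: float = 1.5   # T drop across nucleation -> full freeze
    off_bottom_warm_K: float = 6.0    # warm bias of the gas under suspended vials
    off_liquid_h_scale: float = 5.0   # liquid-phase convective boost (suspended)
    off_equil_offset_K: float = 4.5   # OFF-shelf shelf-below-Tn equilibration offset
    record_dt_s: float = 10.0
    t_max_s: float = 10800.0
    stop_T_K: float = 261.0           # stop once every node is this cold
    dt_safety: float = 0.4


@dataclass
class VialThermalHistory:
    """Simulated axial temperature field for one vial.

    ``T_axial`` is ``(n_nodes, n_times)``; ``heights_mm`` are node (cell
    centre) heights from the vial bottom.  ``front_position_mm`` holds the
    sharp-front position for ON-shelf vials and NaN after nucleation for
    OFF-shelf vials, where no single front exists.  ``T_pre_nucleation``
    and ``f0_nodes`` snapshot the nodal state across the nucleation jump
    for energy-balance checks.
    """

    time_s: np.ndarray
    heights_mm: np.ndarray
    T_axial: np.ndarray
    front_position_mm: np.ndarray
    frozen_fraction: np.ndarray
    t_nucleation_s: float
    t_pulse_start_s: float | None
    T_pre_nucleation: np.ndarray
    f0_nodes: np.ndarray
    loading: Loading
    nucleation_mode: NucleationMode
    vial_id: str = "vial00"

    def __post_init__(self):
        if not np.all(np.isfinite(self.T_axial)):
            raise ValueError("T_axial contains non-finite values")
        ff = self.frozen_fraction
        if np.any(ff < -1e-12) or np.any(ff > 1 + 1e-12):
            raise ValueError("frozen_fraction outside [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.T_axial.shape[0]


def instant_freeze_fraction(Tn: float, props: PhysicalProperties) -> float:
    """Fraction of freezable liquid that solidifies instantly at nucleation.

    Adiabatic balance between the sensible heat gained by the slush
    returning from the supercooled state ``Tn`` to ``T_eq`` and the latent
    heat released by the instantly frozen fraction ``f``::

        f = cp_liquid * (T_eq - Tn) / dHf(Tn)
        dHf(Tn) = dHf(T_eq) - (cp_liquid - cp_ice) * (T_eq - Tn)

    Raises ``ValueError`` if ``Tn`` exceeds ``T_eq`` (no supercooling).
    """
    dT = props.T_eq - Tn
    if dT < 0:
        raise ValueError(f"Tn={Tn} K above T_eq={props.T_eq} K: no supercooling")
    dhf = props.latent_heat_eq - (props.cp_liquid - props.cp_ice) * dT
    if dhf <= 0:
        raise ValueError("latent heat correction became non-positive")
    f = props.cp_liquid * dT / dhf
    if f >= 1.0:
        raise ValueError("supercooling too deep: instant fraction >= 1")
    return f


def _instant_fraction_nodes(T_nodes: np.ndarray, props: PhysicalProperties) -> np.ndarray:
    """Vectorised node-wise instant fraction, zero where T >= T_eq."""
    dT = np.clip(props.T_eq - T_nodes, 0.0, None)
    dhf = props.latent_heat_eq - (props.cp_liquid - props.cp_ice) * dT
    return np.where(dT > 0, props.cp_liquid * dT / dhf, 0.0)


class _ShelfSchedule:
    """Shelf setpoint: pre-nucleation setpoint, post-nucleation hold, ramp."""

    def __init__(self, protocol: FreezingProtocol, settings: SimulationSettings):
        self.protocol = protocol
        if protocol.nucleation_mode is NucleationMode.VISF:
            offset = (settings.visf_equil_offset_K
                      if protocol.loading is Loading.ON_SHELF
                      else settings.off_equil_offset_K)
            self.pre_T = protocol.Tn_target - offset
        else:
            self.pre_T = protocol.T_shelf_hold
        self.t_nucleation: float | None = None

    def __call__(self, t: float) -> float:
        p = self.protocol
        if self.t_nucleation is None or t < self.t_nucleation:
            return self.pre_T
        t_ramp = self.t_nucleation + p.hold_minutes * 60.0
        if t <= t_ramp:
            return p.T_shelf_hold
        return max(p.T_shelf_hold - p.ramp_rate / 60.0 * (t - t_ramp), p.T_final)


class _Recorder:
    """Samples the nodal state on a fixed ``record_dt_s`` grid.

    The state is captured on the first integrator step at or past each grid
    time and stamped with the *nominal* grid time (the step is at most 1 s,
    the grid 10 s, so the mismatch is negligible and every vial in a batch
    lands on one common grid).
    """

    def __init__(self, record_dt: float):
        self.dt = record_dt
        self.next = 0.0
        self.t, self.T, self.z, self.ff = [], [], [], []

    def maybe(self, t, T, z, ff):
        while t + 1e-9 >= self.next:
            self.t.append(self.next)
            self.T.append(T.copy())
            self.z.append(z)
            self.ff.append(ff)
            self.next += self.dt


def _relax(T, idx, T_env, rate, dt):
    """Exact exponential relaxation of node(s) toward an environment."""
    T[idx] = T_env + (T[idx] - T_env) * np.exp(-rate * dt)


def simulate_vial_freezing(
    protocol: FreezingProtocol,
    props: PhysicalProperties | None = None,
    n_nodes: int = 32,
    seed: int = 0,
    settings: SimulationSettings | None = None,
    vial_id: str = "vial00",
) -> VialThermalHistory:
    """Simulate one vial through liquid cooling, nucleation and freezing."""
    if n_nodes < 4:
        raise ValueError("n_nodes must be at least 4")
    props = props if props is not None else default_properties(protocol.loading)
    cfg = settings if settings is not None else SimulationSettings()
    rng = np.random.default_rng(seed)

    H = cfg.cake_height_mm * 1e-3                  # m
    dx = H / n_nodes
    heights_m = (np.arange(n_nodes) + 0.5) * dx
    rho = props.density * 1000.0                   # kg/m^3
    cp_l = props.cp_liquid * 1000.0                # J/(kg K)
    dhf_eq = props.latent_heat_eq * 1000.0         # J/kg
    side_per_vol = 4.0 / (cfg.vial_diameter_mm * 1e-3)

    shelf = _ShelfSchedule(protocol, cfg)
    on_shelf = protocol.loading is Loading.ON_SHELF
    visf = protocol.nucleation_mode is NucleationMode.VISF
    rec = _Recorder(cfg.record_dt_s)

    T = np.full(n_nodes, cfg.T_initial, dtype=float)

    # ---------------- phase 1: liquid cooling -------------------------------
    dt = cfg.dt_safety * rho * cp_l * dx * dx / (2.0 * props.k_liquid)
    inv_rcp = 1.0 / (rho * cp_l)
    a_side = props.h_side * side_per_vol * inv_rcp
    t = 0.0
    t_armed = None
    t_pulse_start = None
    t_nucleation = None
    spont_wait = None
    jitter = float(rng.uniform(0.0, cfg.visf_jitter_s))

    while t < cfg.t_max_s:
        rec.maybe(t, T, 0.0, 0.0)
        Tsh = shelf(t)
        gas = Tsh + (cfg.gas_offset_K if on_shelf else 0.0)
        # the low-pressure pulse (evaporative top cooling + gas-gap
        # decoupling of the bottom contact) is modelled only when enabled;
        # the 263 K scenario nucleates before any pulse gradient develops
        in_pulse = (visf and cfg.visf_pulse_enabled
                    and t_pulse_start is not None)

        lap = np.zeros(n_nodes)
        lap[1:-1] = np.diff(T, 2)
        lap[0] = T[1] - T[0]
        lap[-1] = T[-2] - T[-1]
        T += props.k_liquid * lap / (dx * dx) * inv_rcp * dt
        if in_pulse:
            T -= cfg.visf_pulse_rate * heights_m / H * dt
        liq_scale = 1.0 if on_shelf else cfg.off_liquid_h_scale
        h_b = props.h_bottom * liq_scale * (cfg.visf_bottom_decouple if in_pulse else 1.0)
        T_below = Tsh if on_shelf else gas + cfg.off_bottom_warm_K
        _relax(T, 0, T_below, h_b * inv_rcp / dx, dt)
        _relax(T, -1, gas, props.h_top * liq_scale * inv_rcp / dx, dt)
        _relax(T, slice(None), gas, a_side, dt)
        t += dt

        if visf:
            if t_armed is None and T[0] <= protocol.Tn_target + cfg.equil_tolerance_K:
                t_armed = t
            if t_armed is not None and t_pulse_start is None and t >= t_armed + cfg.equil_hold_s:
                t_pulse_start = t
            if t_pulse_start is not None and t >= t_pulse_start + cfg.visf_pulse_s + jitter:
                t_nucleation = t
                break
        else:
            # clock armed once the whole column is at/below the target
            if t_armed is None and T.max() <= protocol.Tn_target:
                t_armed = t
                spont_wait = float(rng.exponential(1.0 / cfg.spont_rate_per_s))
            if t_armed is not None and t >= t_armed + spont_wait:
                t_nucleation = t
                break

    if t_nucleation is None:
        raise RuntimeError("no nucleation within t_max_s; check protocol/settings")
    shelf.t_nucleation = t_nucleation

    # ---------------- nucleation jump ---------------------------------------
    T_pre = T.copy()
    f0 = _instant_fraction_nodes(T_pre, props)
    T = np.full(n_nodes, props.T_eq, dtype=float)
    f0_mean = float(f0.mean())

    # ---------------- phase 3 -----------------------------------------------
    if on_shelf:
        _march_sharp_front(T, f0_mean, t, shelf, props, cfg, heights_m, dx, rho,
                           dhf_eq, rec)
    else:
        _march_mushy(T, f0, t, shelf, props, cfg, dx, rho, dhf_eq,
                     side_per_vol, rec)

    time_s = np.asarray(rec.t)
    T_axial = np.asarray(rec.T).T
    front = np.asarray(rec.z, dtype=float)
    if not on_shelf:
        front = np.where(time_s > t_nucleation, np.nan, front)
    ff = np.clip(np.asarray(rec.ff), 0.0, 1.0)
    return VialThermalHistory(
        time_s=time_s,
        heights_mm=heights_m * 1e3,
        T_axial=T_axial,
        front_position_mm=front,
        frozen_fraction=ff,
        t_nucleation_s=float(t_nucleation),
        t_pulse_start_s=t_pulse_start,
        T_pre_nucleation=T_pre,
        f0_nodes=f0,
        loading=protocol.loading,
        nucleation_mode=protocol.nucleation_mode,
        vial_id=vial_id,
    )


def _march_sharp_front(T, f0_mean, t, shelf, props, cfg, heights_m, dx, rho,
                       dhf_eq, rec):
    """ON-shelf quasi-steady front growth + slush cooling above the front.

    ``dz/dt = q / (rho * L_eff)`` with the flux limited by the bottom
    contact coefficient in series with the frozen layer; ``L_eff`` is the
    latent heat still to be released after the nucleation jump.
    """
    H = cfg.cake_height_mm * 1e-3
    Teq = props.T_eq
    L_eff = dhf_eq * (1.0 - f0_mean)
    z = 0.0
    dt = 1.0
    # cumulative slush cooling is tracked separately from the quasi-steady
    # gradient anchored at the moving front (side-loss balance in the slush)
    drop = np.zeros_like(T)
    # integrate the quasi-steady balance rho*L*(z^2/2k + z/h) = int dT dt in
    # its integrated variable u, which stays exact even as z -> 0 or h -> inf
    k_i, h_b = props.k_ice, props.h_bottom
    u = 0.0
    while t < cfg.t_max_s and z < H:
        Tsh = shelf(t)
        u += max(Teq - Tsh, 0.0) / (rho * L_eff) * dt
        z = min(k_i * (-1.0 / h_b + np.sqrt(1.0 / h_b**2 + 2.0 * u / k_i)), H)
        q = max(Teq - Tsh, 0.0) / (1.0 / h_b + z / k_i)
        Tb = Tsh + q / h_b
        below = heights_m <= z
        if below.any() and z > 0:
            T[below] = Tb + (Teq - Tb) * heights_m[below] / z
        above = ~below
        if above.any():
            cool = cfg.slush_cool_base + cfg.slush_cool_top * heights_m[above] / H
            drop[above] += cool * dt
            anchored = cfg.slush_grad_K_per_mm * (heights_m[above] - z) * 1e3
            T[above] = np.maximum(Teq - anchored - drop[above], Tsh)
        t += dt
        ff = f0_mean + (1.0 - f0_mean) * z / H
        rec.maybe(t, T, z * 1e3, ff)
    _march_solid(T, t, shelf, props, cfg, dx, rho, rec, z_mm=H * 1e3)


def _march_solid(T, t, shelf, props, cfg, dx, rho, rec, z_mm):
    """Conductive cool-down of the fully frozen ON-shelf product."""
    cp_i = props.cp_ice * 1000.0
    inv_rcp = 1.0 / (rho * cp_i)
    side_per_vol = 4.0 / (cfg.vial_diameter_mm * 1e-3)
    a_side = props.h_side * side_per_vol * inv_rcp
    dt = cfg.dt_safety * rho * cp_i * dx * dx / (2.0 * props.k_ice)
    n = T.size
    while t < cfg.t_max_s:
        Tsh = shelf(t)
        if T.max() <= max(cfg.stop_T_K, Tsh + 1.0):
            break
        gas = Tsh + cfg.gas_offset_K
        lap = np.zeros(n)
        lap[1:-1] = np.diff(T, 2)
        lap[0] = T[1] - T[0]
        lap[-1] = T[-2] - T[-1]
        T += props.k_ice * lap / (dx * dx) * inv_rcp * dt
        _relax(T, 0, Tsh, props.h_bottom * inv_rcp / dx, dt)
        _relax(T, -1, gas, props.h_top * inv_rcp / dx, dt)
        _relax(T, slice(None), gas, a_side, dt)
        t += dt
        rec.maybe(t, T, z_mm, 1.0)


def _march_mushy(T, f0, t, shelf, props, cfg, dx, rho, dhf_eq, side_per_vol, rec):
    """OFF-shelf mushy-zone enthalpy march with bottom+top heat removal.

    While a node's frozen fraction grows from its nucleation value to 1 its
    temperature is tied to the freezing progress through a small mushy
    depression (a cryoconcentration proxy), so the least-frozen mid-height
    region stays warmest -- which is what the camera observes for
    suspended vials.  Freezing closes in from both ends; melting is not
    allowed (the frozen fraction is monotone).
    """
    n = T.size
    delta = cfg.mushy_depression_K
    Teq = props.T_eq
    cp_l = props.cp_liquid * 1000.0
    cp_i = props.cp_ice * 1000.0
    phi = f0.copy()
    one_m_f0 = np.clip(1.0 - f0, 1e-9, None)
    dt = cfg.dt_safety * min(
        rho * cp_i * dx * dx / (2.0 * props.k_ice),
        rho * cp_i * dx / max(props.h_bottom, props.h_top),
    )
    while t < cfg.t_max_s:
        Tsh = shelf(t)
        gas = Tsh
        k = phi * props.k_ice + (1 - phi) * props.k_liquid
        cp = phi * cp_i + (1 - phi) * cp_l
        kf = 2.0 * k[:-1] * k[1:] / (k[:-1] + k[1:])
        flux = kf * np.diff(T) / dx                 # W/m^2, positive = upward gain
        dq = np.zeros(n)                            # W/m^3
        dq[:-1] += flux / dx
        dq[1:] -= flux / dx
        dq[0] += props.h_bottom * (gas - T[0]) / dx
        dq[-1] += props.h_top * (gas - T[-1]) / dx
        dq += props.h_side * side_per_vol * (gas - T)
        dQ = dq * dt                                # J/m^3

        mushy = phi < 1.0
        c_app = rho * (cp + dhf_eq * one_m_f0 / delta)  # apparent heat capacity
        dphi_raw = -dQ / c_app * one_m_f0 / delta
        new_phi = np.clip(phi + dphi_raw, phi, 1.0)
        overshoot = mushy & (phi + dphi_raw > 1.0)
        if overshoot.any():
            used = (1.0 - phi[overshoot]) * delta / one_m_f0[overshoot]
            leftover = dQ[overshoot] + c_app[overshoot] * used
        phi = np.where(mushy, new_phi, phi)
        T[mushy] = Teq - delta * (phi[mushy] - f0[mushy]) / one_m_f0[mushy]
        solid = ~mushy
        T[solid] += dQ[solid] / (rho * cp_i)
        if overshoot.any():
            T[overshoot] += leftover / (rho * cp_i)

        t += dt
        rec.maybe(t, T, np.nan, float(phi.mean()))
        if phi.min() >= 1.0 - 1e-9 and T.max() <= max(cfg.stop_T_K, Tsh + 1.0):
            break


def simulate_batch(
    protocol: FreezingProtocol,
    props: PhysicalProperties | None = None,
    n_vials: int = 10,
    n_nodes: int = 32,
    seed: int = 0,
    settings: SimulationSettings | None = None,
) -> list[VialThermalHistory]:
    """Simulate a batch of vials on one common record grid.

    Each vial gets an independent seeded RNG stream.  Shorter histories are
    padded (state held at the last computed profile) so the whole batch
    shares one time grid, as the renderer requires.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_vials)
    histories = [
        simulate_vial_freezing(
            protocol, props, n_nodes=n_nodes, seed=int(s),
            settings=settings, vial_id=f"vial{i:02d}",
        )
        for i, s in enumerate(seeds)
    ]
    cfg = settings if settings is not None else SimulationSettings()
    n_max = max(h.time_s.size for h in histories)
    grid = np.arange(n_max) * cfg.record_dt_s
    padded = []
    for h in histories:
        k = n_max - h.time_s.size
        if k == 0:
            padded.append(h)
            continue
        T_pad = np.concatenate(
            [h.T_axial, np.repeat(h.T_axial[:, -1:], k, axis=1)], axis=1)
        z_pad = np.concatenate(
            [h.front_position_mm, np.full(k, h.front_position_mm[-1])])
        f_pad = np.concatenate(
            [h.frozen_fraction, np.full(k, h.frozen_fraction[-1])])
        padded.append(replace(
            h, time_s=grid, T_axial=T_pad, front_position_mm=z_pad,
            frozen_fraction=f_pad,
        ))
    return padded
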