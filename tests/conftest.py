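"""Shared fixtures: simulated vials/batches, rendered stacks, SEM suites.

Heavy simulations are session-scoped so the acceptance tests and the unit
tests share them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import cryofront as cf
from cryofront.ir import batch_trace, line_trace, vial_trace
from cryofront.mia import segment_pores
from cryofront.synthetic.render import CameraConfig, render_thermal_stack


@pytest.fixture(scope="session")
def water_props():
    """Pure-water property set (equilibrium at 273.15 K)."""
    return cf.PhysicalProperties(T_eq=273.15)


@pytest.fixture()
def make_history():
    """Factory for hand-built vial histories (for renderer tests)."""

    def _make(T_axial, time_s=None, heights_mm=None, t_nucleation=0.0,
              vial_id="v00", loading="ON_SHELF", mode="VISF"):
        T_axial = np.asarray(T_axial, dtype=float)
        n_nodes, n_times = T_axial.shape
        if time_s is None:
            time_s = np.arange(n_times) * 10.0
        if heights_mm is None:
            heights_mm = (np.arange(n_nodes) + 0.5) * (10.0 / n_nodes)
        return cf.VialThermalHistory(
            time_s=np.asarray(time_s, dtype=float),
            heights_mm=np.asarray(heights_mm, dtype=float),
            T_axial=T_axial,
            front_position_mm=np.zeros(n_times),
            frozen_fraction=np.zeros(n_times),
            t_nucleation_s=t_nucleation,
            t_pulse_start_s=None,
            T_pre_nucleation=T_axial[:, 0].copy(),
            f0_nodes=np.zeros(n_nodes),
            loading=cf.Loading(loading),
            nucleation_mode=cf.NucleationMode(mode),
            vial_id=vial_id,
        )

    return _make


def _protocol(loading, mode, Tn, th):
    return cf.FreezingProtocol(loading=loading, nucleation_mode=mode,
                               Tn_target=Tn, T_shelf_hold=th)


@pytest.fixture(scope="session")
def on_visf271_vial():
    return cf.simulate_vial_freezing(
        _protocol("ON_SHELF", "VISF", 271.0, 258.0), seed=3)


@pytest.fixture(scope="session")
def on_visf263_vial():
    return cf.simulate_vial_freezing(
        _protocol("ON_SHELF", "VISF", 263.0, 258.0),
        settings=cf.SimulationSettings(visf_pulse_enabled=False), seed=3)


@pytest.fixture(scope="session")
def off_visf271_vial():
    return cf.simulate_vial_freezing(
        _protocol("OFF_SHELF", "VISF", 271.0, 248.0), seed=3)


@pytest.fixture(scope="session")
def off_visf263_vial():
    return cf.simulate_vial_freezing(
        _protocol("OFF_SHELF", "VISF", 263.0, 248.0),
        settings=cf.SimulationSettings(visf_pulse_enabled=False), seed=3)


@pytest.fixture(scope="session")
def on_batch10():
    """10-vial ON-shelf VISF-271 batch on a shared grid."""
    return cf.simulate_batch(_protocol("ON_SHELF", "VISF", 271.0, 258.0),
                             n_vials=10, seed=11)


@pytest.fixture(scope="session")
def on_batch_render(on_batch10):
    """Noisy (0.3 K) rendering of the 10-vial batch with traces and truth."""
    camera = CameraConfig(noise_sd=0.3)
    stack, defs = render_thermal_stack(on_batch10, camera, seed=12)
    by_vial: dict[str, list] = {}
    for d in defs:
        by_vial.setdefault(d.vial_id, []).append(d)
    vial_traces = [
        vial_trace([line_trace(stack, d, camera.mm_per_pixel,
                               camera.emissivity, camera.T_reflected)
                    for d in by_vial[h.vial_id]])
        for h in on_batch10
    ]
    batch = batch_trace(vial_traces)
    true_front = np.mean(
        [np.interp(stack.time_s, h.time_s, h.front_position_mm)
         for h in on_batch10], axis=0)
    return dict(stack=stack, defs=defs, camera=camera,
                vial_traces=vial_traces, batch=batch, true_front=true_front)


def render_mean_profiles(history, noise_sd=0.1, seed=5):
    """Render one vial and return its 6-line-mean pixel profiles."""
    from cryofront.ir import line_profile_array

    camera = CameraConfig(noise_sd=noise_sd)
    stack, defs = render_thermal_stack([history], camera, seed=seed)
    profs = np.mean(
        [line_profile_array(stack, d, camera.emissivity, camera.T_reflected)
         for d in defs], axis=0)
    return stack, profs


@pytest.fixture(scope="session")
def sem_suite():
    """Four SEM-like images with 500 pores each plus recovered tables."""
    truths, tables, images = [], [], []
    for i in range(4):
        spec = cf.PoreSpec(n_pores=500, seed=100 + i, porosity_target=0.25)
        image, truth = cf.generate_sem_image(
            spec, image_shape=(1024, 1088), px_size_um=1.0,
            sample_id=f"img{i}")
        _, table = segment_pores(image, score_threshold=0.85)
        truths.append(truth)
        tables.append(table)
        images.append(image)
    return dict(images=images,
                truth=pd.concat(truths, ignore_index=True),
                recovered=pd.concat(tables, ignore_index=True))


def cut_trace(trace, sel):
    """Restrict an ExtremaTrace to a boolean frame selection."""
    kw = {}
    for name in ("Tmax_lo", "Tmax_hi", "Hmax_lo", "Hmax_hi"):
        val = getattr(trace, name)
        kw[name] = val[sel] if val is not None else None
    return dataclasses.replace(
        trace, time_s=trace.time_s[sel], Tmin_K=trace.Tmin_K[sel],
        Tmax_K=trace.Tmax_K[sel], Hmin_mm=trace.Hmin_mm[sel],
        Hmax_mm=trace.Hmax_mm[sel], **kw)
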