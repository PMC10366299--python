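"""Shared fixtures.

The expensive coupled simulations (cell-free calibration, channel
transits, shear-box validations) are session-scoped and shared between
the unit and acceptance tests.  The transit fixture uses the package's
"mini" scaled-down conditions: dx = l/16, membrane subdivision level 3,
domain truncated to x in [-60, 170] um with release at -47 um, and a
Reynolds number of 0.25 (still well below unity); the methods note
documents these choices.
"""

from __future__ import annotations

import copy

import numpy as np
import pytest

from celltransit.channel_geometry import ChannelGeometry
from celltransit.transit_driver import PRESETS, TransitSimulation


def suite_config(**cell_overrides):
    """The transit configuration used throughout the suite."""
    cfg = copy.deepcopy(PRESETS["mini"])
    cfg.geometry = ChannelGeometry(x_min=-60.0, x_max=170.0,
                                   reservoir_width=90.0)
    cfg.numerics.dx_um = 30.0 / 16.0
    cfg.cell.release_x_um = -47.0
    for key, val in cell_overrides.items():
        setattr(cfg.cell, key, val)
    return cfg


@pytest.fixture(scope="session")
def background_cache():
    """Calibrated cell-free flow for the suite geometry."""
    sim = TransitSimulation(suite_config())
    sim.prepare_background()
    return sim.background_cache()


def _run(background_cache, x_stop, **cell_overrides):
    sim = TransitSimulation(suite_config(**cell_overrides))
    sim.prepare_background(cache=background_cache)
    sim.insert_cell()
    return sim.run_transit(x_stop_um=x_stop)


@pytest.fixture(scope="session")
def transit_runs(background_cache):
    """Transit records for the parametric property checks.

    Full-length runs for the hyperelastic baseline and the constant
    membrane-viscosity cell (steady-state comparisons); shorter runs
    through the constriction for the remaining parameter variations.
    """
    runs = {}
    runs["hyper"] = _run(background_cache, 137.0)
    runs["eta5"] = _run(background_cache, 137.0, visc_kind="constant",
                        eta_star=5.0)
    runs["eta40"] = _run(background_cache, 25.0, visc_kind="constant",
                         eta_star=40.0)
    runs["blend"] = _run(background_cache, 25.0,
                         visc_kind="flow_type_blend")
    runs["lam5"] = _run(background_cache, 25.0, lam=5.0)
    runs["nuc07"] = _run(background_cache, 25.0, an_ratio=0.7)
    return runs


def constriction_peak(rec, window=(-30.0, 25.0)):
    """Maximum DI and its station within the converging-region window."""
    x = np.asarray(rec.x)
    di = np.asarray(rec.DI)
    m = (x > window[0]) & (x < window[1])
    i = int(np.argmax(di[m]))
    return float(di[m][i]), float(x[m][i])


def steady_di(rec, x_from=120.0):
    x = np.asarray(rec.x)
    di = np.asarray(rec.DI)
    m = x >= min(x_from, x[-1] - 20.0)
    return float(di[m].mean())


@pytest.fixture(scope="session")
def shear_results():
    """Steady Taylor parameters of the shear-box validation runs."""
    from celltransit.transit_driver import run_shear_box
    out = {}
    for eta, steps in ((0.0, 5000), (5.0, 8000), (10.0, 11000)):
        res = run_shear_box(Ca=0.04, eta_star=eta, C=1.0, steps=steps,
                            record_every=250)
        out[eta] = res
    return out
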