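"""Shared fixtures: Monte Carlo runs are expensive, so transport is run
once per session per geometry and reused; flow states enter only through
the correlation weighting, so one history table serves baseline and
perturbed evaluations alike."""

from __future__ import annotations

import numpy as np
import pytest

from speckleflow.forward import OpticalProperties
from speckleflow.histories import DetectorSpec
from speckleflow.montecarlo import (
    TABLE1_OPTICS,
    SlabGeometry,
    run_layered_mc,
    slab_preset,
)

MC_PHOTONS = 1_000_000


@pytest.fixture(scope="session")
def homogeneous_mc():
    """Homogeneous semi-infinite medium (scalp optics at 850 nm) with
    detectors at 10/15/25 mm: the analytic-oracle geometry."""
    optics = {"scalp": TABLE1_OPTICS[850]["scalp"]}
    geom = SlabGeometry(
        layers=(("scalp", None),),
        detectors=tuple(DetectorSpec(i, s) for i, s in enumerate((10.0, 15.0, 25.0))),
    )
    return run_layered_mc(geom, optics, MC_PHOTONS, seed=101), optics


@pytest.fixture(scope="session")
def slab15_mc():
    """Four-layer head slab, 15 mm scalp-to-brain distance, 850 nm."""
    geom = slab_preset(15.0)
    return run_layered_mc(geom, TABLE1_OPTICS[850], MC_PHOTONS, seed=202)


@pytest.fixture(scope="session")
def slab15_mc_1064():
    """Same slab at the 1064 nm optical properties."""
    geom = slab_preset(15.0)
    return run_layered_mc(geom, TABLE1_OPTICS[1064], MC_PHOTONS, seed=505,
                          wavelength_nm=1064.0)


@pytest.fixture(scope="session")
def slab_mc_by_thickness(slab15_mc):
    """10/15/20 mm extracerebral-thickness runs for the depth sweep."""
    runs = {15.0: slab15_mc}
    for thick, seed in ((10.0, 303), (20.0, 404)):
        geom = slab_preset(thick)
        runs[thick] = run_layered_mc(geom, TABLE1_OPTICS[850], MC_PHOTONS, seed=seed)
    return runs
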