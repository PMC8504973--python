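"""Shared fixtures: model truths, optics, and synthetic panels."""

import numpy as np
import pytest

from mwcgate.allosteric import MWCParameters, SensorOptics
from mwcgate.reference import (
    ANCHOR_L_PA,
    PUBLISHED_FACTORS,
    SENSOR_OPTICS,
    anchor_two_state_parameters,
    study_truth_parameters,
)
from mwcgate.synth import NON_FUNCTIONAL, GeneratorSpec, generate_mutant_panel
from mwcgate.titration import TitrationSeries


@pytest.fixture(scope="session")
def bim136_optics() -> SensorOptics:
    return SENSOR_OPTICS["Bim136-Q101W"]


@pytest.fixture(scope="session")
def bim250_optics() -> SensorOptics:
    return SENSOR_OPTICS["Bim250-Y197"]


@pytest.fixture(scope="session")
def anchor_params() -> MWCParameters:
    """Two-state model with the published anchor constants."""
    return anchor_two_state_parameters()


@pytest.fixture(scope="session")
def sensor_truth() -> MWCParameters:
    """Three-state truth emulating the ECD-compaction sensor."""
    return study_truth_parameters("Bim136-Q101W")


@pytest.fixture(scope="session")
def study_panel(sensor_truth, bim136_optics):
    """Seeded panel: sensor + published-factor pseudo-mutants + pore-dead anchor."""
    factors = dict(PUBLISHED_FACTORS)
    factors["H235F"] = (ANCHOR_L_PA / sensor_truth.L_pA, NON_FUNCTIONAL)
    spec = GeneratorSpec(
        truth="mwc", params=sensor_truth, optics=bim136_optics,
        sigma=0.01, replicates=3, seed=1,
    )
    return generate_mutant_panel(sensor_truth, bim136_optics, factors, spec, sensor_name="sensor")


def make_fluor_series(ph, response, construct="X", replicate="rep1", f_sds=None, normalized=True):
    ph = np.asarray(ph, dtype=float)
    return TitrationSeries(
        construct=construct,
        modality="fluorescence",
        replicate=replicate,
        order=np.arange(ph.size),
        ph=ph,
        response=np.asarray(response, dtype=float),
        is_reference=np.zeros(ph.size, dtype=bool),
        f_sds=f_sds,
        normalized=normalized,
    )


def make_current_series(ph, response, construct="X", replicate="rep1", is_reference=None):
    ph = np.asarray(ph, dtype=float)
    if is_reference is None:
        is_reference = np.zeros(ph.size, dtype=bool)
    return TitrationSeries(
        construct=construct,
        modality="current",
        replicate=replicate,
        order=np.arange(ph.size),
        ph=ph,
        response=np.asarray(response, dtype=float),
        is_reference=np.asarray(is_reference, dtype=bool),
    )
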