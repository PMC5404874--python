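"""Shared fixtures: electrode, analytic field, circuit, waveform, and small
fiber populations (session-scoped to amortize model settling and JIT
compilation across tests)."""

import numpy as np
import pytest

from pamsim.circuit import (CircuitParams, StimulusProtocol,
                            simulate_tissue_waveform)
from pamsim.field import ElectrodeSpec, build_analytic_field
from pamsim.pathways import (AxonTrajectory, FiberGeometry, Streamline,
                             compartmentalize)
from pamsim.axon import build_axon


@pytest.fixture(scope="session")
def electrode():
    return ElectrodeSpec.centered()


@pytest.fixture(scope="session")
def analytic_field(electrode):
    return build_analytic_field(electrode, 0.2, 0.1)


@pytest.fixture(scope="session")
def circuit_params(analytic_field):
    return CircuitParams().with_tissue_resistance(
        analytic_field.access_resistance_ohm)


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol(amplitude_V=1.0, pulse_width_us=60.0,
                            frequency_Hz=130.0, n_pulses=3)


@pytest.fixture(scope="session")
def tissue_waveform(circuit_params, protocol):
    return simulate_tissue_waveform(circuit_params, protocol)


def straight_fiber_model(distance_mm=3.0, n_internodes=21,
                         fiber_diameter_um=5.7):
    """Straight fiber parallel to the electrode axis at a lateral offset."""
    geom = FiberGeometry.from_diameter(fiber_diameter_um)
    length = n_internodes * geom.internode_length_um * 1e-3
    z = np.linspace(-length / 2, length / 2, 400)
    line = Streamline(np.column_stack(
        [np.full_like(z, distance_mm), np.zeros_like(z), z]))
    morph = compartmentalize(AxonTrajectory(main=line), geom)
    return build_axon(morph)


@pytest.fixture(scope="session")
def fiber_model():
    """One settled 21-internode 5.7 um fiber, 3 mm from the contact."""
    return straight_fiber_model()
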