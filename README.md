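# pamsim

Pathway-activation modelling for deep brain stimulation (DBS).

Clinicians program a DBS device by choosing a contact, an amplitude, a
pulse width and a frequency; which axonal pathways those settings
actually drive is invisible at the bedside.  Pathway-activation models
(PAMs) answer that question computationally: they combine a model of
the stimulus reaching the tissue with multi-compartment cable models of
the axon populations around the electrode and report, per pathway, the
percentage of fibers firing one-to-one with the stimulus train.
`pamsim` implements that workflow as a reusable library and command-line
tool for the two pathways at the heart of subthalamic DBS — internal
capsule fibers of passage (side effects) and hyperdirect-pathway axons
with a subthalamic collateral (therapy) — exercisable end to end on
synthetic inputs, with import hooks for externally solved fields and
real tractography streamlines.

## Model core

The extracellular potential factorizes by linearity as

    Phi(x, t) = Phi_unit(x) · A · V_tissue(t)

* **`pamsim.circuit`** — `V_tissue(t)`: an equivalent circuit of the
  implanted system (blocking capacitor 10 uF, wire resistance 55 Ohm,
  electrode-tissue interface 1.8 uF ‖ 2.5 kOhm, tissue resistance from
  the field model, parasitic 3 nF–20 kOhm branch) integrated by forward
  Euler through the four switching topologies of each stimulus period
  and normalized to unit cathodic peak.  Also computes the dynamic load
  impedance an implanted pulse generator reports (70 us into an 80 us
  pulse) and calibrates the encapsulation conductivity to a measured
  impedance.
* **`pamsim.field`** — `Phi_unit(x)`: a spherical-equivalent analytic
  surrogate of the electrode (equal-area contact sphere at -1 V plus
  encapsulation shell, isotropic or anisotropic), or an imported
  structured-grid solution; plus the diffusion-tensor-to-conductivity
  mapping (eigenvectors kept, eigenvalues rescaled to a fixed geometric
  mean).
* **`pamsim.pathways`** — synthetic corticofugal streamline bundles
  with tractography-like jitter, iterated least-squares spline
  smoothing, collateral arcs into the STN mask, and placement of the
  11-compartment repeat (node, MYSA, FLUT, 6×STIN) along the arc
  length.
* **`pamsim.axon`** — the MRG double-cable myelinated axon (McIntyre,
  Richardson & Grill 2002): nodal fast Na+/persistent Na+/slow K+
  channels, passive internodes, myelin and periaxonal space as a second
  cable; implicit (backward-Euler) integration of the pentadiagonal
  2N-potential system, numba-compiled, with one-to-one spike detection.
* **`pamsim.threshold`** — per-axon threshold bisection to 0.01 V with
  cap and distal-initiation exclusions, bootstrap recruitment curves,
  and strength-duration / charge-duration analyses.
* **`pamsim.cli`** — YAML-configured, seeded, manifest-hashed pipeline
  runs and fixture generation (`pamsim` console script).

See `docs/methods.md` for assumptions, parameter provenance and
limitations.

## Worked example

```python
import numpy as np
from pamsim import (CircuitParams, StimulusProtocol, ElectrodeSpec,
                    build_analytic_field, dynamic_impedance,
                    simulate_tissue_waveform, find_threshold)
from pamsim.cli import synthetic_fiber_models

# implanted-system circuit with the published component values
print(f"dynamic load: {dynamic_impedance(CircuitParams()):.0f} Ohm")

# analytic field surrogate and the tissue waveform it implies
electrode = ElectrodeSpec.centered()          # active contact at origin
field = build_analytic_field(electrode, sigma_tissue=0.2,
                             sigma_enc_S_per_m=0.1)
params = CircuitParams().with_tissue_resistance(field.access_resistance_ohm)
proto = StimulusProtocol(amplitude_V=1.0, pulse_width_us=60.0,
                         frequency_Hz=130.0, n_pulses=3)
waveform = simulate_tissue_waveform(params, proto)
print(f"access resistance: {field.access_resistance_ohm:.0f} Ohm; "
      f"cathodic peak: {waveform.raw_peak_V:.3f} V per applied volt")

# activation threshold of one synthetic 5.7 um fiber near the contact
model = synthetic_fiber_models(1, seed=1)[0]
r = find_threshold(model, field, waveform, proto)
d = np.linalg.norm(model.morphology.midpoints_mm[:, :2], axis=1).min()
print(f"fiber at {d:.2f} mm -> threshold {r.threshold_V:.2f} V")
```

prints

```
dynamic load: 1444 Ohm
access resistance: 819 Ohm; cathodic peak: -0.935 V per applied volt
fiber at 2.01 mm -> threshold 1.05 V
```

The dynamic load is the impedance a pulse generator would report for
this circuit (the published worked example measures 1450 Ohm at a
1373 Ohm tissue resistance).  The cathodic peak says that ~94% of an
applied volt appears across the tissue at the pulse peak, the rest
dropping over the wires and interface.  The threshold is the lowest
cathodic amplitude at which the fiber's distal nodes fire one-to-one
with all three pulses.

For a full run producing per-axon thresholds, recruitment curves and
strength-duration tables:

```bash
pamsim fixtures --seed 1 --out fixtures
pamsim run fixtures/config.yaml
```

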