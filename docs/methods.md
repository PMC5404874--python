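# Methods

`pamsim` implements the computational core of a pathway-activation model
(PAM) for deep brain stimulation (DBS): given a stimulus setting
(amplitude, pulse width, frequency) delivered through an implanted
quadripolar lead, it predicts which members of a population of
myelinated corticofugal axons — internal capsule fibers of passage and
hyperdirect-pathway axons with a subthalamic collateral — fire
one-to-one with the stimulus train.  This note records the model, its
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Stimulus model

Because the volume-conduction problem is linear and tissue capacitance
is negligible next to the electrode double layer, the extracellular
potential factorizes as

    Phi(x, t) = Phi_unit(x) * A * V_tissue(t)

with `Phi_unit` the static potential for -1 V on the active contact,
`A` the cathodic amplitude in volts, and `V_tissue(t)` the normalized
voltage developed across the tissue resistance by the implanted-system
circuit.

### Equivalent circuit (`pamsim.circuit`)

The circuit chains a blocking capacitor (10 uF), extension-plus-lead
wire resistance (55 Ohm), the electrode-tissue interface (ETI: lumped
double-layer capacitance 1.8 uF in parallel with a Faradaic resistance
2.5 kOhm, both derived from distributed 30 uF/cm2 and 150 Ohm cm2 over
the 0.0598 cm2 contact), and the tissue (access) resistance of the
field model.  A parasitic branch — 3 nF in *series* with 20 kOhm —
hangs in parallel with the load.  The published circuit description
admits two readings of the parasitic pair (series branch vs. two
parallel elements); the series reading is adopted because (a) it is the
only one under which the recovery-phase switch action "parasitic
capacitance and parasitic resistance are connected to each other" is
meaningful, and (b) it reproduces the published worked example (dynamic
load 1450 Ohm at 70 us into an 80 us pulse with a 1373 Ohm tissue
resistance) to a few parts per thousand, whereas the parallel reading
is ~5% off.

Each stimulus period is integrated through four switching topologies —
drive (pulse width), interphase part 1 (10 us, source disconnected),
interphase part 2 (70 us, parasitics also disconnected, load floating),
passive recovery (3.686 ms, load grounded, parasitic branch closed on
itself) — followed by an interpulse interval with every switch open and
only the Faradaic and parasitic leak paths relaxing.  The interpulse
topology is not described in the source material; all-switches-open
with leak-path relaxation is this package's choice.

Integration is forward Euler at an internal 0.1 us step (the stiffest
surviving time constant is the parasitic branch's ~60 us, so this is
comfortably stable), resampled to the protocol step for export.  The
waveform is normalized to unit cathodic peak with the signed raw peak
recorded, so the amplitude `A` is carried explicitly by the
composition.  Over a steady-state period the net charge through the
blocking capacitor vanishes (verified < 1% of the cathodic-phase charge
after ~50 pulses; early periods carry a start-up transient as the
capacitor bias equilibrates).

### Field surrogate (`pamsim.field`)

The finite-element head model that normally supplies `Phi_unit` is out
of scope; only its two exported products are modelled:

* **Analytic surrogate** — the active cylindrical contact (1.5 mm x
  1.27 mm diameter) is replaced by a sphere of equal surface area
  (radius 0.69 mm) at -1 V, wrapped in a 0.5 mm encapsulation shell of
  conductivity `sigma_enc`, in an infinite medium `sigma_tissue`.
  Access resistance and potential profile follow the closed-form
  two-layer solution (verified against a 1-D radial finite-difference
  solve).  An anisotropic variant warps the radius by the inverse
  conductivity tensor normalized to unit determinant,
  `Phi ~ 1/sqrt(x' sigma^-1 x)`, using the geometric-mean conductivity
  as the scalar reference; it reduces exactly to the isotropic form.
  Inactive contacts are ignored.
* **Grid import** — externally solved potentials on a regular grid
  (documented text format with origin/spacing/dims/access-resistance
  header), evaluated by trilinear interpolation; queries outside the
  grid return 0 V with a warning flag.

Conductivity tensors are derived from diffusion tensors by keeping the
eigenvectors and rescaling eigenvalues so their geometric mean equals a
reference isotropic conductivity ("volume/load preservation": every
output tensor has determinant `sigma_iso^3`).  This geometric-mean
normalization is this package's reading of volume-normalized load
preservation; other scalar mappings exist in the literature.

The encapsulation conductivity is calibrated by bisection so the
circuit's dynamic impedance (with the field's access resistance as
tissue resistance) matches a clinically measured impedance, searched
over 0.05-0.2 S/m.

Default conductivities: tissue 0.2 S/m (isotropic white-matter scale),
encapsulation 0.1 S/m (mid-range of the calibration interval).

## Axon populations

### Trajectories (`pamsim.pathways`)

Real PAMs draw streamlines from probabilistic tractography; the
synthetic generator emulates that raw material: a corticofugal-like
bundle follows a quadratic Bezier centerline past the electrode (default
span +/-14 mm along the lead axis — a truncated corticofugal segment;
truncation is the reason for the distal-initiation exclusion below),
each streamline adding a constant lateral offset within a 2 mm bundle
radius and per-point Gaussian jitter (default SD 0.3 mm, sub-voxel
tractography noise scale).

Streamlines are smoothed before compartment placement because jitter
both inflates the polyline arc length and injects spurious structure
into the second differences of sampled potentials along the fiber — the
quantity that drives extracellular excitation.  The smoother projects
each coordinate onto cubic splines with interior knots every
`smoothing` mm (default 4 mm) of arc length, iterating the fit as the
arc-length parameterization tightens (3 passes), then resamples
uniformly (default 0.25 mm).  The projection character makes the
operator nearly idempotent away from the open ends; a smoothing of 0
requests an interpolating spline.  A fixed-knot least-squares spline
was chosen over a penalized smoothing spline precisely for this
idempotence (penalty operators keep contracting curvature on repeated
application).

Hyperdirect collaterals branch at a node of Ranvier drawn uniformly
from the nodes lying within the axial bounds of the STN mask along the
electrode axis, and terminate at a uniformly drawn mask voxel center.
The connecting arc is a planar circular arc in the plane of branch
point, target and electrode axis, bulging away from the electrode with
a sagitta of 0.25 x chord (the source material says only that an arc
was generated; a straight-line fallback is configurable).  Arcs
intersecting the electrode shaft cylinder trigger a voxel redraw (up to
100 attempts).

### Compartment placement

The 11-compartment repeat of the double-cable fiber — node, MYSA, FLUT,
6 x STIN, FLUT, MYSA — is walked along the arc length from the cortical
end (the starting end is configurable; the source material does not
state it), truncated at the last complete node.  Corticofugal axons use
the published 5.7 um geometry row; collaterals use 1.8 um, with the
first node shortened to 0.5 um and the terminal node made passive.  The
published geometry table bottoms out at 5.7 um, and a linear fit of its
low-diameter rows extrapolates the internodal spacing negative near
1.8 um; the 1.8 um row is therefore the 5.7 um row scaled
proportionally with diameter (node and MYSA lengths kept at the
table-wide 1.0 and 3.0 um), giving a 157.9 um internode and 25
lamellae.  None of these derived numbers are asserted as published
values.

## Axon biophysics (`pamsim.axon`)

The membrane model is the MRG double cable (McIntyre, Richardson &
Grill 2002): nodal fast Na+, persistent Na+, slow K+ and leak
(3.0 / 0.01 / 0.08 / 0.007 S/cm2), passive paranodal and internodal
axolemma, myelin as 0.1 uF/cm2 and 0.001 S/cm2 per lamella membrane
(divided by 2 x lamellae), periaxonal space widths 2-4 nm, axoplasmic
and periaxonal resistivity 70 Ohm cm, rest -80 mV, 36 C with the
published Q10s.  Parameters live in `pamsim.mrg` with provenance notes.

Each compartment carries intracellular and periaxonal potentials; at
nodes the myelin layer is a near-short (1e9 uS) so the periaxonal
potential tracks the imposed extracellular one while the periaxonal
axial pathway stays continuous.  Extracellular potentials enter at the
outer face of each compartment.  One subtlety matters: the integrator
treats the drive at sample 0 as the pre-stimulus history, so stimuli
must begin with a zero sample — otherwise the onset step is hidden from
the myelin capacitance, which breaks gauge invariance (a spatially
uniform potential step must do nothing).  `threshold.make_drive`
handles this.

Time integration is backward Euler on the full 2N system (the NEURON
default for this model class is likewise implicit); gating variables
use a per-gate implicit update staggered with the voltage solve.
Interleaving (phi, psi) makes the matrix pentadiagonal and diagonally
dominant; the solver is a no-pivot banded LU compiled with numba, with
a collateral branch handled as a rank-one Sherman-Morrison correction.
Models are settled to rest (max |dV/dt| < 1e-3 mV/ms) once and the
state cached.

Activation follows the one-to-one criterion: every monitored distal
node (2nd-4th active node from each corticofugal end; width
configurable) must cross 0 mV upward exactly once per inter-pulse
window for all pulses (3 pulses at 130 Hz by default).  The initiation
node is the earliest-crossing node.

The integrator was cross-checked against an independently formulated
method-of-lines integration (node periaxonal potentials eliminated
analytically, scipy BDF): conduction velocity on a straight 5.7 um
fiber agrees within 5% (the suite computes ~24 m/s at 1 us steps).

## Threshold and population analyses (`pamsim.threshold`)

Thresholds are bisected on (0 V, 150 V] to 0.01 V resolution; the
bisection predicate is "at least one spike per pulse at every monitor"
(identical to one-to-one near the boundary, but tolerant of doublets
far above it, which would otherwise spuriously mark the cap silent); a
silent cap excludes the axon (">= cap").  Initiation within 3 nodes of
either corticofugal end excludes it as a truncation artifact ("distal
initiation").  An exhaustive bottom-up 0.01 V sweep is provided as an
independent oracle for the search.

Recruitment curves bootstrap the surviving thresholds: populations
drawn with replacement (default 100 populations of 1000), activation at
amplitude `a` the percentage with threshold <= a, reported mean +/- SD.
Strength-duration points invert the mean recruitment curve (linear
interpolation) for the amplitude band achieving a target activation
(e.g. 15 +/- 5%); charge-duration attaches the cathodic-phase charge,
the trapezoidal integral of `A * values(t) / r_tissue` over the pulse
width, at the band-center amplitude.

## Verification studies and problem sizes

The shipped verification studies (`scripts/acceptance.py`, mirrored in
`tests/test_acceptance.py`) use small synthetic populations: straight
and curved 5.7 um fibers spanning +/-5 mm axially at 1.5-2.5 mm lateral
distance from the contact (20 internodes, ~220 compartments), the
default analytic field, and the 60 us / 130 Hz / 3-pulse protocol.
These sizes are the package's choice of desk-scale study: large enough
for central initiation and distal monitoring, small enough that the
exhaustive-sweep oracle (cost proportional to threshold / 0.01 V
simulations per fiber) stays practical.  The time-step convergence
study bisects at 0.005 V so search quantization does not mask the
discretization effect it measures.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the real inputs — smooth
bundles with tractography-like jitter, a convex target mask near the
electrode, collateral branching, the truncated fiber domain — but not
patient anatomy: no FEM head model, no tissue heterogeneity beyond the
encapsulation shell, no registration or electrode-localization error,
and streamline counts orders of magnitude below the 10^4-scale
tractograms of a patient study.  Passing tests therefore demonstrate
correctness of the machinery (circuit, field composition, cable
integration, search and statistics) and its internal consistency, not
clinical accuracy of any particular activation percentage; absolute
patient-level numbers require the patient's imaging-derived field and
tractography.

## Numerical choices and degenerate inputs

* Circuit: forward Euler 0.1 us internal step; infinite capacitance
  means "shorted" and infinite resistance "open", so reduced circuits
  (pure divider, single RC) are expressible for verification; a
  non-finite state raises an instability error suggesting a smaller
  step.
* Cable: backward Euler at 1 us (0.5 us for convergence checks);
  non-finite membrane state raises with the offending compartment.
* Splines: duplicate arc-length samples are dropped; fewer than 4
  points is an error; zero-length bundles are rejected.
* Thresholds: resolution must be positive; empty threshold lists and
  unreachable strength-duration targets are flagged, not silently
  skipped.
* Determinism: every random draw flows from an explicit
  `numpy.random.Generator` seed; rerunning a pipeline config reproduces
  byte-identical result files (hashes recorded in the run manifest).

## Known limitations

* The spherical-equivalent contact ignores the other three contacts and
  the shaft's insulating boundary; near-field geometry within ~1 mm of
  the contact is approximate.
* Current-regulated stimulation, charge-balanced active biphasic
  pulses, tissue capacitance and stochastic channel gating are out of
  scope.
* The collateral is a single unbranched arc; real hyperdirect
  collaterals arborize.
* The measured pulse-generator decay trace the parasitic elements were
  originally fit to is not public; only the component values are used.
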