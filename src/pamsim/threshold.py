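"""Activation thresholds, exclusions, and population recruitment analyses.

For each model axon the activation threshold is the lowest stimulus
amplitude at which the distal nodes of the corticofugal axon fire
one-to-one with a short stimulus train, found by bisection to a fixed
amplitude resolution.  Axons whose thresholds reach the search cap, or
whose action potentials initiate in the distal-most nodes (an edge
artifact of the truncated fiber), are excluded.  Population-level
results are summarized as bootstrap recruitment curves (percent of a
resampled population active versus amplitude) and condensed into
strength-duration and charge-duration curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axon import AxonModel, default_monitor, detect_activation, integrate
from .circuit import StimulusProtocol, TissueWaveform
from .field import FieldModel, sample_potentials

__all__ = [
    "ThresholdResult",
    "RecruitmentCurve",
    "SDPoint",
    "make_drive",
    "find_threshold",
    "sweep_threshold",
    "apply_exclusions",
    "bootstrap_recruitment",
    "strength_duration",
    "charge_duration",
]

EXCLUDE_CAP = ">= cap"
EXCLUDE_DISTAL = "distal initiation"


@dataclass
class ThresholdResult:
    axon_id: object
    pulse_width_us: float
    threshold_V: float | None       # None when the cap does not activate
    excluded: bool
    exclusion_reason: str | None
    initiation_node: int | None

    @property
    def found(self) -> bool:
        return self.threshold_V is not None


@dataclass
class RecruitmentCurve:
    amplitudes_V: np.ndarray
    mean_pct: np.ndarray
    std_pct: np.ndarray
    n_populations: int
    population_size: int


@dataclass
class SDPoint:
    pulse_width_us: float
    amplitude_min_V: float | None   # band achieving target +/- tol activation
    amplitude_max_V: float | None
    reachable: bool
    charge_uC: float | None = None

    @property
    def amplitude_mid_V(self) -> float | None:
        if not self.reachable:
            return None
        return 0.5 * (self.amplitude_min_V + self.amplitude_max_V)


def make_drive(waveform: TissueWaveform, amplitude_V: float, dt_us: float,
               n_steps: int) -> np.ndarray:
    """Amplitude-scaled drive samples for the integrator.

    Resamples the normalized tissue waveform onto the simulation grid and
    prepends a zero sample so the stimulus onset is an explicit step (the
    integrator treats the sample-0 drive as the pre-stimulus history).
    """
    vals = waveform.resampled_values(dt_us, n_steps)
    return np.concatenate([[0.0], amplitude_V * vals[:-1]])


def _simulate_activation(model: AxonModel, static_V, waveform, protocol,
                         amplitude, dt_us, monitor):
    duration = protocol.n_pulses * protocol.period_us
    n_steps = int(round(duration / dt_us))
    drive = make_drive(waveform, amplitude, dt_us, n_steps)
    rec = integrate(model, (static_V, drive), dt_us, duration)
    return detect_activation(rec, protocol, monitor=monitor)


def find_threshold(axon: AxonModel, field: FieldModel,
                   waveform: TissueWaveform, protocol: StimulusProtocol,
                   resolution_V: float = 0.01, cap_V: float = 150.0,
                   dt_us: float = 1.0, axon_id=None,
                   distal_guard: int = 3,
                   static_V=None) -> ThresholdResult:
    """Bisection search for the lowest activating stimulus amplitude.

    The bracket is (0, cap]: 0 V never activates and the cap is checked
    first — a silent cap marks the axon not-found and excluded.  The
    returned threshold is within ``resolution_V`` of the true boundary;
    the initiation node is taken from the simulation at the returned
    threshold, and initiation within ``distal_guard`` nodes of either
    corticofugal end flags the distal-initiation exclusion.
    ``static_V`` may pass precomputed unit potentials at the compartment
    midpoints (otherwise sampled from ``field``).
    """
    if resolution_V <= 0:
        raise ValueError("resolution_V must be positive")
    if static_V is None:
        static_V = sample_potentials(field, axon.morphology.midpoints_mm)
    nodes = axon.morphology.main_node_indices
    monitor = default_monitor(len(nodes))
    act_cap = _simulate_activation(axon, static_V, waveform, protocol,
                                   cap_V, dt_us, monitor)
    if not act_cap.responds:
        return ThresholdResult(axon_id, protocol.pulse_width_us, None, True,
                               EXCLUDE_CAP, act_cap.initiation_node)
    lo, hi = 0.0, cap_V
    act_at_hi = act_cap
    while hi - lo > resolution_V:
        mid = 0.5 * (lo + hi)
        act = _simulate_activation(axon, static_V, waveform, protocol,
                                   mid, dt_us, monitor)
        if act.responds:
            hi, act_at_hi = mid, act
        else:
            lo = mid
    init = act_at_hi.initiation_node
    distal = _is_distal(init, nodes, distal_guard)
    return ThresholdResult(axon_id, protocol.pulse_width_us, hi,
                           distal, EXCLUDE_DISTAL if distal else None, init)


def _is_distal(initiation_comp, node_comp_indices, guard: int) -> bool:
    if initiation_comp is None:
        return False
    nodes = np.asarray(node_comp_indices)
    where = np.nonzero(nodes == initiation_comp)[0]
    if where.size == 0:
        return False  # initiated on the collateral: not a distal artifact
    k = int(where[0])
    return k < guard or k >= len(nodes) - guard


def sweep_threshold(axon: AxonModel, field: FieldModel,
                    waveform: TissueWaveform, protocol: StimulusProtocol,
                    step_V: float = 0.01, cap_V: float = 150.0,
                    dt_us: float = 1.0, static_V=None) -> float | None:
    """Exhaustive ascending amplitude scan at ``step_V`` resolution.

    Independent oracle for the bisection search: tests every multiple of
    ``step_V`` from the bottom up and returns the first activating
    amplitude (None if the cap is silent).  Cost scales with the
    threshold, so reserve it for small verification populations.
    """
    if static_V is None:
        static_V = sample_potentials(field, axon.morphology.midpoints_mm)
    nodes = axon.morphology.main_node_indices
    monitor = default_monitor(len(nodes))
    n = int(np.floor(cap_V / step_V))
    for k in range(1, n + 1):
        a = k * step_V
        act = _simulate_activation(axon, static_V, waveform, protocol,
                                   a, dt_us, monitor)
        if act.activated:
            return a
    return None


def apply_exclusions(results: list, guard: int | None = None):
    """Filter excluded axons; returns (kept, counts-per-reason).

    ``guard`` optionally re-derives the distal flag with a different node
    guard width (results carry their initiation nodes).
    """
    kept, counts = [], {EXCLUDE_CAP: 0, EXCLUDE_DISTAL: 0}
    for r in results:
        if r.excluded:
            counts[r.exclusion_reason] = counts.get(r.exclusion_reason, 0) + 1
        else:
            kept.append(r)
    return kept, counts


def bootstrap_recruitment(thresholds_V, amplitudes_V, n_populations: int = 100,
                          population_size: int = 1000,
                          rng: np.random.Generator | None = None) -> RecruitmentCurve:
    """Bootstrap recruitment curve from per-axon thresholds.

    Each of ``n_populations`` populations draws ``population_size`` axons
    with replacement; activation at amplitude a is the percentage with
    threshold <= a.  Returns mean and standard deviation over
    populations per amplitude.  Axons without a threshold (cap silent)
    may be encoded as ``inf`` and never activate.
    """
    thr = np.asarray(thresholds_V, dtype=float)
    if thr.size == 0:
        raise ValueError("empty threshold list")
    amps = np.asarray(amplitudes_V, dtype=float)
    rng = rng or np.random.default_rng()
    draws = rng.integers(0, thr.size, size=(n_populations, population_size))
    sampled = thr[draws]                           # (n_pop, pop_size)
    act = (sampled[:, :, None] <= amps[None, None, :]).mean(axis=1) * 100.0
    return RecruitmentCurve(amplitudes_V=amps,
                            mean_pct=act.mean(axis=0),
                            std_pct=act.std(axis=0),
                            n_populations=n_populations,
                            population_size=population_size)


def strength_duration(threshold_sets: dict, target_pct: float = 15.0,
                      tol_pct: float = 5.0) -> list[SDPoint]:
    """Amplitude bands achieving a target activation across pulse widths.

    ``threshold_sets`` maps pulse width (us) to a RecruitmentCurve.  For
    each pulse width the band [amplitude at target - tol, amplitude at
    target + tol] is found by inverse linear interpolation of the mean
    recruitment curve; an unreachable target yields a flagged point.
    """
    points = []
    for pw in sorted(threshold_sets):
        curve = threshold_sets[pw]
        amps, mean = curve.amplitudes_V, curve.mean_pct
        lo_t, hi_t = target_pct - tol_pct, target_pct + tol_pct
        if mean.max() < lo_t or mean.min() > hi_t:
            points.append(SDPoint(pw, None, None, False))
            continue
        a_lo = _inverse_lookup(amps, mean, lo_t)
        a_hi = _inverse_lookup(amps, mean, hi_t)
        if a_hi is None:
            a_hi = float(amps[-1])
        if a_lo is None:
            a_lo = float(amps[0])
        points.append(SDPoint(pw, a_lo, a_hi, True))
    return points


def _inverse_lookup(amps, mean, level) -> float | None:
    """First amplitude at which the non-decreasing mean curve crosses
    ``level`` (linear interpolation between grid points)."""
    above = np.nonzero(mean >= level)[0]
    if above.size == 0:
        return None
    j = int(above[0])
    if j == 0 or mean[j] == mean[j - 1]:
        return float(amps[j])
    f = (level - mean[j - 1]) / (mean[j] - mean[j - 1])
    return float(amps[j - 1] + f * (amps[j] - amps[j - 1]))


def cathodic_charge_uC(waveform: TissueWaveform, amplitude_V: float,
                       r_tissue_ohm: float) -> float:
    """Charge injected during the cathodic phase (uC), by trapezoidal
    integration of the tissue current amplitude*values(t)/r_tissue."""
    t = waveform.times_us
    in_cathodic = t <= waveform.pulse_width_us + 1e-9
    i_A = amplitude_V * waveform.values[in_cathodic] / r_tissue_ohm
    return float(np.trapezoid(i_A, t[in_cathodic]))  # A*us = uC


def charge_duration(sd_points: list, waveform_factory,
                    r_tissue_ohm: float) -> list[SDPoint]:
    """Attach cathodic-phase charge to strength-duration points.

    ``waveform_factory`` maps a pulse width (us) to a TissueWaveform; the
    charge uses the band-center amplitude of each reachable point.
    """
    out = []
    for p in sd_points:
        if not p.reachable:
            out.append(SDPoint(p.pulse_width_us, p.amplitude_min_V,
                               p.amplitude_max_V, False))
            continue
        wf = waveform_factory(p.pulse_width_us)
        q = cathodic_charge_uC(wf, p.amplitude_mid_V, r_tissue_ohm)
        out.append(SDPoint(p.pulse_width_us, p.amplitude_min_V,
                           p.amplitude_max_V, True, charge_uC=q))
    return out
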