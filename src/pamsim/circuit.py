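"""Equivalent electrical circuit of an implanted DBS system.

Voltage-regulated monopolar stimulation is filtered by the pulse generator
output stage, the lead wiring, and the electrode-tissue interface (ETI)
before it reaches the tissue.  This module models that chain as a lumped
circuit — blocking capacitor, wire resistance, double-layer capacitance in
parallel with a Faradaic resistance, tissue (access) resistance, and a
series parasitic R-C branch in parallel with the load — and produces the
voltage waveform developed across the tissue resistance ("tissue waveform")
for one or more stimulus periods, plus the dynamic load impedance that an
implanted pulse generator reports.

The stimulus period has four switching topologies:

1. drive        — voltage source connected (cathodic phase);
2. interphase a — source disconnected, parasitic branch discharges into
                  the load;
3. interphase b — parasitic branch also disconnected, load floats;
4. recovery     — load shorted to ground for passive charge recovery,
                  parasitic branch closed on itself.

The remainder of the period is an interpulse interval with every switch
open and only internal leak paths (Faradaic, parasitic) relaxing.

State integration uses forward Euler at a fine internal step; exported
waveforms are resampled onto the protocol's time step.  Tissue capacitance
is omitted: it is roughly two orders of magnitude smaller than the
double-layer capacitance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "CircuitParams",
    "StimulusProtocol",
    "TissueWaveform",
    "simulate_tissue_waveform",
    "dynamic_impedance",
    "calibrate_encapsulation",
    "save_waveform",
    "load_waveform",
]

#: distributed ETI constants used to derive lumped values from a contact area
DOUBLE_LAYER_CAPACITANCE_UF_PER_CM2 = 30.0
FARADAIC_RESISTIVITY_OHM_CM2 = 150.0

#: Medtronic 3389 contact: 1.27 mm shaft diameter, 1.5 mm contact length
DEFAULT_CONTACT_AREA_CM2 = math.pi * 0.127 * 0.15


class CircuitInstabilityError(RuntimeError):
    """Forward-Euler state became non-finite; retry with a smaller dt."""


@dataclass(frozen=True)
class CircuitParams:
    """Lumped components of the implanted-system circuit.

    Capacitances may be ``inf`` (a short, i.e. component removed from a
    series position) and resistances ``inf`` (branch open) to express the
    standard reduced circuits used for verification.
    """

    c_block_uF: float = 10.0          # IPG output blocking capacitor
    r_wires_ohm: float = 55.0         # extension + lead wire resistance
    c_dl_uF: float = 1.8              # lumped ETI double-layer capacitance
    r_faradaic_ohm: float = 2500.0    # lumped ETI Faradaic resistance
    r_tissue_ohm: float = 1373.0      # access resistance of the field model
    c_parasitic_nF: float = 3.0       # series parasitic branch capacitance
    r_parasitic_ohm: float = 20000.0  # series parasitic branch resistance
    contact_area_cm2: float = DEFAULT_CONTACT_AREA_CM2

    def __post_init__(self) -> None:
        for name in (
            "c_block_uF", "r_wires_ohm", "c_dl_uF", "r_faradaic_ohm",
            "r_tissue_ohm", "c_parasitic_nF", "r_parasitic_ohm",
            "contact_area_cm2",
        ):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @classmethod
    def from_distributed_eti(cls, contact_area_cm2: float = DEFAULT_CONTACT_AREA_CM2,
                             **overrides) -> "CircuitParams":
        """Derive the lumped ETI values from the distributed constants
        (30 uF/cm2 double layer, 150 Ohm cm2 Faradaic) and a contact area."""
        return cls(
            c_dl_uF=DOUBLE_LAYER_CAPACITANCE_UF_PER_CM2 * contact_area_cm2,
            r_faradaic_ohm=FARADAIC_RESISTIVITY_OHM_CM2 / contact_area_cm2,
            contact_area_cm2=contact_area_cm2,
            **overrides,
        )

    def check_lumped_consistency(self, rtol: float = 0.01) -> bool:
        """True when the lumped ETI values match the distributed constants
        scaled by the contact area within ``rtol``."""
        c = DOUBLE_LAYER_CAPACITANCE_UF_PER_CM2 * self.contact_area_cm2
        r = FARADAIC_RESISTIVITY_OHM_CM2 / self.contact_area_cm2
        return (abs(self.c_dl_uF - c) <= rtol * c
                and abs(self.r_faradaic_ohm - r) <= rtol * r)

    def with_tissue_resistance(self, r_tissue_ohm: float) -> "CircuitParams":
        return replace(self, r_tissue_ohm=r_tissue_ohm)


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulus train settings for voltage-regulated monopolar pulses.

    ``amplitude_V`` is the cathodic magnitude A; the source drives -A during
    the cathodic phase.  Interphase and recovery durations default to the
    implanted-system switching schedule (10 us, 70 us, 3.686 ms).
    """

    amplitude_V: float = 1.7
    pulse_width_us: float = 60.0
    frequency_Hz: float = 130.0
    n_pulses: int = 3
    interphase_a_us: float = 10.0
    interphase_b_us: float = 70.0
    recovery_ms: float = 3.686
    dt_us: float = 1.0
    pulse_width_range_us: tuple = (20.0, 120.0)

    def __post_init__(self) -> None:
        if self.amplitude_V < 0:
            raise ValueError("amplitude_V is a cathodic magnitude, must be >= 0")
        lo, hi = self.pulse_width_range_us
        if not (lo <= self.pulse_width_us <= hi):
            raise ValueError(
                f"pulse_width_us={self.pulse_width_us} outside configured "
                f"range {self.pulse_width_range_us}")
        if self.dt_us <= 0 or self.dt_us > 1.0:
            raise ValueError("dt_us must lie in (0, 1] us")
        if self.period_us < self.active_duration_us:
            raise ValueError("stimulus phases do not fit within one period")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")

    @property
    def period_us(self) -> float:
        return 1e6 / self.frequency_Hz

    @property
    def active_duration_us(self) -> float:
        """Cathodic + interphase + recovery duration (excludes interpulse)."""
        return (self.pulse_width_us + self.interphase_a_us
                + self.interphase_b_us + self.recovery_ms * 1e3)

    def with_amplitude(self, amplitude_V: float) -> "StimulusProtocol":
        return replace(self, amplitude_V=amplitude_V)

    def with_pulse_width(self, pulse_width_us: float) -> "StimulusProtocol":
        return replace(self, pulse_width_us=pulse_width_us)


@dataclass
class TissueWaveform:
    """Normalized voltage time course across the tissue resistance.

    ``values`` is dimensionless, normalized so the cathodic-phase peak is
    +1 (the sign convention matches composing with a unit field solved at
    -1 V: field x amplitude x values gives cathodic-negative potentials).
    ``raw_peak_V`` is the signed pre-normalization cathodic peak for the
    protocol amplitude used.
    """

    times_us: np.ndarray
    values: np.ndarray
    raw_peak_V: float
    dt_us: float
    pulse_width_us: float
    period_us: float
    #: current through the blocking capacitor (A) at the protocol amplitude,
    #: populated by the simulator; used for charge-balance checks
    source_current_A: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_us = np.asarray(self.times_us, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_us.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")

    def resampled_values(self, dt_us: float, n_steps: int) -> np.ndarray:
        """Values on a uniform grid ``dt_us * arange(n_steps+1)`` (zero-held
        beyond the simulated train)."""
        t = dt_us * np.arange(n_steps + 1)
        return np.interp(t, self.times_us, self.values, left=0.0, right=0.0)

    def raw(self) -> np.ndarray:
        """De-normalized trace for the amplitude the waveform was run at."""
        return self.raw_peak_V * self.values


# switching-topology codes for the numba kernel
_PH_DRIVE, _PH_IPA, _PH_IPB, _PH_RECOVERY, _PH_INTERPULSE = 0, 1, 2, 3, 4


@njit(cache=True)
def _integrate_phases(phase_codes, phase_steps, dt_s, v_src,
                      inv_cb, rw, inv_cdl, g_far, rt, inv_cp, rp,
                      state, out, i_src_out, record_stride):
    """Forward-Euler integration over a schedule of switching topologies.

    state = (v_block, v_dl, v_par): capacitor voltages.  ``out`` receives the
    tissue voltage every ``record_stride`` steps; ``i_src_out`` the source
    current (same stride, drive phases only, else 0).  Returns the index of
    the last written sample, or -1 on non-finite state.
    """
    vb, vd, vp = state[0], state[1], state[2]
    vt = 0.0
    i_s = 0.0
    g_rp = 1.0 / rp
    g_rt = 1.0 / rt
    g_rw = 1.0 / rw
    k_out = 0
    step = 0
    for ip in range(phase_codes.shape[0]):
        code = phase_codes[ip]
        for _ in range(phase_steps[ip]):
            if code == _PH_DRIVE:
                # node voltage u set by resistive KCL at the load node
                u = ((v_src - vb) * g_rw + vp * g_rp + vd * g_rt) / (g_rw + g_rp + g_rt)
                i_s = (v_src - vb - u) * g_rw
                i_p = (u - vp) * g_rp
                i_l = (u - vd) * g_rt
                vt = u - vd
            elif code == _PH_IPA:
                u = (vp * g_rp + vd * g_rt) / (g_rp + g_rt)
                i_s = 0.0
                i_p = (u - vp) * g_rp
                i_l = (u - vd) * g_rt
                vt = u - vd
            elif code == _PH_IPB:
                i_s = 0.0
                i_p = 0.0
                i_l = 0.0
                vt = 0.0
            elif code == _PH_RECOVERY:
                i_s = -(vb + vd) / (rw + rt)  # loop current through C_block
                i_p = -vp * g_rp              # branch closed on itself
                i_l = i_s
                vt = i_l * rt
            else:  # interpulse: all switches open
                i_s = 0.0
                i_p = -vp * g_rp
                i_l = 0.0
                vt = 0.0
            if step % record_stride == 0:
                out[k_out] = vt
                i_src_out[k_out] = i_s
                k_out += 1
            vb += dt_s * i_s * inv_cb
            vp += dt_s * i_p * inv_cp
            vd += dt_s * (i_l - vd * g_far) * inv_cdl
            step += 1
        if not (np.isfinite(vb) and np.isfinite(vd) and np.isfinite(vp)):
            return -1
    if step % record_stride == 0:
        # final sample (state after the last step, tissue voltage of the
        # following open topology is 0 only at a phase boundary; reuse last vt)
        out[k_out] = vt
        i_src_out[k_out] = 0.0
        k_out += 1
    state[0], state[1], state[2] = vb, vd, vp
    return k_out - 1


def _phase_schedule(protocol: StimulusProtocol, dt_us: float):
    """One-period switching schedule as (codes, step counts)."""
    durations = [
        (_PH_DRIVE, protocol.pulse_width_us),
        (_PH_IPA, protocol.interphase_a_us),
        (_PH_IPB, protocol.interphase_b_us),
        (_PH_RECOVERY, protocol.recovery_ms * 1e3),
    ]
    interpulse = protocol.period_us - protocol.active_duration_us
    if interpulse > 0:
        durations.append((_PH_INTERPULSE, interpulse))
    codes, steps = [], []
    for code, dur_us in durations:
        n = int(round(dur_us / dt_us))
        # the interpulse interval is a derived remainder; it may round
        if code != _PH_INTERPULSE and abs(n * dt_us - dur_us) > 1e-6 * max(dur_us, 1.0):
            raise ValueError(
                f"dt={dt_us} us does not divide phase duration {dur_us} us")
        codes.append(code)
        steps.append(n)
    return np.array(codes, dtype=np.int64), np.array(steps, dtype=np.int64)


def _inv(x: float) -> float:
    return 0.0 if np.isinf(x) else 1.0 / x


def simulate_tissue_waveform(params: CircuitParams,
                             protocol: StimulusProtocol,
                             internal_dt_us: float = 0.1) -> TissueWaveform:
    """Tissue waveform over ``protocol.n_pulses`` periods.

    Integrates the four switching topologies with forward Euler at
    ``internal_dt_us`` and resamples the result to ``protocol.dt_us``.
    The trace is normalized to unit cathodic peak with the signed raw peak
    recorded; a zero-amplitude protocol returns an identically zero trace.
    """
    if internal_dt_us <= 0:
        raise ValueError("internal_dt_us must be positive")
    # integrate finer than the export grid, and divide each phase duration
    stride = max(1, int(round(protocol.dt_us / internal_dt_us)))
    dt_int = protocol.dt_us / stride
    codes, steps = _phase_schedule(protocol, dt_int)
    codes = np.tile(codes, protocol.n_pulses)
    steps = np.tile(steps, protocol.n_pulses)
    n_rec = int(steps.sum()) // stride + 1
    out = np.empty(n_rec)
    i_src = np.empty(n_rec)
    state = np.zeros(3)
    last = _integrate_phases(
        codes, steps, dt_int * 1e-6, -protocol.amplitude_V,
        _inv(params.c_block_uF * 1e-6), params.r_wires_ohm,
        _inv(params.c_dl_uF * 1e-6), _inv(params.r_faradaic_ohm),
        params.r_tissue_ohm, _inv(params.c_parasitic_nF * 1e-9),
        params.r_parasitic_ohm, state, out, i_src, stride)
    if last < 0:
        raise CircuitInstabilityError(
            "circuit integration diverged; use a smaller internal_dt_us")
    out = out[:last + 1]
    times = protocol.dt_us * np.arange(out.size)
    # cathodic peak: extremum within the drive phase of any period
    in_drive = (times % protocol.period_us) <= protocol.pulse_width_us
    if protocol.amplitude_V == 0.0:
        raw_peak = 0.0
        values = np.zeros_like(out)
    else:
        drive_vals = out[in_drive]
        raw_peak = drive_vals[np.argmax(np.abs(drive_vals))]
        values = out / raw_peak
    return TissueWaveform(times_us=times, values=values, raw_peak_V=raw_peak,
                          dt_us=protocol.dt_us,
                          pulse_width_us=protocol.pulse_width_us,
                          period_us=protocol.period_us,
                          source_current_A=i_src[:last + 1])


def dynamic_impedance(params: CircuitParams, probe_time_us: float = 70.0,
                      pulse_width_us: float = 80.0,
                      internal_dt_us: float = 0.01) -> float:
    """Dynamic load impedance (Ohm): applied voltage over source current at
    ``probe_time_us`` into a single rectangular drive pulse.

    This reproduces the impedance check an implanted pulse generator
    performs (probe at 70 us into an 80 us pulse).
    """
    if probe_time_us >= pulse_width_us:
        raise ValueError("probe_time_us must be < pulse_width_us")
    n = int(round(pulse_width_us / internal_dt_us))
    codes = np.array([_PH_DRIVE], dtype=np.int64)
    steps = np.array([n], dtype=np.int64)
    out = np.empty(n + 1)
    i_src = np.empty(n + 1)
    state = np.zeros(3)
    last = _integrate_phases(
        codes, steps, internal_dt_us * 1e-6, 1.0,
        _inv(params.c_block_uF * 1e-6), params.r_wires_ohm,
        _inv(params.c_dl_uF * 1e-6), _inv(params.r_faradaic_ohm),
        params.r_tissue_ohm, _inv(params.c_parasitic_nF * 1e-9),
        params.r_parasitic_ohm, state, out, i_src, 1)
    if last < 0:
        raise CircuitInstabilityError(
            "circuit integration diverged; use a smaller internal_dt_us")
    k = int(round(probe_time_us / internal_dt_us))
    return 1.0 / i_src[k]


def calibrate_encapsulation(field_factory, params: CircuitParams,
                            clinical_impedance_ohm: float,
                            bounds=(0.05, 0.2),
                            tol_ohm: float = 1.0,
                            probe_time_us: float = 70.0,
                            pulse_width_us: float = 80.0) -> float:
    """Encapsulation-layer conductivity (S/m) at which the model impedance
    matches a clinically measured impedance.

    ``field_factory`` maps an encapsulation conductivity to a field model
    exposing ``access_resistance_ohm``; the circuit's tissue resistance is
    replaced by that access resistance and the dynamic impedance is matched
    to ``clinical_impedance_ohm`` within ``tol_ohm`` by bisection (the
    impedance is monotone decreasing in the conductivity).
    """
    def impedance(sigma: float) -> float:
        r = field_factory(sigma).access_resistance_ohm
        return dynamic_impedance(params.with_tissue_resistance(r),
                                 probe_time_us, pulse_width_us)

    lo, hi = bounds
    z_lo, z_hi = impedance(lo), impedance(hi)
    z_min, z_max = min(z_lo, z_hi), max(z_lo, z_hi)
    if not (z_min <= clinical_impedance_ohm <= z_max):
        raise ValueError(
            f"clinical impedance {clinical_impedance_ohm} Ohm outside the "
            f"achievable range [{z_min:.1f}, {z_max:.1f}] Ohm on bounds {bounds}")
    increasing = z_hi > z_lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        z = impedance(mid)
        if abs(z - clinical_impedance_ohm) <= tol_ohm:
            return mid
        if (z < clinical_impedance_ohm) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def save_waveform(wf: TissueWaveform, path) -> None:
    """Two-column delimited text export: time_us, normalized_value."""
    header = (f"raw_peak_V={float(wf.raw_peak_V)!r} dt_us={float(wf.dt_us)!r} "
              f"pulse_width_us={float(wf.pulse_width_us)!r} "
              f"period_us={float(wf.period_us)!r}")
    np.savetxt(path, np.column_stack([wf.times_us, wf.values]), header=header)


def load_waveform(path) -> TissueWaveform:
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    for tok in first.lstrip("# ").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = float(v)
    data = np.loadtxt(path)
    return TissueWaveform(times_us=data[:, 0], values=data[:, 1],
                          raw_peak_V=meta.get("raw_peak_V", np.nan),
                          dt_us=meta.get("dt_us", np.nan),
                          pulse_width_us=meta.get("pulse_width_us", np.nan),
                          period_us=meta.get("period_us", np.nan))
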