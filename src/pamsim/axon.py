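"""Double-cable myelinated axon dynamics under extracellular stimulation.

Implements the MRG double-cable model (McIntyre, Richardson & Grill 2002):
nodes of Ranvier carry fast Na+, persistent Na+ and slow K+ conductances
plus leak; paranodal (MYSA, FLUT) and internodal (STIN) compartments are
passive, with the axolemma and the myelin sheath as two membranes in
series separated by a finite periaxonal space that is itself axially
conductive.  Extracellular stimulation enters as the imposed potential at
the outer face of each compartment.

Electrically, each compartment contributes two potentials — intracellular
``phi`` and periaxonal ``psi`` — coupled by the axolemma; ``psi`` connects
to the extracellular potential through the myelin admittance and axially
to its neighbours through the periaxonal space.  At nodes the myelin
layer is replaced by a near-short so ``psi`` tracks the local
extracellular potential while the periaxonal pathway stays continuous.

Time integration is implicit (backward Euler) on the full ``2N`` system:
the cable equations are stiff, and implicit Euler is also what a NEURON
implementation of the same model uses by default.  Gating variables are
advanced with a per-gate implicit update staggered with the voltage
solve.  The interleaved (phi, psi) ordering makes the system
pentadiagonal; a collateral branch adds one rank-one coupling handled by
a Sherman-Morrison correction.  The hot loop is compiled with numba.

Units follow the NEURON convention internally: mV, ms, nA, uS, nF.
External interfaces use microseconds and volts and convert at the
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np
from numba import njit

from .mrg import MRG_MEMBRANE
from .pathways import AxonMorphology, FLUT, MYSA, NODE, STIN

__all__ = [
    "MembraneDynamics",
    "AxonModel",
    "SimRecord",
    "ActivationResult",
    "build_axon",
    "settle_to_rest",
    "integrate",
    "detect_activation",
]


class SimulationInstabilityError(RuntimeError):
    """Membrane state became non-finite during integration."""

    def __init__(self, compartment: int):
        self.compartment = compartment
        super().__init__(
            f"non-finite membrane state at compartment {compartment}; "
            "reduce dt or check the morphology")


@dataclass(frozen=True)
class MembraneDynamics:
    """Channel densities, kinetic constants and passive parameters.

    Defaults are the published double-cable model values at 36 C.
    Conductances in S/cm^2, capacitances in uF/cm^2, potentials in mV.
    """

    gnabar: float = MRG_MEMBRANE["gnabar_S_per_cm2"]
    gnapbar: float = MRG_MEMBRANE["gnapbar_S_per_cm2"]
    gkbar: float = MRG_MEMBRANE["gkbar_S_per_cm2"]
    gl: float = MRG_MEMBRANE["gl_S_per_cm2"]
    ena: float = MRG_MEMBRANE["ena_mV"]
    ek: float = MRG_MEMBRANE["ek_mV"]
    el: float = MRG_MEMBRANE["el_mV"]
    e_pas: float = MRG_MEMBRANE["e_pas_mV"]
    cm: float = MRG_MEMBRANE["cm_uF_per_cm2"]
    mycm: float = MRG_MEMBRANE["mycm_uF_per_cm2"]
    mygm: float = MRG_MEMBRANE["mygm_S_per_cm2"]
    g_mysa: float = MRG_MEMBRANE["g_mysa_S_per_cm2"]
    g_flut: float = MRG_MEMBRANE["g_flut_S_per_cm2"]
    g_stin: float = MRG_MEMBRANE["g_stin_S_per_cm2"]
    rhoa_ohm_cm: float = MRG_MEMBRANE["rhoa_ohm_cm"]
    vrest: float = MRG_MEMBRANE["vrest_mV"]
    celsius: float = MRG_MEMBRANE["celsius"]

    @property
    def q10_m(self) -> float:
        return 2.2 ** ((self.celsius - 20.0) / 10.0)

    @property
    def q10_h(self) -> float:
        return 2.9 ** ((self.celsius - 20.0) / 10.0)

    @property
    def q10_s(self) -> float:
        return 3.0 ** ((self.celsius - 36.0) / 10.0)


@dataclass
class AxonModel:
    """Assembled electrical discretization of one morphology."""

    morphology: AxonMorphology
    dynamics: MembraneDynamics
    n: int                      # compartment count
    c_ax: np.ndarray            # axolemma capacitance (nF)
    c_my: np.ndarray            # myelin capacitance (nF); 0 at nodes
    g_my: np.ndarray            # myelin conductance (uS); near-short at nodes
    g_pas: np.ndarray           # passive axolemma conductance (uS); 0 at active nodes
    e_pas: np.ndarray           # passive reversal (mV)
    area_node: np.ndarray       # nodal membrane area (cm^2); 0 elsewhere
    is_active_node: np.ndarray  # bool
    g_axial: np.ndarray         # axoplasmic conductance comp k -> k+1 (uS)
    g_peri: np.ndarray          # periaxonal conductance comp k -> k+1 (uS)
    branch_parent: int          # -1 when unbranched
    branch_child: int
    g_branch: float             # axoplasmic coupling across the branch (uS)
    rest_state: dict | None = dfield(default=None, repr=False)


def _axial_resistance_ohm(rhoa_ohm_cm: float, length_um: float,
                          diam_um: float) -> float:
    area_um2 = math.pi * (diam_um / 2.0) ** 2
    return (rhoa_ohm_cm * 1e4) * length_um / area_um2


def build_axon(morph: AxonMorphology,
               dyn: MembraneDynamics | None = None) -> AxonModel:
    """Assemble the double-cable discretization from a morphology.

    Axial axoplasmic and periaxonal conductances come from compartment
    geometry (series half-resistances between adjacent compartments);
    membrane elements from areal densities times the actual axolemma
    area, with myelin elements on the fiber-diameter sheath area divided
    by twice the lamella count (two membranes per lamella).  A collateral
    root couples to its parent node through an axoplasmic resistance.
    """
    dyn = dyn or MembraneDynamics()
    n = morph.n_compartments
    L = morph.length_um
    d = morph.diameter_um
    fd = morph.fiber_diameter_um
    lam = morph.lamellae.astype(float)
    w = morph.periaxonal_space_um
    if np.any(L <= 0):
        raise ValueError("zero-length compartment in morphology")

    area_ax_cm2 = math.pi * d * L * 1e-8
    area_my_cm2 = math.pi * fd * L * 1e-8
    is_node = morph.comp_type == NODE
    is_active_node = is_node & morph.active

    c_ax = dyn.cm * area_ax_cm2 * 1e3          # uF -> nF

    g_dens = np.empty(n)
    g_dens[morph.comp_type == MYSA] = dyn.g_mysa
    g_dens[morph.comp_type == FLUT] = dyn.g_flut
    g_dens[morph.comp_type == STIN] = dyn.g_stin
    g_dens[is_node] = dyn.gl   # passive terminal nodes keep the nodal leak
    g_pas = g_dens * area_ax_cm2 * 1e6         # S -> uS
    g_pas[is_active_node] = 0.0  # active nodes: leak lives in the ionic term

    c_my = np.where(is_node, 0.0,
                    (dyn.mycm / (2.0 * lam)) * area_my_cm2 * 1e3)
    g_my = np.where(is_node, 1e9,
                    (dyn.mygm / (2.0 * lam)) * area_my_cm2 * 1e6)

    half_ax = 0.5 * np.array([_axial_resistance_ohm(dyn.rhoa_ohm_cm, L[i], d[i])
                              for i in range(n)])
    area_peri_um2 = math.pi * ((d / 2.0 + w) ** 2 - (d / 2.0) ** 2)
    half_peri = 0.5 * (dyn.rhoa_ohm_cm * 1e4) * L / area_peri_um2

    n_main = morph.n_main
    g_axial = np.zeros(n)
    g_peri = np.zeros(n)
    for i in range(n - 1):
        if (i < n_main) != (i + 1 < n_main):
            continue  # no chain link across the main/collateral boundary
        g_axial[i] = 1e6 / (half_ax[i] + half_ax[i + 1])
        g_peri[i] = 1e6 / (half_peri[i] + half_peri[i + 1])

    branch_parent, branch_child, g_branch = -1, -1, 0.0
    if morph.branch_parent is not None:
        branch_parent = int(morph.branch_parent)
        branch_child = n_main
        g_branch = 1e6 / (half_ax[branch_parent] + half_ax[branch_child])

    area_node = np.where(is_active_node, area_ax_cm2, 0.0)
    return AxonModel(morphology=morph, dynamics=dyn, n=n,
                     c_ax=c_ax, c_my=c_my, g_my=g_my, g_pas=g_pas,
                     e_pas=np.full(n, dyn.e_pas), area_node=area_node,
                     is_active_node=is_active_node,
                     g_axial=g_axial, g_peri=g_peri,
                     branch_parent=branch_parent, branch_child=branch_child,
                     g_branch=g_branch)


@dataclass
class SimRecord:
    """Membrane potential traces at the main-path nodes of Ranvier."""

    node_vm_mV: np.ndarray      # (n_nodes, n_samples)
    dt_us: float
    node_comp_indices: np.ndarray
    all_node_vm_mV: np.ndarray | None = None
    all_node_comp_indices: np.ndarray | None = None

    @property
    def times_us(self) -> np.ndarray:
        return self.dt_us * np.arange(self.node_vm_mV.shape[1])

    @property
    def duration_us(self) -> float:
        return self.dt_us * (self.node_vm_mV.shape[1] - 1)


@dataclass
class ActivationResult:
    activated: bool
    spikes_per_pulse: np.ndarray  # (n_monitors, n_pulses)
    initiation_node: int | None   # compartment index of earliest crossing

    @property
    def responds(self) -> bool:
        """Every monitored node fires at least once per pulse (used as the
        bisection predicate; coincides with the strict one-to-one
        criterion near threshold but tolerates doublets far above it)."""
        return bool(np.all(self.spikes_per_pulse >= 1))


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _gate_rates(v, q10m, q10h, q10s):
    """Nodal gating rates (1/ms) at membrane potential v (mV)."""
    x = v + 21.4
    am = q10m * 1.86 * (x / (1.0 - math.exp(-x / 10.3)) if abs(x) > 1e-6 else 10.3)
    x = v + 25.7
    bm = q10m * 0.086 * ((-x) / (1.0 - math.exp(x / 9.16)) if abs(x) > 1e-6 else 9.16)
    x = v + 114.0
    ah = q10h * 0.062 * ((-x) / (1.0 - math.exp(x / 11.0)) if abs(x) > 1e-6 else 11.0)
    bh = q10h * 2.3 / (1.0 + math.exp(-(v + 31.8) / 13.4))
    x = v + 27.0
    ap = q10m * 0.01 * (x / (1.0 - math.exp(-x / 10.2)) if abs(x) > 1e-6 else 10.2)
    x = v + 34.0
    bp = q10m * 0.00025 * ((-x) / (1.0 - math.exp(x / 10.0)) if abs(x) > 1e-6 else 10.0)
    as_ = q10s * 0.3 / (1.0 + math.exp(-(v + 53.0) / 5.0))
    bs = q10s * 0.03 / (1.0 + math.exp(-(v + 90.0)))
    return am, bm, ah, bh, ap, bp, as_, bs


@njit(cache=True)
def _penta_solve2(band, rhs1, rhs2, m):
    """LU solve (no pivoting) of a pentadiagonal system for two RHS.

    band is (5, m) with band[2 + i - j, j] = A[i, j]; destroyed in place.
    The cable matrix is diagonally dominant, so pivoting is unnecessary.
    """
    for j in range(m - 1):
        piv = band[2, j]
        lim = min(j + 3, m)
        for i in range(j + 1, lim):
            f = band[2 + i - j, j] / piv
            if f != 0.0:
                for jj in range(j + 1, lim):
                    band[2 + i - jj, jj] -= f * band[2 + j - jj, jj]
                rhs1[i] -= f * rhs1[j]
                rhs2[i] -= f * rhs2[j]
    for i in range(m - 1, -1, -1):
        lim = min(i + 3, m)
        s1 = rhs1[i]
        s2 = rhs2[i]
        for j in range(i + 1, lim):
            s1 -= band[2 + i - j, j] * rhs1[j]
            s2 -= band[2 + i - j, j] * rhs2[j]
        rhs1[i] = s1 / band[2, i]
        rhs2[i] = s2 / band[2, i]


@njit(cache=True)
def _step_loop(n_steps, dt, n,
               phi, psi, vm, m_g, h_g, p_g, s_g,
               c_ax, c_my, g_my, g_pas, e_pas_arr, area_node, active_mask,
               g_axial, g_peri,
               bparent, bchild, g_branch,
               static_mV, amp_wave, dense_e, use_dense,
               gnabar, gnapbar, gkbar, gl, ena, ek, el,
               q10m, q10h, q10s,
               i_inj_comp, i_inj_nA, i_inj_on, i_inj_off,
               rec_idx, rec_out, rec_stride,
               band, rhs, rhs_u):
    """Backward-Euler loop.  Returns -1 on success, else the index of the
    first compartment whose potential went non-finite."""
    two_n = 2 * n
    inv_dt = 1.0 / dt
    rec_col = 1
    for step in range(n_steps):
        t_new = (step + 1) * dt
        w_new = amp_wave[step + 1]
        w_old = amp_wave[step]
        for k in range(n):
            if active_mask[k]:
                am, bm, ah, bh, ap, bp, as_, bs = _gate_rates(
                    vm[k], q10m, q10h, q10s)
                m_g[k] = (m_g[k] + dt * am) / (1.0 + dt * (am + bm))
                h_g[k] = (h_g[k] + dt * ah) / (1.0 + dt * (ah + bh))
                p_g[k] = (p_g[k] + dt * ap) / (1.0 + dt * (ap + bp))
                s_g[k] = (s_g[k] + dt * as_) / (1.0 + dt * (as_ + bs))
        for j in range(5):
            for k in range(two_n):
                band[j, k] = 0.0
        for k in range(n):
            if use_dense:
                e_new = dense_e[step + 1, k]
                e_old = dense_e[step, k]
            else:
                e_new = static_mV[k] * w_new
                e_old = static_mV[k] * w_old
            if active_mask[k]:
                a = area_node[k] * 1e6  # S/cm2 * cm2 -> uS
                g_na = gnabar * m_g[k] ** 3 * h_g[k] * a
                g_np = gnapbar * p_g[k] ** 3 * a
                g_k = gkbar * s_g[k] * a
                g_leak = gl * a
                g_ion = g_na + g_np + g_k + g_leak
                b_ion = (g_na + g_np) * ena + g_k * ek + g_leak * el
            else:
                g_ion = g_pas[k]
                b_ion = g_pas[k] * e_pas_arr[k]
            cax_dt = c_ax[k] * inv_dt
            cmy_dt = c_my[k] * inv_dt
            ip = 2 * k
            iq = 2 * k + 1
            band[2, ip] += cax_dt + g_ion
            band[1, iq] += -(cax_dt + g_ion)      # A[ip, iq]
            rhs[ip] = cax_dt * vm[k] + b_ion
            if i_inj_comp == k and i_inj_on <= t_new < i_inj_off:
                rhs[ip] += i_inj_nA
            band[2, iq] += cmy_dt + g_my[k] + cax_dt + g_ion
            band[3, ip] += -(cax_dt + g_ion)      # A[iq, ip]
            rhs[iq] = (cmy_dt * psi[k] + cmy_dt * (e_new - e_old)
                       + g_my[k] * e_new - cax_dt * vm[k] - b_ion)
            if k < n - 1 and g_axial[k] > 0.0:
                jp = 2 * (k + 1)
                band[2, ip] += g_axial[k]
                band[2, jp] += g_axial[k]
                band[0, jp] += -g_axial[k]        # A[ip, jp]
                band[4, ip] += -g_axial[k]        # A[jp, ip]
            if k < n - 1 and g_peri[k] > 0.0:
                jq = 2 * (k + 1) + 1
                band[2, iq] += g_peri[k]
                band[2, jq] += g_peri[k]
                band[0, jq] += -g_peri[k]
                band[4, iq] += -g_peri[k]
        for k in range(two_n):
            rhs_u[k] = 0.0
        if bparent >= 0:
            up = 2 * bparent
            uc = 2 * bchild
            rhs_u[up] = 1.0
            rhs_u[uc] = -1.0
            # the branch coupling also adds +g to both diagonals and -g off
            # diagonal: A = B + g u u^T exactly
            _penta_solve2(band, rhs, rhs_u, two_n)
            denom = 1.0 + g_branch * (rhs_u[up] - rhs_u[uc])
            factor = g_branch * (rhs[up] - rhs[uc]) / denom
            for k in range(two_n):
                rhs[k] -= factor * rhs_u[k]
        else:
            _penta_solve2(band, rhs, rhs_u, two_n)
        for k in range(n):
            phi[k] = rhs[2 * k]
            psi[k] = rhs[2 * k + 1]
            vm[k] = phi[k] - psi[k]
            if not np.isfinite(vm[k]):
                return k
        if (step + 1) % rec_stride == 0:
            for r in range(rec_idx.shape[0]):
                rec_out[r, rec_col] = vm[rec_idx[r]]
            rec_col += 1
    return -1


_DUMMY_DENSE = np.zeros((1, 1))


def _gate_steady(v: float, dyn: MembraneDynamics):
    am, bm, ah, bh, ap, bp, as_, bs = _gate_rates(
        float(v), dyn.q10_m, dyn.q10_h, dyn.q10_s)
    return (am / (am + bm), ah / (ah + bh), ap / (ap + bp), as_ / (as_ + bs))


def _run_kernel(model: AxonModel, n_steps, dt_ms, phi, psi, vm, gates,
                static_mV, amp_wave, dense_e, use_dense,
                inj, rec_idx, rec, rec_stride, ):
    dyn = model.dynamics
    n = model.n
    band = np.zeros((5, 2 * n))
    rhs = np.zeros(2 * n)
    rhs_u = np.zeros(2 * n)
    bad = _step_loop(n_steps, dt_ms, n, phi, psi, vm,
                     gates[0], gates[1], gates[2], gates[3],
                     model.c_ax, model.c_my, model.g_my, model.g_pas,
                     model.e_pas, model.area_node, model.is_active_node,
                     model.g_axial, model.g_peri,
                     model.branch_parent, model.branch_child, model.g_branch,
                     static_mV, amp_wave, dense_e, use_dense,
                     dyn.gnabar, dyn.gnapbar, dyn.gkbar, dyn.gl,
                     dyn.ena, dyn.ek, dyn.el,
                     dyn.q10_m, dyn.q10_h, dyn.q10_s,
                     inj[0], inj[1], inj[2], inj[3],
                     rec_idx, rec, rec_stride,
                     band, rhs, rhs_u)
    if bad >= 0:
        raise SimulationInstabilityError(bad)


def settle_to_rest(model: AxonModel, dt_us: float = 5.0,
                   max_ms: float = 200.0,
                   tol_mV_per_ms: float = 1e-3) -> dict:
    """Relax the model to steady rest with zero drive.

    Runs the implicit integrator from the nominal rest potential until
    max |dV/dt| < ``tol_mV_per_ms`` (default 1e-3 mV/ms); caches the
    settled state on the model for reuse by subsequent integrations.
    """
    dyn = model.dynamics
    n = model.n
    phi = np.full(n, dyn.vrest)
    psi = np.zeros(n)
    vm = phi - psi
    m0, h0, p0, s0 = _gate_steady(dyn.vrest, dyn)
    gates = [np.full(n, g) for g in (m0, h0, p0, s0)]
    static = np.zeros(n)
    dt_ms = dt_us * 1e-3
    chunk = 200
    wave = np.zeros(chunk + 1)
    rec_idx = np.array([0], dtype=np.int64)
    rec = np.zeros((1, 2))
    inj = (-1, 0.0, 0.0, 0.0)
    total = 0.0
    while total < max_ms:
        vm_before = vm.copy()
        _run_kernel(model, chunk, dt_ms, phi, psi, vm, gates,
                    static, wave, _DUMMY_DENSE, False,
                    inj, rec_idx, rec, chunk + 1)
        total += chunk * dt_ms
        rate = np.abs(vm - vm_before).max() / (chunk * dt_ms)
        if rate < tol_mV_per_ms:
            model.rest_state = dict(phi=phi, psi=psi, vm=vm, m=gates[0],
                                    h=gates[1], p=gates[2], s=gates[3])
            return model.rest_state
    raise SimulationInstabilityError(-1)


def integrate(model: AxonModel, extracellular, dt_us: float,
              duration_us: float, record_all_nodes: bool = False,
              i_inj=None, record_stride: int = 1) -> SimRecord:
    """Integrate the cable system under an extracellular drive.

    ``extracellular`` is either a dense (n_compartments, n_steps+1)
    matrix of potentials in volts sampled at ``dt_us``, or a factored
    tuple ``(static_V, drive)`` whose outer product it represents —
    ``static_V`` the unit potentials (V) and ``drive`` the
    amplitude-scaled waveform samples (dimensionless x V); the factored
    form avoids materializing the matrix during threshold searches.
    ``i_inj`` optionally injects a rectangular intracellular current:
    (compartment, nA, t_on_us, t_off_us).  The model is settled to rest
    first (cached across calls).

    The drive at sample 0 is taken to have been applied for all t < 0:
    a stimulus that switches on must therefore begin with a zero sample
    so its onset step is seen by the myelin capacitance (a drive that is
    "always on" at sample 0 is gauge-equivalent to a different stimulus).
    """
    n = model.n
    n_steps = int(round(duration_us / dt_us))
    if isinstance(extracellular, tuple):
        static_V, wave = extracellular
        static_mV = np.ascontiguousarray(np.asarray(static_V, float) * 1e3)
        amp_wave = np.ascontiguousarray(np.asarray(wave, float)[:n_steps + 1])
        if amp_wave.size < n_steps + 1:
            raise ValueError("drive does not cover the duration")
        dense_e, use_dense = _DUMMY_DENSE, False
    else:
        ex = np.asarray(extracellular, dtype=float)
        if ex.shape[0] != n or ex.shape[1] < n_steps + 1:
            raise ValueError("extracellular matrix must be (n_comp, >= n_steps+1)")
        dense_e = np.ascontiguousarray(ex.T[:n_steps + 1] * 1e3)
        static_mV = np.zeros(n)
        amp_wave = np.zeros(n_steps + 1)
        use_dense = True

    if model.rest_state is None:
        settle_to_rest(model)
    rest = model.rest_state
    phi = rest["phi"].copy()
    psi = rest["psi"].copy()
    vm = rest["vm"].copy()
    gates = [rest[k].copy() for k in ("m", "h", "p", "s")]

    nodes = model.morphology.main_node_indices
    rec_idx = (np.nonzero(model.morphology.comp_type == NODE)[0]
               if record_all_nodes else nodes)
    n_rec = n_steps // record_stride + 1
    rec = np.empty((len(rec_idx), n_rec))
    rec[:, 0] = vm[rec_idx]

    if i_inj is None:
        inj = (-1, 0.0, 0.0, 0.0)
    else:
        comp, nA, t_on, t_off = i_inj
        inj = (int(comp), float(nA), t_on * 1e-3, t_off * 1e-3)

    _run_kernel(model, n_steps, dt_us * 1e-3, phi, psi, vm, gates,
                static_mV, amp_wave, dense_e, use_dense,
                inj, rec_idx, rec, record_stride)

    main_mask = np.isin(rec_idx, nodes)
    return SimRecord(node_vm_mV=rec[main_mask], dt_us=dt_us * record_stride,
                     node_comp_indices=rec_idx[main_mask],
                     all_node_vm_mV=rec if record_all_nodes else None,
                     all_node_comp_indices=rec_idx if record_all_nodes else None)


def default_monitor(n_nodes: int) -> np.ndarray:
    """2nd-4th active node from each corticofugal end (row indices into a
    record's node list)."""
    picks = sorted(set(list(range(1, 4)) + list(range(n_nodes - 4, n_nodes - 1))))
    return np.array([p for p in picks if 0 <= p < n_nodes], dtype=np.int64)


def detect_activation(rec: SimRecord, protocol, monitor=None,
                      threshold_mV: float = 0.0) -> ActivationResult:
    """Check the one-to-one firing criterion against a recorded train.

    Counts upward crossings of ``threshold_mV`` per inter-pulse window at
    each monitored distal node; the fiber counts as activated only when
    every monitored node fires exactly once for every stimulus pulse.
    The initiation node is the compartment with the earliest crossing.
    """
    period_us = protocol.period_us
    n_pulses = protocol.n_pulses
    if rec.duration_us + 1e-9 < (n_pulses - 1) * period_us:
        raise ValueError("record shorter than the stimulus protocol")
    vm = rec.node_vm_mV
    n_nodes = vm.shape[0]
    monitor = (default_monitor(n_nodes) if monitor is None
               else np.asarray(monitor, dtype=np.int64))
    t = rec.times_us
    up = (vm[:, :-1] < threshold_mV) & (vm[:, 1:] >= threshold_mV)
    edges = period_us * np.arange(n_pulses + 1, dtype=float)
    edges[-1] = max(edges[-1], rec.duration_us + 1.0)
    t_mid = t[1:]
    counts = np.zeros((n_nodes, n_pulses), dtype=np.int64)
    for p in range(n_pulses):
        in_win = (t_mid >= edges[p]) & (t_mid < edges[p + 1])
        counts[:, p] = up[:, in_win].sum(axis=1)
    activated = bool(np.all(counts[monitor] == 1))
    initiation = None
    any_cross = np.nonzero(up.any(axis=1))[0]
    if any_cross.size:
        first_times = np.array([t_mid[up[i]].min() for i in any_cross])
        initiation = int(rec.node_comp_indices[any_cross[np.argmin(first_times)]])
    return ActivationResult(activated=activated,
                            spikes_per_pulse=counts[monitor],
                            initiation_node=initiation)
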