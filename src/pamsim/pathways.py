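"""Axon trajectory construction from (synthetic) tractography streamlines.

The corticofugal pathways of interest — internal capsule fibers of
passage and the hyperdirect pathway — are represented by 3D streamlines
sweeping past the electrode from a cortical cap toward the brainstem.
Real studies obtain these from probabilistic tractography; the synthetic
generator here emulates the same raw material: bundles of smooth curves
with point-level jitter mimicking tractography noise.

Processing mirrors the standard pathway-activation workflow:

1. fit a smoothing spline to each streamline (tractography jitter
   otherwise injects spurious second-difference structure into the
   sampled extracellular potentials, which directly biases thresholds);
2. for hyperdirect axons, branch a thin collateral at a randomly chosen
   node of Ranvier within the axial bounds of the target nucleus (STN),
   terminating at a random mask voxel, routed as a planar circular arc
   that must clear the electrode shaft;
3. walk the 11-compartment repeat (node, MYSA, FLUT, 6x STIN) of the
   double-cable fiber geometry along the arc length to place compartment
   coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.interpolate import LSQUnivariateSpline, UnivariateSpline

from .field import ElectrodeSpec
from .mrg import PERIAXONAL_SPACE_UM, geometry_row

__all__ = [
    "Streamline",
    "BundleSpec",
    "AnatomyContext",
    "AxonTrajectory",
    "FiberGeometry",
    "AxonMorphology",
    "generate_streamlines",
    "fit_smoothing_spline",
    "build_collateral",
    "compartmentalize",
    "sample_population",
    "save_streamlines",
    "load_streamlines",
    "NODE", "MYSA", "FLUT", "STIN",
]

# compartment type codes
NODE, MYSA, FLUT, STIN = 0, 1, 2, 3
_TYPE_NAMES = {NODE: "node", MYSA: "mysa", FLUT: "flut", STIN: "stin"}


@dataclass
class Streamline:
    """Ordered 3D polyline (mm) with its cumulative arc-length table."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if len(self.points) < 2:
            raise ValueError("a streamline needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("streamline points must be finite")

    @property
    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s) -> np.ndarray:
        """Linear interpolation of the polyline at arc length(s) ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        arc = self.arc_length
        out = np.empty((len(s), 3))
        for k in range(3):
            out[:, k] = np.interp(s, arc, self.points[:, k])
        return out


@dataclass(frozen=True)
class BundleSpec:
    """Synthetic corticofugal bundle geometry.

    The centerline is a quadratic Bezier from a cortical cap to a
    brainstem cap whose mid control point pulls the bundle past the
    electrode.  Individual streamlines add a constant random lateral
    offset within ``radius_mm`` plus per-point jitter.  The default spans
    a +/-14 mm axial window around the electrode — a truncated
    corticofugal segment with tens of internodes on either side of the
    closest approach.
    """

    cortical_cap_mm: tuple = (6.0, 0.0, 14.0)
    brainstem_cap_mm: tuple = (8.0, 4.0, -14.0)
    mid_control_mm: tuple = (3.0, 0.5, 0.0)
    radius_mm: float = 2.0
    n_points: int = 80

    def centerline(self, t: np.ndarray) -> np.ndarray:
        p0 = np.asarray(self.cortical_cap_mm, float)
        p1 = np.asarray(self.mid_control_mm, float)
        p2 = np.asarray(self.brainstem_cap_mm, float)
        t = t[:, None]
        return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2

    def __post_init__(self) -> None:
        span = np.linalg.norm(np.asarray(self.cortical_cap_mm, float)
                              - np.asarray(self.brainstem_cap_mm, float))
        if span <= 0:
            raise ValueError("degenerate bundle: caps coincide")
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")


@dataclass
class AnatomyContext:
    """Target-nucleus mask (voxel-center points, mm) and electrode."""

    stn_mask_mm: np.ndarray
    voxel_size_mm: float
    electrode: ElectrodeSpec

    def __post_init__(self) -> None:
        self.stn_mask_mm = np.atleast_2d(np.asarray(self.stn_mask_mm, float))
        if self.stn_mask_mm.size == 0:
            raise ValueError("STN mask must be non-empty")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")


@dataclass
class AxonTrajectory:
    """Main corticofugal streamline plus an optional collateral branch."""

    main: Streamline
    collateral: Streamline | None = None
    branch_node_index: int | None = None


@dataclass(frozen=True)
class FiberGeometry:
    """Per-compartment-type dimensions of one myelinated fiber (um)."""

    myelin_diameter_um: float
    node_length_um: float
    node_diameter_um: float
    mysa_length_um: float
    mysa_diameter_um: float
    flut_length_um: float
    flut_diameter_um: float
    stin_length_um: float
    stin_diameter_um: float
    internode_length_um: float
    lamellae: int

    def __post_init__(self) -> None:
        expected = (self.node_length_um + 2 * self.mysa_length_um
                    + 2 * self.flut_length_um + 6 * self.stin_length_um)
        if not np.isclose(expected, self.internode_length_um, rtol=1e-6):
            raise ValueError("internode length inconsistent with the "
                             "11-compartment repeat")
        for f in ("node_length_um", "mysa_length_um", "flut_length_um",
                  "stin_length_um", "internode_length_um"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @classmethod
    def from_diameter(cls, fiber_diameter_um: float) -> "FiberGeometry":
        """Double-cable fiber geometry from the published diameter table."""
        row = geometry_row(fiber_diameter_um)
        return cls(
            myelin_diameter_um=row["fiberD"],
            node_length_um=row["node_len"],
            node_diameter_um=row["nodeD"],
            mysa_length_um=row["mysa_len"],
            mysa_diameter_um=row["nodeD"],
            flut_length_um=row["flut_len"],
            flut_diameter_um=row["axonD"],
            stin_length_um=row["stin_len"],
            stin_diameter_um=row["axonD"],
            internode_length_um=row["deltax"],
            lamellae=int(row["nl"]),
        )

    def type_length(self, code: int) -> float:
        return {NODE: self.node_length_um, MYSA: self.mysa_length_um,
                FLUT: self.flut_length_um, STIN: self.stin_length_um}[code]

    def type_diameter(self, code: int) -> float:
        return {NODE: self.node_diameter_um, MYSA: self.mysa_diameter_um,
                FLUT: self.flut_diameter_um, STIN: self.stin_diameter_um}[code]


@dataclass
class AxonMorphology:
    """Ordered compartments of one (possibly branched) model axon.

    Compartments 0..n_main-1 follow the corticofugal path; any collateral
    compartments follow, with ``branch_parent`` giving the index of the
    main-path node the collateral root attaches to.
    """

    comp_type: np.ndarray        # int codes (NODE/MYSA/FLUT/STIN)
    midpoints_mm: np.ndarray     # (n, 3)
    length_um: np.ndarray
    diameter_um: np.ndarray      # axolemma diameter per compartment
    fiber_diameter_um: np.ndarray
    lamellae: np.ndarray
    periaxonal_space_um: np.ndarray
    active: np.ndarray           # bool; nodes with excitable membrane
    is_main: np.ndarray          # bool; False on collateral compartments
    branch_parent: int | None = None
    main_geometry: FiberGeometry | None = None
    collateral_geometry: FiberGeometry | None = None

    @property
    def n_compartments(self) -> int:
        return len(self.comp_type)

    @property
    def main_node_indices(self) -> np.ndarray:
        return np.nonzero((self.comp_type == NODE) & self.is_main)[0]

    @property
    def n_main(self) -> int:
        return int(self.is_main.sum())


# ---------------------------------------------------------------------------


def generate_streamlines(n: int, bundle_spec: BundleSpec | None = None,
                         jitter_sd_mm: float = 0.3,
                         seed: int | np.random.Generator = 0) -> list[Streamline]:
    """Synthetic corticofugal-like streamlines.

    Each streamline is the bundle centerline plus a constant lateral
    offset (uniform in the disk of the bundle radius, in the plane
    perpendicular to the cap-to-cap chord) plus independent per-point
    Gaussian jitter of standard deviation ``jitter_sd_mm`` emulating
    probabilistic-tractography noise.  Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = bundle_spec or BundleSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, spec.n_points)
    center = spec.centerline(t)
    chord = (np.asarray(spec.brainstem_cap_mm, float)
             - np.asarray(spec.cortical_cap_mm, float))
    chord = chord / np.linalg.norm(chord)
    # orthonormal frame perpendicular to the chord
    ref = np.array([1.0, 0.0, 0.0])
    if abs(chord @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(chord, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(chord, e1)
    out = []
    for _ in range(n):
        r = spec.radius_mm * np.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * np.pi)
        offset = r * (np.cos(th) * e1 + np.sin(th) * e2)
        jitter = rng.normal(0.0, jitter_sd_mm, size=center.shape) \
            if jitter_sd_mm > 0 else 0.0
        out.append(Streamline(center + offset + jitter))
    return out


def fit_smoothing_spline(s: Streamline, smoothing: float = 4.0,
                         resample_step_mm: float = 0.25,
                         n_iter: int = 3) -> Streamline:
    """Smooth a jittered streamline with a least-squares cubic spline and
    resample it uniformly in arc length.

    ``smoothing`` is the interior knot spacing in mm: the curve is
    projected onto the space of cubic splines with knots every
    ``smoothing`` mm of arc length, which suppresses point-level
    tractography jitter while following the bundle geometry; 0 requests
    an interpolating spline through all input points.  Because jitter
    inflates the raw polyline arc length, the fit is iterated: after each
    pass the data are re-parameterized by the fitted curve's arc length
    (``n_iter`` passes).  The projection character makes the operator
    nearly idempotent away from the curve ends.
    """
    pts = s.points
    if len(pts) < 4:
        raise ValueError("need at least 4 points to fit a smoothing spline")
    u = s.arc_length

    def dedup(u, pts):
        keep = np.concatenate([[True], np.diff(u) > 1e-12])
        return u[keep], pts[keep]

    u, pts = dedup(u, pts)
    if smoothing <= 0:
        splines = [UnivariateSpline(u, pts[:, k], k=3, s=0) for k in range(3)]
        dense_u = np.linspace(u[0], u[-1], max(8 * len(u), 400))
        dense = np.column_stack([sp(dense_u) for sp in splines])
    else:
        for _ in range(max(1, n_iter)):
            interior = np.arange(smoothing, u[-1] - 0.5 * smoothing, smoothing)
            splines = [LSQUnivariateSpline(u, pts[:, k], interior, k=3)
                       for k in range(3)]
            dense_u = np.linspace(u[0], u[-1], 8000)
            dense = np.column_stack([sp(dense_u) for sp in splines])
            seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            u = np.interp(u, dense_u, arc)
            u, pts = dedup(u, pts)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n_out = max(2, int(np.floor(arc[-1] / resample_step_mm)) + 1)
    target = np.arange(n_out) * resample_step_mm
    target = np.append(target[target < arc[-1]], arc[-1])
    out = np.column_stack([np.interp(target, arc, dense[:, k]) for k in range(3)])
    return Streamline(out)


def node_arc_positions(total_length_mm: float, geom: FiberGeometry) -> np.ndarray:
    """Arc-length positions (mm) of node-of-Ranvier centers when the
    11-compartment repeat is walked from arc position 0."""
    dx = geom.internode_length_um * 1e-3
    half_node = 0.5 * geom.node_length_um * 1e-3
    n_nodes = int(np.floor((total_length_mm - 2 * half_node) / dx)) + 1
    return half_node + dx * np.arange(max(n_nodes, 0))


def _circular_arc(p: np.ndarray, q: np.ndarray, bulge: np.ndarray,
                  sagitta_ratio: float, step_mm: float) -> np.ndarray:
    """Planar circular arc from p to q bulging along ``bulge`` with a
    sagitta of ``sagitta_ratio`` times the chord length."""
    chord = q - p
    c = np.linalg.norm(chord)
    if c < 1e-9:
        return np.vstack([p, q])
    h = sagitta_ratio * c
    if h < 1e-9:
        n_pts = max(2, int(np.ceil(c / step_mm)) + 1)
        return p + np.linspace(0, 1, n_pts)[:, None] * chord
    radius = h / 2.0 + c * c / (8.0 * h)
    mid = 0.5 * (p + q)
    center = mid + (h - radius) * bulge
    # angular sweep from p to q around the center, in the arc plane
    vp, vq = p - center, q - center
    e1 = vp / np.linalg.norm(vp)
    normal = np.cross(vp, vq)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        n_pts = max(2, int(np.ceil(c / step_mm)) + 1)
        return p + np.linspace(0, 1, n_pts)[:, None] * chord
    normal /= nn
    e2 = np.cross(normal, e1)
    ang = np.arctan2(vq @ e2, vq @ e1) % (2.0 * np.pi)
    arc_len = radius * ang
    n_pts = max(3, int(np.ceil(arc_len / step_mm)) + 1)
    phis = np.linspace(0.0, ang, n_pts)
    return center + radius * (np.outer(np.cos(phis), e1) + np.outer(np.sin(phis), e2))


def build_collateral(main: Streamline, main_geom: FiberGeometry,
                     coll_geom: FiberGeometry, anatomy: AnatomyContext,
                     rng: np.random.Generator,
                     sagitta_ratio: float = 0.25,
                     arc_style: str = "arc",
                     step_mm: float = 0.05,
                     max_attempts: int = 100) -> AxonTrajectory:
    """Attach a thin collateral branching toward the target nucleus.

    The branch point is drawn uniformly from the main-path nodes of
    Ranvier lying within the axial bounds of the STN mask (its extent
    along the electrode axis); the termination is a uniformly drawn mask
    voxel center.  The collateral is a planar circular arc in the plane
    of branch point, target, and electrode axis, bulging away from the
    electrode; if it passes through the electrode shaft the voxel is
    redrawn (up to ``max_attempts`` times).
    """
    el = anatomy.electrode
    axis = el.axis
    node_s = node_arc_positions(main.total_length, main_geom)
    if node_s.size == 0:
        raise ValueError("main streamline shorter than one internode")
    node_pts = main.point_at(node_s)
    proj = (anatomy.stn_mask_mm - el.tip) @ axis
    lo, hi = proj.min() - 0.5 * anatomy.voxel_size_mm, proj.max() + 0.5 * anatomy.voxel_size_mm
    node_proj = (node_pts - el.tip) @ axis
    eligible = np.nonzero((node_proj >= lo) & (node_proj <= hi))[0]
    if eligible.size == 0:
        raise ValueError("no node of Ranvier within the axial bounds of the STN")
    branch_idx = int(rng.choice(eligible))
    p = node_pts[branch_idx]
    for _ in range(max_attempts):
        q = anatomy.stn_mask_mm[rng.integers(len(anatomy.stn_mask_mm))]
        if arc_style == "line":
            pts = _circular_arc(p, q, np.zeros(3), 0.0, step_mm)
        else:
            mid = 0.5 * (p + q)
            away = mid - (el.tip + ((mid - el.tip) @ axis) * axis)
            nrm = np.linalg.norm(away)
            if nrm < 1e-9:
                away = np.cross(axis, q - p)
                nrm = np.linalg.norm(away)
            # restrict the bulge to the plane spanned by the chord and the
            # electrode axis complement so the arc is planar
            away = away / nrm
            chord = q - p
            cn = np.linalg.norm(chord)
            if cn > 1e-9:
                away = away - (away @ chord) * chord / cn ** 2
                nrm = np.linalg.norm(away)
                if nrm < 1e-9:
                    away = np.cross(axis, chord / cn)
                    nrm = np.linalg.norm(away)
                away /= nrm
            pts = _circular_arc(p, q, away, sagitta_ratio, step_mm)
        if not el.intersects(pts):
            return AxonTrajectory(main=main, collateral=Streamline(pts),
                                  branch_node_index=branch_idx)
    raise RuntimeError(
        f"no collateral clearing the electrode after {max_attempts} voxel draws")


def _walk_compartments(length_mm: float, geom: FiberGeometry,
                       first_node_length_um: float | None = None):
    """Sequence of (type, length_um) walking the 11-compartment repeat,
    truncated so the sequence ends on a complete node of Ranvier."""
    pattern = ([NODE] + [MYSA] + [FLUT] + [STIN] * 6 + [FLUT] + [MYSA])
    seq = []
    pos = 0.0
    total_um = length_mm * 1e3
    i = 0
    while True:
        code = pattern[i % 11]
        L = geom.type_length(code)
        if i == 0 and first_node_length_um is not None:
            L = first_node_length_um
        if pos + L > total_um + 1e-9:
            break
        seq.append((code, L))
        pos += L
        i += 1
    # truncate back to the last complete node
    while seq and seq[-1][0] != NODE:
        pos -= seq[-1][1]
        seq.pop()
    if not any(c == NODE for c, _ in seq) or len(seq) < 12:
        raise ValueError("trajectory shorter than one internode")
    return seq


def _place(seq, streamline: Streamline, geom: FiberGeometry):
    types = np.array([c for c, _ in seq], dtype=np.int64)
    lengths = np.array([L for _, L in seq], dtype=float)
    ends = np.cumsum(lengths) * 1e-3
    mids = ends - 0.5 * lengths * 1e-3
    pts = streamline.point_at(mids)
    diam = np.array([geom.type_diameter(c) for c in types])
    space = np.array([PERIAXONAL_SPACE_UM[_TYPE_NAMES[c]] for c in types])
    return types, lengths, pts, diam, space


def compartmentalize(traj: AxonTrajectory, main_geom: FiberGeometry,
                     coll_geom: FiberGeometry | None = None) -> AxonMorphology:
    """Place double-cable compartments along the trajectory arc length.

    The main path is walked from its first point and truncated at the
    last complete node of Ranvier.  A collateral, when present, starts
    with a node shortened to 0.5 um at the branch point, is truncated to
    end on a node, and its terminal node is flagged passive.
    """
    seq = _walk_compartments(traj.main.total_length, main_geom)
    types, lengths, pts, diam, space = _place(seq, traj.main, main_geom)
    n_main = len(types)
    active = types == NODE
    is_main = np.ones(n_main, dtype=bool)
    fiberD = np.full(n_main, main_geom.myelin_diameter_um)
    lam = np.full(n_main, main_geom.lamellae, dtype=np.int64)
    branch_parent = None
    if traj.collateral is not None:
        if coll_geom is None:
            raise ValueError("collateral present but no collateral geometry")
        cseq = _walk_compartments(traj.collateral.total_length, coll_geom,
                                  first_node_length_um=0.5)
        ct, cl, cp, cd, cs = _place(cseq, traj.collateral, coll_geom)
        cactive = ct == NODE
        cactive[-1] = False  # terminal node: passive membrane
        # locate the main-path node compartment at the branch point
        node_comp = np.nonzero(types == NODE)[0]
        branch_parent = int(node_comp[traj.branch_node_index])
        types = np.concatenate([types, ct])
        lengths = np.concatenate([lengths, cl])
        pts = np.vstack([pts, cp])
        diam = np.concatenate([diam, cd])
        space = np.concatenate([space, cs])
        active = np.concatenate([active, cactive])
        is_main = np.concatenate([is_main, np.zeros(len(ct), dtype=bool)])
        fiberD = np.concatenate([fiberD, np.full(len(ct), coll_geom.myelin_diameter_um)])
        lam = np.concatenate([lam, np.full(len(ct), coll_geom.lamellae, dtype=np.int64)])
    return AxonMorphology(comp_type=types, midpoints_mm=pts, length_um=lengths,
                          diameter_um=diam, fiber_diameter_um=fiberD,
                          lamellae=lam, periaxonal_space_um=space,
                          active=active, is_main=is_main,
                          branch_parent=branch_parent,
                          main_geometry=main_geom,
                          collateral_geometry=coll_geom)


def sample_population(streamlines: list, n_total: int, split: tuple,
                      rng: np.random.Generator):
    """Uniform sample without replacement, split disjointly into a
    fibers-of-passage set and a hyperdirect set."""
    if sum(split) != n_total:
        raise ValueError("split must sum to n_total")
    if n_total > len(streamlines):
        raise ValueError(
            f"requested {n_total} of {len(streamlines)} available streamlines")
    idx = rng.choice(len(streamlines), size=n_total, replace=False)
    passage = [streamlines[i] for i in idx[:split[0]]]
    hyperdirect = [streamlines[i] for i in idx[split[0]:]]
    return passage, hyperdirect


def save_streamlines(streamlines: list, path) -> None:
    """Plain delimited text, one point per row, blank line between
    streamlines."""
    with open(path, "w") as fh:
        fh.write("# pamsim streamlines: x_mm y_mm z_mm; blank-line separated\n")
        for s in streamlines:
            for p in s.points:
                fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
            fh.write("\n")


def load_streamlines(path) -> list[Streamline]:
    out, cur = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                continue
            if not line:
                if cur:
                    out.append(Streamline(np.array(cur)))
                    cur = []
                continue
            cur.append([float(v) for v in line.split()])
    if cur:
        out.append(Streamline(np.array(cur)))
    return out
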