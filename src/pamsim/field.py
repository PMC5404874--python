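"""Unit static extracellular potential and its space-time composition.

The stimulation field enters the axon models as the product of three
factors: a unit static potential Phi(x,y,z) solved for -1 V on the active
electrode contact, the stimulus amplitude A, and the normalized tissue
waveform V_tissue(t).  Because the underlying boundary-value problem is
linear, the static solution is computed once and scaled.

The finite-element head model that normally supplies the static solution
is not reproduced here; this module supplies its two exported products —
a unit potential evaluator and an access resistance — from either

* an analytic spherical-equivalent electrode surrogate: the active
  cylindrical contact is replaced by a sphere of equal surface area,
  surrounded by a concentric encapsulation shell, in an infinite
  homogeneous (optionally anisotropic) medium; or
* an externally solved potential sampled on a structured grid and
  interpolated trilinearly.

It also provides the diffusion-tensor-to-conductivity mapping used to
build anisotropic tissue conductivities: conductivity tensors share the
diffusion eigenvectors, with eigenvalues rescaled so each voxel's
geometric-mean conductivity equals a reference isotropic value
(volume/load preservation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "ElectrodeSpec",
    "ConductivityTensorField",
    "FieldModel",
    "conductivity_from_diffusion",
    "build_analytic_field",
    "load_field_grid",
    "save_field_grid",
    "load_tensor_field",
    "save_tensor_field",
    "tensors_to_upper_triangle",
    "upper_triangle_to_tensors",
    "sample_potentials",
    "compose_spacetime",
]


@dataclass(frozen=True)
class ElectrodeSpec:
    """Cylindrical quadripolar DBS lead geometry (dimensions in mm).

    Defaults follow the modelled lead: 1.5 mm contacts with 0.5 mm
    spacing on a 1.27 mm diameter shaft, a 0.5 mm encapsulation sheath,
    and the most distal contact starting 1.5 mm above the tip.
    """

    contact_length_mm: float = 1.5
    contact_spacing_mm: float = 0.5
    shaft_radius_mm: float = 0.635
    active_contact_index: int = 2
    encapsulation_thickness_mm: float = 0.5
    tip_position_mm: tuple = (0.0, 0.0, 0.0)
    axis_direction: tuple = (0.0, 0.0, 1.0)
    tip_to_first_contact_mm: float = 1.5
    shaft_length_mm: float = 60.0

    def __post_init__(self) -> None:
        if not 0 <= self.active_contact_index <= 3:
            raise ValueError("active_contact_index must be 0..3")
        ax = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(ax)
        if not np.isclose(n, 1.0, atol=1e-9):
            object.__setattr__(self, "axis_direction", tuple(ax / n))

    @property
    def axis(self) -> np.ndarray:
        return np.asarray(self.axis_direction, dtype=float)

    @property
    def tip(self) -> np.ndarray:
        return np.asarray(self.tip_position_mm, dtype=float)

    def contact_center(self, index: int | None = None) -> np.ndarray:
        """3D center of a contact (defaults to the active one)."""
        if index is None:
            index = self.active_contact_index
        offset = (self.tip_to_first_contact_mm
                  + index * (self.contact_length_mm + self.contact_spacing_mm)
                  + 0.5 * self.contact_length_mm)
        return self.tip + offset * self.axis

    @property
    def contact_area_cm2(self) -> float:
        """Lateral surface of one cylindrical contact, in cm^2."""
        return (math.pi * 2.0 * self.shaft_radius_mm
                * self.contact_length_mm) * 1e-2

    @property
    def equivalent_radius_mm(self) -> float:
        """Radius of the sphere with the same surface area as one contact."""
        area_mm2 = math.pi * 2.0 * self.shaft_radius_mm * self.contact_length_mm
        return math.sqrt(area_mm2 / (4.0 * math.pi))

    @classmethod
    def centered(cls, active_contact_index: int = 2, **overrides) -> "ElectrodeSpec":
        """Electrode with the active contact center at the origin, axis +z.

        This is the canonical working frame: all streamline and mask
        coordinates are expressed relative to the active contact.
        """
        spec = cls(active_contact_index=active_contact_index, **overrides)
        center = spec.contact_center()
        return cls(active_contact_index=active_contact_index,
                   tip_position_mm=tuple(-center), **overrides)

    def distance_to_shaft_axis(self, points: np.ndarray) -> np.ndarray:
        """Distance (mm) from points (n,3) to the shaft axis segment."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - self.tip
        t = rel @ self.axis
        t = np.clip(t, 0.0, self.shaft_length_mm)
        closest = self.tip + t[:, None] * self.axis
        return np.linalg.norm(pts - closest, axis=1)

    def intersects(self, points: np.ndarray, margin_mm: float = 0.0) -> bool:
        """True when any point lies inside the shaft cylinder."""
        return bool(np.any(self.distance_to_shaft_axis(points)
                           < self.shaft_radius_mm + margin_mm))


@dataclass
class ConductivityTensorField:
    """Per-voxel symmetric conductivity tensors (S/m) on a regular grid."""

    origin_mm: np.ndarray
    spacing_mm: np.ndarray
    tensors: np.ndarray  # (..., 3, 3)

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have trailing shape (3, 3)")


def conductivity_from_diffusion(diffusion_tensors: np.ndarray,
                                sigma_iso_S_per_m: float,
                                origin_mm=(0.0, 0.0, 0.0),
                                spacing_mm=(1.0, 1.0, 1.0)) -> ConductivityTensorField:
    """Map diffusion tensors (mm^2/s) to conductivity tensors (S/m).

    The conductivity tensor in each voxel shares the eigenvectors of the
    diffusion tensor; the eigenvalues are the diffusion eigenvalues scaled
    so that their geometric mean equals ``sigma_iso_S_per_m``.  This keeps
    the determinant of every output tensor at ``sigma_iso**3`` (volume
    preservation), so the tissue "load" seen by the electrode is conserved
    while the local anisotropy ratios follow the measured diffusion.
    """
    d = np.asarray(diffusion_tensors, dtype=float)
    if d.shape[-2:] != (3, 3):
        raise ValueError("diffusion tensors must have trailing shape (3, 3)")
    if not np.allclose(d, np.swapaxes(d, -1, -2), atol=1e-9):
        raise ValueError("diffusion tensors must be symmetric")
    evals, evecs = np.linalg.eigh(d)
    bad = np.nonzero(~np.all(evals > 0.0, axis=-1))
    if bad[0].size:
        raise ValueError(
            f"non-SPD diffusion tensor at voxel index {tuple(b[0] for b in bad)}")
    gm = np.prod(evals, axis=-1) ** (1.0 / 3.0)
    scaled = sigma_iso_S_per_m * evals / gm[..., None]
    sigma = np.einsum("...ij,...j,...kj->...ik", evecs, scaled, evecs)
    return ConductivityTensorField(origin_mm=np.asarray(origin_mm, float),
                                   spacing_mm=np.asarray(spacing_mm, float),
                                   tensors=sigma)


_UT = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]  # upper triangle


def tensors_to_upper_triangle(tensors: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric tensors -> (..., 6) upper-triangle components
    in the order xx, xy, xz, yy, yz, zz."""
    t = np.asarray(tensors, dtype=float)
    return np.stack([t[..., i, j] for i, j in _UT], axis=-1)


def upper_triangle_to_tensors(ut: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tensors_to_upper_triangle`."""
    ut = np.asarray(ut, dtype=float)
    if ut.shape[-1] != 6:
        raise ValueError("expected trailing dimension of 6 components")
    out = np.empty(ut.shape[:-1] + (3, 3))
    for c, (i, j) in enumerate(_UT):
        out[..., i, j] = ut[..., c]
        out[..., j, i] = ut[..., c]
    return out


def load_tensor_field(path, origin_mm=(0.0, 0.0, 0.0),
                      spacing_mm=(1.0, 1.0, 1.0)) -> tuple:
    """Per-voxel symmetric tensors from NIfTI (x, y, z, 6) or delimited
    text (one voxel per row: i j k xx xy xz yy yz zz).

    Returns (tensors, origin_mm, spacing_mm); for NIfTI input the affine
    supplies origin and spacing.
    """
    p = str(path)
    if p.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = nib.load(p)
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4 or data.shape[-1] != 6:
            raise ValueError("tensor NIfTI must have shape (x, y, z, 6)")
        origin = img.affine[:3, 3]
        spacing = np.abs(np.diag(img.affine)[:3])
        return upper_triangle_to_tensors(data), origin, spacing
    raw = np.loadtxt(p, ndmin=2)
    if raw.shape[1] != 9:
        raise ValueError("tensor text rows must be: i j k + 6 components")
    ijk = raw[:, :3].astype(int)
    dims = ijk.max(axis=0) + 1
    ut = np.zeros(tuple(dims) + (6,))
    ut[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = raw[:, 3:]
    return (upper_triangle_to_tensors(ut), np.asarray(origin_mm, float),
            np.asarray(spacing_mm, float))


def save_tensor_field(field: ConductivityTensorField, path) -> None:
    """Delimited-text export matching :func:`load_tensor_field`."""
    ut = tensors_to_upper_triangle(field.tensors)
    dims = ut.shape[:-1]
    rows = []
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                rows.append(np.concatenate([[i, j, k], ut[i, j, k]]))
    np.savetxt(path, np.asarray(rows),
               header="i j k xx xy xz yy yz zz (S/m)")


@dataclass
class FieldModel:
    """Evaluator of the unit static extracellular potential.

    ``evaluate(points)`` returns the potential (V) at mm coordinates for
    -1 V applied at the active contact, vanishing far from the electrode.
    ``access_resistance_ohm`` is the resistance between the contact and
    distant ground implied by the same solution; it is the tissue
    resistance consumed by the stimulus circuit model.
    """

    kind: str  # analytic-isotropic | analytic-anisotropic | grid
    access_resistance_ohm: float
    sigma_enc_S_per_m: float
    electrode: ElectrodeSpec | None
    _evaluator: object = dfield(repr=False, default=None)
    out_of_bounds_warned: bool = dfield(default=False, repr=False)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if not np.all(np.isfinite(pts)):
            raise ValueError("query points must be finite")
        return self._evaluator(pts)

    def scaled(self, k: float) -> "FieldModel":
        """Field with every potential multiplied by ``k`` (for linearity
        checks; the access resistance is left untouched)."""
        base = self._evaluator
        return FieldModel(kind=self.kind,
                          access_resistance_ohm=self.access_resistance_ohm,
                          sigma_enc_S_per_m=self.sigma_enc_S_per_m,
                          electrode=self.electrode,
                          _evaluator=lambda pts: k * base(pts))


def _two_layer_profile(s_mm: np.ndarray, a_mm: float, b_mm: float,
                       sigma_enc: float, sigma_tissue: float,
                       r_access: float) -> np.ndarray:
    """Radial potential profile (V) of the sphere-plus-shell surrogate as a
    function of the (possibly anisotropy-warped) radius ``s_mm``."""
    a, b = a_mm * 1e-3, b_mm * 1e-3
    s = np.maximum(s_mm, a_mm) * 1e-3
    current = 1.0 / r_access  # A for 1 V magnitude
    phi_outer = -current / (4.0 * math.pi * sigma_tissue * np.maximum(s, b))
    phi = np.where(
        s >= b,
        phi_outer,
        -current / (4.0 * math.pi * sigma_tissue * b)
        - current / (4.0 * math.pi * sigma_enc) * (1.0 / s - 1.0 / b),
    )
    return phi


def build_analytic_field(electrode: ElectrodeSpec,
                         sigma_tissue,
                         sigma_enc_S_per_m: float) -> FieldModel:
    """Analytic spherical-equivalent field surrogate.

    The active contact is replaced by a sphere of equal surface area
    (radius ``a``) held at -1 V, wrapped in a concentric encapsulation
    shell of the electrode's encapsulation thickness (outer radius ``b``),
    embedded in an infinite medium of conductivity ``sigma_tissue`` (a
    scalar, or a 3x3 tensor for the anisotropic variant).  The access
    resistance is

        R = (1/4pi) [ (1/sigma_enc)(1/a - 1/b) + 1/(sigma_t b) ]

    with lengths in metres.  The anisotropic variant warps the radius with
    the inverse conductivity tensor, Phi ~ 1/sqrt(x^T sigma^-1 x), using
    the geometric-mean conductivity as the scalar reference, and reduces
    exactly to the isotropic profile for sigma = sigma*I.
    """
    sigma_t = np.asarray(sigma_tissue, dtype=float)
    if sigma_enc_S_per_m <= 0 or np.any(np.diagonal(np.atleast_2d(sigma_t)) <= 0):
        raise ValueError("conductivities must be strictly positive")
    a = electrode.equivalent_radius_mm
    b = a + electrode.encapsulation_thickness_mm
    center = electrode.contact_center()

    if sigma_t.ndim == 0:
        sigma_ref = float(sigma_t)
        kind = "analytic-isotropic"

        def radius(pts):
            return np.linalg.norm(pts - center, axis=1)
    else:
        if sigma_t.shape != (3, 3):
            raise ValueError("tensor sigma_tissue must be 3x3")
        if not np.allclose(sigma_t, sigma_t.T):
            raise ValueError("sigma_tissue tensor must be symmetric")
        evals = np.linalg.eigvalsh(sigma_t)
        if np.any(evals <= 0):
            raise ValueError("sigma_tissue tensor must be positive definite")
        sigma_ref = float(np.prod(evals) ** (1.0 / 3.0))
        # dimensionless unit-determinant anisotropy: warped radius reduces
        # to |x| in the isotropic limit
        inv_norm = np.linalg.inv(sigma_t / sigma_ref)
        kind = "analytic-anisotropic"

        def radius(pts):
            rel = pts - center
            return np.sqrt(np.einsum("ni,ij,nj->n", rel, inv_norm, rel))

    r_access = (1.0 / (4.0 * math.pi)) * (
        (1.0 / sigma_enc_S_per_m) * (1.0 / (a * 1e-3) - 1.0 / (b * 1e-3))
        + 1.0 / (sigma_ref * b * 1e-3))

    def evaluator(pts):
        return _two_layer_profile(radius(pts), a, b, sigma_enc_S_per_m,
                                  sigma_ref, r_access)

    return FieldModel(kind=kind, access_resistance_ohm=r_access,
                      sigma_enc_S_per_m=sigma_enc_S_per_m,
                      electrode=electrode, _evaluator=evaluator)


# ---------------------------------------------------------------------------
# structured-grid import/export (documented text equivalent of a legacy
# structured-points file: header keys, then values with x fastest)

_GRID_MAGIC = "# pamsim-field-grid v1"


def save_field_grid(field: FieldModel, path, origin_mm, spacing_mm, dims) -> None:
    """Sample ``field`` on a regular grid and write the text grid format."""
    origin = np.asarray(origin_mm, float)
    spacing = np.asarray(spacing_mm, float)
    nx, ny, nz = dims
    xs = origin[0] + spacing[0] * np.arange(nx)
    ys = origin[1] + spacing[1] * np.arange(ny)
    zs = origin[2] + spacing[2] * np.arange(nz)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    vals = field.evaluate(grid.reshape(-1, 3)).reshape(nx, ny, nz)
    with open(path, "w") as fh:
        fh.write(_GRID_MAGIC + "\n")
        fh.write(f"origin_mm: {float(origin[0])!r} {float(origin[1])!r} {float(origin[2])!r}\n")
        fh.write(f"spacing_mm: {float(spacing[0])!r} {float(spacing[1])!r} {float(spacing[2])!r}\n")
        fh.write(f"dims: {nx} {ny} {nz}\n")
        fh.write(f"access_resistance_ohm: {float(field.access_resistance_ohm)!r}\n")
        fh.write(f"sigma_enc_S_per_m: {float(field.sigma_enc_S_per_m)!r}\n")
        # x varies fastest
        np.savetxt(fh, vals.reshape(nx * ny * nz, order="F"))


def load_field_grid(path) -> FieldModel:
    """Read a structured potential grid written by :func:`save_field_grid`
    (or an external solver exporting the same documented format)."""
    header = {}
    n_header = 1
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _GRID_MAGIC.strip():
            raise ValueError(f"malformed grid header: {magic!r}")
        for line in fh:
            n_header += 1
            if ":" not in line:
                raise ValueError(f"malformed grid header line: {line!r}")
            key, _, rest = line.partition(":")
            header[key.strip()] = rest.split()
            if key.strip() == "sigma_enc_S_per_m":
                break
    origin = np.array([float(v) for v in header["origin_mm"]])
    spacing = np.array([float(v) for v in header["spacing_mm"]])
    dims = tuple(int(v) for v in header["dims"])
    if np.any(spacing <= 0):
        raise ValueError("grid spacing must be positive and uniform per axis")
    r_access = float(header["access_resistance_ohm"][0])
    sigma_enc = float(header["sigma_enc_S_per_m"][0])
    vals = np.loadtxt(path, skiprows=n_header)
    if vals.size != dims[0] * dims[1] * dims[2]:
        raise ValueError("grid value count does not match dims")
    cube = vals.reshape(dims, order="F")
    axes = [origin[i] + spacing[i] * np.arange(dims[i]) for i in range(3)]
    interp = RegularGridInterpolator(axes, cube, method="linear",
                                     bounds_error=False, fill_value=0.0)

    model = FieldModel(kind="grid", access_resistance_ohm=r_access,
                       sigma_enc_S_per_m=sigma_enc, electrode=None)

    lo = origin
    hi = origin + spacing * (np.array(dims) - 1)

    def evaluator(pts):
        outside = np.any((pts < lo) | (pts > hi), axis=1)
        if np.any(outside) and not model.out_of_bounds_warned:
            model.out_of_bounds_warned = True
            warnings.warn("field grid queried outside its bounds; "
                          "returning 0 V there", stacklevel=3)
        return interp(pts)

    model._evaluator = evaluator
    return model


def sample_potentials(field: FieldModel, points) -> np.ndarray:
    """Unit-drive potential (V) at each of ``points`` (n, 3) in mm."""
    return field.evaluate(points)


def compose_spacetime(static_potentials, amplitude_V: float, waveform) -> np.ndarray:
    """Space-time potential matrix (n_points, n_times) in volts.

    Outer product of the unit static potentials with the amplitude-scaled
    normalized tissue waveform — the full stimulus seen by each
    compartment over time.
    """
    if amplitude_V < 0:
        raise ValueError("amplitude_V is a cathodic magnitude, must be >= 0")
    static = np.asarray(static_potentials, dtype=float)
    return np.outer(static, amplitude_V * waveform.values)
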