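"""Voltage-dependent energy landscapes over the (z, phi) configuration space.

Two construction routes:

* :func:`synthetic_landscape` - a parametric stand-in with inverted-Gaussian
  wells at the three conformational states of the voltage sensor (activated,
  intermediate resting, deep resting), a linear voltage tilt proportional to
  the gating charge, and one-sided quadratic penalty walls mimicking the
  S4-S5 linker constraint.

* :func:`build_landscape_from_structure` - rigid-body scan of a structure:
  the mobile S4-S3 complex is translated/rotated to every grid node and the
  total energy (slab electrostatics with image charges, a uniform
  transmembrane field, Lennard-Jones sterics, penalty walls) is evaluated.

The membrane and both electrolyte half-spaces are continuum dielectrics;
the electrolyte permittivity is taken as infinite, so each interface
reflects charges with coefficient -1 and the image construction is the
alternating two-plate series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import ConfigGrid, EnergyLandscape
from .units import DEFAULT_TEMPERATURE, coulomb_constant_kt, kt_millivolt

__all__ = [
    "Well",
    "PenaltyWalls",
    "LandscapeParams",
    "StructureModel",
    "DielectricModel",
    "synthetic_landscape",
    "transform_structure",
    "electrostatic_energy",
    "steric_energy",
    "build_landscape_from_structure",
    "discretization_error",
]


@dataclass(frozen=True)
class Well:
    """Inverted-Gaussian well: center (z A, phi rad), depth (kT), widths
    (A, rad) = Gaussian sigmas along each axis."""

    center: tuple[float, float]
    depth: float
    widths: tuple[float, float]

    def __post_init__(self) -> None:
        if self.depth <= 0 or min(self.widths) <= 0:
            raise ValueError("well depth and widths must be positive")


@dataclass(frozen=True)
class PenaltyWalls:
    """One-sided quadratic walls restraining S4-S3 excursions:
    0.5*stiffness*(z - z_out_threshold)^2 beyond +4 A outward and the
    mirror term beyond -8 A inward."""

    z_out_threshold: float = 4.0
    z_in_threshold: float = -8.0
    stiffness: float = 0.1  # kT/A^2

    def energy(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        out = np.clip(z - self.z_out_threshold, 0.0, None)
        inn = np.clip(self.z_in_threshold - z, 0.0, None)
        return 0.5 * self.stiffness * (out**2 + inn**2)


# Calibrated synthetic defaults (see docs/methods.md): centers are the three
# conformational states of the voltage sensor; depths/widths are calibrated so
# that the landscape reproduces the gating phenomenology (distinct minima,
# mode switch between -100 and +60 mV, activation within ~150 ms, relaxation
# to steady state well inside 1000 ms).  They are a stand-in, not measured
# values.
_DEFAULT_WELLS = (
    # activated state: broad basin + narrow core at the same minimum
    Well(center=(2.0, 0.2), depth=4.5, widths=(2.4, 0.42)),
    Well(center=(2.0, 0.2), depth=2.5, widths=(1.0, 0.30)),
    Well(center=(-5.0, 0.6), depth=5.0, widths=(2.0, 0.42)),  # intermediate resting
    Well(center=(-10.0, 0.7), depth=4.5, widths=(1.25, 0.34)),  # deep resting
)


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the synthetic three-well landscape."""

    wells: tuple[Well, ...] = _DEFAULT_WELLS
    gating_charge: float = 2.0  # elementary charges moved across the membrane
    membrane_thickness: float = 30.0  # A
    membrane_z_lower: float = -14.0  # lab z of the intracellular membrane face
    penalty: PenaltyWalls = field(default_factory=PenaltyWalls)
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.membrane_thickness <= 0:
            raise ValueError("membrane_thickness must be positive")


def synthetic_landscape(
    params: LandscapeParams, grid: ConfigGrid, vm: float
) -> EnergyLandscape:
    """Parametric landscape Phi(z, phi; Vm) in kT, minimum normalised to 0.

    Phi = sum of inverted-Gaussian wells
          - gating_charge * Vm * ramp(z) / kT   (linear voltage tilt)
          + one-sided quadratic penalty walls.

    The ramp is the fraction of the membrane span crossed, clamped to
    [0, 1]; a positive gating charge therefore lowers the energy of
    outward (positive z) conformations at depolarised potentials.
    """
    for w in params.wells:
        zc, pc = w.center
        if not (grid.z_values[0] <= zc <= grid.z_values[-1]) or not (
            grid.phi_values[0] <= pc <= grid.phi_values[-1]
        ):
            raise ValueError(f"well center {w.center} lies outside the grid")
    if not (
        grid.z_values[0] <= params.penalty.z_in_threshold
        and params.penalty.z_out_threshold <= grid.z_values[-1]
    ):
        raise ValueError("penalty thresholds must lie inside the grid range")

    z = grid.z_values[:, None]
    p = grid.phi_values[None, :]
    phi = np.zeros(grid.shape)
    for w in params.wells:
        zc, pc = w.center
        sz, sp = w.widths
        phi -= w.depth * np.exp(
            -((z - zc) ** 2) / (2 * sz**2) - ((p - pc) ** 2) / (2 * sp**2)
        )
    ramp = np.clip((z - params.membrane_z_lower) / params.membrane_thickness, 0.0, 1.0)
    vm_kt = vm / kt_millivolt(params.temperature)
    phi -= params.gating_charge * vm_kt * ramp
    phi += params.penalty.energy(z)
    return EnergyLandscape(grid, vm, phi).normalized()


# ---------------------------------------------------------------------------
# structure-based route
# ---------------------------------------------------------------------------


@dataclass
class StructureModel:
    """Rigid-body structure: coordinates (A), per-atom partial charges (e)
    and Lennard-Jones parameters, with the S4-S3 complex tagged mobile.

    The rotation axis is parallel to the first principal direction of the
    mobile segment and offset ``axis_offset`` (5 A) from its centroid.
    """

    coords: np.ndarray  # (n, 3) A
    charges: np.ndarray  # (n,) e; nan = uncharged/unknown
    lj_sigma: np.ndarray  # (n,) A; nan = missing
    lj_epsilon: np.ndarray  # (n,) kT; nan = missing
    segment: np.ndarray  # (n,) str tags
    mobile_tag: str = "S4S3"
    membrane_thickness: float = 30.0
    membrane_z_upper: float = 16.0  # A, anchored just above E160 in the full model
    axis_offset: float = 5.0
    serials: np.ndarray | None = None  # PDB atom serials, for sidecar tables
    _axis_point: np.ndarray | None = None
    _axis_dir: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.segment = np.asarray(self.segment)
        if not np.any(self.mobile_mask):
            raise ValueError(f"no atoms tagged {self.mobile_tag!r}: mobile segment empty")
        if self._axis_point is None or self._axis_dir is None:
            self._compute_axis()

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def mobile_mask(self) -> np.ndarray:
        return self.segment == self.mobile_tag

    @property
    def membrane_z_lower(self) -> float:
        return self.membrane_z_upper - self.membrane_thickness

    @property
    def rotation_axis(self) -> tuple[np.ndarray, np.ndarray]:
        """(point, unit direction) of the rotation axis."""
        return self._axis_point, self._axis_dir

    def _compute_axis(self) -> None:
        pts = self.coords[self.mobile_mask]
        center = pts.mean(axis=0)
        centred = pts - center
        # first principal direction of the mobile segment
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        direction = vt[0] / np.linalg.norm(vt[0])
        # offset the axis perpendicular to the principal direction
        perp = np.array([1.0, 0.0, 0.0])
        perp = perp - np.dot(perp, direction) * direction
        if np.linalg.norm(perp) < 1e-8:
            perp = np.array([0.0, 1.0, 0.0])
            perp = perp - np.dot(perp, direction) * direction
        perp /= np.linalg.norm(perp)
        self._axis_point = center + self.axis_offset * perp
        self._axis_dir = direction

    def copy_with_coords(self, coords: np.ndarray) -> "StructureModel":
        return replace(self, coords=coords, _axis_point=self._axis_point, _axis_dir=self._axis_dir)


@dataclass(frozen=True)
class DielectricModel:
    """Continuum dielectric settings for the slab electrostatics."""

    eps_interior: float = 6.0  # protein + membrane
    image_series_terms: int = 500
    debye_layer: float = 7.0  # A, surface-charge layer thickness
    image_plane_offset: float = 3.0  # A, mean depth of the induced surface charge
    charge_taper_distance: float = 3.0  # A, screening ramp at the electrolyte

    def __post_init__(self) -> None:
        if not (2.0 <= self.eps_interior <= 25.0):
            raise ValueError("eps_interior outside the physically plausible [2, 25]")
        if self.image_series_terms < 1:
            raise ValueError("image_series_terms must be >= 1")


def transform_structure(structure: StructureModel, z: float, phi: float) -> StructureModel:
    """Rigid transform of the mobile segment: rotation by phi about the
    stored axis followed by translation z along the membrane normal.
    Static atoms are untouched."""
    coords = structure.coords.copy()
    m = structure.mobile_mask
    point, direction = structure.rotation_axis
    if phi != 0.0:
        k = direction
        rel = coords[m] - point
        cos, sin = np.cos(phi), np.sin(phi)
        rot = (
            rel * cos
            + np.cross(k, rel) * sin
            + np.outer(rel @ k, k) * (1.0 - cos)
        )
        coords[m] = point + rot
    coords[m, 2] += z
    return structure.copy_with_coords(coords)


def _effective_charges(structure: StructureModel, dielectric: DielectricModel):
    """Taper effective charges to zero within ``charge_taper_distance`` of
    the electrolyte; charges outside the slab are fully screened (0) and
    flagged."""
    z = structure.coords[:, 2]
    q = np.nan_to_num(structure.charges, nan=0.0)
    zlo, zup = structure.membrane_z_lower, structure.membrane_z_upper
    depth = np.minimum(z - zlo, zup - z)  # negative outside the slab
    factor = np.clip(depth / dielectric.charge_taper_distance, 0.0, 1.0)
    outside = (depth < 0) & (q != 0)
    return q * factor, outside


def _image_positions(z0: np.ndarray, zlo: float, zup: float, n_terms: int):
    """Axial positions (K, n_charges) and sign factors (K,) of the
    two-plate image series for sources at z0 between mirror planes at zlo
    and zup (reflection coefficient -1 at each).  Images come in the
    standard doubly-mirrored family 2 n L +/- u; the n = 0 'same' image
    (the source itself) is excluded.  Truncation is symmetric in n, so
    the four images of each order largely cancel and the tail decays as
    1/n_terms^2."""
    length = zup - zlo
    u = z0 - zlo
    ns = np.arange(-n_terms, n_terms + 1)
    z_plus = zlo + 2 * length * ns[ns != 0][:, None] + u[None, :]  # sign +1
    z_minus = zlo + 2 * length * ns[:, None] - u[None, :]  # sign -1
    img_z = np.vstack([z_plus, z_minus])
    signs = np.concatenate([np.ones(z_plus.shape[0]), -np.ones(z_minus.shape[0])])
    return img_z, signs


def electrostatic_energy(
    structure: StructureModel,
    dielectric: DielectricModel,
    vm: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Total electrostatic energy (kT): direct Coulomb in the interior
    dielectric, the alternating image-charge series of the slab, and the
    uniform transmembrane field contribution q*Vm*(1 - ramp(z)).

    The mirror planes sit ``image_plane_offset`` beyond the geometric
    interfaces (the induced surface charge is spread through the Debye
    layer with that mean depth).
    """
    q_eff, outside = _effective_charges(structure, dielectric)
    if np.any(outside):
        import warnings

        warnings.warn(
            f"{int(outside.sum())} charged atom(s) outside the membrane slab; "
            "effective charge set to zero",
            stacklevel=2,
        )
    ke = coulomb_constant_kt(dielectric.eps_interior, temperature)
    coords = structure.coords
    charged = q_eff != 0.0
    idx = np.nonzero(charged)[0]
    energy = 0.0
    if idx.size:
        pts = coords[idx]
        qs = q_eff[idx]
        # direct pairwise Coulomb
        if idx.size > 1:
            diff = pts[:, None, :] - pts[None, :, :]
            r = np.sqrt((diff**2).sum(-1))
            iu = np.triu_indices(idx.size, k=1)
            energy += ke * float(np.sum(qs[iu[0]] * qs[iu[1]] / r[iu]))
        # image series (mirror planes offset beyond the interfaces)
        off = dielectric.image_plane_offset
        zlo = structure.membrane_z_lower - off
        zup = structure.membrane_z_upper + off
        img_z, img_s = _image_positions(pts[:, 2], zlo, zup, dielectric.image_series_terms)
        # r[i, k, j]: distance from charge i to the k-th image of charge j
        lat2 = ((pts[:, None, :2] - pts[None, :, :2]) ** 2).sum(-1)  # (n, n)
        dz = pts[:, None, None, 2] - img_z.T[None, :, :]  # (n, n, K) with axes i,j,k
        r = np.sqrt(lat2[:, :, None] + dz**2)
        qq = np.outer(qs, qs)
        e_img = float(np.einsum("ijk,ij,k->", 1.0 / r, qq, img_s))
        energy += 0.5 * ke * e_img
    # uniform transmembrane field: V(z) linear from Vm at the intracellular
    # face to 0 at the extracellular face
    ramp = np.clip(
        (coords[:, 2] - structure.membrane_z_lower) / structure.membrane_thickness,
        0.0,
        1.0,
    )
    vm_kt = vm / kt_millivolt(temperature)
    energy += float(np.sum(q_eff * vm_kt * (1.0 - ramp)))
    return energy


def steric_energy(structure: StructureModel) -> float:
    """Lennard-Jones 12-6 energy (kT) between mobile-segment atoms and
    static atoms.  Intra-static and intra-mobile pairs are constant under
    the rigid degrees of freedom and excluded.  Lorentz-Berthelot
    combination rules."""
    m = structure.mobile_mask
    considered = np.nonzero(m | ~m)[0]  # all atoms take part in some pair
    missing = considered[
        np.isnan(structure.lj_sigma[considered]) | np.isnan(structure.lj_epsilon[considered])
    ]
    if missing.size:
        serials = (
            structure.serials[missing].tolist()
            if structure.serials is not None
            else missing.tolist()
        )
        raise ValueError(f"missing Lennard-Jones parameters for atoms {serials}")
    mob, sta = structure.coords[m], structure.coords[~m]
    if mob.size == 0 or sta.size == 0:
        return 0.0
    sig = 0.5 * (structure.lj_sigma[m][:, None] + structure.lj_sigma[~m][None, :])
    eps = np.sqrt(structure.lj_epsilon[m][:, None] * structure.lj_epsilon[~m][None, :])
    diff = mob[:, None, :] - sta[None, :, :]
    r = np.sqrt((diff**2).sum(-1))
    sr6 = (sig / r) ** 6
    return float(np.sum(4.0 * eps * (sr6**2 - sr6)))


def build_landscape_from_structure(
    structure: StructureModel,
    grid: ConfigGrid,
    dielectric: DielectricModel,
    vm: float,
    penalty: PenaltyWalls | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    include_steric: bool = True,
) -> EnergyLandscape:
    """Scan the rigid-body configuration space: Phi(node) = electrostatic
    + steric + penalty energy of the structure transformed to the node;
    minimum normalised to zero."""
    import warnings

    penalty = penalty or PenaltyWalls()
    phi = np.empty(grid.shape)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # edge conformations may exit the slab
        for i, zv in enumerate(grid.z_values):
            for j, pv in enumerate(grid.phi_values):
                conf = transform_structure(structure, float(zv), float(pv))
                e = electrostatic_energy(conf, dielectric, vm, temperature)
                if include_steric:
                    e += steric_energy(conf)
                phi[i, j] = e
    phi += penalty.energy(grid.z_values)[:, None]
    return EnergyLandscape(grid, vm, phi).normalized()


def discretization_error(landscape: EnergyLandscape) -> dict[str, float]:
    """Per-axis discretisation error of the landscape: maximum midpoint-
    interpolation residual |Phi_i - (Phi_{i-1}+Phi_{i+1})/2| over interior
    nodes, relative to the global landscape range."""
    phi = landscape.phi_grid
    if phi.shape[0] < 3 or phi.shape[1] < 3:
        raise ValueError("grid must have at least 3 nodes per axis")
    rng = float(phi.max() - phi.min())
    if rng == 0.0:
        return {"z": 0.0, "phi": 0.0}
    res_z = np.abs(phi[1:-1, :] - 0.5 * (phi[:-2, :] + phi[2:, :]))
    res_p = np.abs(phi[:, 1:-1] - 0.5 * (phi[:, :-2] + phi[:, 2:]))
    return {"z": float(res_z.max() / rng), "phi": float(res_p.max() / rng)}
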