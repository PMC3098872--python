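"""Configuration-space grid and the gridded containers built on it.

The reduced configuration space of the voltage sensor has two degrees of
freedom: translation of the S4-S3 complex along the membrane normal
(z, angstrom, positive outward) and rotation about its principal axis
(phi, radian, positive counter-clockwise seen from the extracellular
side).  (z=0, phi=0) is the crystal-structure conformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfigGrid", "EnergyLandscape", "ProbabilityGrid"]

_UNIFORM_RTOL = 1e-12


def _check_uniform(values: np.ndarray, name: str) -> float:
    if values.ndim != 1 or values.size < 2:
        raise ValueError(f"{name} must be a 1-D array with at least 2 nodes")
    steps = np.diff(values)
    if np.any(steps <= 0):
        raise ValueError(f"{name} must be strictly ascending")
    h = steps.mean()
    if np.max(np.abs(steps - h)) > _UNIFORM_RTOL * max(abs(h), 1.0):
        raise ValueError(f"{name} spacing is not uniform")
    return float(h)


@dataclass(frozen=True)
class ConfigGrid:
    """Uniform 2-D grid over (z, phi).

    Defaults span z in [-14, +6] A in 0.2 A steps and phi in [-1, +1] rad
    in 0.05 rad steps (101 x 41 nodes), covering up to 14 A inward / 6 A
    outward translation and 1 rad rotation either way.
    """

    z_values: np.ndarray
    phi_values: np.ndarray
    dz: float = field(init=False)
    dphi: float = field(init=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        p = np.asarray(self.phi_values, dtype=float)
        object.__setattr__(self, "z_values", z)
        object.__setattr__(self, "phi_values", p)
        object.__setattr__(self, "dz", _check_uniform(z, "z_values"))
        object.__setattr__(self, "dphi", _check_uniform(p, "phi_values"))

    @classmethod
    def default(cls) -> "ConfigGrid":
        return cls(
            z_values=np.round(np.arange(-70, 31) * 0.2, 10),
            phi_values=np.round(np.arange(-20, 21) * 0.05, 10),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.z_values.size, self.phi_values.size)

    @property
    def nz(self) -> int:
        return self.z_values.size

    @property
    def nphi(self) -> int:
        return self.phi_values.size

    def cell_weights(self) -> np.ndarray:
        """Node-centred finite-volume areas (trapezoid weights; half-cells
        at the boundaries).  Sum equals the domain area exactly."""
        wz = np.full(self.nz, self.dz)
        wz[0] = wz[-1] = self.dz / 2.0
        wp = np.full(self.nphi, self.dphi)
        wp[0] = wp[-1] = self.dphi / 2.0
        return np.outer(wz, wp)

    def index_of(self, z: float, phi: float) -> tuple[int, int]:
        iz = int(round((z - self.z_values[0]) / self.dz))
        ip = int(round((phi - self.phi_values[0]) / self.dphi))
        if not (0 <= iz < self.nz and 0 <= ip < self.nphi):
            raise ValueError(f"({z}, {phi}) is outside the grid")
        return iz, ip

    def same_axes(self, other: "ConfigGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.z_values, other.z_values, atol=tol)
            and np.allclose(self.phi_values, other.phi_values, atol=tol)
        )


def _axis_derivative(values: np.ndarray, h: float, axis: int, order: int) -> np.ndarray:
    """Central-difference derivative along one axis, one-sided at the edges."""
    out = values
    for _ in range(order):
        out = np.gradient(out, h, axis=axis, edge_order=2)
    return out


@dataclass
class EnergyLandscape:
    """Potential energy Phi(z, phi; Vm) in kT on a ConfigGrid.

    The additive constant is arbitrary; builders normalise the grid
    minimum to zero.  Derivatives (orders 1-3 per axis) use central
    differences with one-sided stencils at the boundaries.
    """

    grid: ConfigGrid
    vm: float  # membrane potential, mV
    phi_grid: np.ndarray  # Phi values, shape (nz, nphi), kT

    def __post_init__(self) -> None:
        self.phi_grid = np.asarray(self.phi_grid, dtype=float)
        if self.phi_grid.shape != self.grid.shape:
            raise ValueError("phi_grid shape does not match the grid")
        if not np.all(np.isfinite(self.phi_grid)):
            raise ValueError("landscape must be finite everywhere")

    def normalized(self) -> "EnergyLandscape":
        return EnergyLandscape(self.grid, self.vm, self.phi_grid - self.phi_grid.min())

    def derivative(self, axis: str, order: int = 1) -> np.ndarray:
        """d^order Phi / d axis^order on the grid; axis is 'z' or 'phi'."""
        if order not in (1, 2, 3):
            raise ValueError("derivative order must be 1, 2 or 3")
        if axis == "z":
            return _axis_derivative(self.phi_grid, self.grid.dz, 0, order)
        if axis == "phi":
            return _axis_derivative(self.phi_grid, self.grid.dphi, 1, order)
        raise ValueError("axis must be 'z' or 'phi'")

    def force(self, axis: str) -> np.ndarray:
        """Generalised force f = -dPhi/dx (kT/A or kT/rad)."""
        return -self.derivative(axis, 1)

    def local_minima(self) -> list[tuple[float, float]]:
        """Grid nodes strictly lower than all 8 neighbours (edges use the
        available neighbours)."""
        phi = self.phi_grid
        pad = np.pad(phi, 1, mode="constant", constant_values=np.inf)
        is_min = np.ones_like(phi, dtype=bool)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                nb = pad[1 + di : 1 + di + phi.shape[0], 1 + dj : 1 + dj + phi.shape[1]]
                is_min &= phi < nb
        zz, pp = np.nonzero(is_min)
        return [
            (float(self.grid.z_values[i]), float(self.grid.phi_values[j]))
            for i, j in zip(zz, pp)
        ]


@dataclass
class ProbabilityGrid:
    """Probability density P(z, phi) on a ConfigGrid.

    Total mass (finite-volume quadrature) is 1 for an isolated
    configuration space and may fall below 1 when the distribution is
    coupled to the channel open state.
    """

    grid: ConfigGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match the grid")
        if np.any(self.values < -1e-300):
            raise ValueError("probability density must be non-negative")

    @property
    def mass(self) -> float:
        return float(np.sum(self.values * self.grid.cell_weights()))

    def normalized(self) -> "ProbabilityGrid":
        return ProbabilityGrid(self.grid, self.values / self.mass)

    def mode(self) -> tuple[float, float]:
        """(z, phi) of the highest-density node."""
        i, j = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return float(self.grid.z_values[i]), float(self.grid.phi_values[j])

    def marginal_z(self) -> np.ndarray:
        """Density marginalised over phi (finite-volume phi weights)."""
        wp = np.full(self.grid.nphi, self.grid.dphi)
        wp[0] = wp[-1] = self.grid.dphi / 2.0
        return self.values @ wp
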