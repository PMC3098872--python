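"""Averaged motion trajectories in configuration space.

The window-averaged equation of motion has no inertial term: the average
velocity responds instantaneously to the generalised force,

    zeta_i * v_i = f_i + sum_j omega_ij * d2 f_i / dx_j2  + (stochastic),

where f_i = -dPhi/dx_i and the omega_ij terms are the even-derivative
corrections that appear when the force is not constant over the diffusion
length (odd derivatives cancel by symmetry of the collision statistics).
With omega = 0 the drift reduces exactly to -(1/zeta_i) dPhi/dx_i and the
trajectory ensemble is the sampling view of the drift-diffusion equation
solved in :mod:`gatekin.prob_evolution`.

Internal units: z in A, phi in rad, time in ms, energy in kT
(so 1/zeta_i enters only through D_i = kT/zeta_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import EnergyLandscape
from .units import DEFAULT_TEMPERATURE, diffusion_phi, diffusion_z

__all__ = [
    "MotionParams",
    "Trajectory",
    "correction_force",
    "deterministic_velocity",
    "simulate_trajectory",
    "equivalent_rotational_friction",
]


@dataclass(frozen=True)
class MotionParams:
    """Friction and averaging-window settings.

    zeta_z (kg/s) and zeta_phi (kg.A^2/s) are the calibrated frictions;
    omega is the 2x2 matrix of higher-order friction coefficients
    (A^2/rad^2-flavoured lengths-squared; all zero by default - the
    higher-order frictions are neglected).  window is the averaging
    interval Delta-t in ms over which the stochastic velocity is averaged;
    it is the trajectory integration step.  c1 is the temperature constant
    in kT units (Einstein relation D_i = c1/zeta_i).
    """

    zeta_z: float = 0.5e-3
    zeta_phi: float = 12.5e-3
    omega: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.0), (0.0, 0.0))
    c1: float = 1.0
    window: float = 2.5e-3  # ms
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.zeta_z <= 0 or self.zeta_phi <= 0:
            raise ValueError("frictions must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")

    @property
    def d_z(self) -> float:
        """Translational diffusion constant, A^2/ms (scaled by c1 in kT)."""
        return self.c1 * diffusion_z(self.zeta_z, self.temperature)

    @property
    def d_phi(self) -> float:
        """Rotational diffusion constant, rad^2/ms."""
        return self.c1 * diffusion_phi(self.zeta_phi, self.temperature)


def equivalent_rotational_friction(a: float, zeta_z: float) -> float:
    """Translational-equivalent friction for rotation about an axis:
    zeta_phi = a^2 * zeta_z, with a the RMS distance of the moving
    residues from the rotation axis (A)."""
    if a < 0:
        raise ValueError("a must be non-negative")
    return a * a * zeta_z


def correction_force(
    landscape: EnergyLandscape,
    omega: tuple[tuple[float, float], tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Even-derivative force corrections sum_j omega_ij d2 f_i/dx_j2 on
    the grid, for both axes (kT/A and kT/rad)."""
    g = landscape.grid
    fz = -landscape.derivative("z", 1)
    fp = -landscape.derivative("phi", 1)

    def d2(arr: np.ndarray, axis: int, h: float) -> np.ndarray:
        out = np.gradient(arr, h, axis=axis, edge_order=2)
        return np.gradient(out, h, axis=axis, edge_order=2)

    corr_z = omega[0][0] * d2(fz, 0, g.dz) + omega[0][1] * d2(fz, 1, g.dphi)
    corr_p = omega[1][0] * d2(fp, 0, g.dz) + omega[1][1] * d2(fp, 1, g.dphi)
    return corr_z, corr_p


def _drift_fields(landscape: EnergyLandscape, params: MotionParams):
    """Node-level drift velocities (A/ms, rad/ms): v_i = (D_i/c1) *
    (f_i + corrections)."""
    fz = -landscape.derivative("z", 1)
    fp = -landscape.derivative("phi", 1)
    if any(any(o != 0.0 for o in row) for row in params.omega):
        cz, cp = correction_force(landscape, params.omega)
        fz = fz + cz
        fp = fp + cp
    return (params.d_z / params.c1) * fz, (params.d_phi / params.c1) * fp


def _bilinear(field_: np.ndarray, grid, z: np.ndarray, phi: np.ndarray) -> np.ndarray:
    fz = (z - grid.z_values[0]) / grid.dz
    fp = (phi - grid.phi_values[0]) / grid.dphi
    iz = np.clip(np.floor(fz).astype(int), 0, grid.nz - 2)
    ip = np.clip(np.floor(fp).astype(int), 0, grid.nphi - 2)
    tz = np.clip(fz - iz, 0.0, 1.0)
    tp = np.clip(fp - ip, 0.0, 1.0)
    return (
        field_[iz, ip] * (1 - tz) * (1 - tp)
        + field_[iz + 1, ip] * tz * (1 - tp)
        + field_[iz, ip + 1] * (1 - tz) * tp
        + field_[iz + 1, ip + 1] * tz * tp
    )


def deterministic_velocity(
    landscape: EnergyLandscape, state: tuple[float, float], params: MotionParams
) -> tuple[float, float]:
    """Deterministic (drift) velocity at a configuration-space state,
    bilinearly interpolated between nodes.  Raises if the state lies
    outside the grid."""
    g = landscape.grid
    z, phi = state
    if not (g.z_values[0] <= z <= g.z_values[-1]) or not (
        g.phi_values[0] <= phi <= g.phi_values[-1]
    ):
        raise ValueError(f"state {state} outside the grid")
    vz_field, vp_field = _drift_fields(landscape, params)
    vz = _bilinear(vz_field, g, np.array([z]), np.array([phi]))[0]
    vp = _bilinear(vp_field, g, np.array([z]), np.array([phi]))[0]
    return float(vz), float(vp)


@dataclass
class Trajectory:
    """Averaged configuration-space motion on a uniform clock."""

    times: np.ndarray  # ms, shape (n_samples,)
    states: np.ndarray  # (n_samples, n_traj, 2) or (n_samples, 2)
    vm_series: np.ndarray = field(default=None)

    @property
    def z(self) -> np.ndarray:
        return self.states[..., 0]

    @property
    def phi(self) -> np.ndarray:
        return self.states[..., 1]


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def simulate_trajectory(
    landscapes_by_vm: dict[float, EnergyLandscape],
    protocol: list[tuple[float, float]],
    params: MotionParams,
    x0: tuple[float, float] | np.ndarray,
    rng: np.random.Generator,
    n_traj: int = 1,
    record_every: int = 1,
) -> Trajectory:
    """Euler-Maruyama integration of the averaged equation of motion.

    protocol is a list of (vm_mV, duration_ms) segments; a landscape must
    be supplied for every voltage.  Per window Delta-t the state advances
    by (drift + averaged stochastic velocity) * Delta-t, the stochastic
    part having per-axis variance 2 D_i / Delta-t; boundaries reflect
    (probability conserving, matching the PDE's natural boundaries).

    x0 may be a single state (shared by all trajectories) or an
    (n_traj, 2) array.
    """
    for vm, _ in protocol:
        if vm not in landscapes_by_vm:
            raise ValueError(f"no landscape supplied for Vm = {vm} mV")
    any_ls = next(iter(landscapes_by_vm.values()))
    g = any_ls.grid
    dt = params.window
    sig_z = np.sqrt(2.0 * params.d_z * dt)
    sig_p = np.sqrt(2.0 * params.d_phi * dt)
    max_step = max(
        abs(params.d_z / params.c1) * np.max(np.abs(any_ls.force("z"))) * dt,
        abs(params.d_phi / params.c1) * np.max(np.abs(any_ls.force("phi"))) * dt,
    )
    if max_step > 2 * max(g.dz, g.dphi):
        raise ValueError(
            "drift displacement per window exceeds two grid steps; "
            "reduce the averaging window"
        )

    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    if x0.shape[0] == 1 and n_traj > 1:
        x0 = np.repeat(x0, n_traj, axis=0)
    z = x0[:, 0].copy()
    p = x0[:, 1].copy()

    fields = {
        vm: _drift_fields(ls, params) for vm, ls in landscapes_by_vm.items()
    }
    states = [np.stack([z, p], axis=-1)]
    times = [0.0]
    vms = [protocol[0][0]]
    t = 0.0
    step_count = 0
    for vm, duration in protocol:
        vz_field, vp_field = fields[vm]
        n_steps = int(round(duration / dt))
        for _ in range(n_steps):
            vz = _bilinear(vz_field, g, z, p)
            vp = _bilinear(vp_field, g, z, p)
            z = z + vz * dt + sig_z * rng.standard_normal(z.shape)
            p = p + vp * dt + sig_p * rng.standard_normal(p.shape)
            z = _reflect(z, g.z_values[0], g.z_values[-1])
            p = _reflect(p, g.phi_values[0], g.phi_values[-1])
            t += dt
            step_count += 1
            if step_count % record_every == 0:
                states.append(np.stack([z, p], axis=-1))
                times.append(t)
                vms.append(vm)
    states_arr = np.array(states)
    if states_arr.shape[1] == 1:
        states_arr = states_arr[:, 0, :]
    return Trajectory(
        times=np.array(times), states=states_arr, vm_series=np.array(vms)
    )
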