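"""Channel open probability from subunit configuration-space dynamics.

A channel opens only when the S4-S3 complexes of all four subunits occupy
activated conformations (z at or outside the activated/resting border).
The concerted permissive <-> open transition is Markovian with
voltage-independent rates alpha (permissive -> open) and beta
(open -> permissive).

Steady state: with C_A the probability that one subunit is activated
(and subunits independent), flux balance alpha*A_ss = beta*O_ss with
A_ss = (1 - O_ss) * C_A^4 gives

    O_ss = alpha C_A^4 / (alpha C_A^4 + beta).

Transient: the permissive probability is assembled from two activated-
state probabilities computed on the drift-diffusion substrate -
R_A(t) for subunits that started from the holding-potential distribution,
and U_A(t) for subunits that start all-activated (distributed
proportionally to the final steady state restricted to the activated
region).  Channels exchanged with the open state at time s carry four
activated subunits that subsequently relax like the U ensemble, giving
the convolution closure

    A(t) = (1 - O_0) R_A(t)^4 - int_0^t F(s) U_A(t - s)^4 ds,
    F(t) = alpha A(t) - beta O(t),      dO/dt = F(t).

The configuration-space density of subunits exchanged with the open
state (P_E) is evolved alongside with a source term -F(t) * (activated
profile), so that O(t) plus the total subunit mass is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import EnergyLandscape, ProbabilityGrid
from .prob_evolution import SolverConfig, _Operator, steady_state

__all__ = [
    "GatingParams",
    "GatingTrace",
    "ActivationCurve",
    "activated_probability",
    "steady_state_open_probability",
    "activation_curve",
    "transient_open_probability",
    "run_protocol",
]


@dataclass(frozen=True)
class GatingParams:
    """Concerted-transition rates (1/ms) and the activated/resting border
    (A; conformations with z >= z_border count as activated, border
    included)."""

    alpha: float = 0.2
    beta: float = 0.004
    z_border: float = -2.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("rates must be non-negative")


def _activated_mask(P: ProbabilityGrid, z_border: float) -> np.ndarray:
    g = P.grid
    if not (g.z_values[0] <= z_border <= g.z_values[-1]):
        raise ValueError(f"z_border {z_border} outside the grid")
    return g.z_values >= z_border - 1e-12


def activated_probability(P: ProbabilityGrid, z_border: float) -> float:
    """Probability mass in activated conformations (z >= z_border)."""
    mask = _activated_mask(P, z_border)
    w = P.grid.cell_weights()
    return float(np.sum(P.values[mask, :] * w[mask, :]))


def steady_state_open_probability(c_ass: float, params: GatingParams) -> float:
    """O_ss from the four-subunit flux balance; c_ass is the per-subunit
    steady-state activated probability without open-state coupling."""
    if not (0.0 <= c_ass <= 1.0 + 1e-12):
        raise ValueError("c_ass must lie in [0, 1]")
    entry = params.alpha * c_ass**4
    denom = entry + params.beta
    if denom == 0.0:
        return 0.0
    return entry / denom


@dataclass
class ActivationCurve:
    """Steady-state open probability vs clamped membrane potential."""

    voltages: np.ndarray
    o_ss: np.ndarray

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.o_ss = np.asarray(self.o_ss, dtype=float)
        if np.any((self.o_ss < -1e-12) | (self.o_ss > 1 + 1e-12)):
            raise ValueError("open probabilities must lie in [0, 1]")

    def half_activation_voltage(self) -> float:
        """V at half of the maximal O_ss, linearly interpolated."""
        target = 0.5 * self.o_ss.max()
        above = np.nonzero(self.o_ss >= target)[0]
        if above.size == 0 or above[0] == 0:
            return float(self.voltages[0])
        i = above[0]
        v0, v1 = self.voltages[i - 1], self.voltages[i]
        o0, o1 = self.o_ss[i - 1], self.o_ss[i]
        return float(v0 + (target - o0) * (v1 - v0) / (o1 - o0))

    def midpoint_slope(self) -> float:
        """dO_ss/dV (1/mV) at the half-activation point."""
        if self.voltages.size < 2:
            return 0.0
        vh = self.half_activation_voltage()
        i = int(np.clip(np.searchsorted(self.voltages, vh), 1, self.voltages.size - 1))
        return float(
            (self.o_ss[i] - self.o_ss[i - 1]) / (self.voltages[i] - self.voltages[i - 1])
        )


def activation_curve(
    landscapes: dict[float, EnergyLandscape],
    params: GatingParams,
    c1: float = 1.0,
) -> ActivationCurve:
    """Steady-state activation curve: analytic steady state per voltage ->
    activated probability -> four-subunit open probability."""
    voltages = np.array(sorted(landscapes), dtype=float)
    o = np.empty_like(voltages)
    for i, vm in enumerate(voltages):
        pss = steady_state(landscapes[vm], c1=c1)
        c_ass = activated_probability(pss, params.z_border)
        o[i] = steady_state_open_probability(c_ass, params)
    return ActivationCurve(voltages=voltages, o_ss=o)


@dataclass
class GatingTrace:
    """O(t), A(t), F(t) on a uniform clock for one voltage step, plus the
    final subunit configuration-space distribution."""

    times: np.ndarray  # ms
    open_prob: np.ndarray  # O(t)
    permissive_prob: np.ndarray  # A(t)
    net_flux: np.ndarray  # F(t) = alpha A - beta O, 1/ms
    vm: float
    subunit_mass: np.ndarray | None = None  # mass of P_C = (1-O0) P_R + P_E
    final_distribution: ProbabilityGrid | None = None

    def __post_init__(self) -> None:
        if np.any((self.open_prob < -1e-9) | (self.open_prob > 1 + 1e-9)):
            raise ValueError("open probability outside [0, 1]")


def transient_open_probability(
    landscape_hold: EnergyLandscape,
    landscape_test: EnergyLandscape,
    solver: SolverConfig,
    gating: GatingParams,
    t_end: float,
    sample_dt: float = 0.25,
    c1: float = 1.0,
    track_distribution: bool = True,
) -> GatingTrace:
    """Voltage-clamp step from the holding to the test potential.

    The subunit substrate (P_R from the holding steady state, P_U from
    the all-activated initial condition) is integrated with the explicit
    FD scheme; O(t) is advanced on the sampling clock with the
    convolution closure described in the module docstring.
    """
    if sample_dt < solver.dt:
        raise ValueError("sample_dt must be >= the FD step")
    stride = int(round(sample_dt / solver.dt))
    dt_s = stride * solver.dt
    n_samples = int(round(t_end / dt_s))

    grid = landscape_test.grid
    mask = _activated_mask(
        ProbabilityGrid(grid, np.zeros(grid.shape)), gating.z_border
    )
    w = grid.cell_weights()

    # initial conditions
    p_hold = steady_state(landscape_hold, c1=c1)
    c_hold = activated_probability(p_hold, gating.z_border)
    o0 = steady_state_open_probability(c_hold, gating)
    pss_test = steady_state(landscape_test, c1=c1)
    pu0 = np.zeros(grid.shape)
    pu0[mask, :] = pss_test.values[mask, :]
    pu_mass = float(np.sum(pu0 * w))
    if pu_mass <= 0:
        raise ValueError("activated region carries no steady-state mass")
    pu0 /= pu_mass

    op = _Operator(landscape_test, solver)
    p_r = p_hold.values.copy()
    p_u = pu0.copy()
    p_e = np.zeros(grid.shape) if track_distribution else None

    n_tot = n_samples + 1
    r_a = np.empty(n_tot)
    u_a = np.empty(n_tot)
    o = np.empty(n_tot)
    a = np.empty(n_tot)
    f = np.empty(n_tot)
    mass_c = np.empty(n_tot)

    def _act(p: np.ndarray) -> float:
        return float(np.sum(p[mask, :] * w[mask, :]))

    r_a[0] = _act(p_r)
    u_a[0] = _act(p_u)
    o[0] = o0
    a[0] = (1.0 - o0) * r_a[0] ** 4
    f[0] = gating.alpha * a[0] - gating.beta * o[0]
    mass_c[0] = (1.0 - o0) * float(np.sum(p_r * w)) + (
        0.0 if p_e is None else float(np.sum(p_e * w))
    )

    u4 = np.empty(n_tot)
    u4[0] = u_a[0] ** 4
    for n in range(1, n_tot):
        for _ in range(stride):
            p_r = op.apply(p_r)
            p_u = op.apply(p_u)
            if p_e is not None:
                p_e = op.apply(p_e)
        if p_e is not None:
            # remove/inject the open-state flux with the U-ensemble
            # activated profile (Euler, consistent with the O update)
            profile = np.zeros(grid.shape)
            profile[mask, :] = p_u[mask, :]
            pm = float(np.sum(profile * w))
            profile /= pm
            p_e = p_e - dt_s * f[n - 1] * profile
        r_a[n] = _act(p_r)
        u_a[n] = _act(p_u)
        u4[n] = u_a[n] ** 4
        o[n] = o[n - 1] + dt_s * f[n - 1]
        # convolution term: sum_{m<n} F_m U_A[n-m]^4 * dt  (left rectangle)
        conv = dt_s * float(np.dot(f[:n], u4[n:0:-1]))
        a[n] = (1.0 - o0) * r_a[n] ** 4 - conv
        f[n] = gating.alpha * a[n] - gating.beta * o[n]
        mass_c[n] = (1.0 - o0) * float(np.sum(p_r * w)) + (
            0.0 if p_e is None else float(np.sum(p_e * w))
        )
    if np.any(o < -1e-9) or np.any(o > 1 + 1e-9):
        raise RuntimeError("open probability left [0, 1]: unstable coupling")

    final = None
    if p_e is not None:
        final = ProbabilityGrid(grid, np.clip((1.0 - o0) * p_r + p_e, 0.0, None))
    return GatingTrace(
        times=dt_s * np.arange(n_tot),
        open_prob=o,
        permissive_prob=a,
        net_flux=f,
        vm=landscape_test.vm,
        subunit_mass=mass_c,
        final_distribution=final,
    )


def run_protocol(
    protocol: list[dict],
    landscapes: dict[float, EnergyLandscape],
    solver: SolverConfig,
    gating: GatingParams,
    holding_vm: float = -100.0,
    sample_dt: float = 0.25,
    c1: float = 1.0,
) -> dict:
    """End-to-end voltage-clamp driver.

    protocol: list of {"vm_mV": ..., "duration_ms": ...} test steps, each
    applied from the holding potential.  Returns the per-step gating
    traces and the steady-state activation curve over the union of
    protocol voltages.
    """
    traces: list[GatingTrace] = []
    needed = {holding_vm} | {float(s["vm_mV"]) for s in protocol}
    missing = needed - set(landscapes)
    if missing:
        raise ValueError(f"no landscape for voltages {sorted(missing)}")
    for step in protocol:
        vm = float(step["vm_mV"])
        traces.append(
            transient_open_probability(
                landscapes[holding_vm],
                landscapes[vm],
                solver,
                gating,
                t_end=float(step["duration_ms"]),
                sample_dt=sample_dt,
                c1=c1,
                track_distribution=False,
            )
        )
    curve = activation_curve(landscapes, gating, c1=c1) if landscapes else None
    return {"traces": traces, "activation_curve": curve}
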