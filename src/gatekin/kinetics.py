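"""Collision-level microsimulation of a target particle in a thermal bath.

The target particle (a protein segment, reduced to a point mass) undergoes
hard impacts with equal-mass colliders.  Equal masses exchange their
velocity component along the impact line; the tangential components are
untouched.  Because a collider can reach the target along any line with
any normal velocity (from one side or the other), the statistics of the
impact line, of the collider's normal velocity, and of the inter-impact
times are all independent of the target velocity - the property that lets
the averaged equation of motion be derived without the Langevin friction
ansatz.

This module is the brute-force oracle for those statistical claims, plus
a Langevin reference integrator driven by the same event stream so the
two descriptions can be compared impact by impact.

Reduced units by default: m = 1, kT = 1 (sigma_v = 1), mean free time = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BathParams",
    "CollisionEvent",
    "VelocityTrace",
    "sample_collision",
    "apply_impact",
    "run_collision_trace",
    "langevin_trace",
    "window_average",
]

_RESAMPLE_CAP = 10_000


@dataclass(frozen=True)
class BathParams:
    """Thermal bath of equal-mass colliders.

    sigma_v is the standard deviation of any 1-D component of the collider
    velocity (sqrt(kT/m)); mean_free_time the mean interval between
    impacts (Poisson arrivals, independent of the target velocity).
    """

    mass: float = 1.0
    temperature: float = 1.0
    sigma_v: float | None = None
    mean_free_time: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.temperature <= 0 or self.mean_free_time <= 0:
            raise ValueError("mass, temperature and mean_free_time must be positive")
        if self.sigma_v is None:
            object.__setattr__(self, "sigma_v", math.sqrt(self.temperature / self.mass))
        if self.sigma_v <= 0:
            raise ValueError("sigma_v must be positive")


@dataclass(frozen=True)
class CollisionEvent:
    """One impact.

    The impact line is undirected and stored folded into the upper
    hemisphere: theta in [0, pi/2] (polar angle from the lab z axis),
    phi in [0, 2 pi).  v_n is the collider velocity component along that
    direction; the side the collider comes from is implied by the sign of
    the relative normal velocity v_n - v_target . d.
    """

    time: float
    theta: float
    phi: float
    v_n: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= math.pi / 2 + 1e-12):
            raise ValueError("theta must lie in [0, pi/2]")
        if not (0.0 <= self.phi < 2 * math.pi + 1e-12):
            raise ValueError("phi must lie in [0, 2 pi)")

    @property
    def direction(self) -> np.ndarray:
        st = math.sin(self.theta)
        return np.array(
            [st * math.cos(self.phi), st * math.sin(self.phi), math.cos(self.theta)]
        )


def sample_collision(
    target_velocity,
    bath: BathParams,
    rng: np.random.Generator,
    t_prev: float = 0.0,
) -> CollisionEvent:
    """Draw the next impact for a target moving at ``target_velocity``.

    Rejection sampling: the candidate inward impact normal is uniform on
    the sphere and the candidate normal velocity Gaussian; a candidate is
    a real impact only if the collider overtakes the target along the
    line (v_n > v_target . d).  The accepted undirected line is uniform
    on the hemisphere and the inter-impact time is exponential - both
    independent of the target velocity.
    """
    v = np.asarray(target_velocity, dtype=float)
    tau = rng.exponential(bath.mean_free_time)
    for _ in range(_RESAMPLE_CAP):
        d = rng.standard_normal(3)
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        d /= norm
        v_n = rng.normal(0.0, bath.sigma_v)
        if v_n > float(v @ d):
            if d[2] < 0.0:  # fold the line into the upper hemisphere
                d = -d
                v_n = -v_n
            theta = math.acos(min(1.0, max(-1.0, d[2])))
            phi = math.atan2(d[1], d[0]) % (2 * math.pi)
            return CollisionEvent(time=t_prev + tau, theta=theta, phi=phi, v_n=v_n)
    raise RuntimeError(
        f"no admissible collision after {_RESAMPLE_CAP} draws "
        f"(target speed {np.linalg.norm(v):g} is extreme for this bath)"
    )


def apply_impact(v_before, event: CollisionEvent) -> np.ndarray:
    """Exchange the velocity component along the impact line (equal
    masses): the target's normal component is replaced by the collider's
    v_n; tangential components are unchanged.  A vanishing relative
    normal velocity means the particles are not actually colliding."""
    v = np.asarray(v_before, dtype=float)
    d = event.direction
    rel = event.v_n - float(v @ d)
    if rel == 0.0:
        raise ValueError("inadmissible event: zero relative normal velocity")
    return v + rel * d


@dataclass
class VelocityTrace:
    """Velocity time series sampled immediately after each impact.

    deterministic_part is the force-driven component accumulated through
    the gamma-weighted recursion (gamma_k = fraction of each velocity
    component preserved by the k-th impact); stochastic_part is the
    remainder, so the two always sum to the recorded velocity.
    """

    times: np.ndarray
    velocity: np.ndarray  # (n, 3)
    events: list[CollisionEvent] = field(default_factory=list)
    deterministic_part: np.ndarray | None = None
    stochastic_part: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.deterministic_part is not None and self.stochastic_part is not None:
            if not np.allclose(
                self.deterministic_part + self.stochastic_part,
                self.velocity,
                atol=1e-10,
            ):
                raise ValueError("decomposed parts do not sum to the velocity")


def run_collision_trace(
    n_impacts: int,
    bath: BathParams,
    force=None,
    rng: np.random.Generator | None = None,
    v0=(0.0, 0.0, 0.0),
) -> VelocityTrace:
    """Simulate ``n_impacts`` sequential impacts.

    ``force`` is a constant acceleration 3-vector (per unit mass) or None.
    Between impacts the velocity is constant (force None) or linearly
    accelerated.  The deterministic component follows the exact recursion
    v_d(k+1) = gamma_k * (v_d(k) + f tau_k) per axis, with
    gamma_k = 1 - d_axis^2 the preserved fraction; the stochastic part is
    the remainder.
    """
    if n_impacts < 1:
        raise ValueError("n_impacts must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(bath.rng_seed)
    f = None if force is None else np.asarray(force, dtype=float)
    v = np.asarray(v0, dtype=float).copy()
    v_d = np.zeros(3)
    t = 0.0
    times = np.empty(n_impacts)
    vel = np.empty((n_impacts, 3))
    det = np.empty((n_impacts, 3))
    events: list[CollisionEvent] = []
    for k in range(n_impacts):
        event = sample_collision(v, bath, rng, t_prev=t)
        tau = event.time - t
        if f is not None:
            v = v + f * tau
            v_d = v_d + f * tau
        d = event.direction
        rel = event.v_n - float(v @ d)
        v = v + rel * d
        gamma = 1.0 - d * d  # per-axis preserved fraction, |gamma| < 1 a.s.
        v_d = gamma * v_d
        t = event.time
        times[k] = t
        vel[k] = v
        det[k] = v_d
        events.append(event)
    return VelocityTrace(
        times=times,
        velocity=vel,
        events=events,
        deterministic_part=det,
        stochastic_part=vel - det,
    )


def langevin_trace(
    duration: float | None,
    friction: float,
    bath: BathParams,
    rng: np.random.Generator | None = None,
    events: list[CollisionEvent] | None = None,
    v0=(0.0, 0.0, 0.0),
) -> VelocityTrace:
    """Langevin reference: exponential decay of the velocity between
    impulses (friction per unit mass) and a jump by the collider's full
    normal-velocity contribution v_n*d at each event.

    Pass ``events`` from a collision trace for a paired comparison driven
    by one event stream; otherwise events are drawn for ``duration``.
    The jump adds the collider's contribution without removing the
    target's own normal component - that removal is exactly what the
    continuous friction term stands in for, and the comparison with the
    true exchange dynamics exposes the overestimate right after impact.
    """
    if friction <= 0:
        raise ValueError("friction must be positive")
    if events is None:
        if duration is None or duration <= 0:
            raise ValueError("duration must be positive when events are not supplied")
        rng = rng if rng is not None else np.random.default_rng(bath.rng_seed)
        events = []
        t = 0.0
        v_probe = np.zeros(3)  # admissibility probe; statistics are v-independent
        while True:
            ev = sample_collision(v_probe, bath, rng, t_prev=t)
            if ev.time > duration:
                break
            events.append(ev)
            t = ev.time
        if not events:
            raise ValueError("duration too short: no events drawn")
    v = np.asarray(v0, dtype=float).copy()
    t = 0.0
    times = np.empty(len(events))
    vel = np.empty((len(events), 3))
    for k, ev in enumerate(events):
        v = v * math.exp(-friction * (ev.time - t))
        v = v + ev.v_n * ev.direction
        t = ev.time
        times[k] = t
        vel[k] = v
    return VelocityTrace(times=times, velocity=vel, events=list(events))


def window_average(trace: VelocityTrace, window: float) -> VelocityTrace:
    """Average the velocity over consecutive windows of length ``window``.

    The trace is treated as piecewise constant at the recorded
    post-impact values (exact in the force-free case).  Emits a warning
    when a window spans fewer than ~100 impacts, where the time average
    no longer approximates the ensemble average.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    times = trace.times
    mean_gap = float(np.mean(np.diff(times))) if times.size > 1 else float(times[0])
    if window < 100 * mean_gap:
        import warnings

        warnings.warn(
            f"window {window:g} spans ~{window / mean_gap:.0f} impacts (< 100); "
            "the averaged stochastic velocity will not be well mixed",
            stacklevel=2,
        )
    t_start = times[0]
    t_end = times[-1]
    n_win = int((t_end - t_start) // window)
    if n_win < 1:
        raise ValueError("trace shorter than one window")

    def _avg(series: np.ndarray) -> np.ndarray:
        # integrate the piecewise-constant series over each window
        edges = t_start + window * np.arange(n_win + 1)
        out = np.empty((n_win, series.shape[1]))
        # sample times: value series[k] holds on [times[k], times[k+1])
        idx = 0
        for w in range(n_win):
            lo, hi = edges[w], edges[w + 1]
            acc = np.zeros(series.shape[1])
            t_cursor = lo
            while idx < times.size - 1 and times[idx + 1] <= hi:
                if times[idx + 1] > t_cursor:
                    acc += series[idx] * (times[idx + 1] - t_cursor)
                    t_cursor = times[idx + 1]
                idx += 1
            acc += series[idx] * (hi - t_cursor)
            out[w] = acc / window
        return out

    avg_v = _avg(trace.velocity)
    centers = t_start + window * (np.arange(n_win) + 0.5)
    det = sto = None
    if trace.deterministic_part is not None:
        # rewind the cursor-based integration for each component series
        det = _avg(trace.deterministic_part)
        sto = avg_v - det
    return VelocityTrace(
        times=centers,
        velocity=avg_v,
        events=[],
        deterministic_part=det,
        stochastic_part=sto,
    )
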