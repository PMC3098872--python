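# gatekin

Continuum molecular simulation of large, slow conformational changes
during ion-channel gating.

Molecular dynamics resolves atomic vibrations but cannot reach the tens
of milliseconds over which a voltage-gated channel actually opens.
`gatekin` works at the other end: the voltage sensor's S4–S3 complex is
reduced to two degrees of freedom — translation `z` along the membrane
normal and rotation `φ` about its principal axis — and its motion is
simulated over the *entire* configuration space with equations derived
from collision-level kinetic theory rather than from the Langevin
ansatz. The package is aimed at computational biophysicists who want
channel open-probability predictions from an energy landscape, and at
methods developers who want the collision-level machinery that
justifies (and corrects) overdamped stochastic models.

## What is inside

* **kinetics** — a hard-impact microsimulator of a particle in an
  equal-mass thermal bath, plus a Langevin integrator driven by the
  same event stream. It demonstrates by brute force that the exchange
  dynamics is Maxwell–Boltzmann while the Langevin reference
  overestimates post-impact speeds and produces a leptokurtic velocity
  PDF — the motivation for the averaged equations.
* **motion** — the averaged (inertia-free) equation of motion
  `ζ_i v_i = −∂Φ/∂x_i + Σ_j ω_ij ∂²f_i/∂x_j²` with window-averaged
  stochastic velocity; Euler–Maruyama trajectory ensembles.
* **landscape** — voltage-dependent energy landscapes `Φ(z, φ; Vm)`:
  either a calibrated synthetic three-state landscape, or a rigid-body
  scan of a PDB structure with slab electrostatics (image charges for
  the membrane/electrolyte interfaces, uniform transmembrane field,
  charge screening taper) and Lennard-Jones sterics.
* **prob_evolution** — an explicit flux-form drift–diffusion solver for
  the probability density over configuration space, with zero-flux
  boundaries, machine-precision mass conservation, exact discrete
  detailed balance, and the closed-form Boltzmann steady state as
  reference.
* **gating** — four-subunit cooperativity: a channel opens through a
  concerted Markov step (α = 0.2/ms, β = 0.004/ms) available only when
  all four voltage sensors are activated (z ≥ −2 Å); steady-state
  activation curves and transient voltage-clamp responses, with the
  subunit/open-state exchange solved by an analytic convolution closure
  instead of Monte-Carlo.
* **workbench** (`config`, `io`, `fixtures`, `cli`) — YAML run
  configurations, HDF5/text grid containers, a deterministic toy
  structure generator, and the `gatekin` command line
  (`fixture | collide | landscape | trajectory | evolve | gate`).

See `docs/methods.md` for the model, its assumptions, the calibrated
defaults and known limitations.

## Worked example

```python
import numpy as np
from gatekin.grids import ConfigGrid
from gatekin.landscape import LandscapeParams, synthetic_landscape
from gatekin.prob_evolution import SolverConfig, steady_state
from gatekin.gating import GatingParams, activation_curve, transient_open_probability

grid = ConfigGrid.default()          # 101 x 41 nodes over [-14, 6] A x [-1, 1] rad
params = LandscapeParams()           # calibrated three-state landscape
gating = GatingParams()              # alpha = 0.2/ms, beta = 0.004/ms, border -2 A

landscapes = {vm: synthetic_landscape(params, grid, vm)
              for vm in (-100.0, -60.0, -20.0, 20.0, 60.0)}

print("mode at -100 mV:", steady_state(landscapes[-100.0]).mode())
print("mode at  +60 mV:", steady_state(landscapes[60.0]).mode())

curve = activation_curve(landscapes, gating)
for vm, o in zip(curve.voltages, curve.o_ss):
    print(f"O_ss({vm:+.0f} mV) = {o:.3f}")
print(f"V_half = {curve.half_activation_voltage():.1f} mV")

trace = transient_open_probability(
    landscapes[-100.0], landscapes[60.0], SolverConfig(), gating,
    t_end=150.0, track_distribution=False)
for t in (10, 50, 100, 150):
    i = np.argmin(np.abs(trace.times - t))
    print(f"O({t:3d} ms) = {trace.open_prob[i]:.3f}")
```

Output:

```
mode at -100 mV: (-10.0, 0.7)
mode at  +60 mV: (2.0, 0.2)
O_ss(-100 mV) = 0.090
O_ss(-60 mV) = 0.566
O_ss(-20 mV) = 0.878
O_ss(+20 mV) = 0.950
O_ss(+60 mV) = 0.969
V_half = -66.9 mV
O( 10 ms) = 0.091
O( 50 ms) = 0.159
O(100 ms) = 0.375
O(150 ms) = 0.587
```

Reading it: at the −100 mV holding potential the voltage sensors sit in
the deep resting state (z = −10 Å, φ = 0.7 rad); full depolarisation to
+60 mV moves the probability mode 12 Å outward and 0.5 rad — the
activated conformation — and the steady-state activation curve rises in
the classic S shape. After the voltage step the open probability grows
sigmoidally (the initial delay reflects each subunit's passage through
the resting states) and keeps rising toward its steady-state value of
0.97 on the few-hundred-millisecond scale.

The same pipeline runs from the shell:

```bash
gatekin fixture --seed 0 --out fixture/          # toy structure + configs
gatekin landscape --vm -100 --out rest.h5        # synthetic landscape
gatekin evolve --from-vm -100 --to-vm 60 --t-end 150 --out evolve_out/
gatekin gate --out gate_out/                     # voltage-clamp protocol
```

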