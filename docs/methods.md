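# Methods

## The model

`gatekin` simulates large, slow conformational changes of a
voltage-gated potassium channel's voltage sensor — the millisecond-scale
motion of the S4–S3 helix pair that couples membrane potential to pore
opening — without simulating atomic vibrations. The configuration space
is reduced to two degrees of freedom: translation `z` of the S4–S3
complex along the membrane normal (positive outward, −14…+6 Å in 0.2 Å
steps) and rotation `φ` about an axis parallel to its first principal
direction, offset 5 Å from its centroid (±1 rad in 0.05 rad steps). The
node (z=0, φ=0) is the crystal-structure (activated) conformation.

### Collision statistics (kinetics module)

The starting point is the statistics of thermal impacts on a target
particle in a bath of equal-mass colliders. Equal masses exchange their
velocity component along the impact line; tangential components are
untouched. Because a collider can reach the target along any undirected
line with any normal velocity (from one side or the other), the impact
line (uniform in solid angle), the collider normal velocity (Gaussian,
std `σ_v = sqrt(kT/m)`) and the waiting times (exponential, mean
`mean_free_time`) are all independent of the target velocity. Two
consequences the module verifies by brute force:

* the stationary velocity distribution is Maxwell–Boltzmann, and the
  post-impact velocity expectation decays geometrically (each impact
  preserves on average 2/3 of a component, so memory is gone after ~10
  impacts);
* a Langevin integrator driven by the *same* impulse stream behaves
  differently: it adds each collider contribution without removing the
  target's own normal component (that removal is what the continuous
  friction term stands in for), so it overestimates the speed right
  after an impact and relaxes it exponentially in between, producing a
  stationary velocity PDF with excess weight near zero and in the tails
  (leptokurtic) rather than Gaussian.

The deterministic (force-driven) velocity component is accumulated with
the exact per-axis recursion `v_d(k+1) = γ_k (v_d(k) + f τ_k)` with
`γ_k = 1 − d_axis²` the preserved fraction; this equals the full
weighted series over past impacts with no truncation error.

### Averaged equation of motion (motion module)

Averaging over a window Δt spanning ≥100 impacts removes the inertial
term entirely; the average velocity responds instantaneously to the
generalised force:

    ζ_i v_i = f_i + Σ_j ω_ij ∂²f_i/∂x_j² + (stochastic),
    f_i = −∂Φ/∂x_i.

The `ω_ij` corrections carry the even force derivatives that matter
when the force varies over the diffusion length (odd derivatives cancel
by the symmetry of the collision statistics). They are zero by default
— the higher-order frictions are neglected, as in the calibrated runs —
and the drift then reduces exactly to `−(1/ζ_i) ∂Φ/∂x_i`. The averaged
stochastic velocity is white at the Δt resolution with per-axis variance
`2 D_i / Δt`, `D_i = C1/ζ_i` and `C1 = kT` (Einstein relation).
Trajectories use Euler–Maruyama with bilinear force interpolation and
reflecting boundaries.

Friction defaults are the calibrated values `ζ_z = 0.5e-3 kg/s` and
`ζ_φ = 12.5e-3 kg·Å²/s`; the rotational value is the translational one
mapped through the `a² ζ_z` equivalence with `a = 5 Å` the RMS distance
of the moving residues from the rotation axis. At 310 K these give
`D_z = 0.856 Å²/ms` and `D_φ = 0.0342 rad²/ms`. Scaling both frictions
together only dilates the dynamics in time; the package tests this as
an exact discrete identity.

### Probability evolution (prob_evolution module)

The ensemble view is a drift–diffusion equation for P(z, φ, t) with the
drift above and diffusion `D_i`, integrated explicitly (default
dt = 2.5 µs; 50 ns is the fine reference) with natural zero-flux
boundaries. The face flux is exponentially fitted:

    J_{i+1/2} = −(D/Δx) [P_{i+1} e^{+ΔΦ/2C1} − P_i e^{−ΔΦ/2C1}],

a second-order central scheme in the smooth limit whose discrete
stationary state is the Boltzmann grid function *exactly*. This choice
is what makes the solver meet its accuracy bounds: mass conservation to
machine precision (e1 ≈ 1e-15 over a full activation transition, bound
1e-7), L1 agreement with the closed-form steady state of 1.4e-7 at
t = 1000 ms (bound 1e-6), and discrete detailed balance (max edge flux
< 1e-10, no probability circulation). A positivity/stability bound on
dt is enforced before stepping; the explicit scheme diverges beyond it.

Detailed balance requires the temperature constants to be identical on
all axes; the closed-form stationary distribution is
`P_ss ∝ exp(−(Φ + Σ_j C2_j ∂²Φ/∂x_j²)/C1)`, with the curvature factor
dropped (C2 = None) in all default runs, i.e. the Boltzmann form.

### Energy landscape (landscape module)

Two builders produce Φ(z, φ; Vm) in kT, minimum normalised to zero.

*Structure route*: the S4–S3 complex is rigidly transformed to each
node; the energy is pairwise Coulomb inside a uniform dielectric
(ε = 6) slab (thickness 30 Å), plus the alternating image-charge series
of the slab bounded by infinite-permittivity electrolyte (reflection
coefficient −1 at each interface; mirror planes placed 3 Å beyond the
geometric faces, the mean depth of the induced surface charge in the
7 Å Debye layer), plus `q·Vm·(1 − ramp(z))` for the uniform
transmembrane field, plus Lennard-Jones 12-6 sterics between mobile and
static atoms. Charges within 3 Å of an electrolyte interface have their
effective charge tapered linearly to zero (screening). The image series
is truncated at 500 terms; symmetric truncation makes the tail decay
like 1/N², and 500 terms agree with a 5000-term direct summation to
4e-7 relative. Φ is affine in Vm by construction.

*Synthetic route*: inverted-Gaussian wells at the three conformational
states, a linear voltage tilt `−Q·Vm·ramp(z)` with gating charge Q, and
one-sided quadratic penalty walls beyond +4 Å outward / −8 Å inward
(stiffness 0.1 kT/Å²) standing in for the S4–S5 linker constraint.

### Synthetic landscape calibration

The well centers are the three states of the voltage sensor: activated
(2 Å, 0.2 rad), intermediate resting (−5 Å, 0.6 rad), deep resting
(−10 Å, 0.7 rad). Depths and widths are **calibrated, not measured**:
they were chosen once, numerically, so that the landscape reproduces
the gating phenomenology —

* three distinct minima within one grid step of the state centers at
  both −100 and +60 mV;
* global probability mode at the deep resting state at −100 mV and at
  the activated state at +60 mV, i.e. a 12 Å outward translation and
  0.5 rad rotation upon full depolarisation;
* activation developing over tens of milliseconds (sigmoidal onset,
  near-complete by a few hundred ms) and relaxation to steady state
  well inside 1000 ms (slowest relaxation time ≈ 60 ms at +60 mV);
* landscape smoothness on the default grid: maximum relative
  discretisation error 0.7% along z and 0.8% along φ (bounds 3%/1%).

The frozen defaults: activated state = broad basin (4.5 kT deep,
σ = 2.4 Å / 0.42 rad) plus a narrow core (2.5 kT, 1.0 Å / 0.30 rad) at
the same center; intermediate (5 kT, 2.0 Å / 0.42 rad); deep resting
(4.5 kT, 1.25 Å / 0.34 rad); gating charge 2 e. The two-component
activated state resolves a real tension: the mode must sit at z = 2
against the voltage tilt (needs curvature ≳3 kT/Å²) while the barriers
must stay low enough (≲2 kT) for sub-100 ms relaxation; one Gaussian
cannot do both. A single friction scale and `C1 = kT` are used
throughout — anisotropy was left out for lack of a reason to include it.

### Gating (gating module)

A channel conducts only after a concerted, voltage-independent Markov
transition from the permissive state (all four subunits activated,
z ≥ −2 Å) to the open state, rates α = 0.2/ms (forward) and
β = 0.004/ms (backward). Steady state:
`O_ss = α C_A⁴ / (α C_A⁴ + β)` with `C_A` the per-subunit activated
probability of the Boltzmann steady state. The transient response to a
voltage step couples two FD substrates: `P_R` started from the holding
steady state (activated fraction `R_A(t)`), and `P_U` started from the
final steady state restricted to the activated region (`U_A(t)` — the
relaxation of subunits that begin activated). Channels exchanged with
the open state at time s carry four activated subunits that
subsequently relax like the U ensemble, giving

    A(t) = (1 − O_0) R_A(t)⁴ − ∫₀ᵗ F(s) U_A(t−s)⁴ ds,
    F = αA − βO,  dO/dt = F,

solved on the sampling clock (0.25 ms) with explicit Euler and a
left-rectangle convolution. The density of exchanged subunits (`P_E`)
is evolved alongside with a matching source term, so
`O(t) + (subunit mass) = 1` holds to round-off. Treating re-entrant
subunits as restarting the U clock is a closure: their true activated
profile is P_U(s) restricted to the activated region, which converges
to P_U's own initial condition at long times, so the approximation is
asymptotically exact and tightest exactly where the flux matters.

## What the synthetic data does and does not show

The toy bead structure (fixtures module) and the synthetic landscape
exercise every algorithmic path — slab electrostatics, sterics, FD
evolution, cooperativity — with realistic scales (kT barriers, Å
displacements, ms kinetics). They do not encode a real channel's
geometry: a quantitative landscape for a channel such as Kv7.1 requires
a structural model (homology-built coordinates with assigned charges)
that this package deliberately does not construct, so quantities that
depend on such a landscape (absolute activation-curve midpoint, exact
current time courses) are checked only for their qualitative structure (S-shape, sigmoidal onset,
voltage ordering of delays, direction of border-shift effects). Solver
accuracy bounds, conservation laws, collision statistics and the
mode-separation amplitudes are quantitative.

## Numerical choices and problem sizes

* Default grid 101 × 41; explicit FD at dt = 2.5 µs (≈ 23%/7% of the
  per-axis stability bounds at the default landscape).
* The 1000 ms activation transition (400,000 steps) runs in ≈ 40 s on
  one core; the test suite uses the half-resolution grid (51 × 21,
  dt = 10 µs) where a long integration is needed repeatedly.
* Collision statistics use 1e5-impact traces; post-impact samples carry
  ~10-impact memory, so distributional tests thin by 10.
* Trajectory/PDE agreement uses a 16 × 80,000-window stationary
  ensemble (1.28e6 windows of 25 µs) compared on 10 × 10-node blocks by
  total-variation distance.
* Ties and degeneracies: probability modes are grid argmax (unique on
  the default landscape); local minima require strict 8-neighbour
  descent; the activated border node (z = −2) counts as activated.

## Known limitations

* Overdamped dynamics only; no inertial or position-dependent friction,
  no hydrodynamic coupling between axes.
* The ω ≠ 0 corrections interpolate first derivatives bilinearly; the
  higher-order drift terms are face-averaged, adequate only for the
  small ω regime they are intended to probe.
* Electrolyte screening is the −1-reflection limit (ε → ∞) with a
  linear 3 Å charge taper, not a Poisson–Boltzmann solution.
* Single-channel stochastic gating beyond trajectory threshold
  crossings, ionic-current amplitudes and inactivation are out of
  scope.
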