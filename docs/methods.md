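# Models and methods

## The decision circuit

Every agent steers with a ring attractor: `Ns` neural groups at preferred
angles `alpha_i = 2*pi*(i-1)/Ns` coupled by the circulant kernel
`J_ij = cos(pi * (d(alpha_i, alpha_j)/pi)^nu)`, with `d` the circular
distance in `[0, pi]`.  We read the angular separation circularly even
though it could be read as a plain absolute difference; only the circular
reading keeps the ring symmetric for `nu != 1`.  With `nu = 1` excitation
and inhibition balance; with `nu < 1` coupling is locally more excitatory
and globally more inhibitory.

**Spin back-end.**  States are binary, dynamics are single-spin updates
against the Hamiltonian (self-pairs excluded — with `sigma_i^2 = 1` the
`i = j` term is a state-independent constant, and excluding it keeps the
O(1) cached energy difference exact).  A proposed flip is accepted with
certainty when it lowers the energy and with probability `exp(-beta*dH)`
when it raises it; `dH = 0` proposals are accepted (the continuous limit
of `exp(-beta*dH)`).  This chain has the Boltzmann distribution
`exp(-beta*H)` as its stationary law, which the test suite verifies
against exhaustive enumeration on small rings.  Each movement timestep
runs `T0 * Ns` update attempts ("T0 sweeps").  The per-attempt cost is
O(1) via a cached local field `m = J sigma`, updated in O(Ns) on accepted
flips; the inner loop is numba-compiled.

For `nu = 1` the pair energy is `-(1/Ns) |sum_i sigma_i e^{i alpha_i}|^2`
up to a constant, so the zero-input ground state is a contiguous half-ring
of active spins — the "bump" whose circular mean encodes the goal
direction.  Linearizing the mean-field self-consistency gives an ordering
transition at `beta = 1`: below it activity is uncorrelated and motion is
a slow random walk, far above it the bump freezes.

**Neural-field back-end.**  Real membrane potentials follow the
Euler-discretized field equation with tanh output of slope `beta`.  The
dynamics are deterministic; stochasticity enters only through the initial
potentials `u(0) ~ U(-u0, u0)` (default `u0 = 0.01`; `u = 0` is a
symmetric fixed point, so symmetry breaking needs a perturbation) and
through frame switching.  The two back-ends deliberately use different
sensory conventions, as printed in their definitions: the spin model's
Gaussian source carries the normalizing prefactor `1/sqrt(2*pi*sigma^2)`,
the field model's does not.

At sharp output (`beta ~ 1000`) the field dynamics are multistable: from
small random potentials most initializations develop a half-ring bump
(steady readout speed ~0.32 v0), but a minority converge to uniform
all-positive or all-negative states whose readout velocity is ~0.  The
bump-formation test therefore checks that a majority of seeded
initializations form a bump, and checks speed stabilization conditional on
bump formation.  At such `beta` the bump is also effectively pinned to the
neuron grid: sensory anisotropies smaller than the potential gap at the
bump edge cannot rotate it.

## The embodied loop

Agents live on a flat square torus of side `L` (minimum-image distances
and bearings; positions wrapped to `[0, L)`, displacement ties at exactly
`L/2` resolved to `+L/2`; world angle zero is +x, counterclockwise
positive).  Per synchronous timestep: frames are re-sampled (switch policy
only); sensory fields are computed from positions frozen at the start of
the step, each agent in its own frame; networks update (T0*Ns attempts /
one Euler step); velocities are read out; all agents move and wrap;
headings follow the direction of motion (retained at zero speed — the
agent has no new direction information); egocentric origins follow the new
headings; targets advance.

**Movement clock.**  Displacement per timestep is `v * move_dt` with
`move_dt = 1` for both back-ends; the field model's `dt` clocks only the
Euler integration of the potentials.  Tying displacement to `dt` instead
would rescale all field-model motion by 0.3 and push every kinetic
phenomenon (group formation, coalescence) beyond feasible step counts at
the reference parameters; one movement unit per network update matches the
arena-scale motion the model family is meant to produce.  The convention
is a config knob (`move_dt`) for users who want Euler-time-consistent
displacement.

**Frames and switching.**  With probability `omega` per agent per step the
frame is egocentric, else allocentric (i.i.d. Bernoulli).  On a change the
new frame's zero is the agent's current heading, and the ring state is
circularly shifted by `round((old_origin - new_origin) * Ns / (2*pi))`
indices so the bump keeps encoding the same world direction to within one
neuron spacing, `2*pi/Ns` — continuous re-anchoring; the agent never loses
its sense of direction at a switch.  Degenerate probabilities
(`omega = 0` or `1`) reproduce the pure-frame runs bit-exactly because
every stochastic role draws from its own seeded substream.

**Targets and social coupling.**  A target is a Gaussian source of
amplitude `h0` and width `sigma` at its bearing; a random-walk target
steps `+-v_t` per axis per timestep (position increments by default;
Gaussian increments and velocity-walks are config options).  Conspecifics
are targets of amplitude `h_t^s / N`, optionally with short-range
repulsion (amplitude `h_rep < 0` below the collision radius `r_c`) or
exponential distance decay (`exp(-d / (zeta*L))`).  Conspecific sources
share the global receptive width `sigma`; exactly coincident agents are
skipped for that step (bearing undefined).  Allocentric anchors default to
world +x for every agent (per-agent random anchors by flag; the anchoring
choice does not affect the collective dynamics).

## Key parameters (defaults)

| parameter | spin | field | meaning |
|---|---|---|---|
| `Ns` | 100 | 100 | neural groups on the ring |
| `beta` | 400 | 1000 | inverse noise (spin: temperature; field: tanh slope) |
| `nu` | 1.0 | 0.5 | connectivity exponent |
| `v0` | 10 | 0.05 | speed constant (distance/time unit) |
| `sigma` | 2*pi/Ns | 0.4 | receptive-field width (rad) |
| `h_b` | 0 | 0 | global inhibition |
| `L` | 1000 | 1000 | arena side |
| `T0` | 10 | — | equilibration sweeps per movement step |
| `dt` | — | 0.3 | Euler step of the field dynamics |
| `u0` | — | 0.01 | initial-potential amplitude |

`nu` is stated in the reference parameter lists only for the field model
(0.5); the spin back-end defaults to the balanced kernel `nu = 1`.

`T0` is genuinely open: it sets how far the network relaxes between
movement steps.  `T0 = 10` is the package default and is used for the
collective experiments.  Single-agent target seeking at `v0 = 10` needs
`T0 = 100`: with only 10 sweeps the bump cannot track the target bearing
as the agent moves, and nearly all seeking runs fail at every `beta`; with
100 sweeps decision times reproduce the expected pattern (finite, long
near the transition, minimized in the ordered phase, rising again deep in
it).

## Initial conditions

Positions uniform in `[0, L)^2`, headings uniform, spins i.i.d. `+-1`,
potentials i.i.d. `U(-u0, u0)` — all per-agent seeded substreams, all
overridable with explicit arrays.  Network state persists across movement
steps (resetting would destroy bump continuity).

## Reduced problem sizes in the acceptance suite

The reference experiments run 10,000–30,000 steps with N = 80–320 and
ensembles of 3–10 runs.  The end-to-end suite uses reduced sizes chosen to
keep the full run on one CPU while preserving each phenomenon:

- spin ego/allo contrast: N = 20, 6,000 steps, 5 seeds, `h_t^s = 0.1`,
  time averages over the last third;
- field ego/allo contrast: N = 20, 15,000 steps, 5 seeds,
  `h_t^s = 0.16`, `beta = 1000`, with agents initialized in a central
  100x100 patch.  At field-model speeds (~0.016/step) a population spread
  over the full arena needs far more steps than any reference run just to
  come within effective interaction range; the compact start skips that
  diffusive approach transient and measures what the check is about — the
  frame-dependence of the ordered state itself (allocentric: polarized
  flock; egocentric: disordered aggregate);
- aggregation: N = 20, `h_t^s = 0.4`, 3,000 steps;
- zero-recurrence control (`J = 0`, arena 100): N = 10, 90,000 steps —
  feedforward agents move slowly by construction, and coalescence
  accelerates only once the group compacts;
- target seeking: Ns = 100, `T0 = 100`, cap 4,000 steps, 20 runs per
  `beta` (5 vs 20), moving-target tracking at `v_t = 4` over 5 seeds.

## What the simulator does and does not emulate

All inputs are generated in silico; there is no external data.  The model
abstracts animals as point agents with instantaneous heading alignment,
a single ring network, global (or exponentially decaying) social
visibility, and no body collisions unless the repulsion variant is on.
Passing tests show the implemented circuit reproduces the model family's
phenomenology at reduced scale; they do not show anything about real
animals' circuits, nor about regimes outside the probed parameter ranges
(e.g. full-scale phase diagrams, which the sweep CLI enables but nothing
here certifies).

## Numerical notes

- Degenerate bearings (coincident points) are skipped as sources; a
  standalone `bearing()` call raises instead.
- k-nearest-neighbor ties in LO break toward the smaller agent index
  (stable argsort); relevant only for lattice fixtures.
- `dH = 0` spin flips are accepted with probability 1.
- Field potentials are validated finite after every step; divergence
  raises immediately (unreachable for `dt < 1` with bounded input).
- All randomness flows from one master seed through named substreams
  (per-agent init / updates / switching, per-target walks), so enabling a
  recording option or an unused stochastic component never changes a
  trajectory.

## Known limitations

- The spin back-end's per-step cost is `O(T0 * Ns)` attempts plus
  `O(Ns)` per accepted flip; full-scale sweeps (N = 320, 15,000 steps,
  grids over `beta x h_t^s`) are hours of CPU, not minutes.
- The field collective at sharp output depends strongly on kinetic
  transients (see the pinning note above); quantitative phase boundaries
  at reduced N need not match full-scale ones.
- No synaptic delay, no time-dependent connectivity, no heterogeneous
  per-agent parameters beyond the frame policy, 2-D only.
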