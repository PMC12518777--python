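"""Embodied simulation loop.

Agents live on a periodic square arena.  Each agent carries a ring-attractor
network (spin or neural-field back-end) whose receptive-field centers are
anchored either to the agent's own heading (egocentric frame) or to a fixed
world direction (allocentric frame); a switching policy re-draws the frame
each timestep with egocentric probability ``omega``.  Every other agent and
every environmental target is a Gaussian source on the ring, and the
network's population readout is the agent's velocity.

One synchronous timestep:

1. (switch policy) re-sample each agent's frame; on a change the new frame
   origin is the agent's current heading and the network state is
   re-anchored by a circular shift so the bump keeps encoding the same
   world direction.
2. Freeze all positions; compose each agent's sensory sources (conspecifics
   per the social-coupling variant, plus targets) and evaluate its sensory
   field in its own frame.
3. Update all networks (spin: T0*Ns stochastic update attempts; field: one
   Euler step).
4. Read out velocities.
5. Move all agents synchronously (one movement time unit per step; the
   field back-end's ``dt`` clocks only the Euler integration of the
   membrane potentials) and wrap positions.
6. Update headings to the direction of motion (unchanged at zero speed);
   egocentric origins follow the new headings.
7. Advance targets.

Randomness is organized as one master seed fanned out into independent
substreams per agent and per role (initialization, network updates, frame
switching) plus one per target, so that enabling or disabling one
stochastic component never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .field import FieldRingNetwork, field_sensory_field
from .geometry import PeriodicSpace, ring_angles, wrap_angle
from .spin import SpinRingNetwork, build_connectivity, receptive_centers, \
    spin_sensory_field

__all__ = [
    "Frame", "Agent", "TargetSpec", "SocialCoupling", "SimulationConfig",
    "TrajectoryRecord", "Simulation",
    "sample_frame_mode", "apply_frame_switch", "advance_target",
    "compose_sources", "simulation_step", "run_simulation",
    "social_amplitudes",
]

MODELS = ("spin", "field", "field_heading_only")
FRAME_POLICIES = ("ego", "allo", "switch")


# ---------------------------------------------------------------------------
# domain types

@dataclass
class Frame:
    """Reference frame: mode ('ego'|'allo') and world angle of its zero."""
    mode: str
    origin: float = 0.0


@dataclass
class TargetSpec:
    """An environmental target: a Gaussian source at a (possibly moving)
    world position.

    motion 'static' keeps the position fixed; 'random_walk' adds a per-axis
    increment of magnitude ``v_t`` each step (sign uniform on {-1,+1}; set
    ``increments='gaussian'`` for N(0, v_t) steps instead, or
    ``walk_on='velocity'`` to random-walk the target's velocity rather than
    its position).  ``sigma=None`` uses the simulation's global receptive
    width.
    """
    position: tuple
    amplitude: float
    motion: str = "static"
    v_t: float = 0.0
    sigma: Optional[float] = None
    walk_on: str = "position"
    increments: str = "binary"
    velocity: tuple = (0.0, 0.0)

    def validate(self):
        if self.motion not in ("static", "random_walk"):
            raise ValueError(f"unknown target motion {self.motion!r}")
        if self.walk_on not in ("position", "velocity"):
            raise ValueError(f"unknown walk_on {self.walk_on!r}")
        if self.increments not in ("binary", "gaussian"):
            raise ValueError(f"unknown increments {self.increments!r}")
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("target sigma must be positive")


@dataclass
class SocialCoupling:
    """How conspecifics enter each other's sensory fields.

    The control parameter is the *total* social attraction ``h_t_s``; each
    of the other N-1 agents contributes with per-conspecific amplitude
    ``h_t_s / N``.  Variants:

    - 'baseline': constant attraction.
    - 'short_range_repulsion': amplitude ``h_rep`` (< 0) below the collision
      radius ``r_c``, attraction above it.
    - 'distance_decay': attraction scaled by ``exp(-d / (zeta * L))``;
      ``zeta * L`` is the characteristic length of social attraction.
    """
    h_t_s: float = 0.0
    variant: str = "baseline"
    r_c: Optional[float] = None
    h_rep: Optional[float] = None
    zeta: Optional[float] = None

    def validate(self):
        if self.variant not in ("baseline", "short_range_repulsion",
                                "distance_decay"):
            raise ValueError(f"unknown coupling variant {self.variant!r}")
        if self.variant == "short_range_repulsion":
            if self.r_c is None or not self.r_c > 0:
                raise ValueError("short_range_repulsion requires r_c > 0")
            if self.h_rep is None or not self.h_rep < 0:
                raise ValueError("short_range_repulsion requires h_rep < 0")
        if self.variant == "distance_decay":
            if self.zeta is None or not self.zeta > 0:
                raise ValueError("distance_decay requires zeta > 0")


@dataclass
class Agent:
    """A single embodied agent (convenience container for the per-agent
    operations; full runs use the vectorized engine)."""
    id: int
    position: np.ndarray
    heading: float
    velocity: np.ndarray
    frame: Frame
    network: object  # SpinRingNetwork | FieldRingNetwork
    v0: float
    omega: float = 0.0


@dataclass
class SimulationConfig:
    """Full description of one run.  ``None`` fields take model-dependent
    defaults: spin -> (nu=1, v0=10, sigma=2*pi/Ns, beta=400); field ->
    (nu=0.5, v0=0.05, sigma=0.4, beta=1000)."""
    model: str = "spin"
    frame_policy: str = "allo"
    omega: float = 0.0
    N: int = 1
    Ns: int = 100
    beta: Optional[float] = None
    nu: Optional[float] = None
    h_b: float = 0.0
    v0: Optional[float] = None
    sigma: Optional[float] = None
    L: float = 1000.0
    steps: int = 1000
    dt: float = 0.3
    T0: int = 10
    u0: float = 0.01
    seed: int = 0
    coupling: SocialCoupling = dc_field(default_factory=SocialCoupling)
    targets: list = dc_field(default_factory=list)
    record_every: int = 1
    record_network_state: bool = False
    allo_origin: str = "zero"  # 'zero' | 'random' per agent
    zero_recurrence: bool = False
    stop_at_target_distance: Optional[float] = None
    move_dt: float = 1.0  # displacement time units per simulation step
    agent_seeds: Optional[list] = None  # explicit per-agent seed override
    # optional explicit initial conditions (arrays) for controlled runs
    initial_positions: Optional[np.ndarray] = None
    initial_headings: Optional[np.ndarray] = None
    initial_network_states: Optional[np.ndarray] = None

    def resolved(self) -> "SimulationConfig":
        """Fill model-dependent defaults and validate."""
        cfg = replace(self)
        is_spin = cfg.model == "spin"
        if cfg.nu is None:
            cfg.nu = 1.0 if is_spin else 0.5
        if cfg.v0 is None:
            cfg.v0 = 10.0 if is_spin else 0.05
        if cfg.sigma is None:
            cfg.sigma = 2.0 * np.pi / cfg.Ns if is_spin else 0.4
        if cfg.beta is None:
            cfg.beta = 400.0 if is_spin else 1000.0
        cfg.validate()
        return cfg

    def validate(self):
        checks = [
            (self.model in MODELS, f"model must be one of {MODELS}"),
            (self.frame_policy in FRAME_POLICIES,
             f"frame_policy must be one of {FRAME_POLICIES}"),
            (0.0 <= self.omega <= 1.0, "omega must lie in [0, 1]"),
            (self.N >= 1, "N must be >= 1"),
            (self.Ns >= 3, "Ns must be >= 3"),
            (self.beta is None or self.beta >= 0, "beta must be >= 0"),
            (self.nu is None or self.nu > 0, "nu must be > 0"),
            (self.v0 is None or self.v0 >= 0, "v0 must be >= 0"),
            (self.sigma is None or self.sigma > 0, "sigma must be > 0"),
            (self.L > 0, "L must be > 0"),
            (self.steps >= 0, "steps must be >= 0"),
            (self.dt > 0, "dt must be > 0"),
            (self.T0 >= 1, "T0 must be >= 1"),
            (self.u0 >= 0, "u0 must be >= 0"),
            (self.record_every >= 1, "record_every must be >= 1"),
            (self.move_dt > 0, "move_dt must be > 0"),
            (self.allo_origin in ("zero", "random"),
             "allo_origin must be 'zero' or 'random'"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")
        self.coupling.validate()
        for t in self.targets:
            t.validate()


# ---------------------------------------------------------------------------
# per-agent operations

def sample_frame_mode(omega: float, rng) -> str:
    """Draw this timestep's frame: 'ego' with probability omega."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    return "ego" if rng.random() < omega else "allo"


def frame_shift(old_origin: float, new_origin: float, n_s: int) -> int:
    """Circular index shift that re-anchors a ring state from a frame with
    zero at ``old_origin`` to one with zero at ``new_origin``.

    Activity at index i encodes world angle origin + 2*pi*i/Ns; shifting by
    ``round((old - new) * Ns / (2*pi))`` preserves the encoded world
    direction to within one neuron spacing (2*pi/Ns).
    """
    return int(np.round(wrap_angle(old_origin - new_origin) * n_s
                        / (2.0 * np.pi))) % n_s


def apply_frame_switch(agent: Agent, new_mode: str) -> Agent:
    """Switch an agent's reference frame, re-anchoring continuously.

    In either direction the new frame's zero is the agent's current heading
    (for ego this is forced by the definition of an egocentric frame; for
    allo it is the re-anchoring choice that keeps the encoded world
    direction continuous).  The network state is circularly shifted so that
    the same bump keeps driving motion in the same world direction.
    """
    if new_mode == agent.frame.mode:
        return agent
    old_origin = agent.frame.origin
    new_origin = float(agent.heading)
    shift = frame_shift(old_origin, new_origin, agent.network.n_s)
    if shift:
        agent.network.roll(shift)
    agent.frame = Frame(mode=new_mode, origin=new_origin)
    return agent


def advance_target(target: TargetSpec, rng, space: PeriodicSpace) -> TargetSpec:
    """Advance a target one step (returns a new TargetSpec; static targets
    are returned unchanged)."""
    if target.motion == "static" or target.v_t == 0.0:
        return target
    if target.increments == "binary":
        step = target.v_t * (2.0 * rng.integers(0, 2, size=2) - 1.0)
    else:
        step = rng.normal(0.0, target.v_t, size=2)
    pos = np.asarray(target.position, dtype=float)
    vel = np.asarray(target.velocity, dtype=float)
    if target.walk_on == "velocity":
        vel = vel + step
        pos = space.wrap(pos + vel)
    else:
        pos = space.wrap(pos + step)
    return replace(target, position=tuple(pos), velocity=tuple(vel))


def social_amplitudes(dist, coupling: SocialCoupling, n_agents: int,
                      L: float):
    """Per-conspecific source amplitude(s) as a function of distance."""
    base = coupling.h_t_s / n_agents
    dist = np.asarray(dist, dtype=float)
    if coupling.variant == "baseline":
        return np.full_like(dist, base)
    if coupling.variant == "short_range_repulsion":
        return np.where(dist < coupling.r_c, coupling.h_rep, base)
    return base * np.exp(-dist / (coupling.zeta * L))


def compose_sources(agent: Agent, others, targets, coupling: SocialCoupling,
                    space: PeriodicSpace):
    """List of ``(world bearing, amplitude)`` sources seen by one agent.

    One source per non-self conspecific (amplitude per the coupling
    variant, with the population size taken as len(others) + 1) and one per
    environmental target.  Conspecifics exactly coincident with the agent
    are skipped (their bearing is undefined).
    """
    n = len(others) + 1
    sources = []
    for other in others:
        if other.id == agent.id:
            continue
        d = float(space.distance(agent.position, other.position))
        if d == 0.0:
            continue
        amp = float(social_amplitudes(d, coupling, n, space.L))
        sources.append((float(space.bearing(agent.position, other.position)),
                        amp))
    for t in targets:
        d = float(space.distance(agent.position, np.asarray(t.position)))
        if d == 0.0:
            continue
        sources.append((float(space.bearing(agent.position,
                                            np.asarray(t.position))),
                        t.amplitude))
    return sources


# ---------------------------------------------------------------------------
# trajectory record

class TrajectoryRecord:
    """Recorded run: per recorded timestep, positions/velocities/headings/
    frame modes of all agents and target positions."""

    COLUMNS = ["t", "agent", "x", "y", "vx", "vy", "heading", "frame_mode"]

    def __init__(self, times, positions, velocities, headings, frame_ego,
                 target_positions=None, config=None, reached_step=None,
                 network_states=None):
        self.times = np.asarray(times)
        self.positions = np.asarray(positions)
        self.velocities = np.asarray(velocities)
        self.headings = np.asarray(headings)
        self.frame_ego = np.asarray(frame_ego)
        self.target_positions = None if target_positions is None \
            else np.asarray(target_positions)
        self.config = config
        self.reached_step = reached_step
        self.network_states = network_states

    @property
    def n_agents(self):
        return self.positions.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        t_rec, n = self.positions.shape[:2]
        mode = np.where(self.frame_ego, "ego", "allo")
        return pd.DataFrame({
            "t": np.repeat(self.times, n),
            "agent": np.tile(np.arange(n), t_rec),
            "x": self.positions[:, :, 0].ravel(),
            "y": self.positions[:, :, 1].ravel(),
            "vx": self.velocities[:, :, 0].ravel(),
            "vy": self.velocities[:, :, 1].ravel(),
            "heading": self.headings.ravel(),
            "frame_mode": mode.ravel(),
        })

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrajectoryRecord":
        df = df.sort_values(["t", "agent"])
        times = np.unique(df["t"].to_numpy())
        n = df["agent"].nunique()
        t_rec = len(times)

        def grid(col):
            return df[col].to_numpy().reshape(t_rec, n)

        positions = np.stack([grid("x"), grid("y")], axis=-1)
        velocities = np.stack([grid("vx"), grid("vy")], axis=-1)
        return cls(times, positions, velocities, grid("heading"),
                   grid("frame_mode") == "ego")

    @classmethod
    def from_csv(cls, path) -> "TrajectoryRecord":
        return cls.from_dataframe(pd.read_csv(path))


# ---------------------------------------------------------------------------
# vectorized engine

class Simulation:
    """Vectorized synchronous simulation of N agents.

    State is held in arrays (one row per agent); the spin back-end runs its
    Monte Carlo chains through the same compiled kernel as
    ``SpinRingNetwork.equilibrate``, with per-agent random substreams.
    """

    def __init__(self, config: SimulationConfig):
        cfg = config.resolved()
        self.cfg = cfg
        self.space = PeriodicSpace(cfg.L)
        self.alpha = ring_angles(cfg.Ns)
        if cfg.zero_recurrence:
            self.J = np.zeros((cfg.Ns, cfg.Ns))
        else:
            self.J = build_connectivity(cfg.Ns, cfg.nu)
        self._init_streams()
        self._init_state()
        self.t = 0

    # -- seeding --------------------------------------------------------

    def _init_streams(self):
        cfg = self.cfg
        root = np.random.SeedSequence(cfg.seed)
        targets_ss, agents_ss = root.spawn(2)
        self.target_rngs = [np.random.default_rng(s)
                            for s in targets_ss.spawn(max(1, len(cfg.targets)))]
        if cfg.agent_seeds is not None:
            if len(cfg.agent_seeds) != cfg.N:
                raise ValueError("agent_seeds must have one entry per agent")
            agent_sss = [np.random.SeedSequence(int(s))
                         for s in cfg.agent_seeds]
        else:
            agent_sss = agents_ss.spawn(cfg.N)
        self.agent_init_rngs = []
        self.agent_update_rngs = []
        self.agent_switch_rngs = []
        for a_ss in agent_sss:
            init_ss, upd_ss, sw_ss = a_ss.spawn(3)
            self.agent_init_rngs.append(np.random.default_rng(init_ss))
            self.agent_update_rngs.append(np.random.default_rng(upd_ss))
            self.agent_switch_rngs.append(np.random.default_rng(sw_ss))

    # -- initialization -------------------------------------------------

    def _init_state(self):
        cfg = self.cfg
        n, n_s = cfg.N, cfg.Ns
        pos = np.empty((n, 2))
        head = np.empty(n)
        allo_origin = np.zeros(n)
        if cfg.model == "spin":
            net = np.empty((n, n_s), dtype=np.int8)
        else:
            net = np.empty((n, n_s))
        for a, rng in enumerate(self.agent_init_rngs):
            pos[a] = rng.uniform(0.0, cfg.L, size=2)
            head[a] = rng.uniform(0.0, 2.0 * np.pi)
            if cfg.model == "spin":
                net[a] = 2 * rng.integers(0, 2, size=n_s) - 1
            else:
                net[a] = rng.uniform(-cfg.u0, cfg.u0, size=n_s)
            if cfg.allo_origin == "random":
                allo_origin[a] = rng.uniform(0.0, 2.0 * np.pi)
        if cfg.initial_positions is not None:
            pos = self.space.wrap(np.asarray(cfg.initial_positions,
                                             dtype=float).reshape(n, 2))
        if cfg.initial_headings is not None:
            head = wrap_angle(np.asarray(cfg.initial_headings,
                                         dtype=float).reshape(n))
        if cfg.initial_network_states is not None:
            net = np.asarray(cfg.initial_network_states).reshape(n, n_s)
            net = net.astype(np.int8) if cfg.model == "spin" \
                else net.astype(float)
        self.positions = pos
        self.headings = head
        self.velocities = np.zeros((n, 2))
        if cfg.frame_policy == "switch":
            ego = np.array([rng.random() < cfg.omega
                            for rng in self.agent_switch_rngs])
        else:
            ego = np.full(n, cfg.frame_policy == "ego")
        self.frame_ego = ego
        self.origins = np.where(ego, head, allo_origin)
        self._allo_origin_default = allo_origin
        if cfg.model == "spin":
            self.spin_states = net
            self.spin_m = net.astype(float) @ self.J.T
        else:
            self.u = net.astype(float)
        self.targets = list(cfg.targets)

    # -- one timestep ---------------------------------------------------

    def _centers(self):
        return wrap_angle(self.origins[:, None] + self.alpha[None, :])

    def _sensory_fields(self, centers):
        """(N, Ns) sensory field for every agent, frozen-world convention."""
        cfg = self.cfg
        n = cfg.N
        h = np.zeros((n, cfg.Ns))
        spin = cfg.model == "spin"
        social_active = cfg.coupling.h_t_s != 0.0 or \
            cfg.coupling.variant == "short_range_repulsion"
        if n > 1 and social_active:
            bear, dist = self.space.bearing_matrix(self.positions)
            amp = social_amplitudes(dist, cfg.coupling, n, cfg.L)
            # self-pairs and coincident pairs carry NaN bearings: drop them
            valid = ~np.isnan(bear)
            np.fill_diagonal(valid, False)
            amp = np.where(valid, amp, 0.0)
            bear = np.where(valid, bear, 0.0)
            ang = np.abs(wrap_angle(centers[:, None, :] - bear[:, :, None]))
            ang = np.minimum(ang, 2.0 * np.pi - ang)
            g = np.exp(-(ang**2) / (2.0 * cfg.sigma**2))
            h += np.einsum("ij,ijk->ik", amp, g)
            if spin:
                h *= 1.0 / np.sqrt(2.0 * np.pi * cfg.sigma**2)
        for tgt in self.targets:
            tpos = np.asarray(tgt.position, dtype=float)
            disp = self.space.displacement(self.positions, tpos[None, :])
            dist = np.linalg.norm(disp, axis=-1)
            sig = cfg.sigma if tgt.sigma is None else tgt.sigma
            with np.errstate(invalid="ignore"):
                bear = wrap_angle(np.arctan2(disp[:, 1], disp[:, 0]))
            ang = np.abs(wrap_angle(centers - bear[:, None]))
            ang = np.minimum(ang, 2.0 * np.pi - ang)
            g = tgt.amplitude * np.exp(-(ang**2) / (2.0 * sig**2))
            if spin:
                g *= 1.0 / np.sqrt(2.0 * np.pi * sig**2)
            g[dist == 0.0] = 0.0  # agent sitting exactly on the target
            h += g
        return h

    def _apply_switches(self):
        cfg = self.cfg
        new_ego = np.array([rng.random() < cfg.omega
                            for rng in self.agent_switch_rngs])
        changed = np.nonzero(new_ego != self.frame_ego)[0]
        for a in changed:
            new_origin = self.headings[a]
            shift = frame_shift(self.origins[a], new_origin, cfg.Ns)
            if shift:
                if cfg.model == "spin":
                    self.spin_states[a] = np.roll(self.spin_states[a], shift)
                    self.spin_m[a] = self.J @ self.spin_states[a].astype(float)
                else:
                    self.u[a] = np.roll(self.u[a], shift)
            self.origins[a] = new_origin
        self.frame_ego = new_ego

    def step(self):
        cfg = self.cfg
        n, n_s = cfg.N, cfg.Ns
        if cfg.frame_policy == "switch":
            self._apply_switches()
        centers = self._centers()
        h = self._sensory_fields(centers)
        if cfg.model == "spin":
            attempts = cfg.T0 * n_s
            idx = np.empty((n, attempts), dtype=np.int64)
            u = np.empty((n, attempts))
            for a, rng in enumerate(self.agent_update_rngs):
                idx[a] = rng.integers(0, n_s, size=attempts)
                u[a] = rng.random(attempts)
            _kernels.metropolis_run_multi(self.spin_states, self.spin_m,
                                          self.J, cfg.beta, h, cfg.h_b,
                                          idx, u)
            w = (self.spin_states == 1).astype(float)
        else:
            out = np.tanh(cfg.beta * self.u)
            self.u = self.u + cfg.dt * (-self.u + out @ self.J.T / n_s
                                        - cfg.h_b + h)
            if not np.all(np.isfinite(self.u)):
                raise FloatingPointError("neural-field potentials diverged")
            w = np.maximum(0.0, np.tanh(cfg.beta * self.u))
        vx = np.sum(w * np.cos(centers), axis=1)
        vy = np.sum(w * np.sin(centers), axis=1)
        if cfg.model == "field_heading_only":
            nonzero = (vx != 0.0) | (vy != 0.0)
            new_head = np.where(nonzero,
                                wrap_angle(np.arctan2(vy, vx)),
                                self.headings)
            self.headings = new_head
            self.velocities = cfg.v0 * np.stack(
                [np.cos(new_head), np.sin(new_head)], axis=-1)
        else:
            self.velocities = (cfg.v0 / n_s) * np.stack([vx, vy], axis=-1)
        self.positions = self.space.wrap(self.positions
                                         + self.velocities * cfg.move_dt)
        if cfg.model != "field_heading_only":
            speed = np.linalg.norm(self.velocities, axis=-1)
            moving = speed > 0.0
            self.headings = np.where(
                moving,
                wrap_angle(np.arctan2(self.velocities[:, 1],
                                      self.velocities[:, 0])),
                self.headings)
        self.origins = np.where(self.frame_ego, self.headings, self.origins)
        self.targets = [advance_target(t, rng, self.space)
                        for t, rng in zip(self.targets, self.target_rngs)]
        self.t += 1

    # -- full run -------------------------------------------------------

    def run(self) -> TrajectoryRecord:
        cfg = self.cfg
        rec_times, rec_pos, rec_vel, rec_head, rec_ego, rec_tpos = \
            [], [], [], [], [], []
        rec_net = [] if cfg.record_network_state else None

        def record():
            rec_times.append(self.t)
            rec_pos.append(self.positions.copy())
            rec_vel.append(self.velocities.copy())
            rec_head.append(self.headings.copy())
            rec_ego.append(self.frame_ego.copy())
            rec_tpos.append(np.array([t.position for t in self.targets])
                            if self.targets else np.zeros((0, 2)))
            if rec_net is not None:
                state = self.spin_states if cfg.model == "spin" else self.u
                rec_net.append(state.copy())

        record()
        reached = None
        for k in range(1, cfg.steps + 1):
            self.step()
            if k % cfg.record_every == 0 or k == cfg.steps:
                record()
            if cfg.stop_at_target_distance is not None and self.targets:
                tpos = np.asarray(self.targets[0].position)
                d = float(self.space.distance(self.positions[0], tpos))
                if d <= cfg.stop_at_target_distance:
                    reached = k
                    if k % cfg.record_every != 0 and k != cfg.steps:
                        record()
                    break
        return TrajectoryRecord(
            rec_times, rec_pos, rec_vel, rec_head, rec_ego,
            target_positions=np.array(rec_tpos), config=cfg,
            reached_step=reached,
            network_states=None if rec_net is None else np.array(rec_net))


def simulation_step(sim: Simulation) -> Simulation:
    """Advance a simulation by one synchronous timestep (in place)."""
    sim.step()
    return sim


def run_simulation(config: SimulationConfig) -> TrajectoryRecord:
    """Initialize from ``config.seed`` and run ``config.steps`` timesteps.

    Fully reproducible: two runs with equal configs produce bit-identical
    trajectories.
    """
    return Simulation(config).run()
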