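"""Modified social force model in a bounded square domain.

Newtonian pedestrian dynamics: each agent of mass ``m_i`` obeys

    m_i dv_i/dt = f_self + f_soc + f_obs

where ``f_self = m_i (v_d e_d - v) / tau`` relaxes the velocity towards
the desired one, ``f_soc`` sums anisotropic exponential repulsions from
every other agent closer than the agent's desired interpersonal distance
``d_soc``, and ``f_obs`` repels from the four domain walls.  The social
term carries the interpersonal-stress modification: its support is cut
off at ``d_soc`` exactly, so the repulsion jumps to ``A_soc`` at the
desired-distance shell and decays (length ``beta_soc``) as the intruder
penetrates further, weighted by an angular factor
``gamma + (1 - gamma)(1 + cos phi)/2`` that discounts interactions behind
the agent's back.

Integration is semi-implicit Euler (velocity first, then position); a
rerouting rule redraws the desired direction of 30% of the crowd every
10 s, and agents reaching a wall have direction and normal velocity
reflected inward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactDefinition, DwellState, update_dwell
from .population import (
    ForceParams,
    LocationConfig,
    PedestrianProfile,
    sample_population,
)

__all__ = [
    "Domain",
    "Wall",
    "ForceParams",
    "SimulationState",
    "SimulationError",
    "SimulationResult",
    "self_force",
    "social_force_pair",
    "social_forces",
    "social_forces_brute",
    "obstacle_force",
    "wall_forces",
    "step",
    "reroute",
    "boundary_rule",
    "initial_positions",
    "run_simulation",
]

#: Below this center separation a pair counts as degenerately overlapping.
OVERLAP_EPS = 1e-6


class SimulationError(RuntimeError):
    """Non-finite forces or a failed initial placement."""


@dataclass(frozen=True)
class Wall:
    """An axis-aligned boundary: ``axis`` (0=x, 1=y), coordinate, inward sign."""

    axis: int
    coord: float
    inward: float  # +1 if the domain lies at larger coordinates

    def distance(self, pos: np.ndarray) -> float:
        """Signed distance from a point to the wall (negative = outside)."""
        return float((np.asarray(pos)[..., self.axis] - self.coord) * self.inward)


@dataclass(frozen=True)
class Domain:
    """Square walkable area [0, side] x [0, side] bounded by four walls."""

    side: float = 50.0

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("domain side must be positive")

    @property
    def walls(self) -> tuple[Wall, ...]:
        s = self.side
        return (
            Wall(0, 0.0, 1.0),
            Wall(0, s, -1.0),
            Wall(1, 0.0, 1.0),
            Wall(1, s, -1.0),
        )


@dataclass
class SimulationState:
    """Dynamic state of the crowd at time ``t``."""

    t: float
    positions: np.ndarray  # (n, 2) m
    velocities: np.ndarray  # (n, 2) m/s
    desired_dirs: np.ndarray  # (n, 2) unit vectors
    profiles: list[PedestrianProfile]

    # cached per-agent parameter arrays
    mass: np.ndarray = field(init=False)
    v_d: np.ndarray = field(init=False)
    d_soc: np.ndarray = field(init=False)
    tau: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.profiles)
        for arr in (self.positions, self.velocities, self.desired_dirs):
            if arr.shape != (n, 2):
                raise ValueError("state arrays must be (n, 2) and match the profile list")
        self.mass = np.array([p.mass for p in self.profiles])
        self.v_d = np.array([p.desired_speed for p in self.profiles])
        self.d_soc = np.array([p.desired_distance for p in self.profiles])
        self.tau = np.array([p.relaxation_time for p in self.profiles])

    @property
    def n(self) -> int:
        return len(self.profiles)


# ---------------------------------------------------------------------------
# Force laws
# ---------------------------------------------------------------------------


def self_force(profile: PedestrianProfile, v: np.ndarray, e_d: np.ndarray) -> np.ndarray:
    """Self-driven force m (v_d e_d - v) / tau."""
    if profile.relaxation_time <= 0:
        raise ValueError("relaxation time must be positive")
    return profile.mass * (profile.desired_speed * np.asarray(e_d) - np.asarray(v)) / profile.relaxation_time


def _overlap_direction(i: int, j: int) -> np.ndarray:
    """Deterministic pseudo-random unit vector keyed on the pair ids.

    Used when two centers coincide (d_ij below OVERLAP_EPS) so the force
    stays finite and runs remain reproducible.
    """
    h = math.sin(i * 12.9898 + j * 78.233) * 43758.5453123
    angle = 2.0 * math.pi * (h - math.floor(h))
    return np.array([math.cos(angle), math.sin(angle)])


def social_force_pair(
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    desired_dir_i: np.ndarray,
    d_soc_i: float,
    params: ForceParams,
    pair_ids: tuple[int, int] = (0, 1),
) -> np.ndarray:
    """Social psychological force exerted by agent j on agent i.

    Zero outside the support ``d_ij < d_soc_i``.  Inside, the magnitude is
    ``A_soc exp((d_ij - d_soc)/beta_soc)`` times the angular factor, acting
    along ``e_ij``, the unit vector from j toward i (repulsion).  ``phi`` is
    the angle between i's desired direction and the direction from i to j.
    """
    diff = np.asarray(pos_i, dtype=float) - np.asarray(pos_j, dtype=float)
    d = float(np.hypot(*diff))
    if d >= d_soc_i:
        return np.zeros(2)
    if d < OVERLAP_EPS:
        return params.a_soc * _overlap_direction(*pair_ids)
    e_ij = diff / d
    cos_phi = float(np.dot(np.asarray(desired_dir_i), -e_ij))
    w = params.gamma + (1.0 - params.gamma) * (1.0 + cos_phi) / 2.0
    mag = params.a_soc * math.exp((d - d_soc_i) / params.beta_soc) * w
    return mag * e_ij


def social_forces_brute(state: SimulationState, params: ForceParams) -> np.ndarray:
    """O(n^2) pairwise loop over :func:`social_force_pair` (oracle path)."""
    n = state.n
    out = np.zeros((n, 2))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i] += social_force_pair(
                    state.positions[i],
                    state.positions[j],
                    state.desired_dirs[i],
                    state.d_soc[i],
                    params,
                    pair_ids=(i, j),
                )
    return out


def social_forces(state: SimulationState, params: ForceParams) -> np.ndarray:
    """Vectorized total social force on every agent."""
    x = state.positions
    n = state.n
    diff = x[:, None, :] - x[None, :, :]  # diff[i, j] points j -> i
    d = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(d, np.inf)
    support = d < state.d_soc[:, None]
    regular = support & (d >= OVERLAP_EPS)

    out = np.zeros((n, 2))
    if np.any(regular):
        ii, jj = np.nonzero(regular)
        dd = d[ii, jj]
        e_ij = diff[ii, jj] / dd[:, None]
        cos_phi = -np.einsum("ij,ij->i", state.desired_dirs[ii], e_ij)
        w = params.gamma + (1.0 - params.gamma) * (1.0 + cos_phi) / 2.0
        mag = params.a_soc * np.exp((dd - state.d_soc[ii]) / params.beta_soc) * w
        np.add.at(out, ii, mag[:, None] * e_ij)

    overlap = support & (d < OVERLAP_EPS)
    if np.any(overlap):
        for i, j in zip(*np.nonzero(overlap)):
            out[i] += params.a_soc * _overlap_direction(int(i), int(j))
    return out


def obstacle_force(pos: np.ndarray, wall: Wall, params: ForceParams) -> np.ndarray:
    """Wall repulsion along the inward normal, zero beyond ``d_obs``."""
    d_iw = wall.distance(pos)
    if d_iw >= params.d_obs:
        return np.zeros(2)
    mag = params.a_obs * math.exp((d_iw - params.d_obs) / params.beta_obs)
    out = np.zeros(2)
    out[wall.axis] = mag * wall.inward
    return out


def wall_forces(state: SimulationState, params: ForceParams, domain: Domain) -> np.ndarray:
    """Vectorized total wall force on every agent."""
    x = state.positions
    out = np.zeros_like(x)
    for wall in domain.walls:
        d_iw = (x[:, wall.axis] - wall.coord) * wall.inward
        close = d_iw < params.d_obs
        if np.any(close):
            mag = params.a_obs * np.exp((d_iw[close] - params.d_obs) / params.beta_obs)
            out[close, wall.axis] += mag * wall.inward
    return out


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------


def step(
    state: SimulationState,
    dt: float,
    params: ForceParams,
    domain: Domain,
) -> SimulationState:
    """Advance the crowd by one semi-implicit Euler step.

    Velocity is updated from the summed forces first, then position from
    the new velocity; the boundary rule runs last so no agent ends the
    step outside the domain.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    f = (
        state.mass[:, None] * (state.v_d[:, None] * state.desired_dirs - state.velocities)
        / state.tau[:, None]
    )
    f = f + social_forces(state, params) + wall_forces(state, params, domain)
    if not np.all(np.isfinite(f)):
        bad = int(np.nonzero(~np.isfinite(f).all(axis=1))[0][0])
        raise SimulationError(f"non-finite force on agent {bad} at t={state.t:.3f} s")
    v = state.velocities + f / state.mass[:, None] * dt
    x = state.positions + v * dt
    new = SimulationState(
        t=state.t + dt,
        positions=x,
        velocities=v,
        desired_dirs=state.desired_dirs.copy(),
        profiles=state.profiles,
    )
    return boundary_rule(new, domain)


def boundary_rule(state: SimulationState, domain: Domain) -> SimulationState:
    """Reflect agents at or beyond a wall back into the domain.

    The desired direction and the normal velocity component are turned
    inward and the position is clamped inside; interior agents are
    untouched.  A corner hit composes both reflections.
    """
    x, v, e = state.positions, state.velocities, state.desired_dirs
    s = domain.side
    for axis in (0, 1):
        low = x[:, axis] <= 0.0
        high = x[:, axis] >= s
        if np.any(low):
            e[low, axis] = np.abs(e[low, axis])
            v[low, axis] = np.abs(v[low, axis])
            x[low, axis] = 0.0
        if np.any(high):
            e[high, axis] = -np.abs(e[high, axis])
            v[high, axis] = -np.abs(v[high, axis])
            x[high, axis] = s
    return state


def _reroute_count(n: int, fraction: float) -> int:
    """Nearest-integer count of agents to reroute; half-ties round up."""
    return int(math.floor(fraction * n + 0.5))


def reroute(
    state: SimulationState,
    rng: np.random.Generator,
    fraction: float = 0.3,
) -> SimulationState:
    """Redraw the desired direction of a random ``fraction`` of the crowd.

    The subset is uniform without replacement; new directions are uniform
    on the unit circle.  Positions and velocities are untouched.
    """
    k = _reroute_count(state.n, fraction)
    if k == 0:
        return state
    idx = rng.choice(state.n, size=k, replace=False)
    angles = rng.uniform(0.0, 2.0 * math.pi, size=k)
    state.desired_dirs[idx, 0] = np.cos(angles)
    state.desired_dirs[idx, 1] = np.sin(angles)
    return state


def initial_positions(
    n: int,
    domain: Domain,
    rng: np.random.Generator,
    min_separation: float = 0.4,
    max_tries: int = 2000,
) -> np.ndarray:
    """Uniform random non-overlapping placement (rejection sampling).

    Agents are placed one at a time, resampling any draw closer than
    ``min_separation`` (twice the body radius by default) to an agent
    already placed.
    """
    pos = np.empty((n, 2))
    for i in range(n):
        for _ in range(max_tries):
            cand = rng.uniform(0.0, domain.side, size=2)
            if i == 0 or np.min(np.linalg.norm(pos[:i] - cand, axis=1)) >= min_separation:
                pos[i] = cand
                break
        else:
            raise SimulationError(
                f"could not place agent {i} of {n}: density too high for "
                f"min separation {min_separation} m"
            )
    return pos


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Outcome of one simulation run."""

    profiles: list[PedestrianProfile]
    contact_pairs: list[tuple[int, int]]
    state: SimulationState
    n_steps: int
    dt: float
    duration: float
    trajectory: np.ndarray | None = None  # (frames, n, 4): x, y, vx, vy
    trajectory_times: np.ndarray | None = None

    @property
    def mean_contacts_per_person(self) -> float:
        n = len(self.profiles)
        return 2.0 * len(self.contact_pairs) / n if n else 0.0

    def trajectory_table(self):
        """Recorded frames as a tidy (t, id, x, y, vx, vy) table."""
        import pandas as pd

        if self.trajectory is None:
            raise ValueError("run with record_every > 0 to record a trajectory")
        frames, n, _ = self.trajectory.shape
        return pd.DataFrame(
            {
                "t": np.repeat(self.trajectory_times, n),
                "id": np.tile(np.arange(n), frames),
                "x": self.trajectory[:, :, 0].ravel(),
                "y": self.trajectory[:, :, 1].ravel(),
                "vx": self.trajectory[:, :, 2].ravel(),
                "vy": self.trajectory[:, :, 3].ravel(),
            }
        )


def _draw_reroutes(
    rng: np.random.Generator, n: int, n_events: int, fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-draw reroute subsets and angles for every 10-s event."""
    k = _reroute_count(n, fraction)
    idx = np.empty((n_events, k), dtype=np.int64)
    ang = np.empty((n_events, k))
    for ev in range(n_events):
        idx[ev] = rng.choice(n, size=k, replace=False)
        ang[ev] = rng.uniform(0.0, 2.0 * math.pi, size=k)
    return idx, ang


def run_simulation(
    config: LocationConfig | None = None,
    n: int = 300,
    duration: float = 600.0,
    dt: float = 0.02,
    seed: int | np.random.Generator = 0,
    profiles: list[PedestrianProfile] | None = None,
    force: ForceParams | None = None,
    contact_def: ContactDefinition | None = None,
    domain: Domain | None = None,
    reroute_every: float = 10.0,
    reroute_fraction: float = 0.3,
    engine: str = "auto",
    record_every: int = 0,
) -> SimulationResult:
    """Run one activity-area simulation and collect contacts.

    Agents start uniformly placed (non-overlapping), at rest, with random
    desired directions; every ``reroute_every`` seconds a
    ``reroute_fraction`` subset redraws its direction.  Positions feed the
    dwell-time contact detector each step.  Runs are deterministic given
    the seed.  ``engine`` selects the vectorized numpy reference path
    ("numpy"), the compiled grid-accelerated kernel ("numba"), or the
    kernel when available ("auto"); both paths consume the same
    pre-drawn random streams.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    # one generator drives sampling, placement, initial directions and
    # reroutes so a seed fully determines the run
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if profiles is None:
        if config is None:
            raise ValueError("either a location config or explicit profiles are required")
        profiles = sample_population(config, n, rng)
    n = len(profiles)
    force = force or (config.force if config is not None else ForceParams())
    contact_def = contact_def or ContactDefinition()
    domain = domain or Domain()

    radius = max(p.radius for p in profiles)
    x0 = initial_positions(n, domain, rng, min_separation=2.0 * radius)
    angles = rng.uniform(0.0, 2.0 * math.pi, size=n)
    e0 = np.column_stack([np.cos(angles), np.sin(angles)])

    n_steps = int(round(duration / dt))
    reroute_steps = max(1, int(round(reroute_every / dt)))
    n_events = (n_steps - 1) // reroute_steps if n_steps > 0 else 0
    re_idx, re_ang = _draw_reroutes(rng, n, n_events, reroute_fraction)

    if engine == "auto":
        try:
            from . import _kernel  # noqa: F401

            engine = "numba"
        except ImportError:
            engine = "numpy"

    if engine == "numba":
        from . import _kernel

        return _kernel.run_compiled(
            profiles, x0, e0, force, contact_def, domain, dt, n_steps,
            reroute_steps, re_idx, re_ang, record_every, duration,
        )
    if engine != "numpy":
        raise ValueError(f"unknown engine {engine!r}")

    state = SimulationState(
        t=0.0, positions=x0, velocities=np.zeros((n, 2)), desired_dirs=e0, profiles=profiles
    )
    dwell = DwellState(n)
    contact_pairs: list[tuple[int, int]] = []
    frames, times = [], []
    if record_every:
        frames.append(np.hstack([state.positions, state.velocities]))
        times.append(0.0)
    event = 0
    for s in range(1, n_steps + 1):
        if (s - 1) % reroute_steps == 0 and s > 1 and event < n_events:
            idx = re_idx[event]
            state.desired_dirs[idx, 0] = np.cos(re_ang[event])
            state.desired_dirs[idx, 1] = np.sin(re_ang[event])
            event += 1
        # dwell observes the pre-step positions — the ones this step's
        # forces see — one observation per step
        contact_pairs.extend(update_dwell(state.positions, profiles, dt, contact_def, dwell))
        state = step(state, dt, force, domain)
        if record_every and s % record_every == 0:
            frames.append(np.hstack([state.positions, state.velocities]))
            times.append(state.t)
    return SimulationResult(
        profiles=profiles,
        contact_pairs=contact_pairs,
        state=state,
        n_steps=n_steps,
        dt=dt,
        duration=duration,
        trajectory=np.array(frames) if record_every else None,
        trajectory_times=np.array(times) if record_every else None,
    )
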