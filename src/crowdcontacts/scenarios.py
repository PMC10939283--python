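"""Scenario engines: baseline, social distancing, panic, and sweeps.

Scenarios are counterfactuals applied on top of the baseline population
of each activity area: social distancing forces every agent's desired
interpersonal distance to a homogeneous 2 m, panic raises every desired
speed to 2.5 m/s while weakening the social repulsion amplitude.
Scenario runs reuse the baseline's sampled population and simulation
random streams (common random numbers), so differences between matched
runs are pure treatment effects.

Sensitivity sweeps run homogeneous crowds (every agent shares the swept
value and all other parameters) over a grid of desired speeds or body
masses and report mean contacts per person with replicate spread; the
threshold velocity is the grid argmax of the speed sweep — the speed
beyond which sustained 30-s proximity spells become too rare and the
contact count starts to fall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .contacts import ContactDefinition, ContactMatrix, build_contact_matrix, duration_scaling
from .dynamics import Domain, run_simulation
from .population import (
    ForceParams,
    LocationConfig,
    age_bins,
    override_population,
    PedestrianProfile,
    sample_population,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "SweepResult",
    "run_scenario",
    "reduction",
    "velocity_sweep",
    "weight_sweep",
    "find_threshold_velocity",
]

#: Grid spacing shared by the default sweep grids, m/s.
GRID_STEP = 5.0 / 12.0

#: Default desired-speed grid 0.5 .. 5.92 m/s (d_soc = 1.22 m sweep).
DEFAULT_VELOCITY_GRID = tuple(0.5 + k * GRID_STEP for k in range(14))

#: Shorter grid 0.5 .. 4.25 m/s used for the d_soc = 0.2 m sweep.
SHORT_VELOCITY_GRID = tuple(0.5 + k * GRID_STEP for k in range(10))

#: Default body-mass grid, kg.
DEFAULT_MASS_GRID = tuple(float(m) for m in range(30, 131, 20))


@dataclass(frozen=True)
class ScenarioSpec:
    """A counterfactual intervention over the baseline crowd.

    ``kind`` is one of baseline / distancing / panic / custom.  Distancing
    defaults to a homogeneous desired distance of 2 m; panic to a
    homogeneous desired speed of 2.5 m/s with the social-repulsion
    amplitude halved.
    """

    kind: str = "baseline"
    d_soc: float | None = None
    v_d: float | None = None
    a_soc_multiplier: float = 1.0
    replicates: int = 10

    @classmethod
    def baseline(cls, replicates: int = 10) -> "ScenarioSpec":
        return cls("baseline", replicates=replicates)

    @classmethod
    def distancing(cls, d_soc: float = 2.0, replicates: int = 10) -> "ScenarioSpec":
        return cls("distancing", d_soc=d_soc, replicates=replicates)

    @classmethod
    def panic(
        cls, v_d: float = 2.5, a_soc_multiplier: float = 0.5, replicates: int = 10
    ) -> "ScenarioSpec":
        if not a_soc_multiplier < 1.0:
            warnings.warn("panic normally weakens the repulsion (multiplier < 1)")
        return cls("panic", v_d=v_d, a_soc_multiplier=a_soc_multiplier, replicates=replicates)

    def __post_init__(self) -> None:
        if self.kind not in ("baseline", "distancing", "panic", "custom"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.replicates < 1:
            raise ValueError("at least one replicate is required")


@dataclass
class ScenarioResult:
    """Per-area and overall contact statistics for one scenario."""

    spec: ScenarioSpec
    per_location: dict[str, list[ContactMatrix]]  # replicate matrices, scaled
    params: dict = field(default_factory=dict)

    @property
    def location_m(self) -> dict[str, np.ndarray]:
        """Replicate-averaged per-capita matrix per activity area."""
        return {
            name: np.mean([cm.m for cm in reps], axis=0)
            for name, reps in self.per_location.items()
        }

    @property
    def overall_m(self) -> np.ndarray:
        """Unweighted average of the per-area per-capita matrices."""
        return np.mean(list(self.location_m.values()), axis=0)

    def mean_contacts(self, location: str | None = None) -> float:
        """Replicate-averaged mean contacts per person (one area or overall)."""
        if location is not None:
            reps = self.per_location[location]
            return float(np.mean([cm.mean_contacts_per_person for cm in reps]))
        return float(np.mean([self.mean_contacts(loc) for loc in self.per_location]))


def _scenario_profiles(
    spec: ScenarioSpec, config: LocationConfig, n: int, rng: np.random.Generator
) -> list[PedestrianProfile]:
    profiles = sample_population(config, n, rng)
    if spec.d_soc is not None and spec.d_soc not in config.zone:
        warnings.warn(
            f"{config.name}: override d_soc={spec.d_soc} m lies outside the "
            f"{config.zone.name} zone; the counterfactual override wins"
        )
    return override_population(profiles, desired_distance=spec.d_soc, desired_speed=spec.v_d)


def run_scenario(
    spec: ScenarioSpec,
    configs: dict[str, LocationConfig],
    n: int = 300,
    sim_duration: float = 600.0,
    dt: float = 0.02,
    seed: int = 0,
    scale_to_activity: bool = True,
    domain: Domain | None = None,
    contact_def: ContactDefinition | None = None,
) -> ScenarioResult:
    """Run one scenario over every activity area with matched random streams.

    Population sampling and the simulation noise are seeded per
    (area, replicate) only, so two scenarios run with the same master seed
    share their baseline crowds and differ only through the overrides.
    Simulated windows shorter than the activity duration are linearly
    extrapolated and flagged.
    """
    per_location: dict[str, list[ContactMatrix]] = {}
    for li, (name, config) in enumerate(configs.items()):
        force = config.force
        if spec.a_soc_multiplier != 1.0:
            force = replace(force, a_soc=force.a_soc * spec.a_soc_multiplier)
        reps = []
        for r in range(spec.replicates):
            pop_rng = np.random.default_rng(np.random.SeedSequence([seed, li, r, 0]))
            sim_rng = np.random.default_rng(np.random.SeedSequence([seed, li, r, 1]))
            profiles = _scenario_profiles(spec, config, n, pop_rng)
            res = run_simulation(
                profiles=profiles,
                duration=sim_duration,
                dt=dt,
                seed=sim_rng,
                force=force,
                contact_def=contact_def,
                domain=domain,
            )
            cm = build_contact_matrix(res.contact_pairs, profiles)
            if scale_to_activity:
                cm = duration_scaling(cm, sim_duration, config.duration_h * 3600.0)
            reps.append(cm)
        per_location[name] = reps
    return ScenarioResult(
        spec=spec,
        per_location=per_location,
        params={
            "n": n,
            "sim_duration": sim_duration,
            "dt": dt,
            "seed": seed,
            "scale_to_activity": scale_to_activity,
        },
    )


def reduction(baseline_mean: float, scenario_mean: float) -> float:
    """Fractional decrease 1 - scenario/baseline (negative for an increase)."""
    if baseline_mean <= 0:
        raise ValueError("reduction is undefined for a non-positive baseline")
    return 1.0 - scenario_mean / baseline_mean


@dataclass
class SweepResult:
    """Mean contacts per person over a parameter grid, with replicate SD."""

    parameter: str
    grid: np.ndarray
    means: np.ndarray  # per grid value, averaged over replicates
    sds: np.ndarray  # replicate SD (ddof=1) per grid value
    per_replicate: np.ndarray  # (grid, replicates)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if len(self.grid) and np.any(np.diff(self.grid) <= 0):
            raise ValueError("sweep grid must be strictly increasing")


def _homogeneous_profiles(
    n: int, v_d: float, d_soc: float, mass: float, radius: float, tau: float
) -> list[PedestrianProfile]:
    bin0 = age_bins()[0]
    return [
        PedestrianProfile(
            id=i, age_bin=bin0, mass=mass, radius=radius,
            desired_speed=v_d, desired_distance=d_soc, relaxation_time=tau,
        )
        for i in range(n)
    ]


def _sweep(
    parameter: str,
    grid,
    profile_factory,
    force: ForceParams,
    replicates: int,
    seed: int,
    n: int,
    duration: float,
    dt: float,
    domain: Domain | None,
    contact_def: ContactDefinition | None,
    params: dict,
) -> SweepResult:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sweep grid is empty")
    per_rep = np.zeros((grid.size, replicates))
    for gi, value in enumerate(grid):
        profiles = profile_factory(float(value))
        for r in range(replicates):
            # same replicate stream across grid values: common random numbers
            sim_rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
            res = run_simulation(
                profiles=profiles,
                duration=duration,
                dt=dt,
                seed=sim_rng,
                force=force,
                contact_def=contact_def,
                domain=domain,
            )
            per_rep[gi, r] = res.mean_contacts_per_person
    sds = per_rep.std(axis=1, ddof=1) if replicates > 1 else np.zeros(grid.size)
    return SweepResult(
        parameter=parameter,
        grid=grid,
        means=per_rep.mean(axis=1),
        sds=sds,
        per_replicate=per_rep,
        params=params,
    )


def velocity_sweep(
    v_grid=DEFAULT_VELOCITY_GRID,
    d_soc: float = 1.22,
    a_soc: float = 700.0,
    replicates: int = 5,
    seed: int = 0,
    n: int = 300,
    duration: float = 600.0,
    dt: float = 0.02,
    mass: float = 70.0,
    force: ForceParams | None = None,
    domain: Domain | None = None,
    contact_def: ContactDefinition | None = None,
) -> SweepResult:
    """Mean contacts per person as a function of a homogeneous desired speed.

    Every agent shares the swept speed, the given desired distance and the
    repulsion amplitude; all other constants take their defaults.
    """
    force = replace(force or ForceParams(), a_soc=a_soc)
    factory = lambda v: _homogeneous_profiles(n, v, d_soc, mass, 0.2, 0.5)  # noqa: E731
    return _sweep(
        "desired_speed", v_grid, factory, force, replicates, seed, n, duration,
        dt, domain, contact_def,
        {"d_soc": d_soc, "a_soc": a_soc, "mass": mass, "n": n,
         "duration": duration, "dt": dt, "seed": seed, "replicates": replicates},
    )


def weight_sweep(
    m_grid=DEFAULT_MASS_GRID,
    d_soc: float = 1.22,
    v_d: float = 1.34,
    a_soc: float = 700.0,
    replicates: int = 5,
    seed: int = 0,
    n: int = 300,
    duration: float = 600.0,
    dt: float = 0.02,
    force: ForceParams | None = None,
    domain: Domain | None = None,
    contact_def: ContactDefinition | None = None,
) -> SweepResult:
    """Mean contacts per person as a function of a homogeneous body mass.

    Heavier agents carry a proportionally stronger self-driven force while
    the social repulsion stays fixed, so they deviate less from their
    desired paths.
    """
    force = replace(force or ForceParams(), a_soc=a_soc)
    factory = lambda m: _homogeneous_profiles(n, v_d, d_soc, m, 0.2, 0.5)  # noqa: E731
    return _sweep(
        "mass", m_grid, factory, force, replicates, seed, n, duration,
        dt, domain, contact_def,
        {"d_soc": d_soc, "v_d": v_d, "a_soc": a_soc, "n": n,
         "duration": duration, "dt": dt, "seed": seed, "replicates": replicates},
    )


def find_threshold_velocity(sweep: SweepResult) -> float:
    """Grid value maximizing mean contacts (ties break to the smallest).

    The result is resolved only to the grid spacing.  A curve whose
    maximum sits on the grid boundary is flagged: the true threshold may
    lie outside the swept range.
    """
    if sweep.grid.size < 3:
        raise ValueError("a threshold needs at least three grid points")
    idx = int(np.argmax(sweep.means))  # argmax takes the first maximum
    if idx in (0, sweep.grid.size - 1):
        warnings.warn(
            "contacts curve is monotone over the grid; returning the boundary value"
        )
    return float(sweep.grid[idx])
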