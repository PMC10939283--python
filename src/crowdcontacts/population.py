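"""Heterogeneous pedestrian populations for activity-area simulations.

Each activity area (workplace, school, household, shopping centre,
"other" public space) is parameterized by a proxemic zone — the Hall-style
interpersonal-distance class its occupants try to maintain — together with
per-age-bin Gaussian distributions of desired walking speed and desired
interpersonal distance, an area-level body-mass distribution, and the
demographic weights from which ages are drawn.  Sampling a population
yields a list of :class:`PedestrianProfile` records that the dynamics
engine consumes unchanged.

The bundled :func:`fixture_location_configs` provides five self-consistent
area configurations (same crowd density everywhere, intimate distances at
home, personal at school/work, social in shopping centres and other public
spaces) built from published anchors; the exact per-age calibration tables
the approach was originally run with are not reproduced here, so these
fixtures are an explicit synthetic stand-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AgeBin",
    "ProxemicZone",
    "GaussianSpec",
    "PedestrianProfile",
    "LocationConfig",
    "ConfigurationError",
    "N_AGE_BINS",
    "AGE_BIN_LABELS",
    "PROXEMIC_ZONES",
    "LOCATION_NAMES",
    "DEFAULT_DURATIONS_H",
    "age_bins",
    "sample_population",
    "population_census",
    "population_table",
    "fixture_location_configs",
]

N_AGE_BINS = 16

#: Five-year bins "0–5" … "70–75" plus the open-ended "over 75".
AGE_BIN_LABELS = tuple([f"{5 * i}–{5 * (i + 1)}" for i in range(15)] + ["over 75"])

LOCATION_NAMES = ("workplace", "school", "household", "shopping", "other")

#: Hours of activity per area.
DEFAULT_DURATIONS_H = {
    "workplace": 8.0,
    "school": 8.0,
    "household": 5.0,
    "shopping": 11.0,
    "other": 16.0,
}


class ConfigurationError(ValueError):
    """A location configuration is incomplete or inconsistent."""


@dataclass(frozen=True)
class AgeBin:
    """One of the sixteen contiguous five-year age groups."""

    index: int
    label: str
    lower: float
    upper: float  # math.inf for the open-ended last bin


def age_bins() -> list[AgeBin]:
    """The sixteen five-year age bins, "0–5" through "over 75"."""
    bins = [AgeBin(i, AGE_BIN_LABELS[i], 5.0 * i, 5.0 * (i + 1)) for i in range(15)]
    bins.append(AgeBin(15, AGE_BIN_LABELS[15], 75.0, math.inf))
    return bins


@dataclass(frozen=True)
class ProxemicZone:
    """A Hall interpersonal-distance class, as a closed range in metres."""

    name: str
    range_lo: float
    range_hi: float

    def __contains__(self, d: float) -> bool:
        return self.range_lo <= d <= self.range_hi


#: Intimate 0–46 cm, personal 46–122 cm, social 122–210 cm.
PROXEMIC_ZONES = {
    "intimate": ProxemicZone("intimate", 0.0, 0.46),
    "personal": ProxemicZone("personal", 0.46, 1.22),
    "social": ProxemicZone("social", 1.22, 2.10),
}


@dataclass(frozen=True)
class GaussianSpec:
    """Mean/SD of a (possibly truncated) Gaussian attribute distribution."""

    mean: float
    sd: float


@dataclass(frozen=True)
class PedestrianProfile:
    """Static attributes of one simulated pedestrian.

    Attributes
    ----------
    desired_speed : float
        Walking speed v_d the agent relaxes towards, m/s.
    desired_distance : float
        Interpersonal distance d_soc the agent keeps; also the support
        cutoff of the social repulsion, m.
    relaxation_time : float
        Time constant tau of the self-driven force, s.
    """

    id: int
    age_bin: AgeBin
    mass: float  # kg
    radius: float  # m
    desired_speed: float  # m/s
    desired_distance: float  # m
    relaxation_time: float  # s

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.radius <= 0 or self.relaxation_time <= 0:
            raise ValueError("mass, radius and relaxation time must be positive")
        if self.desired_speed < 0 or self.desired_distance <= 0:
            raise ValueError("speed must be >= 0 and desired distance > 0")


@dataclass(frozen=True)
class ForceParams:
    """Constants of the repulsive force laws.

    A_soc is the strength (N) of the social psychological force, beta_soc
    its fall-off length (m), and gamma in [0, 1] the weight of
    interactions happening behind a pedestrian's back.  A_obs / beta_obs /
    d_obs play the same roles for the wall force and its support cutoff.
    """

    a_soc: float = 700.0
    beta_soc: float = 0.08
    gamma: float = 0.2
    a_obs: float = 2000.0
    beta_obs: float = 0.08
    d_obs: float = 0.5

    def __post_init__(self) -> None:
        if min(self.a_soc, self.beta_soc, self.a_obs, self.beta_obs) <= 0:
            raise ValueError("force amplitudes and fall-off lengths must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass(frozen=True)
class LocationConfig:
    """Full parameterization of one activity area.

    ``speed_dist`` and ``distance_dist`` are per-age-bin Gaussians (16
    entries each); ``mass_dist`` is a single area-level Gaussian because
    body mass varies with the area's population mix but not explicitly
    with the age bin.  Desired distances are truncated to the area's
    proxemic zone, speeds and masses to their configured positive ranges.
    """

    name: str
    zone: ProxemicZone
    duration_h: float
    demographic_weights: tuple[float, ...]
    speed_dist: tuple[GaussianSpec, ...]
    distance_dist: tuple[GaussianSpec, ...]
    mass_dist: GaussianSpec
    force: ForceParams = field(default_factory=ForceParams)
    radius: float = 0.2
    relaxation_time: float = 0.5
    mass_range: tuple[float, float] = (30.0, 130.0)

    def __post_init__(self) -> None:
        w = np.asarray(self.demographic_weights, dtype=float)
        if w.shape != (N_AGE_BINS,):
            raise ConfigurationError(
                f"{self.name}: demographic_weights needs {N_AGE_BINS} entries"
            )
        if np.any(w < 0) or not math.isclose(float(w.sum()), 1.0, abs_tol=1e-8):
            raise ConfigurationError(f"{self.name}: demographic weights must sum to 1")
        for attr in ("speed_dist", "distance_dist"):
            if len(getattr(self, attr)) != N_AGE_BINS:
                raise ConfigurationError(f"{self.name}: {attr} needs {N_AGE_BINS} entries")
        if self.duration_h <= 0 or self.radius <= 0 or self.relaxation_time <= 0:
            raise ConfigurationError(f"{self.name}: durations, radius, tau must be positive")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, max_tries: int = 10000
) -> float:
    """Rejection-sample N(mean, sd) into (lo, hi]; keeps the shape near the mean."""
    if sd == 0.0:
        return float(min(max(mean, lo), hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    raise ConfigurationError(
        f"truncated Gaussian N({mean}, {sd}) rejected {max_tries} draws in ({lo}, {hi}]"
    )


def sample_population(
    config: LocationConfig,
    n: int,
    seed: int | np.random.Generator,
) -> list[PedestrianProfile]:
    """Draw ``n`` pedestrian profiles for one activity area.

    Age bins follow the area's demographic weights; desired speed and
    interpersonal distance come from the bin's Gaussians (distance
    truncated to the proxemic zone, speed to non-negative values), mass
    from the area-level Gaussian truncated to ``config.mass_range``.
    Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("population size must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bins = age_bins()
    weights = np.asarray(config.demographic_weights, dtype=float)
    indices = rng.choice(N_AGE_BINS, size=n, p=weights)
    zone = config.zone
    profiles: list[PedestrianProfile] = []
    for pid, b in enumerate(indices):
        b = int(b)
        sp = config.speed_dist[b]
        dd = config.distance_dist[b]
        if not (math.isfinite(sp.mean) and math.isfinite(dd.mean)):
            raise ConfigurationError(f"{config.name}: age bin {b} not configured")
        speed = _truncated_normal(rng, sp.mean, sp.sd, 0.0, math.inf)
        dist_lo = max(zone.range_lo, 1e-6)  # strictly positive desired distance
        dist = _truncated_normal(rng, dd.mean, dd.sd, dist_lo, zone.range_hi)
        mass = _truncated_normal(rng, config.mass_dist.mean, config.mass_dist.sd, *config.mass_range)
        profiles.append(
            PedestrianProfile(
                id=pid,
                age_bin=bins[b],
                mass=mass,
                radius=config.radius,
                desired_speed=speed,
                desired_distance=dist,
                relaxation_time=config.relaxation_time,
            )
        )
    return profiles


def population_census(profiles: list[PedestrianProfile]) -> np.ndarray:
    """Group sizes n_i: number of sampled pedestrians per age bin."""
    counts = np.zeros(N_AGE_BINS, dtype=np.int64)
    for p in profiles:
        counts[p.age_bin.index] += 1
    return counts


def population_table(profiles: list[PedestrianProfile]):
    """Export a population as a tidy table (one row per pedestrian)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [p.id for p in profiles],
            "age_bin": [p.age_bin.label for p in profiles],
            "mass": [p.mass for p in profiles],
            "radius": [p.radius for p in profiles],
            "v_d": [p.desired_speed for p in profiles],
            "d_soc": [p.desired_distance for p in profiles],
            "tau": [p.relaxation_time for p in profiles],
        }
    )


# ---------------------------------------------------------------------------
# Fixture configurations (synthetic stand-in calibration)
# ---------------------------------------------------------------------------

# National five-year age pyramid (young-skewed, high-fertility shape),
# normalized below.  A synthetic placeholder for census weights.
_NATIONAL_PYRAMID = np.array(
    [9.5, 9.3, 9.0, 8.6, 8.3, 8.0, 7.6, 7.0, 6.3, 5.5, 4.9, 4.3, 3.7, 2.9, 2.0, 3.1]
)

# Desired free-walking speed by age bin (m/s): children slower, a plateau
# through the working ages, decline past 60.
_SPEED_BY_AGE = np.array(
    [0.90, 1.10, 1.25, 1.40, 1.45, 1.45, 1.43, 1.42, 1.40, 1.37, 1.32, 1.25, 1.18, 1.08, 0.95, 0.85]
)

# Area-level multipliers: fastest walking in workplaces/schools, slowest in
# residential areas.
_SPEED_FACTOR = {
    "workplace": 1.10,
    "school": 1.05,
    "household": 0.85,
    "shopping": 1.00,
    "other": 1.00,
}

_ZONE_BY_LOCATION = {
    "workplace": "personal",
    "school": "personal",
    "household": "intimate",
    "shopping": "social",
    "other": "social",
}


def _location_weights(name: str) -> np.ndarray:
    """Plausible occupancy-by-age weights per activity area."""
    base = _NATIONAL_PYRAMID.copy()
    w = np.zeros(N_AGE_BINS)
    if name == "school":
        # pupils 5-20 dominate, teaching/support staff 25-60
        w[1:4] = (0.28, 0.28, 0.22)
        w[5:12] = 0.22 * base[5:12] / base[5:12].sum()
    elif name == "workplace":
        # working ages 20-65
        w[4:13] = base[4:13]
    elif name == "household":
        w = base.copy()
    elif name == "shopping":
        # adolescents through the elderly, adult-weighted
        w[3:] = base[3:]
        w[3] *= 0.8
    else:  # "other" public spaces: everyone but infants under-represented
        w = base.copy()
        w[0] *= 0.4
    return w / w.sum()


def fixture_location_configs(
    force: ForceParams | None = None,
) -> dict[str, LocationConfig]:
    """Five self-consistent activity-area configurations.

    Households use intimate-zone distances, schools and workplaces
    personal, shopping centres and other public spaces social; all areas
    share the same crowd density and the stated activity durations.  The
    per-age tables are synthetic placeholders built from the main-text
    anchors, not the original supplementary calibration.
    """
    force = force or ForceParams()
    configs: dict[str, LocationConfig] = {}
    for name in LOCATION_NAMES:
        zone = PROXEMIC_ZONES[_ZONE_BY_LOCATION[name]]
        width = zone.range_hi - zone.range_lo
        speed = tuple(
            GaussianSpec(float(m * _SPEED_FACTOR[name]), 0.2) for m in _SPEED_BY_AGE
        )
        # Mild age trend: older pedestrians keep slightly larger distances
        # within the zone.
        distance = tuple(
            GaussianSpec(
                float(zone.range_lo + (0.35 + 0.25 * i / (N_AGE_BINS - 1)) * width),
                float(width / 6.0),
            )
            for i in range(N_AGE_BINS)
        )
        configs[name] = LocationConfig(
            name=name,
            zone=zone,
            duration_h=DEFAULT_DURATIONS_H[name],
            demographic_weights=tuple(_location_weights(name)),
            speed_dist=speed,
            distance_dist=distance,
            mass_dist=GaussianSpec(70.0, 12.0),
            force=force,
        )
    return configs


def override_population(
    profiles: list[PedestrianProfile],
    desired_distance: float | None = None,
    desired_speed: float | None = None,
    mass: float | None = None,
) -> list[PedestrianProfile]:
    """Apply homogeneous counterfactual overrides to every profile."""
    out = []
    for p in profiles:
        kwargs = {}
        if desired_distance is not None:
            kwargs["desired_distance"] = desired_distance
        if desired_speed is not None:
            kwargs["desired_speed"] = desired_speed
        if mass is not None:
            kwargs["mass"] = mass
        out.append(replace(p, **kwargs) if kwargs else p)
    return out
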