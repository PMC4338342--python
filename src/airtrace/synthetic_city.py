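"""Synthetic study area and population generator.

Emulates the three inputs of an activity-based exposure study — a road
network, a diurnally varying gridded pollutant field, and a sample of
person-day travel diaries — on a planar Cartesian domain (meters, origin at
the southwest corner).  The city has an urban core, a suburban ring, discrete
second-city pockets, and rural remainder; concentrations are elevated in the
core and along arterial roads with morning and evening traffic peaks; and
household sociodemographics are drawn conditionally on residence urbanicity
(residential sorting), so configured exposure disparities between groups are
recoverable downstream.

All randomness derives from ``CityConfig.seed`` through per-household and
per-person counters, so a given configuration reproduces the identical city
and population, independent of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .concentration import ConcentrationField, GridSpec
from .diary import AGE_GROUPS, PersonDay, Trip
from .routing import RoadNetwork

__all__ = [
    "CityConfig",
    "DEFAULT_DIURNAL_PROFILE",
    "generate_network",
    "assign_urbanicity",
    "generate_field",
    "generate_population",
]

#: Hour-of-day multipliers of the spatial concentration pattern.  Sharp
#: morning commute peak (06–08), broader and slightly lower evening peak
#: (17–21), low overnight values — the canonical traffic-driven NOx cycle.
DEFAULT_DIURNAL_PROFILE = (
    0.55, 0.50, 0.45, 0.45, 0.50, 0.80,   # 00-05
    1.60, 1.80, 1.50,                      # 06-08 morning peak
    1.10, 1.00, 0.95, 0.90, 0.90, 0.95, 1.05,  # 09-15 midday
    1.25, 1.50, 1.60, 1.55, 1.45, 1.30,    # 16-21 evening peak
    1.00, 0.70,                            # 22-23
)

_ZONES = ("urban", "suburban", "second_city", "rural")


def _default_group_probs():
    # strong residential sorting: the black and below-poverty groups
    # concentrate in the urban core, higher incomes in the suburbs
    return {
        "urban": {
            "race": {"black": 0.40, "white": 0.45, "asian": 0.03, "other": 0.12},
            "hispanic": 0.25,
            "income": {"below_poverty": 0.30, "middle": 0.48, "higher": 0.22},
        },
        "suburban": {
            "race": {"black": 0.15, "white": 0.70, "asian": 0.04, "other": 0.11},
            "hispanic": 0.18,
            "income": {"below_poverty": 0.08, "middle": 0.44, "higher": 0.48},
        },
        "second_city": {
            "race": {"black": 0.12, "white": 0.75, "asian": 0.03, "other": 0.10},
            "hispanic": 0.20,
            "income": {"below_poverty": 0.12, "middle": 0.55, "higher": 0.33},
        },
        "rural": {
            "race": {"black": 0.06, "white": 0.85, "asian": 0.02, "other": 0.07},
            "hispanic": 0.12,
            "income": {"below_poverty": 0.15, "middle": 0.55, "higher": 0.30},
        },
    }


@dataclass
class CityConfig:
    """Everything needed to generate one synthetic city and its population."""

    seed: int = 0
    # --- network geometry ---
    grid_n: int = 15                    # nodes per side
    node_spacing: float = 1000.0        # m between adjacent nodes
    arterial_every: int = 5             # every k-th row/column is arterial
    local_speed: float = 13.4           # m/s (~30 mph)
    arterial_speed: float = 22.4        # m/s (~50 mph)
    # --- urbanicity zones ---
    zone_radii: dict = field(
        default_factory=lambda: {"urban": 3000.0, "suburban": 6500.0}
    )
    second_city_centers: tuple = ((12000.0, 12000.0), (2000.0, 12000.0))
    second_city_radius: float = 1500.0
    # --- concentration field ---
    field_background: float = 8.0       # μg/m³ domain-wide floor
    field_urban_amplitude: float = 12.0  # μg/m³ Gaussian bump over the core
    field_road_amplitude: float = 6.0   # μg/m³ per arterial-link kernel
    field_kernel_scale: float = 300.0   # m, road-proximity Gaussian scale
    field_cell_size_m: float = 1000.0
    diurnal_profile: tuple = DEFAULT_DIURNAL_PROFILE
    # --- population ---
    n_households: int = 500
    persons_per_household_max: int = 2
    residence_density_by_zone: dict = field(
        default_factory=lambda: {
            "urban": 3.0, "suburban": 1.0, "second_city": 4.0, "rural": 0.8
        }
    )
    group_probs_by_zone: dict = field(default_factory=_default_group_probs)
    age_probs: tuple = (0.12, 0.27, 0.27, 0.34)   # 5-18, 19-45, 46-65, >65
    no_travel_fraction: float = 0.195   # share of person-days with zero trips
    trips_per_day_rate: dict = field(
        default_factory=lambda: {"5-18": 2.0, "19-45": 2.6, "46-65": 2.4, ">65": 1.6}
    )
    max_stops: int = 4
    dest_decay_m: float = 4000.0        # distance-decay scale of destination choice
    dest_urban_attraction: float = 3.0  # extra weight of urban-core destinations
    # start-time mixture (minutes): morning commute + broader later component
    start_morning: tuple = (480.0, 60.0)
    start_later: tuple = (660.0, 120.0)
    start_morning_weight: float = 0.6
    work_dwell: tuple = (470.0, 60.0)   # minutes, normal
    other_dwell_log: tuple = (4.0, 0.7)  # ln-minutes, lognormal (median ~55 min)
    travel_speed_est: float = 13.0      # m/s used to synthesize reported times
    max_retries: int = 20

    def __post_init__(self) -> None:
        if self.grid_n < 2:
            raise ValueError("grid_n must be at least 2")
        if self.node_spacing <= 0:
            raise ValueError("node_spacing must be positive")
        if self.local_speed <= 0 or self.arterial_speed <= 0:
            raise ValueError("speeds must be positive")
        if len(self.diurnal_profile) != 24 or any(
            m <= 0 for m in self.diurnal_profile
        ):
            raise ValueError("diurnal_profile needs exactly 24 positive entries")
        for zone in _ZONES:
            probs = self.group_probs_by_zone[zone]
            for key in ("race", "income"):
                s = sum(probs[key].values())
                if abs(s - 1.0) > 1e-9:
                    raise ValueError(
                        f"{key} probabilities for zone {zone!r} sum to {s}, not 1"
                    )
        if not 0.0 <= self.no_travel_fraction <= 1.0:
            raise ValueError("no_travel_fraction must be in [0, 1]")

    @property
    def extent_m(self) -> float:
        return (self.grid_n - 1) * self.node_spacing

    @property
    def center(self) -> tuple[float, float]:
        return (self.extent_m / 2.0, self.extent_m / 2.0)

    @property
    def domain_bbox(self) -> tuple[float, float, float, float]:
        """Study domain = coverage of the concentration grid."""
        return self.grid_spec.bbox

    @property
    def grid_spec(self) -> GridSpec:
        d = self.field_cell_size_m
        n = math.ceil((self.extent_m + d) / d)
        return GridSpec(x0=-d / 2.0, y0=-d / 2.0, cell_size_m=d, nx=n, ny=n)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def _is_arterial(index: int, every: int) -> bool:
    return (index + 1) % every == 0


def generate_network(config: CityConfig) -> RoadNetwork:
    """Planar grid network; every k-th row/column carries the arterial speed.

    Node ids are row-major (``id = j * grid_n + i``); all links are straight
    segments of length ``node_spacing``.  Deterministic in the config.
    """
    n, d = config.grid_n, config.node_spacing
    net = RoadNetwork()
    for j in range(n):
        for i in range(n):
            net.add_node(j * n + i, i * d, j * d)
    link_id = 0
    for j in range(n):           # horizontal links along row j
        speed = config.arterial_speed if _is_arterial(j, config.arterial_every) \
            else config.local_speed
        for i in range(n - 1):
            net.add_link(link_id, j * n + i, j * n + i + 1, d, speed)
            link_id += 1
    for i in range(n):           # vertical links along column i
        speed = config.arterial_speed if _is_arterial(i, config.arterial_every) \
            else config.local_speed
        for j in range(n - 1):
            net.add_link(link_id, j * n + i, (j + 1) * n + i, d, speed)
            link_id += 1
    return net


# ---------------------------------------------------------------------------
# Urbanicity
# ---------------------------------------------------------------------------

def assign_urbanicity(point: tuple[float, float], config: CityConfig) -> str:
    """Zone of a point: urban core, second-city pocket, suburban ring, rural.

    Half-open convention: a point exactly on an inner-zone boundary radius
    belongs to the outer zone.  Points outside the study domain raise.
    """
    xmin, ymin, xmax, ymax = config.domain_bbox
    x, y = point
    if not (xmin <= x < xmax and ymin <= y < ymax):
        raise ValueError(f"point {point} outside study domain")
    if math.dist(point, config.center) < config.zone_radii["urban"]:
        return "urban"
    for c in config.second_city_centers:
        if math.dist(point, c) < config.second_city_radius:
            return "second_city"
    if math.dist(point, config.center) < config.zone_radii["suburban"]:
        return "suburban"
    return "rural"


# ---------------------------------------------------------------------------
# Concentration field
# ---------------------------------------------------------------------------

def _segment_distances(px, py, segments) -> np.ndarray:
    """Distances from points (px, py broadcast) to each segment; min over segs."""
    best = np.full(px.shape, np.inf)
    for (ax, ay), (bx, by) in segments:
        dx, dy = bx - ax, by - ay
        L2 = dx * dx + dy * dy
        t = np.clip(((px - ax) * dx + (py - ay) * dy) / L2, 0.0, 1.0)
        d = np.hypot(px - (ax + t * dx), py - (ay + t * dy))
        best = np.minimum(best, d)
    return best


def generate_field(config: CityConfig, network: RoadNetwork) -> ConcentrationField:
    """Diurnal concentration field: background + urban bump + road kernels.

    Spatial pattern at a cell center:
    ``background + A_u·exp(−d_core²/2r_u²) + Σ_links A_r·exp(−d_link²/2s²)``
    summed over arterial links, then multiplied by the hour-of-day profile.
    By construction values are positive everywhere, the urban core exceeds the
    rural corners at every hour, and domain means peak in the commute hours.
    """
    grid = config.grid_spec
    cx, cy = grid.cell_centers()
    px, py = np.meshgrid(cx, cy)          # shape (ny, nx)

    base = np.full(px.shape, config.field_background, dtype=float)
    ru = config.zone_radii["urban"]
    x0, y0 = config.center
    d_core = np.hypot(px - x0, py - y0)
    base += config.field_urban_amplitude * np.exp(-d_core**2 / (2.0 * ru**2))

    if config.field_road_amplitude > 0:
        arterials = [
            (network.node_xy(u), network.node_xy(v))
            for u, v, e in network.graph.edges(data=True)
            if e["speed_mps"] == config.arterial_speed
        ]
        s = config.field_kernel_scale
        for (a, b) in arterials:
            dx, dy = b[0] - a[0], b[1] - a[1]
            L2 = dx * dx + dy * dy
            t = np.clip(((px - a[0]) * dx + (py - a[1]) * dy) / L2, 0.0, 1.0)
            d = np.hypot(px - (a[0] + t * dx), py - (a[1] + t * dy))
            base += config.field_road_amplitude * np.exp(-d**2 / (2.0 * s**2))

    layers = np.array([m * base for m in config.diurnal_profile])
    return ConcentrationField(grid, layers)


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def _choice(rng: np.random.Generator, options: list[str], probs: dict) -> str:
    p = np.array([probs[o] for o in options], dtype=float)
    return options[int(rng.choice(len(options), p=p / p.sum()))]


def _sample_household(config, rng, node_ids, node_xy, node_zone, zone_weights):
    idx = int(rng.choice(len(node_ids), p=zone_weights))
    zone = node_zone[idx]
    probs = config.group_probs_by_zone[zone]
    race = _choice(rng, ["black", "white", "asian", "other"], probs["race"])
    hispanic = bool(rng.random() < probs["hispanic"])
    income = _choice(
        rng, ["below_poverty", "middle", "higher"], probs["income"]
    )
    n_persons = int(rng.integers(1, config.persons_per_household_max + 1))
    return idx, zone, race, hispanic, income, n_persons


def _sample_schedule(config, rng, res_xy, dest_xy, weights, rate, adult):
    """One home-anchored tour; returns a trip list or None if infeasible."""
    k = 1 + int(rng.poisson(max(rate - 1.0, 0.0)))
    k = min(k, config.max_stops)
    stops = []
    cur = np.asarray(res_xy)
    for _ in range(k):
        d = np.hypot(dest_xy[:, 0] - cur[0], dest_xy[:, 1] - cur[1])
        w = weights * np.exp(-d / config.dest_decay_m)
        w[d < 1.0] = 0.0          # never "travel" to the current location
        stop = int(rng.choice(len(dest_xy), p=w / w.sum()))
        stops.append(stop)
        cur = dest_xy[stop]

    if rng.random() < config.start_morning_weight:
        mu, sd = config.start_morning
    else:
        mu, sd = config.start_later
    start = float(np.clip(round(rng.normal(mu, sd)), 240, 1020))

    trips: list[Trip] = []
    loc = tuple(res_xy)
    t = start
    for s_idx, stop in enumerate(stops + [None]):
        dest = tuple(dest_xy[stop]) if stop is not None else tuple(res_xy)
        manhattan = abs(dest[0] - loc[0]) + abs(dest[1] - loc[1])
        travel = max(
            2.0,
            round(manhattan / config.travel_speed_est / 60.0 * rng.uniform(1.1, 1.5)),
        )
        if stop is None:
            purpose, dwell = "home", 0.0   # dwell filled below
        elif s_idx == 0 and adult and rng.random() < 0.55:
            purpose = "work"
            dwell = float(np.clip(round(rng.normal(*config.work_dwell)), 60, 660))
        else:
            purpose = ["meals", "other", "travel"][
                int(rng.choice(3, p=[0.2, 0.7, 0.1]))
            ]
            mu_l, sd_l = config.other_dwell_log
            dwell = float(np.clip(round(rng.lognormal(mu_l, sd_l)), 5, 600))
        trips.append(
            Trip(origin=loc, destination=dest, start_minute=t,
                 reported_travel_minutes=travel, dwell_minutes=dwell,
                 purpose=purpose)
        )
        loc = dest
        t += travel + dwell
    if t > 1440.0:
        return None
    trips[-1].dwell_minutes = 1440.0 - t   # closing at-residence block
    return trips


def generate_population(
    config: CityConfig, network: RoadNetwork, field: ConcentrationField
) -> list[PersonDay]:
    """Draw a population of person-day diaries with residential sorting.

    Households pick a residence node (density-weighted by urbanicity zone);
    race/ethnicity and income are drawn from zone-conditional probabilities.
    A configurable fraction of person-days has no travel; the rest make one
    home-anchored tour whose destinations are drawn with distance decay and
    an urban attraction premium, with commute-peaked start times.  Schedules
    that cannot close by minute 1440 are redrawn with bounded retries.
    Identical config (including seed) reproduces the identical population.
    """
    node_ids = sorted(network.graph.nodes)
    node_xy = np.array([network.node_xy(n) for n in node_ids])
    node_zone = [assign_urbanicity((x, y), config) for x, y in node_xy]

    dens = config.residence_density_by_zone
    zone_weights = np.array([dens[z] for z in node_zone], dtype=float)
    zone_weights /= zone_weights.sum()
    dest_weights = np.array(
        [config.dest_urban_attraction if z == "urban" else 1.0 for z in node_zone]
    )

    population: list[PersonDay] = []
    person_counter = 0
    for hh in range(config.n_households):
        rng_hh = np.random.default_rng([config.seed, 2, hh])
        idx, zone, race, hispanic, income, n_persons = _sample_household(
            config, rng_hh, node_ids, node_xy, node_zone, zone_weights
        )
        res_xy = tuple(node_xy[idx])
        for p in range(n_persons):
            rng = np.random.default_rng([config.seed, 3, person_counter])
            age = AGE_GROUPS[int(rng.choice(4, p=np.asarray(config.age_probs)))]
            gender = "female" if rng.random() < 0.5 else "male"
            pd_ = PersonDay(
                person_id=f"p{person_counter:05d}",
                household_id=f"h{hh:05d}",
                age_group=age,
                black=race == "black",
                hispanic=hispanic,
                white=race == "white",
                asian=race == "asian",
                income_category=income,
                gender=gender,
                residence_urbanicity=zone,
                residence=res_xy,
            )
            if rng.random() >= config.no_travel_fraction:
                rate = config.trips_per_day_rate[age]
                adult = age in ("19-45", "46-65")
                trips = None
                for _attempt in range(config.max_retries):
                    trips = _sample_schedule(
                        config, rng, res_xy, node_xy, dest_weights, rate, adult
                    )
                    if trips is not None:
                        break
                if trips is None:
                    raise RuntimeError(
                        f"person-day {pd_.person_id}: no feasible schedule in "
                        f"{config.max_retries} attempts"
                    )
                pd_.trips = trips
            population.append(pd_)
            person_counter += 1
    return population
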