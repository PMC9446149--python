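"""Spatial environment: wards, recreation centers, schedules, accessibility.

The city is an abstract mosaic of 8 rectangular wards on a planar
km grid (2 rows x 4 columns of squares by default).  Recreation centers
are placed uniformly at random inside their ward's rectangle and hold
50-minute classes at ~6.5 METs on scheduled weekdays.  Objective
accessibility is a binary threshold: an agent can reach a center on foot
within ``walk_reach_km`` of home, or by car within ``drive_reach_km`` if
the household has one.  All distance comparisons use a closed boundary
(<=) and Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MILES_TO_KM = 1.609344

#: default weekday schedule: classes Monday-Friday (day 0 = Monday)
WEEKDAYS = (0, 1, 2, 3, 4)

__all__ = [
    "MILES_TO_KM",
    "RecreationCenter",
    "EnvironmentSpec",
    "ward_rect",
    "build_environment",
    "objective_access",
    "centers_within_geofence",
    "class_available",
    "access_profile",
]


@dataclass(frozen=True)
class RecreationCenter:
    id: int
    ward_id: int
    xy: tuple[float, float]
    schedule: frozenset = frozenset(WEEKDAYS)
    class_duration: float = 50.0  # minutes
    class_intensity: float = 6.5  # METs

    def __post_init__(self) -> None:
        if self.class_duration <= 0:
            raise ValueError("class_duration must be positive")
        if self.class_intensity < 1:
            raise ValueError("class_intensity must be at least 1 MET")
        if not self.schedule:
            raise ValueError("schedule must be non-empty")


@dataclass(frozen=True)
class EnvironmentSpec:
    """Layout and accessibility parameters of the simulated city.

    ``centers_per_ward`` defaults are invented placeholders chosen so
    that ward 6 is the best served and ward 7 the worst, matching the
    qualitative ward gradient of access to free classes.
    """

    centers_per_ward: tuple = (4, 3, 4, 4, 3, 8, 1, 3)
    geofence_miles: float = 0.5
    walk_reach_km: float = 1.0
    drive_reach_km: float = 8.0
    ward_size_km: float = 4.0
    class_days: tuple = WEEKDAYS
    class_duration: float = 50.0
    class_intensity: float = 6.5

    def __post_init__(self) -> None:
        if len(self.centers_per_ward) != 8:
            raise ValueError("centers_per_ward must list 8 wards")
        if any(c < 0 for c in self.centers_per_ward):
            raise ValueError("center counts must be non-negative")
        if self.geofence_miles <= 0 or self.walk_reach_km <= 0:
            raise ValueError("radii must be positive")
        if self.drive_reach_km < self.walk_reach_km:
            raise ValueError("drive_reach_km must be >= walk_reach_km")


def ward_rect(ward_id: int, ward_size_km: float = 4.0) -> tuple[float, float, float, float]:
    """(x0, y0, x1, y1) extent of a ward in the 4x2 mosaic; wards 1-8."""
    if not 1 <= ward_id <= 8:
        raise ValueError(f"ward_id must be in 1..8, got {ward_id}")
    col, row = (ward_id - 1) % 4, (ward_id - 1) // 4
    s = ward_size_km
    return (col * s, row * s, (col + 1) * s, (row + 1) * s)


def _schedule_mask(days) -> np.ndarray:
    mask = np.zeros(7, dtype=bool)
    mask[list(days)] = True
    return mask


def build_environment(spec: EnvironmentSpec, seed: int) -> pd.DataFrame:
    """Place centers uniformly at random within each ward rectangle.

    Returns a table with one row per center: id, ward_id, x_km, y_km,
    one boolean column per weekday (dow_0..dow_6), duration and METs.
    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xE,)))
    rows = []
    cid = 0
    for ward in range(1, 9):
        x0, y0, x1, y1 = ward_rect(ward, spec.ward_size_km)
        for _ in range(spec.centers_per_ward[ward - 1]):
            rows.append(
                {
                    "id": cid,
                    "ward_id": ward,
                    "x_km": rng.uniform(x0, x1),
                    "y_km": rng.uniform(y0, y1),
                }
            )
            cid += 1
    centers = pd.DataFrame(rows, columns=["id", "ward_id", "x_km", "y_km"])
    mask = _schedule_mask(spec.class_days)
    for d in range(7):
        centers[f"dow_{d}"] = mask[d]
    centers["duration"] = spec.class_duration
    centers["mets"] = spec.class_intensity
    return centers


def _distances(xy, centers: pd.DataFrame) -> np.ndarray:
    """Euclidean distance from point(s) (n,2) to every center (n, n_centers)."""
    pts = np.atleast_2d(np.asarray(xy, dtype=float))
    dx = pts[:, 0:1] - centers["x_km"].to_numpy()[None, :]
    dy = pts[:, 1:2] - centers["y_km"].to_numpy()[None, :]
    return np.hypot(dx, dy)


def objective_access(home_xy, has_car, centers: pd.DataFrame, spec: EnvironmentSpec):
    """True iff some center is walkable from home, or drivable with a car.

    Vectorized: ``home_xy`` may be (2,) or (n, 2) with matching
    ``has_car``.  Fixed per agent for a given environment.
    """
    if len(centers) == 0:
        scalar = np.asarray(home_xy).ndim == 1
        return False if scalar else np.zeros(np.atleast_2d(home_xy).shape[0], dtype=bool)
    d = _distances(home_xy, centers)
    car = np.atleast_1d(np.asarray(has_car, dtype=bool))
    reach = np.where(car, spec.drive_reach_km, spec.walk_reach_km)
    ok = (d.min(axis=1) <= reach)
    return bool(ok[0]) if np.asarray(home_xy).ndim == 1 else ok


def centers_within_geofence(xy, centers: pd.DataFrame, radius_miles: float) -> pd.DataFrame:
    """Centers within ``radius_miles`` of a point (closed boundary).

    The geofence radius is given in miles (converted at 1 mile =
    1.609344 km); may return an empty subset.
    """
    if radius_miles <= 0:
        raise ValueError("radius must be positive")
    if len(centers) == 0:
        return centers
    d = _distances(xy, centers)[0]
    return centers[d <= radius_miles * MILES_TO_KM]


def class_available(center, day: int) -> bool:
    """True iff the weekday (0=Monday) is on the center's schedule."""
    dow = day % 7
    if isinstance(center, RecreationCenter):
        return dow in center.schedule
    return bool(center[f"dow_{dow}"])


def access_profile(population: pd.DataFrame, centers: pd.DataFrame, spec: EnvironmentSpec) -> dict:
    """Precompute per-agent accessibility arrays used by the day loop.

    Returns a dict of numpy arrays over the n agents:

    - ``access`` (n,): objective accessibility (walk or drive).
    - ``class_day`` (n, 7): a reachable center holds a class that weekday.
    - ``geofence`` (n,): some center lies within the geofence of home.
    """
    n = len(population)
    home = population[["home_x", "home_y"]].to_numpy()
    if len(centers) == 0:
        return {
            "access": np.zeros(n, dtype=bool),
            "class_day": np.zeros((n, 7), dtype=bool),
            "geofence": np.zeros(n, dtype=bool),
        }
    d = _distances(home, centers)
    car = population["has_car"].to_numpy(dtype=bool)
    reach = np.where(car, spec.drive_reach_km, spec.walk_reach_km)[:, None]
    reachable = d <= reach  # (n, n_centers)
    sched = centers[[f"dow_{k}" for k in range(7)]].to_numpy(dtype=bool)  # (c, 7)
    return {
        "access": reachable.any(axis=1),
        "class_day": (reachable.astype(np.uint8) @ sched.astype(np.uint8)) > 0,
        "geofence": (d <= spec.geofence_miles * MILES_TO_KM).any(axis=1),
    }
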