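"""Place-tailored digital-health app: adoption cascade, attrition, prompts.

The app surfaces free recreation-center classes.  Its reach is the
product of a three-stage cascade — the share of women *aware* of the
app, the share of those aware who *download* it (smartphone required),
and the share of downloaders who opt into *push notifications*.  Only
notified users receive the app's two mechanisms:

- an evening prompt listing the next day's classes at reachable
  centers, which raises the class-awareness and preparedness gates;
- a geofence notification when a center lies within 0.5 miles of the
  user, which raises the perceived-accessibility gate.

Attrition is confined to the first 90 days after introduction: each
adopter either belongs to a retained core (probability ``r_inf``) or
discontinues at a churn time uniform on the attrition window; nobody
churns afterwards and nobody re-adopts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .environment import EnvironmentSpec, centers_within_geofence

__all__ = [
    "AppState",
    "EngagementTriple",
    "AttritionParams",
    "round_half_away",
    "engagement_cascade",
    "sample_app_states",
    "active_mask",
    "apply_attrition",
    "evening_prompt",
    "geofence_notify",
]


@dataclass
class AppState:
    """Per-agent adoption stage."""

    aware: bool = False
    downloaded: bool = False
    notifications_on: bool = False
    active: bool = False
    churn_day: int | None = None

    def __post_init__(self) -> None:
        if self.downloaded and not self.aware:
            raise ValueError("downloaded implies aware")
        if self.notifications_on and not self.downloaded:
            raise ValueError("notifications_on implies downloaded")
        if self.active and not self.downloaded:
            raise ValueError("active implies downloaded")
        if self.churn_day is not None and not 0 <= self.churn_day <= 90:
            raise ValueError("churn_day must lie within the 90-day attrition window")


@dataclass(frozen=True)
class EngagementTriple:
    """(aware, download | aware, notifications | download) proportions."""

    p_aware: float
    p_download: float
    p_notify: float

    def __post_init__(self) -> None:
        for name in ("p_aware", "p_download", "p_notify"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"EngagementTriple.{name} must be a probability")


@dataclass(frozen=True)
class AttritionParams:
    """Retention core ``r_inf`` and attrition window length in days."""

    r_inf: float = 0.3
    window_days: int = 90

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_inf <= 1.0:
            raise ValueError("AttritionParams.r_inf must be a probability")
        if self.window_days <= 0:
            raise ValueError("AttritionParams.window_days must be positive")


def round_half_away(x) -> np.ndarray | int:
    """Round half away from zero (the convention of the published counts)."""
    arr = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return int(arr) if np.ndim(x) == 0 else arr.astype(int)


def engagement_cascade(
    n: int,
    triple: EngagementTriple,
    mode: Literal["expected", "sampled"] = "expected",
    rng: np.random.Generator | None = None,
    has_smartphone: np.ndarray | None = None,
) -> tuple[int, int, int]:
    """Counts (n_aware, n_download, n_notify) of the adoption cascade.

    In ``expected`` mode each stage is the rounded product of the
    previous count and the stage proportion (round half away from
    zero), reproducing the published chains, e.g. 167,356 -> 41,839 ->
    10,460 -> 2,615 at 25%-25%-25%.  In ``sampled`` mode stages are
    sequential Bernoulli thinnings; download is restricted to
    smartphone owners when ``has_smartphone`` is given.
    """
    if n <= 0:
        raise ValueError("population count must be positive")
    if mode == "expected":
        n_aware = round_half_away(triple.p_aware * n)
        n_download = round_half_away(triple.p_download * n_aware)
        n_notify = round_half_away(triple.p_notify * n_download)
        return n_aware, n_download, n_notify
    if rng is None:
        raise ValueError("sampled mode requires an rng")
    aware = rng.random(n) < triple.p_aware
    eligible = aware if has_smartphone is None else aware & np.asarray(has_smartphone, bool)
    downloaded = eligible & (rng.random(n) < triple.p_download)
    notify = downloaded & (rng.random(n) < triple.p_notify)
    return int(aware.sum()), int(downloaded.sum()), int(notify.sum())


def sample_app_states(
    n: int,
    triple: EngagementTriple | None,
    attrition: AttritionParams,
    rng: np.random.Generator,
    has_smartphone: np.ndarray | None = None,
) -> dict:
    """Draw per-agent adoption flags and churn days for the day loop.

    Always consumes the same number of random draws (5 uniform vectors
    of length n) regardless of the triple, so that scenarios sharing a
    seed differ only in which thresholds the same uniforms cross: with
    ``triple=None`` or ``p_aware=0`` the result is exactly the no-app
    scenario, and every adoption set grows monotonically with each
    engagement component.

    Churn days are pre-drawn at adoption: with probability ``r_inf``
    the user is retained forever (churn_day = +inf); otherwise she
    discontinues at a day uniform on [0, window_days].
    """
    u_aware, u_down, u_notify, u_core, u_day = (rng.random(n) for _ in range(5))
    t = triple or EngagementTriple(0.0, 0.0, 0.0)
    aware = u_aware < t.p_aware
    eligible = aware if has_smartphone is None else aware & np.asarray(has_smartphone, bool)
    downloaded = eligible & (u_down < t.p_download)
    notifications = downloaded & (u_notify < t.p_notify)
    churn_day = np.where(u_core < attrition.r_inf, np.inf, u_day * attrition.window_days)
    return {
        "aware": aware,
        "downloaded": downloaded,
        "notifications": notifications,
        "churn_day": churn_day,
    }


def active_mask(states: dict, day_since_intro: float) -> np.ndarray:
    """Users still on the app: downloaded and not yet past their churn day."""
    return states["downloaded"] & (day_since_intro < states["churn_day"])


def apply_attrition(states: dict, day_since_intro: float) -> dict:
    """Return states with the ``active`` flag evaluated at the given day.

    Active fractions are non-increasing in ``day_since_intro`` and
    constant once the attrition window has fully elapsed.
    """
    if day_since_intro < 0:
        raise ValueError("day_since_intro must be non-negative")
    out = dict(states)
    out["active"] = active_mask(states, day_since_intro)
    return out


def evening_prompt(state: AppState, class_tomorrow_at_reachable_center: bool) -> bool:
    """Whether tonight's prompt fires (class selection for tomorrow).

    Only active users with notifications on are prompted, and only when
    some reachable center holds a class the next day.  A prompted agent
    uses the app-modified class-awareness and preparedness gates
    tomorrow.
    """
    return bool(
        state.active and state.notifications_on and class_tomorrow_at_reachable_center
    )


def geofence_notify(state: AppState, home_xy, centers: pd.DataFrame, spec: EnvironmentSpec) -> bool:
    """Whether the geofence notification fires for an agent today.

    True iff the agent is an active, notified user and some center lies
    within the geofence radius of home; raises the perceived-access
    gate to its app-modified value for the day.
    """
    if not (state.active and state.notifications_on):
        return False
    return len(centers_within_geofence(home_xy, centers, spec.geofence_miles)) > 0
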