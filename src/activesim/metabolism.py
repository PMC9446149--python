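"""Two-compartment energy-balance model of body-weight change.

Each agent's body is represented by a fat mass and a lean (fat-free) mass,
in kilograms.  A daily caloric imbalance (intake minus maintenance
expenditure minus class exercise) is partitioned between the two
compartments with a Forbes-type rule, in which the lean share of any
imbalance is ``c / (c + fat_mass)``, and converted to mass through the
energy densities of fat and lean tissue.  Maintenance expenditure is a
physical-activity-level multiple of a resting metabolic rate linear in
lean mass (Cunningham form), so that expenditure falls as weight is lost
and weight converges to a steady state under sustained exercise.

All functions accept scalars or numpy arrays and are used both on single
agents (tests, worked examples) and on whole populations (the simulation
engine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetabolicParams",
    "exercise_kcal",
    "total_expenditure",
    "update_composition",
    "bmi_and_category",
    "bmi_category",
]


@dataclass(frozen=True)
class MetabolicParams:
    """Constants of the energy-balance model.

    Parameters
    ----------
    rho_fat, rho_lean
        Energy density of fat and lean tissue, kcal per kg.
    forbes_c
        Forbes constant (kg): lean share of an imbalance is
        ``forbes_c / (forbes_c + fat_mass)``.
    rmr_slope, rmr_intercept
        Resting metabolic rate, kcal/day, linear in lean mass:
        ``RMR = rmr_slope * lean + rmr_intercept``.
    pal
        Physical-activity level multiplying RMR to give maintenance
        expenditure (class exercise is accounted separately).
    met_resting_subtracted
        If True (default), exercise energy uses net METs (MET - 1),
        since resting expenditure during class is already inside the
        PAL-scaled maintenance term.
    lean_floor, fat_floor
        Physiological floors (kg); mass updates never cross them.
    """

    rho_fat: float = 9440.0
    rho_lean: float = 1807.0
    forbes_c: float = 10.4
    rmr_slope: float = 19.7
    rmr_intercept: float = 413.0
    pal: float = 1.5
    met_resting_subtracted: bool = True
    lean_floor: float = 25.0
    fat_floor: float = 2.0

    def __post_init__(self) -> None:
        for name in ("rho_fat", "rho_lean", "pal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MetabolicParams.{name} must be strictly positive")


def exercise_kcal(weight, mets, minutes, params: MetabolicParams):
    """Energy expended in a class: kcal = (METs [- 1]) * kg * hours.

    Uses the standard convention 1 MET = 1 kcal per kg body weight per
    hour; with ``met_resting_subtracted`` the resting MET is removed so
    the value is the energy *added* by the class.
    """
    minutes = np.asarray(minutes, dtype=float)
    if np.any(minutes < 0):
        raise ValueError("minutes must be non-negative")
    effective = mets - 1.0 if params.met_resting_subtracted else mets
    out = effective * np.asarray(weight, dtype=float) * minutes / 60.0
    return float(out) if out.ndim == 0 else out


def total_expenditure(lean_mass, params: MetabolicParams):
    """Daily maintenance expenditure (kcal/day), excluding class exercise.

    TEE = PAL * (rmr_slope * lean + rmr_intercept); strictly increasing
    in lean mass whenever rmr_slope > 0.
    """
    lean = np.asarray(lean_mass, dtype=float)
    out = params.pal * (params.rmr_slope * lean + params.rmr_intercept)
    return float(out) if out.ndim == 0 else out


def update_composition(fat_mass, lean_mass, net_kcal, params: MetabolicParams):
    """Apply one day's net energy balance to the two compartments.

    The Forbes partition sends fraction ``p = c/(c + fat)`` of the
    imbalance to lean tissue and ``1 - p`` to fat, each converted to
    mass by its energy density.  Masses are floored at the configured
    physiological minima; any residual deficit is discarded.

    Returns ``(fat, lean)`` with the same shape as the inputs.
    """
    fat = np.asarray(fat_mass, dtype=float)
    lean = np.asarray(lean_mass, dtype=float)
    net = np.asarray(net_kcal, dtype=float)
    p = params.forbes_c / (params.forbes_c + fat)
    lean_new = np.maximum(lean + p * net / params.rho_lean, params.lean_floor)
    fat_new = np.maximum(fat + (1.0 - p) * net / params.rho_fat, params.fat_floor)
    if fat_new.ndim == 0:
        return float(fat_new), float(lean_new)
    return fat_new, lean_new


def bmi_category(bmi):
    """Classify BMI into 'normal_or_under', 'overweight' ([25, 30)) or 'obese' (>= 30).

    Overweight and obesity are disjoint; both boundaries are closed on
    the left.
    """
    b = np.asarray(bmi, dtype=float)
    cats = np.where(b >= 30.0, "obese", np.where(b >= 25.0, "overweight", "normal_or_under"))
    return str(cats) if cats.ndim == 0 else cats


def bmi_and_category(fat_mass, lean_mass, height):
    """BMI = (fat + lean) / height**2 and its weight category."""
    h = np.asarray(height, dtype=float)
    if np.any(h <= 0):
        raise ValueError("height must be strictly positive")
    bmi = (np.asarray(fat_mass, float) + np.asarray(lean_mass, float)) / h**2
    if bmi.ndim == 0:
        return float(bmi), bmi_category(float(bmi))
    return bmi, bmi_category(bmi)
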