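"""Peritoneal-surface geometry: body surface area and sub-surface counts.

The peritoneal surface area of a patient is well approximated by the body
surface area (BSA).  The model discretises the peritoneum into sub-surfaces
whose area equals that sampled by one biopsy (about 4 cm^2); the number of
sub-surfaces N is the ratio of the cohort-average peritoneal area to the
biopsy area.  The reference configuration uses 16,000 cm^2 and N = 4000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "SubSurfaceGrid",
    "body_surface_area",
    "peritoneal_area_from_bsa",
    "subsurface_count",
    "grid_from_areas",
    "BIOPSY_AREA_CM2",
    "REFERENCE_PERITONEAL_AREA_CM2",
]

#: Area sampled by a single peritoneal biopsy.
BIOPSY_AREA_CM2 = 4.0
#: Cohort-average peritoneal surface area pinned by the reference analysis.
REFERENCE_PERITONEAL_AREA_CM2 = 16_000.0

_BSA_FORMULAS = ("dubois", "mosteller")


@dataclass(frozen=True)
class SubSurfaceGrid:
    """Discretised peritoneum: N sub-surfaces of one-biopsy area each."""

    n_subsurfaces: int
    biopsy_area_cm2: float = BIOPSY_AREA_CM2
    peritoneal_area_cm2: float = REFERENCE_PERITONEAL_AREA_CM2

    def __post_init__(self) -> None:
        if self.n_subsurfaces < 1:
            raise ValueError("n_subsurfaces must be >= 1")
        if self.biopsy_area_cm2 <= 0 or self.peritoneal_area_cm2 <= 0:
            raise ValueError("areas must be positive")


def body_surface_area(height_cm: float, weight_kg: float, formula: str = "dubois") -> float:
    """Body surface area in m^2 from height (cm) and weight (kg).

    Du Bois:    0.007184 * W^0.425 * H^0.725
    Mosteller:  sqrt(H * W / 3600)
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "dubois":
        return 0.007184 * weight_kg**0.425 * height_cm**0.725
    if formula == "mosteller":
        return math.sqrt(height_cm * weight_kg / 3600.0)
    raise ValueError(f"unknown BSA formula {formula!r}; choose from {_BSA_FORMULAS}")


def peritoneal_area_from_bsa(bsa_m2: float) -> float:
    """Peritoneal surface area in cm^2, taking BSA as its estimate (unit change only)."""
    if bsa_m2 <= 0:
        raise ValueError("body surface area must be positive")
    return bsa_m2 * 1e4


def _round_sigfig(value: float, digits: int) -> float:
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    scale = 10.0 ** (exponent - digits + 1)
    # round-half-even, as in the reference rounding 16,500 -> 16,000
    return float(np.round(value / scale) * scale)


def subsurface_count(
    mean_peritoneal_area_cm2: float,
    biopsy_area_cm2: float = BIOPSY_AREA_CM2,
    rounding: str = "sigfig2",
) -> int:
    """Number of sub-surfaces N = rounded(mean peritoneal area / biopsy area).

    ``rounding`` controls the pre-rounding of the area before division:
    "sigfig2" rounds the area to two significant figures (16,500 -> 16,000,
    reproducing the reference N = 4000), "none" divides directly.  The final
    ratio is rounded to the nearest integer.
    """
    if mean_peritoneal_area_cm2 <= 0 or biopsy_area_cm2 <= 0:
        raise ValueError("areas must be positive")
    if rounding == "sigfig2":
        area = _round_sigfig(mean_peritoneal_area_cm2, 2)
    elif rounding == "none":
        area = mean_peritoneal_area_cm2
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    n = int(round(area / biopsy_area_cm2))
    return max(n, 1)


def grid_from_areas(
    heights_cm: Iterable[float],
    weights_kg: Iterable[float],
    biopsy_area_cm2: float = BIOPSY_AREA_CM2,
    formula: str = "dubois",
    rounding: str = "sigfig2",
) -> SubSurfaceGrid:
    """Build a sub-surface grid from cohort body measurements (data mode)."""
    areas = [
        peritoneal_area_from_bsa(body_surface_area(h, w, formula))
        for h, w in zip(heights_cm, weights_kg, strict=True)
    ]
    if not areas:
        raise ValueError("no body measurements supplied")
    mean_area = float(np.mean(areas))
    return SubSurfaceGrid(
        n_subsurfaces=subsurface_count(mean_area, biopsy_area_cm2, rounding),
        biopsy_area_cm2=biopsy_area_cm2,
        peritoneal_area_cm2=mean_area,
    )
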