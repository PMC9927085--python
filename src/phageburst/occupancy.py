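"""Poisson limiting-dilution math for the 96-well single-cell assay design.

Diluting an induced culture so that each well receives on average λ << 1
cells makes well occupancy Poisson: most wells are empty, most occupied wells
hold a single cell, and a small, predictable fraction holds two or more.
These helpers give the forward design numbers (expected empty wells,
multi-cell probabilities) and the inverse zero-class estimate of λ from an
observed empty-well count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PlateDesign",
    "OccupancyError",
    "p_cells",
    "percent_wells",
    "expected_empty",
    "occupancy_from_empty",
    "multi_cell_fraction",
]


class OccupancyError(ValueError):
    """Invalid occupancy arguments (negative counts/rates, no empty wells)."""


@dataclass(frozen=True)
class PlateDesign:
    """Limiting-dilution plate geometry: well count and mean cells/well (λ)."""

    n_wells: int = 96
    mean_occupancy: float = 0.25

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise OccupancyError(f"n_wells must be >= 1, got {self.n_wells}")
        if not (np.isfinite(self.mean_occupancy) and self.mean_occupancy >= 0):
            raise OccupancyError(
                f"mean_occupancy must be >= 0, got {self.mean_occupancy}"
            )


def p_cells(k: int, mean_occupancy: float) -> float:
    """Poisson probability that a well receives exactly ``k`` cells."""
    if k < 0 or int(k) != k:
        raise OccupancyError(f"k must be a nonnegative integer, got {k}")
    if not (np.isfinite(mean_occupancy) and mean_occupancy >= 0):
        raise OccupancyError(f"mean_occupancy must be >= 0, got {mean_occupancy}")
    return float(stats.poisson.pmf(int(k), mean_occupancy))


def percent_wells(k: int, mean_occupancy: float) -> int:
    """Nearest-integer percent of wells receiving exactly ``k`` cells."""
    return round(100.0 * p_cells(k, mean_occupancy))


def expected_empty(design: PlateDesign) -> float:
    """Expected number of empty wells, ``n_wells * e^{-λ}`` (not rounded).

    Integer presentations floor this value.
    """
    return design.n_wells * math.exp(-design.mean_occupancy)


def occupancy_from_empty(n_empty: int, n_wells: int) -> float:
    """Zero-class Poisson estimate of mean cells/well from empty-well counts.

    Returns ``-ln(n_empty / n_wells)``.  A plate with no empty wells carries
    no information about λ under this estimator and raises.
    """
    if n_wells < 1 or n_empty < 0 or n_empty > n_wells:
        raise OccupancyError(
            f"need 0 <= n_empty <= n_wells, got n_empty={n_empty}, n_wells={n_wells}"
        )
    if n_empty == 0:
        raise OccupancyError("no empty wells: occupancy unestimable by zero class")
    return -math.log(n_empty / n_wells)


def multi_cell_fraction(mean_occupancy: float) -> float:
    """P(N >= 2 | N >= 1): fraction of occupied wells holding multiple cells."""
    if mean_occupancy <= 0:
        return 0.0
    p_occ = -math.expm1(-mean_occupancy)
    p_one = mean_occupancy * math.exp(-mean_occupancy)
    return (p_occ - p_one) / p_occ
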