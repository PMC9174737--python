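"""Uniform age grids and trapezoid quadrature helpers.

All schedules and densities in the package live on one uniform grid in age
(and, for mother densities, the same grid in time-since-last-birth tau).
Integrals are trapezoid sums on that grid; a rate is interpreted as
piecewise linear between nodes and zero beyond the last node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

DEFAULT_A_MAX = 110.0
DEFAULT_STEP = 0.1


@dataclass(frozen=True)
class AgeGrid:
    """Uniform grid of ages 0, step, 2*step, ..., a_max_grid (inclusive).

    Parameters
    ----------
    a_max_grid:
        Maximum tabulated age in years.  Densities are treated as zero
        beyond this age; individuals surviving past it are removed.
    step:
        Grid spacing in years.  The forward integrator uses the same value
        for its time step, so `step` controls both age resolution and
        temporal resolution.
    """

    a_max_grid: float = DEFAULT_A_MAX
    step: float = DEFAULT_STEP

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be positive, got {self.step}")
        if self.a_max_grid <= 0:
            raise ValueError(f"a_max_grid must be positive, got {self.a_max_grid}")

    @property
    def n(self) -> int:
        """Number of nodes."""
        return int(round(self.a_max_grid / self.step)) + 1

    @property
    def nodes(self) -> np.ndarray:
        return np.arange(self.n) * self.step

    def index_of(self, age: float) -> int:
        """Nearest grid index for `age` (the snap used for delta, a_min...)."""
        if not np.isfinite(age):
            raise ValueError(f"cannot snap non-finite age {age}")
        idx = int(round(age / self.step))
        return min(max(idx, 0), self.n - 1)

    def snap(self, age: float) -> float:
        """`age` rounded to the nearest grid node value."""
        return self.index_of(age) * self.step

    # --- quadrature -----------------------------------------------------

    def trapz(self, values: np.ndarray) -> float:
        """Trapezoid integral of nodal values over the full grid."""
        return float(np.trapezoid(values, dx=self.step))

    def cumtrapz(self, values: np.ndarray) -> np.ndarray:
        """Cumulative trapezoid integral from age 0 (same length as input)."""
        return cumulative_trapezoid(values, dx=self.step, initial=0.0)

    def compatible(self, other: "AgeGrid") -> bool:
        return (
            abs(self.step - other.step) < 1e-12
            and abs(self.a_max_grid - other.a_max_grid) < 1e-9
        )


def require_same_grid(*grids: AgeGrid) -> AgeGrid:
    first = grids[0]
    for g in grids[1:]:
        if not first.compatible(g):
            raise ValueError(f"schedules on incompatible grids: {first} vs {g}")
    return first
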