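"""Discoid aggregate ("pressuroid") geometry bookkeeping.

The acoustic trap confines an aggregate axially: once the volume of packed
cells exceeds the sphere that fits under the height cap h_max, further growth
is radial only, yielding a disc of height h_max.  The model is volumetric
bookkeeping with a packing fraction phi; no compaction dynamics, surface
tension or deformation is represented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .field import StandingWaveField
from .medium import Medium
from .stability import confinement_band

__all__ = [
    "AggregateGeometry",
    "predict_geometry",
    "estimate_cell_count",
    "cap_height_from_field",
]

#: Dense-packing default for cells in a compacted aggregate.
DEFAULT_PACKING_FRACTION = 0.74
#: Observed mean aggregate height used as the default axial cap (m).
DEFAULT_HEIGHT_CAP = 200e-6


@dataclass(frozen=True)
class AggregateGeometry:
    """Shape and dimensions of a cell aggregate.

    ``shape`` is "sphere" (height == diameter) or "disc" (height < diameter,
    capped by the trap).  Cell-volume accounting holds to within one cell:
    cell_count * (pi/6) d_cell^3 ~= phi * aggregate volume.
    """

    shape: str
    diameter: float
    height: float
    cell_count: int
    packing_fraction: float
    cell_diameter: float

    @property
    def volume(self) -> float:
        if self.shape == "sphere":
            return (np.pi / 6.0) * self.diameter**3
        return (np.pi / 4.0) * self.diameter**2 * self.height

    @property
    def aspect_ratio(self) -> float:
        return self.diameter / self.height


def _validate(cell_diameter: float, phi: float) -> None:
    if cell_diameter <= 0:
        raise InvalidParameterError("cell diameter must be > 0")
    if not (0 < phi <= 1):
        raise InvalidParameterError("packing fraction must be in (0, 1]")


def predict_geometry(
    cell_count: int,
    cell_diameter: float = 30e-6,
    phi: float = DEFAULT_PACKING_FRACTION,
    h_max: float = DEFAULT_HEIGHT_CAP,
) -> AggregateGeometry:
    """Aggregate shape for a given cell count under an axial height cap.

    The packed volume is V = cell_count (pi/6) d_cell^3 / phi.  While the
    equivalent sphere fits under h_max the aggregate is a sphere; past the
    cap it is a disc of height h_max and diameter sqrt(4V / (pi h_max)),
    continuous at the transition.
    """
    if cell_count < 1:
        raise InvalidParameterError("cell count must be >= 1")
    _validate(cell_diameter, phi)
    if h_max <= 0:
        raise InvalidParameterError("height cap must be > 0")
    volume = cell_count * (np.pi / 6.0) * cell_diameter**3 / phi
    d_eq = (6.0 * volume / np.pi) ** (1.0 / 3.0)
    if d_eq <= h_max:
        return AggregateGeometry(
            "sphere", d_eq, d_eq, int(cell_count), phi, cell_diameter
        )
    diameter = float(np.sqrt(4.0 * volume / (np.pi * h_max)))
    return AggregateGeometry(
        "disc", diameter, h_max, int(cell_count), phi, cell_diameter
    )


def estimate_cell_count(
    diameter: float,
    height: float,
    cell_diameter: float = 30e-6,
    phi: float = DEFAULT_PACKING_FRACTION,
) -> int:
    """Cells in a disc of given diameter and height (inverse of prediction).

    Round-trips with :func:`predict_geometry` to within one cell.  A zero
    height maps to zero cells; the count is linear in height.
    """
    if diameter < 0 or height < 0:
        raise InvalidParameterError("dimensions must be >= 0")
    _validate(cell_diameter, phi)
    disc_volume = (np.pi / 4.0) * diameter**2 * height
    cell_volume = (np.pi / 6.0) * cell_diameter**3
    return int(round(phi * disc_volume / cell_volume))


def cap_height_from_field(
    field: StandingWaveField, medium: Medium, stress_threshold: float
) -> float:
    """Full axial thickness tolerated below a pressure threshold at a node.

    Twice the axial confinement half-band on the axis: the aggregate can span
    the region either side of the node where the local amplitude stays below
    ``stress_threshold``.
    """
    return 2.0 * confinement_band(field, stress_threshold, r=0.0)
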