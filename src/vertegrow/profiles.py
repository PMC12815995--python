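"""Per-physis growth profiles measured along the antero-posterior width.

Fluorochrome pulsed labeling leaves two mineralization fronts in the growth
plate; the distance between them divided by the labeling interval is the
local longitudinal growth rate.  A :class:`PhysisProfile` holds that
measurement at a set of AP stations (x = 0 at the anterior edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import UM_PER_MM

__all__ = ["PhysisProfile", "station_positions", "normalized_positions"]


def station_positions(n_stations: int, width_mm: float) -> np.ndarray:
    """Midpoints of ``n_stations`` equal cells tiling ``[0, width_mm]``."""
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    h = width_mm / n_stations
    return (np.arange(n_stations) + 0.5) * h


def normalized_positions(positions) -> np.ndarray:
    """Rank-normalize station positions onto [0, 1] (anterior -> posterior)."""
    x = np.asarray(positions, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two stations")
    span = x[-1] - x[0]
    if span <= 0:
        raise ValueError("positions must be strictly increasing")
    return (x - x[0]) / span


@dataclass
class PhysisProfile:
    """Growth measured along one physis.

    Attributes
    ----------
    positions
        Station x-coordinates in mm, strictly increasing; 0 is the anterior
        edge of the vertebra.
    label_distance
        Distance between the two fluorochrome labels at each station, mm.
    growth_rate
        Local growth rate at each station, µm/day.  Always equal to
        ``1000 * label_distance / interval_days``.
    interval_days
        Days between the two label administrations.
    vertebra, side
        Optional tags locating the physis: vertebra identifier and
        "proximal" / "distal" face.
    """

    positions: np.ndarray
    label_distance: np.ndarray
    growth_rate: np.ndarray
    interval_days: float = 13.0
    vertebra: str = ""
    side: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.label_distance = np.asarray(self.label_distance, dtype=float)
        self.growth_rate = np.asarray(self.growth_rate, dtype=float)
        if not (
            self.positions.shape
            == self.label_distance.shape
            == self.growth_rate.shape
        ):
            raise ValueError("positions, label_distance, growth_rate must align")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.label_distance < 0):
            raise ValueError("label distances must be non-negative")
        if self.interval_days <= 0:
            raise ValueError("labeling interval must be positive")

    @classmethod
    def from_rates(
        cls,
        positions,
        growth_rate,
        interval_days: float = 13.0,
        vertebra: str = "",
        side: str = "",
    ) -> "PhysisProfile":
        """Build a profile from rates, deriving consistent label distances."""
        rate = np.asarray(growth_rate, dtype=float)
        dist = rate * interval_days / UM_PER_MM
        return cls(
            positions=np.asarray(positions, dtype=float),
            label_distance=dist,
            growth_rate=rate,
            interval_days=interval_days,
            vertebra=vertebra,
            side=side,
        )

    @property
    def n_stations(self) -> int:
        return int(self.positions.size)

    def normalized(self) -> np.ndarray:
        return normalized_positions(self.positions)

    def summed_with(self, other: "PhysisProfile") -> "PhysisProfile":
        """Element-wise sum of two physes measured on the same station grid.

        Used both for apical-vertebra rates (proximal + distal physis of one
        vertebra) and for tethered-space rates (the two physes facing one
        tethered disc).
        """
        if self.n_stations != other.n_stations or not np.allclose(
            self.positions, other.positions
        ):
            raise ValueError("profiles must share the same station grid")
        return PhysisProfile(
            positions=self.positions.copy(),
            label_distance=self.label_distance + other.label_distance,
            growth_rate=self.growth_rate + other.growth_rate,
            interval_days=self.interval_days,
            vertebra=f"{self.vertebra}+{other.vertebra}",
            side="summed",
        )
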