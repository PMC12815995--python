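"""Antero-posterior region schemes for the vertebral physis.

A scheme partitions the normalized AP width of the endplate, x/width in
[0, 1] with 0 at the anterior edge, into contiguous regions.  The default
quarters-half-quarters scheme is anatomical: the annulus fibrosus attaches
over roughly the outer quarter of the vertebral width at each end, while the
nucleus pulposus sits over the central half, so tether load is transmitted
to the growth plate differently in each zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionScheme",
    "QUARTERS",
    "THIRDS",
    "HALVES",
    "FOURTHS",
    "NAMED_SCHEMES",
]


@dataclass(frozen=True)
class RegionScheme:
    """A partition of the normalized AP width into labelled regions.

    Parameters
    ----------
    boundaries
        Interior breakpoints, strictly increasing fractions in (0, 1).
    labels
        One label per region (``len(boundaries) + 1``).  The first region is
        the anterior one, the last the posterior one.
    """

    boundaries: tuple = field(default_factory=tuple)
    labels: tuple = field(default_factory=tuple)

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries)
        if any(not (0.0 < x < 1.0) for x in b):
            raise ValueError("scheme boundaries must lie strictly in (0, 1)")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("scheme boundaries must be strictly increasing")
        labels = tuple(str(s) for s in self.labels)
        if len(labels) != len(b) + 1:
            raise ValueError(
                f"need {len(b) + 1} region labels, got {len(labels)}"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "labels", labels)

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def edges(self) -> np.ndarray:
        """Region edges including 0 and 1."""
        return np.concatenate(([0.0], self.boundaries, [1.0]))

    def assign(self, u) -> np.ndarray:
        """Region index for each normalized position in [0, 1].

        Regions are half-open ``[lo, hi)``; the last region is closed at 1
        so every station has exactly one region.
        """
        u = np.asarray(u, dtype=float)
        if np.any(u < 0.0) or np.any(u > 1.0):
            raise ValueError("normalized positions must lie in [0, 1]")
        idx = np.searchsorted(self.edges, u, side="right") - 1
        return np.clip(idx, 0, self.n_regions - 1)

    @property
    def anterior_label(self) -> str:
        return self.labels[0]

    @property
    def posterior_label(self) -> str:
        return self.labels[-1]


#: Anatomical default: anterior 1/4 (annulus), middle 1/2 (nucleus),
#: posterior 1/4 (annulus).
QUARTERS = RegionScheme((0.25, 0.75), ("anterior", "middle", "posterior"))
THIRDS = RegionScheme((1 / 3, 2 / 3), ("anterior", "middle", "posterior"))
HALVES = RegionScheme((0.5,), ("anterior", "posterior"))
FOURTHS = RegionScheme(
    (0.25, 0.5, 0.75),
    ("anterior", "mid_anterior", "mid_posterior", "posterior"),
)

NAMED_SCHEMES = {
    "quarters": QUARTERS,
    "thirds": THIRDS,
    "halves": HALVES,
    "fourths": FOURTHS,
}
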