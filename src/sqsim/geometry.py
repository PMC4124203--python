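"""Periodic simulation box and striped surface-energy patterns.

All lengths are expressed in units of the particle hard-core diameter ``d``.
The simulation box is the half-open square ``[0, L) x [0, L)`` with periodic
boundaries; pair separations are always measured with the minimum-image
convention, so the largest meaningful separation along each axis is ``L/2``.

The surface is partitioned into vertical stripes (bands parallel to the
*y*-axis).  Each stripe carries a surface-energy factor ``U`` that rescales
the pair-potential well depth for a particle moving inside that stripe:
small ``U`` means strong attraction (a favorable, e.g. laser-ablated,
region), large ``U`` means weak attraction (e.g. a polymer-passivated
region).  The default pattern is three equal-width stripes R1 | R2 | R3 with
factors ``U1, U2, U1`` — two favorable outer bands flanking a passivated
center band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Box",
    "RegionPattern",
    "region_of",
    "minimum_image_displacement",
]


@dataclass(frozen=True)
class Box:
    """Square periodic simulation box with side ``side_length`` (units of d)."""

    side_length: float = 20.0
    periodic_x: bool = True
    periodic_y: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.side_length) or self.side_length <= 0:
            raise ValueError(f"side_length must be positive, got {self.side_length}")

    @property
    def area(self) -> float:
        return self.side_length**2

    def wrap(self, points: np.ndarray) -> np.ndarray:
        """Wrap coordinates into [0, L) along each periodic axis.

        Idempotent: wrapping twice equals wrapping once.  On a non-periodic
        axis coordinates must already lie inside the box.
        """
        pts = np.asarray(points, dtype=float)
        out = pts.copy()
        L = self.side_length
        periodic = (self.periodic_x, self.periodic_y)
        for axis in (0, 1):
            coord = out[..., axis]
            if periodic[axis]:
                coord = coord - L * np.floor(coord / L)
                # floor can leave exactly L for inputs a hair below 0
                coord = np.where(coord >= L, coord - L, coord)
                out[..., axis] = coord
            elif np.any((coord < 0) | (coord >= L)):
                raise ValueError(f"coordinate outside non-periodic axis {axis}")
        return out

    def minimum_image(self, p1: np.ndarray, p2: np.ndarray) -> tuple[np.ndarray, float | np.ndarray]:
        """Displacement ``p2 - p1`` folded to the nearest periodic image.

        Returns ``(displacement, distance)``.  Each displacement component
        has magnitude at most ``L/2`` on periodic axes.
        """
        d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
        d = d.copy()
        L = self.side_length
        if self.periodic_x:
            d[..., 0] = d[..., 0] - L * np.round(d[..., 0] / L)
        if self.periodic_y:
            d[..., 1] = d[..., 1] - L * np.round(d[..., 1] / L)
        dist = np.sqrt(d[..., 0] ** 2 + d[..., 1] ** 2)
        return d, dist


@dataclass(frozen=True)
class RegionPattern:
    """Partition of the box into labeled vertical stripes with energy factors.

    Parameters
    ----------
    labels : sequence of str
        Stripe names, left to right.
    fractions : sequence of float
        Stripe widths as fractions of the box side; must be positive and sum
        to 1 (covering ``[0, L)`` with no gaps or overlaps).
    factors : sequence of float
        Surface-energy factor ``U`` per stripe; strictly positive and finite.
        The pair-well depth for a particle inside the stripe is ``epsilon/U``.
    """

    labels: tuple[str, ...] = ("R1", "R2", "R3")
    fractions: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    factors: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(self, "fractions", tuple(float(x) for x in self.fractions))
        object.__setattr__(self, "factors", tuple(float(x) for x in self.factors))
        if not (len(self.labels) == len(self.fractions) == len(self.factors)):
            raise ValueError("labels, fractions and factors must have equal length")
        if len(self.labels) == 0:
            raise ValueError("pattern must contain at least one stripe")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("stripe width fractions must be strictly positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"stripe fractions must sum to 1, got {sum(self.fractions)}")
        if any((not np.isfinite(u)) or u <= 0 for u in self.factors):
            raise ValueError("energy factors must be strictly positive and finite")

    @classmethod
    def equal_thirds(cls, u1: float = 1.0, u2: float = 1.0) -> "RegionPattern":
        """The default R1 | R2 | R3 pattern: equal thirds, outer factor ``u1``,
        center factor ``u2``."""
        return cls(("R1", "R2", "R3"), (1 / 3, 1 / 3, 1 / 3), (u1, u2, u1))

    @classmethod
    def uniform(cls, u: float = 1.0) -> "RegionPattern":
        """A homogeneous (single-stripe) surface with factor ``u``."""
        return cls(("R1",), (1.0,), (u,))

    def n_regions(self) -> int:
        return len(self.labels)

    def upper_edges(self, box: Box) -> np.ndarray:
        """Absolute x-coordinates of stripe upper boundaries; last edge is L."""
        edges = np.cumsum(self.fractions) * box.side_length
        edges[-1] = box.side_length  # exact, immune to cumsum rounding
        return edges

    def region_index(self, x, box: Box):
        """Stripe index for x-coordinate(s) in ``[0, L)`` (vectorized)."""
        edges = self.upper_edges(box)
        idx = np.searchsorted(edges, np.asarray(x, dtype=float), side="right")
        idx = np.minimum(idx, len(edges) - 1)
        if np.any((np.asarray(x) < 0) | (np.asarray(x) >= box.side_length)):
            raise ValueError("x outside [0, L); wrap positions before region lookup")
        return idx if np.ndim(x) else int(idx)

    def region_of(self, position, box: Box) -> tuple[str, float]:
        """Label and energy factor of the stripe containing ``position``."""
        x = np.asarray(position, dtype=float)[..., 0]
        i = self.region_index(float(x), box)
        return self.labels[i], self.factors[i]

    def area_fractions(self) -> dict[str, float]:
        """Area fraction per label (labels may repeat across stripes)."""
        out: dict[str, float] = {}
        for lab, frac in zip(self.labels, self.fractions):
            out[lab] = out.get(lab, 0.0) + frac
        return out

    def factor_of_label(self, label: str) -> float:
        for lab, u in zip(self.labels, self.factors):
            if lab == label:
                return u
        raise KeyError(label)

    def as_triples(self) -> list[tuple[str, float, float]]:
        """(label, width-fraction, factor) triples, the config-file form."""
        return [
            (lab, frac, u)
            for lab, frac, u in zip(self.labels, self.fractions, self.factors)
        ]


def region_of(position, pattern: RegionPattern, box: Box) -> tuple[str, float]:
    """Stripe label and energy factor at ``position`` (must be wrapped)."""
    return pattern.region_of(position, box)


def minimum_image_displacement(p1, p2, box: Box) -> tuple[np.ndarray, float]:
    """Minimum-image displacement ``p2 - p1`` and its Euclidean norm."""
    d, r = box.minimum_image(p1, p2)
    return d, float(r) if np.ndim(r) == 0 else r
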