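"""Region-scaled triangular-well pair potential.

The pair energy between two adsorbed hard disks a distance ``r`` apart is

    u(r) = +inf                                   r < d        (hard core)
    u(r) = -(eps/U) * (lam*d - r) / (lam*d - d)   d <= r <= lam*d
    u(r) = 0                                      r > lam*d

i.e. a linear (triangular) attractive well running from depth ``eps/U`` at
contact to zero at the cutoff ``lam*d``.  ``U`` is the surface-energy factor
of the region the *moving* particle currently occupies, so the same pair is
bound more deeply while the mobile particle sits on a favorable (small-``U``)
stripe.  Energies are reported in units of ``eps``; with reduced temperature
``T* = kT/eps`` the Boltzmann exponent of an energy ``E`` is ``E / (T* eps)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Box, RegionPattern

__all__ = ["PotentialParams", "pair_energy", "particle_energy"]


@dataclass(frozen=True)
class PotentialParams:
    """Parameters of the triangular-well potential and the thermal scale.

    Attributes
    ----------
    diameter : float
        Hard-core diameter ``d``; the unit of length (default 1).
    lambda_factor : float
        Well-range multiplier ``lam > 1``; the attractive well spans
        ``[d, lam*d]`` so its width is ``(lam - 1) d`` (0.5 d at the
        default ``lam = 1.5``).
    epsilon : float
        Well-depth scale; the unit of energy (default 1).
    reduced_temperature : float
        ``T* = kT/eps`` (default 1.0).
    """

    diameter: float = 1.0
    lambda_factor: float = 1.5
    epsilon: float = 1.0
    reduced_temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.lambda_factor <= 1:
            raise ValueError("lambda_factor must exceed 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.reduced_temperature <= 0:
            raise ValueError("reduced_temperature must be positive")

    @property
    def cutoff(self) -> float:
        """Interaction range ``lam * d``."""
        return self.lambda_factor * self.diameter

    @property
    def well_width(self) -> float:
        return (self.lambda_factor - 1.0) * self.diameter

    @property
    def thermal_energy(self) -> float:
        """kT in units of the energy scale: ``T* * eps``."""
        return self.reduced_temperature * self.epsilon


def pair_energy(r, factor_u: float, params: PotentialParams = PotentialParams()):
    """Triangular-well pair energy at separation ``r`` (vectorized over r).

    ``factor_u`` divides the depth scale: the well runs linearly from
    ``-eps/factor_u`` at contact ``r = d`` to zero at the cutoff ``lam*d``.
    Returns ``+inf`` inside the hard core ``r < d``.
    """
    if not np.isfinite(factor_u) or factor_u <= 0:
        raise ValueError(f"energy factor U must be strictly positive, got {factor_u}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be non-negative")
    d = params.diameter
    lam_d = params.lambda_factor * d
    depth = params.epsilon / factor_u
    well = -depth * (lam_d - r) / (lam_d - d)
    out = np.where(r < d, np.inf, np.where(r <= lam_d, well, 0.0))
    return float(out) if out.ndim == 0 else out


def particle_energy(
    position,
    others,
    pattern: RegionPattern,
    box: Box,
    params: PotentialParams = PotentialParams(),
) -> float:
    """Interaction energy of a particle at ``position`` with all quenched
    particles in ``others`` (minimum-image distances).

    The well-depth factor ``U`` is taken from the region of ``position``
    itself — the moving particle's location — so crossing a stripe boundary
    rescales every pair term at once.  Returns ``+inf`` if any minimum-image
    distance is below the hard-core diameter.  Terms are accumulated in the
    order the quenched particles are stored.
    """
    others = np.asarray(others, dtype=float).reshape(-1, 2)
    if others.shape[0] == 0:
        return 0.0
    pos = np.asarray(position, dtype=float).reshape(2)
    _, factor_u = pattern.region_of(pos, box)

    L = box.side_length
    d = params.diameter
    lam_d = params.lambda_factor * d
    inv_u = params.epsilon / factor_u
    denom = lam_d - d

    total = 0.0
    for j in range(others.shape[0]):
        dx = pos[0] - others[j, 0]
        dy = pos[1] - others[j, 1]
        dx = dx - L * round(dx / L)
        dy = dy - L * round(dy / L)
        r = math.sqrt(dx * dx + dy * dy)
        if r < d:
            return math.inf
        if r <= lam_d:
            total += -inv_u * (lam_d - r) / denom
    return total
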