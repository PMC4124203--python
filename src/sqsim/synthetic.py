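"""Synthetic configurations and independent reference computations.

Everything here exists so the simulator and its analysis stage can be
validated without trusting the code paths they exercise: ideal-gas (fully
random) point sets with known flat structure, square lattices with known
peak positions, a brute-force pair-energy sum, and the exact Boltzmann
distribution on a discretized landscape.  The reference implementations
deliberately share no helpers with the production modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import Configuration
from .geometry import Box, RegionPattern
from .potential import PotentialParams

__all__ = [
    "SyntheticEnsemble",
    "ideal_gas_ensemble",
    "lattice_configuration",
    "brute_force_energy",
    "boltzmann_reference",
]


@dataclass
class SyntheticEnsemble:
    """A reproducible generated ensemble: (generator, parameters, seed)."""

    generator: str
    parameters: dict
    seed: int
    configurations: list = field(default_factory=list)


def _labels_for(pos: np.ndarray, pattern: RegionPattern | None, box: Box) -> np.ndarray:
    if pattern is None:
        return np.full(pos.shape[0], "", dtype=object).astype(str)
    idx = pattern.region_index(pos[:, 0], box)
    return np.asarray(pattern.labels, dtype=object)[idx].astype(str)


def ideal_gas_ensemble(
    n_particles: int,
    box: Box,
    n_configs: int,
    seed: int = 0,
    pattern: RegionPattern | None = None,
) -> SyntheticEnsemble:
    """Uniformly random points with no hard core (ideal-gas reference).

    By construction its radial distribution function is flat (g = 1) up to
    sampling noise, which calibrates the RDF normalization.
    """
    if n_particles < 1 or n_configs < 1:
        raise ValueError("n_particles and n_configs must be at least 1")
    rng = np.random.default_rng(seed)
    configs = []
    for k in range(n_configs):
        pos = rng.random((n_particles, 2)) * box.side_length
        configs.append(
            Configuration(
                positions=pos,
                region_labels=_labels_for(pos, pattern, box),
                energies=np.full(n_particles, np.nan),
                seed=seed,
            )
        )
    return SyntheticEnsemble(
        generator="ideal_gas",
        parameters={"n_particles": n_particles, "n_configs": n_configs,
                    "side_length": box.side_length},
        seed=seed,
        configurations=configs,
    )


def lattice_configuration(
    spacing: float,
    box: Box,
    pattern: RegionPattern | None = None,
) -> Configuration:
    """Square lattice of points with period ``spacing``.

    The pair-distance spectrum is known in closed form (spacing,
    spacing*sqrt(2), 2*spacing, ...), which pins RDF peak positions exactly.
    Requires the box side to be an integer multiple of the spacing so the
    lattice tiles the periodic box.
    """
    if spacing < 1.0:
        raise ValueError("spacing below the hard-core diameter would overlap")
    ratio = box.side_length / spacing
    m = round(ratio)
    if abs(ratio - m) > 1e-9 or m < 1:
        raise ValueError(
            f"box side {box.side_length} is not an integer multiple of spacing {spacing}"
        )
    coords = spacing * np.arange(m)
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    pos = np.column_stack([xx.ravel(), yy.ravel()])
    return Configuration(
        positions=pos,
        region_labels=_labels_for(pos, pattern, box),
        energies=np.zeros(pos.shape[0]),
        seed=0,
    )


def brute_force_energy(
    position,
    others,
    pattern: RegionPattern,
    box: Box,
    params: PotentialParams = PotentialParams(),
) -> float:
    """Plain double-checkable pair-energy sum: the oracle for particle_energy.

    Independent re-implementation: its own minimum-image fold, its own
    piecewise well evaluation, term-by-term accumulation in storage order.
    """
    x, y = float(position[0]), float(position[1])
    others = np.asarray(others, dtype=float).reshape(-1, 2)
    L = box.side_length
    d = params.diameter
    lam_d = params.lambda_factor * d

    # region factor of the evaluated particle's own position
    edges = np.cumsum(pattern.fractions) * L
    edges[-1] = L
    region = len(edges) - 1
    for i in range(len(edges) - 1):
        if x < edges[i]:
            region = i
            break
    inv_u = params.epsilon / pattern.factors[region]

    total = 0.0
    for j in range(others.shape[0]):
        dx = x - others[j, 0]
        dy = y - others[j, 1]
        dx = dx - L * round(dx / L)
        dy = dy - L * round(dy / L)
        r = math.sqrt(dx * dx + dy * dy)
        if r < d:
            return math.inf
        if r <= lam_d:
            total += -inv_u * (lam_d - r) / (lam_d - d)
    return total


def boltzmann_reference(energies, reduced_temperature: float = 1.0) -> np.ndarray:
    """Normalized Boltzmann weights exp(-E / T*) over a discrete landscape.

    Infinite energies (hard-core cells) get probability zero.  This is the
    target stationary distribution for the Metropolis kernel tests.
    """
    if reduced_temperature <= 0:
        raise ValueError("reduced_temperature must be positive")
    e = np.asarray(energies, dtype=float)
    if not np.any(np.isfinite(e)):
        raise ValueError("landscape has no finite-energy cell")
    shift = np.min(e[np.isfinite(e)])  # stabilize exp for deep wells
    with np.errstate(over="ignore"):
        w = np.where(np.isfinite(e), np.exp(-(e - shift) / reduced_temperature), 0.0)
    return w / w.sum()
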