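"""Sequential-quenching (SQ) adsorption protocol.

The SQ model extends random sequential adsorption with a surface-diffusion
step: particles arrive one at a time at uniformly random positions (re-drawn
on hard-core overlap with previously quenched particles), the newcomer then
performs a fixed budget of Metropolis moves among its frozen predecessors,
and is finally quenched in place forever.  Insertions continue until the
reduced number density ``rho* = rho d^2`` reaches its target, i.e. until
``round(rho* L^2 / d^2)`` particles are on the surface.  Only the newest
particle is ever mobile; there is no desorption and no collective
relaxation.

Trial moves displace the particle by independent per-axis offsets uniform in
``[-max_disp, +max_disp]`` (a symmetric proposal), and are accepted with the
Metropolis probability ``min(1, exp(-dE / kT))`` where ``dE`` is the change
in the particle's total pair energy, region factor included.  Rejected moves
leave the position unchanged and still count against the move budget.

:func:`run_realization` executes the whole protocol through a compiled
kernel; :func:`attempt_insertion`, :func:`metropolis_step` and
:func:`diffuse_and_quench` are pure-Python implementations of the individual
protocol steps, usable for inspection and step-by-step experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .geometry import Box, RegionPattern
from .potential import PotentialParams, particle_energy

__all__ = [
    "SimulationParams",
    "Configuration",
    "JammingError",
    "attempt_insertion",
    "metropolis_step",
    "diffuse_and_quench",
    "run_realization",
    "run_ensemble",
    "sample_trajectory",
]


class JammingError(RuntimeError):
    """Insertion retries exhausted: the requested density is not reachable."""

    def __init__(self, attempts: int, particle_index: int):
        self.attempts = attempts
        self.particle_index = particle_index
        super().__init__(
            f"insertion of particle {particle_index} failed after {attempts} "
            f"attempts; the target density appears jammed for this box/pattern"
        )


@dataclass(frozen=True)
class SimulationParams:
    """Protocol parameters of a sequential-quenching run.

    Attributes
    ----------
    target_density : float
        Reduced number density ``rho* = N d^2 / L^2`` at which insertion
        stops (default 0.3; 120 particles on the default 20d box).
    move_budget : int
        Attempted Metropolis moves per particle before quenching
        (default 3000).  ``0`` disables diffusion, reducing the protocol to
        plain random sequential adsorption.
    max_displacement : float
        Per-axis cap on a trial displacement, in units of d (default 0.5).
    insertion_retry_cap : int
        Insertion attempts allowed per particle before raising
        :class:`JammingError` (default 10**6).
    realizations : int
        Number of independent realizations in an ensemble (default 100).
    seed : int
        Master seed; per-realization streams are spawned from it.
    """

    target_density: float = 0.3
    move_budget: int = 3000
    max_displacement: float = 0.5
    insertion_retry_cap: int = 1_000_000
    realizations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_density:
            raise ValueError("target_density must be positive")
        if self.move_budget < 0:
            raise ValueError("move_budget must be non-negative")
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be positive")
        if self.insertion_retry_cap < 1:
            raise ValueError("insertion_retry_cap must be at least 1")
        if self.realizations < 1:
            raise ValueError("realizations must be at least 1")

    def n_particles(self, box: Box, diameter: float = 1.0) -> int:
        """Particle count implied by the density target: round(rho* L^2/d^2)."""
        return int(round(self.target_density * box.area / diameter**2))


@dataclass
class Configuration:
    """A completed realization: quenched positions in insertion order.

    ``energies[k]`` is particle ``k``'s pair-interaction energy (units of
    epsilon) at the moment it was quenched, evaluated with the region factor
    of its own final position.
    """

    positions: np.ndarray  # (N, 2), wrapped into [0, L)
    region_labels: np.ndarray  # (N,) str
    energies: np.ndarray  # (N,) float
    seed: int
    accepted_moves: int = 0
    insertion_energies: np.ndarray | None = None  # energy when first inserted

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def total_energy(self) -> float:
        return float(np.sum(self.energies))


def _derive_seed(entropy: Sequence[int]) -> int:
    """A 31-bit child seed from an entropy tuple, via numpy's SeedSequence."""
    state = np.random.SeedSequence(list(entropy)).generate_state(1, np.uint32)
    return int(state[0] & 0x7FFFFFFF)


def _check_box(box: Box, params: PotentialParams) -> None:
    if not (box.periodic_x and box.periodic_y):
        raise ValueError("the SQ engine requires a fully periodic box")
    if box.side_length <= 2 * params.cutoff:
        raise ValueError(
            f"box side {box.side_length} must exceed twice the interaction "
            f"range {params.cutoff} for the minimum-image convention"
        )


# ---------------------------------------------------------------------------
# pure-Python protocol steps (reference implementations)
# ---------------------------------------------------------------------------

def attempt_insertion(
    positions: np.ndarray,
    box: Box,
    rng: np.random.Generator,
    diameter: float = 1.0,
    retry_cap: int = 1_000_000,
) -> np.ndarray:
    """Draw uniform positions until one clears the hard core of ``positions``.

    Draws are independent across retries.  Raises :class:`JammingError` when
    ``retry_cap`` consecutive draws all overlap.
    """
    existing = np.asarray(positions, dtype=float).reshape(-1, 2)
    L = box.side_length
    for _ in range(retry_cap):
        candidate = rng.random(2) * L
        if existing.shape[0] == 0:
            return candidate
        _, dist = box.minimum_image(existing, candidate[None, :])
        if np.all(dist >= diameter):
            return candidate
    raise JammingError(retry_cap, existing.shape[0])


def metropolis_step(
    current: np.ndarray,
    positions: np.ndarray,
    pattern: RegionPattern,
    box: Box,
    params: PotentialParams,
    rng: np.random.Generator,
    max_displacement: float = 0.5,
    current_energy: float | None = None,
) -> tuple[np.ndarray, float, bool]:
    """One Metropolis trial move of the mobile particle.

    Proposes per-axis offsets uniform in ``[-max_displacement,
    +max_displacement]``, wraps into the box, and accepts with probability
    ``min(1, exp(-dE/kT))``; a proposal overlapping a quenched particle is
    rejected outright.  Returns ``(position, energy, accepted)``; on
    rejection the input position and energy are returned unchanged.
    """
    current = np.asarray(current, dtype=float).reshape(2)
    if current_energy is None:
        current_energy = particle_energy(current, positions, pattern, box, params)
    proposal = box.wrap(current + (2.0 * rng.random(2) - 1.0) * max_displacement)
    new_energy = particle_energy(proposal, positions, pattern, box, params)
    delta = new_energy - current_energy
    if delta <= 0 or (
        math.isfinite(new_energy) and rng.random() < math.exp(-delta / params.thermal_energy)
    ):
        return proposal, new_energy, True
    return current, current_energy, False


def diffuse_and_quench(
    start: np.ndarray,
    positions: np.ndarray,
    pattern: RegionPattern,
    box: Box,
    params: PotentialParams,
    rng: np.random.Generator,
    move_budget: int = 3000,
    max_displacement: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Apply exactly ``move_budget`` Metropolis steps; return the endpoint.

    The endpoint is where the particle is quenched — no convergence test is
    applied, matching the fixed-budget protocol.
    """
    pos = np.asarray(start, dtype=float).reshape(2)
    energy = particle_energy(pos, positions, pattern, box, params)
    for _ in range(move_budget):
        pos, energy, _ = metropolis_step(
            pos, positions, pattern, box, params, rng, max_displacement, energy
        )
    return pos, energy


# ---------------------------------------------------------------------------
# compiled full-protocol drivers
# ---------------------------------------------------------------------------

def run_realization(
    sim: SimulationParams,
    pattern: RegionPattern,
    box: Box,
    params: PotentialParams = PotentialParams(),
    seed: int | Sequence[int] | None = None,
) -> Configuration:
    """Run one full sequential-quenching realization (compiled kernel).

    ``seed`` may be an integer or a tuple of integers (an entropy path, as
    used by :func:`run_ensemble`); identical inputs give bit-identical
    output.  Raises :class:`JammingError` if an insertion exhausts the retry
    cap.
    """
    _check_box(box, params)
    if seed is None:
        seed = sim.seed
    entropy = (seed,) if np.ndim(seed) == 0 else tuple(int(s) for s in seed)
    kernel_seed = _derive_seed(entropy)

    n_target = sim.n_particles(box, params.diameter)
    upper_edges = pattern.upper_edges(box)
    factors = np.asarray(pattern.factors, dtype=float)

    pos, energies, insert_energies, accepted, status, n_placed = _kernels.sq_realization(
        n_target,
        box.side_length,
        params.diameter,
        params.cutoff,
        params.epsilon,
        params.thermal_energy,
        upper_edges,
        factors,
        sim.move_budget,
        sim.max_displacement,
        sim.insertion_retry_cap,
        kernel_seed,
    )
    if status == _kernels.STATUS_JAMMED:
        raise JammingError(sim.insertion_retry_cap, n_placed)

    idx = pattern.region_index(pos[:, 0], box)
    labels = np.asarray(pattern.labels, dtype=object)[idx].astype(str)
    return Configuration(
        positions=pos,
        region_labels=labels,
        energies=energies,
        seed=kernel_seed,
        accepted_moves=int(accepted),
        insertion_energies=insert_energies,
    )


def run_ensemble(
    sim: SimulationParams,
    pattern: RegionPattern,
    box: Box,
    params: PotentialParams = PotentialParams(),
    seed: int | Sequence[int] | None = None,
    realizations: int | None = None,
) -> list[Configuration]:
    """Run independent realizations with per-realization spawned streams.

    Realization ``k`` uses the entropy path ``(*seed, k)``, so results are
    reproducible and independent of execution order.
    """
    if seed is None:
        seed = sim.seed
    base = (seed,) if np.ndim(seed) == 0 else tuple(int(s) for s in seed)
    n_real = sim.realizations if realizations is None else realizations
    configs = []
    for k in range(n_real):
        try:
            configs.append(run_realization(sim, pattern, box, params, seed=base + (k,)))
        except JammingError as err:
            raise JammingError(err.attempts, err.particle_index) from err
    return configs


def sample_trajectory(
    start: np.ndarray,
    frozen: np.ndarray,
    pattern: RegionPattern,
    box: Box,
    params: PotentialParams,
    n_steps: int,
    max_displacement: float = 0.5,
    seed: int = 0,
    record_every: int = 1,
) -> tuple[np.ndarray, int]:
    """Metropolis random walk of one mobile particle in a frozen landscape.

    Runs the same compiled kernel the SQ protocol uses and records the
    position after every ``record_every``-th step.  Returns ``(positions,
    accepted_count)``.  This is the sampling primitive behind the
    Boltzmann-stationarity diagnostics.
    """
    _check_box(box, params)
    start = np.asarray(start, dtype=float).reshape(2)
    frozen = np.asarray(frozen, dtype=float).reshape(-1, 2)
    recorded, accepted = _kernels.metropolis_trajectory(
        float(start[0]),
        float(start[1]),
        frozen,
        box.side_length,
        params.diameter,
        params.cutoff,
        params.epsilon,
        params.thermal_energy,
        pattern.upper_edges(box),
        np.asarray(pattern.factors, dtype=float),
        int(n_steps),
        float(max_displacement),
        int(record_every),
        _derive_seed((seed,)),
    )
    return recorded, int(accepted)
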