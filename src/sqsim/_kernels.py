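"""Compiled inner loops for the sequential-quenching protocol.

These numba kernels implement exactly the same arithmetic as the pure-Python
reference operations in :mod:`sqsim.engine` / :mod:`sqsim.potential` —
minimum-image folding, the triangular well with the moving particle's region
factor, and the Metropolis acceptance rule — but run the full
insert/diffuse/quench protocol in a single JIT-compiled pass.  Positions are
kept wrapped in ``[0, L)`` at all times; because the per-axis displacement
cap never exceeds ``L/2``, a single conditional fold suffices for wrapping.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the realization kernel
STATUS_OK = 0
STATUS_JAMMED = 1


@njit(cache=True)
def _region_index(x, upper_edges):
    for i in range(upper_edges.size - 1):
        if x < upper_edges[i]:
            return i
    return upper_edges.size - 1


@njit(cache=True)
def _energy_at(x, y, pos, k, L, d, lam_d, inv_u):
    """Triangular-well energy of (x, y) against pos[:k]; inf on overlap."""
    half = 0.5 * L
    denom = lam_d - d
    total = 0.0
    for j in range(k):
        dx = x - pos[j, 0]
        dy = y - pos[j, 1]
        if dx > half:
            dx -= L
        elif dx < -half:
            dx += L
        if dy > half:
            dy -= L
        elif dy < -half:
            dy += L
        r2 = dx * dx + dy * dy
        if r2 < d * d:
            return np.inf
        r = np.sqrt(r2)
        if r <= lam_d:
            total += -inv_u * (lam_d - r) / denom
    return total


@njit(cache=True)
def _overlaps(x, y, pos, k, L, d):
    half = 0.5 * L
    d2 = d * d
    for j in range(k):
        dx = x - pos[j, 0]
        dy = y - pos[j, 1]
        if dx > half:
            dx -= L
        elif dx < -half:
            dx += L
        if dy > half:
            dy -= L
        elif dy < -half:
            dy += L
        if dx * dx + dy * dy < d2:
            return True
    return False


@njit(cache=True)
def sq_realization(
    n_target,
    L,
    d,
    lam_d,
    epsilon,
    thermal,
    upper_edges,
    factors,
    move_budget,
    max_disp,
    retry_cap,
    seed,
):
    """One sequential-quenching realization.

    Particles are inserted uniformly at random (re-drawn on hard-core
    overlap), the newest particle performs ``move_budget`` Metropolis moves
    among its frozen predecessors with per-axis displacements uniform in
    ``[-max_disp, +max_disp]``, and is then quenched permanently.

    Returns ``(positions, energies, insert_energies, accepted_moves, status,
    n_placed)``; ``energies[k]`` is the particle's interaction energy at the
    moment of quenching and ``insert_energies[k]`` at the moment of
    insertion, both in units of epsilon.
    """
    np.random.seed(seed)
    pos = np.zeros((n_target, 2))
    energies = np.zeros(n_target)
    insert_energies = np.zeros(n_target)
    accepted = 0

    for k in range(n_target):
        # --- insertion with hard-core rejection ---
        tries = 0
        x = 0.0
        y = 0.0
        while True:
            tries += 1
            if tries > retry_cap:
                return pos, energies, insert_energies, accepted, STATUS_JAMMED, k
            x = np.random.random() * L
            y = np.random.random() * L
            if not _overlaps(x, y, pos, k, L, d):
                break

        inv_u = epsilon / factors[_region_index(x, upper_edges)]
        e = _energy_at(x, y, pos, k, L, d, lam_d, inv_u)
        insert_energies[k] = e

        # --- Metropolis surface diffusion among frozen predecessors ---
        for _ in range(move_budget):
            nx = x + (2.0 * np.random.random() - 1.0) * max_disp
            ny = y + (2.0 * np.random.random() - 1.0) * max_disp
            if nx >= L:
                nx -= L
            elif nx < 0.0:
                nx += L
            if ny >= L:
                ny -= L
            elif ny < 0.0:
                ny += L
            inv_u_new = epsilon / factors[_region_index(nx, upper_edges)]
            en = _energy_at(nx, ny, pos, k, L, d, lam_d, inv_u_new)
            if en <= e:
                x, y, e = nx, ny, en
                accepted += 1
            elif en != np.inf and np.random.random() < np.exp(-(en - e) / thermal):
                x, y, e = nx, ny, en
                accepted += 1

        pos[k, 0] = x
        pos[k, 1] = y
        energies[k] = e

    return pos, energies, insert_energies, accepted, STATUS_OK, n_target


@njit(cache=True)
def metropolis_trajectory(
    x0,
    y0,
    frozen,
    L,
    d,
    lam_d,
    epsilon,
    thermal,
    upper_edges,
    factors,
    n_steps,
    max_disp,
    record_every,
    seed,
):
    """Random walk of a single mobile particle in a frozen landscape.

    Runs ``n_steps`` Metropolis moves and records the position after every
    ``record_every``-th step.  Returns ``(recorded, accepted)`` where
    ``recorded`` has shape ``(n_steps // record_every, 2)``.
    """
    np.random.seed(seed)
    n_frozen = frozen.shape[0]
    x, y = x0, y0
    inv_u = epsilon / factors[_region_index(x, upper_edges)]
    e = _energy_at(x, y, frozen, n_frozen, L, d, lam_d, inv_u)
    n_rec = n_steps // record_every
    out = np.empty((n_rec, 2))
    accepted = 0
    idx = 0
    for step in range(n_steps):
        nx = x + (2.0 * np.random.random() - 1.0) * max_disp
        ny = y + (2.0 * np.random.random() - 1.0) * max_disp
        if nx >= L:
            nx -= L
        elif nx < 0.0:
            nx += L
        if ny >= L:
            ny -= L
        elif ny < 0.0:
            ny += L
        inv_u_new = epsilon / factors[_region_index(nx, upper_edges)]
        en = _energy_at(nx, ny, frozen, n_frozen, L, d, lam_d, inv_u_new)
        if en <= e:
            x, y, e = nx, ny, en
            accepted += 1
        elif en != np.inf and np.random.random() < np.exp(-(en - e) / thermal):
            x, y, e = nx, ny, en
            accepted += 1
        if (step + 1) % record_every == 0:
            out[idx, 0] = x
            out[idx, 1] = y
            idx += 1
    return out, accepted
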