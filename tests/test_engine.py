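"""Sequential-quenching protocol: insertion, diffusion, quenching, ensembles."""

import math

import numpy as np
import pytest

from sqsim import (
    Box,
    Configuration,
    JammingError,
    PotentialParams,
    RegionPattern,
    SimulationParams,
    attempt_insertion,
    diffuse_and_quench,
    metropolis_step,
    region_occupancy,
    run_ensemble,
    run_realization,
    sample_trajectory,
)
from sqsim.analysis import _pair_distances


def min_pair_distance(positions, L):
    d = _pair_distances(np.asarray(positions), L)
    return d.min() if d.size else np.inf


class TestInsertion:
    def test_empty_configuration_first_draw_accepted(self, box20, rng):
        pos = attempt_insertion(np.empty((0, 2)), box20, rng)
        assert pos.shape == (2,)
        assert np.all((pos >= 0) & (pos < 20.0))

    def test_jamming_error_when_no_gap_exists(self, rng):
        # a dense grid leaves no room for another disk
        box = Box(4.0)
        xs = np.arange(0.0, 4.0, 0.5)
        grid = np.array([(x, y) for x in xs for y in xs])
        with pytest.raises(JammingError) as err:
            attempt_insertion(grid, box, rng, retry_cap=2000)
        assert err.value.attempts == 2000

    def test_accepted_position_clears_hard_core(self, box20, rng):
        quenched = rng.random((50, 2)) * 20.0
        # quenched set may itself overlap; only the new particle must clear it
        pos = attempt_insertion(quenched, box20, rng)
        _, dist = box20.minimum_image(quenched, pos[None, :])
        assert np.all(dist >= 1.0)


class _ScriptedRng:
    """Feeds predetermined uniforms to make a Metropolis step deterministic."""

    def __init__(self, draws):
        self.draws = list(draws)

    def random(self, n=None):
        if n is None:
            return self.draws.pop(0)
        return np.array([self.draws.pop(0) for _ in range(n)])


class TestMetropolisStep:
    """Acceptance rule P = min(1, exp(-dE/kT)) with a symmetric proposal."""

    def setup_method(self):
        self.box = Box(20.0)
        self.pattern = RegionPattern.uniform(1.0)
        self.pot = PotentialParams()
        self.frozen = np.array([[10.0, 10.0]])

    def _step(self, start, draws):
        return metropolis_step(
            np.array(start), self.frozen, self.pattern, self.box, self.pot,
            _ScriptedRng(draws), max_displacement=0.5,
        )

    def test_downhill_always_accepted(self):
        # from r=1.5 (E=0) toward r=1.25 (E=-0.5): proposal offsets (0, -0.25)
        # offsets u -> (2u-1)*0.5; u=0.5 gives 0, u=0.25 gives -0.25
        pos, energy, accepted = self._step((10.0, 11.5), [0.5, 0.25])
        assert accepted
        assert energy == pytest.approx(-0.5, rel=1e-12)
        np.testing.assert_allclose(pos, [10.0, 11.25])

    def test_zero_delta_accepted(self):
        # sliding at constant distance beyond the cutoff: E stays 0
        pos, energy, accepted = self._step((10.0, 15.0), [0.75, 0.5])
        assert accepted and energy == 0.0

    def test_uphill_accepted_iff_uniform_below_boltzmann(self):
        # from r=1.25 (E=-0.5) to r=1.5 (E=0): dE=+0.5, P=exp(-0.5)~0.6065
        for u, expect in [(0.60, True), (0.61, False)]:
            pos, energy, accepted = self._step((10.0, 11.25), [0.5, 0.75, u])
            assert accepted is expect
            if expect:
                assert energy == pytest.approx(0.0, abs=1e-12)
            else:
                assert energy == pytest.approx(-0.5, rel=1e-12)
                np.testing.assert_allclose(pos, [10.0, 11.25])

    def test_overlap_rejected_outright(self):
        # proposal moves to r=0.75 < d: certain rejection, no uniform consumed
        pos, energy, accepted = self._step((10.0, 11.25), [0.5, 0.0])
        assert not accepted
        np.testing.assert_allclose(pos, [10.0, 11.25])
        assert energy == pytest.approx(-0.5, rel=1e-12)


class TestDiffuseAndQuench:
    def test_zero_move_budget_returns_start(self, box20, uniform_pattern, pot, rng):
        start = np.array([3.0, 4.0])
        end, energy = diffuse_and_quench(
            start, np.empty((0, 2)), uniform_pattern, box20, pot, rng, move_budget=0
        )
        np.testing.assert_array_equal(end, start)
        assert energy == 0.0

    def test_flat_landscape_walk_is_diffusive(self, pot):
        """No neighbors: every move accepted, MSD grows linearly (var 1/12 per axis)."""
        box = Box(200.0)
        pattern = RegionPattern.uniform(1.0)
        n_walks, n_steps = 400, 400
        start = (100.0, 100.0)
        msd = np.zeros(4)
        checkpoints = np.array([100, 200, 300, 400])
        for k in range(n_walks):
            traj, accepted = sample_trajectory(
                start, np.empty((0, 2)), pattern, box, pot,
                n_steps=n_steps, seed=k, record_every=100,
            )
            assert accepted == n_steps  # flat landscape: all proposals accepted
            disp = traj - np.array(start)
            msd += np.sum(disp**2, axis=1)
        msd /= n_walks
        expected = 2.0 * checkpoints * (1.0 / 12.0)  # 2 axes, var (2*0.5)^2/12
        np.testing.assert_allclose(msd, expected, rtol=0.15)

    def test_deep_well_captures_particle(self, box20, pot):
        """One neighbor with U=1e-4: the endpoint almost surely sits in the well."""
        pattern = RegionPattern.uniform(1e-4)
        neighbor = np.array([[10.0, 10.0]])
        captured = 0
        trials = 1000
        for k in range(trials):
            traj, _ = sample_trajectory(
                (10.0, 11.25), neighbor, pattern, box20, pot,
                n_steps=3000, seed=10_000 + k, record_every=3000,
            )
            _, r = box20.minimum_image(neighbor[0], traj[-1])
            if 1.0 <= r <= 1.5:
                captured += 1
        assert captured / trials >= 0.99


class TestRunRealization:
    def test_particle_count_from_density(self, uniform_pattern, pot):
        sim = SimulationParams(realizations=1, move_budget=50)
        c20 = run_realization(sim, uniform_pattern, Box(20.0), pot, seed=1)
        assert c20.n == 120  # 0.3 * 400
        c1000 = run_realization(sim, uniform_pattern, Box(math.sqrt(1000.0)), pot, seed=1)
        assert c1000.n == 300  # 0.3 * 1000

    def test_seed_determinism(self, thirds, box20, pot):
        sim = SimulationParams(realizations=1, move_budget=200)
        a = run_realization(sim, thirds, box20, pot, seed=42)
        b = run_realization(sim, thirds, box20, pot, seed=42)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.energies, b.energies)
        c = run_realization(sim, thirds, box20, pot, seed=43)
        assert not np.array_equal(a.positions, c.positions)

    def test_hard_core_invariant_and_wrapping(self, box20, pot):
        sim = SimulationParams(realizations=1)
        pattern = RegionPattern.equal_thirds(1e-4, 1.0)
        c = run_realization(sim, pattern, box20, pot, seed=7)
        assert np.all((c.positions >= 0) & (c.positions < 20.0))
        assert min_pair_distance(c.positions, 20.0) >= 1.0

    def test_final_energies_match_reference_sum(self, box20, pot):
        """Kernel-reported quench energies equal the Python energy sum."""
        from sqsim import particle_energy

        pattern = RegionPattern.equal_thirds(0.1, 1.0)
        sim = SimulationParams(realizations=1, move_budget=300)
        c = run_realization(sim, pattern, box20, pot, seed=3)
        for k in [0, 1, 5, 40, 119]:
            ref = particle_energy(c.positions[k], c.positions[:k], pattern, box20, pot)
            assert c.energies[k] == pytest.approx(ref, rel=1e-12, abs=1e-12)

    def test_jamming_propagates(self, uniform_pattern, pot):
        box = Box(4.0)
        sim = SimulationParams(
            target_density=2.0, move_budget=0, insertion_retry_cap=500, realizations=1
        )
        with pytest.raises(JammingError):
            run_realization(sim, uniform_pattern, box, pot, seed=0)

    def test_energetic_descent_with_deep_wells(self, box20, pot):
        """With eps/U >> kT, diffusion almost never raises a particle's energy."""
        pattern = RegionPattern.uniform(1e-4)
        sim = SimulationParams(realizations=1)
        descents = 0
        total = 0
        for seed in range(3):
            c = run_realization(sim, pattern, box20, pot, seed=seed)
            descents += np.sum(c.energies <= c.insertion_energies + 1e-9)
            total += c.n
        assert descents / total >= 0.95


class TestRunEnsemble:
    def test_single_realization_reduces_to_run_realization(self, thirds, box20, pot):
        sim = SimulationParams(realizations=1, move_budget=100)
        ens = run_ensemble(sim, thirds, box20, pot, seed=5)
        direct = run_realization(sim, thirds, box20, pot, seed=(5, 0))
        assert len(ens) == 1
        np.testing.assert_array_equal(ens[0].positions, direct.positions)

    def test_ensemble_determinism_and_stream_independence(self, thirds, box20, pot):
        sim = SimulationParams(realizations=3, move_budget=100)
        a = run_ensemble(sim, thirds, box20, pot, seed=9)
        b = run_ensemble(sim, thirds, box20, pot, seed=9)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.positions, cb.positions)
        # different realizations are genuinely different draws
        assert not np.array_equal(a[0].positions, a[1].positions)

    def test_ensemble_hard_core_sweep(self, box20, pot):
        pattern = RegionPattern.equal_thirds(0.01, 1.0)
        sim = SimulationParams(realizations=8, move_budget=1000)
        for c in run_ensemble(sim, pattern, box20, pot, seed=21):
            assert c.n == 120
            assert min_pair_distance(c.positions, 20.0) >= 1.0


class TestSelectivity:
    """Strongly favorable outer stripes drain the passivated center stripe."""

    def test_selective_vs_homogeneous_occupancy(self, box20, pot):
        sim = SimulationParams(realizations=10)
        selective = run_ensemble(
            sim, RegionPattern.equal_thirds(1e-4, 1.0), box20, pot, seed=2
        )
        occ = region_occupancy(selective, RegionPattern.equal_thirds(1e-4, 1.0), box20)
        assert occ.fraction("R2") < 0.1  # far below the 1/3 area fraction

        homogeneous = run_ensemble(
            sim, RegionPattern.equal_thirds(1.0, 1.0), box20, pot, seed=2
        )
        occ_h = region_occupancy(homogeneous, RegionPattern.equal_thirds(1.0, 1.0), box20)
        i = occ_h.labels.index("R2")
        # statistically consistent with the 1/3 area fraction
        assert abs(occ_h.mean_fractions[i] - 1 / 3) <= 4 * occ_h.stderr[i] + 0.02
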