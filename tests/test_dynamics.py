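"""Force laws, integrator, rerouting and boundary handling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdcontacts import (
    Domain,
    ForceParams,
    age_bins,
    boundary_rule,
    obstacle_force,
    reroute,
    run_simulation,
    self_force,
    social_force_pair,
    social_forces,
    social_forces_brute,
    step,
)
from crowdcontacts.dynamics import SimulationState, Wall, initial_positions
from crowdcontacts.population import PedestrianProfile


def make_profile(i=0, mass=80.0, v_d=1.0, d_soc=1.22, tau=0.5):
    return PedestrianProfile(
        id=i, age_bin=age_bins()[4], mass=mass, radius=0.2,
        desired_speed=v_d, desired_distance=d_soc, relaxation_time=tau,
    )


def make_state(positions, dirs=None, velocities=None, **profile_kw):
    n = len(positions)
    profiles = [make_profile(i, **profile_kw) for i in range(n)]
    positions = np.asarray(positions, dtype=float)
    dirs = np.asarray(dirs, dtype=float) if dirs is not None else np.tile([1.0, 0.0], (n, 1))
    vel = np.asarray(velocities, dtype=float) if velocities is not None else np.zeros((n, 2))
    return SimulationState(t=0.0, positions=positions, velocities=vel, desired_dirs=dirs, profiles=profiles)


class TestSelfForce:
    def test_relaxation_fixed_point(self):
        p = make_profile(v_d=1.3)
        e = np.array([0.6, 0.8])
        f = self_force(p, 1.3 * e, e)
        assert np.allclose(f, 0.0)

    def test_direct_substitution(self):
        # m=80 kg, tau=0.5 s, at rest, desired 1 m/s along x -> 160 N along x
        p = make_profile(mass=80.0, v_d=1.0, tau=0.5)
        f = self_force(p, np.zeros(2), np.array([1.0, 0.0]))
        assert np.allclose(f, [160.0, 0.0])

    @pytest.mark.parametrize("dt", [0.05, 0.0125])
    def test_speed_relaxes_exponentially(self, dt):
        # closed form v(t) = v_d (1 - exp(-t/tau)) for a lone agent
        v_d, tau = 1.34, 0.5
        state = make_state([[25.0, 25.0]], v_d=v_d, tau=tau)
        params, domain = ForceParams(), Domain()
        errs = []
        for _ in range(int(5.0 / dt)):
            state = step(state, dt, params, domain)
            exact = v_d * (1.0 - math.exp(-state.t / tau))
            errs.append(abs(np.linalg.norm(state.velocities[0]) - exact))
        assert max(errs) < v_d * dt / tau
        if dt == 0.0125:
            # O(dt): quartering the step shrinks the error by at least half
            assert max(errs) < 0.5 * v_d * 0.05 / tau


class TestSocialForce:
    params = ForceParams(a_soc=700.0, beta_soc=0.08, gamma=0.2)

    def test_zero_beyond_desired_distance(self):
        f = social_force_pair([0.0, 0.0], [1.3, 0.0], [1.0, 0.0], 1.22, self.params)
        assert np.all(f == 0.0)

    def test_amplitude_at_support_boundary_head_on(self):
        # j straight ahead at the shell: angular factor 1, magnitude A_soc
        d = 1.22 * (1 - 1e-12)
        f = social_force_pair([0.0, 0.0], [d, 0.0], [1.0, 0.0], 1.22, self.params)
        assert np.linalg.norm(f) == pytest.approx(700.0, rel=1e-6)
        assert f[0] < 0  # pushes i away from j

    def test_gamma_attenuation_behind(self):
        # j straight behind: angular factor gamma
        d = 1.22 * (1 - 1e-12)
        f = social_force_pair([0.0, 0.0], [-d, 0.0], [1.0, 0.0], 1.22, self.params)
        assert np.linalg.norm(f) == pytest.approx(0.2 * 700.0, rel=1e-6)

    @given(st.floats(0.0, 2 * math.pi), st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_angular_factor_bounds(self, phi, gamma):
        w = gamma + (1 - gamma) * (1 + math.cos(phi)) / 2
        assert gamma - 1e-12 <= w <= 1.0 + 1e-12

    @given(st.floats(0.01, 3.0), st.floats(0.0, 2 * math.pi))
    @settings(max_examples=200, deadline=None)
    def test_compact_support(self, d, angle):
        pos_j = [d * math.cos(angle), d * math.sin(angle)]
        f = social_force_pair([0.0, 0.0], pos_j, [1.0, 0.0], 1.22, self.params)
        if d >= 1.22:
            assert np.all(f == 0.0)
        else:
            assert np.linalg.norm(f) > 0.0

    def test_mirror_symmetry(self):
        # two agents facing each other inside the shell: equal and opposite
        state = make_state(
            [[0.0, 0.0], [1.0, 0.0]], dirs=[[1.0, 0.0], [-1.0, 0.0]]
        )
        f = social_forces(state, self.params)
        assert np.allclose(f[0], -f[1])
        assert f[0][0] < 0 < f[1][0]

    def test_degenerate_overlap_is_finite_and_reproducible(self):
        f1 = social_force_pair([1.0, 1.0], [1.0, 1.0], [1.0, 0.0], 1.22, self.params, pair_ids=(3, 7))
        f2 = social_force_pair([1.0, 1.0], [1.0, 1.0], [1.0, 0.0], 1.22, self.params, pair_ids=(3, 7))
        assert np.all(np.isfinite(f1))
        assert np.linalg.norm(f1) == pytest.approx(700.0)
        assert np.array_equal(f1, f2)

    def test_vectorized_equals_brute_force(self):
        # pairwise oracle on 100 random crowd configurations
        rng = np.random.default_rng(99)
        params = self.params
        for _ in range(100):
            n = int(rng.integers(2, 25))
            state = make_state(rng.uniform(0, 6, size=(n, 2)))
            angles = rng.uniform(0, 2 * math.pi, size=n)
            state.desired_dirs = np.column_stack([np.cos(angles), np.sin(angles)])
            assert np.allclose(
                social_forces(state, params), social_forces_brute(state, params), atol=1e-9
            )


class TestObstacleForce:
    params = ForceParams(a_obs=2000.0, beta_obs=0.08, d_obs=0.5)
    wall_left = Wall(0, 0.0, 1.0)

    def test_zero_beyond_cutoff(self):
        assert np.all(obstacle_force([0.6, 25.0], self.wall_left, self.params) == 0.0)

    def test_amplitude_at_cutoff(self):
        f = obstacle_force([0.5 * (1 - 1e-12), 25.0], self.wall_left, self.params)
        assert np.linalg.norm(f) == pytest.approx(2000.0, rel=1e-6)
        assert f[0] > 0  # inward

    def test_corner_force_along_diagonal(self):
        domain = Domain(50.0)
        pos = np.array([0.3, 0.3])
        total = sum(
            (obstacle_force(pos, w, self.params) for w in domain.walls), np.zeros(2)
        )
        assert total[0] == pytest.approx(total[1])
        assert total[0] > 0


class TestRerouteAndBoundary:
    def test_reroute_count_and_contract(self, rng):
        state = make_state(np.random.default_rng(0).uniform(0, 50, (300, 2)))
        x0, v0 = state.positions.copy(), state.velocities.copy()
        before = state.desired_dirs.copy()
        reroute(state, rng, fraction=0.3)
        changed = np.any(state.desired_dirs != before, axis=1)
        assert changed.sum() == 90  # 30% of 300
        assert np.array_equal(state.positions, x0)
        assert np.array_equal(state.velocities, v0)
        assert np.allclose(np.linalg.norm(state.desired_dirs, axis=1), 1.0)

    def test_new_directions_isotropic(self):
        # Rayleigh circular-uniformity statistic on ~1e4 fresh directions
        rng = np.random.default_rng(7)
        state = make_state(np.random.default_rng(1).uniform(0, 50, (10_000, 2)))
        before = state.desired_dirs.copy()
        reroute(state, rng, fraction=0.3)
        changed = np.any(state.desired_dirs != before, axis=1)
        dirs = state.desired_dirs[changed]
        n = len(dirs)
        z = n * (np.linalg.norm(dirs.mean(axis=0)) ** 2)
        assert z < 7.0  # p > 1e-3 under uniformity

    def test_boundary_reflection(self):
        domain = Domain(50.0)
        state = make_state([[50.2, 25.0]], dirs=[[1.0, 0.0]], velocities=[[1.5, 0.2]])
        boundary_rule(state, domain)
        assert np.allclose(state.desired_dirs[0], [-1.0, 0.0])
        assert state.velocities[0][0] == -1.5
        assert state.positions[0][0] == 50.0

    def test_interior_agent_unchanged(self):
        domain = Domain(50.0)
        state = make_state([[25.0, 25.0]], dirs=[[0.0, 1.0]], velocities=[[0.3, 0.4]])
        boundary_rule(state, domain)
        assert np.allclose(state.desired_dirs[0], [0.0, 1.0])
        assert np.allclose(state.velocities[0], [0.3, 0.4])

    def test_corner_hit_reflects_both_components(self):
        domain = Domain(50.0)
        e = np.array([[math.sqrt(0.5), -math.sqrt(0.5)]])
        state = make_state([[50.5, -0.5]], dirs=e.copy(), velocities=[[1.0, -1.0]])
        boundary_rule(state, domain)
        assert state.desired_dirs[0][0] < 0 < state.desired_dirs[0][1]
        assert np.allclose(state.positions[0], [50.0, 0.0])


class TestRuns:
    def test_initial_placement_separation(self, rng):
        pos = initial_positions(200, Domain(50.0), rng, min_separation=0.4)
        from scipy.spatial.distance import pdist

        assert pdist(pos).min() >= 0.4

    def test_placement_failure_raises(self, rng):
        from crowdcontacts.dynamics import SimulationError

        with pytest.raises(SimulationError):
            initial_positions(50, Domain(1.0), rng, min_separation=1.0, max_tries=20)

    def test_zero_duration_returns_initial_state(self, configs):
        res = run_simulation(config=configs["other"], n=20, duration=0.0, seed=4, engine="numpy")
        assert res.contact_pairs == []
        assert np.all(res.state.velocities == 0.0)

    def test_ballistic_without_social_force(self):
        # A_soc ~ 0 and agents far from walls: speed relaxes to v_d
        profiles = [make_profile(i, v_d=1.0) for i in range(5)]
        force = ForceParams(a_soc=1e-12, d_obs=1e-6)
        res = run_simulation(profiles=profiles, duration=5.0, seed=8, force=force, engine="numpy")
        speeds = np.linalg.norm(res.state.velocities, axis=1)
        assert np.allclose(speeds, 1.0, atol=1e-3)

    def test_agents_stay_inside_domain(self, configs):
        res = run_simulation(config=configs["school"], n=50, duration=20.0, seed=2)
        assert np.all(res.state.positions >= 0.0)
        assert np.all(res.state.positions <= 50.0)

    def test_bit_identical_given_seed(self, configs):
        a = run_simulation(config=configs["shopping"], n=40, duration=30.0, seed=6)
        b = run_simulation(config=configs["shopping"], n=40, duration=30.0, seed=6)
        assert np.array_equal(a.state.positions, b.state.positions)
        assert a.contact_pairs == b.contact_pairs

    def test_engines_agree(self, configs):
        # chaotic divergence limits exact agreement to short horizons
        kw = dict(config=configs["household"], n=40, duration=8.0, dt=0.05, seed=3)
        r1 = run_simulation(engine="numpy", **kw)
        r2 = run_simulation(engine="numba", **kw)
        assert np.allclose(r1.state.positions, r2.state.positions, atol=1e-9)
        assert sorted(r1.contact_pairs) == sorted(r2.contact_pairs)

    def test_engines_agree_on_contacts(self):
        # slow dense crowd accumulates 30-s dwells within the exact window
        profiles = [make_profile(i, v_d=0.3, d_soc=0.3) for i in range(30)]
        kw = dict(profiles=profiles, duration=40.0, dt=0.05, seed=9, domain=Domain(12.0))
        r1 = run_simulation(engine="numpy", **kw)
        r2 = run_simulation(engine="numba", **kw)
        assert sorted(r1.contact_pairs) == sorted(r2.contact_pairs)
        assert len(r1.contact_pairs) > 0

    def test_trajectory_recording(self, configs):
        res = run_simulation(config=configs["other"], n=10, duration=2.0, dt=0.05, seed=1,
                             record_every=10, engine="numpy")
        assert res.trajectory.shape == (5, 10, 4)  # x, y, vx, vy
        assert res.trajectory_times[-1] == pytest.approx(2.0)
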