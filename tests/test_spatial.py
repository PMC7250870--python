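"""Geometry, motion, occupancy, and neighbour-search oracle tests."""
import math

import numpy as np
import pytest
from scipy import stats

from acbm.core_types import CellAgent, CellSpec
from acbm.spatial import (
    OccupancyGrid,
    PackageStore,
    direction_from_angles,
    occupied_elements,
    random_direction,
    random_directions,
    reflect_positions,
    try_move,
    velocity,
)


def make_spec(radius=0.4, shape="cocci", length=None, **kw):
    return CellSpec(
        name="bug",
        radius_um=radius,
        shape=shape,
        length_um=length,
        mass_pg=0.28,
        search_radius_um=20.0,
        eat_radius_um=10.0,
        survive_time_min=30.0,
        **kw,
    )


def make_agent(position, grid, spec, aid=0):
    agent = CellAgent(
        id=aid,
        species="bug",
        position=np.asarray(position, dtype=float),
        biomass_pg=1.0,
        direction=np.array([1.0, 0.0, 0.0]),
    )
    els = occupied_elements(agent.position, spec, agent.direction)
    agent.occupied = els
    grid.claim(els, agent.id)
    return agent


class TestRandomDirection:
    @pytest.mark.parametrize(
        "phi, theta, expected",
        [
            (0.0, 0.0, (1.0, 0.0, 0.0)),
            (math.pi / 2, 0.7, (0.0, 0.0, 1.0)),
            (math.pi / 2, 2.1, (0.0, 0.0, 1.0)),
        ],
    )
    def test_closed_forms(self, phi, theta, expected):
        assert direction_from_angles(phi, theta) == pytest.approx(expected, abs=1e-12)

    def test_unit_norm_always(self, rng):
        d = random_directions(rng, 100_000)
        assert np.abs(np.linalg.norm(d, axis=1) - 1.0).max() < 1e-12

    def test_dz_follows_sine_of_uniform_angle(self, rng):
        # the construction is deliberately non-uniform on the sphere: d_z is
        # sin(phi) with phi uniform; compare against direct transform sampling
        d = random_directions(rng, 50_000)
        oracle = np.sin(rng.uniform(0.0, 2 * math.pi, 50_000))
        ks = stats.ks_2samp(d[:, 2], oracle)
        assert ks.pvalue > 1e-3

    def test_scalar_matches_vectorised_draws(self):
        a = random_direction(np.random.default_rng(5))
        b = random_directions(np.random.default_rng(5), 1)[0]
        assert a == pytest.approx(b)


class TestVelocity:
    def test_published_speed_along_x(self):
        assert velocity(np.array([1.0, 0, 0]), 8000.0) == pytest.approx((8000, 0, 0))

    def test_zero_speed_zero_vector(self):
        assert np.all(velocity(np.array([0.6, 0.8, 0.0]), 0.0) == 0)

    def test_norm_equals_speed(self, rng):
        for _ in range(20):
            d = random_direction(rng)
            assert np.linalg.norm(velocity(d, 123.4)) == pytest.approx(123.4)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            velocity(np.array([1.0, 0, 0]), -1.0)


class TestOccupiedElements:
    def test_small_coccus_at_element_center_claims_one(self):
        els = occupied_elements(np.array([10.5, 10.5, 10.5]), make_spec(0.4))
        assert els == frozenset({(10, 10, 10)})

    def test_point_cell_claims_containing_element(self):
        els = occupied_elements(np.array([3.2, 7.9, 1.1]), make_spec(1e-9))
        assert els == frozenset({(3, 7, 1)})

    @pytest.mark.parametrize("radius", [0.4, 1.5, 2.3])
    def test_coccus_matches_brute_force(self, rng, radius):
        for _ in range(5):
            c = rng.uniform(5.0, 15.0, 3)
            els = occupied_elements(c, make_spec(radius))
            brute = {
                (i, j, k)
                for i in range(25)
                for j in range(25)
                for k in range(25)
                if np.linalg.norm(np.array([i, j, k]) + 0.5 - c) <= radius
            }
            brute.add(tuple(int(math.floor(x)) for x in c))
            assert els == frozenset(brute)

    def test_bacillus_matches_brute_force_capsule(self, rng):
        spec = make_spec(0.8, shape="bacilli", length=4.0)
        for _ in range(3):
            c = rng.uniform(8.0, 12.0, 3)
            d = random_direction(rng)
            half = spec.length_um / 2 - spec.radius_um
            a, b = c - half * d, c + half * d
            ab = b - a

            def seg_dist(p):
                t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
                return np.linalg.norm(p - (a + t * ab))

            brute = {
                (i, j, k)
                for i in range(20)
                for j in range(20)
                for k in range(20)
                if seg_dist(np.array([i, j, k]) + 0.5) <= spec.radius_um
            }
            brute.add(tuple(int(math.floor(x)) for x in c))
            assert occupied_elements(c, spec, d) == frozenset(brute)


class TestTryMove:
    def test_free_grid_moves_exact_displacement(self, rng):
        grid = OccupancyGrid((100.0, 100.0, 100.0))
        spec = make_spec(0.4)
        agent = make_agent([50.0, 50.0, 50.0], grid, spec)
        before = agent.position.copy()
        moved = try_move(agent, spec, grid, rng, dt_min=1.0, speed_um_per_h=300.0)
        assert moved
        assert np.linalg.norm(agent.position - before) == pytest.approx(5.0)

    def test_fully_blocked_stays(self, rng):
        grid = OccupancyGrid((3.0, 3.0, 3.0))
        spec = make_spec(0.4)
        agent = make_agent([1.5, 1.5, 1.5], grid, spec)
        blocker = 999
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    if (i, j, k) != (1, 1, 1):
                        grid.claim([(i, j, k)], blocker)
        # displacement 1 µm always leaves the center element (corner is 0.87)
        moved = try_move(agent, spec, grid, rng, dt_min=1.0, speed_um_per_h=60.0)
        assert not moved
        assert np.all(agent.position == [1.5, 1.5, 1.5])

    def test_occupancy_stays_exclusive_over_many_steps(self, rng):
        grid = OccupancyGrid((20.0, 20.0, 20.0))
        spec = make_spec(1.2)
        agents = [
            make_agent([6.0, 6.0, 6.0], grid, spec, aid=0),
            make_agent([14.0, 14.0, 14.0], grid, spec, aid=1),
        ]
        for _ in range(2000):
            for a in agents:
                try_move(a, spec, grid, rng, dt_min=1.0, speed_um_per_h=240.0)
            assert agents[0].occupied.isdisjoint(agents[1].occupied)
            assert len(agents[0].occupied) + len(agents[1].occupied) == grid.occupied_count()
            for a in agents:
                assert np.all(a.position >= 0) and np.all(a.position <= 20.0)


class TestPackageQueries:
    def _store(self, positions, mets=None):
        store = PackageStore(["glc", "ac"])
        mets = mets or ["glc"] * len(positions)
        for p, m in zip(positions, mets):
            store.add(m, np.asarray(p, dtype=float), 100.0)
        store.build_index()
        return store

    def test_nearest_prefers_closer_package(self):
        store = self._store([[3.0, 0, 0], [5.0, 0, 0]])
        codes = frozenset({store.met_code["glc"]})
        assert store.nearest(np.zeros(3), 10.0, codes) == 0

    def test_outside_radius_is_none(self):
        store = self._store([[12.0, 0, 0]])
        codes = frozenset({store.met_code["glc"]})
        assert store.nearest(np.zeros(3), 10.0, codes) is None

    def test_ties_break_by_lowest_id(self):
        store = self._store([[4.0, 0, 0], [-4.0, 0, 0], [0, 4.0, 0]])
        codes = frozenset({store.met_code["glc"]})
        assert store.nearest(np.zeros(3), 10.0, codes) == 0

    def test_nearest_and_ball_match_brute_force(self, rng):
        pos = rng.uniform(0, 100, (1000, 3))
        mets = ["glc" if i % 3 else "ac" for i in range(1000)]
        store = self._store(pos, mets)
        codes = frozenset({store.met_code["glc"]})
        for _ in range(50):
            center = rng.uniform(0, 100, 3)
            radius = rng.uniform(5, 40)
            d = np.linalg.norm(pos - center, axis=1)
            ok = np.array([m == "glc" for m in mets])
            inside = np.flatnonzero((d <= radius) & ok)
            got = store.in_radius(center, radius, codes)
            assert set(got) == set(inside)
            if len(inside):
                d_in = d[inside]
                best = inside[np.lexsort((inside, d_in))][0]
                assert store.nearest(center, radius, codes) == best
            else:
                assert store.nearest(center, radius, codes) is None

    def test_everything_within_env_diagonal(self, rng):
        pos = rng.uniform(0, 50, (100, 3))
        store = self._store(pos)
        codes = frozenset({store.met_code["glc"]})
        assert len(store.in_radius(np.zeros(3), 100.0, codes)) == 100

    def test_periodic_index_sees_across_the_boundary(self):
        store = PackageStore(["glc"], periodic_dims=(100.0, 100.0, 100.0))
        store.add("glc", np.array([99.5, 50.0, 50.0]), 10.0)
        store.build_index()
        codes = frozenset({0})
        assert store.nearest(np.array([0.5, 50.0, 50.0]), 2.0, codes) == 0

    def test_debit_drains_nearest_first_and_kills_empties(self):
        store = self._store([[1.0, 0, 0], [2.0, 0, 0]])
        codes = frozenset({store.met_code["glc"]})
        ids = store.in_radius(np.zeros(3), 5.0, codes)
        taken = store.debit(ids, 150.0)
        assert taken == pytest.approx(150.0)
        assert not store.alive[0] and store.n[1] == pytest.approx(50.0)


class TestRandomWalk:
    def test_msd_grows_linearly(self, rng):
        # iid unit steps with zero mean: E|X_k|^2 = k s^2 exactly
        n, k, step = 2000, 40, 2.0
        pos = np.zeros((n, 3))
        traj = []
        for i in range(1, k + 1):
            pos += random_directions(rng, n) * step
            traj.append((pos**2).sum(axis=1))
        msd20, msd40 = traj[19], traj[39]
        for msd, ki in [(msd20, 20), (msd40, 40)]:
            se = msd.std(ddof=1) / math.sqrt(n)
            assert abs(msd.mean() - ki * step**2) < 3 * se
        assert msd40.mean() / msd20.mean() == pytest.approx(2.0, rel=0.1)

    def test_reflection_keeps_positions_inside(self, rng):
        dims = np.array([10.0, 20.0, 5.0])
        pos = rng.uniform(0, 1, (500, 3)) * dims + rng.normal(0, 30, (500, 3))
        folded = reflect_positions(pos, dims)
        assert np.all(folded >= 0) and np.all(folded <= dims)
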