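import numpy as np
import pytest

from atollconnect import dispersal as dp
from atollconnect import lagoonflow as lf


def make_traj(xs, ys, release_time=0.0, n_sources=1, source_index=None):
    """Hand-built hourly trajectory for census tests (one or more particles)."""
    xs = np.atleast_2d(np.asarray(xs, float))
    ys = np.atleast_2d(np.asarray(ys, float))
    n, h = xs.shape
    return dp.Trajectories(
        source_labels=[f"S{i}" for i in range(n_sources)],
        source_index=np.zeros(n, int) if source_index is None else source_index,
        release_time=release_time,
        times=release_time + np.arange(h, dtype=float),
        x=xs,
        y=ys,
        depth=np.full((n, h), 7.0),
        alive=np.ones((n, h), bool),
    )


class TestRelease:
    def test_positions_within_square_and_depth_band(self):
        f = lf.uniform_flow_field(0.0, nx=61, ny=31)
        spec = dp.ReleaseSpec(
            sources={"S": (0.0, 0.0)},
            n_larvae_per_release=1000,
            cohort_start_hours=(0.0,),
        )
        x, y, z, src = dp.release_cohort(spec, f, 0, np.random.default_rng(0))
        assert (np.abs(x) <= 350).all() and (np.abs(y) <= 350).all()
        assert ((z >= 5) & (z <= 10)).all()

    def test_total_count_is_exact_product(self):
        f = lf.uniform_flow_field(0.0, nx=61, ny=31)
        spec = dp.ReleaseSpec(
            sources={f"S{i}": (i * 100.0, 0.0) for i in range(4)},
            n_larvae_per_release=50,
            cohort_start_hours=(0.0, 24.0, 48.0),
        )
        total = 0
        rng = np.random.default_rng(1)
        for c in range(spec.n_cohorts):
            x, *_ = dp.release_cohort(spec, f, c, rng)
            total += len(x)
        assert total == 3 * 4 * 50

    def test_identical_seed_identical_release(self):
        f = lf.uniform_flow_field(0.0, nx=61, ny=31)
        spec = dp.ReleaseSpec(sources={"S": (0.0, 0.0)}, n_larvae_per_release=100)
        a = dp.release_cohort(spec, f, 0, np.random.default_rng(7))
        b = dp.release_cohort(spec, f, 0, np.random.default_rng(7))
        assert all(np.array_equal(u, v) for u, v in zip(a, b))


class TestAdvect:
    def test_uniform_flow_kinematics(self):
        f = lf.uniform_flow_field(0.1)
        params = dp.AdvectionParams(horizontal_diffusivity=0.0, use_dvm=False)
        traj = dp.advect(
            np.array([0.0]), np.array([0.0]), np.array([5.0]),
            np.array([0]), ["S"], f, 0.0, 1.0, params, np.random.default_rng(0),
        )
        assert traj.x[0, -1] - traj.x[0, 0] == pytest.approx(360.0)
        assert traj.y[0, -1] == pytest.approx(0.0)

    def test_diffusion_law(self):
        f = lf.uniform_flow_field(0.0, nx=81, ny=81, cell_size=200.0, n_hours=30)
        n = 10_000
        params = dp.AdvectionParams(
            horizontal_diffusivity=0.5, use_dvm=False, dt_hours=0.25
        )
        traj = dp.advect(
            np.zeros(n), np.zeros(n), np.full(n, 5.0), np.zeros(n, int), ["S"],
            f, 0.0, 24.0, params, np.random.default_rng(1),
        )
        msd = (traj.x**2 + traj.y**2).mean(axis=0)
        t_s = (traj.times - traj.times[0]) * 3600.0
        slope = np.polyfit(t_s[1:], msd[1:], 1)[0]
        assert slope == pytest.approx(4 * 0.5, rel=0.15)

    def test_dvm_day_deeper_than_night(self):
        f = lf.uniform_flow_field(0.0, n_hours=72)
        n = 200
        params = dp.AdvectionParams(horizontal_diffusivity=0.0, use_dvm=True)
        traj = dp.advect(
            np.zeros(n), np.zeros(n), np.full(n, 7.0), np.zeros(n, int), ["S"],
            f, 0.0, 72.0, params, np.random.default_rng(2),
        )
        hod = traj.times % 24
        day = (hod >= 8) & (hod < 18)
        night = (hod >= 20) | (hod < 4)
        for d in range(3):
            sel = (traj.times >= 24 * d) & (traj.times < 24 * (d + 1))
            md = traj.depth[:, sel & day].mean()
            mn = traj.depth[:, sel & night].mean()
            assert mn < md


class TestCensus:
    COLL = dp.CollectorSpec(collectors={"C": (0.0, 0.0)})

    def test_radius_rule(self):
        hours = 11 * 24 + 1
        near = np.full(hours, 5000.0)
        near[-1] = 400.0  # passes within 500 m at age 10 d
        counts, _ = dp.census(make_traj(near, np.zeros(hours)), self.COLL)
        assert counts[0, 0] == 1
        far = np.full(hours, 5000.0)
        far[-1] = 600.0
        counts, _ = dp.census(make_traj(far, np.zeros(hours)), self.COLL)
        assert counts[0, 0] == 0

    def test_pld_ceiling(self):
        hours = 26 * 24 + 1
        xs = np.full(hours, 5000.0)
        xs[-1] = 0.0  # reaches the collector at age 26 d
        counts, _ = dp.census(make_traj(xs, np.zeros(hours)), self.COLL)
        assert counts[0, 0] == 0

    def test_first_entry_counts_each_particle_once(self):
        hours = 48
        xs = np.zeros((10, hours))  # parked on the collector
        counts, tally = dp.census(make_traj(xs, np.zeros_like(xs)), self.COLL)
        assert counts[0, 0] == 10
        assert tally["censused"] == 10 and tally["expired"] == 0

    def test_snapshot_mode_counts_every_hour(self):
        hours = 48
        xs = np.zeros((2, hours))
        counts, _ = dp.census(
            make_traj(xs, np.zeros_like(xs)), self.COLL, mode="snapshot_sum"
        )
        assert counts[0, 0] == 2 * hours

    def test_competency_floor(self):
        spec = dp.CollectorSpec(
            collectors={"C": (0.0, 0.0)}, competency_min=2.0
        )
        hours = 3 * 24 + 1
        xs = np.zeros((1, hours))
        counts, _ = dp.census(make_traj(xs, np.zeros_like(xs)), spec)
        assert counts[0, 0] == 1
        short = np.zeros((1, 24))  # expires before competency
        counts, _ = dp.census(make_traj(short, np.zeros_like(short)), spec)
        assert counts[0, 0] == 0


class TestCumulate:
    def _mat(self, counts):
        return dp.ConnectivityMatrix(
            counts=np.asarray(counts), source_labels=["a", "b"], collector_labels=["c"]
        )

    def test_sum_identity_and_monotonicity(self):
        mats = [self._mat(np.array([[[i], [2 * i]]])) for i in range(4)]
        total = dp.cumulate(mats)
        assert total.cumulated[0, 0] == 0 + 1 + 2 + 3
        assert total.cumulated[1, 0] == 2 * (0 + 1 + 2 + 3)
        partial = dp.cumulate(mats[:-1])
        assert (partial.cumulated <= total.cumulated).all()

    def test_zero_matrices_sum_to_zero(self):
        mats = [self._mat(np.zeros((1, 2, 1), int)) for _ in range(15)]
        assert dp.cumulate(mats).cumulated.sum() == 0

    def test_shape_mismatch_raises(self):
        a = self._mat(np.zeros((1, 2, 1), int))
        b = dp.ConnectivityMatrix(
            counts=np.zeros((1, 3, 1), int),
            source_labels=["a", "b", "c"],
            collector_labels=["c"],
        )
        with pytest.raises(ValueError):
            dp.cumulate([a, b])


class TestRunDispersal:
    def test_particle_conservation(self):
        f = lf.build_flow_field(lf.FlowConfig(n_hours=24 * 6, seed=0))
        rel = dp.ReleaseSpec(
            sources={"E": (2500.0, 0.0), "W": (-2500.0, 0.0)},
            n_larvae_per_release=50,
            cohort_start_hours=(0.0, 24.0),
        )
        col = dp.CollectorSpec(collectors={"C": (0.0, 0.0)}, pld_max=5.0)
        conn, tallies = dp.run_dispersal(
            rel, col, f, dp.AdvectionParams(dt_hours=0.5), seed=1
        )
        for cohort, tally in enumerate(tallies):
            assert tally["released"] == 100
            assert (
                tally["censused"] + tally["expired"] + tally["dropped"]
                == tally["released"]
            )
            assert conn.counts[cohort].sum() == tally["censused"]

    def test_census_invariant_to_particle_relabeling(self):
        hours = 30
        rng = np.random.default_rng(5)
        xs = rng.uniform(-1000, 1000, (20, hours))
        ys = rng.uniform(-1000, 1000, (20, hours))
        traj = make_traj(xs, ys)
        perm = rng.permutation(20)
        traj_p = make_traj(xs[perm], ys[perm])
        c1, _ = dp.census(traj, self_coll())
        c2, _ = dp.census(traj_p, self_coll())
        assert np.array_equal(c1, c2)


def self_coll():
    return dp.CollectorSpec(collectors={"C": (0.0, 0.0)})
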