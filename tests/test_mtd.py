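"""Hill logs, FES reconstruction, minimax barriers, and the toy sampler."""

import numpy as np
import pytest

from introntoggle import mtd, synth
from introntoggle.errors import (
    BasinError,
    ParameterError,
    ReconstructionError,
    SamplerError,
)


def random_log(rng, n=40):
    log = mtd.HillLog()
    for _ in range(n):
        mtd.deposit(log, tuple(rng.normal(0, 1, 2)), tuple(0.05 + rng.random(2) * 0.3))
    return log


class TestAdaptiveWidth:
    def test_constant_history_clips_to_floor(self):
        hist = np.tile([1.0, 2.0], (10, 1))
        assert mtd.adaptive_width(hist, floor=0.03) == (0.03, 0.03)

    def test_recovers_sample_sd(self, rng):
        hist = rng.normal(0, [0.1, 0.5], size=(500, 2))
        ws, wz = mtd.adaptive_width(hist, floor=0.0)
        assert ws == pytest.approx(hist[:, 0].std(ddof=1), rel=1e-12)
        assert wz == pytest.approx(hist[:, 1].std(ddof=1), rel=1e-12)

    def test_too_short_window_rejected(self):
        with pytest.raises(ParameterError):
            mtd.adaptive_width(np.array([[1.0, 2.0]]))


class TestDeposit:
    def test_kj_to_kcal_storage(self):
        log = mtd.HillLog()
        mtd.deposit(log, (0.0, 0.0), (0.1, 0.1), height_kj=0.3)
        assert log.hills[0].height == pytest.approx(0.3 / 4.184, abs=1e-4)

    def test_unit_round_trip_is_exact(self):
        for x in (0.3, 1.0, 7.25):
            assert mtd.kcal_to_kj(mtd.kj_to_kcal(x)) == pytest.approx(x, rel=1e-12)

    def test_lengths_and_final_time(self):
        log = mtd.HillLog(stride=1.0)
        for _ in range(1000):
            mtd.deposit(log, (0.0, 0.0), (0.1, 0.1))
        assert len(log) == 1000
        assert log.hills[-1].time == pytest.approx(1000.0)

    def test_width_below_floor_rejected(self):
        log = mtd.HillLog(width_floor=0.03)
        with pytest.raises(ParameterError):
            mtd.deposit(log, (0.0, 0.0), (0.01, 0.1))


class TestBiasAt:
    def test_single_hill_center_value_is_height(self):
        log = mtd.HillLog()
        mtd.deposit(log, (1.0, 2.0), (0.1, 0.2), height_kj=0.3)
        assert mtd.bias_at(log, (1.0, 2.0)) == pytest.approx(0.3 / 4.184, rel=1e-12)

    def test_five_sigma_away_is_negligible(self):
        log = mtd.HillLog()
        mtd.deposit(log, (0.0, 0.0), (0.1, 0.1), height_kj=0.3)
        assert mtd.bias_at(log, (0.5, 0.0)) < 1e-4 * log.hills[0].height

    def test_matches_direct_loop_summation(self, rng):
        log = random_log(rng)
        point = (0.3, -0.7)
        direct = sum(
            h.height * np.exp(
                -(point[0] - h.center[0]) ** 2 / (2 * h.widths[0] ** 2)
                - (point[1] - h.center[1]) ** 2 / (2 * h.widths[1] ** 2)
            )
            for h in log.hills
        )
        assert mtd.bias_at(log, point) == pytest.approx(direct, rel=1e-12)

    def test_time_cutoff_limits_the_sum(self, rng):
        log = random_log(rng, n=20)
        partial = mtd.bias_at(log, (0.0, 0.0), up_to_time=10 * log.stride)
        direct = sum(
            h.height * np.exp(
                -h.center[0] ** 2 / (2 * h.widths[0] ** 2)
                - h.center[1] ** 2 / (2 * h.widths[1] ** 2)
            )
            for h in log.hills[:10]
        )
        assert partial == pytest.approx(direct, rel=1e-12)


class TestHillLogIO:
    def test_round_trip(self, tmp_path, rng):
        log = random_log(rng, n=25)
        p = tmp_path / "HILLS"
        mtd.write_hills(p, log)
        back = mtd.read_hills(p)
        assert len(back) == len(log)
        for a, b in zip(log.hills, back.hills):
            assert a.center == b.center
            assert a.widths == b.widths
            assert a.height == pytest.approx(b.height, rel=1e-12)

    def test_comments_ignored_and_bad_columns_rejected(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("# a comment\n1.0 0.0 0.0 0.1 0.1 0.3\n")
        assert len(mtd.read_hills(p)) == 1
        p.write_text("1.0 0.0 0.0 0.1\n")
        with pytest.raises(ParameterError, match="columns"):
            mtd.read_hills(p)


class TestReconstructFES:
    def test_single_hill_gives_well_of_hill_depth(self):
        log = mtd.HillLog()
        mtd.deposit(log, (0.0, 0.0), (0.1, 0.1), height_kj=0.3)
        fes = mtd.reconstruct_fes(log, s_axis=np.linspace(-1, 1, 201),
                                  z_axis=np.linspace(-1, 1, 201))
        assert fes.values.min() == 0.0
        # far corner sits at +height above the well bottom
        assert fes.values[0, 0] == pytest.approx(log.hills[0].height, rel=1e-4)

    def test_symmetric_two_hill_log_gives_symmetric_surface(self):
        log = mtd.HillLog()
        mtd.deposit(log, (-0.5, 0.0), (0.1, 0.1))
        mtd.deposit(log, (0.5, 0.0), (0.1, 0.1))
        axis = np.linspace(-1.5, 1.5, 301)
        fes = mtd.reconstruct_fes(log, s_axis=axis, z_axis=np.linspace(-1, 1, 51))
        np.testing.assert_allclose(fes.values, fes.values[::-1, :], atol=1e-10)

    def test_minimum_is_exactly_zero(self, rng):
        fes = mtd.reconstruct_fes(random_log(rng), n_grid=50)
        assert fes.values.min() == 0.0

    def test_empty_log_rejected(self):
        with pytest.raises(ReconstructionError):
            mtd.reconstruct_fes(mtd.HillLog())

    def test_tsv_round_trip(self, tmp_path, rng):
        fes = mtd.reconstruct_fes(random_log(rng), n_grid=20)
        p = tmp_path / "fes.tsv"
        fes.to_tsv(p)
        back = mtd.FreeEnergySurface.from_tsv(p)
        np.testing.assert_allclose(back.values, fes.values, rtol=1e-12)


def analytic_two_well_fes(barrier=5.0, offset=0.0):
    xs = np.linspace(-2, 2, 81)
    ys = np.linspace(-1, 1, 41)
    land = synth.gen_toy_landscape("double-well", barrier=barrier)
    vals = np.array([[land(x, y) + (offset if x > 0 else 0.0) for y in ys] for x in xs])
    vals -= vals.min()
    return mtd.FreeEnergySurface(xs, ys, vals)


class TestBasinsAndBarrier:
    A_HINT = ((-1.4, -0.6), (-0.5, 0.5))
    B_HINT = ((0.6, 1.4), (-0.5, 0.5))

    def test_known_saddle_recovered(self):
        fes = analytic_two_well_fes(barrier=5.0)
        rep = mtd.basins_and_barrier(fes, self.A_HINT, self.B_HINT)
        assert rep.barrier == pytest.approx(5.0, abs=0.05)
        assert rep.offset == pytest.approx(0.0, abs=0.05)

    def test_offset_of_destination_basin(self):
        fes = analytic_two_well_fes(barrier=5.0, offset=2.0)
        rep = mtd.basins_and_barrier(fes, self.A_HINT, self.B_HINT)
        assert rep.offset == pytest.approx(2.0, abs=0.1)
        assert rep.barrier >= rep.offset

    def test_single_well_query_fails(self):
        xs = np.linspace(-1, 1, 41)
        vals = np.add.outer(xs**2, xs**2)
        fes = mtd.FreeEnergySurface(xs, xs, vals - vals.min())
        with pytest.raises(BasinError):
            mtd.basins_and_barrier(fes, ((-1.0, -0.6), (-1.0, 1.0)),
                                   ((0.6, 1.0), (-1.0, 1.0)))

    def test_barrier_non_decreasing_when_saddle_raised(self):
        base = analytic_two_well_fes(barrier=3.0)
        rep0 = mtd.basins_and_barrier(base, self.A_HINT, self.B_HINT)
        raised = base.values + 2.0 * np.exp(
            -np.add.outer(base.s_axis**2, base.z_axis**2 * 0.0) / 0.08)
        fes2 = mtd.FreeEnergySurface(base.s_axis, base.z_axis, raised - raised.min())
        rep1 = mtd.basins_and_barrier(fes2, self.A_HINT, self.B_HINT)
        assert rep1.barrier >= rep0.barrier - 1e-9

    def test_distant_constant_hill_leaves_barrier_unchanged(self, rng):
        land = synth.gen_toy_landscape("double-well", barrier=3.0)
        log = mtd.HillLog()
        # synthesize a bias exactly mirroring the analytic surface
        axis = np.linspace(-1.6, 1.6, 65)
        zaxis = np.linspace(-0.6, 0.6, 33)
        vals = np.array([[land(x, y) for y in zaxis] for x in axis])
        fes0 = mtd.FreeEnergySurface(axis, zaxis, vals - vals.min())
        rep0 = mtd.basins_and_barrier(fes0, self.A_HINT, self.B_HINT)
        far = vals + 0.5 * np.exp(
            -((np.add.outer((axis - 30.0) ** 2, zaxis**2)) / 0.02))
        fes1 = mtd.FreeEnergySurface(axis, zaxis, far - far.min())
        rep1 = mtd.basins_and_barrier(fes1, self.A_HINT, self.B_HINT)
        assert rep1.barrier == pytest.approx(rep0.barrier, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_minimax_matches_exhaustive_threshold_search(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((15, 15))
        start, goal = (2, 2), (12, 12)
        got = mtd.minimax_path_value(vals, start, goal)

        # independent oracle: smallest threshold t such that start and goal
        # are connected through cells with value <= t (BFS flood fill)
        def connected(threshold):
            if vals[start] > threshold or vals[goal] > threshold:
                return False
            seen = {start}
            queue = [start]
            while queue:
                i, j = queue.pop()
                if (i, j) == goal:
                    return True
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if (0 <= ni < 15 and 0 <= nj < 15
                                and (ni, nj) not in seen
                                and vals[ni, nj] <= threshold):
                            seen.add((ni, nj))
                            queue.append((ni, nj))
            return False

        oracle = min(t for t in np.sort(vals.ravel()) if connected(t))
        assert got == pytest.approx(oracle, rel=1e-12)


class TestLangevinSampler:
    def test_zero_everything_is_stationary(self):
        traj, _ = mtd.langevin_sample(lambda x, y: 0.0, lambda x, y: (0.0, 0.0),
                                      x0=(0.3, -0.2), steps=100, temperature=0.0,
                                      height_kj=0.0, seed=0)
        np.testing.assert_allclose(traj, np.tile([0.3, -0.2], (100, 1)), atol=1e-12)

    def test_harmonic_equipartition(self):
        k = 5.0
        traj, _ = mtd.langevin_sample(
            lambda x, y: 0.5 * k * (x * x + y * y),
            lambda x, y: (k * x, k * y),
            steps=200_000, dt=0.01, temperature=300.0, seed=3, height_kj=0.0)
        expected = mtd.KB_KCAL * 300.0 / k
        assert traj[:, 0].var() == pytest.approx(expected, rel=0.05)
        assert traj[:, 1].var() == pytest.approx(expected, rel=0.05)

    def test_seeded_runs_are_bit_reproducible(self):
        land = synth.gen_toy_landscape("double-well")
        runs = [
            mtd.langevin_sample(land.potential, land.gradient, x0=(-1.0, 0.0),
                                steps=2000, dt=0.005, seed=42)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0][0], runs[1][0])
        assert [h.center for h in runs[0][1].hills] == [h.center for h in runs[1][1].hills]
        assert [h.widths for h in runs[0][1].hills] == [h.widths for h in runs[1][1].hills]

    def test_divergence_reported_with_advice(self):
        land = synth.gen_toy_landscape("double-well", barrier=50.0)
        with pytest.raises(SamplerError, match="smaller dt"):
            mtd.langevin_sample(land.potential, land.gradient, x0=(1.5, 0.0),
                                steps=10_000, dt=5.0, seed=1, height_kj=0.0)

    def test_numerical_gradient_fallback(self):
        k = 2.0
        traj, _ = mtd.langevin_sample(lambda x, y: 0.5 * k * (x * x + y * y),
                                      gradient=None, steps=5000, dt=0.01,
                                      temperature=300.0, seed=5, height_kj=0.0)
        assert np.isfinite(traj).all()
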