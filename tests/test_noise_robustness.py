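import numpy as np
import pytest

from cncorr import (EventScript, cell_cmpi, cn_series, cn_series_from_pairs,
                    displacement_pairs, estimate_intrinsic_sigma,
                    inject_displacement_noise, inject_position_noise,
                    noise_implemented_cmpi, robustness_grid, simulate_events,
                    simulate_fixed_cell)
from cncorr.io_formats import TrajectoryPair


def mixed_event_cells(n_cells=6, n_intervals=60, seed=0):
    cells = []
    rs = np.random.default_rng(seed)
    for i in range(n_cells):
        events = list(rs.choice(["detachment", "mixed", "protrusion", "turn"],
                                size=n_intervals, p=[0.3, 0.3, 0.3, 0.1]))
        traj, _ = simulate_events(EventScript(events=events, seed=i))
        cells.append(TrajectoryPair(f"c{i}", traj.times, traj.cell_xy, traj.nuc_xy))
    return cells


class TestEstimateIntrinsicSigma:
    def test_zero_jitter(self):
        traj = simulate_fixed_cell(0.0, n_steps=40, seed=0)
        assert estimate_intrinsic_sigma(traj) == (0.0, 0.0)

    def test_anisotropic_jitter_recovered(self):
        rs = np.random.default_rng(10)
        n = 2000
        cell = np.column_stack([rs.normal(0, 0.3, n), rs.normal(0, 0.1, n)])
        traj = TrajectoryPair("f", np.arange(float(n)), cell, cell)
        sx, sy = estimate_intrinsic_sigma(traj)
        assert sx == pytest.approx(0.3, rel=0.1)
        assert sy == pytest.approx(0.1, rel=0.1)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            estimate_intrinsic_sigma(simulate_fixed_cell(0.1, n_steps=10, seed=0))


class TestInjectNoise:
    def test_sigma_zero_is_identity(self, rng):
        c = rng.normal(size=(20, 2))
        n = rng.normal(size=(20, 2))
        c2, n2 = inject_displacement_noise(c, n, 0.0, rng)
        assert c2 is c and n2 is n

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            inject_displacement_noise(np.zeros((2, 2)), np.zeros((2, 2)), -0.1)

    def test_reproducible_under_seed(self, rng):
        c = rng.normal(size=(20, 2))
        n = rng.normal(size=(20, 2))
        a = inject_displacement_noise(c, n, 0.5, 42)
        b = inject_displacement_noise(c, n, 0.5, 42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_large_noise_reaches_isotropic_region_mix(self):
        # tiny true displacements swamped by sigma = 10: CCD becomes Rayleigh and
        # NCD_// an independent Normal of the same scale, so (NCD_//, CCD) is the
        # (z, sqrt(x^2+y^2)) of an isotropic 3-D Gaussian and theta follows the
        # polar sin(theta)/2 law; region masses are (cos a - cos b)/2
        traj, _ = simulate_events(EventScript.uniform("detachment", 20000,
                                                      cell_step=1e-3))
        c, n = displacement_pairs(traj, 1)
        c2, n2 = inject_displacement_noise(c, n, 10.0, 1)
        series = cn_series_from_pairs(c2, n2)
        frac = series["region"].value_counts(normalize=True)
        deg = np.radians
        expect = {
            "I": (1 - np.cos(deg(45))) / 2,
            "II": (np.cos(deg(45)) - np.cos(deg(75))) / 2,
            "III": (np.cos(deg(75)) - np.cos(deg(105))) / 2,
            "IV": (np.cos(deg(105)) + 1) / 2,
        }
        for region, p in expect.items():
            assert frac[region] == pytest.approx(p, abs=0.02)

    def test_position_noise_mode(self):
        traj, _ = simulate_events(EventScript.uniform("mixed", 30))
        same = inject_position_noise(traj, 0.0)
        assert same is traj
        moved = inject_position_noise(traj, 0.2, 3)
        assert not np.allclose(moved.cell_xy, traj.cell_xy)


class TestNoiseImplementedCmpi:
    def test_sigma_zero_equals_noise_free(self):
        cells = mixed_event_cells()
        sweep = noise_implemented_cmpi(cells, [0.0], repeats=5, seed=1)
        direct = np.mean([cell_cmpi(cn_series(t)).cmpi for t in cells])
        assert sweep.mean_cmpi[0] == direct  # bit-exact identity

    def test_repeat_counts_agree_in_expectation(self):
        cells = mixed_event_cells(n_cells=4, n_intervals=40)
        few = noise_implemented_cmpi(cells, [0.3], repeats=40, seed=2)
        many = noise_implemented_cmpi(cells, [0.3], repeats=400, seed=3)
        assert few.mean_cmpi[0] == pytest.approx(many.mean_cmpi[0], rel=0.1)

    def test_monotone_rise_with_sigma(self):
        cells = mixed_event_cells()
        sweep = noise_implemented_cmpi(cells, [0.3, 0.6, 1.0], repeats=100, seed=4)
        assert sweep.mean_cmpi[0] < sweep.mean_cmpi[1] < sweep.mean_cmpi[2]

    def test_reproducible_under_seed(self):
        cells = mixed_event_cells(n_cells=3, n_intervals=30)
        a = noise_implemented_cmpi(cells, [0.2], repeats=20, seed=5)
        b = noise_implemented_cmpi(cells, [0.2], repeats=20, seed=5)
        np.testing.assert_array_equal(a.mean_cmpi, b.mean_cmpi)


class TestRobustnessGrid:
    def proportional_types(self, steps=(0.2, 0.4, 0.6, 0.8, 1.0, 1.2)):
        # straight detachment walkers: CMPI is exactly 1.5 * step * lag,
        # so assigning mu proportional to step makes the relation exactly linear
        data, mu = {}, {}
        for j, step in enumerate(steps):
            traj, _ = simulate_events(
                EventScript.uniform("detachment", 60, cell_step=step))
            data[f"type{j}"] = [traj] * 3
            mu[f"type{j}"] = 2.5 * step
        return data, mu

    def test_exact_linearity_at_sigma_zero(self):
        data, mu = self.proportional_types()
        grid = robustness_grid(data, mu, taus=(1, 2, 3, 5, 10), sigmas=(0.0,),
                               repeats=1, seed=0)
        assert (grid["r2"] > 0.999999).all()

    def test_r2_degrades_with_noise(self):
        data, mu = self.proportional_types()
        grid = robustness_grid(data, mu, taus=(1,), sigmas=(0.0, 5.0),
                               repeats=30, seed=1)
        r2 = grid.set_index("sigma")["r2"]
        assert r2[5.0] < r2[0.0]

    def test_needs_three_types(self):
        data, mu = self.proportional_types(steps=(0.5, 1.0))
        with pytest.raises(ValueError):
            robustness_grid(data, mu)

    def test_subsampling_equals_coarser_reading(self):
        # lag-2 analysis of 1-min data equals re-reading every other frame
        traj, _ = simulate_events(EventScript.uniform("mixed", 40, seed=0,
                                                      jitter_sigma=0.05))
        lag2 = cn_series(traj, lag_steps=2)
        coarse = TrajectoryPair("c", traj.times[::2], traj.cell_xy[::2],
                                traj.nuc_xy[::2])
        reread = cn_series(coarse, lag_steps=1)
        half = lag2[lag2["interval_index"] % 2 == 0].reset_index(drop=True)
        np.testing.assert_allclose(half["ccd_um"], reread["ccd_um"], atol=1e-12)
        np.testing.assert_allclose(half["ncd_par_um"], reread["ncd_par_um"], atol=1e-12)
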