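import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cncorr import (TrajectoryPair, classify_region, cn_series, displacement_pairs,
                    project_ncd, series_autocorrelation)
from cncorr.cn_core import UNDEFINED, ZERO_CCD_TOL
from conftest import random_cn_series


def brute_force_region(ccd, ncd_par):
    """Independent oracle: angle of the (NCD_//, CCD) point from the NCD_// axis
    via explicit arccos with sign handling, then the printed brackets."""
    if ccd <= ZERO_CCD_TOL:
        return UNDEFINED
    r = np.hypot(ncd_par, ccd)
    theta = np.degrees(np.arccos(np.clip(ncd_par / r, -1.0, 1.0)))  # ccd >= 0 => theta in [0, 180]
    if theta <= 45.0:
        return "I"
    if theta <= 75.0:
        return "II"
    if theta <= 105.0:
        return "III"
    return "IV"


class TestDisplacementPairs:
    def test_single_step(self):
        traj = TrajectoryPair("c", [0.0, 1.0], [[0, 0], [1, 0]], [[0, 0], [0.5, 0]])
        ccd_vecs, ncd_vecs = displacement_pairs(traj, 1)
        np.testing.assert_array_equal(ccd_vecs, [[1.0, 0.0]])
        np.testing.assert_array_equal(ncd_vecs, [[0.5, 0.0]])

    @pytest.mark.parametrize("lag,expected", [(1, 60), (3, 58)])
    def test_count_from_hour_movie(self, rng, lag, expected):
        # a 61-frame one-hour movie at 1-min spacing carries 60 per-minute points
        traj = TrajectoryPair("c", np.arange(61.0), rng.normal(size=(61, 2)),
                              rng.normal(size=(61, 2)))
        ccd_vecs, _ = displacement_pairs(traj, lag)
        assert len(ccd_vecs) == expected

    def test_lag_too_large(self, straight_traj):
        with pytest.raises(ValueError):
            displacement_pairs(straight_traj, straight_traj.n_frames)


class TestProjectNcd:
    @pytest.mark.parametrize(
        "ccd_vec,ncd_vec,expected",
        [
            ((1, 0), (0.5, 0.7), (1.0, 0.5)),  # axis-aligned dot product
            ((1, 0), (0, 2.0), (1.0, 0.0)),  # orthogonal NCD projects to zero
            ((3, 4), (3, 4), (5.0, 5.0)),  # (3*3 + 4*4)/5
        ],
    )
    def test_examples(self, ccd_vec, ncd_vec, expected):
        ccd, ncd_par = project_ncd(ccd_vec, ncd_vec)
        assert ccd == pytest.approx(expected[0])
        assert ncd_par == pytest.approx(expected[1])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            project_ncd((np.nan, 0), (0, 0))


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "ccd,ncd_par,region",
        [
            (1.0, 1.0, "I"),  # theta = 45 exactly: boundary closes the lower region
            (np.tan(np.radians(75.0)), 1.0, "II"),  # theta = 75 exactly: Region II
            (1.0, 0.0, "III"),  # theta = 90, pure protrusion
            (0.2, -1.0, "IV"),  # theta ~ 168.69, large-angle turn
            (0.0, 123.0, UNDEFINED),  # zero CCD has no direction
        ],
    )
    def test_examples(self, ccd, ncd_par, region):
        assert classify_region(ccd, ncd_par) == region

    def test_matches_brute_force_oracle(self, rng):
        ccd_vecs = rng.normal(size=(10_000, 2))
        ncd_vecs = rng.normal(size=(10_000, 2))
        ccd, ncd_par = project_ncd(ccd_vecs, ncd_vecs)
        fast = classify_region(ccd, ncd_par)
        slow = [brute_force_region(c, n) for c, n in zip(ccd, ncd_par)]
        assert list(fast) == slow

    def test_partition(self, rng):
        # every defined point lands in exactly one of I-IV
        labels = random_cn_series(rng, n=2000)["region"]
        assert set(labels) <= {"I", "II", "III", "IV"}


class TestInvariances:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(angle=st.floats(0, 2 * np.pi), dx=st.floats(-50, 50), dy=st.floats(-50, 50))
    def test_rotation_translation(self, angle, dx, dy):
        rs = np.random.default_rng(3)
        times = np.arange(20.0)
        cell = np.cumsum(rs.normal(size=(20, 2)), axis=0)
        nuc = np.cumsum(rs.normal(size=(20, 2)), axis=0)
        base = cn_series(TrajectoryPair("c", times, cell, nuc))
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        shift = np.array([dx, dy])
        moved = cn_series(TrajectoryPair("c", times, cell @ R.T + shift, nuc @ R.T + shift))
        np.testing.assert_allclose(moved["ccd_um"], base["ccd_um"], atol=1e-9)
        np.testing.assert_allclose(moved["ncd_par_um"], base["ncd_par_um"], atol=1e-9)
        assert list(moved["region"]) == list(base["region"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_equivariance(self, scale):
        rs = np.random.default_rng(4)
        times = np.arange(15.0)
        cell = np.cumsum(rs.normal(size=(15, 2)), axis=0)
        nuc = np.cumsum(rs.normal(size=(15, 2)), axis=0)
        base = cn_series(TrajectoryPair("c", times, cell, nuc))
        scaled = cn_series(TrajectoryPair("c", times, scale * cell, scale * nuc))
        np.testing.assert_allclose(scaled["ccd_um"], scale * base["ccd_um"], rtol=1e-9)
        np.testing.assert_allclose(scaled["ncd_par_um"], scale * base["ncd_par_um"],
                                   rtol=1e-9, atol=1e-12 * scale)
        assert list(scaled["region"]) == list(base["region"])


class TestCnSeries:
    def test_straight_comoving_all_region_I(self, straight_traj):
        series = cn_series(straight_traj)
        assert set(series["region"]) == {"I"}
        np.testing.assert_allclose(series["theta_deg"], np.degrees(np.arctan2(1, 1.5)))

    def test_frozen_nucleus_all_protrusion(self, rng):
        times = np.arange(30.0)
        cell = np.cumsum(rng.normal(size=(30, 2)), axis=0)
        nuc = np.tile([2.0, 3.0], (30, 1))
        series = cn_series(TrajectoryPair("c", times, cell, nuc))
        assert set(series["region"]) == {"III"}
        np.testing.assert_allclose(series["ncd_par_um"], 0.0, atol=1e-12)


class TestAutocorrelation:
    def test_constant_series_is_one(self):
        r = series_autocorrelation(np.full(50, 3.3), max_lag=5)
        np.testing.assert_allclose(r, 1.0)

    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 25)
        r = series_autocorrelation(x, max_lag=2)
        assert r[1] == pytest.approx(-1.0)
        assert r[2] == pytest.approx(1.0)

    def test_iid_noise_decorrelates(self, rng):
        x = rng.normal(size=1000)
        r = series_autocorrelation(x, max_lag=3)
        assert np.all(np.abs(r[1:]) < 3 / np.sqrt(1000))

    def test_nan_pairs_excluded(self):
        x = np.array([1.0, 2.0, np.nan, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0])
        r = series_autocorrelation(x, max_lag=1)
        assert np.isfinite(r[1])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            series_autocorrelation([1.0, 2.0, 3.0], max_lag=2)
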