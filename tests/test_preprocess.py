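import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parcelstim.preprocess import (TimeSeriesMatrix, ConfoundSet,
                                   PreprocessError, compute_dvars,
                                   scrub_frames, detrend,
                                   compcor_confounds, regress_confounds,
                                   normalize_variance, preprocess,
                                   _trend_basis)


def make_ts(values, **kw):
    return TimeSeriesMatrix(values=np.asarray(values, float), **kw)


class TestDVARS:
    def test_hand_computed_example(self):
        # two parcels, frame change {3, 4}: rms = sqrt((9+16)/2)
        ts = make_ts([[0, 3], [0, 4]])
        dvars = compute_dvars(ts)
        assert dvars[0] == 0.0
        assert dvars[1] == pytest.approx(np.sqrt(25 / 2), abs=1e-12)

    def test_constant_series_gives_zero(self):
        ts = make_ts(np.full((4, 10), 7.0))
        assert np.all(compute_dvars(ts) == 0.0)

    def test_single_frame_errors(self):
        with pytest.raises(PreprocessError):
            compute_dvars(make_ts([[1.0], [2.0]]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_to_parcel_order(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((6, 20))
        perm = rng.permutation(6)
        np.testing.assert_allclose(compute_dvars(make_ts(x)),
                                   compute_dvars(make_ts(x[perm])),
                                   rtol=1e-12)


class TestScrub:
    def test_uniform_dvars_scrubs_nothing(self):
        ts = make_ts(np.tile([[0, 1, 2, 3, 4, 5]], (3, 1)).astype(float))
        dvars = compute_dvars(ts)  # all equal after frame 0
        out = scrub_frames(ts, dvars)
        assert out.frame_mask.all()

    def test_spiked_frame_is_masked(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 40))
        x[:, 20] += 25.0  # motion spike at frame 20
        ts = make_ts(x)
        dvars = compute_dvars(ts)
        thresh = dvars[1:].mean() + 2 * dvars[1:].std()
        expected_bad = np.flatnonzero(dvars > thresh)
        assert 20 in expected_bad
        out = scrub_frames(ts, dvars)
        assert not out.frame_mask[expected_bad].any()
        # mask false count matches the threshold rule exactly
        assert (~out.frame_mask).sum() == len(expected_bad)

    def test_all_scrubbed_errors(self):
        # frame 0 already masked; a very permissive threshold removes
        # the rest, leaving nothing usable
        mask = np.array([False, True, True, True, True])
        ts = make_ts(np.ones((2, 5)), frame_mask=mask)
        with pytest.raises(PreprocessError, match="all frames"):
            scrub_frames(ts, np.array([0.0, 1, 2, 3, 4]), n_sigma=-10.0)

    def test_rank_deficiency_warns(self):
        rng = np.random.default_rng(3)
        ts = make_ts(rng.standard_normal((30, 20)))
        with pytest.warns(UserWarning, match="rank-deficient"):
            scrub_frames(ts, compute_dvars(ts))


class TestDetrend:
    def test_pure_quadratic_removed_exactly(self):
        t = np.arange(30, dtype=float)
        ts = make_ts(np.vstack([2 + 3 * t - 0.5 * t ** 2,
                                1 - t + 0.02 * t ** 2]))
        out = detrend(ts)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-8)

    def test_projection_reduces_variance_and_centers(self):
        rng = np.random.default_rng(7)
        ts = make_ts(rng.standard_normal((4, 50)))
        out = detrend(ts)
        assert np.all(out.retained().var(axis=1)
                      <= ts.retained().var(axis=1) + 1e-12)
        sd = ts.retained().std()
        assert np.all(np.abs(out.retained().mean(axis=1)) < 1e-9 * sd)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_residual_orthogonal_to_trend_basis(self, seed):
        rng = np.random.default_rng(seed)
        ts = make_ts(rng.standard_normal((3, 40)))
        out = detrend(ts)
        basis = _trend_basis(np.arange(40, dtype=float))
        inner = out.retained() @ basis
        scale = np.linalg.norm(out.retained()) or 1.0
        assert np.abs(inner).max() / scale < 1e-6

    def test_respects_frame_mask(self):
        t = np.arange(30, dtype=float)
        mask = np.ones(30, bool)
        mask[5] = False
        ts = make_ts(np.vstack([t ** 2]), frame_mask=mask)
        out = detrend(ts)
        np.testing.assert_allclose(out.retained(), 0.0, atol=1e-8)

    def test_too_few_frames_errors(self):
        with pytest.raises(PreprocessError):
            detrend(make_ts(np.ones((2, 3))))


class TestConfoundRegression:
    def test_self_regression_zeroes_parcel(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((3, 30))
        conf = ConfoundSet(x[1][:, None])
        out = regress_confounds(make_ts(x), conf)
        np.testing.assert_allclose(out.values[1], 0.0, atol=1e-10)

    def test_no_confounds_is_identity(self):
        rng = np.random.default_rng(12)
        ts = make_ts(rng.standard_normal((3, 30)))
        out = regress_confounds(ts, ConfoundSet(np.empty((0, 0))))
        np.testing.assert_array_equal(out.values, ts.values)

    def test_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(13)
        ts = make_ts(rng.standard_normal((4, 40)))
        conf = ConfoundSet(rng.standard_normal((40, 3)))
        out = regress_confounds(ts, conf)
        inner = out.retained() @ conf.regressors
        assert np.abs(inner).max() < 1e-8

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(14)
        ts = make_ts(rng.standard_normal((3, 30)))
        col = rng.standard_normal((30, 1))
        conf = ConfoundSet(np.hstack([col, 2 * col]))
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_confounds(ts, conf)
        inner = out.retained() @ col
        assert np.abs(inner).max() < 1e-8

    def test_compcor_pool_is_highest_variance(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal((20, 60))
        x[17:] *= 10.0  # noise pool
        conf = compcor_confounds(make_ts(x), n_components=2)
        assert conf.k == 2
        assert conf.regressors.shape == (60, 2)


class TestPipelineDriver:
    def test_output_normalized_and_order_applied(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal((10, 80))
        x[:, 40] += 30.0  # spike to exercise scrubbing
        out = preprocess(make_ts(x))
        assert not out.frame_mask[40]
        np.testing.assert_allclose(out.retained().std(axis=1, ddof=1),
                                   1.0, rtol=1e-10)

    def test_zero_variance_parcel_errors(self):
        x = np.vstack([np.zeros(20), np.random.default_rng(1)
                       .standard_normal(20)])
        with pytest.raises(PreprocessError, match="zero-variance"):
            normalize_variance(make_ts(x))


class TestTimeSeriesIO:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(17)
        ts = make_ts(rng.standard_normal((4, 12)),
                     parcel_ids=[3, 1, 4, 1_5])
        mask = np.ones(12, bool)
        mask[2] = False
        ts.frame_mask = mask
        p = tmp_path / "ts.tsv"
        m = tmp_path / "mask.tsv"
        ts.to_tsv(p, mask_path=m)
        back = TimeSeriesMatrix.from_tsv(p, mask_path=m)
        np.testing.assert_allclose(back.values, ts.values)
        np.testing.assert_array_equal(back.frame_mask, ts.frame_mask)
        assert back.parcel_ids == ts.parcel_ids

    def test_write_read_write_is_identical(self, tmp_path):
        rng = np.random.default_rng(18)
        ts = make_ts(rng.standard_normal((3, 8)))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        ts.to_tsv(p1)
        TimeSeriesMatrix.from_tsv(p1).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_nan_in_retained_frames_rejected(self):
        x = np.ones((2, 5))
        x[0, 2] = np.nan
        with pytest.raises(PreprocessError):
            make_ts(x)
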