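import math

import numpy as np
import pytest

import parcelstim as ps
from parcelstim.normative import (NormativeConnectivity, NormativeError,
                                  n_edges, FLAG_HYPER, FLAG_HYPO,
                                  FLAG_EXCLUDED, FLAG_NORMAL)


def random_tangent_stack(rng, n_subjects, p, scale=0.1):
    stack = rng.normal(0, scale, size=(n_subjects, p, p))
    return (stack + stack.transpose(0, 2, 1)) / 2


class TestFit:
    @pytest.mark.parametrize("p", [4, 10, 25])
    def test_excluded_count_is_ceil_third(self, rng, p):
        res = NormativeConnectivity(
            random_tangent_stack(rng, 15, p)).fit()
        assert res.n_excluded == math.ceil(n_edges(p) / 3)

    def test_exclusion_targets_highest_variance(self, rng):
        stack = random_tangent_stack(rng, 30, 6, scale=0.05)
        stack[:, 0, 1] = stack[:, 1, 0] = rng.normal(0, 5.0, 30)
        res = NormativeConnectivity(stack).fit()
        k = np.flatnonzero((res.edge_i == 0) & (res.edge_j == 1))[0]
        assert res.excluded[k]

    def test_variance_ties_broken_by_edge_index(self):
        # identical variance everywhere: the first ceil(E/3) edge
        # indices must be the excluded ones
        base = np.zeros((4, 4))
        stack = np.stack([base, base + np.triu(np.ones((4, 4)), 1)
                          + np.triu(np.ones((4, 4)), 1).T])
        stack = np.concatenate([stack] * 6)  # 12 subjects, equal edge SD
        res = NormativeConnectivity(stack).fit()
        n_excl = math.ceil(6 / 3)
        assert list(np.flatnonzero(res.excluded)) == list(range(n_excl))

    def test_degenerate_reference_rejected(self, rng):
        stack = np.repeat(random_tangent_stack(rng, 1, 5), 12, axis=0)
        with pytest.raises(NormativeError, match="zero SD"):
            NormativeConnectivity(stack).fit()

    def test_cohort_floor_enforced(self, rng):
        with pytest.raises(NormativeError, match="at least"):
            NormativeConnectivity(random_tangent_stack(rng, 5, 4))

    def test_results_tsv_round_trip(self, rng, tmp_path):
        res = NormativeConnectivity(random_tangent_stack(rng, 12, 5)).fit()
        p = tmp_path / "model.tsv"
        res.to_tsv(p)
        back = type(res).from_tsv(p, n_reference=12)
        np.testing.assert_allclose(back.mean, res.mean)
        np.testing.assert_allclose(back.sd, res.sd)
        np.testing.assert_array_equal(back.excluded, res.excluded)


class TestScore:
    def test_model_means_score_to_zero(self, rng):
        res = NormativeConnectivity(random_tangent_stack(rng, 20, 6)).fit()
        t = np.zeros((6, 6))
        t[res.edge_i, res.edge_j] = res.mean
        t = t + t.T
        a = res.score(t)
        ok = ~res.excluded
        np.testing.assert_allclose(a.z[ok], 0.0, atol=1e-12)
        assert a.counts()["hyper"] == 0 and a.counts()["hypo"] == 0

    def test_flags_match_z_threshold_strictly(self, rng):
        res = NormativeConnectivity(random_tangent_stack(rng, 20, 8)).fit()
        t = random_tangent_stack(rng, 1, 8, scale=0.5)[0]
        a = res.score(t)
        ok = ~np.isnan(a.z)
        assert np.array_equal(a.flags[ok] == FLAG_HYPER, a.z[ok] > 3)
        assert np.array_equal(a.flags[ok] == FLAG_HYPO, a.z[ok] < -3)
        # excluded edges carry no z
        assert np.isnan(a.z[res.excluded]).all()

    def test_translation_consistency(self, rng):
        stack = random_tangent_stack(rng, 20, 6)
        res = NormativeConnectivity(stack).fit()
        t = random_tangent_stack(rng, 1, 6)[0]
        z_before = res.score(t).z
        # shift one non-excluded edge in both the model and the subject
        k = int(np.flatnonzero(~res.excluded)[0])
        i, j = res.edge_i[k], res.edge_j[k]
        res.mean[k] += 0.7
        t2 = t.copy()
        t2[i, j] += 0.7
        t2[j, i] += 0.7
        z_after = res.score(t2).z
        np.testing.assert_allclose(z_after[k], z_before[k], atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        res = NormativeConnectivity(random_tangent_stack(rng, 12, 5)).fit()
        with pytest.raises(NormativeError):
            res.score(np.zeros((6, 6)))

    def test_lower_sigma_yields_superset_of_anomalies(self, rng):
        res = NormativeConnectivity(random_tangent_stack(rng, 20, 8)).fit()
        t = random_tangent_stack(rng, 1, 8, scale=0.4)[0]
        a3 = res.score(t, sigma=3.0)
        a2 = res.score(t, sigma=2.0)
        flagged3 = set(map(tuple, a3.anomalous_edges()[
            ["edge_i", "edge_j"]].to_numpy()))
        flagged2 = set(map(tuple, a2.anomalous_edges()[
            ["edge_i", "edge_j"]].to_numpy()))
        assert flagged3 <= flagged2


class TestNetworkRestriction:
    def test_all_networks_is_identity(self, rng, atlas60, reference):
        t = random_tangent_stack(rng, 1, 60, scale=0.3)[0]
        a = reference.results.score(t)
        nets = set(atlas60.networks.unique())
        b = a.restrict_networks(atlas60, nets)
        assert np.array_equal(a.flags, b.flags)

    def test_single_network_keeps_only_internal_edges(self, rng, atlas60,
                                                      reference):
        t = random_tangent_stack(rng, 1, 60, scale=0.3)[0]
        a = reference.results.score(t)
        b = a.restrict_networks(atlas60, {"DMN"})
        in_dmn = atlas60.parcels_in({"DMN"})
        active = b.flags != FLAG_EXCLUDED
        assert np.all(in_dmn[b.edge_i[active]])
        assert np.all(in_dmn[b.edge_j[active]])
        # z kept for audit on re-excluded edges
        re_excluded = (a.flags != FLAG_EXCLUDED) & (b.flags == FLAG_EXCLUDED)
        assert np.isfinite(b.z[re_excluded]).all()

    def test_multi_network_selection_keeps_cross_edges(self, rng, atlas60,
                                                       reference):
        t = random_tangent_stack(rng, 1, 60, scale=0.3)[0]
        a = reference.results.score(t)
        b = a.restrict_networks(atlas60, {"DMN", "CEN", "Salience"})
        scope = atlas60.parcels_in({"DMN", "CEN", "Salience"})
        cross = (scope[a.edge_i] & scope[a.edge_j]
                 & (a.flags != FLAG_EXCLUDED))
        assert np.array_equal(b.flags[cross], a.flags[cross])

    def test_empty_network_set_rejected(self, rng, atlas60, reference):
        t = random_tangent_stack(rng, 1, 60, scale=0.1)[0]
        a = reference.results.score(t)
        with pytest.raises(NormativeError):
            a.restrict_networks(atlas60, set())


class TestHeatmap:
    def _toy_anomaly(self):
        res = NormativeConnectivity(
            random_tangent_stack(np.random.default_rng(5), 20, 5)).fit()
        t = np.zeros((5, 5))
        t[res.edge_i, res.edge_j] = res.mean
        t = t + t.T
        k = int(np.flatnonzero(~res.excluded)[0])
        i, j = res.edge_i[k], res.edge_j[k]
        t[i, j] = t[j, i] = res.mean[k] + 10 * res.sd[k]
        return res.score(t)

    def test_single_hyper_edge_gives_two_red_cells(self):
        a = self._toy_anomaly()
        m = a.flag_matrix()
        assert (m == 1).sum() == 2  # symmetric pair
        assert np.array_equal(m, m.T)

    def test_color_counts_match_flag_counts(self):
        a = self._toy_anomaly()
        m = a.flag_matrix()
        c = a.counts()
        for code, name in ((1, FLAG_HYPER), (2, FLAG_HYPO),
                           (3, FLAG_EXCLUDED)):
            assert (m == code).sum() == 2 * c[name]
        assert (m == 0).sum() == 2 * c[FLAG_NORMAL] + a.n_parcels

    def test_png_written(self, tmp_path):
        a = self._toy_anomaly()
        out = tmp_path / "heatmap.png"
        ps.render_anomaly_heatmap(a, out, title="toy")
        assert out.exists() and out.stat().st_size > 0

    def test_anomaly_tsv_round_trip(self, tmp_path):
        a = self._toy_anomaly()
        p = tmp_path / "a.tsv"
        a.to_tsv(p)
        back = type(a).from_tsv(p)
        np.testing.assert_allclose(back.z, a.z)
        assert np.array_equal(back.flags, a.flags)
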