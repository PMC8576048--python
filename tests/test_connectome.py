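"""Time-series preprocessing, Pearson FC and network vectorization."""

import numpy as np
import pytest

from hemiconn.atlas import Atlas, AtlasNode, partition_edges
from hemiconn.connectome import (
    ConnectivityMatrix, TimeSeriesPanel, bandpass_filter, build_feature_matrix,
    compute_fc, discard_initial_volumes, vectorize,
)


def panel(values, tr=2.0, sid="S"):
    return TimeSeriesPanel(sid, np.asarray(values, dtype=float), tr)


class TestDiscardVolumes:
    def test_default_discard(self):
        p = panel(np.random.default_rng(0).normal(size=(240, 3)))
        out = discard_initial_volumes(p)
        assert out.n_timepoints == 230
        assert out.tr_seconds == p.tr_seconds
        np.testing.assert_array_equal(out.values, p.values[10:])

    def test_zero_is_identity(self):
        p = panel(np.random.default_rng(1).normal(size=(20, 2)))
        np.testing.assert_array_equal(discard_initial_volumes(p, 0).values, p.values)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            discard_initial_volumes(panel(np.zeros((5, 2)) + np.arange(5)[:, None]), 10)


class TestBandpass:
    def _sinusoid(self, freq, T=512, tr=2.0):
        t = np.arange(T) * tr
        return np.sin(2 * np.pi * freq * t)

    def test_dc_removed(self):
        p = panel(np.column_stack([np.full(256, 5.0), self._sinusoid(0.05, 256)]))
        out = bandpass_filter(p)
        assert np.max(np.abs(out.values[:, 0])) < 1e-6

    def test_passband_preserved(self):
        x = self._sinusoid(0.05)
        out = bandpass_filter(panel(x[:, None])).values[:, 0]
        core = slice(100, 412)  # avoid filtfilt edge transients
        ratio = np.max(np.abs(out[core])) / np.max(np.abs(x[core]))
        assert ratio > 0.9

    def test_stopband_attenuated(self):
        for freq in (0.2, 0.5 / 2.0 * 0.8):  # 0.2 Hz and near-Nyquist
            x = self._sinusoid(freq)
            out = bandpass_filter(panel(x[:, None])).values[:, 0]
            assert np.max(np.abs(out[100:412])) < 0.1

    def test_invalid_band_errors(self):
        p = panel(np.random.default_rng(2).normal(size=(64, 1)), tr=2.0)
        with pytest.raises(ValueError):
            bandpass_filter(p, low=0.01, high=0.3)  # above 0.25 Hz Nyquist
        with pytest.raises(ValueError):
            bandpass_filter(p, low=0.1, high=0.01)

    def test_output_length_and_columns_identical_treatment(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        p = panel(np.column_stack([x, x]))
        out = bandpass_filter(p)
        assert out.n_timepoints == 200
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1])


class TestComputeFC:
    def test_identical_and_negated_columns(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        fc = compute_fc(panel(np.column_stack([x, x, -x])))
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # r((1,2,3),(1,3,2)) = (1/3) / (2/3) = 0.5 by the product-moment formula
        fc = compute_fc(panel(np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0]])))
        assert fc.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_column_named(self):
        with pytest.raises(ValueError, match="ROI_B"):
            compute_fc(
                panel(np.column_stack([np.arange(5.0), np.ones(5)])),
                roi_names=["ROI_A", "ROI_B"],
            )

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(40, 4))
        fc0 = compute_fc(panel(v))
        w = v.copy()
        w[:, 2] = 3.7 * w[:, 2] + 11.0
        np.testing.assert_allclose(compute_fc(panel(w)).values, fc0.values, atol=1e-12)

    def test_matrix_invariants(self):
        rng = np.random.default_rng(6)
        fc = compute_fc(panel(rng.normal(size=(60, 8))))
        assert np.allclose(fc.values, fc.values.T)
        assert np.allclose(np.diag(fc.values), 1.0)
        assert fc.values.min() >= -1 and fc.values.max() <= 1


class TestVectorize:
    def test_ho_row_on_toy_atlas(self, toy4_atlas):
        part = partition_edges(toy4_atlas)
        m = np.eye(4)
        vals = {(1, 3): 0.3, (2, 4): -0.2, (1, 2): 0.5, (3, 4): 0.6,
                (1, 4): 0.1, (2, 3): 0.05}
        for (i, j), v in vals.items():
            m[i - 1, j - 1] = m[j - 1, i - 1] = v
        fc = ConnectivityMatrix("S", m)
        np.testing.assert_array_equal(vectorize(fc, part, "Ho"), [0.3, -0.2])
        np.testing.assert_array_equal(vectorize(fc, part, "LH"), [0.5])
        np.testing.assert_array_equal(vectorize(fc, part, "He"), [0.1, 0.05])

    def test_identity_fc_gives_zeros(self, toy4_atlas):
        part = partition_edges(toy4_atlas)
        fc = ConnectivityMatrix("S", np.eye(4))
        assert not vectorize(fc, part, "He").any()

    def test_lh_length_on_bundled_atlas(self, bundled_atlas):
        part = partition_edges(bundled_atlas)
        fc = ConnectivityMatrix("S", np.eye(246))
        assert vectorize(fc, part, "LH").shape == (7503,)

    def test_dimension_mismatch_errors(self, bundled_atlas):
        part = partition_edges(bundled_atlas)
        with pytest.raises(ValueError):
            vectorize(ConnectivityMatrix("S", np.eye(4)), part, "LH")

    def test_permutation_consistency(self):
        """Relabeling ROIs and the atlas together leaves each named edge's
        feature value unchanged."""
        rng = np.random.default_rng(7)
        from hemiconn.atlas import make_synthetic_atlas

        atlas = make_synthetic_atlas(3)  # 6 nodes
        part = partition_edges(atlas)
        v = rng.normal(size=(80, 6))
        fc = compute_fc(TimeSeriesPanel("S", v, 2.0))

        perm = np.array([3, 1, 5, 2, 6, 4])  # new_id -> old_id, 1-based
        inv = {int(perm[k]): k + 1 for k in range(6)}
        old = {n.node_id: n for n in atlas.nodes}
        new_nodes = tuple(
            AtlasNode(
                node_id=k + 1, name=old[int(perm[k])].name,
                abbrev=old[int(perm[k])].abbrev,
                hemisphere=old[int(perm[k])].hemisphere,
                partner_id=inv[old[int(perm[k])].partner_id],
                gyrus_id=old[int(perm[k])].gyrus_id,
                lobe_id=old[int(perm[k])].lobe_id,
                is_cortical=old[int(perm[k])].is_cortical,
            )
            for k in range(6)
        )
        atlas2 = Atlas(new_nodes)
        part2 = partition_edges(atlas2)
        fc2 = compute_fc(TimeSeriesPanel("S", v[:, perm - 1], 2.0))
        for net in ("LH", "RH", "Ho", "He"):
            row1 = dict(zip(part.edges(net), vectorize(fc, part, net)))
            row2 = dict(zip(part2.edges(net), vectorize(fc2, part2, net)))
            by_name1 = {
                frozenset((old[i].abbrev, old[j].abbrev)): v_
                for (i, j), v_ in row1.items()
            }
            by_name2 = {
                frozenset((atlas2.node(i).abbrev, atlas2.node(j).abbrev)): v_
                for (i, j), v_ in row2.items()
            }
            assert by_name1.keys() == by_name2.keys()
            for key in by_name1:
                assert by_name1[key] == pytest.approx(by_name2[key], abs=1e-12)


def test_feature_matrix_columns_match_edges(tiny_planted_study):
    fm = tiny_planted_study["features"]
    part = tiny_planted_study["partition"]
    assert fm.edge_index == part.rh
    assert fm.values.shape == (12, len(part.rh))
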