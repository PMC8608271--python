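"""Evoked segmentation, F-statistics, RLS decoding, invariance, MDS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from hgmap import phonemes as ph
from hgmap.arpabet import attributes_of
from hgmap.containers import HighGammaResponse


def tiny_table(onsets, labels=None, speakers=None):
    labels = labels or ["AA"] * len(onsets)
    speakers = speakers or ["spk0"] * len(onsets)
    rows = []
    for t, lab, spk in zip(onsets, labels, speakers):
        row = {"phoneme": lab, "onset_s": t, "offset_s": t + 0.1,
               "speaker": spk}
        row.update(attributes_of(lab))
        rows.append(row)
    return pd.DataFrame(rows)


class TestSegmentation:
    def test_window_index_arithmetic(self):
        # onset 1.000 s, window [90, 150) ms, 100 Hz -> frames 109..114
        values = np.arange(300, dtype=float)[None, :]
        hg = HighGammaResponse(values=values, frame_rate=100.0)
        ev = ph.segment_evoked(hg, tiny_table([1.0]), (90.0, 150.0))
        assert ev.X.shape == (1, 6)
        assert np.array_equal(ev.X[0], np.arange(109, 115, dtype=float))

    def test_edge_instance_dropped_and_counted(self):
        hg = HighGammaResponse(values=np.zeros((1, 200)), frame_rate=100.0)
        ev = ph.segment_evoked(hg, tiny_table([0.5, 1.95]), (90.0, 150.0))
        assert ev.X.shape[0] == 1
        assert ev.n_dropped == 1

    def test_feature_matrix_shape(self):
        hg = HighGammaResponse(values=np.zeros((3, 500)), frame_rate=100.0)
        ev = ph.segment_evoked(hg, tiny_table([1.0, 2.0, 3.0, 4.0]),
                               (70.0, 180.0))
        assert ev.X.shape == (4, 11 * 3)

    def test_empty_table_rejected(self):
        hg = HighGammaResponse(values=np.zeros((1, 100)), frame_rate=100.0)
        with pytest.raises(ValueError):
            ph.segment_evoked(hg, tiny_table([]), (90.0, 150.0))

    @given(onset=st.floats(0.5, 3.0), start=st.integers(0, 10),
           width=st.integers(1, 12))
    @settings(max_examples=25, deadline=None)
    def test_window_length_matches_frame_arithmetic(self, onset, start, width):
        start_ms, end_ms = start * 10.0, (start + width) * 10.0
        hg = HighGammaResponse(values=np.zeros((1, 600)), frame_rate=100.0)
        ev = ph.segment_evoked(hg, tiny_table([onset]), (start_ms, end_ms))
        assert ev.X.shape[1] == width


class TestFRatio:
    def test_separated_classes_give_large_f(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        X[30:] += 10.0
        y = np.repeat(["a", "b"], 30)
        assert ph.f_ratio(X, y) > 50.0

    def test_single_instance_class_rejected(self):
        with pytest.raises(ValueError):
            ph.f_ratio(np.zeros((3, 2)), np.array(["a", "a", "b"]))

    def test_zero_within_variance_flagged_infinite(self):
        X = np.repeat([[0.0], [1.0]], 3, axis=0)
        with pytest.warns(UserWarning, match="infinite"):
            f = ph.f_ratio(X, np.repeat(["a", "b"], 3))
        assert np.isinf(f)

    def test_permutation_p_small_for_planted_effect(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = np.repeat(["a", "b"], 20)
        X[y == "b"] += 2.0
        _, p = ph.f_ratio_permutation_p(X, y, n_perm=199, seed=2)
        assert p < 0.01

    def test_null_f_near_one(self):
        rng = np.random.default_rng(3)
        fs = [ph.f_ratio(rng.normal(size=(40, 5)),
                         np.repeat(["a", "b", "c", "d"], 10))
              for _ in range(50)]
        assert abs(np.mean(fs) - 1.0) < 0.25


class TestWindowSelection:
    def test_planted_separability_selects_window(self):
        rng = np.random.default_rng(4)
        n = 80
        onsets = 1.0 + np.arange(n) * 0.5
        labels = list(np.tile(["AA", "S"], n // 2))
        table = tiny_table(onsets, labels=labels)
        values = rng.normal(scale=0.5, size=(2, int(onsets[-1] * 100) + 100))
        for t, lab in zip(onsets, labels):
            i = int(t * 100)
            values[:, i + 9:i + 15] += 3.0 if lab == "AA" else -3.0
        hg = HighGammaResponse(values=values, frame_rate=100.0)
        sel = ph.select_window_by_fstat(
            hg, table, [(10.0, 70.0), (90.0, 150.0), (150.0, 210.0)],
            label_column="phoneme")
        assert sel.window_ms == (90.0, 150.0)
        assert sel.informative

    def test_null_selection_flagged_uninformative_with_tie_toward_earlier(self):
        rng = np.random.default_rng(5)
        onsets = 1.0 + np.arange(60) * 0.5
        table = tiny_table(onsets, labels=list(np.tile(["AA", "S"], 30)))
        values = rng.normal(size=(1, int(onsets[-1] * 100) + 100))
        hg = HighGammaResponse(values=values, frame_rate=100.0)
        sel = ph.select_window_by_fstat(hg, table,
                                        [(10.0, 70.0), (90.0, 150.0)],
                                        label_column="phoneme")
        assert not sel.informative
        # F values computed for both candidates; ties break to earlier
        assert list(sel.f_by_window) == [(10.0, 70.0), (90.0, 150.0)]


class TestRLS:
    def test_separable_classes_decoded(self):
        rng = np.random.default_rng(6)
        X = rng.normal(scale=0.1, size=(200, 5))
        y = np.repeat(["a", "b"], 100)
        X[y == "b", 0] += 5.0
        res = ph.rls_classify(X[::2], y[::2], X[1::2], y[1::2])
        assert res.accuracy >= 0.99
        assert res.confusion.shape == (2, 2)

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(400, 6))
        y = rng.permutation(np.repeat(["a", "b", "c", "d"], 100))
        res = ph.rls_classify(X[::2], y[::2], X[1::2], y[1::2])
        sd = np.sqrt(0.25 * 0.75 / 200)
        assert abs(res.accuracy - 0.25) <= 3 * sd

    def test_unseen_test_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="absent"):
            ph.rls_classify(X, np.array(["a"] * 4), X, np.array(["b"] * 4))

    def test_chance_level(self):
        assert ph.chance_level(np.array(["a", "b", "c", "d"])) == 0.25


class TestInvariance:
    def test_invariant_code_si_near_one(self, evoked_invariant):
        res = ph.speaker_invariance(evoked_invariant, site=0)
        assert res.si >= 0.9
        assert set(res.per_attribute) <= {"manner", "place", "voicing",
                                          "height", "backness"}
        assert not res.unreliable

    def test_si_invariant_to_affine_rescaling(self, evoked_invariant):
        res0 = ph.speaker_invariance(evoked_invariant, site=1)
        ev = ph.EvokedMatrix(X=evoked_invariant.X * 7.0 - 3.0,
                             labels=evoked_invariant.labels,
                             window_ms=evoked_invariant.window_ms,
                             n_sites=evoked_invariant.n_sites,
                             n_frames=evoked_invariant.n_frames)
        res1 = ph.speaker_invariance(ev, site=1)
        assert res1.si == pytest.approx(res0.si, abs=1e-9)

    def test_cross_cannot_beat_within_beyond_noise(self, evoked_invariant):
        res = ph.speaker_invariance(evoked_invariant, site=2)
        n = len(evoked_invariant.labels) // 4
        sd = np.sqrt(res.within_acc * (1 - res.within_acc) / max(n, 1))
        assert res.cross_acc <= res.within_acc + 3 * sd

    def test_single_speaker_rejected(self):
        hg = HighGammaResponse(values=np.zeros((1, 400)), frame_rate=100.0)
        table = tiny_table([1.0, 2.0], labels=["AA", "S"])
        ev = ph.segment_evoked(hg, table, (70.0, 180.0))
        with pytest.raises(ValueError, match="speakers"):
            ph.speaker_invariance(ev)


class TestMDS:
    def test_collinear_points_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        coords, stress = ph.mds_embed(D)
        assert stress <= 1e-3
        fit = squareform(pdist(coords))
        mask = D > 0
        assert np.allclose(fit[mask], D[mask], rtol=0.01)

    def test_equal_distances_give_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, stress = ph.mds_embed(D)
        sides = pdist(coords)
        assert stress <= 1e-3
        assert np.allclose(sides, sides[0], rtol=0.01)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ph.mds_embed(D)

    def test_group_dissimilarity_keys(self, evoked_invariant):
        sub = ph.EvokedMatrix(X=evoked_invariant.X[:100],
                              labels=evoked_invariant.labels.iloc[:100],
                              window_ms=evoked_invariant.window_ms,
                              n_sites=evoked_invariant.n_sites,
                              n_frames=evoked_invariant.n_frames)
        D, keys = ph.phoneme_dissimilarity(sub, by=("speaker",))
        assert D.shape == (len(keys), len(keys))
        assert np.allclose(D, D.T)
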