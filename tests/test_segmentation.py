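"""GFP, peak maps, outlier screening, clustering, polarity, back-fitting,
temporal smoothing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from mgsms import segmentation as seg
from mgsms import synth


class TestGFP:
    def test_constant_map_has_zero_gfp(self):
        assert seg.gfp(np.full((4, 1), 7.0))[0] == 0.0

    def test_hand_value(self):
        # average-referenced map [2,-2,0,0]: population SD = sqrt(2)
        g = seg.gfp(np.array([[2.0], [-2.0], [0.0], [0.0]]))
        assert g[0] == pytest.approx(np.sqrt(2.0))

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(8, 20))
        np.testing.assert_allclose(seg.gfp(3.5 * data), 3.5 * seg.gfp(data))


class TestGFPPeaks:
    def test_simple_peaks(self):
        np.testing.assert_array_equal(seg.gfp_peaks([0, 1, 0, 2, 0]), [1, 3])

    def test_monotone_has_none(self):
        assert seg.gfp_peaks(np.arange(10.0)).size == 0

    def test_plateau_assigned_to_first_sample(self):
        np.testing.assert_array_equal(seg.gfp_peaks([0, 1, 1, 0]), [1])

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=300)
        expect = [
            i for i in range(1, 299) if g[i - 1] < g[i] >= g[i + 1]
        ]
        np.testing.assert_array_equal(seg.gfp_peaks(g), expect)


class TestOutlierRemoval:
    def test_homogeneous_norms_untouched(self):
        rng = np.random.default_rng(2)
        maps = rng.normal(size=(50, 20))
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        kept, removed = seg.remove_outlier_maps(maps)
        assert removed == 0 and kept.shape == maps.shape

    def test_single_extreme_norm_removed(self):
        rng = np.random.default_rng(3)
        maps = rng.normal(size=(100, 20))
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        maps[37] *= 100.0
        kept, removed = seg.remove_outlier_maps(maps)
        assert removed == 1
        assert kept.shape[0] == 99
        assert np.linalg.norm(kept, axis=1).max() < 2.0

    def test_too_few_maps_rejected(self):
        with pytest.raises(ValueError):
            seg.remove_outlier_maps(np.ones((5, 4)))


class TestClustering:
    def test_planted_prototype_recovery(self, templates):
        rng = np.random.default_rng(4)
        idx = rng.integers(0, 8, size=2000)
        maps = templates.maps[idx] * rng.uniform(0.8, 1.2, size=(2000, 1))
        centers = seg.cluster_maps(maps, k=8, n_restarts=10, seed=0)
        corr = centers.maps @ templates.maps.T
        best = corr.max(axis=1)
        assert (best > 0.99).all()
        # each signed planted prototype claimed by exactly one center
        assert len(set(corr.argmax(axis=1))) == 8

    def test_k1_center_is_normalized_mean(self):
        rng = np.random.default_rng(5)
        maps = rng.normal(size=(200, 10)) + 2.0
        centers = seg.cluster_maps(maps, k=1, n_restarts=3, seed=0)
        mean = maps.mean(axis=0)
        expect = mean / np.linalg.norm(mean)
        assert abs(seg.spatial_correlation(centers.maps[0], expect)) > 1 - 1e-9

    def test_same_seed_same_centers(self):
        rng = np.random.default_rng(6)
        maps = rng.normal(size=(300, 12))
        c1 = seg.cluster_maps(maps, k=4, n_restarts=5, seed=9)
        c2 = seg.cluster_maps(maps, k=4, n_restarts=5, seed=9)
        np.testing.assert_array_equal(c1.maps, c2.maps)


class TestPolarityPairing:
    def test_exact_negations_recovered(self, templates):
        paired = seg.pair_polarity(templates)
        pairs = {tuple(sorted(v)) for v in paired.pairing.values()}
        assert pairs == {(0, 1), (2, 3), (4, 5), (6, 7)}

    def test_invariant_to_input_order(self, templates):
        rng = np.random.default_rng(7)
        for _ in range(10):
            perm = rng.permutation(8)
            shuffled = seg.PrototypeSet(
                maps=templates.maps[perm], channel_names=templates.channel_names
            )
            paired = seg.pair_polarity(shuffled)
            pairs = {
                tuple(sorted((perm[i], perm[j])))
                for i, j in paired.pairing.values()
            }
            assert pairs == {(0, 1), (2, 3), (4, 5), (6, 7)}

    def test_paired_correlation_below_cross_class(self, templates):
        rng = np.random.default_rng(8)
        noisy = templates.maps + rng.normal(0, 0.05, size=templates.maps.shape)
        noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
        pset = seg.PrototypeSet(maps=noisy, channel_names=templates.channel_names)
        paired = seg.pair_polarity(pset)
        corr = noisy @ noisy.T
        for i, j in paired.pairing.values():
            assert corr[i, j] == pytest.approx(corr.min(axis=1)[i], abs=1e-9)

    def test_weak_polarity_warns(self):
        rng = np.random.default_rng(9)
        maps = rng.normal(size=(8, 20))
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        pset = seg.PrototypeSet(maps=maps, channel_names=tuple(f"c{i}" for i in range(20)))
        with pytest.warns(UserWarning, match="weak polarity"):
            seg.pair_polarity(pset)


class TestCanonicalLabels:
    def test_identity_assignment(self, templates):
        paired = seg.pair_polarity(templates)
        labeled = seg.assign_canonical_labels(paired, templates)
        assert labeled.labels == seg.STATES_8
        np.testing.assert_allclose(labeled.maps, templates.maps, atol=1e-12)

    def test_permuted_input_recovered(self, templates):
        rng = np.random.default_rng(10)
        perm = rng.permutation(8)
        shuffled = seg.PrototypeSet(
            maps=templates.maps[perm], channel_names=templates.channel_names
        )
        labeled = seg.assign_canonical_labels(
            seg.pair_polarity(shuffled), templates
        )
        np.testing.assert_allclose(labeled.maps, templates.maps, atol=1e-12)

    def test_robust_to_small_noise(self, templates):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            noisy = templates.maps + rng.normal(0, 0.1, size=templates.maps.shape)
            noisy -= noisy.mean(axis=1, keepdims=True)
            noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
            pset = seg.PrototypeSet(maps=noisy, channel_names=templates.channel_names)
            try:
                labeled = seg.assign_canonical_labels(
                    seg.pair_polarity(pset), templates
                )
            except ValueError:
                continue
            corr = np.array(
                [
                    seg.spatial_correlation(labeled.map_for(s), templates.map_for(s))
                    for s in seg.STATES_8
                ]
            )
            hits += (corr > 0.5).all()
        assert hits >= 99


class TestSpatialCorrelation:
    def test_identical_and_negated(self):
        x = np.array([1.0, -2.0, 0.5])
        assert seg.spatial_correlation(x, x) == pytest.approx(1.0)
        assert seg.spatial_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_value_without_centering(self):
        # cosine of [1,2,3] and [3,2,1] is 10/14; Pearson would differ
        v = seg.spatial_correlation(np.array([1.0, 2, 3]), np.array([3.0, 2, 1]))
        assert v == pytest.approx(10.0 / 14.0)

    @given(
        a=hst.floats(-3.0, 3.0).filter(lambda v: abs(v) > 1e-3),
        b=hst.floats(-3.0, 3.0).filter(lambda v: abs(v) > 1e-3),
    )
    def test_scale_invariance_up_to_sign(self, a, b):
        x = np.array([0.5, -1.0, 2.0, 0.1])
        y = np.array([1.0, 0.3, -0.7, 0.9])
        lhs = seg.spatial_correlation(a * x, b * y)
        rhs = np.sign(a * b) * seg.spatial_correlation(x, y)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_zero_map_rejected(self):
        with pytest.raises(ValueError):
            seg.spatial_correlation(np.zeros(3), np.ones(3))


class TestBackfit:
    def test_prototype_samples_get_their_own_label(self, templates):
        data = templates.map_for("D+")[:, None]
        s8 = seg.backfit(data, templates, seg.MODE_8, 250.0)
        s4 = seg.backfit(data, templates, seg.MODE_4, 250.0)
        assert s8.states[s8.labels[0]] == "D+"
        assert s4.states[s4.labels[0]] == "D"

    def test_negated_prototype_polarity_semantics(self, templates):
        data = -templates.map_for("C+")[:, None]
        s8 = seg.backfit(data, templates, seg.MODE_8, 250.0)
        s4 = seg.backfit(data, templates, seg.MODE_4, 250.0)
        assert s8.states[s8.labels[0]] == "C-"
        assert s4.states[s4.labels[0]] == "C"

    def test_matches_bruteforce_argmax_oracle(self, templates):
        rng = np.random.default_rng(12)
        data = rng.normal(size=(20, 1500))
        for mode in (seg.MODE_4, seg.MODE_8):
            got = seg.backfit(data, templates, mode, 250.0)
            if mode == seg.MODE_8:
                protos = templates.maps
                sim = lambda x, m: seg.spatial_correlation(x, m)
            else:
                protos = templates.class_maps()
                sim = lambda x, m: abs(seg.spatial_correlation(x, m))
            for n in range(data.shape[1]):
                sims = [sim(data[:, n], m) for m in protos]
                assert got.labels[n] == int(np.argmax(sims))


class TestSmoothing:
    def _epoch_data(self, templates, labels):
        return templates.maps[np.asarray(labels)].T.copy()

    def test_sequence_without_short_segments_is_fixed_point(self, templates):
        labels = np.repeat([0, 2, 4], 20)
        data = self._epoch_data(templates, labels)
        sq = seg.LabelSequence(labels=labels, fs=250.0)
        out = seg.smooth_labels(sq, data, templates)
        np.testing.assert_array_equal(out.labels, labels)

    def test_short_middle_segment_absorbed(self, templates):
        # A+ (100 ms) B+ (8 ms) A+ (100 ms) at 250 Hz; the B+ samples are
        # made more similar to A+ so both halves join the flanks
        labels = np.array([0] * 25 + [2] * 2 + [0] * 25)
        data = self._epoch_data(templates, labels)
        data[:, 25:27] = templates.maps[0][:, None]  # actually A+-like
        sq = seg.LabelSequence(labels=labels, fs=250.0)
        out = seg.smooth_labels(sq, data, templates)
        assert out.n_segments == 1
        assert (out.labels == 0).all()

    def test_interior_segments_reach_window_after_smoothing(self, templates):
        rng = np.random.default_rng(13)
        sq0 = synth.simulate_label_sequence(
            synth.uniform_chain(), 0.04, 4.0, 250.0, seed=14
        )
        data = self._epoch_data(templates, sq0.labels)
        data += rng.normal(0, 0.15, size=data.shape)
        raw = seg.backfit(data, templates, seg.MODE_8, 250.0)
        out = seg.smooth_labels(raw, data, templates, window=0.03)
        w = int(round(0.03 * 250.0))
        segs = out.segments
        assert all(ln >= w for _, _, ln in segs[1:-1])
        assert out.n_segments <= raw.n_segments

    def test_smoothing_never_increases_segment_count_either_mode(self, templates):
        rng = np.random.default_rng(15)
        data = rng.normal(size=(20, 400))
        for mode in (seg.MODE_4, seg.MODE_8):
            raw = seg.backfit(data, templates, mode, 250.0)
            out = seg.smooth_labels(raw, data, templates)
            assert out.n_segments <= raw.n_segments


def test_end_to_end_planted_recovery(templates):
    """Peaks -> outlier screen -> k-means -> pairing -> labels recovers the
    planted prototypes from clean simulated trials."""
    rng = np.random.default_rng(16)
    maps = []
    for t in range(40):
        sq = synth.simulate_label_sequence(
            synth.uniform_chain(), 0.08, 2.3, 250.0, seed=rng
        )
        eeg = synth.simulate_eeg(sq, templates, snr=8.0, seed=rng)
        g = seg.gfp(eeg)
        maps.append(eeg[:, seg.gfp_peaks(g)].T)
    maps = np.concatenate(maps)
    maps, _ = seg.remove_outlier_maps(maps)
    centers = seg.cluster_maps(maps, k=8, n_restarts=20, seed=17)
    labeled = seg.assign_canonical_labels(seg.pair_polarity(centers), templates)
    for s in seg.STATES_8:
        corr = seg.spatial_correlation(labeled.map_for(s), templates.map_for(s))
        assert abs(corr) > 0.95
        assert corr > 0  # sign convention: "+" member matches its template
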