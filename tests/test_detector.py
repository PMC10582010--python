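"""Detection pipeline: frontend geometry, augmentation algebra,
rebalancing, metrics, scoring and presence calling."""

import numpy as np
import pytest

from helpers import ap_bruteforce
from sonoscape import detector as det
from sonoscape.audio import Waveform


def mk_input(fill=0.0, shape=(8, det.N_MELS)):
    return det.ModelInput(np.full(shape, float(fill)))


class TestFrontend:
    def test_three_seconds_yield_117_frames(self):
        w = Waveform(np.zeros(3 * 16_000), 16_000)
        mi = det.make_model_input(w)
        assert mi.features.shape == (117, det.N_MELS)

    def test_pure_tone_lands_in_matching_mel_bin(self):
        t = np.arange(3 * 16_000) / 16_000
        w = Waveform(0.8 * np.sin(2 * np.pi * 440.0 * t), 16_000)
        mi = det.make_model_input(w)
        got = int(np.argmax(mi.features.mean(axis=0)))
        want = int(np.argmin(np.abs(det.mel_center_freqs() - 440.0)))
        assert abs(got - want) <= 1

    def test_zero_clip_floors_at_log_epsilon(self):
        mi = det.make_model_input(Waveform(np.zeros(3 * 16_000), 16_000))
        assert np.allclose(mi.features, np.log(det.LOG_EPS))

    def test_resampling_preserves_tone_location(self):
        t = np.arange(3 * 22_050) / 22_050
        w = Waveform(0.8 * np.sin(2 * np.pi * 2000.0 * t), 22_050)
        mi = det.make_model_input(w)
        got = det.mel_center_freqs()[int(np.argmax(mi.features.mean(axis=0)))]
        assert got == pytest.approx(2000.0, rel=0.05)

    def test_empty_clip_raises(self):
        with pytest.raises(ValueError, match="empty"):
            det.make_model_input(Waveform(np.zeros(0), 16_000))


class TestAugmentation:
    def test_blending_a_sample_with_itself_is_identity(self):
        a = det.ModelInput(np.random.default_rng(0).normal(size=(8, det.N_MELS)))
        lab = np.array([1.0, 0.0])
        out, labels = det.augment_pair((a, lab), (a, lab), (50.0, 8000.0))
        assert np.array_equal(out.features, a.features)
        assert np.array_equal(labels, lab)

    def test_silent_partner_leaves_sample_unchanged(self):
        a = det.ModelInput(np.random.default_rng(1).uniform(-1, 1, (8, det.N_MELS)))
        b = mk_input(np.log(det.LOG_EPS))  # digital silence floor
        la, lb = np.array([1.0, 0.0]), np.array([0.0, 0.0])
        out, labels = det.augment_pair((a, la), (b, lb), (50.0, 8000.0))
        assert np.array_equal(out.features, a.features)
        assert np.array_equal(labels, la)

    def test_disjoint_bands_union_labels_and_preserve_cells(self):
        floor = np.log(det.LOG_EPS)
        bins_a = det.band_to_mel_bins((500.0, 1000.0))
        bins_b = det.band_to_mel_bins((4000.0, 5000.0))
        a, b = mk_input(floor), mk_input(floor)
        a.features[:, bins_a] = -1.0
        b.features[:, bins_b] = -2.0
        la = np.array([1.0, 0.0])
        lb = np.array([0.0, 1.0])
        out, labels = det.augment_pair((a, la), (b, lb), (4000.0, 5000.0))
        assert np.array_equal(labels, [1.0, 1.0])
        assert np.all(out.features[:, bins_a] == -1.0)
        assert np.all(out.features[:, bins_b] == -2.0)

    def test_augmentation_never_decreases_cells_or_clears_labels(self):
        rng = np.random.default_rng(2)
        a = det.ModelInput(rng.normal(size=(8, det.N_MELS)))
        b = det.ModelInput(rng.normal(size=(8, det.N_MELS)))
        la = (rng.uniform(size=3) > 0.5).astype(float)
        lb = (rng.uniform(size=3) > 0.5).astype(float)
        out, labels = det.augment_pair((a, la), (b, lb), (1000.0, 3000.0))
        assert np.all(out.features >= a.features - 1e-12)
        assert np.all(labels >= la)

    def test_band_covering_no_bins_raises(self):
        a = mk_input()
        with pytest.raises(ValueError, match="band"):
            det.band_to_mel_bins((50.0, 50.5))


def _samples(class_id, n_pos, n_neg):
    out = []
    for i in range(n_pos):
        out.append(det.TrainingSample(mk_input(i), class_id, True))
    for i in range(n_neg):
        out.append(det.TrainingSample(mk_input(-i - 1), class_id, False))
    return out


class TestRebalance:
    def test_class_below_minimum_positives_is_dropped(self):
        samples = _samples("a", 9, 5) + _samples("b", 10, 5)
        kept, out = det.rebalance(samples, seed=0)
        assert kept == ["b"]

    def test_excess_positives_downsampled_to_target(self):
        kept, out = det.rebalance(_samples("a", 500, 50), seed=0)
        pos = [s for s in out if s.known_label]
        neg = [s for s in out if not s.known_label]
        assert len(pos) == 200 and len(neg) == 50

    def test_short_class_upsampled_with_replacement_from_originals(self):
        originals = _samples("a", 12, 5)
        kept, out = det.rebalance(originals, seed=0)
        pos = [s for s in out if s.known_label]
        assert len(pos) == 200
        original_ids = {id(s) for s in originals}
        assert all(id(s) in original_ids for s in pos)

    def test_no_surviving_class_raises(self):
        with pytest.raises(ValueError, match="positive"):
            det.rebalance(_samples("a", 3, 3), seed=0)


class TestAveragePrecision:
    def test_perfect_ranking_scores_one(self):
        assert det.average_precision([1, 1, 0, 0], [.9, .8, .2, .1]) == 1.0

    def test_interleaved_ranking_hand_value(self):
        got = det.average_precision([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6])
        assert got == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_matches_bruteforce_and_sklearn_on_random_lists(self):
        from sklearn.metrics import average_precision_score
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(2, 11))
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                y[rng.integers(n)] = 1
            s = np.round(rng.uniform(size=n), 2)  # rounded to force ties
            got = det.average_precision(y, s)
            assert got == pytest.approx(ap_bruteforce(y, s), abs=1e-12)
            assert got == pytest.approx(average_precision_score(y, s),
                                        abs=1e-9)

    def test_no_positives_is_undefined(self):
        with pytest.raises(ValueError):
            det.average_precision([0, 0], [0.5, 0.4])


class TestEvaluate:
    def test_zero_positive_class_excluded_with_warning(self):
        truth = np.array([[1, 0], [0, 0], [1, 0]])
        scores = np.array([[.9, .1], [.2, .3], [.8, .2]])
        with pytest.warns(UserWarning, match="without positives"):
            m = det.mean_average_precision(truth, scores)
        assert m == 1.0

    def test_all_negative_predictions_zero_by_convention(self):
        truth = np.array([[1], [0], [1]])
        scores = np.array([[.4], [.2], [.3]])
        out = det.evaluate(truth, scores, threshold=0.9)
        assert out["recall"] == 0.0
        assert out["precision"] == 0.0
        assert out["f1"] == 0.0


class _ConstantModel:
    def __init__(self, value=0.7, n_classes=2):
        self.value, self.n = value, n_classes

    def score(self, inputs):
        return np.full((len(inputs), self.n), self.value)


class TestScoringWindows:
    def test_two_minute_file_yields_118_windows(self):
        w = Waveform(np.zeros(120 * 16_000), 16_000)
        scores = det.score_file(_ConstantModel(), w, "f")
        assert len(scores) == 118
        assert scores[0].window_start == 0.0
        assert scores[-1].window_start == 117.0

    def test_three_second_file_yields_single_window(self):
        w = Waveform(np.zeros(3 * 16_000), 16_000)
        assert len(det.score_file(_ConstantModel(), w, "f")) == 1

    def test_constant_input_scores_identically_across_windows(self):
        t = np.arange(20 * 16_000) / 16_000
        w = Waveform(0.5 * np.sin(2 * np.pi * 1000 * t), 16_000)
        net = det.MLPDetector(n_classes=3, seed=1)
        scores = det.score_file(net, w, "f")
        mats = np.stack([s.scores for s in scores[:-3]])
        assert np.allclose(mats, mats[0], atol=1e-6)


class TestPresence:
    def _scores(self, peaks):
        return {f"file{i}": [det.DetectionScore(f"file{i}", 0.0,
                                                np.array([p]))]
                for i, p in enumerate(peaks)}

    def test_score_below_threshold_is_absent(self):
        table = det.call_presence(self._scores([0.79]), ["c"], threshold=0.8)
        assert not table.presence.iloc[0, 0]

    def test_lower_threshold_is_monotone_superset(self):
        peaks = [0.45, 0.55, 0.79, 0.85, 0.95]
        t5 = det.call_presence(self._scores(peaks), ["c"], threshold=0.5)
        t8 = det.call_presence(self._scores(peaks), ["c"], threshold=0.8)
        assert (t5.presence.to_numpy() >= t8.presence.to_numpy()).all()

    def test_frequency_counts_positive_files_per_plot(self):
        peaks = [0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        scores = self._scores(peaks)
        plot_of = {f: "plotA" for f in scores}
        table = det.call_presence(scores, ["c"], threshold=0.8,
                                  plot_of_file=plot_of)
        assert table.frequency.loc["plotA", "c"] == 3


class TestTrainingContract:
    def _tiny_problem(self, seed=0, shuffle_labels=False):
        from sonoscape import pipeline as pl, simulate as sim
        pool = sim.build_species_pool(30, seed=5)
        specs = pl.make_song_classes(pool, 3)
        cs = {c.class_id: next(s for s in pool if s.species_id == c.species_id)
              for c in specs}
        train = pl.make_training_clips(cs, 12, 6, 22_050, -45.0, seed=6)
        if shuffle_labels:
            rng = np.random.default_rng(9)
            labels = [s.known_label for s in train]
            rng.shuffle(labels)
            train = [det.TrainingSample(s.input, s.known_class, l)
                     for s, l in zip(train, labels)]
        val = pl.make_validation_clips(cs, 24, 22_050, -45.0, seed=7)
        cfg = det.DetectorConfig(epochs=12, target_pos=30, target_neg=10)
        return train, val, specs, cfg

    def test_fixed_seed_reproduces_epoch_selection_trace(self):
        train, val, specs, cfg = self._tiny_problem()
        a = det.train_detector(train, val, specs, cfg, seed=3)
        b = det.train_detector(train, val, specs, cfg, seed=3)
        assert a.val_map_history == b.val_map_history
        assert a.best_epoch == b.best_epoch

    def test_label_shuffling_destroys_validation_skill(self):
        train, val, specs, cfg = self._tiny_problem()
        real = det.train_detector(train, val, specs, cfg, seed=3)
        strain, sval, sspecs, scfg = self._tiny_problem(shuffle_labels=True)
        shuffled = det.train_detector(strain, sval, sspecs, scfg, seed=3)
        assert max(shuffled.val_map_history) < max(real.val_map_history)
        assert max(real.val_map_history) > 0.9
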