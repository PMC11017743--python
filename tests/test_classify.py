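"""Interval-forest tests: features against independent oracles, training
protocol, frame-budget contract, cross-validation properties."""

import numpy as np
import pytest
from statsmodels.regression.linear_model import yule_walker

from spontact import (TraceMatrix, TrainingSet, build_training_set,
                      crossvalidate, predict, train_rise, train_tsf)
from spontact.classify import (FRAME_BUDGET_RULE, ar_coefficients,
                               autocorrelation, interval_summary_features,
                               periodogram_power, rise_features)
from spontact.trace import ACTIVE, AMBIGUOUS, INACTIVE, LabelSet


def toy_training_set(n_per_class=50, n_frames=300, seed=0,
                     amplitude=40.0, noise=2.0):
    """Linearly separable set: flat noise vs one large square transient."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for _ in range(n_per_class):
        X.append(rng.normal(0, noise, n_frames))
        y.append(INACTIVE)
    for _ in range(n_per_class):
        x = rng.normal(0, noise, n_frames)
        start = int(rng.integers(0, max(n_frames - 25, 1)))
        x[start:start + 20] += amplitude
        X.append(x)
        y.append(ACTIVE)
    return TrainingSet(X=np.array(X), y=np.array(y, dtype=object),
                       sampling_rate=3.65, segment_frames=n_frames)


def periodic_training_set(n_per_class=50, n_frames=400, seed=0):
    """0.3 Hz square-wave transient trains vs white noise, equal variance."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / 3.65
    X, y = [], []
    for _ in range(n_per_class):
        phase = rng.uniform(0, 1 / 0.3)
        sq = 10.0 * (((t + phase) * 0.3) % 1.0 < 0.3)
        X.append(sq + rng.normal(0, 1.0, n_frames))
        y.append(ACTIVE)
    sd = np.std(10.0 * ((t * 0.3) % 1.0 < 0.3))
    for _ in range(n_per_class):
        X.append(rng.normal(0, sd, n_frames) + rng.normal(0, 1.0, n_frames))
        y.append(INACTIVE)
    return TrainingSet(X=np.array(X), y=np.array(y, dtype=object),
                       sampling_rate=3.65, segment_frames=n_frames)


class TestFeatures:
    def test_slope_of_a_line_is_one_per_frame(self):
        feats = interval_summary_features(np.array([[0.0, 1.0, 2.0, 3.0]]))
        mean, sd, slope = feats[0]
        assert slope == pytest.approx(1.0)
        assert mean == pytest.approx(1.5)

    def test_summary_features_match_numpy_oracles(self, rng):
        X = rng.normal(size=(6, 40))
        feats = interval_summary_features(X)
        for i in range(6):
            assert feats[i, 0] == pytest.approx(X[i].mean())
            assert feats[i, 1] == pytest.approx(X[i].std())
            assert feats[i, 2] == pytest.approx(
                np.polyfit(np.arange(40), X[i], 1)[0])

    def test_acf_of_constant_trace_is_all_zero(self):
        acf = autocorrelation(np.full((2, 64), 3.0), n_lags=10)
        assert np.array_equal(acf, np.zeros((2, 10)))

    def test_acf_matches_direct_oracle(self, rng):
        x = rng.normal(size=(1, 200))
        acf = autocorrelation(x, n_lags=5)[0]
        xc = x[0] - x[0].mean()
        denom = np.dot(xc, xc) / 200
        for k in range(1, 6):
            direct = np.dot(xc[:-k], xc[k:]) / 200 / denom
            assert acf[k - 1] == pytest.approx(direct, abs=1e-10)

    def test_ar_matches_statsmodels_yule_walker(self, rng):
        # independent oracle: statsmodels Yule-Walker with biased ('mle')
        # autocovariances, the convention our Levinson recursion uses
        x = rng.normal(size=400).cumsum() * 0.1 + rng.normal(size=400)
        ours = ar_coefficients(x[None, :], order=6)[0]
        rho, _sigma = yule_walker(x, order=6, method="mle")
        assert np.allclose(ours, rho, atol=1e-8)

    def test_periodogram_peak_at_signal_frequency(self):
        fs, f0, n = 3.65, 0.3, 512
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * f0 * t)[None, :]
        power = periodogram_power(x)[0]
        freqs = np.fft.rfftfreq(n, d=1 / fs)[1: n // 2 + 1]
        peak_freq = freqs[np.argmax(power)]
        bin_width = fs / n
        assert abs(peak_freq - f0) <= bin_width

    def test_rise_feature_vector_has_fixed_length(self, rng):
        X = rng.normal(size=(4, 500))
        full = (min(100, 499), min(12, 125), 250)
        for a, b in [(0, 500), (100, 180), (10, 40)]:
            feats = rise_features(X[:, a:b], full, 100, 12)
            assert feats.shape == (4, sum(full))


class TestTraining:
    def test_separable_data_perfect_holdout_accuracy(self):
        table = crossvalidate(toy_training_set(), algorithm="tsf", k=5,
                              seed=0, n_trees=30, holdout_fraction=0.2)
        assert table.attrs["holdout"]["accuracy"] == 1.0
        assert table.attrs["mean"]["accuracy"] == 1.0

    def test_same_seed_identical_predictions(self, small_benchmark_dff):
        dff = small_benchmark_dff[0]
        train = toy_training_set(n_frames=dff.n_frames)
        for trainer in (train_tsf, train_rise):
            m1 = trainer(train, n_trees=10, seed=42)
            m2 = trainer(train, n_trees=10, seed=42)
            l1, v1 = predict(m1, dff)
            l2, v2 = predict(m2, dff)
            assert l1.labels == l2.labels
            assert np.array_equal(v1, v2)

    def test_rise_separates_periodic_from_noise(self):
        table = crossvalidate(periodic_training_set(), algorithm="rise",
                              k=5, seed=1, n_trees=50)
        assert table.attrs["mean"]["accuracy"] >= 0.95

    def test_single_class_rejected(self):
        train = toy_training_set(n_per_class=10)
        only_inactive = TrainingSet(
            X=train.X[train.y == INACTIVE],
            y=train.y[train.y == INACTIVE],
            sampling_rate=3.65, segment_frames=train.segment_frames)
        for trainer in (train_tsf, train_rise):
            with pytest.raises(ValueError, match="both classes"):
                trainer(only_inactive, n_trees=5, seed=0)

    def test_training_set_reproduced_on_itself(self):
        train = toy_training_set(n_per_class=30)
        model = train_tsf(train, n_trees=30, seed=0)
        traces = TraceMatrix(train.X, 3.65, normalized=True)
        labels, _ = predict(model, traces)
        got = np.array([labels[n] for n in traces.neuron_ids], dtype=object)
        assert np.array_equal(got, train.y)


@pytest.fixture(scope="module")
def toy_model():
    return train_tsf(toy_training_set(n_frames=200), n_trees=20, seed=0)


class TestPredictContracts:

    def test_longer_input_rejected_with_frame_budget_rule(self, toy_model):
        too_long = TraceMatrix(np.zeros((2, 201)), 3.65, normalized=True)
        with pytest.raises(ValueError) as err:
            predict(toy_model, too_long)
        assert FRAME_BUDGET_RULE in str(err.value)

    def test_exact_boundary_accepted(self, toy_model):
        ok = TraceMatrix(np.zeros((2, 200)), 3.65, normalized=True)
        labels, _ = predict(toy_model, ok)
        assert len(labels) == 2

    def test_shorter_input_padded_with_warning(self, toy_model):
        short = TraceMatrix(np.zeros((2, 150)), 3.65, normalized=True)
        with pytest.warns(RuntimeWarning, match="right-padding"):
            labels, _ = predict(toy_model, short)
        assert len(labels) == 2

    def test_tie_vote_goes_to_inactive(self):
        # an even forest at exactly a 50:50 split must call "inactive"
        from spontact.classify import ForestModel

        class HalfVotes:
            def vote_fractions(self, X):
                return np.full(X.shape[0], 0.5)

        model = ForestModel(algorithm="tsf", forest=HalfVotes(),
                            training_length=50, sampling_rate=3.65,
                            seed=0, n_trees=2)
        probe = TraceMatrix(np.zeros((5, 50)), 3.65, normalized=True)
        labels, votes = predict(model, probe)
        assert np.all(votes == 0.5)
        assert all(v == INACTIVE for v in labels.labels.values())

    def test_neuron_permutation_permutes_predictions(self, toy_model, rng):
        values = rng.normal(0, 2, size=(8, 200))
        values[2, 50:70] += 40.0
        tr = TraceMatrix(values, 3.65, normalized=True)
        labels, votes = predict(toy_model, tr)
        perm = rng.permutation(8)
        tr_p = TraceMatrix(values[perm], 3.65,
                           neuron_ids=[tr.neuron_ids[i] for i in perm],
                           normalized=True)
        labels_p, votes_p = predict(toy_model, tr_p)
        assert labels_p.labels == {tr.neuron_ids[i]: labels[tr.neuron_ids[i]]
                                   for i in perm}
        assert np.array_equal(votes_p, votes[perm])

    def test_normalization_mode_enforced(self, toy_model):
        raw = TraceMatrix(np.zeros((2, 200)), 3.65, normalized=False)
        with pytest.raises(ValueError, match="ΔF/F0"):
            predict(toy_model, raw)


class TestBuildTrainingSet:
    def make_recording(self, n_neurons, n_frames=2300, rate=3.65, seed=0):
        rng = np.random.default_rng(seed)
        return TraceMatrix(rng.normal(0, 5, size=(n_neurons, n_frames)),
                           rate, normalized=True)

    def test_counts_follow_protocol(self):
        # 10 lidocaine-confirmed SA + 30 silent → 10 active + 40 inactive
        traces = self.make_recording(40)
        verdicts = {f"n{i}": (ACTIVE if i < 10 else INACTIVE)
                    for i in range(40)}
        train = build_training_set([(traces, 300.0, verdicts)],
                                   segment_frames=1100)
        assert train.metadata["n_active"] == 10
        assert train.metadata["n_inactive"] == 40
        origins = [p["origin"] for p in train.provenance]
        assert origins.count("pre_lidocaine_sa") == 10
        assert origins.count("post_lidocaine_sa") == 10
        assert origins.count("post_lidocaine_non_sa") == 30

    def test_segments_come_from_head_and_tail(self):
        traces = self.make_recording(2)
        verdicts = {"n0": ACTIVE, "n1": INACTIVE}
        train = build_training_set([(traces, 300.0, verdicts)],
                                   segment_frames=1100)
        by_origin = {p["origin"]: i for i, p in enumerate(train.provenance)}
        assert np.array_equal(train.X[by_origin["pre_lidocaine_sa"]],
                              traces.values[0, :1100])
        assert np.array_equal(train.X[by_origin["post_lidocaine_sa"]],
                              traces.values[0, -1100:])

    def test_all_ambiguous_yields_empty_set_and_train_error(self):
        traces = self.make_recording(5)
        verdicts = {nid: AMBIGUOUS for nid in traces.neuron_ids}
        train = build_training_set([(traces, 300.0, verdicts)])
        assert len(train) == 0
        with pytest.raises(ValueError, match="empty"):
            train_rise(train, n_trees=5, seed=0)

    def test_short_recording_skipped_with_warning(self):
        short = self.make_recording(3, n_frames=1500)
        verdicts = {nid: INACTIVE for nid in short.neuron_ids}
        with pytest.warns(RuntimeWarning, match="skipped"):
            train = build_training_set([(short, 200.0, verdicts)],
                                       segment_frames=1100)
        assert len(train) == 0

    def test_published_scale_class_imbalance_recorded(self):
        # 8 recordings yielding 272 active and 1036 inactive segments:
        # per recording 34 SA neurons; non-SA neurons 95 or 96
        recordings = []
        for r in range(8):
            n_non_sa = 95 if r < 4 else 96
            n = 34 + n_non_sa
            traces = self.make_recording(n, n_frames=120, seed=r)
            verdicts = {f"n{i}": (ACTIVE if i < 34 else INACTIVE)
                        for i in range(n)}
            recordings.append((traces, 5.0, verdicts))
        train = build_training_set(recordings, segment_frames=50)
        assert train.metadata["n_active"] == 272
        assert train.metadata["n_inactive"] == 1036
        assert train.metadata["imbalance_ratio"] == pytest.approx(
            272 / 1036, abs=1e-12)


class TestCrossValidation:
    def test_each_segment_tested_exactly_once(self):
        train = toy_training_set(n_per_class=50, n_frames=100)
        table = crossvalidate(train, algorithm="tsf", k=5, seed=0, n_trees=5)
        counts = table["tp"] + table["tn"] + table["fp"] + table["fn"]
        assert counts.sum() == 100
        assert (counts == 20).all()

    def test_class_smaller_than_k_rejected(self):
        train = toy_training_set(n_per_class=3, n_frames=60)
        with pytest.raises(ValueError, match="fewer than"):
            crossvalidate(train, algorithm="tsf", k=5, seed=0, n_trees=5)

    def test_label_shuffle_gives_chance_accuracy(self):
        # permutation null: shuffled labels → accuracy near the majority
        # class proportion (0.5 here), within 3 SE across folds
        rng = np.random.default_rng(8)
        train = toy_training_set(n_per_class=40, n_frames=100, seed=2)
        shuffled = TrainingSet(
            X=train.X, y=rng.permutation(train.y),
            sampling_rate=3.65, segment_frames=train.segment_frames)
        table = crossvalidate(shuffled, algorithm="tsf", k=5, seed=0,
                              n_trees=25)
        acc = table["accuracy"].to_numpy()
        se = acc.std(ddof=1) / np.sqrt(len(acc))
        assert abs(acc.mean() - 0.5) < max(3 * se, 0.15)
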