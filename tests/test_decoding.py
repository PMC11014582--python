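import numpy as np
import pytest
from scipy.stats import norm

from metastable import decoding as dec
from metastable.simulate import SpikeData


def toy_trials(spike_specs, n=4, T=1.0, t_stim=0.5):
    out = []
    for k, (times, ids, sid) in enumerate(spike_specs):
        sd = SpikeData(times=np.asarray(times, float),
                       ids=np.asarray(ids, np.int64), n_neurons=n, T=T,
                       t_stim=t_stim, stimulus_id=sid, trial_id=k)
        out.append(sd)
    return out


def gaussian_tensor(rng, n_units, n_per_class, means, n_windows=3,
                    informative_window=1, scale=1.0):
    """Integer-count tensor with class-separated counts in one window."""
    n_classes = len(means)
    n_trials = n_per_class * n_classes
    counts = rng.poisson(3.0, size=(n_units, n_trials, n_windows))
    labels = np.repeat(np.arange(n_classes), n_per_class)
    for c, m in enumerate(means):
        sel = labels == c
        counts[:, sel, informative_window] = rng.poisson(
            m * scale, size=(n_units, sel.sum()))
    return dec.TrialTensor(counts=counts, labels=labels,
                           window_starts=np.arange(n_windows) * 0.1 - 0.1)


def test_lda_matches_sklearn_reference():
    """The internal pooled-covariance LDA equals scikit-learn's lsqr LDA."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    rng = np.random.default_rng(0)
    for trial in range(5):
        X = rng.poisson(3.0, size=(80, 12)).astype(float)
        y = rng.integers(0, 5, 80)
        X[np.arange(80), y] += rng.poisson(4.0, 80)
        ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.01)
        ref.fit(X[:60], y[:60])
        mine = dec._PooledCovLDA(shrinkage=0.01).fit(X[:60], y[:60])
        assert np.array_equal(mine.predict(X[60:]), ref.predict(X[60:]))
        np.testing.assert_allclose(mine.coef_, ref.coef_, rtol=1e-8)


class TestSlidingCounts:
    def test_empty_trains_give_zero_tensor(self):
        trials = toy_trials([([], [], 0), ([], [], 1)])
        t = dec.sliding_counts(trials, np.arange(4), window=0.1, step=0.05,
                               t_range=(-0.1, 0.3))
        assert t.counts.sum() == 0

    def test_single_spike_covered_windows_only(self):
        trials = toy_trials([([0.5], [2], 0)])   # aligned time 0.0
        t = dec.sliding_counts(trials, np.arange(4), window=0.1, step=0.05,
                               t_range=(-0.2, 0.2))
        got = t.counts[2, 0]
        # windows [-0.1,0.0), [-0.05,0.05), [0.0,0.1) -> spike at 0.0 in last two
        expect = [(s <= 0.0 < s + 0.1) for s in t.window_starts]
        assert np.array_equal(got > 0, expect)

    def test_tiling_windows_sum_to_total(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0.0, 1.0, 100))
        trials = toy_trials([(times, np.zeros(100, int), 0)])
        t = dec.sliding_counts(trials, np.array([0]), window=0.1, step=0.1,
                               t_range=(-0.5, 0.5))
        assert t.counts[0, 0].sum() == 100


class TestDecodeTimecourse:
    def test_separable_classes_reach_unit_accuracy(self):
        rng = np.random.default_rng(0)
        t = gaussian_tensor(rng, 8, 15, means=[2, 20, 60, 120, 250])
        res = dec.decode_timecourse(t, seed=1)
        assert res.peak_accuracy == 1.0
        assert res.window_starts[np.argmax(res.accuracy)] \
            == pytest.approx(t.window_starts[1])

    def test_uninformative_labels_decode_at_chance(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(4.0, size=(10, 100, 2))
        labels = np.repeat(np.arange(5), 20)
        t = dec.TrialTensor(counts, labels, np.array([0.0, 0.1]))
        res = dec.decode_timecourse(t, seed=2)
        assert abs(res.accuracy.mean() - 0.2) < 0.08

    def test_two_class_accuracy_approaches_bayes(self):
        """LDA on unit-variance Gaussians: accuracy -> Phi(delta/2)."""
        rng = np.random.default_rng(2)
        delta = 1.2
        n = 800
        X = rng.normal(0.0, 1.0, size=(2 * n, 5))
        X[n:, 0] += delta
        labels = np.repeat([0, 1], n)
        counts = np.round((X - X.min() + 1) * 10).astype(int)[:, :, None]
        t = dec.TrialTensor(np.transpose(counts, (1, 0, 2)), labels,
                            np.array([0.0]))
        res = dec.decode_timecourse(t, seed=3)
        bayes = norm.cdf(delta / 2)   # Bayes rate for unit-variance classes
        assert abs(res.peak_accuracy - bayes) < 0.03

    def test_errors(self):
        t = dec.TrialTensor(np.zeros((2, 10, 1), int), np.zeros(10, int),
                            np.array([0.0]))
        with pytest.raises(ValueError):
            dec.decode_timecourse(t, seed=0)
        t2 = dec.TrialTensor(np.zeros((2, 6, 1), int),
                             np.array([0, 0, 0, 1, 1, 1]), np.array([0.0]))
        with pytest.raises(ValueError, match="folds"):
            dec.decode_timecourse(t2, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        t = gaussian_tensor(rng, 6, 10, means=[3, 8, 15, 25, 40])
        a = dec.decode_timecourse(t, seed=9).accuracy
        b = dec.decode_timecourse(t, seed=9).accuracy
        assert np.array_equal(a, b)


class TestShuffleNull:
    def test_informative_data_significant(self):
        rng = np.random.default_rng(5)
        t = gaussian_tensor(rng, 8, 15, means=[2, 20, 60, 120, 250])
        null, sig = dec.shuffle_null(t, window_index=1, seed=6,
                                     true_accuracy=1.0)
        assert sig
        assert abs(null.mean() - 0.2) < 0.06

    def test_stratified_split_preserves_label_counts(self):
        rng = np.random.default_rng(6)
        labels = np.repeat(np.arange(5), 20)
        # oracle: stratified 80/20 keeps 4 test trials per label
        from sklearn.model_selection import train_test_split
        y = rng.permutation(labels)
        tr, te = train_test_split(np.arange(100), test_size=0.2, stratify=y,
                                  random_state=0)
        _, cnt = np.unique(y[te], return_counts=True)
        assert np.all(cnt == 4)


class TestPupilPartition:
    def test_equal_partitions_and_balance(self):
        rng = np.random.default_rng(7)
        pupil = rng.uniform(0, 1, 200)
        labels = np.tile(np.arange(5), 40)
        part = dec.pupil_partition(pupil, labels, seed=0)
        sizes = [(part.assignment == b).sum() for b in range(10)]
        assert sizes == [20] * 10
        for b, chosen in enumerate(part.balanced_trials):
            if chosen.size:
                _, cnt = np.unique(labels[chosen], return_counts=True)
                assert np.all(cnt == cnt[0])

    def test_decile_edges_match_sort_oracle(self):
        rng = np.random.default_rng(8)
        pupil = rng.uniform(0, 1, 500)
        labels = np.tile(np.arange(5), 100)
        part = dec.pupil_partition(pupil, labels, seed=0)
        srt = np.sort(pupil)
        for b in range(10):
            sel = pupil[part.assignment == b]
            assert np.all(sel >= srt[b * 50] - 1e-12)
            assert np.all(sel <= srt[min(499, (b + 1) * 50)] + 1e-12)

    def test_locomotion_exclusion(self):
        pupil = np.linspace(0, 1, 100)
        labels = np.tile(np.arange(5), 20)
        vel = np.zeros(100)
        vel[:30] = 5.0
        part = dec.pupil_partition(pupil, labels, seed=0, velocity=vel)
        assert np.all(part.assignment[:30] == -1)


class TestFeatureSampling:
    def test_feature_count_p18(self):
        rng = np.random.default_rng(9)
        membership = np.repeat(np.arange(1, 20), 20)   # p=18 + background
        t = gaussian_tensor(rng, membership.size, 10,
                            means=[3, 10, 30, 80, 200])
        res = dec.model_feature_sample(t, np.arange(membership.size),
                                       membership, seed=1, n_runs=2)
        assert res.meta["n_features"] == 19

    def test_run_averaging_reduces_variance(self):
        rng = np.random.default_rng(10)
        membership = np.repeat(np.arange(1, 20), 10)
        t = gaussian_tensor(rng, membership.size, 10,
                            means=[3, 6, 9, 13, 18], scale=1.0)
        single = [dec.model_feature_sample(t, np.arange(membership.size),
                                           membership, seed=s, n_runs=1).peak_accuracy
                  for s in range(12)]
        avged = [dec.model_feature_sample(t, np.arange(membership.size),
                                          membership, seed=100 + s,
                                          n_runs=8).peak_accuracy
                 for s in range(12)]
        assert np.var(avged) < np.var(single)


class TestSessionPooling:
    def test_single_session_zscore(self):
        acc = np.array([0.3, 0.5, 0.4, 0.6, 0.45, 0.55, 0.35, 0.65, 0.5, 0.4])
        centers = np.linspace(0.05, 0.95, 10)
        out = dec.pool_sessions([acc], [centers])
        vals = np.concatenate([v for v in out["values"] if v])
        assert np.mean(vals) == pytest.approx(0.0, abs=1e-12)
        assert np.std(vals) == pytest.approx(1.0, abs=1e-12)

    def test_two_identical_sessions_equal_single(self):
        acc = np.linspace(0.3, 0.7, 10)
        centers = np.linspace(0.05, 0.95, 10)
        one = dec.pool_sessions([acc], [centers])
        two = dec.pool_sessions([acc, acc], [centers, centers])
        np.testing.assert_allclose(one["mean"], two["mean"])

    def test_same_bin_points_averaged_before_pooling(self):
        acc = np.array([0.0, 1.0, 0.5])
        centers = np.array([0.11, 0.12, 0.55])   # first two share a bin
        out = dec.pool_sessions([acc], [centers])
        z = (acc - acc.mean()) / acc.std()
        assert out["mean"][1] == pytest.approx(0.5 * (z[0] + z[1]))
        assert out["mean"][5] == pytest.approx(z[2])


class TestMidVsExtreme:
    def make_sessions(self, rng, shape, n=15):
        accs, cents = [], []
        for _ in range(n):
            c = np.linspace(0.08, 0.92, 10)
            base = shape(c) + rng.normal(0, 0.01, 10)
            accs.append(base)
            cents.append(c)
        return accs, cents

    def test_inverted_u_detected(self):
        rng = np.random.default_rng(11)
        accs, cents = self.make_sessions(
            rng, lambda c: 0.6 - 0.5 * (c - 0.5) ** 2 * 4)
        out = dec.mid_vs_extreme(accs, cents)
        assert out["p_mid_vs_low"] < 0.05 and out["mid_minus_low"] > 0
        assert out["p_mid_vs_high"] < 0.05 and out["mid_minus_high"] > 0

    def test_flat_sessions_type_one_control(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_sims = 120
        for _ in range(n_sims):
            accs, cents = self.make_sessions(rng, lambda c: 0.5 * np.ones(10))
            out = dec.mid_vs_extreme(accs, cents)
            rejections += (out["p_mid_vs_high"] < 0.05
                           and out["mid_minus_high"] > 0)
        # one-sided false-positive rate ~ 2.5%; allow binomial slack
        assert rejections / n_sims < 0.08

    def test_exclusion_rule(self):
        rng = np.random.default_rng(13)
        accs, cents = self.make_sessions(rng, lambda c: 0.5 + 0.1 * c, n=6)
        cents[0] = np.linspace(0.3, 0.92, 10)   # first decile not < 25%
        out = dec.mid_vs_extreme(accs, cents)
        assert out["n_low_sessions"] == 5
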