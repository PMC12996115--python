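"""Offline analyses: epoch QC, nested CV, importance, topographies, stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fearloop.features import EpochSet
from fearloop.offline import (
    benjamini_hochberg,
    correlation_matrix,
    grand_average_topomap,
    hr_window_means,
    level_stats,
    make_binary_labels,
    nested_cv_classify,
    rank_feature_importance,
    reject_epochs,
)
from fearloop.simulator import ParticipantParams, simulate_labeled_epochs


def toy_epochs(n=6, n_ch=4, n_samp=100, levels=None):
    rng = np.random.default_rng(0)
    data = rng.standard_normal((n, n_ch, n_samp))
    return EpochSet(
        data,
        [f"c{i}" for i in range(n_ch)],
        100.0,
        np.arange(n) * 1.0,
        None if levels is None else np.asarray(levels),
    )


class TestEpochRejection:
    def test_clean_epochs_all_kept(self):
        ep = toy_epochs()
        kept, mask = reject_epochs(ep)
        assert kept.n_epochs == ep.n_epochs
        assert mask.all()

    def test_planted_spike_removed_exactly(self):
        ep = toy_epochs()
        ep.data[3, 1, 50] = 500.0
        kept, mask = reject_epochs(ep)
        assert not mask[3]
        assert mask.sum() == 5
        np.testing.assert_array_equal(kept.data[0], ep.data[0])

    def test_infinite_threshold_is_identity(self):
        ep = toy_epochs()
        kept, mask = reject_epochs(ep, np.inf)
        assert mask.all()

    def test_all_rejected(self):
        ep = toy_epochs()
        with pytest.raises(ValueError):
            reject_epochs(ep, 0.0)


class TestBinaryLabels:
    def test_level_mapping(self):
        lab = make_binary_labels([1, 2, 3, 4, 5])
        np.testing.assert_array_equal(lab.binary_label, [0, 0, -1, 1, 1])

    def test_all_level_three_warns_empty(self):
        with pytest.warns(UserWarning):
            lab = make_binary_labels([3, 3, 3])
        assert not lab.included.any()

    def test_counts_bookkeeping(self):
        levels = [1, 1, 2, 4, 5, 5, 3]
        lab = make_binary_labels(levels)
        assert np.sum(lab.binary_label == 0) == 3
        assert np.sum(lab.binary_label == 1) == 3
        assert np.sum(~lab.included) == 1


class TestNestedCV:
    def test_separable_data_is_perfect(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (20, 164)), rng.normal(6, 1, (20, 164))])
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        rep = nested_cv_classify(X, y, "svm", "PSD+FAA", seed=0)
        assert rep.accuracy_mean == 100.0
        assert rep.accuracy_sd == 0.0

    def test_noise_features_stay_at_chance(self):
        """With no class signal the leak-free pipeline must not rise above
        chance (a leaking scaler or grid search would)."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 164))
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        rep = nested_cv_classify(X, y, "svm", "PSD+FAA", seed=0)
        assert rep.accuracy_mean == pytest.approx(50.0, abs=15.0)

    def test_permuted_simulator_labels_at_chance(self, offline_dataset):
        _, X, y = offline_dataset
        yp = np.random.default_rng(5).permutation(y)
        rep = nested_cv_classify(X, yp, "svm", "PSD+FAA", seed=0)
        assert rep.accuracy_mean == pytest.approx(50.0, abs=15.0)

    def test_psd_at_least_as_good_as_faa_only(self, offline_dataset):
        """Whole-scalp bandpower carries at least the information of the
        four asymmetry indices on simulated participants."""
        _, X, y = offline_dataset
        wins = 0
        for seed in range(5):
            psd = nested_cv_classify(X, y, "svm", "PSD", seed=seed).accuracy_mean
            faa = nested_cv_classify(X, y, "svm", "FAA", seed=seed).accuracy_mean
            wins += psd >= faa
        assert wins >= 4

    def test_too_few_samples_rejected(self):
        X = np.zeros((8, 164))
        y = np.r_[np.zeros(4, int), np.ones(4, int)]
        with pytest.raises(ValueError):
            nested_cv_classify(X, y)


class TestFeatureImportance:
    def make_planted(self, rng, n=80, n_feat=20, informative=(7,)):
        X = rng.standard_normal((n, n_feat))
        y = rng.integers(0, 2, n)
        for k in informative:
            X[:, k] += 3.0 * y
        return X, y

    def test_planted_feature_ranked_first(self):
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(3)
        X, y = self.make_planted(rng)
        rf = RandomForestClassifier(random_state=0).fit(X, y)
        names = [f"f{i}" for i in range(20)]
        ranked = rank_feature_importance(rf, names)
        assert ranked[0][0] == "f7"

    def test_duplicated_informative_features_in_top3(self):
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(4)
        X, y = self.make_planted(rng, informative=(7, 8))
        X[:, 8] = X[:, 7]
        rf = RandomForestClassifier(random_state=0).fit(X, y)
        ranked = rank_feature_importance(rf, [f"f{i}" for i in range(20)])
        top3 = {name for name, _ in ranked[:3]}
        assert {"f7", "f8"} <= top3

    def test_noise_features_have_unstable_ranking(self):
        from sklearn.ensemble import RandomForestClassifier

        ranks = []
        for seed in (0, 1):
            rng = np.random.default_rng(50 + seed)
            X = rng.standard_normal((80, 20))
            y = rng.integers(0, 2, 80)
            rf = RandomForestClassifier(random_state=seed).fit(X, y)
            imp = rf.feature_importances_
            ranks.append(np.argsort(np.argsort(-imp)))
        rho = stats.spearmanr(ranks[0], ranks[1]).statistic
        assert abs(rho) < 0.3

    def test_linear_svm_uses_absolute_weights(self):
        from sklearn.svm import SVC

        rng = np.random.default_rng(6)
        X, y = self.make_planted(rng)
        svc = SVC(kernel="linear").fit(X, y)
        ranked = rank_feature_importance(svc, [f"f{i}" for i in range(20)])
        assert ranked[0][0] == "f7"


class TestTopomap:
    def test_identical_epochs_identical_rows(self):
        ep = toy_epochs(n=4, n_ch=4, n_samp=400, levels=[1, 2, 1, 2])
        ep.data[:] = ep.data[0]
        matrix, levels, bands = grand_average_topomap(ep, levels=(1, 2))
        np.testing.assert_allclose(matrix[0], matrix[1])

    def test_empty_level_gives_nan_row(self):
        ep = toy_epochs(n=2, n_samp=400, levels=[1, 1])
        with pytest.warns(UserWarning):
            matrix, _, _ = grand_average_topomap(ep, levels=(1, 2))
        assert np.isnan(matrix[1]).all()
        assert np.isfinite(matrix[0]).all()

    def test_simulated_band_trends_across_levels(self, params):
        """Frontal theta grows and alpha shrinks as the stimulus level
        (hence fear) increases."""
        levels = [1, 1, 3, 3, 5, 5]
        ep = simulate_labeled_epochs(params, levels, epoch_s=10.0, seed=6)
        matrix, levs, bands = grand_average_topomap(ep)
        theta, alpha = bands.index("theta"), bands.index("alpha")
        theta_means = [np.nanmean(matrix[levs.index(k), theta]) for k in (1, 3, 5)]
        alpha_means = [np.nanmean(matrix[levs.index(k), alpha]) for k in (1, 3, 5)]
        assert theta_means[0] < theta_means[1] < theta_means[2]
        assert alpha_means[0] > alpha_means[1] > alpha_means[2]


class TestLevelStats:
    def test_ten_hr_window_means_per_run(self, params):
        from fearloop.simulator import simulate_session

        session, _ = simulate_session(params, "main", seed=9)
        t0 = session.markers.first_time()
        means = hr_window_means(session.hr.times - t0, session.hr.values)
        assert means.shape == (10,)
        assert np.isfinite(means).all()

    def test_type_one_error_controlled(self):
        """Identical distributions: across 200 simulated runs, at least 95%
        produce no significant pair after BH."""
        rng = np.random.default_rng(10)
        clean = 0
        for _ in range(200):
            groups = {k: rng.normal(70, 1, 10) for k in range(1, 6)}
            table = level_stats(groups)
            clean += not table["significant"].any()
        assert clean / 200 >= 0.95

    def test_planted_shift_detected(self):
        """A 2-bpm shift at one level (n = 40/level, 1-bpm jitter) is found
        with power >= 0.8."""
        rng = np.random.default_rng(11)
        hits = 0
        n_runs = 50
        for _ in range(n_runs):
            groups = {k: rng.normal(70, 1, 40) for k in range(1, 5)}
            groups[5] = rng.normal(72, 1, 40)
            table = level_stats(groups)
            row = table[(table.group_a == 1) & (table.group_b == 5)]
            hits += bool(row["significant"].iloc[0])
        assert hits / n_runs >= 0.8

    def test_degenerate_variance_flagged(self):
        table = level_stats({1: np.ones(5), 2: np.ones(5), 3: np.random.default_rng(0).normal(0, 1, 5)})
        row = table[(table.group_a == 1) & (table.group_b == 2)]
        assert np.isnan(row["statistic"].iloc[0])
        assert not row["significant"].iloc[0]

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            level_stats({1: np.arange(5)})


class TestCorrelationMatrix:
    def test_diagonal_is_one(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.standard_normal((21, 3)), columns=list("abc"))
        r, _, _, _ = correlation_matrix(df)
        np.testing.assert_allclose(np.diag(r.to_numpy()), 1.0)

    def test_independent_pair_usually_masked(self):
        rng = np.random.default_rng(13)
        masked = 0
        for _ in range(200):
            df = pd.DataFrame(
                rng.standard_normal((21, 2)), columns=["x", "y"]
            )
            _, _, _, sig = correlation_matrix(df)
            masked += not sig.loc["x", "y"]
        assert masked / 200 >= 0.90

    def test_strong_linear_relation_unmasked(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(21)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1e-6 * rng.standard_normal(21)})
        r, _, _, sig = correlation_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0, abs=1e-6)
        assert sig.loc["x", "y"]

    def test_zero_variance_column_flagged(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({"x": rng.standard_normal(10), "c": np.ones(10)})
        r, p, _, sig = correlation_matrix(df)
        assert np.isnan(r.loc["x", "c"])
        assert not sig.loc["x", "c"]


def bh_bruteforce(p, alpha=0.05):
    """Independent step-up oracle: largest k with p_(k) <= k/m * alpha."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    if k_star:
        reject[order[:k_star]] = True
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * sorted_p[i] / (i + 1))
        adj[order[i]] = running
    return adj, reject


class TestBenjaminiHochberg:
    def test_simple_cases(self):
        adj, rej = benjamini_hochberg([0.01, 0.02, 0.03])
        assert rej.all()
        _, rej1 = benjamini_hochberg([1.0, 1.0, 1.0])
        assert not rej1.any()
        _, rej2 = benjamini_hochberg([0.04])
        assert rej2.all()

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(16)
        for _ in range(1000):
            m = rng.integers(1, 13)
            p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 3)
            adj, rej = benjamini_hochberg(p)
            adj_o, rej_o = bh_bruteforce(p)
            np.testing.assert_array_equal(rej, rej_o)
            np.testing.assert_allclose(adj, adj_o, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])
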