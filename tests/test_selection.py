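"""The signature selector: group statistics, selection score, AUPR, CV,
combined ranking, brute-force baseline, and the unsupervised pre-filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score

import simplesig as ss
from simplesig.selection import average_precision


def make_matrix(vals, prefix="cg"):
    vals = np.asarray(vals, dtype=float)
    return ss.MethylMatrix(
        np.clip(vals, 0, 1),
        [f"{prefix}{i + 1:06d}" for i in range(vals.shape[0])],
        [f"s{j + 1}" for j in range(vals.shape[1])],
    )


def planted_marker_data(n_noise=500, n_pos=10, n_neg=30, seed=0):
    """One perfectly separating hyper marker on top of uniform noise."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * n_pos + [0] * n_neg)
    marker = np.where(y == 1, 0.9, 0.1) + rng.uniform(-0.05, 0.05, y.size)
    noise = rng.uniform(0.3, 0.7, size=(n_noise, y.size))
    X = make_matrix(np.vstack([marker, noise]))
    return X, y, X.feature_ids[0]


class TestGroupStats:
    def test_hand_example(self):
        X = make_matrix([[0.8, 0.9, 0.1, 0.2]])
        s = ss.group_stats(X, np.array([1, 1, 0, 0]))
        assert s.delta[0] == pytest.approx(0.7)
        assert s.sigma[0] == pytest.approx(0.01)
        assert s.mu_target[0] == pytest.approx(0.85)
        assert s.var_others[0] == pytest.approx(0.005)

    def test_identical_groups_zero_delta(self):
        X = make_matrix([[0.2, 0.4, 0.2, 0.4]])
        s = ss.group_stats(X, np.array([1, 1, 0, 0]))
        assert s.delta[0] == 0
        assert s.sigma[0] == pytest.approx(2 * np.var([0.2, 0.4], ddof=1))

    def test_matches_naive_loop_on_random_matrix(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.05, 0.95, size=(50, 12))
        y = rng.permutation([1] * 5 + [0] * 7)
        s = ss.group_stats(make_matrix(vals), y)
        for i in range(50):
            t, o = vals[i, y == 1], vals[i, y == 0]
            assert s.delta[i] == pytest.approx(t.mean() - o.mean())
            assert s.sigma[i] == pytest.approx(
                t.var(ddof=1) + o.var(ddof=1)
            )

    def test_group_smaller_than_two_raises(self):
        X = make_matrix([[0.1, 0.2, 0.3]])
        with pytest.raises(ValueError, match=">= 2"):
            ss.group_stats(X, np.array([1, 0, 0]))

    def test_permutation_and_target_swap_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 1, size=(10, 8))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        s1 = ss.group_stats(make_matrix(vals), y)
        perm = rng.permutation(8)
        s2 = ss.group_stats(make_matrix(vals[:, perm]), y[perm])
        np.testing.assert_allclose(s1.delta, s2.delta, atol=1e-12)
        np.testing.assert_allclose(s1.sigma, s2.sigma, atol=1e-12)
        s3 = ss.group_stats(make_matrix(vals), 1 - y)
        np.testing.assert_allclose(s1.delta, -s3.delta, atol=1e-12)
        np.testing.assert_allclose(s1.sigma, s3.sigma, atol=1e-12)

    def test_features_with_missing_values_are_excluded(self):
        vals = np.array([[0.1, 0.2, 0.8, 0.9], [np.nan, 0.2, 0.3, 0.4]])
        s = ss.group_stats(make_matrix(vals), np.array([1, 1, 0, 0]))
        assert s.feature_ids == ["cg000001"]
        assert s.n_excluded_missing == 1


class TestSelectionScore:
    def _stats(self, delta, sigma):
        n = len(delta)
        return ss.FeatureStats(
            [f"f{i}" for i in range(n)],
            np.asarray(delta, float),
            np.asarray(sigma, float),
            np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n),
        )

    def test_hand_arithmetic(self):
        a = ss.selection_score(self._stats([0.7], [0.01]), b=2)
        assert a[0] == pytest.approx(0.01 / 0.49)

    def test_zero_delta_gives_infinity(self):
        a = ss.selection_score(self._stats([0.0], [0.3]), b=2)
        assert np.isinf(a[0])

    def test_odd_b_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ss.selection_score(self._stats([0.5], [0.1]), b=3)

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(min_value=1e-3, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.sampled_from([0, 2, 4]),
    )
    def test_sign_invariance(self, delta, sigma, b):
        ap = ss.selection_score(self._stats([delta], [sigma]), b=b)
        am = ss.selection_score(self._stats([-delta], [sigma]), b=b)
        assert ap[0] == pytest.approx(am[0])

    def test_matches_naive_recomputation_for_b2_and_b4(self):
        rng = np.random.default_rng(9)
        delta = rng.uniform(-1.5, 1.5, 100)
        sigma = rng.uniform(0, 0.5, 100)
        stats = self._stats(delta, sigma)
        for b in (2, 4):
            expected = np.array(
                [s / d**b if d != 0 else np.inf for d, s in zip(delta, sigma)]
            )
            np.testing.assert_allclose(ss.selection_score(stats, b), expected)


class TestPreselectActive:
    def test_smallest_fraction_selected(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(np.linspace(0.01, 10, 1000))
        ids = [f"f{i}" for i in range(1000)]
        sel = ss.preselect_active(scores, ids, 0.005)
        expected = [ids[i] for i in np.argsort(scores)[:5]]
        assert sorted(sel) == sorted(expected)

    def test_all_ties_all_selected(self):
        sel = ss.preselect_active(
            np.full(10, 2.5), [f"f{i}" for i in range(10)], 0.1
        )
        assert len(sel) == 10

    def test_matches_sort_oracle_with_infinities(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 1, 200)
        scores[rng.choice(200, 50, replace=False)] = np.inf
        ids = [f"f{i}" for i in range(200)]
        p = 0.05
        sel = set(ss.preselect_active(scores, ids, p))
        finite = scores[np.isfinite(scores)]
        thr = np.quantile(finite, p)
        oracle = {f for f, s in zip(ids, scores) if np.isfinite(s) and s <= thr}
        assert sel == oracle
        assert len(sel) >= max(1, int(np.floor(p * finite.size)))

    def test_all_infinite_raises(self):
        with pytest.raises(ValueError, match="no discriminative"):
            ss.preselect_active(np.array([np.inf, np.inf]), ["a", "b"], 0.5)


def aupr_threshold_oracle(scores, y):
    """Exhaustive enumeration: step through distinct thresholds descending."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_recall = 0.0, 0.0
    n_pos = y.sum()
    for t in thresholds:
        called = scores >= t
        precision = y[called].sum() / called.sum()
        recall = y[called].sum() / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestFeatureAupr:
    def test_perfect_separator(self):
        x = np.array([0.9, 0.8, 0.85, 0.1, 0.2, 0.15])
        y = np.array([1, 1, 1, 0, 0, 0])
        assert ss.feature_aupr(x, y, "hyper") == 1.0
        assert ss.feature_aupr(-x, y, "hypo") == 1.0
        assert ss.feature_aupr(x, y, "auto") == 1.0

    def test_constant_feature_equals_prevalence(self):
        y = np.array([1, 0, 0, 1, 0])
        assert ss.feature_aupr(np.full(5, 0.5), y, "hyper") == pytest.approx(2 / 5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ss.feature_aupr(np.arange(4.0), np.ones(4, int), "hyper")

    def test_matches_oracle_on_all_label_arrangements(self):
        """Exact agreement with threshold enumeration on all 2^6 labelings."""
        scores = np.array([0.1, 0.25, 0.4, 0.55, 0.7, 0.85])
        for bits in range(1, 63):  # both classes present
            y = np.array([(bits >> i) & 1 for i in range(6)])
            assert average_precision(scores, y) == pytest.approx(
                aupr_threshold_oracle(scores, y), abs=1e-12
            )

    def test_matches_oracle_and_sklearn_under_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=12)
            y = rng.integers(0, 2, 12)
            if y.sum() in (0, 12):
                continue
            ours = average_precision(scores, y)
            assert ours == pytest.approx(aupr_threshold_oracle(scores, y), abs=1e-12)
            assert ours == pytest.approx(
                average_precision_score(y, scores), abs=1e-12
            )

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**8 - 2))
    def test_monotone_transform_invariance(self, bits):
        rng = np.random.default_rng(bits)
        x = rng.normal(size=8)
        y = np.array([(bits >> i) & 1 for i in range(8)])
        if y.sum() in (0, 8):
            return
        base = ss.feature_aupr(x, y, "hyper")
        assert ss.feature_aupr(np.exp(x), y, "hyper") == pytest.approx(base)
        assert ss.feature_aupr(3 * x + 7, y, "hyper") == pytest.approx(base)


class TestCrossValidate:
    def test_planted_perfect_marker_active_in_every_fold(self):
        X, y, marker = planted_marker_data()
        cfg = ss.SelectionConfig(k=5, quantile_p=0.005, seed=11)
        cv = ss.cross_validate(X, y, cfg)
        i = cv.feature_ids.index(marker)
        assert cv.fold_activity[i] == 5
        assert cv.aupr_train_mean[i] == 1.0
        assert cv.aupr_valid_mean[i] == 1.0

    def test_k_reduced_to_target_class_size(self):
        X, y, _ = planted_marker_data(n_noise=50, n_pos=4, n_neg=20)
        cv = ss.cross_validate(X, y, ss.SelectionConfig(k=10, seed=0))
        assert cv.k == 4

    def test_deterministic_given_seed(self):
        X, y, _ = planted_marker_data(n_noise=80)
        cfg = ss.SelectionConfig(k=5, seed=3)
        cv1 = ss.cross_validate(X, y, cfg)
        cv2 = ss.cross_validate(X, y, cfg)
        assert cv1.feature_ids == cv2.feature_ids
        np.testing.assert_array_equal(cv1.fold_activity, cv2.fold_activity)
        np.testing.assert_array_equal(cv1.aupr_valid_mean, cv2.aupr_valid_mean)

    def test_too_few_positives_raise(self):
        X, _, _ = planted_marker_data(n_noise=10, n_pos=2, n_neg=10)
        with pytest.raises(ValueError):
            ss.cross_validate(
                X, np.array([1] + [0] * 11), ss.SelectionConfig(seed=0)
            )


class TestCombineAndRank:
    def test_upper_bound_score(self):
        """a~=1, both AUPRs 1 and full fold activity give C = 0.8 + 0.2 + 0.2."""
        cv = ss.CVResult(
            ["cgA", "cgB"],
            np.array([10, 5]),
            np.array([1.0, 1.0]),
            np.array([1.0, 1.0]),
            k=10,
        )
        stats = ss.FeatureStats(
            ["cgA", "cgB"],
            np.array([0.8, 0.4]),
            np.array([0.005, 0.02]),
            np.array([0.9, 0.7]),
            np.array([0.1, 0.3]),
            np.array([0.002, 0.01]),
            np.array([0.003, 0.01]),
        )
        sig = ss.combine_and_rank(
            cv, stats, ss.SelectionConfig(n_sigs=2, seed=0), target="t"
        )
        assert sig.top().feature_id == "cgA"
        assert sig.top().score_c == pytest.approx(1.2)

    def test_fold_activity_monotonicity(self):
        cv = ss.CVResult(
            ["cgA", "cgB"],
            np.array([10, 5]),
            np.array([1.0, 1.0]),
            np.array([1.0, 1.0]),
            k=10,
        )
        stats = ss.FeatureStats(
            ["cgA", "cgB"],
            np.array([0.5, 0.5]),
            np.array([0.01, 0.01]),
            *(np.zeros(2),) * 4,
        )
        sig = ss.combine_and_rank(cv, stats, ss.SelectionConfig(n_sigs=2, seed=0))
        assert sig.feature_ids == ["cgA", "cgB"]
        assert sig.entries[0].score_c > sig.entries[1].score_c

    def test_full_ranking_matches_naive_loop(self, small_simulation):
        """Scripted re-computation of the combined score reproduces the order."""
        _, X, labels, _ = small_simulation
        cfg = ss.SelectionConfig(
            n_sigs=5, quantile_p=0.02, k=5, seed=2
        )
        y = labels.binarize("ct2")
        stats = ss.group_stats(X, y)
        cv = ss.cross_validate(X, y, cfg)
        sig = ss.combine_and_rank(cv, stats, cfg, target="ct2")

        a_all = ss.selection_score(stats, cfg.b)
        pos = {f: i for i, f in enumerate(stats.feature_ids)}
        a = np.array([a_all[pos[f]] for f in cv.feature_ids])
        fin = np.isfinite(a)
        a_t = np.zeros_like(a)
        lo, hi = a[fin].min(), a[fin].max()
        a_t[fin] = 1.0 if hi == lo else 1 - (a[fin] - lo) / (hi - lo)
        rows = []
        for j, f in enumerate(cv.feature_ids):
            c = (
                cfg.alpha1 * a_t[j]
                + cfg.alpha2 * cv.aupr_train_mean[j]
                + cfg.alpha2 * np.nan_to_num(cv.aupr_valid_mean[j])
            ) * cv.fold_activity[j] / cv.k
            rows.append((f, c, np.nan_to_num(cv.aupr_valid_mean[j])))
        rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
        assert sig.feature_ids == [r[0] for r in rows[: cfg.n_sigs]]
        for e, r in zip(sig.entries, rows):
            assert e.score_c == pytest.approx(r[1], abs=1e-12)

    def test_empty_cv_raises(self):
        stats = ss.FeatureStats(["cgA"], *(np.zeros(1),) * 6)
        cv = ss.CVResult([], np.array([]), np.array([]), np.array([]), k=5)
        with pytest.raises(ValueError):
            ss.combine_and_rank(cv, stats, ss.SelectionConfig(seed=0))


class TestBruteForce:
    def test_unique_perfect_marker_ranked_first(self):
        Xtr, ytr, marker = planted_marker_data(n_noise=100, seed=1)
        Xte, yte, _ = planted_marker_data(n_noise=100, seed=2)
        ranking = ss.brute_force_select(Xtr, ytr, Xte, yte)
        assert ranking.iloc[0]["feature_id"] == marker
        assert ranking.iloc[0]["aupr_test"] == 1.0

    def test_noise_aupr_near_prevalence(self):
        """With labels independent of features, the max AUPR stays near the
        class prevalence (mean over 20 seeds within +/- 0.15)."""
        tops = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.array([1] * 20 + [0] * 80)
            vals = rng.uniform(0, 1, size=(30, 100))
            X = make_matrix(vals)
            ranking = ss.brute_force_select(X, y, X, y)
            tops.append(ranking["aupr_test"].mean())
        assert abs(np.mean(tops) - 0.2) < 0.15

    def test_agrees_with_selector_on_dominant_marker(self, small_simulation):
        _, X, labels, marker_map = small_simulation
        sheet = ss.assign_split(labels, seed=0)
        Xtr = X.select_samples(sheet.ids("train"))
        Xte = X.select_samples(sheet.ids("test"))
        for t in labels.cell_types:
            ytr = sheet.labels("train").binarize(t)
            yte = sheet.labels("test").binarize(t)
            bf_top = ss.brute_force_select(Xtr, ytr, Xte, yte).iloc[0]["feature_id"]
            sig = ss.train_signature(
                Xtr, sheet.labels("train"), t, ss.SelectionConfig(seed=1, k=5)
            )
            assert sig.top().feature_id == bf_top == marker_map[t][0][0]


class TestPrefilter:
    def test_constant_duplicate_and_linear_combo_removed(self):
        rng = np.random.default_rng(6)
        f1 = rng.uniform(0, 1, 10)
        f2 = rng.uniform(0, 1, 10)
        vals = np.vstack(
            [
                f1,
                f2,
                np.clip(0.5 * f1 + 0.5 * f2, 0, 1),  # exact linear combination
                np.full(10, 0.4),  # constant
                f1,  # duplicate (|r| = 1)
            ]
        )
        X = make_matrix(vals)
        kept = ss.prefilter_features(X)
        assert X.feature_ids[3] not in kept  # constant dropped
        # exactly one copy of the duplicated feature survives
        assert (X.feature_ids[0] in kept) + (X.feature_ids[4] in kept) == 1
        assert X.feature_ids[2] not in kept  # linear combination dropped

    def test_independent_features_all_kept(self):
        rng = np.random.default_rng(7)
        X = make_matrix(rng.uniform(0, 1, size=(6, 20)))
        assert ss.prefilter_features(X) == X.feature_ids
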