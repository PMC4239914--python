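"""Boosted BP-network classifier: coding, training, boosting algebra, voting."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fermfuse.bp_adaboost import (
    UNASSIGNED,
    BPNetConfig,
    StrongPredictor,
    WeakPredictor,
    decode_labels,
    encode_labels,
    forward,
    load_predictor,
    predict,
    save_predictor,
    train_bp,
    train_ensemble,
    update_distribution,
    vote_weight,
    weak_error,
)

TOY_X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
TOY_DAYS = np.array([0, 0, 1, 1])


class TestLabelCoding:
    def test_day3_one_of_seven(self):
        Y, classes = encode_labels([3], classes=np.arange(7))
        assert np.array_equal(Y[0], [0, 0, 0, 1, 0, 0, 0])

    def test_roundtrip_and_row_sums(self):
        days = np.array([0, 6, 3, 3, 5])
        Y, classes = encode_labels(days, classes=np.arange(7))
        assert np.array_equal(decode_labels(Y, classes), days)
        assert np.all(Y.sum(axis=1) == 1)

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError):
            encode_labels([7], classes=np.arange(7))


class TestTrainBP:
    def test_toy_reaches_target_mse_for_most_seeds(self):
        Y, _ = encode_labels(TOY_DAYS)
        cfg = BPNetConfig()
        hits = sum(
            train_bp(TOY_X, Y, cfg, rng=s).final_mse <= cfg.target_mse
            for s in range(10)
        )
        assert hits >= 8

    def test_identical_seed_identical_weights(self):
        Y, _ = encode_labels(TOY_DAYS)
        a = train_bp(TOY_X, Y, BPNetConfig(), rng=3)
        b = train_bp(TOY_X, Y, BPNetConfig(), rng=3)
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.w2, b.w2)

    def test_zero_epoch_budget_forbidden(self):
        with pytest.raises(ValueError):
            BPNetConfig(max_epochs=0)

    def test_nan_input_rejected(self):
        Y, _ = encode_labels(TOY_DAYS)
        X = TOY_X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_bp(X, Y, BPNetConfig(), rng=0)

    @pytest.mark.parametrize("optimizer", ["rprop", "gdm"])
    def test_both_optimizers_learn_the_toy(self, optimizer):
        Y, _ = encode_labels(TOY_DAYS)
        net = train_bp(TOY_X, Y, BPNetConfig(optimizer=optimizer), rng=1)
        out = forward(net, TOY_X)
        assert np.array_equal(np.argmax(out, axis=1), TOY_DAYS)

    def test_loss_weighting_emphasizes_heavy_rows(self):
        # a conflicting dataset: two identical inputs with opposite labels;
        # the heavily weighted row must win the network's prediction
        X = np.array([[0.5, 0.5], [0.5, 0.5]])
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        D = np.array([0.95, 0.05])
        net = train_bp(X, Y, BPNetConfig(), rng=0, row_weights=D)
        out = forward(net, X[:1])
        assert out[0, 0] > out[0, 1]


class TestWeakError:
    def test_uniform_quarter(self):
        D = np.full(4, 0.25)
        Y = np.eye(4)
        Yhat = Y.copy()
        Yhat[1] = [0.5, 0.5, 0.0, 0.0]  # deviation 0.5 > 0.2 on sample 1
        e, flags = weak_error(D, Y, Yhat)
        assert e == pytest.approx(0.25)
        assert np.array_equal(flags, [False, True, False, False])

    def test_no_flags_zero_error_and_all_flags_one(self):
        D = np.full(3, 1 / 3)
        Y = np.eye(3)
        e0, _ = weak_error(D, Y, Y + 0.1)
        assert e0 == 0.0
        e1, _ = weak_error(D, Y, 1.0 - Y)
        assert e1 == pytest.approx(1.0)

    @pytest.mark.parametrize("rule,expected", [
        ("max_abs", [True, False]),
        ("mean_abs", [False, False]),
        ("argmax", [False, False]),
    ])
    def test_flag_rules(self, rule, expected):
        # sample 0: one output off by 0.3 (max>0.2, mean 0.1, argmax correct)
        D = np.full(2, 0.5)
        Y = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        Yhat = np.array([[0.7, 0.0, 0.0], [0.0, 0.9, 0.05]])
        _, flags = weak_error(D, Y, Yhat, flag_rule=rule)
        assert list(flags) == expected


class TestVoteWeight:
    def test_half_gives_zero(self):
        assert vote_weight(0.5) == pytest.approx(0.0)

    def test_point_one_gives_half_ln_nine(self):
        assert vote_weight(0.1) == pytest.approx(0.5 * np.log(9.0))
        assert vote_weight(0.1) == pytest.approx(1.0986, abs=1e-4)

    def test_zero_clamped_to_large_finite(self):
        a = vote_weight(0.0)
        assert np.isfinite(a) and a > 10

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            vote_weight(-0.1)
        with pytest.raises(ValueError):
            vote_weight(1.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(e=st.floats(0.0, 1.0))
    def test_sign_matches_better_than_chance(self, e):
        a = vote_weight(e)
        assert (a > 0) == (e < 0.5)


class TestUpdateDistribution:
    def test_hand_example_four_samples(self):
        D = np.full(4, 0.25)
        flags = np.array([True, False, False, False])
        out = update_distribution(D, flags, k=1.1)
        assert np.allclose(out, [0.2683, 0.2439, 0.2439, 0.2439], atol=1e-4)

    def test_no_flags_unchanged(self):
        D = np.array([0.4, 0.6])
        assert np.allclose(update_distribution(D, np.zeros(2, bool)), D)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            update_distribution(np.array([]), np.array([], dtype=bool))

    def test_exponential_rule_hand_example(self):
        # a_t = 0.5*ln(9) makes the margin factors exactly 3 and 1/3
        from fermfuse.bp_adaboost import update_distribution_exp

        D = np.full(4, 0.25)
        flags = np.array([True, False, False, False])
        out = update_distribution_exp(D, flags, a_t=0.5 * np.log(9.0))
        assert np.allclose(out, [0.75, 1 / 12, 1 / 12, 1 / 12])
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        weights=st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20),
        data=st.data(),
    )
    def test_normalization_and_relative_bump(self, weights, data):
        D = np.asarray(weights) / np.sum(weights)
        flags = np.array(
            data.draw(st.lists(st.booleans(), min_size=len(D), max_size=len(D)))
        )
        out = update_distribution(D, flags, k=1.1)
        assert abs(out.sum() - 1.0) < 1e-12
        # flagged samples never lose weight relative to unflagged (k > 1)
        ratio = out / D
        if flags.any() and (~flags).any():
            assert ratio[flags].min() >= ratio[~flags].max() - 1e-12


class TestEnsemble:
    def _separable(self, m_per_class=10, n_classes=4, seed=0):
        rng = np.random.default_rng(seed)
        days = np.repeat(np.arange(n_classes), m_per_class)
        centers = 4.0 * rng.standard_normal((n_classes, 3))
        X = centers[days] + 0.2 * rng.standard_normal((len(days), 3))
        return X, days

    def test_distribution_conserved_every_round(self):
        X, days = self._separable()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strong = train_ensemble(X, days, seed=1)
        sums = strong.distribution_trace.sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) < 1e-12

    def test_t1_equals_its_single_weak_decision(self):
        X, days = self._separable(seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strong = train_ensemble(X, days, T=1, seed=3)
        labels, _ = predict(strong, X)
        weak_out = forward(strong.weaks[0], X)
        weak_labels = strong.classes[np.argmax(weak_out, axis=1)]
        assigned = labels != UNASSIGNED
        assert np.array_equal(labels[assigned], weak_labels[assigned])

    def test_training_rate_high_on_separable_data(self):
        X, days = self._separable(m_per_class=15, n_classes=7, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strong = train_ensemble(X, days, seed=5)
        labels, _ = predict(strong, X)
        assert np.mean(labels == days) >= 0.95

    def test_boosting_median_rate_non_decreasing(self):
        rng = np.random.default_rng(3)
        days = np.repeat(np.arange(7), 15)
        centers = rng.standard_normal((7, 5)) * 1.2
        X = centers[days] + 0.6 * rng.standard_normal((105, 5))
        rates = {1: [], 10: []}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(10):
                for T in (1, 10):
                    strong = train_ensemble(X, days, T=T, seed=s)
                    labels, _ = predict(strong, X)
                    rates[T].append(np.mean(labels == days))
        assert np.median(rates[10]) >= np.median(rates[1])

    def test_pure_function_of_data_config_seed(self):
        X, days = self._separable(seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = train_ensemble(X, days, seed=7)
            b = train_ensemble(X, days, seed=7)
        assert np.array_equal(a.votes, b.votes)
        assert np.array_equal(a.weaks[3].w1, b.weaks[3].w1)
        la, sa = predict(a, X)
        lb, sb = predict(b, X)
        assert np.array_equal(la, lb) and np.array_equal(sa, sb)

    def test_exponential_update_rule_trains_and_conserves_weights(self):
        X, days = self._separable(seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strong = train_ensemble(X, days, update_rule="exp", seed=9)
        sums = strong.distribution_trace.sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) < 1e-12
        labels, _ = predict(strong, X)
        assert np.mean(labels == days) >= 0.9

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            train_ensemble(X, np.zeros(5, dtype=int), seed=0)

    def test_all_flagged_round_warns_and_is_retained(self):
        # constant features with conflicting labels: every sample misfit
        X = np.zeros((10, 2))
        days = np.tile([0, 1], 5)
        with pytest.warns(RuntimeWarning):
            strong = train_ensemble(X, days, T=2, seed=0)
        assert len(strong.weaks) == 2


class TestPredict:
    def _one_hot_net(self, n=7, gain=40.0):
        """Network that relays a scaled one-hot input to its outputs."""
        w1 = gain * np.eye(n)
        b1 = -gain / 2 * np.ones(n)
        w2 = gain * np.eye(n)
        b2 = -gain / 2 * np.ones(n)
        return WeakPredictor(w1, b1, w2, b2)

    def test_single_net_argmax_and_score(self):
        net = self._one_hot_net()
        strong = StrongPredictor([net], np.array([1.0]), np.arange(7))
        x = np.zeros((1, 7))
        x[0, 2] = 1.0
        labels, scores = predict(strong, x)
        assert labels[0] == 2
        assert scores[0, 2] > 0.99

    def test_equal_vote_tie_is_unassigned(self):
        up = self._one_hot_net(2)
        down = WeakPredictor(up.w1, up.b1, -up.w2, up.b2 + 40.0)  # inverted vote
        strong = StrongPredictor([up, down], np.array([1.0, 1.0]), np.arange(2))
        x = np.array([[1.0, 0.0]])
        labels, scores = predict(strong, x)
        assert labels[0] == UNASSIGNED
        assert scores[0, 0] == pytest.approx(scores[0, 1], abs=1e-6)

    def test_scores_invariant_to_vote_rescaling(self):
        net = self._one_hot_net()
        x = np.zeros((3, 7))
        x[np.arange(3), [0, 4, 6]] = 1.0
        s1 = StrongPredictor([net, net], np.array([0.5, 1.5]), np.arange(7))
        s2 = StrongPredictor([net, net], np.array([5.0, 15.0]), np.arange(7))
        _, a = predict(s1, x)
        _, b = predict(s2, x)
        assert np.allclose(a, b)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            StrongPredictor([], np.array([]), np.arange(7))

    def test_serialization_roundtrip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(8)
        days = np.repeat(np.arange(3), 8)
        X = np.eye(3)[days] * 3 + 0.1 * rng.standard_normal((24, 3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strong = train_ensemble(X, days, seed=9)
        save_predictor(strong, tmp_path / "model.json")
        back = load_predictor(tmp_path / "model.json")
        la, sa = predict(strong, X)
        lb, sb = predict(back, X)
        assert np.array_equal(la, lb)
        assert np.allclose(sa, sb)
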