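"""Grad-CAM mechanics: alpha weights, heatmaps, grouping, group statistics."""

import numpy as np
import pandas as pd
import pytest

from residual_eegnet.architecture import ModelConfig, build_model
from residual_eegnet.attribution import (
    AttributionMap,
    ChannelScoreTable,
    FeatureMapStack,
    alpha_weights,
    cam_heatmap,
    capture_layer,
    channel_scores,
    gradcam_for_correct_trials,
    significance_vs_baseline,
)
from residual_eegnet.data_model import TaskLabel

TINY = ModelConfig(F1=2, D=2, F2=4, n_type1_blocks=2, n_type3_blocks=1,
                   temporal_kernel=8, separable_kernel=4)


def _stack(maps, grads, c=0):
    return FeatureMapStack(maps=np.asarray(maps, float),
                           grads=np.asarray(grads, float),
                           class_index=c, layer="test")


class TestAlphaWeights:
    def test_constant_gradients(self):
        stack = _stack(np.zeros((3, 4, 5)), np.ones((3, 4, 5)))
        np.testing.assert_allclose(alpha_weights(stack), [1, 1, 1])
        stack = _stack(np.zeros((3, 4, 5)), np.zeros((3, 4, 5)))
        np.testing.assert_allclose(alpha_weights(stack), 0)

    def test_matches_double_sum_over_z(self, rng):
        grads = rng.normal(size=(4, 6, 9))
        stack = _stack(np.zeros_like(grads), grads)
        brute = np.array([
            sum(grads[k, i, j] for i in range(6) for j in range(9)) / (6 * 9)
            for k in range(4)
        ])
        np.testing.assert_allclose(alpha_weights(stack), brute, atol=1e-12)
        assert stack.Z == 54


class TestHeatmap:
    def test_relu_kills_negative_combination(self):
        stack = _stack(-np.ones((1, 2, 3)), np.zeros((1, 2, 3)))
        amap = cam_heatmap(stack, np.array([1.0]))
        np.testing.assert_array_equal(amap.heatmap, 0)

    def test_small_worked_example(self):
        stack = _stack(np.array([[[1.0, -1.0]]]), np.zeros((1, 1, 2)))
        amap = cam_heatmap(stack, np.array([2.0]))
        np.testing.assert_array_equal(amap.heatmap, [[2.0, 0.0]])

    def test_matches_brute_force_weighted_sum(self, rng):
        maps = rng.normal(size=(5, 4, 7))
        alphas = rng.normal(size=5)
        amap = cam_heatmap(_stack(maps, np.zeros_like(maps)), alphas)
        brute = np.maximum(sum(alphas[k] * maps[k] for k in range(5)), 0.0)
        np.testing.assert_allclose(amap.heatmap, brute, atol=1e-12)
        assert (amap.heatmap >= 0).all()

    def test_prerelu_linearity_in_gradient_scale(self, rng):
        grads = rng.normal(size=(3, 4, 5))
        maps = rng.normal(size=(3, 4, 5))
        a1 = alpha_weights(_stack(maps, grads))
        a5 = alpha_weights(_stack(maps, 5.0 * grads))
        np.testing.assert_allclose(a5, 5.0 * a1, atol=1e-12)


class TestCaptureLayer:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        return build_model(TINY, seed=2, input_samples=96)

    def test_geometry_and_map_count(self, rng, tiny_model):
        x = rng.normal(size=(64, 96))
        stack = capture_layer(tiny_model, x, class_index=1, layer="conv2dtype1.2")
        assert stack.maps.shape == (2, 64, 96)  # K = F1
        assert stack.grads.shape == (2, 64, 96)

    def test_gradients_match_finite_differences(self, rng, tiny_model):
        x = rng.normal(size=(64, 96))
        layer = "conv2dtype1.2"
        # differentiate the log-softmax output: forward_from ends there,
        # giving the finite-difference oracle the same scalar
        stack = capture_layer(tiny_model, x, class_index=0, layer=layer,
                              score="log_softmax")
        a = tiny_model.captured_activation(layer)
        eps = 1e-3
        for idx in [(0, 0, 3, 10), (0, 1, 50, 80)]:
            ap = a.copy(); ap[idx] += eps
            am = a.copy(); am[idx] -= eps
            fp = tiny_model.forward_from(layer, ap)[0, 0]
            fm = tiny_model.forward_from(layer, am)[0, 0]
            num = (fp - fm) / (2 * eps)
            ana = stack.grads[idx[1:]]
            assert abs(num - ana) <= 1e-3 * max(abs(num), 1e-6) + 1e-9

    def test_logit_and_logsoftmax_scores_differ_but_correlate(self, rng, tiny_model):
        x = rng.normal(size=(64, 96))
        s1 = capture_layer(tiny_model, x, 0, "conv2dtype1.2", score="log_softmax")
        s2 = capture_layer(tiny_model, x, 0, "conv2dtype1.2", score="logit")
        assert not np.allclose(s1.grads, s2.grads)

    def test_unknown_layer_rejected(self, rng, tiny_model):
        with pytest.raises(KeyError):
            capture_layer(tiny_model, rng.normal(size=(64, 96)), 0, "nope")


class TestGrouping:
    def test_correct_trial_filter_contract(self, small_planted_dataset):
        """An untrained model still produces maps only for trials it happens
        to classify correctly, grouped by participant and task."""
        model = build_model(TINY, seed=4, input_samples=720, dtype=np.float32)
        groups = gradcam_for_correct_trials(model, small_planted_dataset.epochs,
                                            layer="conv2dtype1.2")
        from residual_eegnet.evaluation import predict
        from residual_eegnet.training import prepare_arrays
        x, y, subj = prepare_arrays(small_planted_dataset.epochs, dtype=np.float32)
        preds, _ = predict(model, x)
        n_correct = int((preds == y).sum())
        assert sum(len(v) for v in groups.values()) == n_correct
        for (s, task), maps in groups.items():
            for m in maps:
                assert m.subject_id == s
                assert m.class_index == int(task)
                assert (m.heatmap >= 0).all()


class TestChannelScores:
    def test_uniform_map_gives_uniform_scores_and_baseline(self):
        amap = AttributionMap(heatmap=np.full((64, 10), 3.0), class_index=0,
                              subject_id=1, layer="l")
        table = channel_scores({(1, TaskLabel.REST): [amap]})
        row = table.scores[TaskLabel.REST].loc[1]
        np.testing.assert_allclose(row, 3.0)
        assert table.baseline(TaskLabel.REST)[1] == pytest.approx(3.0)

    def test_single_hot_channel(self):
        h = np.zeros((64, 10))
        h[8] = np.arange(10)
        amap = AttributionMap(heatmap=h, class_index=1, subject_id=2, layer="l")
        table = channel_scores({(2, TaskLabel.LEFT): [amap]})
        row = table.scores[TaskLabel.LEFT].loc[2]
        assert row[8] == pytest.approx(np.arange(10).mean())
        assert table.baseline(TaskLabel.LEFT)[2] == pytest.approx(row[8] / 64)

    def test_matches_brute_force_nested_means(self, rng):
        maps = {(s, TaskLabel.RIGHT): [
            AttributionMap(heatmap=np.abs(rng.normal(size=(64, 12))),
                           class_index=2, subject_id=s, layer="l")
            for _ in range(3)] for s in (1, 2)}
        table = channel_scores(maps)
        for s in (1, 2):
            stackmean = np.mean([m.heatmap for m in maps[(s, TaskLabel.RIGHT)]],
                                axis=0)
            np.testing.assert_allclose(table.scores[TaskLabel.RIGHT].loc[s],
                                       stackmean.mean(axis=1), atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            channel_scores({})


class TestSignificance:
    def _table_from_scores(self, scores):
        t = ChannelScoreTable()
        t.scores[TaskLabel.REST] = pd.DataFrame(
            scores, columns=pd.RangeIndex(scores.shape[1], name="channel"))
        return t

    def test_flat_scores_yield_no_significance(self, rng):
        scores = np.tile(rng.normal(size=(6, 1)), (1, 64))  # every channel = baseline
        res = significance_vs_baseline(self._table_from_scores(scores))
        assert not res[TaskLabel.REST]["rejected"].any()
        assert len(res[TaskLabel.REST]) == 64  # per-task family size

    def test_strongly_elevated_channel_is_flagged(self, rng):
        scores = np.abs(rng.normal(size=(8, 64))) * 0.01
        scores[:, 8] += 5.0
        res = significance_vs_baseline(self._table_from_scores(scores))
        df = res[TaskLabel.REST]
        assert bool(df.loc[8, "rejected"]) and df.loc[8, "t"] > 0

    def test_single_participant_rejected(self, rng):
        with pytest.raises(ValueError):
            significance_vs_baseline(self._table_from_scores(rng.normal(size=(1, 64))))

    def test_timepoint_axis_family_and_baseline(self, rng):
        t = ChannelScoreTable()
        maps = {s: np.abs(rng.normal(size=(8, 6))) for s in range(5)}
        t.mean_maps[TaskLabel.LEFT] = maps
        t.scores[TaskLabel.LEFT] = pd.DataFrame(
            {c: [maps[s][c].mean() for s in range(5)] for c in range(8)})
        res = significance_vs_baseline(t, axis="timepoint")[TaskLabel.LEFT]
        assert len(res) == 8 * 6
        # t statistics match a direct per-cell Welch computation
        from residual_eegnet.evaluation import welch_t_test
        S = np.stack([maps[s] for s in range(5)])
        B = S.mean(axis=1)
        cell = res[(res["channel"] == 3) & (res["time"] == 2)].iloc[0]
        ref = welch_t_test(S[:, 3, 2], B[:, 2])
        assert cell["t"] == pytest.approx(ref.t, abs=1e-9)
        assert cell["p"] == pytest.approx(ref.p, abs=1e-9)
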