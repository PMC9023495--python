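import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compressnet.distill import TransferConfig
from compressnet.imaging import AugmentationConfig
from compressnet.network import build_network, copy_model, forward, parameter_count
from compressnet.prune import (
    CutConfig, FilterScoreTable, PruneError, compress, cut_counts,
    reference_layer, remove_filters, replay_cut_history, retrain_layer,
    score_filters, select_filters,
)
from compressnet.training import TrainConfig

from conftest import plain_conv_spec
from oracles import brute_force_filter_scores, model_to_layer_params


def make_plain_model(seed=0, widths=(5, 6, 4), has_norm=True, input_size=8):
    spec = plain_conv_spec(widths=widths, has_norm=has_norm, input_size=input_size)
    m = build_network(spec, seed=seed, dtype=np.float64)
    # non-trivial running stats so evaluation mode is exercised for real
    rng = np.random.default_rng(seed + 100)
    for p in m.params:
        if "running_mean" in p:
            p["running_mean"] = rng.normal(0, 0.3, p["running_mean"].shape)
            p["running_var"] = rng.uniform(0.5, 2.0, p["running_var"].shape)
    return m


class TestCutCounts:
    def test_examples(self):
        assert cut_counts(8, 0.5) == (4, 4)
        assert cut_counts(7, 0.5) == (4, 3)   # ceil(3.5) removed
        assert cut_counts(10, 0.3) == (3, 7)  # float artifact guard

    def test_float_artifacts(self):
        for c in range(1, 65):
            for a in [0.1 * i for i in range(1, 10)]:
                removed, reserved = cut_counts(c, a)
                assert removed + reserved == c
                assert removed >= 1


class TestSelectFilters:
    def test_ranked_example(self):
        t = FilterScoreTable(0, {i: s for i, s in enumerate([9, 1, 8, 2, 7, 3, 6, 4])})
        assert select_filters(t, 0.5) == (1, 3, 5, 7)

    def test_ceiling_example(self):
        t = FilterScoreTable(0, {i: float(i) for i in range(7)})
        sel = select_filters(t, 0.5)
        assert len(sel) == 4
        assert sel == (0, 1, 2, 3)

    def test_tie_break_ascending_index(self):
        t = FilterScoreTable(0, {i: 1.0 for i in range(4)})
        assert select_filters(t, 0.5) == (0, 1)

    def test_insertion_order_irrelevant(self):
        scores = {0: 3.0, 1: 1.0, 2: 2.0, 3: 0.5}
        a = select_filters(FilterScoreTable(0, dict(scores)), 0.5)
        b = select_filters(FilterScoreTable(0, dict(reversed(list(scores.items())))), 0.5)
        assert a == b == (1, 3)

    def test_refuses_removing_everything(self):
        t = FilterScoreTable(0, {0: 1.0})
        with pytest.raises(PruneError):
            select_filters(t, 0.5)

    def test_alpha_zero_selects_nothing(self):
        t = FilterScoreTable(0, {0: 1.0, 1: 2.0})
        assert select_filters(t, 0.0) == ()

    @given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False),
                    min_size=2, max_size=32),
           st.floats(min_value=0.05, max_value=0.9))
    @settings(max_examples=60, deadline=None)
    def test_selection_is_pure_and_sized(self, values, alpha):
        scores = {i: v for i, v in enumerate(values)}
        table = FilterScoreTable(0, scores)
        n_cut, n_keep = cut_counts(len(values), alpha)
        if n_keep == 0:
            with pytest.raises(PruneError):
                select_filters(table, alpha)
            return
        sel = select_filters(table, alpha)
        assert len(sel) == n_cut
        perm = np.random.default_rng(0).permutation(len(values))
        shuffled = FilterScoreTable(0, {int(i): scores[int(i)] for i in perm})
        assert select_filters(shuffled, alpha) == sel


class TestScoreFilters:
    def test_matches_brute_force_oracle(self, rng):
        m = make_plain_model(seed=3, widths=(6, 5, 4))
        images = [rng.normal(size=(3, 8, 8)) for _ in range(8)]
        batch = np.stack(images)
        for t in (0, 1):
            got = score_filters(m, t, batch)
            want = brute_force_filter_scores(model_to_layer_params(m, 3), images, t)
            for i in want:
                rel = abs(got.scores[i] - want[i]) / max(1e-12, abs(want[i]))
                assert rel < 1e-5

    def test_zeroed_filter_scores_zero(self, rng):
        m = make_plain_model(seed=1)
        m.params[0]["W"][2] = 0.0
        m.params[0]["beta"][2] = 0.0
        m.params[0]["running_mean"][2] = 0.0
        got = score_filters(m, 0, np.stack([rng.normal(size=(3, 8, 8))
                                            for _ in range(4)]))
        assert got.scores[2] == 0.0
        assert any(v > 0 for i, v in got.scores.items() if i != 2)

    def test_duplicate_filters_equal_scores(self, rng):
        m = make_plain_model(seed=2)
        for key in ("W", "gamma", "beta", "running_mean", "running_var"):
            m.params[0][key][1] = m.params[0][key][3]
        m.params[1]["W"][:, 1] = m.params[1]["W"][:, 3]
        got = score_filters(m, 0, np.stack([rng.normal(size=(3, 8, 8))
                                            for _ in range(4)]))
        assert got.scores[1] == pytest.approx(got.scores[3], rel=1e-9)

    def test_scores_nonnegative(self, micro_student, rng):
        batch = rng.uniform(0, 1, (4, 3, 16, 16)).astype(np.float32)
        for t in micro_student.spec.prunable_layers():
            got = score_filters(micro_student, t, batch)
            assert all(v >= 0 for v in got.scores.values())
            assert len(got.scores) == micro_student.spec.layers[t].out_filters

    def test_last_layer_has_no_reference(self):
        spec = plain_conv_spec(widths=(4, 4), prunable_mask=[True, True])
        m = build_network(spec, seed=0)
        with pytest.raises(PruneError, match="reference"):
            reference_layer(spec, 1)

    def test_empty_subset_rejected(self, micro_student):
        with pytest.raises(PruneError):
            score_filters(micro_student, 1, np.zeros((0, 3, 16, 16)))


class TestRemoveFilters:
    def test_shape_arithmetic(self):
        spec = plain_conv_spec(widths=(4, 6), input_size=8)
        m = build_network(spec, seed=0)
        cut = remove_filters(m, 0, [1, 3])
        assert cut.params[0]["W"].shape == (2, 3, 3, 3)
        assert cut.params[1]["W"].shape == (6, 2, 3, 3)
        assert cut.spec.layers[0].out_filters == 2
        assert cut.cut_history == [(0, [1, 3])]

    def test_empty_removal_identity(self, micro_student):
        same = remove_filters(micro_student, 1, [])
        for pa, pb in zip(micro_student.params, same.params):
            for k in pa:
                np.testing.assert_array_equal(pa[k], pb[k])
        assert same.cut_history == micro_student.cut_history

    def test_out_of_range(self, micro_student):
        with pytest.raises(PruneError):
            remove_filters(micro_student, 1, [99])

    def test_zero_mask_equivalence_plain(self, rng):
        m = make_plain_model(seed=5, widths=(6, 5, 4))
        idx = [0, 4]
        cut = remove_filters(m, 0, idx)
        for _ in range(5):
            x = rng.normal(size=(2, 3, 8, 8))
            a = forward(cut, x).logits
            b = forward(m, x, mask_channels={0: idx}).logits
            np.testing.assert_allclose(a, b, atol=1e-5)

    def test_zero_mask_equivalence_depthwise_coupled(self, micro_student_spec, rng):
        m = build_network(micro_student_spec, seed=7, dtype=np.float64)
        r = np.random.default_rng(3)
        for p in m.params:
            if "running_mean" in p:
                p["running_mean"] = r.normal(0, 0.3, p["running_mean"].shape)
                p["running_var"] = r.uniform(0.5, 2.0, p["running_var"].shape)
        t = 1  # expansion conv; coupled depthwise is layer 2
        idx = [1, 4]
        cut = remove_filters(m, t, idx)
        assert cut.params[2]["W"].shape[0] == m.params[2]["W"].shape[0] - 2
        x = rng.uniform(0, 1, (3, 3, 16, 16))
        a = forward(cut, x).logits
        b = forward(m, x, mask_channels={1: idx, 2: idx}).logits
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_replay_reproduces_shapes(self, micro_student):
        m = remove_filters(micro_student, 4, [0, 2])
        m = remove_filters(m, 1, [5])
        spec = replay_cut_history(m.base_spec, m.cut_history)
        assert [l.out_filters for l in spec.layers] == \
            [l.out_filters for l in m.spec.layers]
        m.validate_shapes()


class TestRetrainAndCompress:
    def test_retrain_zero_iterations_returns_unchanged(self, micro_student,
                                                       micro_dataset, micro_aug):
        cfg = CutConfig(alpha=0.5, subset_size=4, retrain=TransferConfig(
            lambda_=1.0, train=TrainConfig(lr_schedule=((0.001, 0),))))
        teacher = copy_model(micro_student)
        out, trace = retrain_layer(micro_student, teacher, micro_dataset,
                                   micro_aug, cfg)
        assert out is micro_student
        assert trace == []

    def test_compress_bookkeeping(self, micro_student_spec, micro_dataset, micro_aug):
        student = build_network(micro_student_spec, seed=0)
        teacher = build_network(micro_student_spec, seed=1)
        cfg = CutConfig(alpha=0.5, subset_size=6, subset_seed=0,
                        retrain=TransferConfig(lambda_=1.0, train=TrainConfig(
                            lr_schedule=((0.001, 4),), batch_size=8)))
        before = {t: micro_student_spec.layers[t].out_filters
                  for t in micro_student_spec.prunable_layers()}
        out, report = compress(student, teacher, micro_dataset, micro_aug, cfg)
        assert [t for t, _ in out.cut_history] == sorted(before, reverse=True)
        for t, c in before.items():
            assert out.spec.layers[t].out_filters == c // 2
        assert report.prunable_params_after < report.prunable_params_before
        assert len(report.layers) == len(before)

    def test_compress_alpha_zero_is_identity(self, micro_student_spec,
                                             micro_dataset, micro_aug):
        student = build_network(micro_student_spec, seed=3)
        teacher = build_network(micro_student_spec, seed=4)
        cfg = CutConfig(alpha=0.0, subset_size=4, retrain=TransferConfig(
            lambda_=1.0, train=TrainConfig(lr_schedule=((0.001, 0),))))
        holdout = micro_dataset
        out, report = compress(student, teacher, micro_dataset, micro_aug, cfg,
                               holdout=holdout)
        for pa, pb in zip(student.params, out.params):
            for k in pa:
                np.testing.assert_array_equal(pa[k], pb[k])
        accs = [h["top1"] for h in report.holdout_accuracy]
        assert all(a == accs[0] for a in accs)

    def test_invalid_config(self):
        with pytest.raises(PruneError):
            CutConfig(alpha=1.0)
        with pytest.raises(PruneError):
            CutConfig(subset_size=0)
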