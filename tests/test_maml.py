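"""MAML inner/outer loops, fine-tuning, and the direct-learning baseline."""

import numpy as np
import pytest

from metasurv.maml import (
    MetaConfig,
    TaskData,
    TaskSplit,
    _flat,
    direct_learning_baseline,
    finetune_evaluate,
    inner_adapt,
    meta_train,
    pooled_folds,
    task_meta_gradient,
)
from metasurv.network import RiskNetwork, cox_loss, cox_param_grad

from conftest import random_net


def make_task(seed, n_support=60, n_query=30, p=8, beta=None, censor_q=0.8):
    rng = np.random.default_rng(seed)
    if beta is None:
        beta = np.zeros(p)
        beta[:3] = [1.5, -1.5, 1.0]
    n = n_support + n_query
    X = rng.normal(size=(n, p))
    T = rng.exponential(scale=np.exp(-(X @ beta)))
    C = rng.uniform(0, np.quantile(T, censor_q), size=n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return TaskData(
        name=f"task{seed}",
        X_support=X[:n_support],
        time_support=time[:n_support],
        event_support=event[:n_support],
        X_query=X[n_support:],
        time_query=time[n_support:],
        event_query=event[n_support:],
    )


class TestTaskSplit:
    def test_overlapping_support_query_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TaskSplit("t", ["a", "b"], ["b", "c"])


class TestInnerAdapt:
    def test_zero_learning_rate_is_identity(self):
        task = make_task(0)
        net = random_net(8, seed=1)
        cfg = MetaConfig(inner_lr=0.0)
        out = inner_adapt(net, task.X_support, task.time_support, task.event_support, cfg)
        np.testing.assert_array_equal(_flat(out.params), _flat(net.params))

    def test_single_step_equals_theta_minus_alpha_grad(self):
        task = make_task(1)
        net = random_net(8, seed=2)
        cfg = MetaConfig(inner_lr=0.05, inner_steps=1)
        _, grads = cox_param_grad(net, task.X_support, task.time_support, task.event_support)
        expected = [
            (W - 0.05 * gW, b - 0.05 * gb)
            for (W, b), (gW, gb) in zip(net.params, grads)
        ]
        out = inner_adapt(net, task.X_support, task.time_support, task.event_support, cfg)
        for (W, b), (eW, eb) in zip(out.params, expected):
            np.testing.assert_allclose(W, eW, atol=1e-12)
            np.testing.assert_allclose(b, eb, atol=1e-12)

    def test_one_parameter_toy_matches_hand_gradient(self):
        # linear net eta = w*x; two patients, times (1, 2), both events:
        # L(w) = -1/2 [ w x1 - log(e^{w x1} + e^{w x2}) ]
        # dL/dw = -1/2 [ x1 - (x1 e^{w x1} + x2 e^{w x2})/(e^{w x1} + e^{w x2}) ]
        w0, x1, x2, alpha = 0.4, 1.0, -2.0, 0.1
        net = RiskNetwork([(np.array([[w0]]), np.array([0.0]))])
        cfg = MetaConfig(inner_lr=alpha, inner_steps=1)
        out = inner_adapt(
            net, np.array([[x1], [x2]]), np.array([1.0, 2.0]), np.array([1, 1]), cfg
        )
        e1, e2 = np.exp(w0 * x1), np.exp(w0 * x2)
        # second event's risk set is itself only, contributing zero gradient
        dL = -0.5 * (x1 - (x1 * e1 + x2 * e2) / (e1 + e2))
        assert out.params[0][0][0, 0] == pytest.approx(w0 - alpha * dL, abs=1e-12)

    def test_two_half_steps_approximate_one_full_step(self):
        task = make_task(3)
        net = random_net(8, seed=4)
        alpha = 1e-4  # locally linear gradient field
        one = inner_adapt(
            net, task.X_support, task.time_support, task.event_support,
            MetaConfig(inner_lr=alpha, inner_steps=1),
        )
        two = inner_adapt(
            net, task.X_support, task.time_support, task.event_support,
            MetaConfig(inner_lr=alpha / 2, inner_steps=2),
        )
        np.testing.assert_allclose(_flat(one.params), _flat(two.params), atol=1e-6)

    def test_does_not_mutate_input_network(self):
        task = make_task(5)
        net = random_net(8, seed=6)
        before = _flat(net.params).copy()
        inner_adapt(
            net, task.X_support, task.time_support, task.event_support,
            MetaConfig(inner_lr=0.1, inner_steps=3),
        )
        np.testing.assert_array_equal(_flat(net.params), before)

    def test_no_events_leaves_parameters_unchanged(self):
        task = make_task(7)
        net = random_net(8, seed=8)
        with pytest.warns(UserWarning, match="no observed events"):
            out = inner_adapt(
                net, task.X_support, task.time_support,
                np.zeros_like(task.event_support), MetaConfig(),
            )
        np.testing.assert_array_equal(_flat(out.params), _flat(net.params))


class TestMetaGradient:
    def test_zero_inner_steps_reduces_to_query_gradient(self):
        task = make_task(9)
        net = random_net(8, seed=10)
        cfg = MetaConfig(inner_steps=0)
        q_loss, g = task_meta_gradient(net, task, cfg)
        expected_loss, expected_g = cox_param_grad(
            net, task.X_query, task.time_query, task.event_query
        )
        assert q_loss == pytest.approx(expected_loss)
        np.testing.assert_allclose(_flat(g), _flat(expected_g), atol=1e-12)

    def test_first_and_second_order_agree_as_alpha_vanishes(self):
        task = make_task(11)
        net = random_net(8, seed=12)
        diffs = []
        for alpha in (1e-2, 1e-6):
            _, g_so = task_meta_gradient(net, task, MetaConfig(inner_lr=alpha))
            _, g_fo = task_meta_gradient(
                net, task, MetaConfig(inner_lr=alpha, first_order=True)
            )
            diffs.append(np.linalg.norm(_flat(g_so) - _flat(g_fo)))
        # the curvature term scales linearly in alpha: 4 orders smaller alpha
        # must shrink the gap by at least 3 orders, into the 1e-4 range
        assert diffs[1] < 1e-3 * max(diffs[0], 1e-12)
        assert diffs[1] < 1e-4

    def test_meta_gradient_matches_finite_differences(self):
        """Full second-order check: d/dtheta of the post-adaptation query
        loss, against central finite differences through the inner loop."""
        task = make_task(13, n_support=25, n_query=15, p=3)
        net = random_net(3, hidden=(4, 3, 2), seed=14, bias_scale=0.3)
        cfg = MetaConfig(inner_lr=0.05, inner_steps=1)

        def query_loss_after_adaptation(n):
            adapted = inner_adapt(
                n, task.X_support, task.time_support, task.event_support, cfg
            )
            return cox_loss(
                adapted.forward(task.X_query), task.time_query, task.event_query
            )

        _, g = task_meta_gradient(net, task, cfg)
        h = 1e-5
        for li, (W, b) in enumerate(net.params):
            for arr, ga in ((W, g[li][0]), (b, g[li][1])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    old = arr[idx]
                    arr[idx] = old + h
                    lp = query_loss_after_adaptation(net)
                    arr[idx] = old - h
                    lm = query_loss_after_adaptation(net)
                    arr[idx] = old
                    fd = (lp - lm) / (2 * h)
                    assert abs(fd - ga[idx]) < 5e-4 * max(1.0, abs(fd))


class TestMetaTrain:
    def test_same_seed_identical_parameters(self):
        tasks = [make_task(s) for s in range(3)]
        cfg = MetaConfig(meta_iterations=10, seed=5)
        net = random_net(8, seed=5)
        a = meta_train(net, tasks, cfg).network
        b = meta_train(net, tasks, cfg).network
        assert hash(_flat(a.params).tobytes()) == hash(_flat(b.params).tobytes())

    def test_identical_tasks_improve_over_random_init(self):
        # paired over 5 seeds: meta-trained initialisation achieves lower
        # query loss than the random initialisation on the same task
        wins = 0
        for seed in range(5):
            task = make_task(100 + seed)
            net = random_net(8, seed=seed)
            cfg = MetaConfig(meta_iterations=60, outer_lr=0.005, seed=seed)
            trained = meta_train(net, [task], cfg).network
            loss0 = cox_loss(net.forward(task.X_query), task.time_query, task.event_query)
            loss1 = cox_loss(trained.forward(task.X_query), task.time_query, task.event_query)
            wins += loss1 < loss0
        assert wins >= 4

    def test_empty_task_list_rejected(self):
        with pytest.raises(ValueError, match="source task"):
            meta_train(random_net(8), [], MetaConfig())

    def test_loss_trace_recorded_per_iteration(self):
        tasks = [make_task(s) for s in range(2)]
        res = meta_train(random_net(8), tasks, MetaConfig(meta_iterations=7))
        assert len(res.loss_trace) == 7
        assert set(res.per_task_trace[0]) == {t.name for t in tasks}


class TestFinetuneEvaluate:
    def test_zero_steps_evaluates_raw_initialization(self):
        task = make_task(20)
        net = random_net(8, seed=21)
        _, eta0, _ = finetune_evaluate(net, task, MetaConfig(), steps=0, compute_brier=False)
        np.testing.assert_allclose(eta0, net.forward(task.X_query))

    def test_finetuning_improves_over_no_adaptation(self):
        # paired over 20 seeds on tasks sharing the generative signal
        deltas = []
        for seed in range(20):
            task = make_task(200 + seed)
            net = random_net(8, seed=22)
            cfg = MetaConfig(inner_lr=0.05, finetune_steps=25)
            _, _, res0 = finetune_evaluate(net, task, cfg, steps=0, compute_brier=False)
            _, _, res1 = finetune_evaluate(net, task, cfg, compute_brier=False)
            deltas.append(res1.c_index - res0.c_index)
        assert np.mean(deltas) > 0

    def test_brier_score_computed_from_support_baseline(self):
        task = make_task(23)
        net = random_net(8, seed=24)
        _, _, res = finetune_evaluate(net, task, MetaConfig())
        assert res.integrated_brier is not None
        assert 0 <= res.integrated_brier <= 1


class TestDirectBaseline:
    def test_fold_partition_covers_all_samples_once(self):
        fold_of = pooled_folds(103, folds=5, seed=1)
        counts = np.bincount(fold_of, minlength=5)
        assert counts.sum() == 103
        assert counts.max() - counts.min() <= 1

    def test_baseline_returns_metrics_per_target(self):
        sources = [make_task(s) for s in range(3)]
        targets = [make_task(30), make_task(31)]
        res = direct_learning_baseline(sources, targets, max_epochs=40, seed=0)
        assert set(res) == {"task30", "task31"}
        for r in res.values():
            assert 0 <= r.c_index <= 1
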