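import dataclasses

import numpy as np
import pytest

from conftest import make_probe_task
from fsdta.base_learner import BaseLearner, LearnerConfig, ProbeRecord
from fsdta.meta_engine import (MetaTrainConfig, NoiseConfig, finetune_and_predict,
                               inject_label_noise, inner_adapt, meta_train,
                               outer_update, task_meta_grad, validation_loss)
from fsdta.tasks import Task, TaskSplit, split_random


class TestInjectLabelNoise:
    def test_sigma_zero_is_identity(self):
        recs = [ProbeRecord(1.0, 5.0), ProbeRecord(2.0, 7.0)]
        out = inject_label_noise(recs, NoiseConfig(sigma=0.0), np.random.default_rng(0))
        assert [r.affinity for r in out] == [5.0, 7.0]

    def test_bounded_perturbations(self):
        recs = [ProbeRecord(1.0, 5.0)] * 1000
        sigma = 0.3
        out = inject_label_noise(recs, NoiseConfig(sigma=sigma), np.random.default_rng(1))
        eps = np.array([r.affinity - 5.0 for r in out])
        assert np.all(np.abs(eps) <= sigma)

    def test_copy_semantics(self):
        recs = [ProbeRecord(1.0, 5.0)]
        inject_label_noise(recs, NoiseConfig(sigma=1.0), np.random.default_rng(2))
        assert recs[0].affinity == 5.0

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig(sigma=-0.1)


class TestInnerAdapt:
    def test_zero_steps_identity(self, probe):
        theta = np.array([1.3])
        out = inner_adapt(probe, theta, [ProbeRecord(1.0, 2.0)], alpha=0.1, n_steps=0)
        assert np.array_equal(out, theta)

    def test_zero_gradient_fixed_point(self, probe):
        out = inner_adapt(probe, np.array([2.0]),
                          [ProbeRecord(1.0, 2.0)], alpha=0.1, n_steps=7)
        assert out[0] == pytest.approx(2.0)

    def test_worked_single_step(self, probe):
        """theta0=0, support {(x=1, y=2)}, alpha=0.1: grad = 2(0-2) = -4 -> 0.4."""
        out = inner_adapt(probe, np.array([0.0]), [ProbeRecord(1.0, 2.0)],
                          alpha=0.1, n_steps=1)
        assert out[0] == pytest.approx(0.4, abs=1e-12)

    def test_empty_support_raises(self, probe):
        with pytest.raises(ValueError):
            inner_adapt(probe, np.array([0.0]), [], alpha=0.1, n_steps=1)

    def test_does_not_mutate_theta0(self, probe):
        theta = np.array([0.0])
        inner_adapt(probe, theta, [ProbeRecord(1.0, 2.0)], alpha=0.1, n_steps=3)
        assert theta[0] == 0.0


class TestOuterUpdate:
    def _probe_task(self, s, q):
        recs = tuple(ProbeRecord(x, y) for x, y in s + q)
        return Task("p", recs, tuple(range(len(s))), tuple(range(len(s), len(s) + len(q))))

    def test_zero_query_gradients_leave_theta_unchanged(self, probe):
        # theta=2 interpolates everything: query gradient vanishes
        task = self._probe_task([(1.0, 2.0)], [(3.0, 6.0)])
        out = outer_update(probe, np.array([2.0]), [task], alpha=0.1, beta=0.5, n_steps=1)
        assert out[0] == pytest.approx(2.0)

    def test_no_inner_steps_reduces_to_plain_gradient_step(self, probe):
        task = self._probe_task([(1.0, 2.0)], [(2.0, 3.0)])
        theta0 = np.array([0.5])
        for mode in ("first_order", "second_order"):
            out = outer_update(probe, theta0, [task], alpha=0.1, beta=0.2,
                               n_steps=0, mode=mode)
            # plain step on the query loss: grad = 2(0.5*2 - 3)*2 = -8
            expected = 0.5 - 0.2 * 2 * (0.5 * 2 - 3.0) * 2.0
            assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_second_order_matches_analytic_chain_rule(self, probe):
        """One inner step on the scalar model: d/dtheta0 L_Q(theta1)
        = (1 - alpha * 2 x_s^2) * 2 (theta1 x_q - y_q) x_q."""
        xs, ys, xq, yq, alpha, th0 = 1.0, 2.0, 2.0, 1.0, 0.1, 0.5
        sb = probe.make_batch([ProbeRecord(xs, ys)])
        qb = probe.make_batch([ProbeRecord(xq, yq)])
        mg = task_meta_grad(probe, np.array([th0]), sb, qb, alpha, 1, "second_order")
        th1 = th0 - alpha * 2 * (th0 * xs - ys) * xs
        analytic = (1 - alpha * 2 * xs**2) * 2 * (th1 * xq - yq) * xq
        assert mg[0] == pytest.approx(analytic, rel=1e-9)

    def test_empty_query_raises(self, probe):
        task = Task("p", (ProbeRecord(1.0, 2.0),), (0,), ())
        with pytest.raises(ValueError):
            outer_update(probe, np.array([0.0]), [task], alpha=0.1, beta=0.1, n_steps=1)


@pytest.fixture(scope="module")
def tiny_split(tiny_family):
    usable = [t for t in tiny_family.tasks if t.n_records >= 8]
    return split_random(usable, ratio=(6, 1, 1), seed=0)


@pytest.fixture(scope="module")
def tiny_train_cfg():
    return MetaTrainConfig(epochs=1, updates_per_epoch=2, batch_candidates=3,
                           n_select=2, support_size=4, mode="first_order",
                           val_batch=1, adapter_lr=1.0)


class TestMetaTrain:
    def test_history_length_equals_schedule(self, tiny_learner, tiny_split, tiny_train_cfg):
        cfg = dataclasses.replace(tiny_train_cfg, epochs=2, updates_per_epoch=3)
        state = meta_train(tiny_learner, tiny_split, cfg, NoiseConfig(0.1), seed=4)
        assert state.k == 6
        assert len(state.history) == 6
        assert len(state.val_curve) == 2

    def test_same_seed_bit_identical(self, tiny_learner, tiny_split, tiny_train_cfg):
        a = meta_train(tiny_learner, tiny_split, tiny_train_cfg, NoiseConfig(0.1), seed=9)
        b = meta_train(tiny_learner, tiny_split, tiny_train_cfg, NoiseConfig(0.1), seed=9)
        assert a.history == b.history
        assert np.array_equal(a.theta0, b.theta0)

    def test_candidate_pool_clipped_with_warning(self, tiny_learner, tiny_split, tiny_train_cfg, caplog):
        cfg = dataclasses.replace(tiny_train_cfg, batch_candidates=50)
        with caplog.at_level("WARNING"):
            state = meta_train(tiny_learner, tiny_split, cfg, NoiseConfig(0.0), seed=1)
        assert "clipped" in caplog.text
        assert len(state.history[0]["candidates"]) == len(tiny_split.train)

    def test_best_checkpoint_tracks_minimum(self, tiny_learner, tiny_split, tiny_train_cfg):
        cfg = dataclasses.replace(tiny_train_cfg, epochs=3, updates_per_epoch=1)
        state = meta_train(tiny_learner, tiny_split, cfg, NoiseConfig(0.1), seed=2)
        assert state.best_val_loss == pytest.approx(min(state.val_curve))

    def test_requires_validation_tasks(self, tiny_learner, tiny_split, tiny_train_cfg):
        bad = TaskSplit(tiny_split.train, (), tiny_split.test,
                        tiny_split.strategy, tiny_split.seed)
        with pytest.raises(ValueError):
            meta_train(tiny_learner, bad, tiny_train_cfg, NoiseConfig(0.0), seed=0)


class TestFinetuneAndPredict:
    def test_zero_steps_gives_zero_shot_outputs(self, tiny_learner, tiny_split):
        task = tiny_split.test[0]
        from fsdta.tasks import sample_support_query

        ep = sample_support_query(task, 4, 0)
        th = tiny_learner.init_flat(0)
        preds, _ = finetune_and_predict(tiny_learner, th, ep, n_steps=0)
        assert np.allclose(preds, tiny_learner.predict(th, ep.query))

    def test_support_loss_decreases_on_probe(self, probe):
        task = make_probe_task(3, n=10)
        th0 = np.array([0.0])
        th = inner_adapt(probe, th0, task.support, alpha=0.05, n_steps=5)
        assert probe.loss(th, task.support) <= probe.loss(th0, task.support)

    def test_report_contains_regression_metrics(self, tiny_learner, tiny_split):
        from fsdta.tasks import sample_support_query

        ep = sample_support_query(tiny_split.test[0], 4, 1)
        _, report = finetune_and_predict(tiny_learner, tiny_learner.init_flat(1), ep)
        assert report.mse >= 0
        assert report.ci is None or 0 <= report.ci <= 1


def test_validation_loss_is_mean_over_tasks(probe):
    tasks = [make_probe_task(s, n=8, name=f"v{s}") for s in range(3)]
    theta = np.array([0.3])
    per_task = []
    for t in tasks:
        th = inner_adapt(probe, theta, t.support, alpha=0.05, n_steps=2)
        per_task.append(probe.loss(th, t.query))
    assert validation_loss(probe, theta, tasks, 0.05, 2) == pytest.approx(np.mean(per_task))
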