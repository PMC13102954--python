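import numpy as np
import pytest

from conftest import make_probe_task
from fsdta.adaptive_sampler import (Adapter, TaskStats, adapter_scores,
                                    adapter_validation_loss, sample_tasks,
                                    task_statistics, update_adapter)
from fsdta.base_learner import ProbeRecord
from fsdta.tasks import Task


@pytest.fixture
def adapter():
    return Adapter(hidden=4)


class TestTaskStatistics:
    def test_support_equals_query_gives_similarity_one(self, probe):
        recs = tuple(ProbeRecord(float(x), float(2 * x + 1)) for x in range(1, 5))
        task = Task("t", recs + recs, tuple(range(4)), tuple(range(4, 8)))
        stats = task_statistics(probe, np.array([0.3]), task, 0.05, 1)
        assert stats.grad_similarity == pytest.approx(1.0)

    def test_antiparallel_gradients_give_minus_one(self, probe):
        # at theta0=0: grad_S = 2(0-y)x; support (1, 1) -> -2, query (1, -1) -> +2
        recs = (ProbeRecord(1.0, 1.0), ProbeRecord(1.0, -1.0))
        task = Task("t", recs, (0,), (1,))
        stats = task_statistics(probe, np.array([0.0]), task, 0.05, 1)
        assert stats.grad_similarity == pytest.approx(-1.0)

    def test_perfectly_fit_query_has_zero_loss(self, probe):
        recs = tuple(ProbeRecord(float(x), float(2 * x)) for x in range(1, 7))
        task = Task("t", recs, (0, 1, 2), (3, 4, 5))
        stats = task_statistics(probe, np.array([2.0]), task, 0.05, 3)
        assert stats.query_loss_adapted == pytest.approx(0.0, abs=1e-12)

    def test_zero_gradient_similarity_defined_as_zero(self, probe):
        # theta0 = 2 interpolates: both gradients vanish
        recs = (ProbeRecord(1.0, 2.0), ProbeRecord(2.0, 4.0))
        task = Task("t", recs, (0,), (1,))
        stats = task_statistics(probe, np.array([2.0]), task, 0.05, 1)
        assert stats.grad_similarity == 0.0

    def test_dot_similarity_switch(self, probe):
        recs = (ProbeRecord(1.0, 1.0), ProbeRecord(1.0, -1.0))
        task = Task("t", recs, (0,), (1,))
        stats = task_statistics(probe, np.array([0.0]), task, 0.05, 1, similarity="dot")
        assert stats.grad_similarity == pytest.approx(-4.0)  # (-2) * (+2)


class TestAdapterScores:
    def test_identical_stats_uniform_any_batch_size(self, adapter):
        phi = adapter.init_flat(3)
        for b in (2, 3, 7):
            stats = [TaskStats(1.7, 0.4)] * b
            w = adapter_scores(adapter, phi, stats)
            assert np.allclose(w, 1.0 / b, atol=1e-12)

    def test_singleton_batch(self, adapter):
        w = adapter_scores(adapter, adapter.init_flat(0), [TaskStats(2.0, 0.1)])
        assert w.tolist() == [1.0]

    def test_probability_vector(self, adapter):
        rng = np.random.default_rng(8)
        stats = [TaskStats(float(l), float(s))
                 for l, s in zip(rng.uniform(0, 5, 9), rng.uniform(-1, 1, 9))]
        w = adapter_scores(adapter, adapter.init_flat(1), stats)
        assert abs(w.sum() - 1.0) < 1e-9
        assert np.all(w > 0)

    def test_order_exchangeable(self, adapter):
        """Permuting the candidate order permutes the weights identically."""
        rng = np.random.default_rng(2)
        stats = [TaskStats(float(l), float(s))
                 for l, s in zip(rng.uniform(0, 5, 6), rng.uniform(-1, 1, 6))]
        phi = adapter.init_flat(5)
        w = adapter_scores(adapter, phi, stats)
        perm = rng.permutation(6)
        w_perm = adapter_scores(adapter, phi, [stats[i] for i in perm])
        assert np.allclose(w[perm], w_perm, atol=1e-12)

    def test_nonfinite_stats_rejected(self, adapter):
        with pytest.raises(ValueError):
            TaskStats(np.inf, 0.0)


class TestSampleTasks:
    def test_select_all_returns_every_index(self):
        rng = np.random.default_rng(0)
        sel = sample_tasks(np.array([0.9, 0.05, 0.05]), 3, rng)
        assert sorted(sel) == [0, 1, 2]

    def test_dominant_weight_dominates_frequency(self):
        rng = np.random.default_rng(1)
        w = np.array([0.999, 0.0005, 0.0005])
        hits = sum(sample_tasks(w, 1, rng)[0] == 0 for _ in range(10_000))
        assert hits / 10_000 >= 0.99

    def test_indices_unique(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            sel = sample_tasks(np.full(6, 1 / 6), 4, rng)
            assert len(set(sel)) == 4

    def test_same_rng_state_same_selection(self):
        w = np.array([0.3, 0.2, 0.5])
        a = sample_tasks(w, 2, np.random.default_rng(7))
        b = sample_tasks(w, 2, np.random.default_rng(7))
        assert a == b

    def test_oversized_selection_raises(self):
        with pytest.raises(ValueError):
            sample_tasks(np.array([0.5, 0.5]), 3, np.random.default_rng(0))


class TestUpdateAdapter:
    def _setting(self, adapter, probe, seed=1, n_cand=3):
        rng = np.random.default_rng(seed)
        cands = [make_probe_task(int(rng.integers(1e6)), n=8, name=f"c{k}")
                 for k in range(n_cand)]
        theta0 = np.array([0.2])
        stats = [task_statistics(probe, theta0, t, 0.05, 2) for t in cands]
        vals = [make_probe_task(int(rng.integers(1e6)), n=8, name="val")]
        return cands, stats, vals, theta0

    def test_zero_rate_leaves_phi_unchanged(self, adapter, probe):
        cands, stats, vals, theta0 = self._setting(adapter, probe)
        phi = adapter.init_flat(0)
        out = update_adapter(adapter, phi, probe, theta0, cands, stats, vals,
                             alpha=0.05, meta_beta=0.1, adapter_beta=0.0, n_steps=2)
        assert np.array_equal(out, phi)

    def test_zero_candidate_gradients_leave_phi_unchanged(self, adapter, probe):
        # theta0 = slope of every task: all meta-gradients vanish, so the
        # virtual meta-step is independent of the weights
        recs = tuple(ProbeRecord(float(x), 2.0 * x) for x in range(1, 9))
        cands = [Task(f"c{k}", recs, tuple(range(4)), tuple(range(4, 8)))
                 for k in range(3)]
        theta0 = np.array([2.0])
        stats = [task_statistics(probe, theta0, t, 0.05, 2) for t in cands]
        vals = [make_probe_task(5, n=8)]
        phi = adapter.init_flat(4)
        out = update_adapter(adapter, phi, probe, theta0, cands, stats, vals,
                             alpha=0.05, meta_beta=0.1, adapter_beta=0.5, n_steps=2)
        assert np.allclose(out, phi, atol=1e-12)

    def test_hypergradient_matches_finite_differences(self, adapter, probe):
        """Chain-rule hypergradient vs central differences of the exact
        validation objective, on >= 5 random coordinates."""
        cands, stats, vals, theta0 = self._setting(adapter, probe, seed=3)
        phi = adapter.init_flat(7)
        out = update_adapter(adapter, phi, probe, theta0, cands, stats, vals,
                             alpha=0.05, meta_beta=0.1, adapter_beta=0.5, n_steps=2)
        hyper = (phi - out) / 0.5

        def val_at(ph):
            return adapter_validation_loss(adapter, ph, probe, theta0, cands,
                                           stats, vals, 0.05, 0.1, 2)

        # some coordinates carry no hypergradient by construction (forget-gate
        # blocks see a zero initial cell state; the head bias cancels in the
        # softmax) -- check 5+ informative coordinates, sampled at random
        rng = np.random.default_rng(0)
        informative = np.flatnonzero(np.abs(hyper) > 1e-9)
        assert informative.size >= 5
        for i in rng.choice(informative, size=min(8, informative.size), replace=False):
            eps = 1e-5
            pp, pm = phi.copy(), phi.copy()
            pp[i] += eps
            pm[i] -= eps
            fd = (val_at(pp) - val_at(pm)) / (2 * eps)
            assert abs(fd - hyper[i]) / max(abs(fd), 1e-10) < 1e-3, f"coord {i}"

    def test_empty_inputs_rejected(self, adapter, probe):
        phi = adapter.init_flat(0)
        with pytest.raises(ValueError):
            update_adapter(adapter, phi, probe, np.array([0.0]), [], [], [],
                           alpha=0.1, meta_beta=0.1, adapter_beta=0.1, n_steps=1)
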