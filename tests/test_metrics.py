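import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle_metrics as om
from fsdta.metrics import (RankedScreen, bedroc, concordance_index,
                           enrichment_factor, mse, pearson, precision_at_n,
                           r_squared, regression_report, spearman)


def _random_pair(rng, n):
    return rng.normal(size=n) * 2 + 7, rng.normal(size=n) * 2 + 7


class TestExactCases:
    def test_mse(self):
        assert mse([1, 2], [1, 2]) == 0
        assert mse([0, 0], [1, -1]) == 1

    def test_ci_monotone_extremes(self):
        y = [1.0, 2.0, 3.0, 4.0]
        assert concordance_index(y, [10, 20, 30, 40]) == 1.0
        assert concordance_index(y, [40, 30, 20, 10]) == 0.0

    def test_ci_constant_predictor_is_half(self):
        assert concordance_index([1, 2, 3], [5, 5, 5]) == 0.5

    def test_ci_all_labels_tied_raises(self):
        with pytest.raises(ValueError):
            concordance_index([2, 2, 2], [1, 2, 3])

    def test_r2_extremes(self):
        y = [1.0, 2.0, 4.0]
        assert r_squared(y, y) == 1.0
        assert r_squared(y, [np.mean(y)] * 3) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            r_squared([3, 3, 3], [1, 2, 3])

    def test_correlation_extremes(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        assert spearman(y, y**3) == pytest.approx(1.0)  # monotone map
        assert spearman(y, -y) == pytest.approx(-1.0)
        assert pearson(y, 2 * y + 3) == pytest.approx(1.0)
        assert pearson(y, -y) == pytest.approx(-1.0)


class TestOracleEquivalence:
    """Implementation vs independent brute-force / direct-formula oracles."""

    @pytest.mark.parametrize("seed", range(5))
    def test_regression_metrics(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = int(rng.integers(5, 200))
            y, yhat = _random_pair(rng, n)
            assert concordance_index(y, yhat) == om.ci_bruteforce(y, yhat)
            assert mse(y, yhat) == pytest.approx(om.mse_direct(y, yhat), abs=1e-9)
            assert r_squared(y, yhat) == pytest.approx(om.r2_direct(y, yhat), abs=1e-9)
            assert pearson(y, yhat) == pytest.approx(om.pearson_direct(y, yhat), abs=1e-9)
            assert spearman(y, yhat) == pytest.approx(
                om.spearman_untied_direct(y, yhat), abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_screening_metrics(self, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(20):
            n = int(rng.integers(40, 200))
            scores = rng.normal(size=n)
            labels = rng.random(n) < 0.15
            if not 0 < labels.sum() < n:
                continue
            screen = RankedScreen(scores=scores, labels=labels)
            for k in (1.0, 5.0, 20.0):
                assert enrichment_factor(screen, k) == pytest.approx(
                    om.ef_direct(scores, labels, k), abs=1e-12)
            for topn in (5, 10):
                assert precision_at_n(screen, topn) == pytest.approx(
                    om.precision_direct(scores, labels, topn), abs=1e-12)
            assert bedroc(screen, 80.5) == pytest.approx(
                om.bedroc_rdkit(scores, labels, 80.5), abs=1e-9)

    def test_bedroc_perfect_ranking_near_one(self):
        labels = np.zeros(1000, dtype=bool)
        labels[:20] = True
        screen = RankedScreen(scores=-np.arange(1000, dtype=float), labels=labels)
        value = bedroc(screen, 80.5)
        assert value >= 0.99
        assert value == pytest.approx(om.bedroc_rdkit(screen.scores, labels, 80.5), abs=1e-9)

    def test_bedroc_random_mean_matches_reference(self):
        rng = np.random.default_rng(7)
        labels = np.zeros(200, dtype=bool)
        labels[:20] = True
        mine, ref = [], []
        for _ in range(300):
            scores = rng.normal(size=200)
            screen = RankedScreen(scores=scores, labels=labels)
            mine.append(bedroc(screen, 80.5))
            ref.append(om.bedroc_rdkit(scores, labels, 80.5))
        assert abs(np.mean(mine) - np.mean(ref)) < 0.02


class TestEnrichmentFactor:
    def test_all_actives_on_top(self):
        labels = np.zeros(100, dtype=bool)
        labels[:10] = True
        screen = RankedScreen(scores=-np.arange(100, dtype=float), labels=labels)
        assert enrichment_factor(screen, 10.0) == pytest.approx(10.0)

    def test_full_list_is_one(self):
        rng = np.random.default_rng(0)
        labels = rng.random(50) < 0.3
        screen = RankedScreen(scores=rng.normal(size=50), labels=labels)
        assert enrichment_factor(screen, 100.0) == pytest.approx(1.0)

    def test_random_null_mean_near_one(self):
        rng = np.random.default_rng(1)
        labels = np.zeros(100, dtype=bool)
        labels[:10] = True
        efs = [enrichment_factor(
            RankedScreen(scores=rng.normal(size=100), labels=labels), 10.0)
            for _ in range(10_000)]
        assert abs(np.mean(efs) - 1.0) < 0.05

    def test_no_actives_raises(self):
        screen = RankedScreen(scores=np.arange(5.0), labels=np.zeros(5, dtype=bool))
        with pytest.raises(ValueError):
            enrichment_factor(screen, 10.0)


class TestPrecisionAtN:
    def test_half_active_top(self):
        labels = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 0, 0], dtype=bool)
        screen = RankedScreen(scores=-np.arange(12, dtype=float), labels=labels)
        assert precision_at_n(screen, 10) == 0.5

    def test_all_active(self):
        screen = RankedScreen(scores=np.arange(6, dtype=float),
                              labels=np.ones(6, dtype=bool))
        for n in (1, 3, 6):
            assert precision_at_n(screen, n) == 1.0

    def test_out_of_range_raises(self):
        screen = RankedScreen(scores=np.arange(4.0), labels=np.array([1, 0, 0, 1], dtype=bool))
        with pytest.raises(ValueError):
            precision_at_n(screen, 5)


class TestInvariances:
    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_joint_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        y, yhat = _random_pair(rng, 30)
        perm = rng.permutation(30)
        for fn in (mse, concordance_index, r_squared, spearman, pearson):
            assert fn(y, yhat) == pytest.approx(fn(y[perm], yhat[perm]), abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_rank_metrics_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y, yhat = _random_pair(rng, 25)
        transformed = np.exp(yhat / 3.0) + 1.0  # strictly increasing
        assert concordance_index(y, yhat) == pytest.approx(
            concordance_index(y, transformed), abs=1e-12)
        assert spearman(y, yhat) == pytest.approx(spearman(y, transformed), abs=1e-9)

    def test_screening_metrics_depend_only_on_ranking(self):
        rng = np.random.default_rng(3)
        labels = rng.random(60) < 0.2
        labels[0] = True
        scores = rng.normal(size=60)
        monotone = np.tanh(scores) * 5 + 100
        a = RankedScreen(scores=scores, labels=labels)
        b = RankedScreen(scores=monotone, labels=labels)
        assert enrichment_factor(a, 10.0) == enrichment_factor(b, 10.0)
        assert bedroc(a, 80.5) == pytest.approx(bedroc(b, 80.5), abs=1e-12)


def test_regression_report_bundles_screening_block():
    rng = np.random.default_rng(4)
    y, yhat = _random_pair(rng, 80)
    labels = rng.random(80) < 0.2
    labels[:2] = True
    rep = regression_report(y, yhat, screen=RankedScreen(scores=yhat, labels=labels))
    d = rep.to_dict()
    assert set(d) >= {"mse", "ci", "r2", "spearman", "pearson", "ef", "precision", "bedroc"}
    assert d["bedroc_alpha"] == 80.5
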