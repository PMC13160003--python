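"""HiNCE losses: closed forms, scalar-loop oracles, gradients, stability."""

import math

import numpy as np
import pytest

from hince.ec import ECLabel
from hince.losses import (Centroid, ContrastiveBatch, LossWeights,
                          compute_centroids, exemplar_loss,
                          exemplar_loss_at_depth, hince_loss,
                          hince_loss_and_grad, instance_loss, loo_centroid)

from conftest import (oracle_centroids, oracle_exemplar, oracle_exemplar_depth,
                      oracle_hince, oracle_instance, random_labeled_batch)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestInstanceLoss:
    def test_single_positive_no_negatives_is_zero(self):
        a = _unit([1, 1])
        assert instance_loss(a, a[None], np.empty((0, 2)), 0.1) == pytest.approx(0.0)

    def test_two_symmetric_positives_give_log2(self):
        a = np.array([1.0, 0.0])
        pos = np.array([[0.0, 1.0], [0.0, -1.0]])  # equal similarity to anchor
        for tau in (0.05, 0.1, 1.0, 7.0):
            assert instance_loss(a, pos, np.empty((0, 2)), tau) == \
                pytest.approx(math.log(2))

    def test_closed_form_spot_check(self):
        a = np.array([1.0, 0.0])
        assert instance_loss(a, a[None], np.array([[-1.0, 0.0]]), 1.0) == \
            pytest.approx(math.log(1 + math.exp(-2)))

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError):
            instance_loss(np.ones(2), np.empty((0, 2)), np.ones((1, 2)), 0.1)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(20):
            a = _unit(rng.normal(size=5))
            pos = rng.normal(size=(3, 5))
            pos /= np.linalg.norm(pos, axis=1, keepdims=True)
            neg = rng.normal(size=(4, 5))
            neg /= np.linalg.norm(neg, axis=1, keepdims=True)
            assert instance_loss(a, pos, neg, 0.1) == \
                pytest.approx(oracle_instance(a, pos, neg, 0.1), abs=1e-10)

    def test_monotone_in_positive_similarity(self):
        """Raising a positive's similarity to the anchor lowers the loss."""
        a = np.array([1.0, 0.0])
        neg = np.array([[0.0, 1.0]])
        losses = []
        for angle in (1.2, 0.8, 0.4, 0.1):
            p = np.array([[math.cos(angle), math.sin(angle)]])
            losses.append(instance_loss(a, p, neg, 0.1))
        assert all(l1 > l2 for l1, l2 in zip(losses, losses[1:]))


class TestCentroids:
    def test_grouping_at_depth3(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        labels = [ECLabel((1, 1, 1, 1)), ECLabel((1, 1, 1, 2))]
        table = compute_centroids(Z, labels, 3)
        assert set(table) == {"1.1.1"}
        assert np.allclose(table["1.1.1"].mean, [0.5, 0.5])  # not renormalized

    def test_single_member_centroid_is_member(self):
        Z = np.array([[0.3, 0.4]])
        table = compute_centroids(Z, [ECLabel((2, 3, 4, 5))], 2)
        assert np.allclose(table["2.3"].mean, Z[0])

    def test_matches_scalar_means(self, rng):
        Z = rng.normal(size=(10, 4))
        labels = [ECLabel(tuple(int(x) for x in rng.integers(1, 3, size=4)))
                  for _ in range(10)]
        for depth in (1, 2, 3, 4):
            table = compute_centroids(Z, labels, depth)
            oracle = oracle_centroids([list(r) for r in Z], labels, depth)
            assert set(table) == set(oracle)
            for c in table:
                assert np.allclose(table[c].mean, oracle[c][0], atol=1e-12)

    def test_empty_input(self):
        assert compute_centroids(np.empty((0, 3)), [], 1) == {}


class TestLooCentroid:
    def test_pair_gives_other_member(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        table = compute_centroids(Z, [ECLabel((1, 1, 1, 1))] * 2, 4)
        assert np.allclose(loo_centroid(table["1.1.1.1"], 0, Z), Z[1])

    def test_singleton_returns_self(self):
        Z = np.array([[0.6, 0.8]])
        table = compute_centroids(Z, [ECLabel((1, 1, 1, 1))], 4)
        assert np.allclose(loo_centroid(table["1.1.1.1"], 0, Z), Z[0])

    def test_triple_is_mean_of_others(self, rng):
        Z = rng.normal(size=(3, 4))
        table = compute_centroids(Z, [ECLabel((1, 1, 1, 1))] * 3, 4)
        assert np.allclose(loo_centroid(table["1.1.1.1"], 1, Z),
                           (Z[0] + Z[2]) / 2, atol=1e-12)

    def test_non_member_rejected(self):
        Z = np.eye(2)
        table = compute_centroids(Z[:1], [ECLabel((1, 1, 1, 1))], 4)
        with pytest.raises(ValueError):
            loo_centroid(table["1.1.1.1"], 1, Z)


class TestExemplarLoss:
    def test_sole_singleton_class_is_zero(self):
        Z = _unit([1, 2, 3])[None]
        assert exemplar_loss_at_depth(0, Z, [ECLabel((1, 1, 1, 1))], 2, 0.1) == \
            pytest.approx(0.0)

    def test_two_orthogonal_members_closed_form(self):
        Z = np.eye(2)
        labels = [ECLabel((1, 1, 1, 1))] * 2
        for tau in (0.1, 0.5):
            # single class: loss = (1 - z_a . z_b) / (2 tau)
            assert exemplar_loss_at_depth(0, Z, labels, 3, tau) == \
                pytest.approx((1 - 0.0) / (2 * tau))
        assert exemplar_loss_at_depth(0, Z, labels, 3, 0.1) == pytest.approx(5.0)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(10):
            Z = rng.normal(size=(8, 4))
            Z /= np.linalg.norm(Z, axis=1, keepdims=True)
            labels = [ECLabel(tuple(int(x) for x in rng.integers(1, 3, size=4)))
                      for _ in range(8)]
            for depth in (1, 2, 3, 4):
                got = exemplar_loss_at_depth(0, Z, labels, depth, 0.1)
                want = oracle_exemplar_depth(0, [list(r) for r in Z], labels,
                                             depth, 0.1)
                assert got == pytest.approx(want, abs=1e-10)

    def test_depth_average(self, rng):
        Z = rng.normal(size=(6, 4))
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        labels = [ECLabel(tuple(int(x) for x in rng.integers(1, 3, size=4)))
                  for _ in range(6)]
        per_depth = [exemplar_loss_at_depth(2, Z, labels, d, 0.1) for d in (1, 2, 3, 4)]
        assert exemplar_loss(2, Z, labels, 0.1) == pytest.approx(np.mean(per_depth))

    def test_absent_class_rejected(self):
        Z = np.eye(2)
        labels = [ECLabel((1, 1, 1, 1)), ECLabel((2, 2, 2, 2))]
        table = compute_centroids(Z[:1], labels[:1], 1)
        with pytest.raises(ValueError):
            exemplar_loss_at_depth(1, Z, labels, 1, 0.1, table=table)


class TestLossWeights:
    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0.0, 0.0)

    @pytest.mark.parametrize("tau", [0.0, -1.0])
    def test_bad_temperature(self, tau):
        with pytest.raises(ValueError):
            LossWeights(tau=tau)


class TestHinceLoss:
    def test_weight_zero_reduces_to_single_term(self, rng):
        batch = random_labeled_batch(rng)
        inst_only = hince_loss(batch, LossWeights(1.0, 0.0, 0.1))
        exem_only = hince_loss(batch, LossWeights(0.0, 1.0, 0.1))
        both = hince_loss(batch, LossWeights(1.0, 1.0, 0.1))
        assert inst_only.total == pytest.approx(inst_only.instance_mean)
        assert exem_only.total == pytest.approx(exem_only.exemplar_mean)
        assert both.total == pytest.approx(
            inst_only.instance_mean + exem_only.exemplar_mean)

    def test_matches_scalar_oracle_50_batches(self):
        """Vectorized loss equals the per-anchor scalar loop on 50 random batches."""
        for trial in range(50):
            rng = np.random.default_rng(trial)
            batch = random_labeled_batch(
                rng,
                n_anchors=int(rng.integers(2, 17)),
                dim=int(rng.integers(2, 9)))
            w = LossWeights(1.0, 1.0, 0.1)
            got = hince_loss(batch, w)
            want_total, want_i, want_e = oracle_hince(batch, 1.0, 1.0, 0.1)
            assert abs(got.total - want_total) < 1e-6
            assert abs(got.instance_mean - want_i) < 1e-6
            assert abs(got.exemplar_mean - want_e) < 1e-6

    @pytest.mark.parametrize("tau", [0.01, 0.1, 1.0, 10.0])
    def test_finite_for_extreme_temperatures(self, rng, tau):
        batch = random_labeled_batch(rng)
        value = hince_loss(batch, LossWeights(1.0, 1.0, tau))
        assert np.isfinite(value.total)

    def test_gradient_matches_finite_differences(self):
        """Analytic dL/dZ vs central differences (1e-4 step) on small batches."""
        for trial in range(5):
            rng = np.random.default_rng(100 + trial)
            batch = random_labeled_batch(rng, n_anchors=5, dim=4)
            w = LossWeights(1.0, 1.0, 0.1)
            _, dZ = hince_loss_and_grad(batch, w)
            eps = 1e-4
            fd = np.zeros_like(dZ)
            for i in range(dZ.shape[0]):
                for j in range(dZ.shape[1]):
                    for sign, store in ((1, "up"), (-1, "dn")):
                        Zs = batch.embeddings.copy()
                        Zs[i, j] += sign * eps
                        shifted = ContrastiveBatch(
                            Zs, batch.anchor_idx, batch.anchor_labels,
                            batch.pos_sets, batch.neg_sets)
                        if store == "up":
                            up = hince_loss(shifted, w).total
                        else:
                            dn = hince_loss(shifted, w).total
                    fd[i, j] = (up - dn) / (2 * eps)
            denom = max(np.max(np.abs(fd)), 1e-12)
            assert np.max(np.abs(fd - dZ)) / denom < 1e-4
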