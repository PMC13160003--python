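"""Training loop: distance map, sampling, mask augmentation, optimization."""

import numpy as np
import pytest

from hince.containers import EmbeddingSet
from hince.ec import ECLabel
from hince.losses import LossWeights
from hince.projection import ProjectionConfig
from hince.synthetic import SyntheticSpec, generate_dataset, synthetic_provider
from hince.training import (TrainConfig, build_distance_map, mask_augment,
                            sample_batch, train)

SMALL_SPEC = SyntheticSpec(
    n_ec1=2, n_ec2_per_ec1=2, n_ec3_per_ec2=1, n_ec4_per_ec3=2,
    proteins_per_ec4=(3, 6), dim=12, nuisance_dims=6, seed=7)

FAST = dict(epochs=4, batch_size=8, refresh_interval=2,
            projection=ProjectionConfig(input_dim=18, output_dim=8, hidden=(12,)))


def _label(ec):
    return ECLabel(tuple(int(x) for x in ec.split(".")))


class TestMaskAugment:
    def test_exactly_one_mask_position(self, rng):
        for _ in range(20):
            seq = "ACDEFGHIKLMNPQ"
            out = mask_augment(seq, rng)
            assert len(out) == len(seq)
            diffs = [i for i, (a, b) in enumerate(zip(seq, out)) if a != b]
            assert len(diffs) == 1 and out[diffs[0]] == "*"

    def test_length_one(self, rng):
        assert mask_augment("M", rng) == "*"

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            mask_augment("", rng)

    def test_seeded_determinism(self):
        a = mask_augment("ACDEF", np.random.default_rng(5))
        b = mask_augment("ACDEF", np.random.default_rng(5))
        assert a == b


class TestDistanceMap:
    def test_three_proteins_two_labels(self):
        Z = np.array([[1.0, 0.0], [0.9, np.sqrt(1 - 0.81)], [0.0, 1.0]])
        emb = EmbeddingSet(ids=["a1", "a2", "b1"], matrix=Z)
        labels = {"a1": _label("1.1.1.1"), "a2": _label("1.1.1.1"),
                  "b1": _label("2.2.2.2")}
        dm = build_distance_map(emb, labels, k=5)
        assert dm.shortlists["a1"] == ["b1"]
        assert dm.shortlists["a2"] == ["b1"]
        assert dm.shortlists["b1"] == ["a2", "a1"]  # a2 more similar to b1

    def test_brute_force_oracle(self, rng):
        Z = rng.normal(size=(20, 5))
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        ids = [f"P{i:02d}" for i in range(20)]
        labels = {i: ECLabel(tuple(int(x) for x in rng.integers(1, 3, size=4)))
                  for i in ids}
        emb = EmbeddingSet(ids=ids, matrix=Z)
        k = 4
        dm = build_distance_map(emb, labels, k=k)
        sims = Z @ Z.T
        for qi, q in enumerate(ids):
            cands = [(float(-sims[qi, j]), ids[j]) for j in range(20)
                     if str(labels[ids[j]]) != str(labels[q])]
            expected = [e for _, e in sorted(cands)][:k]
            assert dm.shortlists[q] == expected

    def test_no_shortlist_member_shares_owner_label(self, rng):
        Z = rng.normal(size=(15, 4))
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        ids = [f"Q{i}" for i in range(15)]
        labels = {i: ECLabel(tuple(int(x) for x in rng.integers(1, 3, size=4)))
                  for i in ids}
        dm = build_distance_map(EmbeddingSet(ids=ids, matrix=Z), labels, k=6)
        for owner, shortlist in dm.shortlists.items():
            assert all(str(labels[n]) != str(labels[owner]) for n in shortlist)


class TestSampleBatch:
    def _setup(self, rng):
        ids = [f"P{i}" for i in range(12)]
        ecs = ["1.1.1.1"] * 4 + ["1.1.1.2"] * 4 + ["2.2.2.2"] * 4
        labels = {i: _label(e) for i, e in zip(ids, ecs)}
        members = {}
        for i in ids:
            members.setdefault(str(labels[i]), []).append(i)
        Z = rng.normal(size=(12, 4))
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        dm = build_distance_map(EmbeddingSet(ids=ids, matrix=Z), labels, k=3)
        return ids, labels, members, dm

    def test_hard_only_negatives_come_from_shortlist_classes(self, rng):
        ids, labels, members, dm = self._setup(rng)
        cfg = TrainConfig(p_hard=1.0, n_negatives=6,
                          projection=ProjectionConfig(input_dim=4, output_dim=2))
        samples = sample_batch(ids[:4], labels, members, dm, cfg, rng)
        for anchor, (pos, neg) in zip(ids[:4], samples):
            pool = set(dm.hard_classes(anchor, labels))
            assert all(str(labels[n]) in pool for n in neg)
            assert all(str(labels[p]) == str(labels[anchor]) for p in pos)

    def test_uniform_negatives_never_share_anchor_label(self, rng):
        ids, labels, members, dm = self._setup(rng)
        cfg = TrainConfig(p_hard=0.0, n_negatives=6,
                          projection=ProjectionConfig(input_dim=4, output_dim=2))
        samples = sample_batch(ids[:4], labels, members, dm, cfg, rng)
        for anchor, (_, neg) in zip(ids[:4], samples):
            assert all(str(labels[n]) != str(labels[anchor]) for n in neg)

    def test_seeded_determinism(self, rng):
        ids, labels, members, dm = self._setup(rng)
        cfg = TrainConfig(projection=ProjectionConfig(input_dim=4, output_dim=2))
        a = sample_batch(ids, labels, members, dm, cfg, np.random.default_rng(3))
        b = sample_batch(ids, labels, members, dm, cfg, np.random.default_rng(3))
        assert a == b

    def test_singleton_without_view_raises(self, rng):
        ids, labels, members, dm = self._setup(rng)
        labels["X"] = _label("3.3.3.3")
        members["3.3.3.3"] = ["X"]
        cfg = TrainConfig(projection=ProjectionConfig(input_dim=4, output_dim=2))
        with pytest.raises(ValueError, match="augment"):
            sample_batch(["X"], labels, members, dm, cfg, rng)

    def test_singleton_with_registered_view(self, rng):
        ids, labels, members, dm = self._setup(rng)
        labels["X"] = _label("3.3.3.3")
        labels["X::aug"] = _label("3.3.3.3")
        members["3.3.3.3"] = ["X"]
        cfg = TrainConfig(projection=ProjectionConfig(input_dim=4, output_dim=2))
        samples = sample_batch(["X"], labels, members, dm, cfg, rng,
                               augmented_view={"X": "X::aug"})
        pos, _ = samples[0]
        assert set(pos) == {"X::aug"}


def _training_inputs(spec=SMALL_SPEC):
    ds = generate_dataset(spec)
    labels = {r.entry: r.ec for r in ds.records}
    sequences = {r.entry: r.sequence for r in ds.records}
    return ds.embeddings, labels, sequences, synthetic_provider(spec, ds)


class TestTrain:
    def test_loss_decreases(self):
        base, labels, sequences, provider = _training_inputs()
        cfg = TrainConfig(seed=0, **FAST)
        _, log = train(base, labels, sequences, provider, cfg)
        assert log.epochs[-1]["loss"] < log.epochs[0]["loss"]

    def test_determinism(self):
        base, labels, sequences, provider = _training_inputs()
        cfg = TrainConfig(seed=11, **FAST)
        p1, l1 = train(base, labels, sequences, provider, cfg)
        p2, l2 = train(base, labels, sequences, provider, cfg)
        for w1, w2 in zip(p1.weights, p2.weights):
            assert np.array_equal(w1, w2)
        assert l1.epochs == l2.epochs

    def test_refresh_schedule_and_staleness(self):
        base, labels, sequences, provider = _training_inputs()
        cfg = TrainConfig(seed=0, epochs=7, batch_size=8, refresh_interval=3,
                          projection=FAST["projection"])
        _, log = train(base, labels, sequences, provider, cfg)
        assert log.refresh_epochs == [0, 3, 6]
        for rec in log.epochs:
            assert rec["epoch"] - rec["distance_map_epoch"] < cfg.refresh_interval

    def test_refresh_interval_beyond_epochs_builds_once(self):
        base, labels, sequences, provider = _training_inputs()
        cfg = TrainConfig(seed=0, epochs=3, batch_size=8, refresh_interval=50,
                          projection=FAST["projection"])
        _, log = train(base, labels, sequences, provider, cfg)
        assert log.refresh_epochs == [0]

    def test_singleton_class_gets_augmented_positive(self):
        """A one-member EC4 class trains via its mask-augmented positive view."""
        rng = np.random.default_rng(0)
        ids = ["S0"] + [f"B{i}" for i in range(5)]
        labels = {"S0": _label("3.3.3.3")}
        labels.update({f"B{i}": _label("1.1.1.1") for i in range(5)})
        sequences = {e: "ACDEFGHIKLMNPQRSTVWY" for e in ids}
        Z = rng.normal(size=(6, 8))
        base = EmbeddingSet(ids=ids, matrix=Z / np.linalg.norm(Z, axis=1, keepdims=True))

        calls = []

        class StubProvider:
            def base_embedding(self, entry):
                return base.vector(entry)

            def embed_sequence(self, sequence):
                calls.append(sequence)
                v = base.vector("S0") + 0.01
                return v / np.linalg.norm(v)

        cfg = TrainConfig(seed=0, epochs=2, batch_size=4,
                          projection=ProjectionConfig(input_dim=8, output_dim=4))
        _, log = train(base, labels, sequences, StubProvider(), cfg)
        assert len(log.epochs) == 2  # ran without positive-starvation errors
        assert len(calls) == 1 and calls[0].count("*") == 1  # one masked re-embedding

    def test_hierarchy_shaping_improves(self):
        """Within-EC3 minus between-EC1 similarity increases after training."""
        from hince.benchmark import hierarchy_gap
        base, labels, sequences, provider = _training_inputs()
        cfg = TrainConfig(seed=2, epochs=100, batch_size=16, refresh_interval=10,
                          projection=FAST["projection"],
                          weights=LossWeights(1.0, 1.0, 0.1))
        projector, _ = train(base, labels, sequences, provider, cfg)
        labs = [labels[e] for e in base.ids]
        before = hierarchy_gap(base.matrix, labs)
        after = hierarchy_gap(projector.project(base.matrix), labs)
        assert after > before
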