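"""Mini-batch contrastive training with hard-negative mining.

Every protein in a mini-batch serves as an anchor; positives are sampled
from its EC4 class and negatives preferentially from a *distance map* — a
periodically refreshed shortlist, per training protein, of its most similar
different-EC4 neighbors in the current projected space.  Mining hard
negatives focuses the objective on separating confusable enzyme families.

EC4 classes with a single training sequence would contribute no positive
pair, so before training each singleton gets an augmented positive view:
one residue of its sequence is replaced by the mask character ``*`` and the
frozen encoder (the :class:`EmbeddingProvider`) re-embeds the mutated
sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence

import numpy as np

from .containers import EmbeddingSet
from .ec import ECLabel
from .losses import ContrastiveBatch, LossWeights, hince_loss_and_grad
from .projection import Adam, ProjectionConfig, Projector, init_projector

AUG_SUFFIX = "::aug"


class EmbeddingProvider(Protocol):
    """Contract for the frozen base encoder."""

    def base_embedding(self, entry: str) -> np.ndarray: ...

    def embed_sequence(self, sequence: str) -> np.ndarray: ...


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    n_positives: int = 2
    n_negatives: int = 8
    p_hard: float = 0.7
    shortlist_k: int = 20
    refresh_interval: int = 5
    learning_rate: float = 1e-3
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    validation_fraction: float = 0.0
    projection: Optional[ProjectionConfig] = None

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "n_positives", "n_negatives",
                     "shortlist_k", "refresh_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.p_hard <= 1.0):
            raise ValueError("p_hard must be in [0,1]")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0,1)")


@dataclass
class DistanceMap:
    """Per-protein ranked shortlist of most-similar different-EC4 proteins."""

    shortlists: dict[str, list[str]]  # entry -> neighbor entries, best first
    epoch: int  # refresh stamp

    def hard_classes(self, entry: str, labels: Mapping[str, ECLabel]) -> list[str]:
        """Distinct EC4 labels occurring in this entry's shortlist, in rank order."""
        seen: list[str] = []
        for nb in self.shortlists.get(entry, []):
            ec4 = str(labels[nb])
            if ec4 not in seen:
                seen.append(ec4)
        return seen


def build_distance_map(
    projected: EmbeddingSet,
    labels: Mapping[str, ECLabel],
    k: int,
    epoch: int = 0,
) -> DistanceMap:
    """Brute-force k most similar different-EC4 neighbors per protein.

    Similarity is the inner product of the (unit-norm) projected vectors;
    ties are broken by entry id.  When fewer than ``k`` different-label
    proteins exist, the shortlist is all of them.
    """
    ids = projected.ids
    Z = projected.matrix
    ec4 = np.array([str(labels[i]) for i in ids])
    sims = Z @ Z.T
    shortlists: dict[str, list[str]] = {}
    order_ids = np.array(ids)
    for i, entry in enumerate(ids):
        cand = np.flatnonzero(ec4 != ec4[i])
        ranked = sorted(cand, key=lambda j: (-sims[i, j], order_ids[j]))
        shortlists[entry] = [ids[j] for j in ranked[:k]]
    return DistanceMap(shortlists=shortlists, epoch=epoch)


def mask_augment(sequence: str, rng: np.random.Generator) -> str:
    """Replace one uniformly chosen residue with the mask character ``*``."""
    if len(sequence) < 1:
        raise ValueError("cannot mask-augment an empty sequence")
    pos = int(rng.integers(len(sequence)))
    return sequence[:pos] + "*" + sequence[pos + 1:]


def sample_batch(
    anchor_ids: Sequence[str],
    labels: Mapping[str, ECLabel],
    members_by_ec4: Mapping[str, list[str]],
    distance_map: DistanceMap,
    config: TrainConfig,
    rng: np.random.Generator,
    augmented_view: Optional[Mapping[str, str]] = None,
) -> list[tuple[list[str], list[str]]]:
    """Sample positive and negative ids for each anchor.

    Positives are uniform over the anchor's EC4 class (anchor excluded),
    including a registered augmented view for singleton classes.  Each
    negative is, with probability ``p_hard``, a uniform member of a uniform
    EC4 class from the anchor's shortlist; otherwise uniform over all
    different-EC4 proteins.
    """
    augmented_view = augmented_view or {}
    all_ids = [e for members in members_by_ec4.values() for e in members]
    out: list[tuple[list[str], list[str]]] = []
    for anchor in anchor_ids:
        ec4 = str(labels[anchor])
        pool = [e for e in members_by_ec4[ec4] if e != anchor]
        if anchor in augmented_view:
            pool.append(augmented_view[anchor])
        if not pool:
            raise ValueError(
                f"EC4 class {ec4} has no positive source for {anchor}; "
                "register a mask-augmented view for singleton classes")
        replace = len(pool) < config.n_positives
        pos = list(rng.choice(pool, size=config.n_positives, replace=replace))
        hard = distance_map.hard_classes(anchor, labels)
        neg: list[str] = []
        for _ in range(config.n_negatives):
            if hard and rng.random() < config.p_hard:
                cls = hard[int(rng.integers(len(hard)))]
                members = members_by_ec4[cls]
                neg.append(members[int(rng.integers(len(members)))])
            else:
                while True:
                    c = all_ids[int(rng.integers(len(all_ids)))]
                    if str(labels[c]) != ec4:
                        neg.append(c)
                        break
        out.append((pos, neg))
    return out


@dataclass
class TrainLog:
    epochs: list[dict] = field(default_factory=list)
    refresh_epochs: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"epochs": self.epochs,
                           "refresh_epochs": self.refresh_epochs}, indent=2)


def train(
    base: EmbeddingSet,
    labels: Mapping[str, ECLabel],
    sequences: Mapping[str, str],
    provider: EmbeddingProvider,
    config: TrainConfig,
) -> tuple[Projector, TrainLog]:
    """Optimize the projection head with the HiNCE objective.

    Fully reproducible given ``config.seed``: sampling, initialization, and
    augmentation all draw from generators derived from it.
    """
    entries = [e for e in base.ids if e in labels]
    if not entries:
        raise ValueError("no training entries: base embeddings and labels are disjoint")
    rng = np.random.default_rng(config.seed)

    members_by_ec4: dict[str, list[str]] = {}
    for e in entries:
        members_by_ec4.setdefault(str(labels[e]), []).append(e)

    # augmented positive views for singleton EC4 classes
    aug_rows: list[np.ndarray] = []
    aug_ids: list[str] = []
    augmented_view: dict[str, str] = {}
    work_labels: dict[str, ECLabel] = {e: labels[e] for e in entries}
    for ec4, members in members_by_ec4.items():
        if len(members) == 1:
            owner = members[0]
            if owner not in sequences:
                raise ValueError(f"singleton class {ec4}: no sequence for {owner}")
            masked = mask_augment(sequences[owner], rng)
            try:
                vec = np.asarray(provider.embed_sequence(masked), dtype=np.float64)
            except Exception as exc:  # surface the failing entry
                raise RuntimeError(f"embedding provider failed for {owner}") from exc
            aug_id = owner + AUG_SUFFIX
            aug_ids.append(aug_id)
            aug_rows.append(vec)
            augmented_view[owner] = aug_id
            work_labels[aug_id] = labels[owner]

    all_ids = entries + aug_ids
    base_mat = np.vstack([base.subset(entries).matrix]
                         + ([np.vstack(aug_rows)] if aug_rows else []))
    work = EmbeddingSet(ids=all_ids, matrix=base_mat)

    # held-out validation entries (excluded from anchors and sampling pools)
    val_entries: list[str] = []
    train_entries = entries
    if config.validation_fraction > 0:
        n_val = int(round(config.validation_fraction * len(entries)))
        val_entries = list(rng.choice(entries, size=n_val, replace=False))
        val_set = set(val_entries)
        train_entries = [e for e in entries if e not in val_set]
        members_by_ec4 = {}
        for e in train_entries:
            members_by_ec4.setdefault(str(labels[e]), []).append(e)

    d = work.dim
    proj_cfg = config.projection or ProjectionConfig(
        input_dim=d, seed=int(rng.integers(2**31)))
    if proj_cfg.input_dim != d:
        raise ValueError(f"projection input_dim {proj_cfg.input_dim} != embedding dim {d}")
    projector = init_projector(proj_cfg)
    opt = Adam(projector, lr=config.learning_rate)

    log = TrainLog()
    distance_map: Optional[DistanceMap] = None
    train_rows = [work.row(e) for e in train_entries]

    for epoch in range(config.epochs):
        if epoch % config.refresh_interval == 0:
            Z_train = projector.project(work.matrix[train_rows])
            projected = EmbeddingSet(ids=list(train_entries), matrix=Z_train)
            distance_map = build_distance_map(
                projected, work_labels, config.shortlist_k, epoch=epoch)
            log.refresh_epochs.append(epoch)

        order = rng.permutation(len(train_entries))
        totals, insts, exems = [], [], []
        for start in range(0, len(order), config.batch_size):
            anchor_ids = [train_entries[i] for i in order[start:start + config.batch_size]]
            samples = sample_batch(anchor_ids, work_labels, members_by_ec4,
                                   distance_map, config, rng,
                                   augmented_view=augmented_view)
            batch_ids: list[str] = list(anchor_ids)
            pos_rows: list[list[int]] = []
            neg_rows: list[list[int]] = []
            local = {e: k for k, e in enumerate(batch_ids)}

            def local_row(e: str) -> int:
                if e not in local:
                    local[e] = len(batch_ids)
                    batch_ids.append(e)
                return local[e]

            for pos, neg in samples:
                pos_rows.append([local_row(p) for p in pos])
                neg_rows.append([local_row(n) for n in neg])

            X = np.stack([work.vector(e) for e in batch_ids])
            Z, cache = projector.project_with_cache(X)
            batch = ContrastiveBatch(
                embeddings=Z,
                anchor_idx=np.arange(len(anchor_ids)),
                anchor_labels=[work_labels[e] for e in anchor_ids],
                pos_sets=[np.asarray(p) for p in pos_rows],
                neg_sets=[np.asarray(n) for n in neg_rows],
                row_labels=[work_labels[e] for e in batch_ids],
            )
            value, dZ = hince_loss_and_grad(batch, config.weights)
            dws, dbs = projector.backward(cache, dZ)
            opt.step(dws, dbs)
            totals.append(value.total)
            insts.append(value.instance_mean)
            exems.append(value.exemplar_mean)

        record = {
            "epoch": epoch,
            "loss": float(np.mean(totals)),
            "instance": float(np.mean(insts)),
            "exemplar": float(np.mean(exems)),
            "distance_map_epoch": distance_map.epoch,
        }
        if val_entries:
            record["val_nn_ec4_accuracy"] = _nn_accuracy(
                projector, work, train_entries, val_entries, work_labels)
        log.epochs.append(record)
    return projector, log


def _nn_accuracy(projector, work, train_entries, val_entries, labels) -> float:
    Z_tr = projector.project(np.stack([work.vector(e) for e in train_entries]))
    Z_va = projector.project(np.stack([work.vector(e) for e in val_entries]))
    nn = np.argmax(Z_va @ Z_tr.T, axis=1)
    hits = sum(str(labels[val_entries[i]]) == str(labels[train_entries[j]])
               for i, j in enumerate(nn))
    return hits / len(val_entries)
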