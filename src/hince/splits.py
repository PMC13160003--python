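"""Train/test split construction and similarity/evidence filtering.

Two splits model two evaluation regimes:

* **unseen** — EC4-grouped: within each EC3 family the most populous EC4
  group (the "established" class) goes to training; remaining EC4 groups,
  taken whole in ascending size order, fill the test-candidate set.  Test
  EC4 labels never occur in training, but every test EC3 family does, so
  nearest-neighbor transfer is evaluated on genuinely novel serial numbers
  inside known families.
* **seen** — conventional random split with the constraint that every test
  EC4 label also occurs in training.

Similarity filtering removes test proteins with a close training homolog,
judged from an alignment hit table (BLAST outfmt-6 style): a record is
dropped when some hit has percent identity at or above the threshold AND
alignment coverage >= 80% of either the query or the subject sequence.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ec import ECLabel, ProteinRecord, ec_prefix


@dataclass(frozen=True)
class SimilarityHit:
    """One alignment hit: query, subject, percent identity, aligned residues."""

    qseqid: str
    sseqid: str
    pident: float
    length: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident must be in [0,100], got {self.pident}")
        if self.length < 1:
            raise ValueError(f"alignment length must be >= 1, got {self.length}")


@dataclass
class SplitResult:
    train: list[ProteinRecord]
    test: list[ProteinRecord]
    mode: str  # "unseen" | "seen"
    provenance: dict[str, str] = field(default_factory=dict)  # EC4 group -> reason

    def validate(self) -> None:
        """Assert the split invariants for this mode; raises AssertionError."""
        train_entries = {r.entry for r in self.train}
        assert not train_entries & {r.entry for r in self.test}, "train/test share entries"
        train_ec4 = {str(r.ec) for r in self.train}
        test_ec4 = {str(r.ec) for r in self.test}
        if self.mode == "unseen":
            assert not train_ec4 & test_ec4, "unseen split shares EC4 labels"
            train_ec3 = {ec_prefix(r.ec, 3) for r in self.train}
            assert {ec_prefix(r.ec, 3) for r in self.test} <= train_ec3, \
                "test EC3 family missing from train"
        elif self.mode == "seen":
            assert test_ec4 <= train_ec4, "seen split has test label absent from train"


def build_unseen_split(records: Sequence[ProteinRecord], test_fraction: float) -> SplitResult:
    """EC4-grouped split with unseen test labels inside seen EC3 families.

    Per EC3 family the largest EC4 group (ties broken by canonical EC string)
    is assigned to training.  The remaining EC4 groups, sorted ascending by
    size (ties again by EC string), are appended whole to the test-candidate
    set until it first reaches ``ceil(test_fraction * N)``; the final group is
    added whole, so the test set may overshoot the target.  Deterministic.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    groups: dict[str, list[ProteinRecord]] = defaultdict(list)
    for r in records:
        groups[str(r.ec)].append(r)
    by_family: dict[str, list[str]] = defaultdict(list)
    for ec4 in groups:
        by_family[".".join(ec4.split(".")[:3])].append(ec4)

    provenance: dict[str, str] = {}
    candidates: list[str] = []
    for family, ec4s in by_family.items():
        largest = max(ec4s, key=lambda e: (len(groups[e]), _neg_lex(e)))
        provenance[largest] = "train:largest_in_family"
        for e in ec4s:
            if e != largest:
                candidates.append(e)

    target = math.ceil(test_fraction * len(records))
    candidates.sort(key=lambda e: (len(groups[e]), e))
    test_groups: list[str] = []
    size = 0
    for e in candidates:
        if size >= target:
            provenance[e] = "train:target_reached"
            continue
        test_groups.append(e)
        provenance[e] = "test:candidate"
        size += len(groups[e])

    test_set = set(test_groups)
    train = [r for r in records if str(r.ec) not in test_set]
    test = [r for r in records if str(r.ec) in test_set]
    result = SplitResult(train=train, test=test, mode="unseen", provenance=provenance)
    result.validate()
    return result


class _neg_lex:
    """Key wrapper reversing lexicographic order (for max-with-ascending-tiebreak)."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_neg_lex") -> bool:
        return self.s > other.s


def build_seen_split(
    records: Sequence[ProteinRecord], test_fraction: float, seed: int
) -> SplitResult:
    """Random split retaining only test records whose EC4 also occurs in training."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    n = len(records)
    n_test = math.ceil(test_fraction * n)
    idx = rng.permutation(n)
    test_idx = set(idx[:n_test].tolist())
    train = [records[i] for i in range(n) if i not in test_idx]
    train_labels = {str(r.ec) for r in train}
    candidates = [records[i] for i in sorted(test_idx)]
    test = [r for r in candidates if str(r.ec) in train_labels]
    dropped = len(candidates) - len(test)
    result = SplitResult(
        train=train,
        test=test,
        mode="seen",
        provenance={"dropped_unseen_label_candidates": str(dropped)},
    )
    result.validate()
    return result


def filter_by_similarity(
    test: Sequence[ProteinRecord],
    hits: Sequence[SimilarityHit],
    lengths: Mapping[str, int],
    identity_threshold: float,
    coverage_threshold: float = 0.8,
) -> list[ProteinRecord]:
    """Drop test records with a close training homolog.

    A record is removed iff some hit with it as query satisfies
    ``pident >= identity_threshold`` and alignment coverage
    ``length / len(query) >= coverage_threshold`` or
    ``length / len(subject) >= coverage_threshold``.  Coverage denominators
    are full (unaligned) sequence lengths.  Hits where a test id appears
    only as subject are ignored.
    """
    for h in hits:
        for hid in (h.qseqid, h.sseqid):
            if hid not in lengths:
                raise KeyError(f"hit references unknown id {hid!r}: no sequence length")
    removed: set[str] = set()
    for h in hits:
        if h.pident < identity_threshold:
            continue
        cov_q = h.length / lengths[h.qseqid]
        cov_s = h.length / lengths[h.sseqid]
        if cov_q >= coverage_threshold or cov_s >= coverage_threshold:
            removed.add(h.qseqid)
    return [r for r in test if r.entry not in removed]


def filter_experimental(test: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep only records whose annotation is experimentally supported.

    A missing flag (``None``) counts as not supported.
    """
    return [r for r in test if r.evidence_experimental is True]


@dataclass
class DatasetStats:
    n_records: int
    n_unique_ec4: int
    sequences_per_ec4: dict[str, int]
    sequences_per_ec1: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_unique_ec4": self.n_unique_ec4,
            "sequences_per_ec4": dict(self.sequences_per_ec4),
            "sequences_per_ec1": dict(self.sequences_per_ec1),
        }


def compute_dataset_stats(records: Sequence[ProteinRecord]) -> DatasetStats:
    per4 = Counter(str(r.ec) for r in records)
    per1 = Counter(ec_prefix(r.ec, 1) for r in records)
    return DatasetStats(
        n_records=len(records),
        n_unique_ec4=len(per4),
        sequences_per_ec4=dict(per4),
        sequences_per_ec1=dict(per1),
    )
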