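"""Synthetic datasets with a planted EC hierarchy.

Generates everything the pipeline consumes — valid four-level EC labels,
amino-acid sequences, base embeddings with hierarchical cluster structure,
evidence flags, and alignment hit tables — so every module can run and be
tested end-to-end without any download or pretrained encoder.

The embedding generative model mirrors the geometry the method assumes: a
four-level Gaussian hierarchy.  Each EC4 class mean is the sum of nested
offsets drawn at scales sigma1 > sigma2 > sigma3 > sigma4, so classes
sharing a longer EC prefix sit closer together; proteins scatter around
their EC4 mean with within-class noise sigma_e; pure-noise nuisance
dimensions are appended (mimicking directions of a pretrained embedding
that carry no functional signal) and the result is unit-normalized.

Class sizes reproduce the head-tail imbalance of real EC data: within each
EC3 family one EC4 class receives the top of the size range (the
"established" class the unseen split sends to training) and the rest draw
uniformly from the range.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import EmbeddingSet
from .ec import ECLabel, ProteinRecord
from .splits import SimilarityHit

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic benchmark (all seeded)."""

    n_ec1: int = 3
    n_ec2_per_ec1: int = 2
    n_ec3_per_ec2: int = 2
    n_ec4_per_ec3: int = 3
    proteins_per_ec4: tuple[int, int] = (6, 20)
    dim: int = 32                 # signal dimensions
    nuisance_dims: int = 16       # pure-noise dimensions appended (dim // 2)
    sigma1: float = 1.0
    sigma2: float = 0.5
    sigma3: float = 0.3
    sigma4: float = 0.12
    sigma_e: float = 0.25
    nuisance_scale: float = 1.0
    sequence_length: tuple[int, int] = (50, 200)
    evidence_rate: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sigma1 > self.sigma2 > self.sigma3 > self.sigma4 > 0):
            raise ValueError("need sigma1 > sigma2 > sigma3 > sigma4 > 0")
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")
        for name in ("n_ec1", "n_ec2_per_ec1", "n_ec3_per_ec2", "n_ec4_per_ec3", "dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nuisance_dims < 0:
            raise ValueError("nuisance_dims must be >= 0")
        lo, hi = self.proteins_per_ec4
        if not (1 <= lo <= hi):
            raise ValueError("proteins_per_ec4 range must satisfy 1 <= lo <= hi")
        if any(v >= 99 for v in (self.n_ec1, self.n_ec2_per_ec1,
                                 self.n_ec3_per_ec2, self.n_ec4_per_ec3)):
            raise ValueError("fan-out must stay below the forbidden field value 99")

    @property
    def total_dim(self) -> int:
        return self.dim + self.nuisance_dims


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    records: list[ProteinRecord]
    embeddings: EmbeddingSet
    class_means: dict[str, np.ndarray] = field(default_factory=dict)  # EC4 -> mean


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a full dataset: labels, sizes, embeddings, sequences, evidence flags."""
    rng = np.random.default_rng(spec.seed)
    d, dn = spec.dim, spec.nuisance_dims

    labels: list[ECLabel] = []
    means: dict[str, np.ndarray] = {}
    for e1 in range(1, spec.n_ec1 + 1):
        m1 = rng.normal(0.0, spec.sigma1, size=d)
        for e2 in range(1, spec.n_ec2_per_ec1 + 1):
            m2 = m1 + rng.normal(0.0, spec.sigma2, size=d)
            for e3 in range(1, spec.n_ec3_per_ec2 + 1):
                m3 = m2 + rng.normal(0.0, spec.sigma3, size=d)
                for e4 in range(1, spec.n_ec4_per_ec3 + 1):
                    lab = ECLabel((e1, e2, e3, e4))
                    labels.append(lab)
                    means[str(lab)] = m3 + rng.normal(0.0, spec.sigma4, size=d)

    lo, hi = spec.proteins_per_ec4
    records: list[ProteinRecord] = []
    vectors: list[np.ndarray] = []
    ids: list[str] = []
    counter = 0
    for lab in labels:
        # head-tail imbalance: serial 1 is the "established" head class
        size = hi if lab.fields[3] == 1 else int(rng.integers(lo, hi + 1))
        for _ in range(size):
            entry = f"P{counter:06d}"
            counter += 1
            signal = means[str(lab)] + rng.normal(0.0, spec.sigma_e, size=d)
            nuisance = rng.normal(0.0, spec.nuisance_scale, size=dn)
            vec = np.concatenate([signal, nuisance])
            vec = vec / np.linalg.norm(vec)
            length = int(rng.integers(spec.sequence_length[0],
                                      spec.sequence_length[1] + 1))
            seq = "".join(AMINO_ACIDS[i]
                          for i in rng.integers(0, len(AMINO_ACIDS), size=length))
            records.append(ProteinRecord(
                entry=entry, ec=lab, sequence=seq,
                evidence_experimental=bool(rng.random() < spec.evidence_rate)))
            ids.append(entry)
            vectors.append(vec)

    padded_means = {k: np.concatenate([v, np.zeros(dn)]) for k, v in means.items()}
    return SyntheticDataset(
        spec=spec,
        records=records,
        embeddings=EmbeddingSet(ids=ids, matrix=np.stack(vectors)),
        class_means=padded_means,
    )


class SyntheticProvider:
    """Frozen-encoder stand-in over a generated dataset.

    ``base_embedding`` returns the stored vector.  ``embed_sequence`` of an
    original sequence returns its stored embedding exactly; of a mask-
    augmented variant (one residue replaced by ``*``) it returns the owner's
    embedding plus a small deterministic perturbation (pre-normalization
    norm <= 0.05), so a masked view behaves as a near-duplicate positive.
    """

    PERTURBATION_NORM = 0.05

    def __init__(self, spec: SyntheticSpec, dataset: SyntheticDataset):
        self.spec = spec
        self.dataset = dataset
        self._by_entry = {r.entry: dataset.embeddings.vector(r.entry)
                          for r in dataset.records}
        self._by_sequence = {r.sequence: r.entry for r in dataset.records}

    def base_embedding(self, entry: str) -> np.ndarray:
        if entry not in self._by_entry:
            raise KeyError(f"unknown entry {entry!r}")
        return self._by_entry[entry]

    def embed_sequence(self, sequence: str) -> np.ndarray:
        if sequence in self._by_sequence:
            return self._by_entry[self._by_sequence[sequence]]
        owner = self._find_masked_owner(sequence)
        base = self._by_entry[owner]
        digest = zlib.crc32(sequence.encode()) ^ (self.spec.seed & 0x7FFFFFFF)
        rng = np.random.default_rng(digest)
        noise = rng.normal(0.0, 1.0, size=base.shape)
        noise *= self.PERTURBATION_NORM / np.linalg.norm(noise)
        vec = base + noise
        return vec / np.linalg.norm(vec)

    def _find_masked_owner(self, sequence: str) -> str:
        for original, entry in self._by_sequence.items():
            if len(original) != len(sequence):
                continue
            if all(a == b or a == "*" for a, b in zip(sequence, original)):
                return entry
        raise KeyError("sequence matches no dataset record (even allowing masks)")


def synthetic_provider(spec: SyntheticSpec, dataset: SyntheticDataset) -> SyntheticProvider:
    return SyntheticProvider(spec, dataset)


def generate_hit_table(
    records: Sequence[ProteinRecord],
    embeddings: EmbeddingSet,
    seed: int,
    hits_per_record: int = 4,
) -> list[SimilarityHit]:
    """Emit an alignment hit table whose identities track embedding similarity.

    Percent identity = 50*(1 + cosine) plus Gaussian noise (sd 12), clipped
    to [1, 100], so the 10/30/50% identity-threshold regimes are all
    populated; alignment length is a uniform 0.3-1.0 fraction of the shorter
    sequence, exercising both branches of the coverage rule.
    """
    if not records:
        return []
    rng = np.random.default_rng(seed)
    n = len(records)
    hits: list[SimilarityHit] = []
    for i, rec in enumerate(records):
        others = [j for j in range(n) if j != i]
        if not others:
            continue
        chosen = rng.choice(others, size=min(hits_per_record, len(others)),
                            replace=False)
        zi = embeddings.vector(rec.entry)
        for j in chosen:
            other = records[int(j)]
            cos = float(zi @ embeddings.vector(other.entry))
            pident = float(np.clip(50.0 * (1.0 + cos) + rng.normal(0, 12.0), 1.0, 100.0))
            frac = rng.uniform(0.3, 1.0)
            length = max(1, int(frac * min(len(rec.sequence), len(other.sequence))))
            hits.append(SimilarityHit(qseqid=rec.entry, sseqid=other.entry,
                                      pident=round(pident, 1), length=length))
    return hits
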