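"""In-memory containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EmbeddingSet:
    """A record-ID-keyed matrix of fixed-length real vectors.

    Rows of ``matrix`` align with ``ids``; vectors may be base (frozen)
    embeddings or projected unit vectors depending on provenance.
    """

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.matrix.shape[0]} matrix rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in embedding set")
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, entry: str) -> bool:
        return entry in self._index

    def vector(self, entry: str) -> np.ndarray:
        return self.matrix[self._index[entry]]

    def row(self, entry: str) -> int:
        return self._index[entry]

    def subset(self, entries: list[str]) -> "EmbeddingSet":
        rows = [self._index[e] for e in entries]
        return EmbeddingSet(ids=list(entries), matrix=self.matrix[rows].copy())
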