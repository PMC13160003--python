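"""Shared fixtures and an independent scalar-loop oracle for the losses.

The oracle deliberately avoids the package's vectorized code paths: plain
Python loops, ``math.exp`` / ``math.log``, explicit max-shift for
stability.  It exists so vectorized losses are checked against a second,
independently written computation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from hince.ec import ECLabel, ec_prefix
from hince.losses import ContrastiveBatch


# ---------------------------------------------------------------- oracle

def _dot(a, b):
    return sum(x * y for x, y in zip(a, b))


def _lse(vals):
    m = max(vals)
    return m + math.log(sum(math.exp(v - m) for v in vals))


def oracle_instance(z_a, positives, negatives, tau):
    sims = [_dot(z_a, p) / tau for p in positives] + \
           [_dot(z_a, n) / tau for n in negatives]
    lse = _lse(sims)
    return -sum(_dot(z_a, p) / tau - lse for p in positives) / len(positives)


def oracle_centroids(vectors, labels, depth):
    groups = {}
    for vec, lab in zip(vectors, labels):
        groups.setdefault(ec_prefix(lab, depth), []).append(vec)
    table = {}
    for c, members in groups.items():
        dim = len(members[0])
        mean = [sum(m[j] for m in members) / len(members) for j in range(dim)]
        table[c] = (mean, members)
    return table


def oracle_exemplar_depth(i, vectors, labels, depth, tau):
    table = oracle_centroids(vectors, labels, depth)
    c_a = ec_prefix(labels[i], depth)
    mean, members = table[c_a]
    z_a = vectors[i]
    if len(members) > 1:
        dim = len(z_a)
        loo = [(sum(m[j] for m in members) - z_a[j]) / (len(members) - 1)
               for j in range(dim)]
    else:
        loo = mean
    num = _dot(z_a, loo) / tau
    den = _lse([_dot(z_a, m) / tau for m, _ in table.values()])
    return -(num - den)


def oracle_exemplar(i, vectors, labels, tau):
    return sum(oracle_exemplar_depth(i, vectors, labels, d, tau)
               for d in (1, 2, 3, 4)) / 4.0


def oracle_hince(batch: ContrastiveBatch, lambda_inst, lambda_exem, tau):
    Z = [list(map(float, row)) for row in np.atleast_2d(batch.embeddings)]
    anchors = [int(a) for a in batch.anchor_idx]
    anchor_vecs = [Z[a] for a in anchors]
    total_i, total_e = 0.0, 0.0
    for k, a in enumerate(anchors):
        if lambda_inst > 0:
            total_i += oracle_instance(
                Z[a],
                [Z[int(p)] for p in batch.pos_sets[k]],
                [Z[int(n)] for n in batch.neg_sets[k]],
                tau)
        if lambda_exem > 0:
            total_e += oracle_exemplar(k, anchor_vecs, batch.anchor_labels, tau)
    B = len(anchors)
    return (lambda_inst * total_i / B + lambda_exem * total_e / B,
            total_i / B, total_e / B)


# --------------------------------------------------------------- fixtures

def random_labeled_batch(rng, n_anchors=8, dim=6, max_field=3,
                         n_pos=2, n_neg=4):
    """A valid ContrastiveBatch with random unit vectors and random EC labels."""
    n_extra = n_anchors * (n_pos + 1)
    n = n_anchors + n_extra
    Z = rng.normal(size=(n, dim))
    Z /= np.linalg.norm(Z, axis=1, keepdims=True)
    labels = [ECLabel(tuple(int(x) for x in rng.integers(1, max_field + 1, size=4)))
              for _ in range(n)]
    pos_sets, neg_sets = [], []
    cursor = n_anchors
    for i in range(n_anchors):  # first pass: fix all labels (forced positives)
        pos = []
        for _ in range(n_pos):
            labels[cursor] = labels[i]  # force same-EC4 positives
            pos.append(cursor)
            cursor += 1
        pos_sets.append(np.asarray(pos))
    for i in range(n_anchors):  # second pass: negatives against final labels
        ec4 = str(labels[i])
        neg_pool = [j for j in range(n) if str(labels[j]) != ec4]
        neg = list(rng.choice(neg_pool, size=min(n_neg, len(neg_pool)),
                              replace=False))
        neg_sets.append(np.asarray(neg, dtype=int))
    batch = ContrastiveBatch(
        embeddings=Z,
        anchor_idx=np.arange(n_anchors),
        anchor_labels=labels[:n_anchors],
        pos_sets=pos_sets,
        neg_sets=neg_sets,
        row_labels=labels,
    )
    batch.validate()
    return batch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_records():
    """13 records over two EC3 families, matching the worked split example."""
    from hince.ec import ProteinRecord

    def rec(entry, ec, seq="ACDEFGHIK"):
        from hince.ec import normalize_and_parse
        return ProteinRecord(entry=entry, ec=normalize_and_parse(ec), sequence=seq)

    sizes = {"1.1.1.1": 5, "1.1.1.2": 2, "1.1.1.3": 1, "2.1.3.4": 4, "2.1.3.9": 1}
    records, k = [], 0
    for ec, n in sizes.items():
        for _ in range(n):
            records.append(rec(f"P{k:02d}", ec))
            k += 1
    return records
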