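"""The HiNCE objective: instance supervised contrastive loss + hierarchical exemplar NCE.

Two terms shape the projected space:

* **instance term** — for an anchor embedding z_a with sampled positives P_a
  (same EC4) and negatives N_a (different EC4), S_a = P_a u N_a:

      L_inst(a) = -(1/|P_a|) sum_{p in P_a} log
                  [ exp(z_a.z_p / tau) / sum_{u in S_a} exp(z_a.z_u / tau) ]

* **exemplar term** — for each hierarchy depth l in {1,2,3,4}, class
  centroids are the plain means of the batch-anchor embeddings sharing the
  depth-l EC prefix (no renormalization).  The anchor is classified against
  all depth-l centroids by a softmax, with a leave-one-out (LOO) centroid in
  the numerator so the anchor does not attract itself:

      L_exem^l(a) = -log [ exp(z_a.mu~_{c_a} / tau)
                           / sum_c exp(z_a.mu_c / tau) ]

  where mu~ is the LOO centroid when the anchor's class has more than one
  member and the full centroid otherwise; the denominator always uses full
  centroids, including the anchor's own class.  L_exem(a) averages the four
  depths.

The combined loss over a batch of B anchors is

    L = (1/B) sum_a [ lambda_inst * L_inst(a) + lambda_exem * L_exem(a) ].

All losses use overflow-safe log-sum-exp.  :func:`hince_loss_and_grad`
additionally returns the analytic gradient with respect to every embedding
row, derived by hand and checked against finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp, softmax

from .ec import ECLabel, ec_prefix

DEPTHS = (1, 2, 3, 4)


@dataclass
class LossWeights:
    """Trade-off between local instance discrimination and hierarchy shaping."""

    lambda_inst: float = 1.0
    lambda_exem: float = 1.0
    tau: float = 0.1

    def __post_init__(self) -> None:
        if self.lambda_inst < 0 or self.lambda_exem < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda_inst == 0 and self.lambda_exem == 0:
            raise ValueError("at least one loss weight must be positive")
        if self.tau <= 0:
            raise ValueError(f"temperature must be positive, got {self.tau}")


@dataclass
class ContrastiveBatch:
    """Embeddings plus per-anchor positive/negative index sets.

    ``embeddings`` holds every referenced vector (anchors, sampled positives
    and negatives, augmented views) as rows.  ``anchor_idx[i]`` is the row of
    the i-th anchor and ``anchor_labels[i]`` its EC4 label; centroids are
    computed from anchor rows only.  ``row_labels``, when given, labels every
    row and enables validation that positives share the anchor's EC4 and
    negatives do not.
    """

    embeddings: np.ndarray
    anchor_idx: np.ndarray
    anchor_labels: list[ECLabel]
    pos_sets: list[np.ndarray]
    neg_sets: list[np.ndarray]
    row_labels: Optional[list[ECLabel]] = None

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_idx)

    def validate(self) -> None:
        B = self.n_anchors
        assert len(self.anchor_labels) == B and len(self.pos_sets) == B \
            and len(self.neg_sets) == B
        for i in range(B):
            assert len(self.pos_sets[i]) >= 1, f"anchor {i} has no positives"
            if self.row_labels is not None:
                ec4 = str(self.anchor_labels[i])
                assert all(str(self.row_labels[int(p)]) == ec4
                           for p in self.pos_sets[i]), "positive with wrong EC4"
                assert all(str(self.row_labels[int(n)]) != ec4
                           for n in self.neg_sets[i]), "negative sharing anchor EC4"


def instance_loss(
    anchor: np.ndarray,
    positives: np.ndarray,
    negatives: np.ndarray,
    tau: float,
) -> float:
    """Supervised contrastive loss for one anchor (overflow-safe)."""
    positives = np.atleast_2d(positives)
    negatives = (np.atleast_2d(negatives) if np.size(negatives)
                 else np.empty((0, len(anchor))))
    if positives.shape[0] < 1:
        raise ValueError("instance loss requires at least one positive")
    sims_p = positives @ anchor / tau
    sims_all = np.concatenate([sims_p, negatives @ anchor / tau])
    lse = logsumexp(sims_all)
    return float(-(np.mean(sims_p) - lse))


@dataclass
class Centroid:
    """Per-class mean of member embeddings, with bookkeeping for LOO updates."""

    mean: np.ndarray
    total: np.ndarray
    count: int
    member_idx: np.ndarray


def compute_centroids(
    embeddings: np.ndarray,
    labels: Sequence[ECLabel],
    depth: int,
) -> dict[str, Centroid]:
    """Arithmetic-mean centroids of the depth-``depth`` prefix classes.

    Centroids are plain means of member embeddings — not renormalized.
    """
    embeddings = np.atleast_2d(embeddings)
    if len(labels) != embeddings.shape[0]:
        raise ValueError("embeddings and labels must be aligned")
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(ec_prefix(lab, depth), []).append(i)
    table: dict[str, Centroid] = {}
    for prefix, idx in groups.items():
        members = embeddings[idx]
        total = members.sum(axis=0)
        table[prefix] = Centroid(
            mean=total / len(idx),
            total=total,
            count=len(idx),
            member_idx=np.asarray(idx, dtype=int),
        )
    return table


def loo_centroid(centroid: Centroid, anchor_index: int, embeddings: np.ndarray) -> np.ndarray:
    """Leave-one-out centroid of the anchor's class.

    ``(total - z_a) / (n - 1)`` when the class has n > 1 members; for a
    singleton class the full centroid (which equals z_a) is returned.
    """
    if anchor_index not in centroid.member_idx:
        raise ValueError(f"anchor row {anchor_index} is not a member of this class")
    if centroid.count > 1:
        return (centroid.total - embeddings[anchor_index]) / (centroid.count - 1)
    return centroid.mean


def exemplar_loss_at_depth(
    anchor_index: int,
    embeddings: np.ndarray,
    labels: Sequence[ECLabel],
    depth: int,
    tau: float,
    table: Optional[dict[str, Centroid]] = None,
) -> float:
    """Exemplar NCE of one anchor against all depth-``depth`` batch centroids.

    The numerator uses the LOO centroid of the anchor's class; the
    denominator sums full centroids over every class at this depth,
    the anchor's own class included.
    """
    if table is None:
        table = compute_centroids(embeddings, labels, depth)
    prefix = ec_prefix(labels[anchor_index], depth)
    if prefix not in table:
        raise ValueError(f"anchor class {prefix!r} absent from centroid table")
    z_a = embeddings[anchor_index]
    mu_t = loo_centroid(table[prefix], anchor_index, embeddings)
    sims = np.array([z_a @ c.mean / tau for c in table.values()])
    return float(-(z_a @ mu_t / tau - logsumexp(sims)))


def exemplar_loss(
    anchor_index: int,
    embeddings: np.ndarray,
    labels: Sequence[ECLabel],
    tau: float,
    tables: Optional[dict[int, dict[str, Centroid]]] = None,
) -> float:
    """Mean of the per-depth exemplar losses over depths 1..4."""
    vals = []
    for depth in DEPTHS:
        table = tables[depth] if tables is not None else None
        vals.append(exemplar_loss_at_depth(anchor_index, embeddings, labels,
                                           depth, tau, table=table))
    return float(np.mean(vals))


@dataclass
class HinceLoss:
    """Total loss plus the two component means, for logging."""

    total: float
    instance_mean: float
    exemplar_mean: float


def hince_loss(batch: ContrastiveBatch, weights: LossWeights) -> HinceLoss:
    """Combined HiNCE loss over a batch (value only)."""
    value, _ = _hince(batch, weights, want_grad=False)
    return value


def hince_loss_and_grad(
    batch: ContrastiveBatch, weights: LossWeights
) -> tuple[HinceLoss, np.ndarray]:
    """Combined loss and its analytic gradient w.r.t. every embedding row."""
    return _hince(batch, weights, want_grad=True)


def _hince(
    batch: ContrastiveBatch, weights: LossWeights, want_grad: bool
) -> tuple[HinceLoss, Optional[np.ndarray]]:
    Z = np.atleast_2d(np.asarray(batch.embeddings, dtype=np.float64))
    B = batch.n_anchors
    if B < 1:
        raise ValueError("batch has no anchors")
    tau = weights.tau
    dZ = np.zeros_like(Z) if want_grad else None

    anchors = np.asarray(batch.anchor_idx, dtype=int)
    Z_anchor = Z[anchors]

    inst_vals = np.zeros(B)
    if weights.lambda_inst > 0:
        scale = weights.lambda_inst / B
        for i in range(B):
            a = int(anchors[i])
            z_a = Z[a]
            pos = np.asarray(batch.pos_sets[i], dtype=int)
            neg = np.asarray(batch.neg_sets[i], dtype=int)
            if len(pos) < 1:
                raise ValueError(f"anchor {i} has no positives")
            s_idx = np.concatenate([pos, neg])
            sims = Z[s_idx] @ z_a / tau
            lse = logsumexp(sims)
            n_p = len(pos)
            inst_vals[i] = -(np.mean(sims[:n_p]) - lse)
            if want_grad:
                w = softmax(sims)  # weights over S_a
                # d/dz_a
                dZ[a] += scale * (
                    -(Z[pos].sum(axis=0) / n_p) / tau
                    + (w[:, None] * Z[s_idx]).sum(axis=0) / tau
                )
                # d/dz_u for members of S_a (accumulate per occurrence)
                coeff = w / tau
                coeff[:n_p] -= 1.0 / (n_p * tau)
                np.add.at(dZ, s_idx, scale * coeff[:, None] * z_a)

    exem_vals = np.zeros(B)
    if weights.lambda_exem > 0:
        scale = weights.lambda_exem / (B * len(DEPTHS))
        for depth in DEPTHS:
            table = compute_centroids(Z_anchor, batch.anchor_labels, depth)
            classes = list(table.keys())
            mus = np.stack([table[c].mean for c in classes])
            class_of = {c: k for k, c in enumerate(classes)}
            for i in range(B):
                a = int(anchors[i])
                z_a = Z[a]
                prefix = ec_prefix(batch.anchor_labels[i], depth)
                cen = table[prefix]
                n_a = cen.count
                if n_a > 1:
                    mu_t = (cen.total - z_a) / (n_a - 1)
                else:
                    mu_t = cen.mean
                p = mus @ z_a / tau
                lse = logsumexp(p)
                exem_vals[i] += (-(z_a @ mu_t / tau - lse)) / len(DEPTHS)
                if want_grad:
                    v = softmax(p)
                    # numerator: -(1/tau) dq/dz
                    if n_a > 1:
                        # d(z_a . mu~)/dz_a = mu~ : the class total contains z_a,
                        # so the product-rule terms collapse to (total - z_a)/(n-1)
                        dZ[a] += scale * (-mu_t / tau)
                        member_rows = anchors[cen.member_idx]
                        others = member_rows[member_rows != a]
                        np.add.at(dZ, others, -scale * z_a / ((n_a - 1) * tau))
                    else:
                        dZ[a] += scale * (-(2.0 * z_a) / tau)
                    # denominator: +(1/tau) sum_c v_c dp_c/dz
                    dZ[a] += scale * ((v[:, None] * mus).sum(axis=0) / tau)
                    dZ[a] += scale * (v[class_of[prefix]] * z_a / (cen.count * tau))
                    for c in classes:
                        cen_c = table[c]
                        member_rows = anchors[cen_c.member_idx]
                        others = member_rows[member_rows != a]
                        np.add.at(dZ, others,
                                  scale * v[class_of[c]] * z_a / (cen_c.count * tau))

    inst_mean = float(np.mean(inst_vals)) if weights.lambda_inst > 0 else 0.0
    exem_mean = float(np.mean(exem_vals)) if weights.lambda_exem > 0 else 0.0
    total = weights.lambda_inst * inst_mean + weights.lambda_exem * exem_mean
    return HinceLoss(total=total, instance_mean=inst_mean, exemplar_mean=exem_mean), dZ
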