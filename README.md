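# hince

Hierarchy-aware contrastive embeddings for placing enzymes with **unseen EC
numbers** into their correct EC1–3 functional neighborhoods.

## The problem

The Enzyme Commission (EC) system classifies enzyme function with four
hierarchical fields `class.subclass.sub-subclass.serial` (e.g. `2.1.3.4`).
High-throughput sequencing keeps producing enzymes whose exact function —
the fourth, serial field — has never been characterized: no training example
carries their EC4 label. A classifier over known labels cannot help, but
*placing* such a protein in the right EC3 family (reaction chemistry) still
narrows the experimental search space enormously: distinguishing a
phosphodiesterase from a kinase is a large reduction in functional
uncertainty.

`hince` learns an embedding space in which nearest-neighbor label transfer
remains informative at EC1–3 even when EC4 labels shift. It is aimed at
computational biologists benchmarking enzyme-function annotation under
unseen-label evaluation protocols.

## The model

Frozen per-protein embeddings h(x) ∈ R^d (e.g. from a pretrained protein
language model) are mapped by a small trainable MLP f_θ and ℓ2-normalized:

    z = norm(f_θ(h(x))) ∈ R^D .

The space is shaped by the **HiNCE** objective, the sum of two terms over a
mini-batch of B anchors:

* **Instance supervised contrastive loss.** For anchor z_a with sampled
  positives 𝒫_a (same EC4) and negatives 𝒩_a (different EC4),
  𝒮_a = 𝒫_a ∪ 𝒩_a:

      L_inst(a) = −(1/|𝒫_a|) Σ_{p∈𝒫_a} log [ exp(z_aᵀz_p/τ) / Σ_{u∈𝒮_a} exp(z_aᵀz_u/τ) ] .

* **Hierarchical exemplar NCE.** At each depth ℓ ∈ {1,2,3,4}, centroids
  μ_c^(ℓ) are plain means of the batch-anchor embeddings sharing the depth-ℓ
  EC prefix c. The anchor is softmax-classified against all depth-ℓ
  centroids, with a leave-one-out centroid μ̃ in the numerator so it does not
  attract itself:

      L_exem^(ℓ)(a) = −log [ exp(z_aᵀμ̃_{c_a}^(ℓ)/τ) / Σ_c exp(z_aᵀμ_c^(ℓ)/τ) ] ,
      L_exem(a) = (1/4) Σ_ℓ L_exem^(ℓ)(a) .

* **Combined:** L = (1/B) Σ_a [ λ_inst L_inst(a) + λ_exem L_exem(a) ],
  τ = 0.1 by default.

Negatives are mined *hard*: a periodically refreshed distance map stores,
per training protein, its most similar different-EC4 neighbors in the
current learned space, and negatives are drawn preferentially from those
confusable classes. Singleton EC4 classes contribute a positive pair via a
mask-augmented sequence view (one residue replaced by `*`, re-embedded by
the frozen encoder).

At test time a query is projected and assigned the EC4 label of its nearest
training neighbor (cosine similarity; k-NN voting available). Evaluation
compares EC prefixes at depths 1–3: accuracy and macro-averaged
precision/recall/F1, with a nonparametric bootstrap (1,000 resamples)
reported as mean ± half of the 95% percentile-interval width.

The package also implements the full data machinery: EC label cleaning
(multifunction removal, invalid/99 rejection, EC-sequence deduplication),
the unseen (EC4-grouped) and seen (random) splits, BLAST-style
identity/coverage filtering, evidence filtering, and a synthetic-data
generator with a planted four-level Gaussian hierarchy so the whole
pipeline runs with no downloads.

## Worked example

```python
from hince.benchmark import run_hierarchy_recovery

result = run_hierarchy_recovery(seed=1)
print("EC3 accuracy (learned space):", result.accuracy_trained[3])
print("EC3 accuracy (raw embeddings):", result.accuracy_raw[3])
print("chance:", round(result.chance_ec3, 3))
print("hierarchy gap:", round(result.gap_before, 3), "->",
      round(result.gap_after, 3))
```

prints

```
EC3 accuracy (learned space): 1.0
EC3 accuracy (raw embeddings): 0.8833333333333333
chance: 0.083
hierarchy gap: 0.631 -> 1.05
```

This generates a synthetic corpus (3×2×2×3 EC hierarchy, 6–20 proteins per
EC4 class, half the embedding dimensions pure noise), builds the unseen
split — test proteins' EC4 labels never occur in training, their EC3
families do — trains the projection head, and transfers labels by nearest
neighbor. In the learned space every unseen test protein is placed in its
correct EC3 family, while raw-embedding transfer errs on 12% of them
(chance would be 8.3%). The "hierarchy gap" (mean within-EC3 pairwise
cosine minus mean between-EC1 cosine on training proteins) widening from
0.63 to 1.05 shows the geometry was reshaped toward the EC hierarchy, not
just toward flat EC4 separation.

The same pipeline is scriptable from the shell:

```bash
hince simulate --seed 1 --out-dir fixtures/
hince split-unseen --labels fixtures/labels.tsv --test-fraction 0.2 --out split.tsv
hince train --embeddings train_emb.tsv --labels train_labels.tsv \
            --seed 1 --out model.json
hince predict --model model.json --reference train_emb.tsv \
              --reference-labels train_labels.tsv --query test_emb.tsv --out preds.tsv
hince evaluate --predictions preds.tsv --truth test_labels.tsv \
               --depths 1,2,3 --bootstrap 1000 --seed 1 --out metrics.json
```

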