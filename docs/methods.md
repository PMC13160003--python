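# Methods

## Scope and model

`hince` learns a metric space for enzyme function placement. The inputs are
frozen fixed-length protein embeddings (the package never computes
sequence→embedding itself; an `EmbeddingProvider` contract supplies
vectors, and the synthetic generator implements that contract for
self-contained runs). A multi-layer perceptron followed by ℓ2 normalization
maps base embeddings to unit vectors; similarity is the inner product
(cosine). Training minimizes the combined objective

L = (1/B) Σ_a [ λ_inst·L_inst(a) + λ_exem·L_exem(a) ]

whose two terms are documented in the README and in `hince/losses.py`. The
exemplar term is what distinguishes this objective from flat supervised
contrastive learning: per-depth class centroids inject the four-level EC
hierarchy into the geometry, so neighborhoods stay informative at EC1–3
when the exact EC4 label has never been seen.

### Conventions fixed by the objective's definition

- Centroids are arithmetic means of the *batch anchors'* embeddings only;
  sampled positives/negatives do not enter centroids.
- Centroids are **not** renormalized to unit length.
- The exemplar numerator uses the leave-one-out centroid of the anchor's
  class (full centroid for singletons); the denominator sums **full**
  centroids over all classes at that depth, the anchor's own class
  included.
- The depth average runs over all four depths, including depths where the
  anchor's class is the only one in the batch (such a depth contributes a
  small positive constant, not zero, because the numerator is LOO while the
  denominator is not).
- All soft-max computations go through log-sum-exp; losses are finite for
  unit-norm inputs and τ ∈ [0.01, 10].

An alternative reading in which the denominator also uses the LOO centroid
for the anchor's own class is plausible; we implement the definition above
and treat the variant as out of scope.

## Gradients and optimization

The projection head, the loss gradients, and the Adam optimizer are
implemented directly in NumPy. Gradients of the combined loss with respect
to every embedding row are derived analytically (the product rule through
the batch centroids and the LOO centroid is the only subtle part:
∂(z_aᵀμ̃)/∂z_a collapses to μ̃ because the class total contains z_a), then
back-propagated through the normalization and the affine/tanh stack. The
test suite checks these gradients against central finite differences
(1e-4 step, 1e-4 relative tolerance) on random batches, and the losses
against independent scalar-loop oracles on 50 random batches at 1e-6.

Defaults: two hidden layers of max(D, d/2) units, tanh, output D = 128,
Glorot-uniform seeded initialization; Adam with learning rate 1e-3;
τ = 0.1; λ_inst = λ_exem = 1. The head's architecture and the loss weights
are engineering choices exposed in `ProjectionConfig` / `LossWeights`.

## Training loop

Each epoch shuffles training entries into batches of 32 anchors. Per
anchor, 2 positives are drawn uniformly from its EC4 class and 8 negatives
are drawn from a *hard-negative* pool with probability p_hard = 0.7 (else
uniformly over different-EC4 proteins). The pool is defined by a distance
map — per protein, the K = 20 most similar different-EC4 proteins in the
current projected space, ties broken by entry id — rebuilt every 5 epochs
(and at epoch 0), so the map's staleness never exceeds the refresh
interval. A negative is sampled by picking a distinct EC4 class occurring
in the shortlist uniformly, then a uniform member of that class; this
reconciles the protein-level shortlist with class-level pooling. Positives
and negatives are projected with the current parameters in the same
forward pass as anchors, so every sampled embedding receives gradient.

Singleton EC4 classes would otherwise starve of positives: before
training, each gets an augmented view — one residue replaced by the mask
character `*`, re-embedded by the frozen provider — registered as a
same-label positive row. K, p_hard, sampling counts, refresh interval and
batch size are engineering defaults, all exposed in `TrainConfig`.

All randomness (initialization, shuffling, sampling, augmentation
positions, validation holdout) flows from a single integer seed through
NumPy generators; identical config + seed + data reproduces parameters
bit-for-bit.

## Data cleaning and splits

Cleaning applies three ordered rules to (entry, raw EC, sequence) rows,
counting each row under the first rule that removes it: (1) every row of an
entry carrying ≥ 2 distinct EC strings (multifunction enzymes — including
entries mixing one valid and one malformed EC); (2) rows whose EC fails
normalization — fewer than four fields, non-digit fields after stripping an
optional `EC` prefix and whitespace, or any field equal to 99 (the EC
catch-all; we reject a *field* equal to 99, not the substring, which would
wrongly reject classes like 199); (3) duplicate (canonical EC, sequence)
pairs, keeping the first in input order. Cleaning is idempotent.

The **unseen split** groups records by EC4. Per EC3 family the largest EC4
group (ties: lexicographically smallest EC string) is assigned to training
as the established class; the remaining groups, ascending by size (same
tie-break), fill the test-candidate set whole-group-at-a-time until it
first reaches ⌈test_fraction·N⌉ — the last group is added whole, so the
test side may overshoot the target. N is the total cleaned record count.
The construction guarantees EC4-disjoint train/test with every test EC3
family present in training, and is deterministic. The **seen split** is a
seeded uniform sample of ⌈test_fraction·N⌉ candidates, dropping candidates
whose EC4 vanished from the training pool.

Similarity filtering consumes a BLAST-tabular hit table (qseqid, sseqid,
pident, length; extra columns ignored) with test records as queries: a
record is removed iff some hit reaches the identity threshold *and* covers
≥ 80% of either the query or the subject, with full (unaligned) sequence
lengths as coverage denominators — the hit table itself does not define
coverage, so this is our convention. Hits listing a test id only as
subject are ignored. Evidence filtering keeps records whose
(entry, EC, sequence) annotation is flagged experimentally supported; a
missing flag counts as unsupported.

## Evaluation

Prefix metrics at depth ℓ compare the first ℓ EC fields of prediction and
truth. Macro precision/recall/F1 average over the **union** of true and
predicted prefix classes with the zero-division→0 convention (union
penalizes spurious predicted classes symmetrically; a truth-only variant is
available as `class_set="truth"`). Per-class F1 is the harmonic mean of
that class's precision and recall; macro F1 averages per-class F1 values.
Accuracy is non-increasing in depth by construction. Uncertainty is a
nonparametric bootstrap over test proteins (default 1,000 resamples),
reported as bootstrap mean ± half the width of the 95% percentile interval
— percentile, not BCa. Nearest-neighbor ties resolve to the smallest entry
id; k-NN voting breaks ties by vote count, then summed similarity, then
smallest id.

## Synthetic generator

The generator emulates the statistical shape of curated enzyme corpora
while staying fully self-contained:

- **Hierarchy**: a proper 4-level label tree (defaults 3×2×2×3 = 36 EC4
  classes in 12 EC3 families). Fields are small positive integers, never 99.
- **Embeddings**: EC4 class means are nested Gaussian offsets with scales
  σ1 = 1.0 > σ2 = 0.5 > σ3 = 0.3 > σ4 = 0.12 over d = 32 signal
  dimensions, so sharing a longer EC prefix means a closer mean. Proteins
  scatter around their class mean with σ_e = 0.25 — deliberately larger
  than σ4, making exact-EC4 discrimination hard while EC3 structure stays
  recoverable, which is the regime the method targets. Half as many
  (16) pure-noise nuisance dimensions at scale 1.0 are appended, standing
  in for directions of pretrained embeddings that carry no functional
  signal; vectors are then unit-normalized.
- **Head–tail imbalance**: per EC3 family, serial 1 receives the top of the
  6–20 per-class size range (the "established" class the unseen split
  sends to training); other classes draw uniformly.
- **Sequences** are uniform random amino-acid strings (50–200 residues);
  they carry no homology signal and exist to exercise masking, FASTA I/O
  and joins.
- **Provider**: re-embedding an original sequence returns its stored
  vector; a mask-augmented variant returns the owner's vector plus a
  deterministic perturbation of pre-normalization norm ≤ 0.05 (cosine
  ≥ 0.99), a near-duplicate positive.
- **Hit table**: percent identity is 50·(1+cosine) plus Gaussian noise
  (sd 12), clipped to [1, 100], populating the 10/30/50% threshold regimes;
  alignment length is a uniform 0.3–1.0 fraction of the shorter sequence.

What passing the synthetic benchmark does and does not show: it
demonstrates that the objective, mining, and transfer machinery recover a
planted hierarchy from noisy, nuisance-diluted features — it does **not**
demonstrate performance on real protein-language-model embeddings, whose
geometry is not Gaussian, whose class structure is far less separable, and
where sequence homology correlates with function. Real-data accuracy
claims require real embeddings and are out of scope here.

## Benchmark problem sizes

The end-to-end benchmark (`hince.benchmark.run_hierarchy_recovery`, also
driven by `scripts/acceptance.py`) uses the generator defaults above
(~550 proteins, ~430 train / ~120 unseen test after the EC4-grouped split)
and the training defaults (50 epochs, batch 32). These desk-scale sizes
keep a full run around a minute on one CPU while leaving a clear margin
between learned-space transfer, raw-embedding transfer, and chance. The
CLI pipeline tests use a smaller 2×2×2×2 hierarchy and short training
purely to exercise composition and determinism.

## Degenerate inputs and numerical choices

- A projector whose pre-normalization output is numerically zero raises a
  `DegenerateEmbeddingError` rather than dividing by zero.
- Rejected EC strings are *values* with reasons (`incomplete`, `invalid`,
  `forbidden_99`), not exceptions; readers surface rejects with line
  numbers instead of dropping rows silently.
- Empty inputs yield empty outputs with zeroed reports throughout.
- Embedding TSV round-trips use full `repr` precision (< 1e-12 error);
  split manifests, metrics and reports are TSV/JSON.

## Known limitations

- Single-label enzymes only; multifunction proteins are removed during
  cleaning rather than modeled.
- The mined-negative pool samples classes uniformly from the shortlist;
  rank-weighted sampling might mine harder negatives.
- Exact k-NN by brute force; fine at desk scale, would need an ANN index
  for corpora in the 10^5–10^6 range.
- Validation holdout reports EC4 NN accuracy for monitoring only; no
  automated hyper-parameter search is included.
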