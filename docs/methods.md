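# Methods

## Problem and model

Given an assembled plasmid contig, the package predicts its bacterial host
taxon top-down through a fixed seven-level taxonomy (a synthetic root plus
phylum, class, order, family, genus, species). The taxonomy of the training
plasmids' hosts forms the *backbone tree*; every internal node with more than
one child owns its own classifier, and nodes with a single child are descended
automatically. A query therefore triggers at most six classifier decisions,
and usually fewer.

Each per-node classifier consumes three views of the contig:

1. **Protein-cluster (PC) sentence** — the contig's predicted proteins, in
   gene order, mapped to protein-cluster tokens. Clusters come from Markov
   Clustering (MCL) of the all-vs-all protein similarity graph: nodes are
   proteins, edge weights are `-log10(E)` of the best alignment E-value
   (edges only for E ≤ 1e-3; weights capped at 300 so E = 0 stays finite).
   MCL alternates *expansion* (squaring the column-stochastic matrix) and
   *inflation* (elementwise power 2.0, then renormalization), pruning entries
   below 1e-5, until the iteration is stationary; clusters are the connected
   components of the limit matrix, and only clusters with ≥ 2 members become
   vocabulary tokens (token 0 is padding). Each protein takes the token of
   its minimum-E-value hit into a clustered member; ties resolve to the lower
   token id. The sentence is truncated/padded to 400 slots, and each kept
   token carries its 1-based protein ordinal as the position index.
2. **MOB/MPF sentence** — conjugation-typing annotations (9 relaxase MOB
   families + 4 mating-pair-formation MPF types = 13 tokens) in gene order,
   padded to 50 slots. The type-to-token mapping is configurable data
   (`MobMpfVocabulary`), because the published figure's numbering (MOBF = 6,
   MPFG = 12) does not follow any derivable order; the default order is
   declared in `config.py` and any order can be loaded from TSV.
3. **Inc one-hot** — the contig's best replicon-typing hit (highest bitscore,
   then alphabetical) over the incompatibility-group table, with a dedicated
   `none` slot when nothing qualifies.

The PC and MOB/MPF sentences each pass through one Transformer encoder
block: summed token + learned positional embeddings, masked multi-head
scaled-dot-product attention (per head i,
`head_i = softmax(X W_i^Q (X W_i^K)^T / sqrt(d_head)) X W_i^V`,
`d_head = embed / h`, h = 8 by default, heads concatenated and projected by
`W^O`), then a two-layer ReLU feed-forward network, then a masked mean-pool
over non-padding positions. There are no residual connections or layer
normalization — the block follows the minimal published architecture. The
two pooled vectors are concatenated with the Inc one-hot and a linear head
produces logits over the node's child taxa.

Dropout (rate 0.2) is applied at seven sites: embedding sum, FFN hidden, and
FFN output in each of the two blocks, plus the fused concatenation. These
same sites drive the MC-dropout uncertainty estimate.

## Training

Each node classifier is trained independently with softmax cross-entropy and
Adam at learning rate 0.005 for up to 50 epochs (the published recipe).
Samples reaching a node are those whose (possibly truncated) lineage passes
through it and extends at least one rank below. The training split is
*temporal*: plasmids sorted by release date, oldest 70% train / next 15%
validation / newest 15% test (floor arithmetic, ties broken by plasmid id,
groups of < 3 go wholly to train). Taxa with fewer than 10 plasmids are
pruned from the backbone before training; affected lineages are truncated at
the surviving ancestor. Fragment augmentation (uniform 1.5–10 kb substrings
of full plasmids inheriting the source label) is available for
robustness-to-incomplete-assembly experiments.

A node is skipped (constant classifier, warning) when its training data
contains a single class. Per-node seeds are derived deterministically from
the run seed and the node's taxon path (CRC32), so retraining any subset of
nodes reproduces byte-identical models.

## Uncertainty and tree search

At each classifier node the dropout-disabled forward pass picks the child
taxon (argmax, ties to the lower index). The same input then makes T = 100
stochastic passes with dropout enabled; the probability assigned to the
chosen class is recorded per pass. The estimate's first moment is the mean
over passes and its uncertainty the population variance
`E[y^2] - E[y]^2`. The `tau^-1` model-precision term of the full variational
treatment only offsets the second moment by a constant and never changes a
stopping decision, so it is documented (`uncertainty.TAU`) but unused.

Three modes interpret the variance: **sensitive** never stops early,
**specific** stops when variance exceeds 0.01, **accurate** when it exceeds
0.002 (strict inequality; a variance exactly at the cutoff continues). On a
stop, the current node's child prediction is discarded and the lineage ends
at the parent taxon. Because the argmax descent is mode-independent, one
traversal serves all three modes (`predict_all_modes`), which also makes the
depth monotonicity accurate ≤ specific ≤ sensitive hold by construction.

## Evaluation

Per rank: `prediction_rate = predicted/total`, `accuracy =
correct/predicted` (undefined — NaN — when nothing is predicted), and
micro-F1 `2TP / (2TP + FP + FN)`. A contig without a prediction at a rank is
an FN for its true class there and at every deeper rank (predictions only
truncate downward). A useful consequence checked property-based in the
tests: `prediction_rate x accuracy = correct/total` at every rank.

## Synthetic benchmark

The generator (`synthetic.py`) builds a balanced taxonomy (default binary
branching, 64 species), a designed cluster universe (each cluster has 2
members connected by all-vs-all hits, so MCL must recover the design), and
per-species disjoint marker-token pools plus shared background tokens.
Plasmids draw ~Poisson(30) proteins, each a species marker with probability
`marker_strength` (0.9 by default) or background otherwise; E-values are
log-uniform; half the plasmids carry 1–3 uninformative MOB/MPF annotations;
Inc hits are species-linked. Release dates are sequential so the temporal
split is exercised. Optionally, *out-of-label* species (novel species under
an existing genus, with their own marker pools) are added as queries only —
the early-stop use case.

What it deliberately does not emulate: sequence evolution, GC/codon signal
(the model never reads nucleotides), alignment noise between clusters, class
imbalance, or database-scale vocabulary sizes. A passing recovery run shows
the pipeline learns host signal carried by protein-cluster composition; it
says nothing about accuracy on real plasmids.

At `marker_strength = 0` the corpus carries no host signal and species-level
accuracy falls to chance (1/64); the recovery harness checks both regimes.

## Numerical choices

- **No torch.** The execution environment provides no deep-learning
  framework, so the package carries a ~300-line reverse-mode autograd over
  numpy (`autograd.py`) implementing exactly the ops the model needs.
  Gradients are validated against central finite differences (max observed
  error ~1e-9 on float64) and attention against an independent per-position
  brute-force oracle.
- **float32 parameters.** Models train and infer in float32; oracle and
  identity tests run in float64 (the engine preserves dtype). This halves
  memory and roughly doubles throughput with no effect on the checked
  properties.
- **Inference mode.** `predict_proba` runs under a no-graph context and in
  256-sample chunks, bounding inference memory regardless of corpus size.
- **Attention scaling** is folded into Q (`Q' = Q / sqrt(d_head)`), which is
  algebraically identical to scaling the L×L score matrix and cheaper.
- **Plateau early exit.** Training stops before the 50-epoch cap once the
  epoch mean loss has improved by less than 1e-3 for 5 consecutive epochs.
  This is a generic convergence criterion (most synthetic nodes converge by
  epoch ~15–20); the cap itself is unchanged and the exit can be disabled
  (`plateau_patience=0`).
- **Desk-scale harness sizes.** The end-to-end recovery harness uses encoder
  widths 32 (PC) / 16 (MOB) and batch 128 instead of the production defaults
  (64/32/32) so the full 64-species run fits a single-CPU time budget; unit
  tests still exercise the production widths.
- Fully-masked attention rows degenerate to a uniform distribution; such
  sequences pool to the zero vector and are excluded downstream by the
  pooling mask, so the degenerate softmax value is never consumed.

## Limitations

- Trained per-node models are only as good as the taxon sampling at that
  node; rare-taxon pruning trades species coverage for classifier quality.
- The MC-dropout variance is a heuristic uncertainty — it is calibrated by
  mode cutoffs chosen in the source publication, not re-calibrated here.
- Published headline benchmarks require the full RefSeq-scale corpus and are
  out of scope at desk scale; the synthetic recovery harness is the
  substitute evidence.
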