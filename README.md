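# plasmidhost

Hierarchical prediction of a plasmid's bacterial host taxon from an
assembled contig, with Monte-Carlo-dropout uncertainty deciding how deep
into the taxonomy to commit.

Plasmids move genes — including resistance genes — between bacteria, and
knowing which hosts a plasmid can reside in is central to tracking that
flow. Reference-based host assignment fails for the large fraction of
plasmid contigs whose host was never observed. This package instead learns
host signal from the plasmid sequence's *protein content*: which protein
clusters it carries, in what order, plus conjugation (MOB/MPF) and replicon
(Inc) typing.

## Model

A backbone tree spans the training hosts' taxonomy (root + phylum … species,
depth 7). Every internal node with more than one child owns a classifier
over its children; prediction walks top-down from the root, auto-descending
single-child nodes.

Each classifier reads three fixed-shape encodings of the contig:

- a 400-token protein-cluster sentence (clusters from Markov Clustering of
  the all-vs-all protein similarity graph, edge weight `-log10 E`, E ≤ 1e-3),
- a 50-token MOB/MPF conjugation-typing sentence (13 token types),
- an Inc-group one-hot with a `none` slot,

and is a pair of Transformer encoder blocks (token + positional embeddings,
masked 8-head scaled-dot-product attention, feed-forward, masked mean-pool)
whose pooled features are concatenated with the Inc one-hot into a linear
head. Training: cross-entropy, Adam, lr 0.005, ≤ 50 epochs per node.

At each node the deterministic pass picks the child; T = 100 dropout-enabled
passes (7 dropout sites, rate 0.2) give the predictive variance
`E[y²] − E[y]²` of the chosen class's probability. Three search modes:
**sensitive** (never stop early), **specific** (stop when variance > 0.01)
and **accurate** (variance > 0.002). Stopping discards the child prediction
and reports the lineage down to the current taxon, so output depth satisfies
accurate ≤ specific ≤ sensitive.

Per rank the evaluation reports prediction rate (predicted/total), accuracy
(correct/predicted; NA when nothing is predicted) and micro-F1, with
unpredicted contigs counted as false negatives at that rank and below.

See `docs/methods.md` for the full method description, numerical choices
and limitations.

## Worked example

Generate a small synthetic corpus (4 species), run the whole pipeline
(vocabulary → encoding → per-node training → uncertainty-guided search) and
evaluate on the temporal test split:

```python
from plasmidhost.synthetic import SyntheticSpec, end_to_end_recovery
from plasmidhost.model import TrainingConfig
from plasmidhost.uncertainty import UncertaintyConfig
from plasmidhost.metrics import evaluation_table

spec = SyntheticSpec(branching=(2, 1, 1, 1, 1, 2), plasmids_per_species=16,
                     markers_per_species=6, n_background_tokens=20, seed=3)
res = end_to_end_recovery(spec,
                          training=TrainingConfig(epochs=25, batch_size=16, seed=3),
                          uncertainty=UncertaintyConfig(T=10, seed=3))
print(evaluation_table(res.evaluations["sensitive"]).to_string(index=False))
p = res.predictions["sensitive"][0]
print("predicted lineage:", " > ".join(name for _, name in p.lineage))
```

Output (about 15 s on one CPU):

```
   rank  n_total  n_predicted  prediction_rate  accuracy  f1  macro_f1
 phylum        8            8              1.0       1.0 1.0       1.0
  class        8            8              1.0       1.0 1.0       1.0
  order        8            8              1.0       1.0 1.0       1.0
 family        8            8              1.0       1.0 1.0       1.0
  genus        8            8              1.0       1.0 1.0       1.0
species        8            8              1.0       1.0 1.0       1.0
predicted lineage: P0 > C0 > O0 > F0 > G0 > S0
```

The same pipeline is available as a CLI
(`plasmidhost simulate / build-vocab / encode / train / predict / evaluate`);
run `plasmidhost --help` for the options, or see `tests/test_cli.py` for a
complete file-based walk-through.

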