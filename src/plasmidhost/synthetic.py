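"""Synthetic benchmark generator: taxonomies, vocabularies, plasmids, hits.

Makes the whole pipeline testable without external databases or aligners.
The generator emulates the statistical structure the method assumes: a
balanced host taxonomy, a protein-cluster vocabulary in which some clusters
are host-informative (species-specific marker pools) and the rest are shared
background, plasmids whose protein content mixes the two at a controllable
``marker_strength``, conjugation-typing (MOB/MPF) annotations on a fraction
of plasmids, replicon (Inc) hits correlated with the species, release dates
for the temporal split, and optionally species that are *absent from the
label set* yet present among query contigs (the early-stop use case).

What it deliberately does not emulate: real sequence evolution, codon usage
or GC signal (the model never consumes the nucleotides themselves), and
realistic inter-cluster alignment noise.  Passing tests therefore show that
the pipeline recovers hosts whose signal is carried by protein-cluster
composition, not that it matches any benchmark on real plasmids.

Alignment hits are emitted directly (protein -> cluster member with an
E-value drawn log-uniformly from [1e-20, 1e-4]) so no aligner is needed.
All outputs are byte-reproducible under the spec's seed.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .backbone import (BackboneTree, HostLineage, build_tree, prune_rare,
                       temporal_split)
from .config import RANKS
from .encode import EncodedSample, PlasmidContig, ProteinCall, encode_contig
from .metrics import RankEvaluation, evaluate_all_ranks
from .model import TrainingConfig, train_hierarchy
from .uncertainty import ModelStore, UncertaintyConfig, predict_all_modes
from .vocab import (AlignmentHit, IncTable, MobMpfVocabulary, PCVocabulary,
                    build_pc_vocabulary, build_similarity_graph, mcl_cluster,
                    DEFAULT_MOBMPF_ORDER)

logger = logging.getLogger(__name__)

_RANK_PREFIX = ("P", "C", "O", "F", "G", "S")


@dataclass(frozen=True)
class SyntheticSpec:
    branching: tuple[int, ...] = (2, 2, 2, 2, 2, 2)   # children per rank
    plasmids_per_species: int = 40
    tokens_per_plasmid_mean: float = 30.0             # Poisson, min 3
    marker_strength: float = 0.9
    markers_per_species: int = 12
    n_background_tokens: int = 120
    members_per_cluster: int = 2
    mobmpf_rate: float = 0.5
    inc_groups: tuple[str, ...] = ("IncF", "IncI", "IncP", "IncN", "IncW", "IncX")
    inc_hit_rate: float = 0.7
    fragment_range: tuple[int, int] = (1500, 10_000)
    out_of_label_species: int = 0
    plasmids_per_out_species: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.branching) != len(RANKS):
            raise ValueError("branching must give one factor per rank")
        if not 0.0 <= self.marker_strength <= 1.0:
            raise ValueError("marker_strength must be in [0, 1]")

    @property
    def n_species(self) -> int:
        return int(np.prod(self.branching))


@dataclass
class SyntheticCorpus:
    spec: SyntheticSpec
    lineages: list[HostLineage]                      # labeled plasmids only
    contigs: dict[str, PlasmidContig]
    pc_hits: dict[str, list[AlignmentHit]]
    mobmpf_hits: dict[str, list[tuple[str, str, float]]]
    inc_hits: dict[str, list[tuple[str, float, float]]]
    all_vs_all: list[AlignmentHit]
    truth: dict[str, tuple[str, ...]]                # incl. out-of-label contigs
    out_of_label_ids: set[str]
    mobmpf_vocab: MobMpfVocabulary = field(default_factory=MobMpfVocabulary)
    inc_table: IncTable = None  # type: ignore[assignment]

    # -- file emission (the exact external formats the pipeline consumes) --
    def write(self, outdir: str | Path) -> None:
        from . import io_tables
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        io_tables.write_lineage_table(self.lineages, out / "lineages.tsv")
        io_tables.write_fasta(
            {cid: c.sequence for cid, c in sorted(self.contigs.items())},
            out / "contigs.fasta")
        io_tables.write_fasta(
            {p.protein_id: (p.sequence or "M")
             for cid, c in sorted(self.contigs.items()) for p in c.proteins},
            out / "proteins.faa")
        io_tables.write_protein_table(self.contigs, out / "proteins.tsv")
        io_tables.write_tabular_hits(
            [(h.query_id, h.subject_id, h.evalue, h.bitscore)
             for hits in _sorted_values(self.pc_hits) for h in hits],
            out / "pc_hits.tsv")
        io_tables.write_tabular_hits(
            [(pid, t, ev, 100.0) for hits in _sorted_values(self.mobmpf_hits)
             for pid, t, ev in hits],
            out / "mobmpf_hits.tsv")
        io_tables.write_tabular_hits(
            [(cid, grp, ev, bs) for cid in sorted(self.inc_hits)
             for grp, ev, bs in self.inc_hits[cid]],
            out / "inc_hits.tsv")
        io_tables.write_tabular_hits(
            [(h.query_id, h.subject_id, h.evalue, h.bitscore)
             for h in self.all_vs_all],
            out / "allvsall.tsv")
        io_tables.write_truth_table(self.truth, out / "truth.tsv")


def _sorted_values(d: dict) -> list:
    return [d[k] for k in sorted(d)]


def _species_lineage(spec: SyntheticSpec, species_idx: int) -> tuple[str, ...]:
    """Global per-rank indices for a species in the balanced tree."""
    idx = species_idx
    path_rev = []
    for rank_pos in range(len(RANKS) - 1, -1, -1):
        path_rev.append(idx)
        idx //= spec.branching[rank_pos]
    path = path_rev[::-1]
    return tuple(f"{_RANK_PREFIX[i]}{path[i]}" for i in range(len(RANKS)))


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Generate the full corpus; byte-reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_marker_pools = spec.n_species + spec.out_of_label_species
    n_tokens = n_marker_pools * spec.markers_per_species + spec.n_background_tokens
    if spec.markers_per_species > n_tokens:
        raise ValueError("more markers per species than vocabulary tokens")

    # Cluster universe: cluster k owns members pc{k}m{j}; all-vs-all hits
    # connect members within a cluster only.
    members = {k: [f"pc{k:05d}m{j}" for j in range(spec.members_per_cluster)]
               for k in range(n_tokens)}
    all_vs_all: list[AlignmentHit] = []
    for k in range(n_tokens):
        ms = members[k]
        for a in range(len(ms)):
            for b in range(a + 1, len(ms)):
                ev = 10.0 ** rng.uniform(-20, -10)
                all_vs_all.append(AlignmentHit(ms[a], ms[b], ev, 200.0))

    marker_pool = {s: list(range(s * spec.markers_per_species,
                                 (s + 1) * spec.markers_per_species))
                   for s in range(n_marker_pools)}
    background = list(range(n_marker_pools * spec.markers_per_species, n_tokens))

    mob_types = list(DEFAULT_MOBMPF_ORDER)
    inc_table = IncTable(list(spec.inc_groups))

    lineages: list[HostLineage] = []
    contigs: dict[str, PlasmidContig] = {}
    pc_hits: dict[str, list[AlignmentHit]] = {}
    mobmpf_hits: dict[str, list[tuple[str, str, float]]] = {}
    inc_hits: dict[str, list[tuple[str, float, float]]] = {}
    truth: dict[str, tuple[str, ...]] = {}
    out_ids: set[str] = set()
    base_date = _dt.date(2015, 1, 1)

    def _make_plasmid(pid: str, species_pool_idx: int,
                      lineage_names: tuple[str, ...]) -> int:
        n_tok = max(3, int(rng.poisson(spec.tokens_per_plasmid_mean)))
        draws = rng.random(n_tok)
        tokens = [int(rng.choice(marker_pool[species_pool_idx]))
                  if d < spec.marker_strength else int(rng.choice(background))
                  for d in draws]
        length = max(1500, 200 + 250 * n_tok)
        seq_codes = rng.integers(0, 4, size=length)
        seq = "".join("ACGT"[c] for c in seq_codes)
        proteins = []
        hits: list[AlignmentHit] = []
        for i, tok in enumerate(tokens):
            pid_i = f"{pid}_g{i}"
            start = 100 + 250 * i
            proteins.append(ProteinCall(protein_id=pid_i, start=start,
                                        end=start + 200,
                                        strand=1 if rng.random() < 0.5 else -1))
            subject = members[tok][int(rng.integers(len(members[tok])))]
            ev = 10.0 ** rng.uniform(-20, -4)
            hits.append(AlignmentHit(pid_i, subject, ev, 150.0))
        contigs[pid] = PlasmidContig(contig_id=pid, sequence=seq,
                                     proteins=proteins)
        pc_hits[pid] = hits
        # MOB/MPF: some plasmids carry 1-3 typed proteins (uninformative).
        mhits: list[tuple[str, str, float]] = []
        if rng.random() < spec.mobmpf_rate:
            k = int(rng.integers(1, 4))
            for g in sorted(rng.choice(len(tokens), size=min(k, len(tokens)),
                                       replace=False)):
                mhits.append((f"{pid}_g{g}", mob_types[int(rng.integers(13))],
                              10.0 ** rng.uniform(-15, -5)))
        mobmpf_hits[pid] = mhits
        # Inc: species-linked replicon hit most of the time.
        ih: list[tuple[str, float, float]] = []
        if rng.random() < spec.inc_hit_rate:
            grp = spec.inc_groups[species_pool_idx % len(spec.inc_groups)]
            ih.append((grp, 1e-10, 150.0 + float(rng.random() * 50)))
        inc_hits[pid] = ih
        truth[pid] = lineage_names
        return length

    for s in range(spec.n_species):
        names = _species_lineage(spec, s)
        for j in range(spec.plasmids_per_species):
            pid = f"{names[-1]}_pl{j:03d}"
            length = _make_plasmid(pid, s, names)
            lineages.append(HostLineage(
                plasmid_id=pid, ranks=names,
                release_date=base_date + _dt.timedelta(days=int(j)),
                length_bp=length))

    for o in range(spec.out_of_label_species):
        pool_idx = spec.n_species + o
        # Out-of-label species sit under an existing genus but are unknown to
        # the label set; their lineage is the in-label prefix + a novel name.
        sibling = _species_lineage(spec, o % spec.n_species)
        names = sibling[:-1] + (f"X{o}",)
        for j in range(spec.plasmids_per_out_species):
            pid = f"X{o}_pl{j:03d}"
            _make_plasmid(pid, pool_idx, names)
            out_ids.add(pid)

    return SyntheticCorpus(spec=spec, lineages=lineages, contigs=contigs,
                           pc_hits=pc_hits, mobmpf_hits=mobmpf_hits,
                           inc_hits=inc_hits, all_vs_all=all_vs_all,
                           truth=truth, out_of_label_ids=out_ids,
                           inc_table=inc_table)


# ---------------------------------------------------------------------------
# End-to-end recovery harness
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    tree: BackboneTree
    vocabulary: PCVocabulary
    split: object
    models: ModelStore
    predictions: dict[str, list]                 # mode -> [HostPrediction]
    evaluations: dict[str, list[RankEvaluation]] # mode -> per-rank metrics
    test_ids: list[str]
    out_of_label_ids: set[str]

    def species_accuracy(self, mode: str) -> float:
        return self.evaluations[mode][-1].accuracy


def encode_corpus(corpus: SyntheticCorpus, vocabulary: PCVocabulary,
                  tree: BackboneTree) -> dict[str, EncodedSample]:
    """Encode every contig; labels are pruned-tree-truncated lineages."""
    samples = {}
    for cid in sorted(corpus.contigs):
        label = tree.truncated_label(corpus.truth[cid])
        samples[cid] = encode_contig(
            corpus.contigs[cid], corpus.pc_hits[cid], corpus.mobmpf_hits[cid],
            corpus.inc_hits[cid], vocabulary, corpus.mobmpf_vocab,
            corpus.inc_table, label=label)
    return samples


def end_to_end_recovery(
    spec: SyntheticSpec,
    training: TrainingConfig | None = None,
    uncertainty: UncertaintyConfig | None = None,
    modes: Sequence[str] = ("sensitive", "specific", "accurate"),
) -> RecoveryResult:
    """Full pipeline on a synthetic corpus: vocab -> encode -> train ->
    predict -> evaluate, using the temporal split's test subset (plus any
    out-of-label contigs) as queries."""
    corpus = generate_corpus(spec)
    # desk-scale defaults: larger minibatches and smaller encoders than the
    # production defaults keep the full recovery run within a laptop budget
    # without hurting recovery on corpora of this size
    training = training or TrainingConfig(seed=spec.seed, batch_size=128)
    uncertainty = uncertainty or UncertaintyConfig(seed=spec.seed)

    tree = prune_rare(build_tree(corpus.lineages))
    split = temporal_split(corpus.lineages)
    graph = build_similarity_graph(corpus.all_vs_all)
    vocabulary = build_pc_vocabulary(mcl_cluster(graph))
    logger.info("synthetic vocabulary: %d tokens", vocabulary.size)

    samples = encode_corpus(corpus, vocabulary, tree)
    train_samples = [samples[cid] for cid in sorted(split.train)]
    models = ModelStore(train_hierarchy(
        tree, train_samples, pc_vocab_size=vocabulary.size,
        inc_dim=corpus.inc_table.size, cfg=training,
        vocab_hash=vocabulary.content_hash(),
        pc_embed=32, mob_embed=16))

    test_ids = sorted(split.test) + sorted(corpus.out_of_label_ids)
    test_samples = [samples[cid] for cid in test_ids]
    preds = predict_all_modes(test_samples, tree, models, uncertainty)
    preds = {m: preds[m] for m in modes}

    evaluations = {}
    in_label = [cid for cid in test_ids if cid not in corpus.out_of_label_ids]
    truths = {cid: corpus.truth[cid] for cid in in_label}
    for mode, plist in preds.items():
        pred_map = {p.contig_id: tuple(name for _, name in p.lineage)
                    for p in plist if p.contig_id in truths}
        evaluations[mode] = evaluate_all_ranks(truths, pred_map)
    return RecoveryResult(tree=tree, vocabulary=vocabulary, split=split,
                          models=models, predictions=preds,
                          evaluations=evaluations, test_ids=test_ids,
                          out_of_label_ids=corpus.out_of_label_ids)
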