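"""Encode one plasmid contig into the classifier's three fixed-shape inputs.

A contig's predicted proteins become a protein-cluster (PC) sentence of
length 400, its conjugation-typing annotations a MOB/MPF sentence of length
50, and its replicon typing an Inc one-hot vector.  Shapes are identical for
every contig regardless of length; token 0 pads short sentences.  Positions
are the 1-based ordinal of the protein on the contig (gene index), recorded
for the positional embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import EVALUE_CUTOFF, MIN_CONTIG_LEN, MOBMPF_SENTENCE_LEN, PC_SENTENCE_LEN
from .vocab import AlignmentHit, IncTable, MobMpfVocabulary, PCVocabulary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinCall:
    protein_id: str
    start: int          # 1-based inclusive, nucleotide coords
    end: int
    strand: int         # +1 / -1
    sequence: str = ""  # amino acids; optional for precomputed-hit workflows


@dataclass
class PlasmidContig:
    contig_id: str
    sequence: str
    proteins: list[ProteinCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_CONTIG_LEN:
            raise ValueError(
                f"{self.contig_id}: contig is {len(self.sequence)} bp; "
                f"minimum accepted length is {MIN_CONTIG_LEN} bp"
            )
        self.proteins = sorted(self.proteins, key=lambda p: (p.start, p.protein_id))


@dataclass(frozen=True)
class EncodedSample:
    """Model input for one contig: fixed shapes (400,), (400,), (50,), (|Inc|,)."""

    contig_id: str
    pc_tokens: np.ndarray
    pc_positions: np.ndarray
    mobmpf_tokens: np.ndarray
    inc_onehot: np.ndarray
    label: tuple[str, ...] | None = None   # truncated lineage; training only


# ---------------------------------------------------------------------------
# PC sentence
# ---------------------------------------------------------------------------

def assign_pc_tokens(
    contig: PlasmidContig,
    hits: Sequence[AlignmentHit],
    vocabulary: PCVocabulary,
    evalue_cutoff: float = EVALUE_CUTOFF,
) -> list[tuple[str, int]]:
    """Best-hit token per protein, preserving gene order.

    Each protein takes the token of its minimum-E-value qualifying hit
    (E <= cutoff); E-value ties resolve to the lower token id.  Proteins
    without a qualifying hit are omitted (the vocabulary has no
    out-of-vocabulary token).  Hits whose subject is not a clustered member
    are skipped and counted.
    """
    best: dict[str, tuple[float, int]] = {}
    unknown = 0
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        token = vocabulary.token_of_member(hit.subject_id)
        if token is None:
            unknown += 1
            continue
        cand = (hit.evalue, token)
        if hit.query_id not in best or cand < best[hit.query_id]:
            best[hit.query_id] = cand
    if unknown:
        logger.info("%s: %d hits referenced proteins outside the vocabulary",
                    contig.contig_id, unknown)
    return [(p.protein_id, best[p.protein_id][1])
            for p in contig.proteins if p.protein_id in best]


def encode_pc_sentence(
    token_pairs: Sequence[tuple[str, int]],
    n_proteins: int | None = None,
    protein_ordinals: Mapping[str, int] | None = None,
    max_len: int = PC_SENTENCE_LEN,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-length PC sentence and positional index vector.

    The first ``max_len`` tokens are kept; shorter sentences are padded with
    token 0.  Positions are the 1-based protein ordinal on the contig when
    ``protein_ordinals`` is given, else 1..k over the tokenized proteins;
    position 0 marks padding.
    """
    tokens = np.zeros(max_len, dtype=np.int64)
    positions = np.zeros(max_len, dtype=np.int64)
    kept = token_pairs[:max_len]
    for i, (pid, tok) in enumerate(kept):
        tokens[i] = tok
        if protein_ordinals is not None:
            positions[i] = protein_ordinals[pid]
        else:
            positions[i] = i + 1
    return tokens, positions


# ---------------------------------------------------------------------------
# MOB/MPF sentence
# ---------------------------------------------------------------------------

def best_mobmpf_annotations(
    hits: Sequence[tuple[str, str, float]],
    evalue_cutoff: float = EVALUE_CUTOFF,
) -> dict[str, str]:
    """protein_id -> MOB/MPF type from (protein_id, type, evalue) hits.

    A protein matching both MOB and MPF references takes the lower-E-value
    annotation; ties resolve alphabetically on the type name.
    """
    best: dict[str, tuple[float, str]] = {}
    for pid, mtype, evalue in hits:
        if evalue > evalue_cutoff:
            continue
        cand = (evalue, mtype)
        if pid not in best or cand < best[pid]:
            best[pid] = cand
    return {pid: t for pid, (_, t) in best.items()}


def encode_mobmpf_sentence(
    contig: PlasmidContig,
    annotations: Mapping[str, str],
    table: MobMpfVocabulary,
    max_len: int = MOBMPF_SENTENCE_LEN,
) -> np.ndarray:
    """MOB/MPF tokens in gene order, padded/truncated to ``max_len``.

    An unknown type string raises (stale token table).  With no annotated
    protein the sentence is all padding, which is a valid model input.
    """
    tokens = np.zeros(max_len, dtype=np.int64)
    i = 0
    for protein in contig.proteins:
        mtype = annotations.get(protein.protein_id)
        if mtype is None:
            continue
        if i >= max_len:
            break
        tokens[i] = table.token_of(mtype)
        i += 1
    return tokens


# ---------------------------------------------------------------------------
# Inc one-hot
# ---------------------------------------------------------------------------

def encode_inc(
    inc_hits: Sequence[tuple[str, float, float]],
    table: IncTable,
    evalue_cutoff: float = EVALUE_CUTOFF,
) -> np.ndarray:
    """One-hot over Inc groups from (group, evalue, bitscore) nucleotide hits.

    The best hit wins (highest bitscore, then alphabetical group name); with
    no qualifying hit the dedicated 'none' position is set.
    """
    onehot = np.zeros(table.size, dtype=np.float64)
    qualifying = [(grp, bs) for grp, ev, bs in inc_hits if ev <= evalue_cutoff]
    if not qualifying:
        onehot[table.none_pos] = 1.0
        return onehot
    best_group = min(qualifying, key=lambda x: (-x[1], x[0]))[0]
    onehot[table.position(best_group)] = 1.0
    return onehot


# ---------------------------------------------------------------------------
# Whole-contig encoding
# ---------------------------------------------------------------------------

def save_samples(samples: Sequence[EncodedSample], path: str) -> None:
    """Persist encoded samples (npz: ids, the three tensors, labels)."""
    np.savez(path,
             ids=np.array([s.contig_id for s in samples]),
             pc_tokens=np.stack([s.pc_tokens for s in samples]),
             pc_positions=np.stack([s.pc_positions for s in samples]),
             mobmpf_tokens=np.stack([s.mobmpf_tokens for s in samples]),
             inc_onehot=np.stack([s.inc_onehot for s in samples]),
             labels=np.array(["|".join(s.label) if s.label else ""
                              for s in samples]))


def load_samples(path: str) -> list[EncodedSample]:
    with np.load(path, allow_pickle=False) as d:
        return [EncodedSample(contig_id=str(d["ids"][i]),
                              pc_tokens=d["pc_tokens"][i],
                              pc_positions=d["pc_positions"][i],
                              mobmpf_tokens=d["mobmpf_tokens"][i],
                              inc_onehot=d["inc_onehot"][i],
                              label=(tuple(str(d["labels"][i]).split("|"))
                                     if str(d["labels"][i]) else None))
                for i in range(len(d["ids"]))]


def encode_contig(
    contig: PlasmidContig,
    pc_hits: Sequence[AlignmentHit],
    mobmpf_hits: Sequence[tuple[str, str, float]],
    inc_hits: Sequence[tuple[str, float, float]],
    pc_vocab: PCVocabulary,
    mobmpf_vocab: MobMpfVocabulary,
    inc_table: IncTable,
    label: tuple[str, ...] | None = None,
    evalue_cutoff: float = EVALUE_CUTOFF,
) -> EncodedSample:
    """Pure function contig + hits -> EncodedSample (deterministic)."""
    ordinals = {p.protein_id: i + 1 for i, p in enumerate(contig.proteins)}
    pairs = assign_pc_tokens(contig, pc_hits, pc_vocab, evalue_cutoff)
    pc_tokens, pc_positions = encode_pc_sentence(pairs, protein_ordinals=ordinals)
    annotations = best_mobmpf_annotations(mobmpf_hits, evalue_cutoff)
    mob_tokens = encode_mobmpf_sentence(contig, annotations, mobmpf_vocab)
    inc = encode_inc(inc_hits, inc_table, evalue_cutoff)
    return EncodedSample(contig_id=contig.contig_id, pc_tokens=pc_tokens,
                         pc_positions=pc_positions, mobmpf_tokens=mob_tokens,
                         inc_onehot=inc, label=label)
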