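"""Host-taxonomy backbone: build, prune and query the tree of known hosts.

The backbone is a rooted tree over bacterial taxa from phylum to species.
Every internal node with more than one child owns a classifier that picks
among its children during the top-down search; single-child nodes are
descended automatically.  This module also manages the date-ordered
train/validation/test split and the fragment augmentation used to train on
contig-length inputs.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .config import MAX_CONTIG_LEN, RANKS, ROOT_NAME, ROOT_RANK

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HostLineage:
    """Complete phylum-to-species host annotation for one plasmid."""

    plasmid_id: str
    ranks: tuple[str, str, str, str, str, str]  # phylum..species
    release_date: _dt.date
    length_bp: int

    def __post_init__(self) -> None:
        if len(self.ranks) != 6 or any(not r for r in self.ranks):
            raise ValueError(
                f"{self.plasmid_id}: lineage must have 6 non-empty ranks, got {self.ranks}"
            )
        if not 0 < self.length_bp <= MAX_CONTIG_LEN:
            raise ValueError(
                f"{self.plasmid_id}: length {self.length_bp} outside (0, {MAX_CONTIG_LEN}]"
            )


@dataclass
class TaxonNode:
    name: str
    rank: str
    children: dict[str, "TaxonNode"] = field(default_factory=dict)
    sample_count: int = 0

    @property
    def has_classifier(self) -> bool:
        """A node owns a classifier iff it is internal with >1 child."""
        return self.rank != "species" and len(self.children) > 1

    def walk(self) -> Iterator["TaxonNode"]:
        yield self
        for child in self.children.values():
            yield from child.walk()


class BackboneTree:
    """Rooted taxonomy tree; depth is 7 when lineages are complete."""

    def __init__(self, root: TaxonNode):
        if root.rank != ROOT_RANK:
            raise ValueError("root node must have rank 'root'")
        self.root = root

    # -- queries ---------------------------------------------------------
    @property
    def depth(self) -> int:
        def _d(node: TaxonNode) -> int:
            return 1 + max((_d(c) for c in node.children.values()), default=0)
        return _d(self.root)

    def nodes(self) -> Iterator[TaxonNode]:
        return self.root.walk()

    def classifier_nodes(self) -> list[TaxonNode]:
        return [n for n in self.nodes() if n.has_classifier]

    def path_for(self, ranks: Sequence[str]) -> list[TaxonNode]:
        """Nodes from root down the given taxon names; truncates at the
        deepest taxon still present in the (possibly pruned) tree."""
        path = [self.root]
        node = self.root
        for name in ranks:
            if name in node.children:
                node = node.children[name]
                path.append(node)
            else:
                break
        return path

    def truncated_label(self, ranks: Sequence[str]) -> tuple[str, ...]:
        """Rank tuple truncated at the deepest surviving ancestor."""
        return tuple(n.name for n in self.path_for(ranks)[1:])

    # -- serialization ---------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        rows = []
        def _walk(node: TaxonNode, parent: str) -> None:
            rows.append(dict(name=node.name, rank=node.rank, parent=parent,
                             sample_count=node.sample_count,
                             has_classifier=node.has_classifier))
            for child in node.children.values():
                _walk(child, node.name)
        _walk(self.root, "")
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BackboneTree":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        nodes: dict[tuple[str, str], TaxonNode] = {}
        root = None
        for row in df.itertuples():
            node = TaxonNode(name=row.name, rank=row.rank,
                             sample_count=int(row.sample_count))
            nodes[(row.rank, row.name)] = node
            if row.rank == ROOT_RANK:
                root = node
        if root is None:
            raise ValueError(f"{path}: no root node in tree table")
        order = [ROOT_RANK, *RANKS]
        parent_rank = {order[i]: order[i - 1] for i in range(1, len(order))}
        for row in df.itertuples():
            if row.rank == ROOT_RANK:
                continue
            parent = nodes[(parent_rank[row.rank], row.parent)]
            parent.children[row.name] = nodes[(row.rank, row.name)]
        return cls(root)

    def to_newick(self) -> str:
        """Newick string with rank annotations in node comments."""
        def _fmt(node: TaxonNode) -> str:
            label = f"{_escape(node.name)}[&&rank={node.rank},n={node.sample_count}]"
            if not node.children:
                return label
            inner = ",".join(_fmt(c) for c in node.children.values())
            return f"({inner}){label}"
        return _fmt(self.root) + ";"


def _escape(name: str) -> str:
    return name.replace(" ", "_").replace("(", "").replace(")", "").replace(",", "")


# ---------------------------------------------------------------------------
# Tree construction and pruning
# ---------------------------------------------------------------------------

def build_tree(lineages: Iterable[HostLineage]) -> BackboneTree:
    """Build the backbone from complete lineages.

    One node exists per distinct (rank, name, parent) triple; a taxon name
    observed under two different parents at the same rank is a conflicting
    annotation and is rejected with a diagnostic naming the taxon.
    ``sample_count`` is the number of lineages whose path passes through the
    node.
    """
    root = TaxonNode(name=ROOT_NAME, rank=ROOT_RANK)
    # (rank, name) -> parent name, to detect conflicting parentage
    seen_parent: dict[tuple[str, str], str] = {}
    n = 0
    for lin in lineages:
        n += 1
        root.sample_count += 1
        node = root
        for rank, name in zip(RANKS, lin.ranks):
            key = (rank, name)
            prev = seen_parent.get(key)
            if prev is not None and prev != node.name:
                raise ValueError(
                    f"taxon {name!r} at rank {rank!r} appears under two parents: "
                    f"{prev!r} and {node.name!r}"
                )
            seen_parent[key] = node.name
            child = node.children.get(name)
            if child is None:
                child = TaxonNode(name=name, rank=rank)
                node.children[name] = child
            child.sample_count += 1
            node = child
    if n == 0:
        raise ValueError("no lineages given")
    return BackboneTree(root)


def prune_rare(tree: BackboneTree, min_samples: int = 10) -> BackboneTree:
    """Remove every non-root subtree with fewer than ``min_samples`` plasmids.

    Lineages through pruned nodes are retained upstream: their labels are
    simply truncated at the deepest surviving ancestor (see
    :meth:`BackboneTree.truncated_label`), so they still train the
    higher-rank classifiers.
    """
    def _copy(node: TaxonNode) -> TaxonNode:
        clone = TaxonNode(name=node.name, rank=node.rank,
                          sample_count=node.sample_count)
        for name, child in node.children.items():
            if child.sample_count >= min_samples:
                clone.children[name] = _copy(child)
        return clone

    new_root = _copy(tree.root)
    if not new_root.children and tree.root.children:
        raise ValueError(
            f"pruning at min_samples={min_samples} removed every phylum"
        )
    return BackboneTree(new_root)


# ---------------------------------------------------------------------------
# Temporal split
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    train: set[str]
    validation: set[str]
    test: set[str]

    def __post_init__(self) -> None:
        if (self.train & self.validation) or (self.train & self.test) or (
                self.validation & self.test):
            raise ValueError("split subsets must be disjoint")

    @property
    def all_ids(self) -> set[str]:
        return self.train | self.validation | self.test


def temporal_split(
    lineages: Sequence[HostLineage],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    group_rank: str = "species",
) -> DatasetSplit:
    """Date-ordered split: oldest plasmids train, newest test.

    Within each taxon group at ``group_rank`` the plasmids are sorted by
    release date (ties broken by plasmid id) and partitioned in order
    train -> validation -> test.  Sizes: train = floor(f_train * n),
    test = floor(f_test * n), validation = remainder, so newest items land
    in test.  Groups with fewer than 3 members go entirely to train.
    """
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rank_idx = RANKS.index(group_rank)
    groups: dict[tuple[str, ...], list[HostLineage]] = {}
    for lin in lineages:
        groups.setdefault(lin.ranks[: rank_idx + 1], []).append(lin)

    train: set[str] = set()
    val: set[str] = set()
    test: set[str] = set()
    for key, members in groups.items():
        members.sort(key=lambda l: (l.release_date, l.plasmid_id))
        n = len(members)
        if n < 3:
            logger.warning("taxon %s has %d plasmids (<3); all assigned to train",
                           "/".join(key), n)
            train.update(l.plasmid_id for l in members)
            continue
        n_train = int(np.floor(f_train * n))
        n_test = int(np.floor(f_test * n))
        n_val = n - n_train - n_test
        train.update(l.plasmid_id for l in members[:n_train])
        val.update(l.plasmid_id for l in members[n_train:n_train + n_val])
        test.update(l.plasmid_id for l in members[n_train + n_val:])
    return DatasetSplit(train=train, validation=val, test=test)


# ---------------------------------------------------------------------------
# Fragment augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    source_id: str
    start: int          # 0-based inclusive
    end: int            # 0-based exclusive
    sequence: str
    label: tuple[str, ...]


def augment_fragments(
    sequences: dict[str, str],
    labels: dict[str, tuple[str, ...]],
    n_per_seq: int,
    seed: int,
    min_len: int = 1500,
    max_len: int = 10_000,
) -> list[Fragment]:
    """Cut random contiguous fragments from training sequences.

    Fragment length is uniform on [min_len, min(max_len, len(source))] and
    the start is uniform over valid offsets; labels are inherited from the
    source plasmid.  Sources shorter than ``min_len`` are skipped with a
    warning.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: list[Fragment] = []
    for sid in sorted(sequences):
        seq = sequences[sid]
        if len(seq) < min_len:
            logger.warning("sequence %s is %d bp < %d; skipped", sid, len(seq), min_len)
            continue
        hi = min(max_len, len(seq))
        for _ in range(n_per_seq):
            length = int(rng.integers(min_len, hi + 1))
            start = int(rng.integers(0, len(seq) - length + 1))
            out.append(Fragment(source_id=sid, start=start, end=start + length,
                                sequence=seq[start:start + length],
                                label=labels[sid]))
    return out
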