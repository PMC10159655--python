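"""Token vocabularies: protein clusters via Markov Clustering, MOB/MPF, Inc.

The protein-cluster (PC) vocabulary is built from an all-against-all protein
alignment: hits at E <= 1e-3 define a similarity graph whose edge weights are
-log10(E), the graph is clustered with the Markov Clustering algorithm (MCL),
and every cluster with at least two members becomes one token.  Token 0 is
reserved for padding in every vocabulary.

MCL is implemented from its definition: the column-stochastic transition
matrix is alternately expanded (matrix self-multiplication) and inflated
(elementwise power followed by column renormalization), with small entries
pruned, until successive matrices stop changing.  Clusters are read off the
nonzero structure of the limit matrix.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .config import DEFAULT_MOBMPF_ORDER, EVALUE_CUTOFF, N_MOBMPF_TOKENS

logger = logging.getLogger(__name__)

#: weight assigned to an E-value of exactly 0 (-log10 diverges); ~ the
#: smallest positive double's exponent.
MAX_EDGE_WEIGHT = 300.0


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column tabular (outfmt-6 style) alignment."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.query_id}->{self.subject_id}")


class SimilarityGraph:
    """Weighted undirected protein similarity graph (no self-edges)."""

    def __init__(self) -> None:
        self._weights: dict[tuple[str, str], float] = {}
        self._nodes: set[str] = set()

    @property
    def nodes(self) -> set[str]:
        return self._nodes

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for (a, b), w in self._weights.items():
            yield a, b, w

    def n_edges(self) -> int:
        return len(self._weights)

    def add_node(self, node: str) -> None:
        self._nodes.add(node)

    def add_hit(self, a: str, b: str, weight: float) -> None:
        self._nodes.add(a)
        self._nodes.add(b)
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        prev = self._weights.get(key)
        if prev is None or weight > prev:
            self._weights[key] = weight

    def weight(self, a: str, b: str) -> float | None:
        key = (a, b) if a < b else (b, a)
        return self._weights.get(key)


def evalue_weight(evalue: float) -> float:
    """-log10(E), capped so that E = 0 stays finite."""
    if evalue <= 0:
        return MAX_EDGE_WEIGHT
    return min(-np.log10(evalue), MAX_EDGE_WEIGHT)


def build_similarity_graph(
    hits: Iterable[AlignmentHit],
    evalue_cutoff: float = EVALUE_CUTOFF,
) -> SimilarityGraph:
    """Graph over proteins with an edge for every qualifying pair.

    An edge (a, b) exists iff some hit in either direction has
    E <= ``evalue_cutoff``; its weight is -log10 of the smallest such
    E-value.  Self-hits contribute the node but no edge.
    """
    g = SimilarityGraph()
    for hit in hits:
        g.add_node(hit.query_id)
        g.add_node(hit.subject_id)
        if hit.evalue <= evalue_cutoff:
            g.add_hit(hit.query_id, hit.subject_id, evalue_weight(hit.evalue))
    return g


# ---------------------------------------------------------------------------
# Markov Clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinCluster:
    cluster_id: int
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune_threshold: float = 1e-5,
) -> list[ProteinCluster]:
    """Markov Clustering on the similarity graph.

    Self-loops are added with weight equal to the node's maximum incident
    edge weight (isolated nodes get weight 1) before column normalization;
    this is the usual regularization that keeps the random walk from
    oscillating on bipartite-like structures.  Returns a partition of the
    graph's nodes as clusters, deterministically ordered.
    """
    names = sorted(graph.nodes)
    if not names:
        raise ValueError("empty similarity graph")
    index = {n: i for i, n in enumerate(names)}
    n = len(names)

    rows, cols, vals = [], [], []
    max_incident = np.zeros(n)
    for a, b, w in graph.edges():
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        max_incident[i] = max(max_incident[i], w)
        max_incident[j] = max(max_incident[j], w)
    # self-loops
    loop = np.where(max_incident > 0, max_incident, 1.0)
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loop)

    m = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))

    def _normalize(mat: sp.csc_matrix) -> sp.csc_matrix:
        colsum = np.asarray(mat.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        return mat @ sp.diags(1.0 / colsum)

    m = _normalize(m)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m                      # expansion
        m = m.power(inflation)         # inflation
        m.data[m.data < prune_threshold] = 0.0
        m.eliminate_zeros()
        m = _normalize(m)
        diff = abs(m - prev)
        if diff.nnz == 0 or diff.max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; returning current "
                       "clustering", max_iter)

    # Clusters = connected components of the limit matrix's nonzero structure.
    structure = m + m.T
    n_comp, labels = connected_components(structure, directed=False)
    groups: dict[int, set[str]] = {}
    for name, lab in zip(names, labels):
        groups.setdefault(int(lab), set()).add(name)
    clusters = [frozenset(g) for g in groups.values()]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return [ProteinCluster(cluster_id=i, members=c) for i, c in enumerate(clusters)]


# ---------------------------------------------------------------------------
# PC vocabulary
# ---------------------------------------------------------------------------

class PCVocabulary:
    """Token ids 1..V over protein clusters with >= 2 members; 0 = padding."""

    PAD = 0

    def __init__(self, clusters: Sequence[ProteinCluster]):
        qualifying = [c for c in clusters if len(c) >= 2]
        if not qualifying:
            raise ValueError("no cluster has >= 2 members; vocabulary unusable")
        qualifying.sort(key=lambda c: (-len(c), min(c.members)))
        self._clusters: dict[int, ProteinCluster] = {}
        self._member_to_token: dict[str, int] = {}
        for tok, cluster in enumerate(qualifying, start=1):
            self._clusters[tok] = cluster
            for member in cluster.members:
                self._member_to_token[member] = tok

    @property
    def size(self) -> int:
        return len(self._clusters)

    def cluster(self, token: int) -> ProteinCluster:
        return self._clusters[token]

    def token_of_member(self, member_id: str) -> int | None:
        """Token for a clustered protein; None for an unknown/singleton."""
        return self._member_to_token.get(member_id)

    def __contains__(self, token: int) -> bool:
        return token in self._clusters

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for tok in sorted(self._clusters):
            h.update(f"{tok}:{','.join(sorted(self._clusters[tok].members))};".encode())
        return h.hexdigest()[:16]

    # -- persistence -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        rows = [dict(token_id=tok, member_ids=",".join(sorted(c.members)))
                for tok, c in sorted(self._clusters.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PCVocabulary":
        df = pd.read_csv(path, sep="\t")
        clusters = [ProteinCluster(cluster_id=int(r.token_id) - 1,
                                   members=frozenset(str(r.member_ids).split(",")))
                    for r in df.itertuples()]
        return cls(clusters)


def build_pc_vocabulary(clusters: Sequence[ProteinCluster]) -> PCVocabulary:
    """Vocabulary from MCL clusters (>= 2 members, deterministic numbering)."""
    return PCVocabulary(clusters)


# ---------------------------------------------------------------------------
# MOB/MPF and Inc token tables
# ---------------------------------------------------------------------------

class MobMpfVocabulary:
    """Fixed table of the 13 conjugation-typing tokens (9 MOB + 4 MPF).

    The mapping from family name to token id is configuration, loadable from
    a two-column TSV (token_id, name); ids must be exactly 1..13.
    """

    PAD = 0

    def __init__(self, order: Sequence[str] = DEFAULT_MOBMPF_ORDER):
        if len(order) != N_MOBMPF_TOKENS or len(set(order)) != N_MOBMPF_TOKENS:
            raise ValueError(f"MOB/MPF table must have exactly {N_MOBMPF_TOKENS} "
                             "distinct tokens")
        self._token_of = {name: i for i, name in enumerate(order, start=1)}
        self._name_of = {i: name for name, i in self._token_of.items()}

    @property
    def size(self) -> int:
        return N_MOBMPF_TOKENS

    def token_of(self, name: str) -> int:
        try:
            return self._token_of[name]
        except KeyError:
            raise KeyError(f"unknown MOB/MPF type {name!r}; known: "
                           f"{sorted(self._token_of)}") from None

    def name_of(self, token: int) -> str:
        return self._name_of[token]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MobMpfVocabulary":
        df = pd.read_csv(path, sep="\t").sort_values("token_id")
        if list(df.token_id) != list(range(1, N_MOBMPF_TOKENS + 1)):
            raise ValueError(f"{path}: token ids must be exactly 1..{N_MOBMPF_TOKENS}")
        return cls(list(df.name))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"token_id": sorted(self._name_of),
                      "name": [self._name_of[i] for i in sorted(self._name_of)]}
                     ).to_csv(path, sep="\t", index=False)


class IncTable:
    """Inc (incompatibility) group -> one-hot position, plus a 'none' slot."""

    NONE = "none"

    def __init__(self, groups: Sequence[str]):
        if len(set(groups)) != len(groups):
            raise ValueError("duplicate Inc group names")
        self.groups = list(groups)
        self._pos = {g: i for i, g in enumerate(self.groups)}
        self.none_pos = len(self.groups)

    @property
    def size(self) -> int:
        """One-hot vector length (groups + the 'none' position)."""
        return len(self.groups) + 1

    def position(self, group: str | None) -> int:
        if group is None:
            return self.none_pos
        try:
            return self._pos[group]
        except KeyError:
            raise KeyError(f"unknown Inc group {group!r}") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IncTable":
        df = pd.read_csv(path, sep="\t")
        return cls(list(df.name))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"name": self.groups}).to_csv(path, sep="\t", index=False)
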