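"""MC-dropout uncertainty and the uncertainty-guided top-down tree search.

At every classifier node the deterministic (dropout-disabled) forward pass
picks the child taxon; the same input then flows through the
dropout-enabled model T times (T = 100 by default) and the probability of
the predicted class is recorded for each pass.  The first moment of the
predictive distribution is approximated by the mean over the T passes and
the predictive variance by the second central moment, E[y^2] - E[y]^2
(population variance over the passes).  The tau^-1 model-precision term of
the full variational treatment is a constant offset that the stopping rule
never consults, so the sample variance alone acts as the uncertainty.

If the variance exceeds the active mode's cutoff, the tree search ends and
the current node's child prediction is discarded: the output lineage stops
at the current (parent) taxon.  Three modes: 'sensitive' never stops early,
'specific' stops at a loose cutoff, 'accurate' at a stricter one.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .backbone import BackboneTree, TaxonNode
from .config import CUTOFF_ACCURATE, CUTOFF_SPECIFIC, MC_PASSES, RANKS
from .encode import EncodedSample
from .model import NodeClassifier, model_path, stack_samples

logger = logging.getLogger(__name__)

MODES = ("sensitive", "specific", "accurate")

#: tau — the model-precision hyper-parameter of the variational derivation.
#: It only shifts the second moment by a constant (tau^-1) and therefore
#: never changes which predictions stop early; documented but unused.
TAU: float | None = None


@dataclass(frozen=True)
class UncertaintyConfig:
    mode: str = "sensitive"
    T: int = MC_PASSES
    cutoff_specific: float = CUTOFF_SPECIFIC
    cutoff_accurate: float = CUTOFF_ACCURATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.cutoff_accurate >= self.cutoff_specific:
            raise ValueError("accurate mode must use a stricter (smaller) cutoff "
                             "than specific mode")

    @property
    def cutoff(self) -> float | None:
        if self.mode == "specific":
            return self.cutoff_specific
        if self.mode == "accurate":
            return self.cutoff_accurate
        return None


@dataclass(frozen=True)
class UncertaintyEstimate:
    predicted_class: int
    mean_prob: float
    variance: float
    pass_probs: tuple[float, ...] = ()   # audit trail of the T recorded values


@dataclass
class HostPrediction:
    contig_id: str
    lineage: list[tuple[str, str]]              # (rank, taxon), phylum downward
    uncertainties: dict[str, float] = field(default_factory=dict)  # rank of the
    # classifier node (the parent) -> variance observed there
    stopped_early: bool = False
    stop_rank: str | None = None                # rank of the last reported taxon
    missing_model: bool = False

    def taxon_at(self, rank: str) -> str | None:
        for r, name in self.lineage:
            if r == rank:
                return name
        return None


# ---------------------------------------------------------------------------
# MC-dropout estimation
# ---------------------------------------------------------------------------

def mc_dropout_estimate(
    sample: EncodedSample,
    model: NodeClassifier,
    T: int = MC_PASSES,
    seed: int = 0,
) -> UncertaintyEstimate:
    """Mean and variance of the predicted class's probability over T passes."""
    est = mc_dropout_estimate_batch([sample], model, T=T, seed=seed)
    return est[0]


def mc_dropout_estimate_batch(
    samples: Sequence[EncodedSample],
    model: NodeClassifier,
    T: int = MC_PASSES,
    seed: int = 0,
) -> list[UncertaintyEstimate]:
    """Vectorized MC-dropout over a batch sharing one classifier.

    The predicted class per sample is the argmax of the deterministic pass
    (ties to the lower class index); its probability is then tracked across
    the T dropout-enabled passes.
    """
    if T < 2:
        raise ValueError("T must be >= 2 for a variance estimate")
    det = model.predict_proba(samples, rng=None)
    pred = det.argmax(axis=1)          # np.argmax takes the first (lowest) max
    if model.constant_class is not None:
        return [UncertaintyEstimate(int(p), 1.0, 0.0, tuple([1.0] * T))
                for p in pred]
    rng = np.random.default_rng(seed)
    track = np.empty((T, len(samples)))
    for t in range(T):
        probs = model.predict_proba(samples, rng=rng)
        track[t] = probs[np.arange(len(samples)), pred]
    mean = track.mean(axis=0)
    var = track.var(axis=0)            # population variance (divide by T)
    return [UncertaintyEstimate(int(pred[i]), float(mean[i]), float(var[i]),
                                tuple(track[:, i]))
            for i in range(len(samples))]


def early_stop_decision(est: UncertaintyEstimate, cfg: UncertaintyConfig) -> bool:
    """True iff the search should stop before accepting this node's prediction.

    Sensitive mode never stops; the other modes stop on strict inequality
    (variance exactly at the cutoff continues).
    """
    cutoff = cfg.cutoff
    if cutoff is None:
        return False
    return est.variance > cutoff


# ---------------------------------------------------------------------------
# Model store
# ---------------------------------------------------------------------------

class ModelStore:
    """Per-node classifier lookup, either in memory or lazily from disk.

    On-disk layout: one .npz per classifier node named by its sanitized
    root-to-node taxon path.  Only one model is held from disk at a time
    unless caching is enabled.
    """

    def __init__(self, models: Mapping[tuple[str, ...], NodeClassifier] | None = None,
                 directory: str | Path | None = None,
                 expect_vocab_hash: str | None = None, cache: bool = True):
        self._models = dict(models or {})
        self._dir = Path(directory) if directory else None
        self._hash = expect_vocab_hash
        self._cache = cache

    def get(self, node_path: tuple[str, ...]) -> NodeClassifier | None:
        if node_path in self._models:
            return self._models[node_path]
        if self._dir is not None:
            path = model_path(self._dir, node_path)
            if path.exists():
                model = NodeClassifier.load(path, expect_vocab_hash=self._hash)
                if self._cache:
                    self._models[node_path] = model
                return model
        return None

    def put(self, node_path: tuple[str, ...], model: NodeClassifier) -> None:
        self._models[node_path] = model
        if self._dir is not None:
            self._dir.mkdir(parents=True, exist_ok=True)
            model.save(model_path(self._dir, node_path))


# ---------------------------------------------------------------------------
# Tree search
# ---------------------------------------------------------------------------

@dataclass
class _Trace:
    """Full sensitive-depth trajectory with per-node variances.

    Modes only differ in where they truncate this trajectory, because the
    deterministic argmax descent is mode-independent; recording it once lets
    every mode's prediction be derived without re-running the network.
    """
    contig_id: str
    steps: list[tuple[str, str, float]]   # (rank of chosen taxon, taxon, variance
    #                                        observed at the parent classifier)
    auto_ranks: set[str] = field(default_factory=set)  # single-child descents
    missing_model: bool = False


def _trace_batch(samples: Sequence[EncodedSample], tree: BackboneTree,
                 models: ModelStore, T: int, seed: int,
                 need_uncertainty: bool = True) -> list[_Trace]:
    traces = [_Trace(s.contig_id, []) for s in samples]
    # frontier: node -> (node_path, list of sample indices)
    frontier: dict[tuple[str, ...], tuple[TaxonNode, list[int]]] = {
        (tree.root.name,): (tree.root, list(range(len(samples))))}
    while frontier:
        nxt: dict[tuple[str, ...], tuple[TaxonNode, list[int]]] = {}
        for node_path, (node, idxs) in sorted(frontier.items()):
            if not node.children:
                continue
            if len(node.children) == 1:
                (child,) = node.children.values()
                for i in idxs:
                    traces[i].steps.append((child.rank, child.name, np.nan))
                    traces[i].auto_ranks.add(child.rank)
                nxt.setdefault(node_path + (child.name,), (child, []))[1].extend(idxs)
                continue
            model = models.get(node_path)
            if model is None:
                logger.warning("no model for classifier node %s; predictions "
                               "truncated there", "/".join(node_path))
                for i in idxs:
                    traces[i].missing_model = True
                continue
            batch = [samples[i] for i in idxs]
            node_seed = (seed * 100003
                         + zlib.crc32("/".join(node_path).encode())) % (2**31)
            if need_uncertainty:
                ests = mc_dropout_estimate_batch(batch, model, T=T, seed=node_seed)
            else:
                det = model.predict_proba(batch, rng=None)
                ests = [UncertaintyEstimate(int(c), float(det[j, c]), float("nan"))
                        for j, c in enumerate(det.argmax(axis=1))]
            children = list(node.children.values())
            by_name = {c.name: c for c in children}
            for i, est in zip(idxs, ests):
                chosen = model.classes[est.predicted_class]
                child = by_name[chosen]
                traces[i].steps.append((child.rank, child.name, est.variance))
                nxt.setdefault(node_path + (child.name,),
                               (child, []))[1].extend([i])
        frontier = nxt
    return traces


def _apply_mode(trace: _Trace, cfg: UncertaintyConfig) -> HostPrediction:
    cutoff = cfg.cutoff
    lineage: list[tuple[str, str]] = []
    uncertainties: dict[str, float] = {}
    stopped = False
    for rank, name, var in trace.steps:
        if rank not in trace.auto_ranks:
            uncertainties[rank] = var
            if cutoff is not None and var > cutoff:
                stopped = True
                break
        lineage.append((rank, name))
    stop_rank = lineage[-1][0] if lineage else "root"
    return HostPrediction(contig_id=trace.contig_id, lineage=lineage,
                          uncertainties=uncertainties,
                          stopped_early=stopped and stop_rank != "species",
                          stop_rank=stop_rank,
                          missing_model=trace.missing_model)


def predict_host(sample: EncodedSample, tree: BackboneTree, models: ModelStore,
                 cfg: UncertaintyConfig = UncertaintyConfig()) -> HostPrediction:
    """Top-down search from the root for one contig.

    Single-child nodes are descended automatically; at classifier nodes the
    deterministic forward pass picks the child, MC-dropout estimates the
    uncertainty, and the mode's cutoff decides whether to stop.  On early
    stop the discarded child prediction is not reported and the lineage ends
    at the current node.
    """
    return predict_hosts([sample], tree, models, cfg)[0]


def predict_hosts(samples: Sequence[EncodedSample], tree: BackboneTree,
                  models: ModelStore,
                  cfg: UncertaintyConfig = UncertaintyConfig(),
                  report_uncertainty: bool = True) -> list[HostPrediction]:
    """Batched tree search; equivalent to predict_host per sample.

    ``report_uncertainty=False`` skips the MC passes in sensitive mode (where
    they never affect the lineage) and reports NaN uncertainties instead.
    """
    need_mc = cfg.mode != "sensitive" or report_uncertainty
    traces = _trace_batch(samples, tree, models, T=cfg.T, seed=cfg.seed,
                          need_uncertainty=need_mc)
    return [_apply_mode(t, cfg) for t in traces]


def predict_all_modes(samples: Sequence[EncodedSample], tree: BackboneTree,
                      models: ModelStore, cfg: UncertaintyConfig
                      ) -> dict[str, list[HostPrediction]]:
    """One traversal, all three modes (they share the same MC estimates)."""
    traces = _trace_batch(samples, tree, models, T=cfg.T, seed=cfg.seed)
    out = {}
    for mode in MODES:
        mode_cfg = UncertaintyConfig(mode=mode, T=cfg.T,
                                     cutoff_specific=cfg.cutoff_specific,
                                     cutoff_accurate=cfg.cutoff_accurate,
                                     seed=cfg.seed)
        out[mode] = [_apply_mode(t, mode_cfg) for t in traces]
    return out
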