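"""Per-node taxon classifier: two Transformer encoders + fused linear head.

Each classifier node of the backbone owns one of these models.  The
protein-cluster sentence and the MOB/MPF sentence each pass through a
Transformer encoder block (token embedding + learned positional embedding,
dropout on their sum, masked multi-head self-attention, a two-layer
feed-forward network with one dropout inside and one after — three dropout
sites per block).  The two pooled feature vectors are concatenated with the
Inc one-hot, a seventh dropout is applied to the concatenation, and a linear
layer produces logits over the node's child taxa.

Multi-head attention follows the standard scaled-dot-product form: per head
i, head_i = Attention(X W_i^Q, X W_i^K, X W_i^V) with all three projections
of shape embed x d_head (d_head = embed / h, h = 8 by default); the h heads
are concatenated and projected by W^O of shape (h * d_head) x embed.
Padding positions are masked out of the attention softmax, so appending
padding never changes the pooled features.

Training uses cross-entropy loss and Adam at learning rate 0.005 for 50
epochs (the published recipe); classifiers at different nodes are trained
individually.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor
from .config import (BATCH_SIZE, DROPOUT_RATE, EPOCHS, LEARNING_RATE,
                     MOBMPF_SENTENCE_LEN, N_MOBMPF_TOKENS, PC_SENTENCE_LEN)
from .encode import EncodedSample

logger = logging.getLogger(__name__)

_NEG = -1e30  # additive attention mask for padded keys


@dataclass(frozen=True)
class TransformerConfig:
    vocab_size: int                 # number of non-padding tokens V
    max_len: int                    # 400 (PC) or 50 (MOB/MPF)
    embed: int = 64
    h: int = 8                      # attention heads
    ffn_width: int = 128
    dropout_rate: float = DROPOUT_RATE

    def __post_init__(self) -> None:
        if self.embed % self.h != 0:
            raise ValueError(f"embed={self.embed} not divisible by h={self.h}")

    @property
    def d_head(self) -> int:
        return self.embed // self.h


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = LEARNING_RATE
    epochs: int = EPOCHS
    batch_size: int = BATCH_SIZE
    seed: int = 0
    # plateau exit: stop before the epoch cap once the mean epoch loss has
    # improved by less than ``plateau_min_delta`` for ``plateau_patience``
    # consecutive epochs; set patience to 0 to disable
    plateau_patience: int = 5
    plateau_min_delta: float = 1e-3


@dataclass
class AttentionWeights:
    """Per-head projection matrices, shapes per the multi-head definition."""

    wq: np.ndarray  # (h, embed, d_head)
    wk: np.ndarray  # (h, embed, d_head)
    wv: np.ndarray  # (h, embed, d_head)
    wo: np.ndarray  # (h * d_head, embed)


def multi_head_attention(
    x: np.ndarray,
    weights: AttentionWeights,
    key_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Multi-head scaled-dot-product attention on one sequence.

    ``x``: (len, embed).  Per head: softmax(Q K^T / sqrt(d_head)) V with
    Q = X W^Q etc.; heads are concatenated and projected by W^O.  Keys where
    ``key_mask`` is False are excluded from every softmax.  Returns
    (len, embed).
    """
    out = _attention_graph(Tensor(x[None]), weights_as_params(weights),
                           key_mask if key_mask is None else key_mask[None])
    return out.data[0]


def weights_as_params(w: AttentionWeights) -> dict[str, Tensor]:
    return {"wq": Tensor(w.wq), "wk": Tensor(w.wk), "wv": Tensor(w.wv),
            "wo": Tensor(w.wo)}


def _attention_graph(x: Tensor, w: dict[str, Tensor],
                     key_mask: np.ndarray | None) -> Tensor:
    """Batched attention graph; x: (B, L, E) -> (B, L, E)."""
    b, length, embed = x.shape
    h, _, d_head = w["wq"].shape
    x4 = ag.reshape(x, (b, 1, length, embed))
    # scaling by 1/sqrt(d_head) applied to Q (cheaper than scaling the
    # L x L score matrix; identical result)
    q = ag.scale(ag.matmul(x4, w["wq"]), 1.0 / np.sqrt(d_head))  # (B, h, L, d)
    k = ag.matmul(x4, w["wk"])
    v = ag.matmul(x4, w["wv"])
    scores = ag.matmul(q, ag.transpose(k, (0, 1, 3, 2)))         # (B, h, L, L)
    mask_add = None
    if key_mask is not None:
        mask_add = np.where(key_mask[:, None, None, :], 0.0, _NEG)
    attn = ag.softmax(scores, mask_add=mask_add)
    ctx = ag.matmul(attn, v)                        # (B, h, L, d)
    ctx = ag.transpose(ctx, (0, 2, 1, 3))           # (B, L, h, d)
    ctx = ag.reshape(ctx, (b, length, h * d_head))
    return ag.matmul(ctx, w["wo"])                  # (B, L, E)


class TransformerBlock:
    """One encoder block producing a pooled fixed-length feature vector."""

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        self.cfg = cfg
        e, h, d = cfg.embed, cfg.h, cfg.d_head
        def init(*shape: int, scale: float | None = None) -> Parameter:
            if scale is None:
                scale = np.sqrt(2.0 / sum(shape[-2:]))
            return Parameter(rng.normal(0.0, scale, size=shape)
                             .astype(np.float32))
        self.tok_emb = init(cfg.vocab_size + 1, e, scale=0.1)
        self.pos_emb = init(cfg.max_len + 1, e, scale=0.1)
        self.tok_emb.data[0] = 0.0
        self.pos_emb.data[0] = 0.0
        self.attn = {"wq": init(h, e, d), "wk": init(h, e, d),
                     "wv": init(h, e, d), "wo": init(h * d, e)}
        self.w1 = init(e, cfg.ffn_width)
        self.b1 = Parameter(np.zeros(cfg.ffn_width, dtype=np.float32))
        self.w2 = init(cfg.ffn_width, e)
        self.b2 = Parameter(np.zeros(e, dtype=np.float32))

    def parameters(self) -> list[Parameter]:
        return [self.tok_emb, self.pos_emb, *self.attn.values(),
                self.w1, self.b1, self.w2, self.b2]

    def forward(self, tokens: np.ndarray, positions: np.ndarray,
                rng: np.random.Generator | None) -> Tensor:
        """tokens/positions: (B, max_len) -> pooled features (B, embed).

        The computation is trimmed to the longest non-padding prefix in the
        batch; because padded keys are masked out of attention and excluded
        from pooling, trimming does not change the result.
        """
        if np.any(tokens > self.cfg.vocab_size):
            raise ValueError("token id exceeds vocabulary size (stale vocabulary?)")
        mask = tokens > 0
        eff = int(mask.any(axis=0).nonzero()[0].max()) + 1 if mask.any() else 1
        tokens = tokens[:, :eff]
        positions = np.clip(positions[:, :eff], 0, self.cfg.max_len)
        mask = mask[:, :eff]

        p = self.cfg.dropout_rate
        x = ag.add(ag.embedding(self.tok_emb, tokens),
                   ag.embedding(self.pos_emb, positions))
        x = ag.dropout(x, p, rng)                       # dropout site 1
        x = _attention_graph(x, self.attn, mask)
        hmid = ag.relu(ag.add(ag.matmul(x, self.w1), self.b1))
        hmid = ag.dropout(hmid, p, rng)                 # dropout site 2
        x = ag.add(ag.matmul(hmid, self.w2), self.b2)
        x = ag.dropout(x, p, rng)                       # dropout site 3
        return ag.masked_mean_pool(x, mask)


class NodeClassifier:
    """Classifier over one backbone node's child taxa."""

    def __init__(self, classes: Sequence[str], pc_cfg: TransformerConfig,
                 mob_cfg: TransformerConfig, inc_dim: int, seed: int = 0,
                 dropout_rate: float = DROPOUT_RATE):
        if len(classes) < 2:
            raise ValueError("a classifier needs at least two child taxa")
        self.classes = list(classes)
        self.pc_cfg = pc_cfg
        self.mob_cfg = mob_cfg
        self.inc_dim = inc_dim
        self.seed = seed
        self.dropout_rate = dropout_rate
        self.vocab_hash: str | None = None
        self.constant_class: int | None = None
        self.training_log: list[float] = []

        rng = np.random.default_rng(seed)
        self.pc_block = TransformerBlock(pc_cfg, rng)
        self.mob_block = TransformerBlock(mob_cfg, rng)
        concat_dim = pc_cfg.embed + mob_cfg.embed + inc_dim
        self.head_w = Parameter(rng.normal(0, np.sqrt(1.0 / concat_dim),
                                           size=(concat_dim, len(classes)))
                                .astype(np.float32))
        self.head_b = Parameter(np.zeros(len(classes), dtype=np.float32))

    # -- introspection ---------------------------------------------------
    def dropout_sites(self) -> list[str]:
        """Names of the distinct dropout sites applied in one forward pass."""
        return (["pc.embedding_sum", "pc.ffn_hidden", "pc.ffn_out",
                 "mob.embedding_sum", "mob.ffn_hidden", "mob.ffn_out",
                 "fusion.concat"])

    def parameters(self) -> list[Parameter]:
        return (self.pc_block.parameters() + self.mob_block.parameters()
                + [self.head_w, self.head_b])

    # -- forward ---------------------------------------------------------
    def forward_batch(self, pc_tokens: np.ndarray, pc_positions: np.ndarray,
                      mob_tokens: np.ndarray, inc: np.ndarray,
                      rng: np.random.Generator | None) -> Tensor:
        """Logits (B, C); ``rng`` enables the 7 dropout sites."""
        mob_positions = np.where(mob_tokens > 0,
                                 np.arange(1, mob_tokens.shape[1] + 1), 0)
        pc_feat = self.pc_block.forward(pc_tokens, pc_positions, rng)
        mob_feat = self.mob_block.forward(mob_tokens, mob_positions, rng)
        fused = ag.concat([pc_feat, mob_feat, Tensor(inc)], axis=-1)
        fused = ag.dropout(fused, self.dropout_rate, rng)   # dropout site 7
        return ag.add(ag.matmul(fused, self.head_w), self.head_b)

    def predict_proba(self, samples: Sequence[EncodedSample],
                      rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities (B, C); deterministic when ``rng`` is None."""
        if self.constant_class is not None:
            probs = np.zeros((len(samples), len(self.classes)))
            probs[:, self.constant_class] = 1.0
            return probs
        pc_t, pc_p, mob_t, inc = stack_samples(samples)
        chunks = []
        with ag.no_grad():
            for lo in range(0, len(samples), 256):
                hi = lo + 256
                logits = self.forward_batch(pc_t[lo:hi], pc_p[lo:hi],
                                            mob_t[lo:hi], inc[lo:hi], rng)
                chunks.append(ag.softmax(logits).data)
        return np.concatenate(chunks, axis=0)

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        manifest = dict(classes=self.classes, inc_dim=self.inc_dim,
                        seed=self.seed, dropout_rate=self.dropout_rate,
                        vocab_hash=self.vocab_hash,
                        constant_class=self.constant_class,
                        pc_cfg=vars_of(self.pc_cfg), mob_cfg=vars_of(self.mob_cfg))
        np.savez(path, manifest=json.dumps(manifest), **arrays)

    @classmethod
    def load(cls, path: str | Path,
             expect_vocab_hash: str | None = None) -> "NodeClassifier":
        with np.load(Path(path), allow_pickle=False) as data:
            manifest = json.loads(str(data["manifest"]))
            if (expect_vocab_hash is not None
                    and manifest["vocab_hash"] != expect_vocab_hash):
                raise ValueError(
                    f"{path}: model was trained against vocabulary "
                    f"{manifest['vocab_hash']}, expected {expect_vocab_hash}")
            model = cls(classes=manifest["classes"],
                        pc_cfg=TransformerConfig(**manifest["pc_cfg"]),
                        mob_cfg=TransformerConfig(**manifest["mob_cfg"]),
                        inc_dim=manifest["inc_dim"], seed=manifest["seed"],
                        dropout_rate=manifest["dropout_rate"])
            model.vocab_hash = manifest["vocab_hash"]
            model.constant_class = manifest["constant_class"]
            for i, p in enumerate(model.parameters()):
                p.data = np.array(data[f"p{i}"])
        return model


def vars_of(cfg: TransformerConfig) -> dict:
    return dict(vocab_size=cfg.vocab_size, max_len=cfg.max_len, embed=cfg.embed,
                h=cfg.h, ffn_width=cfg.ffn_width, dropout_rate=cfg.dropout_rate)


def stack_samples(samples: Sequence[EncodedSample]
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    return (np.stack([s.pc_tokens for s in samples]),
            np.stack([s.pc_positions for s in samples]),
            np.stack([s.mobmpf_tokens for s in samples]),
            np.stack([s.inc_onehot for s in samples]))


def classifier_forward(sample: EncodedSample, model: NodeClassifier,
                       dropout_enabled: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Probability vector over the node's child taxa for one sample."""
    if dropout_enabled and rng is None:
        rng = np.random.default_rng(0)
    return model.predict_proba([sample], rng=rng if dropout_enabled else None)[0]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_node_classifier(
    samples: Sequence[EncodedSample],
    classes: Sequence[str],
    pc_cfg: TransformerConfig,
    mob_cfg: TransformerConfig,
    inc_dim: int,
    cfg: TrainingConfig = TrainingConfig(),
    vocab_hash: str | None = None,
    label_index: int | None = None,
) -> NodeClassifier:
    """Train one node's classifier on samples labeled with its child taxa.

    When ``label_index`` is given, the class is the element at that depth of
    the sample's (truncated) lineage; otherwise the deepest element that is
    one of ``classes``.  Single-class input produces a constant classifier
    with a warning; empty input is an error.
    """
    if not samples:
        raise ValueError("no training samples for this node")
    class_idx = {c: i for i, c in enumerate(classes)}
    labels = []
    for s in samples:
        if s.label is None:
            raise ValueError(f"{s.contig_id}: sample has no label")
        if label_index is not None:
            hit = [s.label[label_index]] if len(s.label) > label_index else []
        else:
            hit = [t for t in s.label if t in class_idx]
        if not hit or hit[-1] not in class_idx:
            raise ValueError(f"{s.contig_id}: label {s.label} contains none of "
                             f"the node's children {list(classes)}")
        labels.append(class_idx[hit[-1]])
    labels = np.asarray(labels)

    model = NodeClassifier(classes, pc_cfg, mob_cfg, inc_dim, seed=cfg.seed,
                           dropout_rate=pc_cfg.dropout_rate)
    model.vocab_hash = vocab_hash
    present = np.unique(labels)
    if len(present) == 1:
        logger.warning("single-class training input; emitting constant classifier "
                       "for %s", classes[present[0]])
        model.constant_class = int(present[0])
        return model

    pc_t, pc_p, mob_t, inc = stack_samples(samples)
    rng = np.random.default_rng(cfg.seed)
    opt = ag.Adam(model.parameters(), lr=cfg.learning_rate)
    n = len(samples)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits = model.forward_batch(pc_t[idx], pc_p[idx], mob_t[idx],
                                         inc[idx], rng)
            loss = ag.cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.training_log.append(float(np.mean(losses)))
        logger.debug("epoch %d mean loss %.4f", epoch + 1, model.training_log[-1])
        if cfg.plateau_patience > 0 and len(model.training_log) > cfg.plateau_patience:
            recent = model.training_log[-(cfg.plateau_patience + 1):]
            if all(prev - cur < cfg.plateau_min_delta
                   for prev, cur in zip(recent, recent[1:])):
                logger.info("loss plateaued; stopping after epoch %d", epoch + 1)
                break
    return model


def train_hierarchy(
    tree,                              # BackboneTree (kept untyped: no import cycle)
    samples: Sequence[EncodedSample],
    pc_vocab_size: int,
    inc_dim: int,
    cfg: TrainingConfig = TrainingConfig(),
    vocab_hash: str | None = None,
    pc_embed: int = 64,
    mob_embed: int = 32,
    dropout_rate: float = DROPOUT_RATE,
) -> dict[tuple[str, ...], NodeClassifier]:
    """Train every classifier node of the backbone individually.

    Samples carry (possibly truncated) lineage labels; a sample trains the
    classifier at a node iff its label passes through the node and extends at
    least one rank below it.  Single-child nodes get no model (the search
    auto-descends).  Returns models keyed by root-to-node taxon path.
    """
    import zlib

    pc_cfg = TransformerConfig(vocab_size=pc_vocab_size, max_len=PC_SENTENCE_LEN,
                               embed=pc_embed, ffn_width=2 * pc_embed,
                               dropout_rate=dropout_rate)
    mob_cfg = TransformerConfig(vocab_size=N_MOBMPF_TOKENS,
                                max_len=MOBMPF_SENTENCE_LEN, embed=mob_embed,
                                ffn_width=2 * mob_embed, dropout_rate=dropout_rate)
    models: dict[tuple[str, ...], NodeClassifier] = {}

    def _walk(node, node_path: tuple[str, ...]) -> None:
        depth = len(node_path) - 1      # lineage index of this node's children
        if node.has_classifier:
            prefix = node_path[1:]
            node_samples = [s for s in samples
                            if s.label is not None and len(s.label) > depth
                            and s.label[:depth] == prefix]
            if node_samples:
                node_seed = (cfg.seed * 100003
                             + zlib.crc32("/".join(node_path).encode())) % (2**31)
                node_cfg = TrainingConfig(learning_rate=cfg.learning_rate,
                                          epochs=cfg.epochs,
                                          batch_size=cfg.batch_size,
                                          seed=node_seed,
                                          plateau_patience=cfg.plateau_patience,
                                          plateau_min_delta=cfg.plateau_min_delta)
                classes = list(node.children)
                logger.info("training %s (%d classes, %d samples)",
                            "/".join(node_path), len(classes), len(node_samples))
                models[node_path] = train_node_classifier(
                    node_samples, classes, pc_cfg, mob_cfg, inc_dim,
                    cfg=node_cfg, vocab_hash=vocab_hash, label_index=depth)
            else:
                logger.warning("classifier node %s has no training samples",
                               "/".join(node_path))
        for child in node.children.values():
            _walk(child, node_path + (child.name,))

    _walk(tree.root, (tree.root.name,))
    return models


# ---------------------------------------------------------------------------
# Model directory layout
# ---------------------------------------------------------------------------

def sanitize_node_name(path_names: Sequence[str]) -> str:
    joined = "__".join(path_names)
    return re.sub(r"[^A-Za-z0-9_.-]", "_", joined)


def model_path(models_dir: str | Path, node_path: Sequence[str]) -> Path:
    return Path(models_dir) / (sanitize_node_name(node_path) + ".npz")
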