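"""Pipeline configuration and the scalar constants shared across the pipeline.

All thresholds that govern preprocessing, encoding, model shape and the
uncertainty-guided tree search live here so that a run can log one resolved
configuration object.  Defaults follow the published method: alignment hits
are kept at E-value <= 1e-3, contigs must be 1.5--350 kb, the protein-cluster
sentence is 400 tokens, the MOB/MPF sentence 50 tokens, uncertainty is
estimated from T = 100 stochastic forward passes, and training uses Adam at
learning rate 0.005 for 50 epochs with cross-entropy loss.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("plasmidhost")

# Taxonomic ranks, root first.  Depth of a complete tree is 7.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")
ROOT_RANK = "root"
ROOT_NAME = "Bacteria"

# Preprocessing / encoding constants.
EVALUE_CUTOFF = 1e-3
MIN_CONTIG_LEN = 1500
MAX_CONTIG_LEN = 350_000
PC_SENTENCE_LEN = 400
MOBMPF_SENTENCE_LEN = 50
N_MOBMPF_TOKENS = 13  # nine MOB relaxase families + four MPF system types

# Default MOB/MPF token table (ids 1..13; 0 is padding).  The mapping is data,
# not code: replicon/conjugation typing pipelines differ in the order they
# emit families, so the table can be overridden from a token-table file.
DEFAULT_MOBMPF_ORDER: tuple[str, ...] = (
    "MOBF", "MOBH", "MOBQ", "MOBC", "MOBP", "MOBV", "MOBT", "MOBB", "MOBM",
    "MPFT", "MPFF", "MPFG", "MPFI",
)

# Uncertainty / search defaults.
MC_PASSES = 100
CUTOFF_SPECIFIC = 0.01
CUTOFF_ACCURATE = 0.002

# Training defaults.
LEARNING_RATE = 0.005
EPOCHS = 50
BATCH_SIZE = 32
DROPOUT_RATE = 0.2

# Rare-taxon pruning.
MIN_SAMPLES_PER_TAXON = 10

# Fragment augmentation bounds (bp).
FRAGMENT_MIN_LEN = 1500
FRAGMENT_MAX_LEN = 10_000


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    Paths may be None when a stage does not need them; thresholds default to
    the published constants above.  ``dump``/``load`` round-trip through YAML.
    """

    vocabulary_path: Path | None = None
    mobmpf_table_path: Path | None = None
    inc_table_path: Path | None = None
    models_dir: Path | None = None
    tree_path: Path | None = None

    evalue_cutoff: float = EVALUE_CUTOFF
    min_contig_len: int = MIN_CONTIG_LEN
    max_contig_len: int = MAX_CONTIG_LEN
    pc_sentence_len: int = PC_SENTENCE_LEN
    mobmpf_sentence_len: int = MOBMPF_SENTENCE_LEN
    mc_passes: int = MC_PASSES
    cutoff_specific: float = CUTOFF_SPECIFIC
    cutoff_accurate: float = CUTOFF_ACCURATE
    min_samples_per_taxon: int = MIN_SAMPLES_PER_TAXON
    seed: int = 0

    # Command templates for external annotators ({input}/{output} placeholders).
    tool_templates: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("vocabulary_path", "mobmpf_table_path", "inc_table_path",
                    "models_dir", "tree_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def log_resolved(self) -> None:
        logger.info("resolved config: %s", json.dumps(self.to_dict(), sort_keys=True))


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with a terse format."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("plasmidhost")
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(level)
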