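import datetime as dt

import numpy as np
import pytest

from plasmidhost.backbone import HostLineage
from plasmidhost.encode import EncodedSample
from plasmidhost.model import TrainingConfig, TransformerConfig


def make_lineage(pid, ranks, date="2020-01-01", length=5000):
    return HostLineage(plasmid_id=pid, ranks=tuple(ranks),
                       release_date=dt.date.fromisoformat(date),
                       length_bp=length)


def lineage_path(phylum="P", cls="C", order="O", family="F", genus="G",
                 species="S"):
    return (phylum, cls, order, family, genus, species)


@pytest.fixture
def small_transformer_cfgs():
    pc = TransformerConfig(vocab_size=30, max_len=400, embed=16, h=2,
                           ffn_width=32, dropout_rate=0.2)
    mob = TransformerConfig(vocab_size=13, max_len=50, embed=8, h=2,
                            ffn_width=16, dropout_rate=0.2)
    return pc, mob


def make_sample(contig_id, pc_token_list, label=None, inc_dim=4, seed=None,
                mob_token_list=()):
    pc = np.zeros(400, dtype=np.int64)
    pos = np.zeros(400, dtype=np.int64)
    pc[:len(pc_token_list)] = pc_token_list
    pos[:len(pc_token_list)] = np.arange(1, len(pc_token_list) + 1)
    mob = np.zeros(50, dtype=np.int64)
    mob[:len(mob_token_list)] = mob_token_list
    inc = np.zeros(inc_dim)
    inc[-1] = 1.0
    return EncodedSample(contig_id=contig_id, pc_tokens=pc, pc_positions=pos,
                         mobmpf_tokens=mob, inc_onehot=inc, label=label)


@pytest.fixture(scope="session")
def quick_training_cfg():
    return TrainingConfig(epochs=8, seed=3)
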