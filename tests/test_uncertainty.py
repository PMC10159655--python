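"""MC-dropout estimates, the stopping rule and the top-down tree search."""

import numpy as np
import pytest

from plasmidhost.backbone import build_tree
from plasmidhost.model import TrainingConfig, train_hierarchy
from plasmidhost.uncertainty import (MODES, ModelStore, UncertaintyConfig,
                                     UncertaintyEstimate, early_stop_decision,
                                     mc_dropout_estimate_batch,
                                     predict_all_modes, predict_host,
                                     predict_hosts)
from tests.conftest import make_lineage, make_sample


class StubModel:
    """Scripted per-pass probabilities for checking the moment arithmetic."""

    constant_class = None

    def __init__(self, det, passes):
        self.det = np.asarray(det)
        self.passes = [np.asarray(p) for p in passes]
        self.classes = [f"k{i}" for i in range(self.det.shape[1])]
        self._i = 0

    def predict_proba(self, samples, rng=None):
        if rng is None:
            return self.det
        out = self.passes[self._i % len(self.passes)]
        self._i += 1
        return out


class TestMomentArithmetic:
    def test_frozen_oracle_mean_and_variance(self):
        # Predicted class 0 with per-pass probabilities .5, .7, .6, .6:
        # mean .6, population variance ((.1)^2+(.1)^2+0+0)/4 = 0.005.
        det = [[0.9, 0.1]]
        passes = [[[p, 1 - p]] for p in (0.5, 0.7, 0.6, 0.6)]
        (est,) = mc_dropout_estimate_batch([make_sample("a", [1])],
                                           StubModel(det, passes), T=4, seed=0)
        assert est.predicted_class == 0
        assert est.mean_prob == pytest.approx(0.6)
        assert est.variance == pytest.approx(0.005)
        assert est.pass_probs == (0.5, 0.7, 0.6, 0.6)

    def test_deterministic_argmax_tie_takes_lower_class(self):
        det = [[0.5, 0.5]]
        (est,) = mc_dropout_estimate_batch([make_sample("a", [1])],
                                           StubModel(det, [det, det]),
                                           T=2, seed=0)
        assert est.predicted_class == 0

    def test_t_below_two_rejected(self):
        with pytest.raises(ValueError):
            mc_dropout_estimate_batch([make_sample("a", [1])],
                                      StubModel([[1.0, 0.0]], [[[1.0, 0.0]]]),
                                      T=1)

    def test_zero_dropout_model_has_zero_variance(self, small_transformer_cfgs):
        from plasmidhost.model import NodeClassifier, TransformerConfig
        pc = TransformerConfig(vocab_size=30, max_len=400, embed=16, h=2,
                               ffn_width=32, dropout_rate=0.0)
        mob = TransformerConfig(vocab_size=13, max_len=50, embed=8, h=2,
                                ffn_width=16, dropout_rate=0.0)
        model = NodeClassifier(["X", "Y"], pc, mob, inc_dim=4, seed=1,
                               dropout_rate=0.0)
        (est,) = mc_dropout_estimate_batch([make_sample("a", [2, 5])], model,
                                           T=5, seed=0)
        assert est.variance == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_reproduces_estimates(self, small_transformer_cfgs):
        from plasmidhost.model import NodeClassifier
        pc_cfg, mob_cfg = small_transformer_cfgs
        model = NodeClassifier(["X", "Y"], pc_cfg, mob_cfg, inc_dim=4, seed=1)
        s = [make_sample("a", [2, 5, 9])]
        e1 = mc_dropout_estimate_batch(s, model, T=10, seed=4)[0]
        e2 = mc_dropout_estimate_batch(s, model, T=10, seed=4)[0]
        e3 = mc_dropout_estimate_batch(s, model, T=10, seed=5)[0]
        assert e1.pass_probs == e2.pass_probs
        assert e1.pass_probs != e3.pass_probs


class TestStoppingRule:
    def cfg(self, mode):
        return UncertaintyConfig(mode=mode)

    def test_sensitive_never_stops(self):
        est = UncertaintyEstimate(0, 0.5, 1.0)
        assert not early_stop_decision(est, self.cfg("sensitive"))

    def test_variance_exactly_at_cutoff_continues(self):
        est = UncertaintyEstimate(0, 0.5, 0.01)
        assert not early_stop_decision(est, self.cfg("specific"))
        assert early_stop_decision(UncertaintyEstimate(0, 0.5, 0.0100001),
                                   self.cfg("specific"))

    def test_accurate_cutoff_is_stricter(self):
        est = UncertaintyEstimate(0, 0.5, 0.005)
        assert not early_stop_decision(est, self.cfg("specific"))
        assert early_stop_decision(est, self.cfg("accurate"))

    def test_invalid_mode_and_cutoff_order_rejected(self):
        with pytest.raises(ValueError):
            UncertaintyConfig(mode="bogus")
        with pytest.raises(ValueError):
            UncertaintyConfig(cutoff_specific=0.001, cutoff_accurate=0.01)


@pytest.fixture(scope="module")
def trained_search():
    """Tiny two-classifier hierarchy trained on separable token blocks.

    Root splits P1 / P2; under P1 the genus node splits S1a / S1b; every
    other node is a single-child auto-descent.
    """
    lineages = []
    samples = []
    blocks = {("P1", "C1", "O1", "F1", "G1", "S1a"): range(1, 10),
              ("P1", "C1", "O1", "F1", "G1", "S1b"): range(11, 20),
              ("P2", "C2", "O2", "F2", "G2", "S2"): range(21, 30)}
    rng = np.random.default_rng(0)
    i = 0
    for lineage, block in blocks.items():
        for _ in range(8):
            pid = f"p{i}"; i += 1
            lineages.append(make_lineage(pid, lineage))
            samples.append(make_sample(pid, list(rng.choice(list(block), 6)),
                                       label=lineage))
    tree = build_tree(lineages)
    models = ModelStore(train_hierarchy(
        tree, samples, pc_vocab_size=40, inc_dim=4,
        cfg=TrainingConfig(epochs=25, batch_size=8, seed=2),
        pc_embed=16, mob_embed=8))
    return tree, models, blocks


class TestTreeSearch:
    def test_sensitive_mode_reaches_species_with_valid_lineage(
            self, trained_search):
        tree, models, blocks = trained_search
        s = make_sample("q", [3, 5, 7, 2])
        pred = predict_host(s, tree, models, UncertaintyConfig(T=5))
        assert [r for r, _ in pred.lineage] == ["phylum", "class", "order",
                                                "family", "genus", "species"]
        names = tuple(n for _, n in pred.lineage)
        assert names in blocks            # a real root-to-leaf path
        assert pred.stop_rank == "species" and not pred.stopped_early

    def test_separable_queries_recover_their_species(self, trained_search):
        tree, models, blocks = trained_search
        for lineage, block in blocks.items():
            s = make_sample("q", list(block)[:5])
            pred = predict_host(s, tree, models, UncertaintyConfig(T=5))
            assert tuple(n for _, n in pred.lineage) == lineage

    def test_uncertainties_recorded_only_at_classifier_ranks(
            self, trained_search):
        tree, models, _ = trained_search
        pred = predict_host(make_sample("q", [3, 5]), tree, models,
                            UncertaintyConfig(T=5))
        assert set(pred.uncertainties) == {"phylum", "species"}

    def test_sensitive_equals_specific_with_infinite_cutoff(
            self, trained_search):
        tree, models, _ = trained_search
        s = [make_sample("q", [13, 15, 17])]
        sens = predict_hosts(s, tree, models,
                             UncertaintyConfig(mode="sensitive", T=5, seed=9))
        spec = predict_hosts(s, tree, models,
                             UncertaintyConfig(mode="specific", T=5, seed=9,
                                               cutoff_specific=1e9))
        assert sens[0].lineage == spec[0].lineage

    def test_modes_give_nested_lineages(self, trained_search):
        tree, models, _ = trained_search
        queries = [make_sample(f"q{i}", [1 + i, 12, 25]) for i in range(6)]
        by_mode = predict_all_modes(queries, tree, models,
                                    UncertaintyConfig(T=8, seed=1))
        assert set(by_mode) == set(MODES)
        for i in range(len(queries)):
            sens = by_mode["sensitive"][i].lineage
            spec = by_mode["specific"][i].lineage
            acc = by_mode["accurate"][i].lineage
            assert spec == sens[:len(spec)]
            assert acc == spec[:len(acc)]

    def test_tight_cutoff_truncates_ambiguous_query(self, trained_search):
        tree, models, _ = trained_search
        # tokens straddling both phyla blocks: high variance at some node
        s = [make_sample("q", [5, 25, 15, 2, 28])]
        pred = predict_hosts(s, tree, models,
                             UncertaintyConfig(mode="accurate", T=20, seed=0,
                                               cutoff_specific=1e-11,
                                               cutoff_accurate=1e-12))[0]
        assert len(pred.lineage) < 6 and pred.stopped_early

    def test_missing_model_truncates_and_flags(self, trained_search):
        tree, _, _ = trained_search
        empty = ModelStore({})
        pred = predict_host(make_sample("q", [3]), tree, empty,
                            UncertaintyConfig(T=5))
        assert pred.lineage == [] and pred.missing_model
        assert pred.stop_rank == "root"

    def test_report_uncertainty_false_keeps_lineage(self, trained_search):
        tree, models, _ = trained_search
        s = [make_sample("q", [3, 5, 7])]
        with_u = predict_hosts(s, tree, models, UncertaintyConfig(T=5, seed=2))
        without = predict_hosts(s, tree, models, UncertaintyConfig(T=5, seed=2),
                                report_uncertainty=False)
        assert with_u[0].lineage == without[0].lineage
        assert all(np.isnan(v) for v in without[0].uncertainties.values())


class TestModelStoreDisk:
    def test_round_trip_through_directory(self, tmp_path, trained_search):
        tree, models, _ = trained_search
        node_path = ("Bacteria",)
        disk = ModelStore(directory=tmp_path)
        disk.put(node_path, models.get(node_path))
        fresh = ModelStore(directory=tmp_path)
        s = [make_sample("q", [3, 5])]
        assert np.allclose(models.get(node_path).predict_proba(s),
                           fresh.get(node_path).predict_proba(s))

    def test_missing_path_returns_none(self, tmp_path):
        assert ModelStore(directory=tmp_path).get(("nope",)) is None
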