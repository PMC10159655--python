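"""Transformer classifier: attention oracle, gradients, training behavior."""

import numpy as np
import pytest

from plasmidhost import autograd as ag
from plasmidhost.autograd import Tensor
from plasmidhost.model import (AttentionWeights, NodeClassifier,
                               TrainingConfig, TransformerConfig,
                               multi_head_attention, train_node_classifier)
from tests.conftest import make_sample


def reference_attention(x, w: AttentionWeights, key_mask=None):
    """Independent per-position oracle for multi-head attention."""
    h, embed, d_head = w.wq.shape
    length = x.shape[0]
    heads = []
    for i in range(h):
        q, k, v = x @ w.wq[i], x @ w.wk[i], x @ w.wv[i]
        out = np.zeros((length, d_head))
        for t in range(length):
            scores = np.array([q[t] @ k[s] / np.sqrt(d_head)
                               for s in range(length)])
            if key_mask is not None:
                scores = np.where(key_mask, scores, -np.inf)
            weights = np.exp(scores - scores.max())
            weights /= weights.sum()
            out[t] = sum(weights[s] * v[s] for s in range(length))
        heads.append(out)
    return np.concatenate(heads, axis=-1) @ w.wo


def random_weights(rng, h, embed):
    d = embed // h
    return AttentionWeights(wq=rng.normal(size=(h, embed, d)),
                            wk=rng.normal(size=(h, embed, d)),
                            wv=rng.normal(size=(h, embed, d)),
                            wo=rng.normal(size=(h * d, embed)))


class TestAttentionOracle:
    def test_matches_brute_force_over_random_draws(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            h = int(rng.choice([1, 2]))
            embed = int(rng.choice([2, 4]))
            length = int(rng.integers(1, 5))
            x = rng.normal(size=(length, embed))
            w = random_weights(rng, h, embed)
            got = multi_head_attention(x, w)
            want = reference_attention(x, w)
            worst = max(worst, float(np.abs(got - want).max()))
        assert worst < 1e-9

    def test_identity_projections_average_values(self):
        # With W^Q = W^K = 0 all scores are equal, so each output position is
        # the mean of the value projections; W^V = W^O = I makes that the
        # mean of the inputs.
        embed = 4
        w = AttentionWeights(wq=np.zeros((1, embed, embed)),
                             wk=np.zeros((1, embed, embed)),
                             wv=np.eye(embed)[None],
                             wo=np.eye(embed))
        x = np.arange(12.0).reshape(3, 4)
        out = multi_head_attention(x, w)
        assert np.allclose(out, np.tile(x.mean(axis=0), (3, 1)))

    def test_masked_keys_excluded(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 4))
        w = random_weights(rng, 2, 4)
        mask = np.array([True, True, False, False])
        got = multi_head_attention(x, w, key_mask=mask)
        want = reference_attention(x, w, key_mask=mask)
        assert np.allclose(got[:2], want[:2], atol=1e-9)
        # changing a masked key must not change unmasked outputs
        x2 = x.copy()
        x2[3] += 10.0
        got2 = multi_head_attention(x2, w, key_mask=mask)
        assert np.allclose(got[:2], got2[:2], atol=1e-9)


class TestGradients:
    def test_finite_difference_check_through_full_model(self):
        cfgs = (TransformerConfig(vocab_size=6, max_len=8, embed=4, h=2,
                                  ffn_width=6, dropout_rate=0.0),
                TransformerConfig(vocab_size=5, max_len=6, embed=4, h=2,
                                  ffn_width=6, dropout_rate=0.0))
        model = NodeClassifier(["X", "Y"], cfgs[0], cfgs[1], inc_dim=3, seed=0)
        for p in model.parameters():       # float64 for the numeric check
            p.data = p.data.astype(np.float64)
        rng = np.random.default_rng(2)
        pc_t = rng.integers(1, 7, size=(3, 8)); pc_t[:, 5:] = 0
        pc_p = np.where(pc_t > 0, np.arange(1, 9), 0)
        mob_t = rng.integers(0, 6, size=(3, 6))
        inc = np.eye(3)[[0, 1, 2]].astype(float)
        labels = np.array([0, 1, 0])

        def loss_value():
            logits = model.forward_batch(pc_t, pc_p, mob_t, inc, rng=None)
            return ag.cross_entropy(logits, labels)

        loss = loss_value()
        loss.backward()
        eps = 1e-6
        worst = 0.0
        check_rng = np.random.default_rng(3)
        for p in model.parameters():
            flat = p.data.ravel()
            for idx in check_rng.choice(flat.size, size=min(5, flat.size),
                                        replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = float(loss_value().data)
                flat[idx] = orig - eps
                down = float(loss_value().data)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = p.grad.ravel()[idx]
                worst = max(worst, abs(numeric - analytic))
        assert worst < 1e-6

    def test_no_grad_builds_no_graph(self):
        a = ag.Parameter(np.ones(3))
        with ag.no_grad():
            out = ag.scale(a, 2.0)
        assert not out.requires_grad and out._parents == ()


class TestForwardProperties:
    def test_padding_invariance(self, small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        model = NodeClassifier(["X", "Y"], pc_cfg, mob_cfg, inc_dim=4, seed=5)
        short = make_sample("a", [3, 7, 2])
        longer = make_sample("b", [3, 7, 2, 9, 9, 9])
        # same tokens, batched with a longer companion (more padding in use)
        p_alone = model.predict_proba([short])
        p_batched = model.predict_proba([short, longer])[0]
        assert np.allclose(p_alone[0], p_batched, atol=1e-5)

    def test_empty_sentences_are_valid_input(self, small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        model = NodeClassifier(["X", "Y"], pc_cfg, mob_cfg, inc_dim=4, seed=5)
        probs = model.predict_proba([make_sample("a", [])])
        assert probs.shape == (1, 2) and np.isclose(probs.sum(), 1.0)

    def test_token_beyond_vocab_raises(self, small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        model = NodeClassifier(["X", "Y"], pc_cfg, mob_cfg, inc_dim=4, seed=5)
        with pytest.raises(ValueError, match="vocabulary"):
            model.predict_proba([make_sample("a", [pc_cfg.vocab_size + 1])])

    def test_seven_dropout_sites(self, small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        model = NodeClassifier(["X", "Y"], pc_cfg, mob_cfg, inc_dim=4)
        assert len(model.dropout_sites()) == 7

    def test_dropout_changes_output_and_determinism_off(self,
                                                        small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        model = NodeClassifier(["X", "Y"], pc_cfg, mob_cfg, inc_dim=4, seed=5)
        s = make_sample("a", [3, 7, 2])
        det1 = model.predict_proba([s])
        det2 = model.predict_proba([s])
        assert np.array_equal(det1, det2)
        stoch = model.predict_proba([s], rng=np.random.default_rng(0))
        assert not np.allclose(det1, stoch)

    def test_chunked_prediction_matches_small_batches(self,
                                                      small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        model = NodeClassifier(["X", "Y"], pc_cfg, mob_cfg, inc_dim=4, seed=5)
        rng = np.random.default_rng(7)
        samples = [make_sample(f"s{i}", list(rng.integers(1, 20, 5)))
                   for i in range(300)]          # crosses the chunk boundary
        all_at_once = model.predict_proba(samples)
        one_by_one = np.concatenate(
            [model.predict_proba([s]) for s in samples])
        assert np.allclose(all_at_once, one_by_one, atol=1e-5)


def two_class_samples(n=40, seed=0):
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        cls = i % 2
        tokens = list(10 * cls + rng.integers(1, 10, 6))
        samples.append(make_sample(f"s{i}", tokens, label=("X",) if cls == 0
                                   else ("Y",)))
    return samples


class TestTraining:
    def test_separable_classes_are_recovered(self, small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        samples = two_class_samples()
        model = train_node_classifier(
            samples, ["X", "Y"], pc_cfg, mob_cfg, inc_dim=4,
            cfg=TrainingConfig(epochs=30, batch_size=8, seed=1), label_index=0)
        probs = model.predict_proba(samples)
        pred = np.array(["X", "Y"])[probs.argmax(axis=1)]
        truth = np.array([s.label[0] for s in samples])
        assert (pred == truth).mean() == 1.0
        assert model.training_log[-1] < model.training_log[0]

    def test_plateau_exit_can_stop_before_epoch_cap(self, small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        model = train_node_classifier(
            two_class_samples(), ["X", "Y"], pc_cfg, mob_cfg, inc_dim=4,
            cfg=TrainingConfig(epochs=50, batch_size=8, seed=1,
                               plateau_patience=3, plateau_min_delta=1e-2),
            label_index=0)
        assert len(model.training_log) < 50

    def test_single_class_input_gives_constant_classifier(self,
                                                          small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        samples = [make_sample(f"s{i}", [1, 2], label=("Y",)) for i in range(4)]
        model = train_node_classifier(samples, ["X", "Y"], pc_cfg, mob_cfg,
                                      inc_dim=4, label_index=0)
        assert model.constant_class == 1
        assert model.predict_proba(samples)[:, 1].tolist() == [1.0] * 4

    def test_empty_input_is_error(self, small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        with pytest.raises(ValueError):
            train_node_classifier([], ["X", "Y"], pc_cfg, mob_cfg, inc_dim=4)

    def test_label_outside_children_is_error(self, small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        s = make_sample("a", [1], label=("Z",))
        with pytest.raises(ValueError, match="Z"):
            train_node_classifier([s], ["X", "Y"], pc_cfg, mob_cfg,
                                  inc_dim=4, label_index=0)


class TestPersistence:
    def test_save_load_round_trip_preserves_predictions(
            self, tmp_path, small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        model = NodeClassifier(["X", "Y", "Z"], pc_cfg, mob_cfg, inc_dim=4,
                               seed=9)
        model.vocab_hash = "abc123"
        path = tmp_path / "node.npz"
        model.save(path)
        back = NodeClassifier.load(path, expect_vocab_hash="abc123")
        s = make_sample("a", [4, 4, 9])
        assert np.allclose(model.predict_proba([s]), back.predict_proba([s]))
        assert back.classes == ["X", "Y", "Z"]

    def test_vocab_hash_mismatch_rejected(self, tmp_path,
                                          small_transformer_cfgs):
        pc_cfg, mob_cfg = small_transformer_cfgs
        model = NodeClassifier(["X", "Y"], pc_cfg, mob_cfg, inc_dim=4)
        model.vocab_hash = "abc123"
        path = tmp_path / "node.npz"
        model.save(path)
        with pytest.raises(ValueError, match="abc123"):
            NodeClassifier.load(path, expect_vocab_hash="other")
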