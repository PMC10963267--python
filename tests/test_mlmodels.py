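"""Architecture accounting, masking statistics, and training behaviour."""

import numpy as np
import pytest

from deepscreen import mlmodels
from deepscreen.mlmodels import (BertSpec, MaskingScheme, MlpSpec, TrainConfig,
                                 build_bert, build_mlp, mask_batch,
                                 fine_tune_classifier, score_candidates,
                                 soft_label, tokenize)


def bert_param_oracle(spec: BertSpec) -> int:
    """Independent layer-by-layer shape accounting for the transformer."""
    d, f, v, L = spec.d_model, spec.d_ff, spec.vocab, spec.max_len
    emb = v * d + L * d
    attn = 4 * (d * d + d)            # q, k, v, output projections
    lns = 2 * (2 * d)                 # two layer norms, gain + offset each
    ff = (d * f + f) + (f * d + d)
    block = attn + lns + ff
    mlm = 2 * (d * d + d) + 2 * d + (d * v + v)
    return emb + spec.n_blocks * block + mlm


def mlp_param_oracle(spec: MlpSpec, n_out: int) -> int:
    emb = spec.vocab * spec.embed_dim
    fc1 = spec.input_len * spec.embed_dim * spec.hidden1   # no bias
    ln1 = 2 * spec.hidden1
    fc2 = spec.hidden1 * spec.hidden2                      # no bias
    ln2 = 2 * spec.hidden2
    head = spec.hidden2 * n_out + n_out
    return emb + fc1 + ln1 + fc2 + ln2 + head


class TestParameterCounts:
    def test_published_transformer_size_rounds_to_86_million(self):
        _, n = build_bert(BertSpec())
        assert round(n / 1e6) == 86
        assert n == bert_param_oracle(BertSpec())

    def test_small_spec_matches_hand_accounting(self):
        spec = BertSpec(vocab=4, max_len=5, n_blocks=1, n_heads=1,
                        d_model=8, d_ff=16, dropout=0.0)
        _, n = build_bert(spec)
        assert n == bert_param_oracle(spec)

    def test_mlp_published_sizes(self):
        _, n3 = build_mlp(head="three_class")
        _, n1 = build_mlp(head="scalar")
        assert n3 == 46979
        assert n1 == 46849
        assert n3 - n1 == 64 * 3 + 3 - (64 * 1 + 1)  # head shapes only
        assert n3 == mlp_param_oracle(MlpSpec(), 3)
        assert n1 == mlp_param_oracle(MlpSpec(), 1)

    def test_builds_are_seed_deterministic(self):
        spec = BertSpec(n_blocks=1, d_model=16, d_ff=32, n_heads=2, max_len=8)
        m1, _ = build_bert(spec, seed=5)
        m2, _ = build_bert(spec, seed=5)
        for a, b in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            BertSpec(d_model=10, n_heads=3)


class TestMasking:
    def test_zero_select_probability_changes_nothing(self):
        ids = tokenize(["ACDEF", "GHIKL"], 8)
        corrupted, labels = mask_batch(ids, MaskingScheme(select_p=0.0))
        assert np.array_equal(corrupted, ids)
        assert (labels == mlmodels.IGNORE_INDEX).all()

    def test_full_masking_hits_every_residue(self):
        ids = tokenize(["ACDEF"], 8)
        corrupted, labels = mask_batch(
            ids, MaskingScheme(select_p=1.0, mask_p=1.0, mutate_p=0.0, keep_p=0.0))
        aa = ids >= mlmodels.FIRST_AA_TOKEN
        assert (corrupted[aa] == mlmodels.MASK).all()
        assert np.array_equal(labels[aa], ids[aa])
        # specials untouched
        assert (corrupted[~aa] == ids[~aa]).all()

    def test_masked_fraction_matches_binomial_expectation(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list(mlmodels.AA20), 50)) for _ in range(2000)]
        ids = tokenize(seqs, 52)
        corrupted, labels = mask_batch(ids, rng_seed=2)
        n_pos = 2000 * 50
        frac_mask = (corrupted == mlmodels.MASK).sum() / n_pos
        sd = np.sqrt(0.12 * 0.88 / n_pos)
        assert abs(frac_mask - 0.15 * 0.8) < 3 * sd
        frac_sel = (labels != mlmodels.IGNORE_INDEX).sum() / n_pos
        assert abs(frac_sel - 0.15) < 3 * np.sqrt(0.15 * 0.85 / n_pos)

    def test_labels_exactly_at_selected_positions(self):
        ids = tokenize(["ACDEFGHIKL"] * 10, 12)
        corrupted, labels = mask_batch(ids, rng_seed=0)
        sel = labels != mlmodels.IGNORE_INDEX
        assert np.array_equal(labels[sel], ids[sel])
        assert not (ids == mlmodels.PAD)[sel].any()

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MaskingScheme(mask_p=0.8, mutate_p=0.3, keep_p=0.1)


def test_soft_labels():
    assert soft_label("non_hit") == 0.0
    assert soft_label("low_hit") == 0.5
    assert soft_label("high_hit") == 1.0
    with pytest.raises(ValueError):
        soft_label("medium")


SMALL_SPEC = BertSpec(vocab=25, max_len=12, n_blocks=2, n_heads=2,
                      d_model=32, d_ff=64, dropout=0.0, classifier_hidden=16)


def _separable_dataset(n=200, seed=0):
    """Two classes distinguished by a single residue at position 4."""
    rng = np.random.default_rng(seed)
    seqs, labels = [], []
    for i in range(n):
        s = list(rng.choice(list(mlmodels.AA20), 10))
        s[4] = "W" if i % 2 else "A"
        seqs.append("".join(s))
        labels.append(i % 2)
    return seqs, labels


class TestFineTune:
    def test_separable_classes_reach_perfect_f1(self):
        seqs, labels = _separable_dataset()
        model, _ = build_bert(SMALL_SPEC, seed=0)
        cfg = TrainConfig(lr=1e-3, epochs=20, batch_size=32, seed=0)
        res = fine_tune_classifier(model, seqs, labels, cfg, n_classes=2)
        assert res["f1_per_class"][0] == 1.0
        assert res["f1_per_class"][1] == 1.0

    def test_class_weighting_raises_minority_recall(self):
        # 99:1 imbalance, few epochs: unweighted training stays at the
        # majority prediction while inverse-frequency weighting learns the
        # minority class
        rng = np.random.default_rng(3)
        seqs, labels = [], []
        for i in range(1000):
            s = list(rng.choice(list(mlmodels.AA20), 10))
            minority = i % 100 == 0
            s[4] = "W" if minority else "A"
            seqs.append("".join(s))
            labels.append(int(minority))
        recalls = {}
        for mode in ("uniform", "inverse"):
            model, _ = build_mlp(MlpSpec(input_len=10), head="three_class",
                                 seed=0)
            cfg = TrainConfig(lr=3e-4, epochs=2, batch_size=50, seed=0,
                              class_weights=mode)
            res = fine_tune_classifier(model, seqs, labels, cfg, n_classes=3)
            va = res["val_indices"]
            probs = score_candidates(model, [seqs[i] for i in va])
            preds = np.argmax(probs, axis=1)
            truth = np.array([labels[i] for i in va])
            mask = truth == 1
            recalls[mode] = (preds[mask] == 1).mean() if mask.any() else 0.0
        assert recalls["inverse"] > recalls["uniform"]

    def test_fixed_seed_reproduces_loss_trajectory(self):
        seqs, labels = _separable_dataset(n=80)
        cfg = TrainConfig(lr=1e-3, epochs=3, batch_size=20, seed=4)
        runs = []
        for _ in range(2):
            model, _ = build_bert(SMALL_SPEC, seed=4)
            runs.append(fine_tune_classifier(model, seqs, labels, cfg,
                                             n_classes=2)["train_losses"])
        assert runs[0] == runs[1]

    def test_single_class_dataset_rejected(self):
        model, _ = build_mlp(MlpSpec(input_len=5), seed=0)
        with pytest.raises(ValueError):
            fine_tune_classifier(model, ["AAAAA"] * 10, [0] * 10)


class TestScoring:
    def test_probabilities_sum_to_one_and_are_deterministic(self):
        model, _ = build_bert(SMALL_SPEC, seed=1)
        model.add_classifier()
        probs = score_candidates(model, ["ACDEFGHIKL", "ACDEFGHIKL", "WWWWWWWWWW"])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert np.allclose(probs[0], probs[1])

    def test_overlong_sequence_rejected(self):
        model, _ = build_bert(SMALL_SPEC, seed=1)
        model.add_classifier()
        with pytest.raises(ValueError):
            score_candidates(model, ["A" * 50])

    def test_trained_model_scores_heldout_class_confidently(self):
        seqs, labels = _separable_dataset()
        model, _ = build_bert(SMALL_SPEC, seed=0)
        cfg = TrainConfig(lr=1e-3, epochs=20, batch_size=32, seed=0)
        res = fine_tune_classifier(model, seqs, labels, cfg, n_classes=2)
        held = [seqs[i] for i in res["val_indices"]
                if labels[i] == 1]
        probs = score_candidates(model, held)
        assert (probs[:, 1] > 0.9).all()


def test_pretrain_smoke_reduces_mlm_loss():
    rng = np.random.default_rng(5)
    seqs = ["".join(rng.choice(list(mlmodels.AA20), 10)) for _ in range(200)]
    model, _ = build_bert(SMALL_SPEC, seed=2)
    cfg = TrainConfig(lr=1e-3, batch_size=32, seed=2)
    losses = mlmodels.pretrain_smoke(model, seqs, cfg=cfg, steps=60)
    assert np.mean(losses[-10:]) < np.mean(losses[:10])
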