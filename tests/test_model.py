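"""Dual-branch classifier: branch forwards, fusion, loss, training, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dppiv.chem import StructTensor, encode_peptide, MAX_ATOMS, N_FEATURES
from dppiv.data import MotifSpec, generate_synthetic
from dppiv.model import (
    ModelConfig,
    ModelParams,
    classify,
    focal_loss,
    fuse,
    load_model,
    predict,
    predict_report,
    save_model,
    structural_forward,
    text_forward,
    train,
)


class TestFuse:
    def test_worked_example(self):
        assert fuse([1, 4, 2, 8], [5, 7, 1, 4]).tolist() == [5, 28, 2, 32]

    def test_ones_identity(self):
        v = np.array([0.3, -2.0, 7.5])
        assert np.array_equal(fuse(v, np.ones(3)), v)

    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=8).flatmap(
            lambda a: st.tuples(
                st.just(a),
                st.lists(
                    st.floats(-10, 10, allow_nan=False), min_size=len(a), max_size=len(a)
                ),
            )
        )
    )
    @settings(deadline=None)
    def test_commutative(self, ab):
        a, b = ab
        assert np.array_equal(fuse(a, b), fuse(b, a))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fuse([1, 2], [1, 2, 3])


class TestClassify:
    def test_probability_range_and_determinism(self, untrained_tiny):
        v = np.random.default_rng(0).normal(size=untrained_tiny.config.fusion_dim)
        p1 = classify(v, untrained_tiny)
        p2 = classify(v, untrained_tiny)
        assert 0.0 < p1 < 1.0
        assert p1 == p2  # dropout inactive at inference

    def test_zero_final_layer_gives_half(self, untrained_tiny):
        untrained_tiny.head2.W.data[:] = 0.0
        untrained_tiny.head2.b.data[:] = 0.0
        v = np.random.default_rng(1).normal(size=untrained_tiny.config.fusion_dim)
        assert classify(v, untrained_tiny) == 0.5

    def test_wrong_length_rejected(self, untrained_tiny):
        with pytest.raises(ValueError):
            classify(np.zeros(untrained_tiny.config.fusion_dim + 1), untrained_tiny)


class TestFocalLoss:
    def test_gamma_zero_reduces_to_scaled_cross_entropy(self):
        rng = np.random.default_rng(2)
        probs = rng.uniform(0.05, 0.95, size=32)
        labels = rng.integers(0, 2, size=32)
        bce = -np.mean(np.log(np.where(labels == 1, probs, 1 - probs)))
        assert focal_loss(probs, labels, gamma=0.0, alpha=0.5) == pytest.approx(0.5 * bce)

    def test_perfect_predictions_vanish(self):
        assert focal_loss(np.array([1.0, 0.0]), np.array([1, 0]), 2.0, 0.5) < 1e-10

    def test_uninformative_half_probabilities(self):
        # p_t = 0.5 everywhere: loss per sample = 0.5 * 0.25 * log 2
        probs = np.full(10, 0.5)
        labels = np.array([1, 0] * 5)
        assert focal_loss(probs, labels, gamma=2.0, alpha=0.5) == pytest.approx(
            0.5 * 0.25 * np.log(2.0)
        )

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(3)
        probs = rng.uniform(0.01, 0.99, size=50)
        labels = rng.integers(0, 2, size=50)
        gamma, alpha = 1.7, 0.3
        total = 0.0
        for p, y in zip(probs, labels):
            pt = p if y == 1 else 1 - p
            at = alpha if y == 1 else 1 - alpha
            total += -at * (1 - pt) ** gamma * np.log(pt)
        assert abs(focal_loss(probs, labels, gamma, alpha) - total / 50) <= 1e-8

    def test_extreme_probabilities_stay_finite(self):
        val = focal_loss(np.array([0.0, 1.0]), np.array([1, 0]), 2.0, 0.5)
        assert np.isfinite(val)


class TestBranchForwards:
    def test_zero_tensor_finite(self, untrained_tiny):
        R = untrained_tiny.config.max_residues
        t = StructTensor(
            values=np.zeros((R, MAX_ATOMS, N_FEATURES)),
            residue_mask=np.zeros(R, dtype=bool),
            atom_mask=np.zeros((R, MAX_ATOMS), dtype=bool),
        )
        v = structural_forward(t, untrained_tiny)
        assert np.isfinite(v).all()

    def test_structural_deterministic(self, untrained_tiny):
        t = encode_peptide("ACDEF", untrained_tiny.config.max_residues)
        assert np.array_equal(
            structural_forward(t, untrained_tiny), structural_forward(t, untrained_tiny)
        )

    def test_padding_region_does_not_leak(self, untrained_tiny):
        R = untrained_tiny.config.max_residues
        a = encode_peptide("ACDEF", R)
        # same peptide, tensor rebuilt with explicitly re-zeroed padding
        values = a.values.copy()
        values[~a.atom_mask] = 0.0
        values[~a.residue_mask] = 0.0
        b = StructTensor(values=values, residue_mask=a.residue_mask, atom_mask=a.atom_mask)
        assert np.array_equal(
            structural_forward(a, untrained_tiny), structural_forward(b, untrained_tiny)
        )

    def test_text_single_residue_finite(self, untrained_tiny):
        v = text_forward("A", untrained_tiny)
        assert np.isfinite(v).all()

    def test_text_order_sensitivity(self, untrained_tiny):
        assert not np.array_equal(
            text_forward("ACCA", untrained_tiny), text_forward("CAAC", untrained_tiny)
        )


class TestTraining:
    def test_loss_decreases_on_planted_motif(self, tiny_model):
        history = tiny_model.epoch_history
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_same_seed_reproduces_history_and_predictions(self):
        config = ModelConfig(
            struct_channels=(4, 8),
            text_embed_dim=8,
            text_filters_per_width=4,
            fusion_dim=16,
            head_hidden=8,
            learning_rate=1e-3,
            batch_size=16,
            max_epochs=3,
            seed=11,
            max_residues=12,
        )
        records = generate_synthetic(10, 10, MotifSpec(length_range=(5, 12), seed=11))
        seqs = [r.sequence for r in records]
        a = train(records, config)
        b = train(records, config)
        assert [h["train_loss"] for h in a.epoch_history] == [
            h["train_loss"] for h in b.epoch_history
        ]
        assert np.array_equal(predict(seqs, a), predict(seqs, b))

    def test_single_class_rejected(self):
        records = [r for r in generate_synthetic(5, 5, MotifSpec(seed=0)) if r.label == 1]
        with pytest.raises(ValueError, match="single class"):
            train(records, ModelConfig(max_residues=30, max_epochs=1))

    def test_unencodable_sequences_listed(self):
        records = generate_synthetic(3, 3, MotifSpec(seed=0))
        config = ModelConfig(max_residues=10, max_epochs=1)  # shorter than some records
        too_long = [r for r in records if len(r.sequence) > 10]
        if too_long:
            with pytest.raises(ValueError, match=too_long[0].id):
                train(records, config)

    def test_preprocessing_cache_reused(self, tmp_path):
        config = ModelConfig(
            struct_channels=(4, 8),
            text_embed_dim=8,
            text_filters_per_width=4,
            fusion_dim=16,
            head_hidden=8,
            learning_rate=1e-3,
            max_epochs=1,
            seed=0,
            max_residues=12,
        )
        records = generate_synthetic(5, 5, MotifSpec(length_range=(5, 12), seed=2))
        train(records, config, cache_dir=tmp_path)
        cached = list(tmp_path.glob("encodings_*.npz"))
        assert len(cached) == 1
        mtime = cached[0].stat().st_mtime_ns
        train(records, config, cache_dir=tmp_path)
        assert cached[0].stat().st_mtime_ns == mtime  # reused, not rewritten


class TestPredict:
    def test_order_preserving_and_batch_independent(self, tiny_model):
        records = generate_synthetic(5, 5, MotifSpec(length_range=(5, 12), seed=9))
        seqs = [r.sequence for r in records]
        full = predict(seqs, tiny_model)
        assert len(full) == len(seqs)
        assert full[0] == predict([seqs[0]], tiny_model)[0]
        assert np.array_equal(predict([seqs[0], seqs[0]], tiny_model), [full[0], full[0]])

    def test_invalid_sequences_reported_others_scored(self, tiny_model):
        scores, errors = predict_report(["ACDEF", "ACXDE", "GHIKL"], tiny_model)
        assert set(errors) == {1}
        assert np.isnan(scores[1])
        assert np.isfinite(scores[[0, 2]]).all()
        with pytest.raises(Exception, match="X"):
            predict(["ACXDE"], tiny_model)

    def test_branches_give_different_scores(self):
        records = generate_synthetic(8, 8, MotifSpec(length_range=(5, 12), seed=13))
        seqs = [r.sequence for r in records]
        outs = {}
        for branch in ("both", "structural_only"):
            config = ModelConfig(
                struct_channels=(4, 8),
                text_embed_dim=8,
                text_filters_per_width=4,
                fusion_dim=16,
                head_hidden=8,
                learning_rate=1e-3,
                max_epochs=2,
                seed=5,
                branch=branch,
                max_residues=12,
            )
            outs[branch] = predict(seqs, train(records, config))
        assert not np.allclose(outs["both"], outs["structural_only"])


class TestSerialization:
    def test_round_trip_bit_identical(self, tiny_model, tmp_path):
        path = tmp_path / "model.ckpt"
        save_model(tiny_model, path)
        loaded = load_model(path)
        seqs = [r.sequence for r in generate_synthetic(4, 4, MotifSpec(length_range=(5, 12), seed=21))]
        assert np.array_equal(predict(seqs, tiny_model), predict(seqs, loaded))
        assert loaded.epoch_history == tiny_model.epoch_history
        assert loaded.config == tiny_model.config
        assert loaded.trained


class TestConfig:
    def test_paper_protocol_defaults(self):
        config = ModelConfig()
        assert config.batch_size == 32
        assert config.learning_rate == 5e-6
        assert config.max_epochs == 150

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(branch="structural")
        with pytest.raises(ValueError):
            ModelConfig(struct_kernel=2)
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)
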