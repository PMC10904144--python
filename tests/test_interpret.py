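"""Grad-CAM, perturbation scanning, AAC fold and the conversion matrix."""

import numpy as np
import pytest

from dppiv.data import ALPHABET, MotifSpec, generate_synthetic
from dppiv.interpret import (
    ConversionMatrix,
    ImportanceReport,
    aac_fold,
    aggregate_cam,
    cam_scores,
    conversion_matrix,
    pair_mean_deltas,
    perturb_scan,
    perturbation_importance,
)
from dppiv.chem import build_molecule, AMINO_ACID_SMILES
from dppiv.model import predict


def _constant_model(tiny_model):
    """Constant-output clone: zeroing the final layer in place would be
    destructive to the shared fixture, so work on a reloaded copy."""
    import tempfile
    from pathlib import Path
    from dppiv.model import load_model, save_model

    with tempfile.TemporaryDirectory() as d:
        path = Path(d) / "clone.ckpt"
        save_model(tiny_model, path)
        clone = load_model(path)
    clone.head2.W.data[:] = 0.0
    clone.head2.b.data[:] = 0.0
    return clone


class TestCamScores:
    def test_scores_nonnegative_and_within_bounds(self, tiny_model):
        seq = "ACPWG"
        pos_rep, atom_rep = cam_scores(tiny_model, seq)
        assert set(pos_rep.scores) == set(range(len(seq)))
        assert all(v >= 0 for v in pos_rep.scores.values())
        for (r, a), v in atom_rep.scores.items():
            assert 0 <= r < len(seq)
            n_atoms = build_molecule(AMINO_ACID_SMILES[seq[r]]).n_atoms
            assert 0 <= a < n_atoms
            assert v >= 0

    def test_position_score_is_atom_sum(self, tiny_model):
        seq = "MKPTA"
        pos_rep, atom_rep = cam_scores(tiny_model, seq)
        for r in range(len(seq)):
            total = sum(v for (rr, _), v in atom_rep.scores.items() if rr == r)
            assert pos_rep.scores[r] == pytest.approx(total)

    def test_untrained_model_flagged(self, untrained_tiny):
        pos_rep, _ = cam_scores(untrained_tiny, "ACDEF")
        assert not pos_rep.from_trained_model

    def test_text_only_model_rejected(self):
        from dppiv.model import ModelConfig, ModelParams

        params = ModelParams(ModelConfig(branch="text_only", max_residues=12))
        with pytest.raises(ValueError, match="structural"):
            cam_scores(params, "ACDEF")


class TestAggregateCam:
    def test_single_report_is_identity(self, tiny_model):
        pos_rep, _ = cam_scores(tiny_model, "ACPWG")
        agg = aggregate_cam([pos_rep], by="position")
        assert agg.scores == pytest.approx(pos_rep.scores)

    def test_position_mean_skips_short_sequences(self):
        a = ImportanceReport("position", {0: 1.0, 1: 3.0}, "cam", "AC")
        b = ImportanceReport("position", {0: 2.0, 1: 5.0, 2: 9.0}, "cam", "ACD")
        agg = aggregate_cam([a, b], by="position")
        assert agg.scores == {0: 1.5, 1: 4.0, 2: 9.0}

    def test_aa_type_group_sums_match_loop_oracle(self, tiny_model):
        seqs = ["ACPWG", "PPAMK", "WGACD"]
        reports = [cam_scores(tiny_model, s)[0] for s in seqs]
        agg = aggregate_cam(reports, by="aa_type")
        oracle: dict[str, float] = {}
        for s, rep in zip(seqs, reports):
            for pos, score in rep.scores.items():
                oracle[s[pos]] = oracle.get(s[pos], 0.0) + score
        assert agg.scores == pytest.approx(oracle)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cam([], by="position")


class TestPerturbScan:
    def test_shape_and_identity_zero(self, tiny_model):
        seq = "ACPWG"
        deltas = perturb_scan(tiny_model, seq)
        assert deltas.shape == (len(seq), 20)
        for i, c in enumerate(seq):
            assert deltas[i, ALPHABET.index(c)] == 0.0

    def test_matches_individual_predict_oracle(self, tiny_model):
        seq = "MKPTA"
        deltas = perturb_scan(tiny_model, seq)
        base = predict([seq], tiny_model)[0]
        for i in (0, 2, 4):
            for b, residue in enumerate(ALPHABET):
                mutant = seq[:i] + residue + seq[i + 1 :]
                expected = predict([mutant], tiny_model)[0] - base
                assert deltas[i, b] == pytest.approx(expected, abs=1e-12)


class TestPerturbationImportance:
    def test_constant_model_scores_zero(self, tiny_model):
        const = _constant_model(tiny_model)
        scans = [(s, perturb_scan(const, s)) for s in ["ACPWG", "MKPTA"]]
        for mode in ("absolute", "signed"):
            rep = perturbation_importance(scans, mode=mode, by="position")
            assert all(v == 0.0 for v in rep.scores.values())

    def test_absolute_dominates_signed(self, tiny_model):
        seqs = [r.sequence for r in generate_synthetic(4, 4, MotifSpec(length_range=(5, 12), seed=31))]
        scans = [(s, perturb_scan(tiny_model, s)) for s in seqs]
        for by in ("position", "aa_type"):
            abs_rep = perturbation_importance(scans, mode="absolute", by=by)
            signed_rep = perturbation_importance(scans, mode="signed", by=by)
            for key in abs_rep.scores:
                assert abs_rep.scores[key] >= abs(signed_rep.scores[key]) - 1e-12

    def test_signed_pair_means_agree_with_conversion_matrix(self, tiny_model):
        seqs = ["ACPWG", "PPAMK", "WGACD", "AAPGW"]
        scans = [(s, perturb_scan(tiny_model, s)) for s in seqs]
        pairs = pair_mean_deltas(scans)
        cm = conversion_matrix(tiny_model, seqs, aa_subset=["A", "P", "G", "W"], scans=scans)
        for x in cm.aa_subset:
            for y in cm.aa_subset:
                if x != y and (x, y) in pairs:
                    assert cm.matrix.loc[x, y] == pytest.approx(pairs[(x, y)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            perturbation_importance([], mode="absolute")


class TestAacFold:
    def test_identical_sets_give_unit_folds(self):
        seqs = ["ACDEF", "GHIKL"]
        folds = aac_fold(seqs, list(seqs))
        present = {c for s in seqs for c in s}
        for r in present:
            assert folds[r] == pytest.approx(1.0)

    def test_hand_computed_toy_sets(self):
        folds = aac_fold(["AAAG"], ["AGGG"])
        # AAC_pos(A)=3/4, AAC_neg(A)=1/4 -> 3; AAC_pos(G)=1/4, AAC_neg(G)=3/4 -> 1/3
        assert folds["A"] == pytest.approx(3.0)
        assert folds["G"] == pytest.approx(1.0 / 3.0)

    def test_enrichment_direction(self):
        spec_pos = ["PAPA", "APAP"]
        spec_neg = ["GLGL", "LGLG"]
        folds = aac_fold(spec_pos, spec_neg)
        assert folds["P"] == np.inf  # absent from negatives, flagged infinite
        assert np.isnan(folds["W"])  # absent everywhere

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            aac_fold([], ["ACDEF"])
        with pytest.raises(ValueError):
            aac_fold(["ACDEF"], [])


class TestConversionMatrix:
    def test_diagonal_exactly_zero(self, tiny_model):
        cm = conversion_matrix(tiny_model, ["ACPWG", "PPAMK"], aa_subset=["A", "P", "C"])
        for r in cm.aa_subset:
            assert cm.matrix.loc[r, r] == 0.0

    def test_constant_model_all_zero(self, tiny_model):
        const = _constant_model(tiny_model)
        cm = conversion_matrix(const, ["ACPWG", "PPAMK"], aa_subset=["A", "P"])
        assert (cm.matrix.to_numpy() == 0).all()

    def test_default_subset_is_four_most_frequent(self, tiny_model):
        seqs = ["AAAAG", "AAGGC", "GGGAC"]
        cm = conversion_matrix(tiny_model, seqs, scans=[(s, np.zeros((5, 20))) for s in seqs])
        assert cm.aa_subset == ["A", "G", "C", "D"]  # ties broken alphabetically

    def test_matches_per_occurrence_enumeration(self, tiny_model):
        seqs = ["ACPWG", "PPAMK"]
        cm = conversion_matrix(tiny_model, seqs, aa_subset=["A", "P"])
        base = {s: predict([s], tiny_model)[0] for s in seqs}
        for x, y in [("A", "P"), ("P", "A")]:
            acc, n = 0.0, 0
            for s in seqs:
                for i, c in enumerate(s):
                    if c == x:
                        mutant = s[:i] + y + s[i + 1 :]
                        acc += predict([mutant], tiny_model)[0] - base[s]
                        n += 1
            assert cm.matrix.loc[x, y] == pytest.approx(acc / n)

    def test_absent_residue_flagged_missing(self, tiny_model):
        cm = conversion_matrix(tiny_model, ["ACDEF"], aa_subset=["A", "W"])
        assert "W" in cm.missing
        assert np.isnan(cm.matrix.loc["W", "A"])
        assert cm.matrix.loc["W", "W"] == 0.0


class TestReportRoundTrips:
    def test_importance_report_csv_lossless(self, tiny_model, tmp_path):
        pos_rep, atom_rep = cam_scores(tiny_model, "ACPWG")
        for rep in (pos_rep, atom_rep):
            path = tmp_path / f"{rep.granularity}.csv"
            rep.to_csv(path)
            back = ImportanceReport.from_csv(path)
            assert back.scores == rep.scores  # exact, via repr round-trip
            assert back.granularity == rep.granularity
            assert back.method == rep.method
            assert back.sequence_context == rep.sequence_context

    def test_conversion_matrix_csv_round_trip(self, tiny_model, tmp_path):
        cm = conversion_matrix(tiny_model, ["ACPWG", "PPAMK"], aa_subset=["A", "P", "C"])
        path = tmp_path / "conversion.csv"
        cm.to_csv(path)
        back = ConversionMatrix.from_csv(path)
        assert back.aa_subset == cm.aa_subset
        assert np.allclose(back.matrix.to_numpy(), cm.matrix.to_numpy())
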