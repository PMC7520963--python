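import numpy as np
import pytest

from plastaudit import (
    AssemblyFeatures,
    NovelCriteria,
    PlastomeSpec,
    SeqRecord,
    classify_novel_mode,
    classify_reference_mode,
    make_component,
    make_plastome,
    make_variant,
    prf,
    select_cutoffs,
)
from plastaudit.success_classify import classify_features


class TestReferenceMode:
    @pytest.mark.parametrize(
        "score,success", [(99.0, True), (98.99, False), (100.0, True), (0.0, False)]
    )
    def test_threshold_inclusive_at_99(self, score, success):
        outcome = classify_reference_mode(score)
        assert outcome.success is success
        assert bool(outcome.reasons) is not success

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_reference_mode(100.5)


class TestNovelMode:
    def test_qualifying_plastome_succeeds(self, full_plastome):
        genome, _ = full_plastome  # 135 kb, 20 kb IR
        outcome = classify_novel_mode([genome])
        assert outcome.success and not outcome.reasons

    def test_multi_contig_fails_on_count(self, full_plastome):
        genome, structure = full_plastome
        contigs = make_variant(genome, structure, "split", n=2)
        contigs = [SeqRecord(c.id, c.seq, "circular") for c in contigs]
        outcome = classify_novel_mode(contigs)
        assert not outcome.success
        assert any("contig" in r for r in outcome.reasons)

    def test_short_single_contig_fails_on_length(self):
        genome, _ = make_plastome(PlastomeSpec(60_000, 10_000, 20_000, seed=2))  # 110 kb
        outcome = classify_novel_mode([genome])
        assert not outcome.success
        assert any("total length" in r for r in outcome.reasons)

    def test_short_ir_fails_on_ir(self):
        genome, _ = make_plastome(PlastomeSpec(100_000, 20_000, 10_000, seed=3))  # IR 10 kb
        outcome = classify_novel_mode([genome])
        assert not outcome.success
        assert any("IR" in r for r in outcome.reasons)

    def test_no_ir_random_contig_fails(self):
        rec = make_component(140_000, seed=4)
        outcome = classify_novel_mode([SeqRecord("r", rec.seq, "circular")])
        assert not outcome.success

    @pytest.mark.parametrize(
        "features,success",
        [
            (AssemblyFeatures(1, 130_000, 17_000), True),  # both exactly at cutoff
            (AssemblyFeatures(1, 129_999, 17_000), False),
            (AssemblyFeatures(1, 130_000, 16_999), False),
            (AssemblyFeatures(2, 200_000, 20_000), False),
        ],
    )
    def test_boundary_inclusivity_on_features(self, features, success):
        outcome = classify_features(features, NovelCriteria())
        assert outcome.success is success

    def test_monotonicity_raising_cutoffs(self):
        rng = np.random.default_rng(0)
        feats = [
            AssemblyFeatures(
                int(rng.integers(1, 4)),
                int(rng.integers(50_000, 200_000)),
                int(rng.integers(0, 40_000)),
            )
            for _ in range(200)
        ]
        lo = NovelCriteria(min_total_len=120_000, min_ir_len=15_000)
        hi = NovelCriteria(min_total_len=140_000, min_ir_len=20_000)
        for f in feats:
            if classify_features(f, hi).success:
                assert classify_features(f, lo).success


class TestPrf:
    def test_perfect_predictions(self):
        truth = [True, False, True, False]
        result = prf(truth, truth)
        assert (result.precision, result.recall, result.f1) == (1.0, 1.0, 1.0)

    def test_closed_form_counts(self):
        predicted = [True, True, True, False, False]
        truth = [True, True, False, True, False]
        result = prf(predicted, truth)
        assert (result.tp, result.fp, result.fn, result.tn) == (2, 1, 1, 1)
        assert result.precision == pytest.approx(2 / 3)
        assert result.recall == pytest.approx(2 / 3)
        assert result.f1 == pytest.approx(2 / 3)

    def test_all_negative_predictions_zero_by_convention(self):
        result = prf([False, False, False], [True, False, True])
        assert (result.precision, result.recall, result.f1) == (0.0, 0.0, 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            prf([True], [True, False])

    def test_matches_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(1)
        predicted = rng.random(50) > 0.5
        truth = rng.random(50) > 0.4
        ours = prf(predicted.tolist(), truth.tolist())
        p, r, f, _ = precision_recall_fscore_support(
            truth, predicted, average="binary", zero_division=0
        )
        assert ours.precision == pytest.approx(p)
        assert ours.recall == pytest.approx(r)
        assert ours.f1 == pytest.approx(f)


class TestSelectCutoffs:
    def _separable_set(self):
        """Labeled set that only the (130 kbp, 17 kbp) pair separates perfectly."""
        positives = [
            AssemblyFeatures(1, 130_000, 17_000),
            AssemblyFeatures(1, 150_000, 25_000),
            AssemblyFeatures(1, 131_000, 17_500),
        ]
        negatives = [
            AssemblyFeatures(1, 129_000, 25_000),  # kills length cutoffs < 130k
            AssemblyFeatures(1, 160_000, 16_500),  # kills IR cutoffs < 17k
            AssemblyFeatures(2, 160_000, 25_000),
            AssemblyFeatures(1, 100_000, 10_000),
        ]
        return [(f, True) for f in positives] + [(f, False) for f in negatives]

    def test_recovers_constructed_cutoffs(self):
        length, ir, best = select_cutoffs(self._separable_set())
        assert (length, ir) == (130_000, 17_000)
        assert best.f1 == 1.0

    def test_all_positive_truth_tie_breaks_to_smallest_pair(self):
        labeled = [
            (AssemblyFeatures(1, 200_000, 40_000), True),
            (AssemblyFeatures(1, 180_000, 35_000), True),
        ]
        length, ir, best = select_cutoffs(labeled)
        assert (length, ir) == (100_000, 10_000)
        assert best.f1 == 1.0

    def test_single_point_grid(self):
        length, ir, _ = select_cutoffs(
            self._separable_set(), length_grid=[125_000], ir_grid=[12_000]
        )
        assert (length, ir) == (125_000, 12_000)

    def test_best_f1_matches_double_loop_oracle(self):
        labeled = self._separable_set()
        length_grid = list(range(120_000, 140_001, 5_000))
        ir_grid = list(range(15_000, 20_001, 1_000))
        _, _, best = select_cutoffs(labeled, length_grid, ir_grid)
        oracle_best = 0.0
        for length_cut in length_grid:
            for ir_cut in ir_grid:
                predicted = [
                    f.n_contigs == 1 and f.total_len >= length_cut and f.max_ir_len >= ir_cut
                    for f, _ in labeled
                ]
                truth = [t for _, t in labeled]
                oracle_best = max(oracle_best, prf(predicted, truth).f1)
        assert best.f1 == pytest.approx(oracle_best)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            select_cutoffs([])
        with pytest.raises(ValueError):
            select_cutoffs(self._separable_set(), length_grid=[], ir_grid=[1])
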