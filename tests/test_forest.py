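"""Feature extraction, portable forest model, and per-base forest decisions."""

import numpy as np
import pytest

from msacorrect.align import AlignmentResult, Candidate
from msacorrect.classic import QualityThresholds, classify_msa, correct_anchor_classic
from msacorrect.forest import (
    ANCHOR_FEATURES,
    CANDIDATE_FEATURES,
    ForestModel,
    ModelError,
    MsaContext,
    correct_anchor_forest,
    extract_features,
    predict_correction,
)
from msacorrect.io_encodings import EncodedRead
from msacorrect.msa import build_msa


def _read(seq, read_id=0):
    return EncodedRead.from_sequence(seq, read_id=read_id)


def _cand(seq, read_id, mismatches=0):
    return Candidate(
        _read(seq, read_id), AlignmentResult(0, len(seq), mismatches, "fwd", True)
    )


@pytest.fixture(scope="module")
def toy_forest():
    """A forest fit on separable toy data, wrapped in the portable container."""
    from sklearn.ensemble import RandomForestClassifier

    rng = np.random.default_rng(0)
    X = rng.random((400, len(ANCHOR_FEATURES)))
    y = (X[:, 0] < 0.5).astype(int)  # decision on the first feature only
    clf = RandomForestClassifier(n_estimators=16, random_state=0, n_jobs=1)
    clf.fit(X, y)
    return clf, ForestModel.from_sklearn(clf, "anchor", ANCHOR_FEATURES)


class TestFeatureExtraction:
    def test_single_row_msa_degenerate(self):
        msa = build_msa(_read("ACGT"), [])
        fv = extract_features(msa, msa.anchor, 0, estimated_coverage=30)
        named = dict(zip(ANCHOR_FEATURES, fv))
        assert named["orig_base_count_frac"] == 1.0
        assert named["cons_base_count_frac"] == 1.0
        assert named["column_support"] == 1.0
        assert named["column_coverage"] == 1.0
        assert named["relative_position"] == 0.0

    def test_count_fractions(self):
        # column 0: consensus A (9 rows + anchor T -> 9/10 vs 1/10)
        msa = build_msa(_read("TAAA"), [_cand("AAAA", i + 1) for i in range(9)])
        fv = extract_features(msa, msa.anchor, 0, estimated_coverage=30)
        named = dict(zip(ANCHOR_FEATURES, fv))
        assert named["orig_base_count_frac"] == pytest.approx(0.1)
        assert named["cons_base_count_frac"] == pytest.approx(0.9)

    def test_candidate_alignment_features(self):
        msa = build_msa(_read("A" * 100), [_cand("A" * 100, 1, mismatches=4)])
        member = msa.members[1]
        aln = AlignmentResult(0, 80, 4, "fwd", True)
        fv = extract_features(msa, member, 0, 30, alignment=aln)
        named = dict(zip(CANDIDATE_FEATURES, fv))
        assert named["mismatch_ratio"] == pytest.approx(0.05)
        assert named["overlap_frac"] == pytest.approx(0.8)
        assert named["mismatches"] == 4

    def test_fractional_features_in_unit_interval(self, small_simulation):
        _, reads, _, _, _ = small_simulation
        msa = build_msa(reads[0], [])
        fractional = [
            "orig_base_count_frac", "cons_base_count_frac",
            "orig_base_weight_frac", "cons_base_weight_frac",
            "orig_base_quality", "cons_mean_quality", "column_support",
            "relative_position", "read_mean_support",
            "msa_min_support", "msa_avg_support",
        ]
        for j in range(0, reads[0].length, 7):
            named = dict(zip(ANCHOR_FEATURES, extract_features(msa, msa.anchor, j, 30)))
            for name in fractional:
                assert 0.0 <= named[name] <= 1.0, name

    def test_extraction_deterministic(self):
        msa = build_msa(_read("ACGTACGT"), [_cand("ACGTACGT", 1)])
        a = extract_features(msa, msa.anchor, 3, 30)
        b = extract_features(msa, msa.anchor, 3, 30)
        assert np.array_equal(a, b)

    def test_uncovered_position_rejected(self):
        msa = build_msa(_read("ACGT"), [])
        with pytest.raises(ValueError):
            extract_features(msa, msa.anchor, 4, 30)


class TestForestModel:
    def test_traversal_matches_sklearn(self, toy_forest):
        clf, model = toy_forest
        rng = np.random.default_rng(1)
        X = rng.random((200, len(ANCHOR_FEATURES)))
        expected = clf.predict_proba(X)[:, list(clf.classes_).index(1)]
        assert np.allclose(model.predict_proba(X), expected)

    def test_save_load_round_trip(self, toy_forest, tmp_path):
        _, model = toy_forest
        path = tmp_path / "model.json.gz"
        model.save(path)
        loaded = ForestModel.load(path)
        rng = np.random.default_rng(2)
        X = rng.random((50, len(ANCHOR_FEATURES)))
        assert np.allclose(model.predict_proba(X), loaded.predict_proba(X))
        assert loaded.feature_names == model.feature_names

    def test_schema_mismatch_rejected(self, toy_forest):
        _, model = toy_forest
        with pytest.raises(ModelError):
            model.predict_proba(np.zeros((1, 3)))

    def test_threshold_strictly_surpassed(self, toy_forest):
        _, model = toy_forest
        fv = np.full(len(ANCHOR_FEATURES), 0.01)  # feature 0 tiny -> positive class
        p = model.predict_proba(fv)[0]
        assert p > 0.5
        assert predict_correction(model, fv, p / 2)
        assert not predict_correction(model, fv, p)  # boundary: not strict above

    def test_threshold_monotone(self, toy_forest):
        _, model = toy_forest
        rng = np.random.default_rng(3)
        for _ in range(20):
            fv = rng.random(len(ANCHOR_FEATURES))
            decisions = [
                predict_correction(model, fv, t) for t in (0.1, 0.3, 0.5, 0.7, 0.9)
            ]
            # once the rising threshold stops a correction it stays stopped
            assert decisions == sorted(decisions, reverse=True)


class TestForestAnchorCorrection:
    def _hq_setup(self):
        anchor = _read("TAAA")
        msa = build_msa(anchor, [_cand("AAAA", i + 1) for i in range(10)])
        quality = classify_msa(msa, QualityThresholds())
        assert quality.is_high_quality
        return anchor, msa, quality

    def test_high_quality_matches_classic(self, toy_forest):
        _, model = toy_forest
        anchor, msa, quality = self._hq_setup()
        forest_rec = correct_anchor_forest(anchor, msa, quality, model, 0.7, 30)
        classic_rec = correct_anchor_classic(anchor, msa, quality)
        assert forest_rec.corrected_sequence == classic_rec.corrected_sequence

    def test_extreme_threshold_blocks_low_quality_corrections(self, toy_forest):
        _, model = toy_forest
        anchor = _read("TAAA")
        msa = build_msa(anchor, [_cand("AAAA", 1)])
        quality = classify_msa(msa, QualityThresholds(min_coverage=50))
        assert not quality.is_high_quality
        rec = correct_anchor_forest(anchor, msa, quality, model, 0.999999, 30)
        probs = model.predict_proba(
            extract_features(msa, msa.anchor, 0, 30)
        )
        if probs[0] < 1.0:
            assert rec.corrected_sequence == anchor.sequence

    def test_concordant_positions_never_scored(self, toy_forest):
        """Positions where the anchor already equals the consensus stay put."""
        _, model = toy_forest
        anchor = _read("AAAA")
        msa = build_msa(anchor, [_cand("AAAA", 1)])
        quality = classify_msa(msa, QualityThresholds(min_coverage=50))
        rec = correct_anchor_forest(anchor, msa, quality, model, 0.000001, 30)
        assert rec.corrected_sequence == "AAAA" and rec.edits == []
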