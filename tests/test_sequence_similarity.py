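"""Smith-Waterman scores, X_AA similarity histograms and f_AA probabilities."""

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from ecfuse.sequence_similarity import (
    ScoringScheme,
    SequenceRecord,
    SimilarityMatrix,
    TrainingIndex,
    class_probabilities_aa,
    pairwise_similarities,
    similarity_features,
    sw_score,
)

from oracles import f_aa_oracle, similarity_features_oracle, sw_bruteforce

SIMPLE = ScoringScheme(matrix=None, match=2, mismatch=-1, gap_open=2, gap_extend=1)


class TestSwScore:
    def test_perfect_match_scores_sum_of_matches(self):
        assert sw_score("ACD", "ACD", SIMPLE) == 6.0

    def test_no_positive_alignment_scores_zero(self):
        assert sw_score("AAAA", "CCCC", SIMPLE) == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sw_score("", "ACD", SIMPLE)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="not covered"):
            sw_score(SequenceRecord("q", "ACDX").sequence + "1", "ACD")

    def test_x_scored_via_matrix_row(self):
        # BLOSUM62 carries an X row, so X-containing sequences score
        assert sw_score("AXA", "AXA") > 0

    def test_matches_bruteforce_enumeration_simple_scoring(self, rng):
        alphabet = "ACGT"
        sub = lambda x, y: 2.0 if x == y else -1.0
        for _ in range(60):
            a = "".join(rng.choice(list(alphabet), rng.integers(1, 7)))
            b = "".join(rng.choice(list(alphabet), rng.integers(1, 7)))
            assert sw_score(a, b, SIMPLE) == sw_bruteforce(a, b, sub, 2.0, 1.0)

    def test_matches_bruteforce_enumeration_blosum62(self, rng):
        blosum = substitution_matrices.load("BLOSUM62")
        sub = lambda x, y: float(blosum[x, y])
        alphabet = "ACGTW"
        for _ in range(40):
            a = "".join(rng.choice(list(alphabet), rng.integers(1, 6)))
            b = "".join(rng.choice(list(alphabet), rng.integers(1, 6)))
            assert sw_score(a, b) == sw_bruteforce(a, b, sub, 11.0, 1.0)

    def test_symmetric_for_symmetric_matrix(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(25):
            a = "".join(rng.choice(aas, rng.integers(3, 30)))
            b = "".join(rng.choice(aas, rng.integers(3, 30)))
            assert sw_score(a, b) == sw_score(b, a)

    def test_self_score_dominates_under_identity_scoring(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, 25))
        for _ in range(10):
            b = "".join(rng.choice(aas, rng.integers(3, 30)))
            assert sw_score(a, a, SIMPLE) >= sw_score(a, b, SIMPLE)


def _matrix_from_dict(scores, refs, queries):
    data = np.array([[scores[(r, q)] for q in queries] for r in refs])
    return SimilarityMatrix(pd.DataFrame(data, index=refs, columns=queries))


def _index(class_sets):
    return TrainingIndex(
        {x: set(members) for x, members in class_sets.items()}
    )


class TestSimilarityFeatures:
    def test_degenerate_similarity_concentrates_mass(self):
        refs = [f"t{x}" for x in range(1, 7)]
        class_sets = {x: {f"t{x}"} for x in range(1, 7)}
        scores = {(r, "q"): 0.0 for r in refs}
        scores[("t3", "q")] = 42.0
        fv = similarity_features("q", _matrix_from_dict(scores, refs, ["q"]), _index(class_sets))
        assert fv.block(3)[-1] == 1.0  # the identical sample: top bin
        for x in (1, 2, 4, 5, 6):
            assert fv.block(x)[0] == 1.0  # all-zero classes: bottom bin

    def test_single_sample_classes_give_one_hot_blocks(self, rng):
        refs = [f"t{x}" for x in range(1, 7)]
        class_sets = {x: {f"t{x}"} for x in range(1, 7)}
        scores = {(r, "q"): float(rng.uniform(1, 50)) for r in refs}
        fv = similarity_features("q", _matrix_from_dict(scores, refs, ["q"]), _index(class_sets))
        assert np.count_nonzero(fv.values == 1.0) == 6
        assert fv.values.sum() == pytest.approx(6.0)
        for x in range(1, 7):
            assert fv.block(x).sum() == pytest.approx(1.0)

    def test_matches_loop_oracle_on_random_index(self, rng):
        refs = [f"t{i}" for i in range(30)]
        class_sets = {x: set() for x in range(1, 7)}
        for i, r in enumerate(refs):
            class_sets[(i % 6) + 1].add(r)
        scores = {(r, "q"): float(rng.uniform(0, 100)) for r in refs}
        fv = similarity_features("q", _matrix_from_dict(scores, refs, ["q"]), _index(class_sets))
        np.testing.assert_allclose(
            fv.values, similarity_features_oracle("q", scores, class_sets)
        )

    def test_empty_class_after_self_exclusion_raises(self):
        refs = ["q", "t2", "t3", "t4", "t5", "t6"]
        class_sets = {1: {"q"}, **{x: {f"t{x}"} for x in range(2, 7)}}
        scores = {(r, "q"): 1.0 for r in refs}
        with pytest.raises(ValueError, match="class 1"):
            similarity_features("q", _matrix_from_dict(scores, refs, ["q"]), _index(class_sets))

    def test_all_zero_similarities_raise(self):
        refs = [f"t{x}" for x in range(1, 7)]
        class_sets = {x: {f"t{x}"} for x in range(1, 7)}
        scores = {(r, "q"): 0.0 for r in refs}
        with pytest.raises(ValueError, match="all-zero"):
            similarity_features("q", _matrix_from_dict(scores, refs, ["q"]), _index(class_sets))


class TestClassProbabilitiesAa:
    def test_equal_maxima_give_uniform(self):
        refs = [f"t{x}" for x in range(1, 7)]
        class_sets = {x: {f"t{x}"} for x in range(1, 7)}
        scores = {(r, "q"): 10.0 for r in refs}
        probs = class_probabilities_aa("q", _matrix_from_dict(scores, refs, ["q"]), _index(class_sets))
        np.testing.assert_allclose(probs.values, np.full(6, 1 / 6))

    def test_direct_normalization(self):
        refs = [f"t{x}" for x in range(1, 7)]
        class_sets = {x: {f"t{x}"} for x in range(1, 7)}
        maxima = [3.0, 1.0, 0.0, 0.0, 0.0, 0.0]
        scores = {(f"t{x}", "q"): maxima[x - 1] for x in range(1, 7)}
        probs = class_probabilities_aa("q", _matrix_from_dict(scores, refs, ["q"]), _index(class_sets))
        np.testing.assert_allclose(probs.values, [0.75, 0.25, 0, 0, 0, 0])

    def test_matches_two_loop_oracle(self, rng):
        refs = [f"t{i}" for i in range(20)]
        class_sets = {x: set() for x in range(1, 7)}
        for i, r in enumerate(refs):
            class_sets[(i % 6) + 1].add(r)
        scores = {(r, "q"): float(rng.uniform(0, 50)) for r in refs}
        probs = class_probabilities_aa("q", _matrix_from_dict(scores, refs, ["q"]), _index(class_sets))
        np.testing.assert_allclose(probs.values, f_aa_oracle("q", scores, class_sets))
        assert probs.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_leave_self_out_blocks_self_inflation(self, rng):
        refs = [f"t{i}" for i in range(12)]
        class_sets = {x: set() for x in range(1, 7)}
        for i, r in enumerate(refs):
            class_sets[(i % 6) + 1].add(r)
        scores = {(r, "t0"): float(rng.uniform(1, 20)) for r in refs}
        scores[("t0", "t0")] = 1e6  # would dominate class 1 if not excluded
        S = _matrix_from_dict(scores, refs, ["t0"])
        with_self = class_probabilities_aa("t0", S, _index(class_sets))
        no_self_sets = {x: s - {"t0"} for x, s in class_sets.items()}
        no_self_sets[1].add("t11")  # keep class 1 populated identically
        np.testing.assert_allclose(
            with_self.values, f_aa_oracle("t0", scores, class_sets)
        )
        assert with_self.values[0] < 0.9  # the 1e6 self-score did not leak

    def test_zero_denominator_raises_or_uniform(self):
        refs = [f"t{x}" for x in range(1, 7)]
        class_sets = {x: {f"t{x}"} for x in range(1, 7)}
        scores = {(r, "q"): 0.0 for r in refs}
        S = _matrix_from_dict(scores, refs, ["q"])
        with pytest.raises(ValueError, match="no positive similarity"):
            class_probabilities_aa("q", S, _index(class_sets))
        fallback = class_probabilities_aa("q", S, _index(class_sets), on_zero="uniform")
        np.testing.assert_allclose(fallback.values, np.full(6, 1 / 6))

    def test_class_permutation_permutes_output(self, rng):
        refs = [f"t{i}" for i in range(12)]
        class_sets = {x: set() for x in range(1, 7)}
        for i, r in enumerate(refs):
            class_sets[(i % 6) + 1].add(r)
        scores = {(r, "q"): float(rng.uniform(0, 50)) for r in refs}
        S = _matrix_from_dict(scores, refs, ["q"])
        base = class_probabilities_aa("q", S, _index(class_sets)).values
        perm = [4, 2, 6, 1, 3, 5]
        permuted_sets = {x: class_sets[perm[x - 1]] for x in range(1, 7)}
        permuted = class_probabilities_aa("q", S, _index(permuted_sets)).values
        np.testing.assert_allclose(permuted, base[[p - 1 for p in perm]])


class TestPairwiseSimilarities:
    def test_layout_and_symmetry(self):
        records = [
            SequenceRecord("a", "ACDEFGHIKL"),
            SequenceRecord("b", "ACDEFGWIKL"),
            SequenceRecord("c", "MNPQRSTVWY"),
        ]
        S = pairwise_similarities(records, records)
        assert S.reference_ids == ["a", "b", "c"]
        assert S.query_ids == ["a", "b", "c"]
        for r in "abc":
            assert S.score(r, r) > 0
            for q in "abc":
                assert S.score(r, q) == S.score(q, r)

    def test_tsv_round_trip(self, tmp_path):
        records = [SequenceRecord("a", "ACDEF"), SequenceRecord("b", "ACDFF")]
        S = pairwise_similarities(records, records)
        path = tmp_path / "scores.tsv"
        S.to_tsv(path)
        loaded = SimilarityMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(S.scores, loaded.scores)
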