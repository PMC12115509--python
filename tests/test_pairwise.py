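"""Global alignment: DP correctness against exhaustive enumeration, an
independent library cross-check, and the percentage definitions."""

import itertools

import numpy as np
import pytest

from conftest import brute_force_align_score
from mpact.pairwise import (
    AlignmentResult,
    SubstitutionMatrix,
    all_vs_all_sequences,
    default_matrix,
    nw_align,
    percent_identity,
    percent_similarity,
    threedi_similarity,
)
from mpact.seqio import SequenceRecord

NT = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _rec(rid, seq, alphabet="nucleotide"):
    return SequenceRecord(rid, alphabet, seq)


class TestSubstitutionMatrices:
    @pytest.mark.parametrize("alphabet", ["nucleotide", "amino_acid", "threedi"])
    def test_symmetric_and_complete(self, alphabet):
        from mpact.seqio import ALPHABETS

        m = default_matrix(alphabet)
        assert np.allclose(m.scores, m.scores.T)
        for a in ALPHABETS[alphabet]:
            for b in ALPHABETS[alphabet]:
                m.score(a, b)  # must be defined

    def test_blosum62_published_entries(self):
        m = default_matrix("amino_acid")
        assert m.score("W", "W") == 11
        assert m.score("V", "I") == 3
        assert m.score("A", "A") == 4
        assert m.score("R", "D") == -2

    def test_positive_self_scores(self):
        # guarantees identity_pct <= similarity_pct for the bundled matrices
        for alphabet in ("nucleotide", "amino_acid", "threedi"):
            m = default_matrix(alphabet)
            from mpact.seqio import ALPHABETS

            for a in ALPHABETS[alphabet] - {"*", "X", "N", "B", "Z", "D", "H", "V", "S", "W", "K", "M", "R", "Y"}:
                assert m.score(a, a) > 0, (alphabet, a)

    def test_emboss_file_roundtrip(self, tmp_path):
        m = default_matrix("threedi")
        path = tmp_path / "mat.txt"
        m.write_emboss_file(path)
        back = SubstitutionMatrix.from_emboss_file(path, "threedi")
        assert back.letters == m.letters
        assert np.allclose(back.scores, m.scores)


class TestNwAlign:
    def test_identical_sequences(self):
        r = nw_align(_rec("a", "ACGT"), _rec("b", "ACGT"))
        assert r.identity_pct == 100.0
        assert r.similarity_pct == 100.0
        assert r.gaps == 0

    def test_single_mismatch(self):
        r = nw_align(_rec("a", "ACGT"), _rec("b", "ACGA"))
        assert r.gaps == 0
        assert r.identity_pct == 75.0

    def test_ungapping_recovers_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = "".join(rng.choice(list(NT), size=rng.integers(5, 40)))
            b = "".join(rng.choice(list(NT), size=rng.integers(5, 40)))
            r = nw_align(_rec("a", a), _rec("b", b))
            assert r.aligned_a.replace("-", "") == a
            assert r.aligned_b.replace("-", "") == b
            assert len(r.aligned_a) == len(r.aligned_b)

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError, match="alphabet mismatch"):
            nw_align(_rec("a", "ACGT"), _rec("b", "ACDE", "amino_acid"))

    @pytest.mark.parametrize("end_gaps_penalized", [False, True])
    def test_score_equals_bruteforce_enumeration(self, end_gaps_penalized):
        """DP optimum equals exhaustive enumeration over all global
        alignments for 200 random short pairs."""
        rng = np.random.default_rng(1234)
        m = default_matrix("nucleotide")
        for _ in range(200):
            a = "".join(rng.choice(list(NT), size=rng.integers(1, 7)))
            b = "".join(rng.choice(list(NT), size=rng.integers(1, 7)))
            r = nw_align(
                _rec("a", a), _rec("b", b), end_gaps_penalized=end_gaps_penalized
            )
            expected = brute_force_align_score(
                a, b, m.score, 10.0, 0.5, end_gaps_penalized
            )
            assert r.score == pytest.approx(expected, abs=1e-9), (a, b)

    def test_score_matches_biopython_aligner(self):
        """Independent cross-check: Biopython's PairwiseAligner under the
        same gap convention gives the same optimal score."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
        rng = np.random.default_rng(7)
        for _ in range(40):
            a = "".join(rng.choice(list(AA20), size=rng.integers(5, 60)))
            b = "".join(rng.choice(list(AA20), size=rng.integers(5, 60)))
            r = nw_align(_rec("a", a, "amino_acid"), _rec("b", b, "amino_acid"))
            assert r.score == pytest.approx(aligner.score(a, b), abs=1e-6)

    def test_score_symmetric_in_argument_order(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = "".join(rng.choice(list(NT), size=rng.integers(3, 30)))
            b = "".join(rng.choice(list(NT), size=rng.integers(3, 30)))
            r1 = nw_align(_rec("a", a), _rec("b", b))
            r2 = nw_align(_rec("b", b), _rec("a", a))
            assert r1.score == pytest.approx(r2.score)
            assert r1.identity_pct == pytest.approx(r2.identity_pct)
            assert r1.similarity_pct == pytest.approx(r2.similarity_pct)

    def test_point_mutations_never_increase_identity(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list(AA20), size=80))
        rec = _rec("a", base, "amino_acid")
        prev = 100.0
        mutated = list(base)
        for k in range(1, 20, 4):
            while sum(1 for x, y in zip(base, mutated) if x != y) < k:
                pos = rng.integers(0, len(base))
                mutated[pos] = rng.choice([c for c in AA20 if c != base[pos]])
            r = nw_align(rec, _rec("b", "".join(mutated), "amino_acid"))
            assert r.identity_pct <= prev + 1e-9
            prev = r.identity_pct


class TestPercentages:
    def test_similar_but_not_identical_column(self):
        m = default_matrix("amino_acid")
        r = AlignmentResult("AV", "AI", 0.0, 0.0, 0.0, 0)
        assert percent_identity(r) == 50.0
        assert m.score("V", "I") > 0
        assert percent_similarity(r, m) == 100.0

    def test_gap_columns_in_denominator(self):
        r = AlignmentResult("A-C", "AGC", 0.0, 0.0, 0.0, 1)
        assert percent_identity(r) == pytest.approx(66.6667, abs=1e-3)

    def test_identity_le_similarity_for_bundled_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = "".join(rng.choice(list(AA20), size=40))
            b = "".join(rng.choice(list(AA20), size=40))
            r = nw_align(_rec("a", a, "amino_acid"), _rec("b", b, "amino_acid"))
            assert r.identity_pct <= r.similarity_pct + 1e-9


class TestAllVsAll:
    def test_identical_records_give_100(self):
        recs = [_rec(f"r{i}", "ACGTACGT") for i in range(3)]
        ident, simil = all_vs_all_sequences(recs)
        assert np.allclose(ident.values, 100.0)
        assert np.allclose(simil.values, 100.0)

    def test_pair_count_and_oracle_loop(self):
        rng = np.random.default_rng(5)
        recs = [
            _rec(f"r{i}", "".join(rng.choice(list(NT), size=30))) for i in range(4)
        ]
        executed = []
        ident, simil = all_vs_all_sequences(recs, on_pair=lambda a, b, r: executed.append((a, b)))
        assert len(executed) == 6  # n(n-1)/2
        for i, j in itertools.combinations(range(4), 2):
            r = nw_align(recs[i], recs[j])
            assert ident.values[i, j] == pytest.approx(r.identity_pct)
            assert simil.values[i, j] == pytest.approx(r.similarity_pct)

    def test_label_order_follows_input(self):
        recs = [_rec("z", "ACGT"), _rec("a", "ACGG"), _rec("m", "ACCT")]
        ident, _ = all_vs_all_sequences(recs)
        assert ident.labels == ["z", "a", "m"]


class TestThreedi:
    def test_identical_strings_give_100(self):
        recs = [
            SequenceRecord("x", "threedi", "DDVVLACD"),
            SequenceRecord("y", "threedi", "DDVVLACD"),
        ]
        m = threedi_similarity(recs)
        assert m.values[0, 1] == pytest.approx(100.0)
        assert m.metric == "threedi_similarity_pct"

    def test_permutation_only_permutes_labels(self):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list(AA20), size=25)) for _ in range(4)]
        recs = [SequenceRecord(f"r{i}", "threedi", s) for i, s in enumerate(seqs)]
        m1 = threedi_similarity(recs)
        perm = [2, 0, 3, 1]
        m2 = threedi_similarity([recs[i] for i in perm])
        assert np.allclose(m2.values, m1.reorder(m2.labels).values)

    def test_agrees_with_naive_pair_loop(self):
        rng = np.random.default_rng(8)
        recs = [
            SequenceRecord(f"r{i}", "threedi", "".join(rng.choice(list(AA20), size=20)))
            for i in range(3)
        ]
        m = threedi_similarity(recs)
        tdm = default_matrix("threedi")
        for i, j in itertools.combinations(range(3), 2):
            r = nw_align(recs[i], recs[j], tdm)
            assert m.values[i, j] == pytest.approx(r.similarity_pct)

    def test_non_threedi_records_rejected(self):
        with pytest.raises(ValueError, match="not in 3Di"):
            threedi_similarity([_rec("a", "ACGT"), _rec("b", "ACGT")])
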