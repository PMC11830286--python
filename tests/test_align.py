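"""Pairwise alignment engines, E-values and proteome search."""

import math

import numpy as np
import pytest

from fragid import align, fragsim
from fragid.align import (
    KarlinAltschulParams,
    bit_score,
    evalue,
    needle_stats,
    needleman_wunsch,
    search_proteome,
    smith_waterman,
)
from fragid.errors import AlphabetError, InvalidInputError

from ._oracles import oracle_global_score, oracle_local_score
from .conftest import random_protein


class TestNeedlemanWunsch:
    def test_identity_alignment(self, blosum):
        a = needleman_wunsch("AAAA", "AAAA")
        assert (a.identity, a.similarity, a.gaps) == (100.0, 100.0, 0.0)
        assert a.score == 4 * blosum.score("A", "A")

    def test_single_end_gap_geometry(self):
        a = needleman_wunsch("AAAA", "AAA", end_gaps_free=True)
        assert a.n_columns == 4
        assert (a.aligned_query.count("-"), a.aligned_subject.count("-")) == (0, 1)
        assert a.identity == 75.0

    def test_score_symmetry(self, blosum):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(5, 30)))
            b = random_protein(rng, int(rng.integers(5, 30)))
            for free in (True, False):
                s1 = needleman_wunsch(a, b, end_gaps_free=free).score
                s2 = needleman_wunsch(b, a, end_gaps_free=free).score
                assert s1 == pytest.approx(s2)

    @pytest.mark.parametrize("free", [True, False])
    def test_matches_bruteforce_oracle(self, blosum, free):
        got = needleman_wunsch("HEAGAWGHEE", "PAWHEAE", end_gaps_free=free)
        want = oracle_global_score(
            "HEAGAWGHEE", "PAWHEAE", blosum.score, 10.0, 0.5, free
        )
        assert got.score == pytest.approx(want)

    def test_score_recomputes_from_aligned_strings(self, blosum):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = random_protein(rng, int(rng.integers(5, 40)))
            b = random_protein(rng, int(rng.integers(5, 40)))
            aln = needleman_wunsch(a, b)
            assert aln.recompute_score(blosum, 10.0, 0.5, True) == pytest.approx(aln.score)

    def test_degapped_rows_reproduce_inputs(self):
        aln = needleman_wunsch("HEAGAWGHEE", "PAWHEAE")
        assert aln.aligned_query.replace("-", "") == "HEAGAWGHEE"
        assert aln.aligned_subject.replace("-", "") == "PAWHEAE"

    def test_identity_never_exceeds_similarity(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            a = random_protein(rng, 20)
            b = random_protein(rng, 25)
            aln = needleman_wunsch(a, b)
            assert 0 <= aln.identity <= aln.similarity <= 100

    def test_cross_check_against_biopython(self, blosum):
        """Independent engine: Bio.Align.PairwiseAligner, same gap convention."""
        from Bio import Align as BioAlign

        aligner = BioAlign.PairwiseAligner()
        aligner.substitution_matrix = BioAlign.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -(10.0 + 0.5)
        aligner.extend_gap_score = -0.5
        aligner.mode = "global"
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
        rng = np.random.default_rng(3)
        for _ in range(15):
            a = random_protein(rng, int(rng.integers(8, 35)))
            b = random_protein(rng, int(rng.integers(8, 35)))
            assert needleman_wunsch(a, b).score == pytest.approx(aligner.score(a, b))

    def test_empty_and_alphabet_errors(self):
        with pytest.raises(InvalidInputError):
            needleman_wunsch("", "AAA")
        with pytest.raises(AlphabetError):
            needleman_wunsch("AB/", "AAA")

    def test_x_is_neutral_never_identical(self):
        aln = needleman_wunsch("AXA", "AXA", end_gaps_free=False)
        assert aln.identity == pytest.approx(100 * 2 / 3)
        assert aln.similarity == pytest.approx(100 * 2 / 3)


class TestSubstitutionMatrix:
    def test_ncbi_text_format_roundtrip(self, tmp_path, blosum):
        from Bio.Align import substitution_matrices

        path = tmp_path / "BLOSUM62.txt"
        path.write_text(str(substitution_matrices.load("BLOSUM62")))
        loaded = align.SubstitutionMatrix.from_ncbi(path, name="BLOSUM62")
        assert (loaded.scores == blosum.scores).all()

    def test_asymmetric_and_nonpositive_diagonal_rejected(self):
        import numpy as np

        from fragid.errors import InvalidParameterError

        bad = np.zeros((20, 20), dtype=int)
        bad[0, 1] = 3  # asymmetric
        with pytest.raises(InvalidParameterError):
            align.SubstitutionMatrix(bad)
        sym = np.eye(20, dtype=int) * 0  # zero diagonal
        with pytest.raises(InvalidParameterError):
            align.SubstitutionMatrix(sym)


class TestSmithWaterman:
    def test_all_negative_pairs_give_no_hit(self):
        # L vs D/E scores negative under BLOSUM62
        assert smith_waterman("LLLL", "DEDE") is None

    def test_exact_substring_scores_sum_of_self_scores(self, blosum):
        q = "AWGHE"
        hit = smith_waterman(q, "HEAGAWGHEE")
        assert hit.raw_score == sum(blosum.score(c, c) for c in q)
        assert hit.subject_span == (4, 9)
        assert hit.query_span == (0, 5)

    def test_self_alignment_scores_diagonal_sum(self, blosum):
        rng = np.random.default_rng(4)
        s = random_protein(rng, 30)
        hit = smith_waterman(s, s)
        assert hit.raw_score == sum(blosum.score(c, c) for c in s)

    def test_matches_bruteforce_oracle_on_seeded_pair(self, blosum):
        rng = np.random.default_rng(5)
        q = random_protein(rng, 30)
        s = random_protein(rng, 200)
        hit = smith_waterman(q, s)
        want = oracle_local_score(q, s, blosum.score, 11.0, 1.0)
        assert (hit.raw_score if hit else 0.0) == pytest.approx(want)


class TestEvalue:
    def test_zero_score_gives_kmn(self):
        ka = KarlinAltschulParams(0.267, 0.041)
        assert evalue(0, 100, 1000, ka) == pytest.approx(0.041 * 100 * 1000)

    def test_score_increment_scales_exponentially(self):
        ka = KarlinAltschulParams()
        assert evalue(60, 50, 500, ka) / evalue(50, 50, 500, ka) == pytest.approx(
            math.exp(-ka.lam * 10)
        )

    def test_direct_formula_evaluation(self):
        ka = KarlinAltschulParams(0.267, 0.041)
        got = evalue(50, 100, 10_000, ka)
        assert got == pytest.approx(0.041 * 100 * 10_000 * math.exp(-0.267 * 50))

    def test_bit_score_relation(self):
        ka = KarlinAltschulParams()
        assert bit_score(100, ka) == pytest.approx(
            (ka.lam * 100 - math.log(ka.K)) / math.log(2)
        )


class TestSearchProteome:
    def test_exact_copy_ranks_first(self, reference, standard_db):
        table = search_proteome(reference, standard_db)
        assert table.hits[0].subject_id == "TARGET"

    def test_empty_db_gives_empty_table(self, reference):
        table = search_proteome(reference, fragsim.ProteomeDB([]))
        assert len(table) == 0

    def test_truncation_to_top_100(self, reference):
        """A db of 150 easily-hit subjects yields exactly 100 rows."""
        records = [
            fragsim.ProteomeRecord(f"S{i:03d}", "copy", reference) for i in range(150)
        ]
        table = search_proteome(reference, fragsim.ProteomeDB(records), max_evalue=1e30)
        assert len(table) == 100

    def test_sorted_by_evalue_then_bits_then_id(self, reference, standard_db):
        table = search_proteome(reference, standard_db)
        keys = [align.HitTable.sort_key(h) for h in table]
        assert keys == sorted(keys)

    def test_evalue_order_equals_score_order(self, reference, standard_db):
        table = search_proteome(reference, standard_db)
        raws = [h.raw_score for h in table]
        assert raws == sorted(raws, reverse=True)

    def test_empty_query_rejected(self, standard_db):
        with pytest.raises(InvalidInputError):
            search_proteome("", standard_db)


class TestNeedleStats:
    def test_prefix_exclusion_truncates_reference(self, reference):
        """Consensus validation convention: drop the unresolved N-terminus,
        then align globally with free end gaps."""
        consensus_like = reference[170:]
        aln = needle_stats(reference, consensus_like, exclude_reference_prefix=170)
        assert aln.identity == 100.0
        full = needle_stats(reference, consensus_like, exclude_reference_prefix=0)
        assert full.identity < 100.0
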