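import math

import numpy as np
import pytest
from Bio import Align
from scipy.optimize import brentq

from asmob.errors import ConfigError, DataError
from asmob.homology import (
    ReferenceSet,
    aligned_columns,
    screen_proteins,
    smith_waterman,
)
from asmob.records import ProteinRecord
from asmob.scoring import (
    ALPHABET,
    ScoringScheme,
    blosum62_matrix,
    calibrate_lambda,
    robinson_background,
)
from asmob.synthetic import diverge, random_protein

from .oracles import sw_score_oracle


class TestSmithWaterman:
    def test_self_alignment_is_diagonal_sum(self, scheme):
        seq = "HEAGAWGHEE"
        bl = Align.substitution_matrices.load("BLOSUM62")
        score, qspan, sspan = smith_waterman(seq, seq, scheme)
        assert score == sum(int(bl[c][c]) for c in seq)
        assert qspan == sspan == (1, len(seq))

    def test_all_negative_pairs_floor_at_zero(self, scheme):
        score, qspan, sspan = smith_waterman("WWWW", "PPPP", scheme)
        assert (score, qspan, sspan) == (0, None, None)

    def test_empty_sequence_rejected(self, scheme):
        with pytest.raises(DataError):
            smith_waterman("", "MKV", scheme)

    def test_known_pair_matches_oracle(self, scheme):
        score, _, _ = smith_waterman("PAWHEAE", "HEAGAWGHEE", scheme)
        assert score == sw_score_oracle("PAWHEAE", "HEAGAWGHEE", scheme)

    def test_random_pairs_match_oracle_and_symmetry(self, scheme):
        rng = np.random.default_rng(11)
        for _ in range(40):
            a = random_protein(rng, int(rng.integers(5, 50)))
            b = random_protein(rng, int(rng.integers(5, 50)))
            score, _, _ = smith_waterman(a, b, scheme)
            assert score == sw_score_oracle(a, b, scheme)
            assert score == smith_waterman(b, a, scheme)[0]

    def test_biopython_agrees_on_scores(self, scheme):
        """Cross-check against an independent aligner implementation."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = random_protein(rng, 60)
            b = diverge(rng, a, 70.0)
            assert smith_waterman(a, b, scheme)[0] == int(aligner.score(a, b))

    def test_traceback_rescores_to_raw_score(self, scheme):
        rng = np.random.default_rng(23)
        idx = {c: i for i, c in enumerate(ALPHABET)}
        for _ in range(25):
            a = random_protein(rng, 40)
            b = diverge(rng, a, 60.0)
            score, _, _ = smith_waterman(a, b, scheme)
            cols = aligned_columns(a, b, scheme)
            total, in_gap_q, in_gap_s = 0, False, False
            for qp, sp in cols:
                if qp and sp:
                    total += int(scheme.matrix[idx[a[qp - 1]], idx[b[sp - 1]]])
                    in_gap_q = in_gap_s = False
                elif qp:
                    total -= scheme.gap_extend + (0 if in_gap_q else scheme.gap_open)
                    in_gap_q, in_gap_s = True, False
                else:
                    total -= scheme.gap_extend + (0 if in_gap_s else scheme.gap_open)
                    in_gap_s, in_gap_q = True, False
            assert total == score


class TestKarlinAltschul:
    def test_evalue_decreases_with_score(self, scheme):
        evs = [scheme.evalue(s, 300, 2000) for s in range(50, 500, 50)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_match_mismatch_lambda_closed_form(self):
        matrix = np.full((4, 4), -1.0)
        np.fill_diagonal(matrix, 1.0)
        lam = calibrate_lambda(matrix, np.full(4, 0.25))
        assert lam == pytest.approx(math.log(3), abs=1e-6)

    def test_matrix_scaling_halves_lambda(self):
        matrix = np.full((4, 4), -1.0)
        np.fill_diagonal(matrix, 1.0)
        lam1 = calibrate_lambda(matrix, np.full(4, 0.25))
        lam2 = calibrate_lambda(2.0 * matrix, np.full(4, 0.25))
        assert lam2 == pytest.approx(lam1 / 2, abs=1e-6)

    def test_blosum62_lambda_matches_independent_solver(self):
        """Bisection result vs an independent Brent root-finder."""
        matrix = blosum62_matrix()[:20, :20].astype(float)
        p = robinson_background()
        p = p / p.sum()
        lam = calibrate_lambda(matrix, p)
        pp = np.outer(p, p)

        def f(x):
            return float((pp * np.exp(x * matrix)).sum()) - 1.0

        lam_ref = brentq(f, 1e-6, 1.0, xtol=1e-12)
        assert lam == pytest.approx(lam_ref, abs=1e-3)

    def test_nonnegative_expected_score_rejected(self):
        matrix = np.ones((4, 4))
        with pytest.raises(ConfigError, match="no valid lambda"):
            calibrate_lambda(matrix, np.full(4, 0.25))


@pytest.fixture(scope="module")
def family(scheme):
    rng = np.random.default_rng(42)
    seed = random_protein(rng, 300)
    members = tuple(
        ProteinRecord(id=f"ref{i}", sequence=diverge(rng, seed, 88.0))
        for i in range(4)
    )
    refs = [ReferenceSet(family="arsB", role="target", members=members)]
    return rng, seed, refs


class TestScreen:
    def test_planted_member_recovered(self, scheme, family):
        rng, seed, refs = family
        planted = ProteinRecord(id="q1", sequence=diverge(rng, seed, 90.0))
        hits = screen_proteins([planted], refs, scheme)
        assert [h.query_id for h in hits] == ["q1"]
        assert hits[0].evalue <= 1e-40

    def test_shuffled_compositions_do_not_pass(self, scheme, family):
        rng, seed, refs = family
        decoys = []
        for i in range(20):
            shuffled = "".join(rng.permutation(list(seed)))
            decoys.append(ProteinRecord(id=f"d{i}", sequence=shuffled))
        assert screen_proteins(decoys, refs, scheme) == []

    def test_disabled_gate_reports_best_hit_per_family(self, scheme, family):
        rng, seed, refs = family
        anything = ProteinRecord(id="x", sequence=random_protein(rng, 120))
        hits = screen_proteins([anything], refs, scheme, evalue_max=float("inf"))
        assert len(hits) == 1 and hits[0].family == "arsB"

    def test_one_hit_per_protein_family_pair(self, scheme, family):
        rng, seed, refs = family
        prots = [
            ProteinRecord(id=f"q{i}", sequence=diverge(rng, seed, 92.0))
            for i in range(3)
        ]
        hits = screen_proteins(prots, refs, scheme)
        assert len(hits) == 3
        assert len({(h.query_id, h.family) for h in hits}) == 3

    def test_evalue_invariant_holds(self, scheme, family):
        rng, seed, refs = family
        planted = ProteinRecord(id="q1", sequence=diverge(rng, seed, 90.0))
        (hit,) = screen_proteins([planted], refs, scheme)
        n = refs[0].total_residues
        expected = scheme.k * len(planted) * n * math.exp(-scheme.lam * hit.raw_score)
        assert hit.evalue == pytest.approx(expected, rel=1e-12)
        assert hit.bitscore == pytest.approx(
            (scheme.lam * hit.raw_score - math.log(scheme.k)) / math.log(2), rel=1e-12
        )
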