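import numpy as np
import pytest

import lcsalign.aligner as aligner_mod
from lcsalign.aligner import (
    align_profile_seq,
    align_profiles,
    align_seq_seq,
    column_costs,
    progressive_align,
)
from lcsalign.alphabet import GAP_GE, N_RESIDUES
from lcsalign.gap_model import GapModel, pair_gap_score, pair_score_table
from lcsalign.guide_tree import chained_tree, tree_from_sequences
from lcsalign.profile import profile_from_rows, profile_from_sequence
from lcsalign.scoring import model_score
from lcsalign.seqio import Sequence, SequenceSet
from lcsalign.substitution import load_matrix
from lcsalign.synthetic import generate_family

from .conftest import random_protein
from .oracles import alignment_score, apply_matching, enumerate_matchings, gotoh_terminal


def toy_matrix(tmp_path, match=1.0, mismatch=-1.0):
    """Unit matrix over the full alphabet via the file loader."""
    import itertools

    from lcsalign.alphabet import RESIDUES
    from lcsalign.substitution import SubstitutionMatrix

    scores = np.full((N_RESIDUES, N_RESIDUES), mismatch)
    np.fill_diagonal(scores, match)
    return SubstitutionMatrix("unit", scores)


def test_column_costs_single_sequence(miqs, model):
    s = Sequence.from_string("s", "ACDE")
    p = profile_from_sequence(s, 0)
    table = column_costs(p, miqs, model)
    for j, ch in enumerate("ACDE"):
        for r in range(20):
            assert table[j, r] == pytest.approx(miqs.scores[s.codes[j], r])


def test_column_costs_gap_extension_linearity(miqs, model):
    p = profile_from_rows(["AC", "GC", "WC"])
    table = column_costs(p, miqs, model)
    assert table[0, GAP_GE] == pytest.approx(3 * model.penalty(GAP_GE))


def test_column_costs_match_bruteforce(rng, miqs, model):
    rows = ["AC-E", "A-DE", "GCD-"]
    p = profile_from_rows(rows)
    table = column_costs(p, miqs, model)
    typed = p.typed_matrix()
    for j in range(p.width):
        for s in range(N_RESIDUES):
            expected = sum(
                pair_gap_score(int(c), s, miqs, model) for c in typed[:, j]
            )
            assert table[j, s] == pytest.approx(expected)


def test_seq_pair_equals_gotoh_oracle_spec_example(tmp_path):
    unit = toy_matrix(tmp_path)
    model = GapModel(go=-2.0, ge=-1.0, to=0.0, te=0.0)
    res = align_seq_seq(
        Sequence.from_string("x", "CC"), Sequence.from_string("y", "CAC"), unit, model
    )
    expected = gotoh_terminal(
        "CC", "CAC", lambda a, b: 1.0 if a == b else -1.0, -2.0, -1.0, 0.0, 0.0
    )
    assert res.score == pytest.approx(expected)


def test_seq_pair_equals_gotoh_oracle_random(rng, miqs, model):
    for _ in range(250):
        a = random_protein(rng, int(rng.integers(1, 35)))
        b = random_protein(rng, int(rng.integers(1, 35)))
        res = align_seq_seq(
            Sequence.from_string("a", a), Sequence.from_string("b", b), miqs, model
        )
        expected = gotoh_terminal(
            a, b, miqs.score, model.go, model.ge, model.to, model.te
        )
        assert res.score == pytest.approx(expected), (a, b)


def test_identical_sequences_align_without_gaps(miqs, model):
    s = Sequence.from_string("s", "WCNDAYW")
    res = align_seq_seq(s, s, miqs, model)
    expected = sum(miqs.score(c, c) for c in "WCNDAYW")
    assert res.score == pytest.approx(expected)
    assert res.counts() == (7, 0, 0)


def test_length_one_degenerate(miqs, model):
    a = Sequence.from_string("a", "A")
    b = Sequence.from_string("b", "W")
    res = align_seq_seq(a, b, miqs, model)
    assert res.profile.width in (1, 2)
    assert res.score == pytest.approx(res.dp_score)


def test_specialized_variants_match_general(rng, miqs, model):
    for _ in range(40):
        a = random_protein(rng, int(rng.integers(2, 25)))
        b = random_protein(rng, int(rng.integers(2, 25)))
        sa, sb = Sequence.from_string("a", a), Sequence.from_string("b", b)
        r1 = align_seq_seq(sa, sb, miqs, model)
        r2 = align_profiles(
            profile_from_sequence(sa, 0), profile_from_sequence(sb, 1), miqs, model
        )
        assert r1.score == pytest.approx(r2.score)
        assert np.array_equal(r1.matching, r2.matching)


def test_profile_seq_matches_general(rng, miqs, model):
    for _ in range(20):
        rows = ["ACDEFG", "AC-EFG", "GCDE-G"]
        b = random_protein(rng, int(rng.integers(2, 12)))
        sb = Sequence.from_string("b", b)
        r1 = align_profile_seq(profile_from_rows(rows, [0, 1, 2]), sb, miqs, model, 3)
        r2 = align_profiles(
            profile_from_rows(rows, [0, 1, 2]),
            profile_from_sequence(sb, 3),
            miqs,
            model,
        )
        assert r1.score == pytest.approx(r2.score)
        assert np.array_equal(r1.matching, r2.matching)


def test_dp_score_equals_realized_model_score(rng, miqs, model):
    """The reported score is the model score of the realized merge."""
    pen = {
        "To": model.to,
        "Te": model.te,
        "Go": model.go,
        "Ge": model.ge,
    }
    for _ in range(25):
        wx = int(rng.integers(2, 6))
        rows_x = [random_protein(rng, wx) for _ in range(int(rng.integers(1, 3)))]
        wy = int(rng.integers(2, 6))
        rows_y = [random_protein(rng, wy) for _ in range(int(rng.integers(1, 3)))]
        px = profile_from_rows(rows_x, list(range(len(rows_x))))
        py = profile_from_rows(rows_y, list(range(100, 100 + len(rows_y))))
        res = align_profiles(px, py, miqs, model)
        rows = res.profile.realize_rows()
        expected = alignment_score(rows, miqs.score, pen)
        assert res.score == pytest.approx(expected)


def test_tiny_profiles_dp_at_least_enumeration(rng, miqs, model):
    """On tiny gapless profiles the DP reaches the enumerated optimum."""
    pen = {"To": model.to, "Te": model.te, "Go": model.go, "Ge": model.ge}
    for _ in range(8):
        rows_x = [random_protein(rng, 3) for _ in range(2)]
        rows_y = [random_protein(rng, 4) for _ in range(2)]
        best = -np.inf
        for ops in enumerate_matchings(3, 4):
            merged = apply_matching(rows_x, rows_y, ops)
            best = max(best, alignment_score(merged, miqs.score, pen))
        res = align_profiles(
            profile_from_rows(rows_x, [0, 1]),
            profile_from_rows(rows_y, [2, 3]),
            miqs,
            model,
        )
        assert res.score == pytest.approx(best)


def test_progressive_two_sequences_equals_pairwise(miqs, model):
    seqs = SequenceSet(
        [Sequence.from_string("a", "GARFIELD"), Sequence.from_string("b", "FIELD")]
    )
    tree = chained_tree(2)
    aln = progressive_align(seqs, tree, miqs, model)
    res = align_seq_seq(seqs[0], seqs[1], miqs, model)
    assert aln.rows == res.profile.realize_rows()


def test_no_indel_family_aligns_gapless(miqs, model):
    fam = generate_family(k=5, root_len=50, sub_rate=0.1, indel_rate=0.0, seed=4)
    tree = tree_from_sequences(fam.sequences, "sl")
    aln = progressive_align(fam.sequences, tree, miqs, model.scaled_for(5))
    assert aln.width == 50
    assert all("-" not in row for row in aln.rows)


def test_progressive_order_equivariance(miqs, model):
    fam = generate_family(k=5, root_len=40, sub_rate=0.15, indel_rate=0.05, seed=9)
    seqs = fam.sequences
    tree = tree_from_sequences(seqs, "sl")
    aln = progressive_align(seqs, tree, miqs, model)
    # reverse the input order and relabel the same tree accordingly
    k = seqs.k
    rev = SequenceSet(list(seqs)[::-1])
    perm = {i: k - 1 - i for i in range(k)}
    left = tree.left.copy()
    right = tree.right.copy()
    for n in range(len(left)):
        if left[n] != -1 and left[n] < k:
            left[n] = perm[left[n]]
        if right[n] != -1 and right[n] < k:
            right[n] = perm[right[n]]
    from lcsalign.guide_tree import GuideTree

    tree2 = GuideTree(k, left, right, tree.height.copy())
    aln2 = progressive_align(rev, tree2, miqs, model)
    assert dict(zip(aln.ids, aln.rows)) == dict(zip(aln2.ids, aln2.rows))


def test_progressive_output_invariants(miqs, model):
    fam = generate_family(k=8, root_len=60, sub_rate=0.2, indel_rate=0.05, seed=2)
    tree = tree_from_sequences(fam.sequences, "sl")
    aln = progressive_align(fam.sequences, tree, miqs, model.scaled_for(8))
    for i in range(aln.k):
        assert aln.stripped(i) == str(fam.sequences[i])
    # constructor already rejects all-gap columns; re-check explicitly
    for j in range(aln.width):
        assert any(r[j] != "-" for r in aln.rows)


def test_tree_set_mismatch_rejected(miqs, model):
    seqs = SequenceSet([Sequence.from_string(c, "ACDE") for c in "abc"])
    with pytest.raises(ValueError, match="leaves"):
        progressive_align(seqs, chained_tree(4), miqs, model)
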