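"""Global alignment, site transfer and cross-study overlap accounting."""

import numpy as np
import pandas as pd
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from succmap.synthetic import simulate_ortholog
from succmap.xspecies import (
    MATCHED,
    UNMAPPED_GAP,
    UNMAPPED_NO_ORTHOLOG,
    UNMAPPED_RESIDUE,
    UNMODIFIED_IN_OTHER,
    OverlapSummary,
    fold_change_concordance,
    global_align,
    match_site_sets,
    site_count_correlation,
    transfer_site,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


def biopython_score(a: str, b: str) -> float:
    """Independent optimal-score oracle (Biopython's global aligner)."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return float(aligner.score(a, b))


def exhaustive_score(a: str, b: str, go: float = 10.0, ge: float = 0.5) -> float:
    """Enumerate every global alignment of two tiny sequences."""

    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, BLOSUM62[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            best = max(best, -(ge if state == "X" else go) + rec(i + 1, j, "X"))
        if j < len(b):
            best = max(best, -(ge if state == "Y" else go) + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, "M")


def test_identical_sequences_score_is_diagonal_sum():
    aln = global_align("MKLK", "MKLK")
    expected = sum(BLOSUM62[c, c] for c in "MKLK")
    assert aln.score == pytest.approx(expected)
    assert aln.columns == [(1, 1), (2, 2), (3, 3), (4, 4)]
    assert aln.percent_identity == pytest.approx(100.0)


def test_single_insertion_opens_one_gap_in_a():
    aln = global_align("MKLK", "MKALK")
    gap_cols = [c for c in aln.columns if c[0] is None]
    assert len(gap_cols) == 1
    (gap,) = gap_cols
    assert aln.seq_b[gap[1] - 1] == "A"
    assert aln.score == pytest.approx(biopython_score("MKLK", "MKALK"))


def test_alignment_columns_cover_each_residue_once():
    rng = np.random.default_rng(5)
    for _ in range(10):
        a = "".join(rng.choice(list(AA), rng.integers(3, 25)))
        b = "".join(rng.choice(list(AA), rng.integers(3, 25)))
        aln = global_align(a, b)
        a_idx = [i for i, _ in aln.columns if i is not None]
        b_idx = [j for _, j in aln.columns if j is not None]
        assert a_idx == list(range(1, len(a) + 1))
        assert b_idx == list(range(1, len(b) + 1))


def test_score_matches_exhaustive_enumeration_on_tiny_pairs():
    rng = np.random.default_rng(9)
    for _ in range(12):
        a = "".join(rng.choice(list(AA), rng.integers(1, 6)))
        b = "".join(rng.choice(list(AA), rng.integers(1, 6)))
        assert global_align(a, b).score == pytest.approx(exhaustive_score(a, b))


def test_score_matches_biopython_on_random_pairs():
    rng = np.random.default_rng(17)
    for _ in range(15):
        a = "".join(rng.choice(list(AA), rng.integers(5, 41)))
        b = "".join(rng.choice(list(AA), rng.integers(5, 41)))
        assert global_align(a, b).score == pytest.approx(biopython_score(a, b))


def test_empty_sequence_is_hard_error():
    with pytest.raises(ValueError):
        global_align("", "MK")


def test_unknown_residue_scored_as_x():
    assert global_align("MJLK", "MKLK").score == pytest.approx(
        global_align("MXLK", "MKLK").score
    )


def test_transfer_identity_on_identical_sequences():
    aln = global_align("MKLKWK", "MKLKWK")
    for pos in range(1, 7):
        res = transfer_site(aln, pos, require_lysine=False)
        assert res.pos_b == pos


def test_transfer_statuses():
    # B has an insertion; A position 2 is K aligned to K
    aln = global_align("MKLKWWK", "MKALKWWK")
    assert transfer_site(aln, 2).pos_b == 2
    # K aligned to a non-lysine residue
    aln2 = global_align("MKLK", "MRLK")
    assert transfer_site(aln2, 2).status == UNMAPPED_RESIDUE
    assert transfer_site(aln2, 2, require_lysine=False).pos_b == 2
    # residue aligned opposite a gap
    aln3 = global_align("MKALK", "MKLK")
    gap_pos = next(i for i, j in aln3.columns if j is None)
    assert transfer_site(aln3, gap_pos, require_lysine=False).status == UNMAPPED_GAP
    with pytest.raises(ValueError):
        transfer_site(aln, 99)


def test_round_trip_transfer_is_identity_on_mapped_positions():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list(AA), 120))
    mut, _ = simulate_ortholog(seq, 0.08, 0.02, seed=13)
    fwd = global_align(seq, mut)
    rev = global_align(mut, seq)
    for pos in range(1, len(seq) + 1):
        image = fwd.a_to_b(pos)
        if image is not None:
            assert rev.a_to_b(image) == pos


def test_transfer_recovers_generator_truth_map():
    rng = np.random.default_rng(21)
    seq = "".join(rng.choice(list(AA), 300))
    k_pos = {int(p) + 1 for p in rng.choice(300, 10, replace=False)}
    seq = "".join("K" if i + 1 in k_pos else c for i, c in enumerate(seq))
    mut, amap = simulate_ortholog(seq, 0.05, 0.01, preserved_positions=k_pos, seed=7)
    aln = global_align(seq, mut)
    hits = sum(transfer_site(aln, p).pos_b == amap[p] for p in k_pos)
    assert hits / len(k_pos) >= 0.95


def _ab_fixture():
    seqs_a = {"P1": "MKLKWWK", "P2": "AAKWDE"}
    seqs_b = {"Q1": "MKALKWWK", "Q2": "AAKWDE"}
    sites_a = pd.DataFrame(
        {
            "protein_id": ["P1", "P1", "P2"],
            "position": [2, 7, 3],
            "log2fc": [2.0, 1.0, 3.0],
        }
    )
    sites_b = pd.DataFrame(
        {"protein_id": ["Q1", "Q2"], "position": [2, 3], "log2fc": [0.5, 1.5]}
    )
    omap = pd.DataFrame({"a": ["P1", "P2"], "b": ["Q1", "Q2"]})
    return sites_a, sites_b, seqs_a, seqs_b, omap


def test_match_site_sets_with_known_correspondence():
    sites_a, sites_b, seqs_a, seqs_b, omap = _ab_fixture()
    matches, summary = match_site_sets(sites_a, sites_b, seqs_a, seqs_b, omap)
    status = matches.set_index(["protein_a", "pos_a"])["status"]
    assert status[("P1", 2)] == MATCHED
    assert status[("P2", 3)] == MATCHED
    assert status[("P1", 7)] == UNMODIFIED_IN_OTHER
    assert summary.n_proteins_common == 2
    assert summary.n_sites_matched == 2
    # fold changes carried through for matched rows
    row = matches[(matches["protein_a"] == "P1") & (matches["pos_a"] == 2)].iloc[0]
    assert row["log2fc_b"] == pytest.approx(0.5)


def test_match_statuses_partition_all_a_sites():
    sites_a, sites_b, seqs_a, seqs_b, omap = _ab_fixture()
    matches, summary = match_site_sets(sites_a, sites_b, seqs_a, seqs_b, omap)
    assert len(matches) == len(sites_a)
    assert (matches["status"] == MATCHED).sum() == summary.n_sites_matched


def test_empty_b_study_gives_zero_overlap():
    sites_a, _, seqs_a, seqs_b, omap = _ab_fixture()
    empty_b = pd.DataFrame({"protein_id": [], "position": []})
    matches, summary = match_site_sets(sites_a, empty_b, seqs_a, seqs_b, omap)
    assert summary.n_proteins_common == 0
    assert summary.n_sites_matched == 0
    assert set(matches["status"]) == {UNMAPPED_NO_ORTHOLOG}


def test_same_study_matches_itself_completely():
    sites_a, _, seqs_a, _, _ = _ab_fixture()
    matches, summary = match_site_sets(sites_a, sites_a, seqs_a, seqs_a)
    assert (matches["status"] == MATCHED).all()
    assert summary.fraction_of_a == 1.0 and summary.fraction_of_b == 1.0


def test_overlap_counts_symmetric_under_study_swap():
    sites_a, sites_b, seqs_a, seqs_b, omap = _ab_fixture()
    _, fwd = match_site_sets(sites_a, sites_b, seqs_a, seqs_b, omap)
    rev_map = pd.DataFrame({"a": omap["b"], "b": omap["a"]})
    _, rev = match_site_sets(sites_b, sites_a, seqs_b, seqs_a, rev_map)
    assert fwd.n_proteins_common == rev.n_proteins_common
    assert fwd.n_sites_matched == rev.n_sites_matched
    assert (fwd.n_proteins_a, fwd.n_proteins_b) == (rev.n_proteins_b, rev.n_proteins_a)


def test_many_to_many_orthology_resolved_by_score():
    seqs_a = {"P1": "MKLKWWKDE"}
    seqs_b = {"Q1": "MKLKWWKDE", "Q2": "CCCCC"}
    sites_a = pd.DataFrame({"protein_id": ["P1"], "position": [2]})
    sites_b = pd.DataFrame({"protein_id": ["Q1", "Q2"], "position": [2, 1]})
    omap = pd.DataFrame({"a": ["P1", "P1"], "b": ["Q1", "Q2"]})
    matches, _ = match_site_sets(sites_a, sites_b, seqs_a, seqs_b, omap)
    assert matches.iloc[0]["protein_b"] == "Q1"
    assert matches.iloc[0]["status"] == MATCHED


def _summary_from_counts(xa, xb):
    df = pd.DataFrame(
        {
            "protein_a": [f"P{i}" for i in range(len(xa))],
            "protein_b": [f"Q{i}" for i in range(len(xa))],
            "n_sites_a": xa,
            "n_sites_b": xb,
            "n_matched": [0] * len(xa),
        }
    )
    return OverlapSummary(len(xa), len(xa), len(xa), sum(xa), sum(xb), 0, 1, 1, df)


def test_site_count_correlation_examples():
    r, r2 = site_count_correlation(_summary_from_counts([1, 2, 3], [1, 2, 3]))
    assert r2 == pytest.approx(1.0)
    r, r2 = site_count_correlation(_summary_from_counts([1, 2, 3], [3, 2, 1]))
    assert r == pytest.approx(-1.0) and r2 == pytest.approx(1.0)
    x, y = np.array([1, 2, 4.0]), np.array([1, 3, 4.0])
    hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    r, _ = site_count_correlation(_summary_from_counts([1, 2, 4], [1, 3, 4]))
    assert r == pytest.approx(hand)


def test_site_count_correlation_errors():
    with pytest.raises(ValueError, match=">= 3"):
        site_count_correlation(_summary_from_counts([1, 2], [1, 2]))
    with pytest.raises(ValueError, match="zero variance"):
        site_count_correlation(_summary_from_counts([2, 2, 2], [1, 2, 3]))


def test_fold_change_concordance_medians():
    matches = pd.DataFrame(
        {
            "protein_a": ["P1"] * 3 + ["P2"],
            "pos_a": [1, 2, 3, 9],
            "log2fc_a": [1.0, 2.0, 3.0, 5.0],
            "protein_b": ["Q1"] * 3 + ["Q2"],
            "pos_b": [1, 2, 3, 9],
            "log2fc_b": [0.0, 1.0, 2.0, np.nan],
            "status": [MATCHED, MATCHED, MATCHED, UNMAPPED_GAP],
        }
    )
    medians, paired = fold_change_concordance(matches)
    assert len(medians) == 1  # P2 has no matched site
    row = medians.iloc[0]
    assert row["median_log2fc_a"] == pytest.approx(2.0)
    assert row["median_log2fc_b"] == pytest.approx(1.0)
    assert paired["fc_diff"].tolist() == pytest.approx([1.0, 1.0, 1.0])
    # invariant to row order
    shuffled, _ = fold_change_concordance(matches.iloc[::-1])
    pd.testing.assert_frame_equal(medians, shuffled)
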