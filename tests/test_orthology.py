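"""End-gap-free alignment, RBH orthology and the persistent genome."""

import numpy as np
import pytest

from cooccurevo.orthology import (
    AlignmentBlock,
    OrthologyParams,
    PairwiseAlignment,
    align_semiglobal,
    build_families,
    build_persistent_genome,
    concatenate,
    persistent_filter,
    pivot_anchored_msa,
    quorum_threshold,
    reciprocal_best_hits,
    relative_length_difference,
    similarity,
    trim_columns,
    OrthologFamily,
)
from cooccurevo.synthetic import simulate_proteomes

from oracles import brute_force_semiglobal_score


class TestAlignSemiglobal:
    def test_identity(self, ortho_params):
        a = align_semiglobal("MKV", "MKV", ortho_params)
        assert a.similarity == 1.0
        assert "-" not in a.aligned_a + a.aligned_b

    def test_end_gaps_free(self, ortho_params):
        inner = align_semiglobal("MKV", "AAMKVAA", ortho_params)
        exact = align_semiglobal("MKV", "MKV", ortho_params)
        assert inner.score == exact.score
        assert inner.aligned_a == "--MKV--"

    def test_invalid_residue_rejected(self, ortho_params):
        with pytest.raises(ValueError, match="invalid residue"):
            align_semiglobal("MK1", "MKV", ortho_params)
        with pytest.raises(ValueError, match="empty"):
            align_semiglobal("", "MKV", ortho_params)

    def test_score_matches_brute_force_on_short_pairs(self, ortho_params, rng):
        matrix = ortho_params.matrix()
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(40):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(aas, la))
            b = "".join(rng.choice(aas, lb))
            got = align_semiglobal(a, b, ortho_params).score
            want = brute_force_semiglobal_score(
                a, b, matrix, ortho_params.gap_open, ortho_params.gap_extend)
            assert got == pytest.approx(want), (a, b)


class TestSimilarity:
    def test_hand_built_ten_column_alignment(self, ortho_params):
        # 4 positive-scoring columns (identities), 4 negative mismatches
        # (A-W scores -3), 2 internal gap columns -> 4/10
        aln = PairwiseAlignment(
            aligned_a="MKVL--AAAA",
            aligned_b="MKVLCCWWWW",
            score=0.0, similarity=0.0, core_start=0, core_end=10)
        assert similarity(aln, ortho_params) == pytest.approx(0.4)

    def test_zero_length_core_raises(self, ortho_params):
        aln = PairwiseAlignment(
            aligned_a="----MKVL", aligned_b="CHNQ----",
            score=0.0, similarity=0.0, core_start=0, core_end=0)
        with pytest.raises(ValueError, match="undefined similarity"):
            similarity(aln, ortho_params)

    def test_all_negative_pairs(self, ortho_params):
        aln = align_semiglobal("AAAA", "WWWW", ortho_params)
        assert aln.similarity == 0.0

    def test_terminal_gaps_excluded_from_core(self, ortho_params):
        aln = align_semiglobal("MKV", "AAMKVAA", ortho_params)
        assert (aln.core_start, aln.core_end) == (2, 5)
        assert aln.similarity == 1.0


class TestLengthConvention:
    def test_longer_sequence_denominator(self):
        # 100 vs 121: 21/121 = 0.1736 under the longer-sequence
        # convention (kept at the 20% threshold), not 21/100 = 0.21
        assert relative_length_difference("A" * 100, "A" * 121) == \
            pytest.approx(21 / 121)

    def test_rbh_boundary_kept_and_dropped(self, ortho_params):
        core = "MKVLWEAIRDNPQHFYCSTG" * 5  # 100 residues
        kept_partner = core + "MKVLWEAIRDNPQHFYCSTG" + "A"  # 121
        dropped_partner = core + "MKVLWEAIRDNPQHFYCSTG" + "AAAAA"  # 125: 25/125 = 0.2
        res = reciprocal_best_hits({"p": core}, {"o": kept_partner}, ortho_params)
        assert res.pairs == [("p", "o")]
        # exactly at the threshold (0.2 <= 0.2): still kept ("more than 20%" drops)
        res2 = reciprocal_best_hits({"p": core}, {"o": dropped_partner}, ortho_params)
        assert res2.pairs == [("p", "o")]
        dropped2 = core + "MKVLWEAIRDNPQHFYCSTG" + "AAAAAA"  # 126: 26/126 > 0.2
        res3 = reciprocal_best_hits({"p": core}, {"o": dropped2}, ortho_params)
        assert res3.pairs == []
        assert res3.filtered[0][2] == "length-difference"


class TestSimilarityFilter:
    def _pair(self, m):
        # m identical anchor columns followed by divergent tails; the
        # optimal end-gap-free alignment keeps the anchor in register and
        # the core carries exactly m positive columns out of 100
        anchor = ("MKVLWEAIRDNPQHFYCSTG" * 5)[:m]
        a = anchor + "A" * (100 - m)
        b = anchor + "W" * (100 - m)
        return a, b

    def test_just_below_threshold_similarity(self, ortho_params):
        a, b = self._pair(36)
        aln = align_semiglobal(a, b, ortho_params)
        assert aln.similarity == pytest.approx(0.36)

    def test_filter_applies_at_0_37(self):
        params = OrthologyParams()
        a_keep, b_keep = self._pair(37)   # sim 0.37: kept ("<37%" discards)
        a_drop, b_drop = self._pair(36)   # sim 0.36: discarded
        kept = reciprocal_best_hits({"p": a_keep}, {"o": b_keep}, params)
        dropped = reciprocal_best_hits({"p": a_drop}, {"o": b_drop}, params)
        assert kept.pairs == [("p", "o")]
        assert dropped.pairs == []
        assert dropped.filtered[0][2] == "low-similarity"


class TestRBH:
    def test_zero_mutation_full_recovery(self, ortho_params):
        prot, truth = simulate_proteomes([f"g{i}" for i in range(4)],
                                         6, 0.0, 0.0, 11)
        fams = build_families("g0", prot, ortho_params)
        got = {frozenset(f.members.values()) for f in fams}
        want = {frozenset(m.values()) for m in truth.members.values()}
        assert got == want

    def test_symmetry(self, ortho_params):
        prot, _ = simulate_proteomes(["g0", "g1"], 5, 0.03, 0.0, 13)
        fwd = reciprocal_best_hits(prot["g0"], prot["g1"], ortho_params)
        rev = reciprocal_best_hits(prot["g1"], prot["g0"], ortho_params)
        assert {(b, a) for a, b in fwd.pairs} == set(rev.pairs)

    def test_tie_is_skipped(self, ortho_params):
        # two identical pivot proteins tie as best hit for one target
        prot_p = {"p1": "MKVLWEAIRDNPQHFYCSTG", "p2": "MKVLWEAIRDNPQHFYCSTG"}
        prot_o = {"o1": "MKVLWEAIRDNPQHFYCSTG"}
        res = reciprocal_best_hits(prot_p, prot_o, ortho_params)
        assert res.pairs == []
        reasons = {r for _, _, r in res.filtered}
        assert "ambiguous-best-hit-tie" in reasons

    def test_empty_proteome_rejected(self, ortho_params):
        with pytest.raises(ValueError, match="nonempty"):
            reciprocal_best_hits({}, {"o": "MKV"}, ortho_params)

    def test_dropped_family_missing_from_members(self, ortho_params):
        prot, truth = simulate_proteomes([f"g{i}" for i in range(4)],
                                         8, 0.0, 0.3, 17)
        pivot = "g0"
        fams = build_families(pivot, prot, ortho_params)
        by_pivot_pid = {f.pivot_protein_id: f for f in fams}
        for fam_id, members in truth.members.items():
            if pivot not in members:
                continue
            fam = by_pivot_pid.get(members[pivot])
            if fam is None:
                continue
            assert set(fam.members) == set(members)

    def test_mutated_recovery_over_replicates(self, ortho_params):
        for seed in range(3):
            prot, truth = simulate_proteomes([f"g{i}" for i in range(4)],
                                             5, 0.05, 0.0, 100 + seed)
            fams = build_families("g0", prot, ortho_params)
            got = {frozenset(f.members.values()) for f in fams}
            want = {frozenset(m.values()) for m in truth.members.values()}
            assert got == want


class TestQuorum:
    @pytest.mark.parametrize("n_members,n_genomes,kept", [
        (9, 10, True), (8, 10, False),
    ])
    def test_boundaries(self, n_members, n_genomes, kept):
        fam = OrthologFamily("F1", "p", {f"g{i}": f"p{i}" for i in range(n_members)})
        out = persistent_filter([fam], n_genomes, 0.90)
        assert (len(out) == 1) is kept

    def test_threshold_245(self):
        assert quorum_threshold(245, 0.90) == 221


class TestMSA:
    def test_identical_members_no_gaps(self, ortho_params):
        prot, truth = simulate_proteomes(["g0", "g1", "g2"], 2, 0.0, 0.0, 19)
        fams = build_families("g0", prot, ortho_params)
        block = pivot_anchored_msa(fams[0], prot, ortho_params)
        assert all("-" not in row for row in block.rows.values())

    def test_single_insertion_creates_one_gap_column(self, ortho_params):
        prot, _ = simulate_proteomes(["g0", "g1", "g2"], 1, 0.0, 0.0, 23)
        fams = build_families("g0", prot, ortho_params)
        fam = fams[0]
        seqs = {g: dict(p) for g, p in prot.items()}
        pid = fam.members["g1"]
        s = seqs["g1"][pid]
        seqs["g1"][pid] = s[:10] + "W" + s[10:]
        block = pivot_anchored_msa(fam, seqs, ortho_params)
        other = np.array([list(block.rows[g]) for g in ("g0", "g2")])
        allgap = (other == "-").all(axis=0)
        assert allgap.sum() == 1
        for g, p in fam.members.items():
            assert block.rows[g].replace("-", "") == seqs[g][p]

    def test_missing_member_sequence_raises(self, ortho_params):
        fam = OrthologFamily("F1", "p0", {"g0": "p0", "g1": "p1"})
        with pytest.raises(ValueError, match="missing"):
            pivot_anchored_msa(fam, {"g0": {"p0": "MKV"}, "g1": {}}, ortho_params)


class TestTrimAndConcat:
    def test_gap_free_block_unchanged(self):
        b = AlignmentBlock({"g0": "MKV", "g1": "MKL"})
        assert trim_columns(b, 0.5).rows == b.rows

    def test_majority_gap_column_removed(self):
        b = AlignmentBlock({"g0": "M-V", "g1": "M-L", "g2": "MKV", "g3": "M-V"})
        out = trim_columns(b, 0.5)
        assert out.rows == {"g0": "MV", "g1": "ML", "g2": "MV", "g3": "MV"}

    def test_all_columns_removed_warns(self):
        b = AlignmentBlock({"g0": "--", "g1": "AA"})
        with pytest.warns(UserWarning, match="empty"):
            out = trim_columns(b, 0.4)
        assert out.width == 0

    def test_concatenate_lengths_and_gap_fill(self):
        b1 = AlignmentBlock({"g0": "A" * 10, "g1": "C" * 10})
        b2 = AlignmentBlock({"g0": "D" * 7})
        pg = concatenate([("F1", b1), ("F2", b2)], ["g0", "g1"])
        assert all(len(s) == 17 for s in pg.concat.values())
        assert pg.concat["g1"][10:] == "-" * 7
        assert pg.block_spans == {"F1": (0, 10), "F2": (10, 17)}

    def test_spans_partition_total_length(self, ortho_params):
        prot, _ = simulate_proteomes([f"g{i}" for i in range(4)], 5,
                                     0.03, 0.1, 29)
        pg = build_persistent_genome(prot, "g0", ortho_params)
        spans = sorted(pg.block_spans.values())
        assert spans[0][0] == 0
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 == s2
        assert spans[-1][1] == pg.length
        assert all(len(s) == pg.length for s in pg.concat.values())
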