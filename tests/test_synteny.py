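import pytest

from synbreak.synteny import (
    BreakpointRegion,
    SyntenyBlock,
    block_metrics,
    capture_stats,
    delineate_blocks,
    locate_breakpoint_regions,
    roman,
    to_signed_permutation,
)

from conftest import make_genes


class TestRoman:
    @pytest.mark.parametrize("n,s", [(1, "I"), (4, "IV"), (9, "IX"), (14, "XIV")])
    def test_values(self, n, s):
        assert roman(n) == s

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            roman(0)


class TestDelineate:
    def test_identity_is_one_block(self):
        ref = ["a", "b", "c"]
        blocks, singles = delineate_blocks(ref, ref)
        assert len(blocks) == 1 and not singles
        assert blocks[0].member_genes == ("a", "b", "c")
        assert blocks[0].sign == 1

    def test_mixed_blocks_and_singleton(self):
        ref = ["a", "b", "c", "d", "e", "f"]
        tgt = ["a", "b", "e", "d", "c", "f"]
        blocks, singles = delineate_blocks(ref, tgt)
        assert [b.member_genes for b in blocks] == [("a", "b"), ("c", "d", "e")]
        assert [b.sign for b in blocks] == [1, -1]
        assert singles == ["f"]
        assert to_signed_permutation(blocks) == (1, -2)

    def test_membership_is_orientation_insensitive(self):
        # a fully reversed chromosome is one block of sign -1
        ref = ["a", "b", "c", "d"]
        blocks, singles = delineate_blocks(ref, ref[::-1])
        assert len(blocks) == 1 and blocks[0].sign == -1 and not singles

    def test_single_gene_transposition_is_singleton(self):
        # gene c jumped; it must not seed a block
        ref = ["a", "b", "c", "d", "e"]
        tgt = ["a", "b", "d", "e", "c"]
        blocks, singles = delineate_blocks(ref, tgt)
        assert singles == ["c"]
        assert [b.member_genes for b in blocks] == [("a", "b"), ("d", "e")]

    def test_direction_locked_within_run(self):
        # tpos pattern 0,1,0-like zigzags must split
        ref = ["a", "b", "c"]
        tgt = ["b", "a", "c"]  # tpos: a1 b0 c2 -> steps -1 then +2
        blocks, singles = delineate_blocks(ref, tgt)
        assert [b.member_genes for b in blocks] == [("a", "b")]
        assert blocks[0].sign == -1
        assert singles == ["c"]

    def test_duplicate_ref_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            delineate_blocks(["a", "a"], ["a", "a"])

    def test_gene_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            delineate_blocks(["a", "b"], ["a", "c"])


class TestSignedPermutation:
    def test_paper_arrangement(self, paper_sim):
        from synbreak.simulate import derive_target_species

        order, _ = derive_target_species(
            paper_sim.genes, paper_sim.truth, paper_sim.config
        )
        blocks, _ = delineate_blocks([g.gene_id for g in paper_sim.genes], order)
        assert to_signed_permutation(blocks) == (1, -4, 3, -2, 5)

    def test_duplicate_rank_rejected(self):
        b1 = SyntenyBlock(1, ("a", "b"), 1, 1)
        b2 = SyntenyBlock(2, ("c", "d"), 1, 1)
        with pytest.raises(ValueError, match="duplicate target rank"):
            to_signed_permutation([b1, b2])


class TestBreakpointRegions:
    def test_interval_between_flank_genes(self):
        genes = make_genes([(0, 100), (200, 300), (1000, 1100), (1200, 1300)])
        blocks = [
            SyntenyBlock(1, ("g1", "g2"), 2, 1),
            SyntenyBlock(2, ("g3", "g4"), 1, -1),
        ]
        (br,) = locate_breakpoint_regions(blocks, genes)
        assert (br.br_id, br.start, br.end) == ("I", 300, 1000)
        assert (br.left_flank_gene, br.right_flank_gene) == ("g2", "g3")
        assert br.length == 700

    def test_roman_numbering_left_to_right(self, paper_sim):
        from synbreak.simulate import derive_target_species

        order, _ = derive_target_species(
            paper_sim.genes, paper_sim.truth, paper_sim.config
        )
        blocks, _ = delineate_blocks([g.gene_id for g in paper_sim.genes], order)
        brs = locate_breakpoint_regions(blocks, paper_sim.genes)
        assert [r.br_id for r in brs] == ["I", "II", "III", "IV"]
        assert all(a.end <= b.start for a, b in zip(brs, brs[1:]))

    def test_degenerate_region_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            BreakpointRegion("I", "a", "b", 100, 100)

    def test_abutting_flanks_rejected(self):
        genes = make_genes([(0, 100), (200, 300), (300, 400), (500, 600)])
        blocks = [
            SyntenyBlock(1, ("g1", "g2"), 1, 1),
            SyntenyBlock(2, ("g3", "g4"), 2, 1),
        ]
        with pytest.raises(ValueError):
            locate_breakpoint_regions(blocks, genes)


class TestBlockMetrics:
    def test_total_row_sums(self):
        genes = make_genes([(0, 1000), (9000, 10_000), (20_000, 21_000), (29_000, 30_000)])
        blocks = [
            SyntenyBlock(1, ("g1", "g2"), 1, 1),
            SyntenyBlock(2, ("g3", "g4"), 2, 1),
        ]
        df = block_metrics(blocks, genes)
        total = df[df["block"] == "Total"].iloc[0]
        assert total["length_bp"] == 20_000
        assert total["n_genes"] == 4
        assert total["density_per_100kb"] == pytest.approx(4 / 0.2)

    def test_density_rounding_half_even(self):
        # 2 genes over 1,600,000 bp -> 0.125 per 100 kb -> 0.12 half-even
        genes = make_genes([(0, 100), (1_599_900, 1_600_000)])
        blocks = [SyntenyBlock(1, ("g1", "g2"), 1, 1)]
        df = block_metrics(blocks, genes)
        assert df.iloc[0]["density_2dp"] == 0.12


class TestCaptureStats:
    def test_fractions(self):
        genes = make_genes([(0, 100), (900, 1000), (2000, 2100), (2900, 3000)])
        blocks = [
            SyntenyBlock(1, ("g1", "g2"), 1, 1),
            SyntenyBlock(2, ("g3", "g4"), 2, 1),
        ]
        stats = capture_stats([1], blocks, genes)
        assert stats["n_genes"] == 2
        assert stats["total_bp"] == 1000
        assert stats["gene_fraction"] == 0.5
        assert stats["bp_fraction"] == 0.5

    def test_unknown_index_rejected(self):
        genes = make_genes([(0, 100), (900, 1000)])
        blocks = [SyntenyBlock(1, ("g1", "g2"), 1, 1)]
        with pytest.raises(ValueError, match="unknown block"):
            capture_stats([3], blocks, genes)


class TestBlockValidation:
    def test_blocks_need_two_genes(self):
        with pytest.raises(ValueError):
            SyntenyBlock(1, ("a",), 1, 1)

    def test_sign_validated(self):
        with pytest.raises(ValueError):
            SyntenyBlock(1, ("a", "b"), 1, 0)
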