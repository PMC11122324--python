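import pytest
from scipy import stats as st

from synbreak.annotations import RepeatElement
from synbreak.brstats import (
    count_in_region,
    gene_density_anova,
    neighborhood_profile,
    poisson_br_test,
)
from synbreak.synteny import BreakpointRegion, SyntenyBlock

from conftest import make_genes


def rep(start, end, label="Simple_repeat", group="simple_repeat"):
    return RepeatElement("X", start, end, label, group)


class TestCountInRegion:
    def test_counted_by_start_only(self):
        # element straddling the boundary belongs to the bin of its start
        els = [rep(90, 110), rep(100, 120), rep(99, 200)]
        assert count_in_region(els, (100, 200)) == 1
        assert count_in_region(els, (0, 100)) == 2

    def test_group_filter(self):
        els = [rep(0, 10), rep(20, 30, "LTR/Gypsy", "retrotransposon")]
        assert count_in_region(els, (0, 100), group="retrotransposon") == 1


class TestPoissonBrTest:
    def test_hand_checked_lambda_and_p(self):
        # chromosome 1000 bp, region width 100 -> 10 whole bins;
        # 20 elements across the span -> lambda 2; 5 in the region
        els = [rep(i * 50, i * 50 + 10) for i in range(20)]
        region = (100, 200)
        res = poisson_br_test(region, els, chrom_length=1000)
        assert res.lam == pytest.approx(2.0)
        assert res.observed == count_in_region(els, region)
        assert res.p_value == pytest.approx(
            float(st.poisson.sf(res.observed - 1, 2.0))
        )

    def test_zero_observed_gives_p_one(self):
        els = [rep(500, 510)]
        res = poisson_br_test((0, 100), els, chrom_length=1000)
        assert res.observed == 0 and res.p_value == 1.0

    def test_trailing_partial_bin_excluded(self):
        # chrom 1050 with width 100: lambda uses only [0, 1000)
        els = [rep(1010, 1020)] * 5 + [rep(10, 20)]
        res = poisson_br_test((0, 100), els, chrom_length=1050)
        assert res.lam == pytest.approx(1 / 10)

    def test_breakpoint_region_input(self):
        br = BreakpointRegion("II", "a", "b", 100, 200)
        res = poisson_br_test(br, [rep(110, 120)], chrom_length=1000)
        assert res.region_id == "II"

    def test_coding_mask_drops_elements_and_bp(self):
        # mask covers [0,500); only non-coding elements and bp count
        els = [rep(100, 110), rep(600, 610), rep(700, 710)]
        res = poisson_br_test(
            (600, 700), els, chrom_length=1000, coding_mask=[(0, 500)]
        )
        assert res.masked_coding
        assert res.observed == 1  # only the 600-start element
        # 2 usable elements over 500 non-coding bp, region fully non-coding
        assert res.lam == pytest.approx(2 / 500 * 100)

    def test_region_wider_than_chromosome_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            poisson_br_test((0, 2000), [], chrom_length=1000)

    def test_degenerate_region_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            poisson_br_test((100, 100), [], chrom_length=1000)

    def test_full_mask_rejected(self):
        with pytest.raises(ValueError, match="whole binned span"):
            poisson_br_test(
                (0, 100), [], chrom_length=1000, coding_mask=[(0, 1000)]
            )


class TestNeighborhoodProfile:
    BR = BreakpointRegion("I", "a", "b", 50_000, 60_000)

    def test_bar_layout(self):
        prof = neighborhood_profile(self.BR, [], chrom_length=200_000)
        # 50 kb flanks in 10 kb bars: 5 left + BR + 5 right
        assert len(prof.bars) == 11
        assert prof.br_bar_index == 5
        assert prof.bars[5][:2] == (50_000, 60_000)
        assert all(e - s == 10_000 for s, e, _ in prof.bars)

    def test_truncation_at_chromosome_start(self):
        br = BreakpointRegion("I", "a", "b", 5_000, 15_000)
        prof = neighborhood_profile(br, [], chrom_length=200_000)
        left = prof.bars[: prof.br_bar_index]
        assert left[0][0] == 0  # clipped, not negative
        assert sum(e - s for s, e, _ in left) == 5_000

    def test_counts_per_bar(self):
        els = [rep(51_000, 51_100), rep(52_000, 52_100), rep(41_000, 41_100)]
        prof = neighborhood_profile(self.BR, els, chrom_length=200_000)
        assert prof.bars[prof.br_bar_index][2] == 2
        assert prof.bars[prof.br_bar_index - 1][2] == 1

    def test_tiny_br_rejected(self):
        br = BreakpointRegion("I", "a", "b", 100, 600)
        with pytest.raises(ValueError, match="1 kb"):
            neighborhood_profile(br, [], chrom_length=10_000)


class TestGeneDensityAnova:
    def test_bin_counts_by_start_coordinate(self):
        # block 1 spans [0, 400000): 4 whole bins; starts at 0, 10k, 399.9k
        genes = make_genes(
            [(0, 100), (10_000, 10_100), (399_900, 400_000),
             (500_000, 500_100), (699_900, 700_000)]
        )
        b1 = SyntenyBlock(1, ("g1", "g2", "g3"), 1, 1)
        b2 = SyntenyBlock(2, ("g4", "g5"), 2, 1)
        _, _, groups = gene_density_anova([b1, b2], genes, bin_size=100_000)
        assert groups[1] == [2, 0, 0, 1]
        assert groups[2] == [1, 1]

    def test_distinct_densities_detected(self):
        dense = make_genes(
            [(i * 10_000, i * 10_000 + 100) for i in range(30)]
            + [(299_900, 300_000)],
            prefix="d",
        )
        sparse = make_genes(
            [(1_000_000 + i * 100_000, 1_000_000 + i * 100_000 + 100) for i in range(3)]
            + [(1_299_900, 1_300_000)],
            prefix="s",
        )
        b1 = SyntenyBlock(1, tuple(g.gene_id for g in dense), 1, 1)
        b2 = SyntenyBlock(2, tuple(g.gene_id for g in sparse), 2, 1)
        f_stat, p, groups = gene_density_anova([b1, b2], dense + sparse)
        assert len(groups[1]) == 3 and len(groups[2]) == 3
        assert p < 0.01

    def test_equal_constant_input_early_return(self):
        spans = []
        for offset in (0, 400_000):
            spans += [
                (offset, offset + 100),
                (offset + 100_000, offset + 100_100),
                (offset + 299_900, offset + 300_000),
            ]
        genes = make_genes(spans)
        b1 = SyntenyBlock(1, ("g1", "g2", "g3"), 1, 1)
        b2 = SyntenyBlock(2, ("g4", "g5", "g6"), 2, 1)
        f_stat, p, groups = gene_density_anova([b1, b2], genes, bin_size=100_000)
        assert all(c == 1 for counts in groups.values() for c in counts)
        assert (f_stat, p) == (0.0, 1.0)

    def test_short_block_rejected(self):
        genes = make_genes(
            [(0, 100), (50_000, 50_100), (500_000, 500_100), (699_900, 700_000)]
        )
        b1 = SyntenyBlock(1, ("g1", "g2"), 1, 1)  # 50 kb span: < 2 bins
        b2 = SyntenyBlock(2, ("g3", "g4"), 2, 1)
        with pytest.raises(ValueError, match="at least 2"):
            gene_density_anova([b1, b2], genes, bin_size=100_000)

    def test_single_block_rejected(self):
        genes = make_genes([(0, 100), (299_900, 300_000)])
        b = SyntenyBlock(1, ("g1", "g2"), 1, 1)
        with pytest.raises(ValueError, match="two blocks"):
            gene_density_anova([b], genes, bin_size=100_000)
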