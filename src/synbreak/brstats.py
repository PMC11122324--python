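"""Repeat and gene density statistics around breakpoint regions.

The central test asks whether a breakpoint region (BR) carries more
repetitive elements than the chromosome-wide expectation.  The chromosome is
tiled into bins of width equal to the BR; the mean per-bin count of the
element group is the Poisson rate λ, the BR's own count is x, and the
reported P(x) is the upper tail P(X ≥ x) under Poisson(λ).  Elements are
assigned to bins and regions by their start coordinate, so no element is
ever counted twice.  Optionally coding intervals are masked out: coding
base pairs are removed from both the bins and the BR, and elements starting
inside coding sequence are dropped, turning λ into a non-coding rate.

A one-way ANOVA over per-100-kb gene counts grouped by synteny block tests
whether gene density differs between blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .annotations import GeneAnnotation, RepeatElement
from .synteny import BreakpointRegion, SyntenyBlock, _block_interval, _gene_index

__all__ = [
    "PoissonTestResult",
    "NeighborhoodProfile",
    "count_in_region",
    "poisson_br_test",
    "neighborhood_profile",
    "gene_density_anova",
]


@dataclass(frozen=True)
class PoissonTestResult:
    region_id: str
    group: str
    lam: float  # expected count per BR-sized bin
    observed: int
    p_value: float  # upper tail P(X >= observed)
    masked_coding: bool


@dataclass(frozen=True)
class NeighborhoodProfile:
    """Per-bar element counts across a BR and its 50 kb flanks.

    Bars have width equal to the BR itself; partial bars at chromosome ends
    keep their true (truncated) width for density normalization.
    """

    br_id: str
    group: str
    bar_width: int
    bars: tuple[tuple[int, int, int], ...]  # (start, end, count), left→right
    br_bar_index: int
    lambda_ref: float


def _starts_in(elements: Sequence[RepeatElement], start: int, end: int,
               group: str | None) -> int:
    return sum(
        1
        for el in elements
        if start <= el.start < end and (group is None or el.group == group)
    )


def count_in_region(
    elements: Sequence[RepeatElement],
    region: tuple[int, int],
    group: str | None = None,
) -> int:
    """Count elements whose start coordinate lies inside ``region``."""
    return _starts_in(elements, region[0], region[1], group)


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _masked_bp(mask: Sequence[tuple[int, int]], start: int, end: int) -> int:
    return sum(max(0, min(e, end) - max(s, start)) for s, e in mask)


def _in_mask(mask: Sequence[tuple[int, int]], pos: int) -> bool:
    return any(s <= pos < e for s, e in mask)


def poisson_br_test(
    region: BreakpointRegion | tuple[int, int],
    elements: Sequence[RepeatElement],
    chrom_length: int,
    group: str | None = None,
    coding_mask: Sequence[tuple[int, int]] | None = None,
    region_id: str | None = None,
) -> PoissonTestResult:
    """Upper-tail Poisson test of element density in one breakpoint region.

    Bins of width equal to the region tile the chromosome from coordinate 0;
    the trailing partial bin is excluded from λ.  With a coding mask, both λ
    and x are computed on non-coding base pairs only.
    """
    if isinstance(region, BreakpointRegion):
        start, end, rid = region.start, region.end, region.br_id
    else:
        start, end = region
        rid = region_id or f"{start}-{end}"
    width = end - start
    if width <= 0:
        raise ValueError(f"region {rid}: non-positive width")
    n_bins = chrom_length // width
    if n_bins < 1:
        raise ValueError(
            f"chromosome ({chrom_length} bp) shorter than one {width} bp bin"
        )
    span = n_bins * width

    if coding_mask:
        mask = _merge_intervals(coding_mask)
        usable = [
            el
            for el in elements
            if (group is None or el.group == group) and not _in_mask(mask, el.start)
        ]
        total = sum(1 for el in usable if 0 <= el.start < span)
        total_nc_bp = span - _masked_bp(mask, 0, span)
        region_nc_bp = width - _masked_bp(mask, start, end)
        if total_nc_bp <= 0:
            raise ValueError("coding mask covers the whole binned span")
        lam = total / total_nc_bp * region_nc_bp
        observed = sum(1 for el in usable if start <= el.start < end)
        masked = True
    else:
        total = _starts_in(elements, 0, span, group)
        lam = total / n_bins
        observed = _starts_in(elements, start, end, group)
        masked = False

    p = float(stats.poisson.sf(observed - 1, lam)) if observed > 0 else 1.0
    return PoissonTestResult(
        region_id=rid,
        group=group or "all",
        lam=lam,
        observed=observed,
        p_value=p,
        masked_coding=masked,
    )


def neighborhood_profile(
    br: BreakpointRegion,
    elements: Sequence[RepeatElement],
    chrom_length: int,
    group: str | None = None,
    flank: int = 50_000,
) -> NeighborhoodProfile:
    """Element counts in BR-width bars across [BR − flank, BR + flank]."""
    width = br.length
    if width < 1_000:
        raise ValueError(f"breakpoint region {br.br_id} shorter than 1 kb")

    left_bars: list[tuple[int, int]] = []
    edge = br.start
    remaining = flank
    while remaining > 0 and edge > 0:
        w = min(width, remaining, edge)
        left_bars.append((edge - w, edge))
        edge -= w
        remaining -= w
    left_bars.reverse()

    right_bars: list[tuple[int, int]] = []
    edge = br.end
    remaining = flank
    while remaining > 0 and edge < chrom_length:
        w = min(width, remaining, chrom_length - edge)
        right_bars.append((edge, edge + w))
        edge += w
        remaining -= w

    spans = left_bars + [(br.start, br.end)] + right_bars
    bars = tuple(
        (s, e, _starts_in(elements, s, e, group)) for s, e in spans
    )

    n_bins = chrom_length // width
    lam = _starts_in(elements, 0, n_bins * width, group) / n_bins if n_bins else 0.0
    return NeighborhoodProfile(
        br_id=br.br_id,
        group=group or "all",
        bar_width=width,
        bars=bars,
        br_bar_index=len(left_bars),
        lambda_ref=lam,
    )


def gene_density_anova(
    blocks: Sequence[SyntenyBlock],
    annotation: Sequence[GeneAnnotation],
    bin_size: int = 100_000,
) -> tuple[float, float, dict[int, list[int]]]:
    """One-way ANOVA of per-bin gene counts across synteny blocks.

    Each block is tiled with ``bin_size`` bins from its start; the trailing
    partial bin is dropped.  Genes are assigned to bins by start coordinate.
    Returns (F, p, per-block bin counts).
    """
    if len(blocks) < 2:
        raise ValueError("need at least two blocks to compare densities")
    genes = _gene_index(annotation)
    groups: dict[int, list[int]] = {}
    for b in blocks:
        start, end = _block_interval(b, genes)
        n_bins = (end - start) // bin_size
        if n_bins < 2:
            raise ValueError(
                f"block {b.index} spans only {n_bins} whole {bin_size} bp bins; "
                "need at least 2 per block"
            )
        counts = [0] * n_bins
        for gid in b.member_genes:
            offset = genes[gid].start - start
            idx = offset // bin_size
            if 0 <= idx < n_bins:
                counts[idx] += 1
        groups[b.index] = counts
    flat = [c for counts in groups.values() for c in counts]
    if max(flat) == min(flat):  # constant input: no variance anywhere
        return 0.0, 1.0, groups
    f_stat, p = stats.f_oneway(*groups.values())
    return float(f_stat), float(p), groups
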