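"""Synteny-block delineation and breakpoint-region extraction.

A synteny block is a maximal run of at least two genes that are consecutive
in both species' orders, regardless of orientation; membership ignores
strand, and the block's sign records whether the within-block gene order is
preserved (+1) or reversed (−1) in the target species.  Single genes that
break collinearity are reported as singletons and never form blocks — this
guards against misreading a single-gene transposition as an inversion
breakpoint.

The breakpoint region between two reference-adjacent blocks is the interval
from the end of the last gene of the left block to the start of the first
gene of the right block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotations import GeneAnnotation

__all__ = [
    "SyntenyBlock",
    "BreakpointRegion",
    "delineate_blocks",
    "to_signed_permutation",
    "locate_breakpoint_regions",
    "block_metrics",
    "capture_stats",
    "roman",
]


@dataclass(frozen=True)
class SyntenyBlock:
    """A maximal collinear run of genes, indexed by reference order."""

    index: int  # 1-based position along the reference
    member_genes: tuple[str, ...]
    target_rank: int  # 1-based position along the target
    sign: int  # +1 preserved order, -1 reversed

    def __post_init__(self) -> None:
        if len(self.member_genes) < 2:
            raise ValueError(
                f"block {self.index}: needs >= 2 member genes, "
                f"got {len(self.member_genes)}"
            )
        if self.sign not in (1, -1):
            raise ValueError(f"block {self.index}: sign must be +1 or -1")

    @property
    def n_genes(self) -> int:
        return len(self.member_genes)


@dataclass(frozen=True)
class BreakpointRegion:
    """The reference interval between two adjacent synteny blocks."""

    br_id: str  # Roman numeral, assigned left to right
    left_flank_gene: str
    right_flank_gene: str
    start: int  # end of the left flank gene (0-based half-open interval)
    end: int  # start of the right flank gene

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"breakpoint region {self.br_id}: degenerate interval "
                f"[{self.start}, {self.end}) — flank genes abut or overlap"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
    (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
    (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def delineate_blocks(
    ref_order: Sequence[str],
    target_order: Sequence[str],
) -> tuple[list[SyntenyBlock], list[str]]:
    """Split two gene orders into maximal bi-consecutive runs.

    Returns (blocks, singletons).  Both orders must be permutations of the
    same gene set.  A run is a maximal stretch of reference-consecutive genes
    whose target positions are consecutive ascending (+1 per step) or
    consecutive descending (−1 per step); runs of length 1 are singletons.
    """
    ref = list(ref_order)
    tgt = list(target_order)
    if len(set(ref)) != len(ref):
        raise ValueError("reference order contains duplicate gene ids")
    if set(ref) != set(tgt):
        diff = sorted(set(ref) ^ set(tgt))
        raise ValueError(f"gene sets differ; symmetric difference: {diff}")
    tpos = {g: i for i, g in enumerate(tgt)}

    runs: list[tuple[list[str], int]] = []  # (genes, direction)
    i = 0
    n = len(ref)
    while i < n:
        j = i
        direction = 0
        while j + 1 < n:
            step = tpos[ref[j + 1]] - tpos[ref[j]]
            if step in (1, -1) and (direction == 0 or step == direction):
                direction = step
                j += 1
            else:
                break
        runs.append((ref[i : j + 1], direction if direction else 1))
        i = j + 1

    proto = [(genes, sign) for genes, sign in runs if len(genes) >= 2]
    singletons = [genes[0] for genes, _ in runs if len(genes) == 1]

    # target rank: order blocks by their leftmost target position
    order = sorted(range(len(proto)), key=lambda k: min(tpos[g] for g in proto[k][0]))
    rank_of = {k: r + 1 for r, k in enumerate(order)}
    blocks = [
        SyntenyBlock(
            index=k + 1,
            member_genes=tuple(genes),
            target_rank=rank_of[k],
            sign=sign,
        )
        for k, (genes, sign) in enumerate(proto)
    ]
    return blocks, singletons


def to_signed_permutation(blocks: Sequence[SyntenyBlock]) -> tuple[int, ...]:
    """Target-species arrangement of the reference-indexed blocks.

    Output position k carries sign × index of the block whose target rank
    is k.
    """
    n = len(blocks)
    by_rank: dict[int, SyntenyBlock] = {}
    for b in blocks:
        if b.target_rank in by_rank:
            raise ValueError(f"duplicate target rank {b.target_rank}")
        by_rank[b.target_rank] = b
    missing = [r for r in range(1, n + 1) if r not in by_rank]
    if missing:
        raise ValueError(f"missing target ranks: {missing}")
    return tuple(by_rank[r].sign * by_rank[r].index for r in range(1, n + 1))


def _gene_index(annotation: Sequence[GeneAnnotation]) -> dict[str, GeneAnnotation]:
    return {g.gene_id: g for g in annotation}


def _block_interval(
    block: SyntenyBlock, genes: Mapping[str, GeneAnnotation]
) -> tuple[int, int]:
    """Reference span from first member gene start to last member gene end."""
    members = [genes[g] for g in block.member_genes]
    return min(g.start for g in members), max(g.end for g in members)


def locate_breakpoint_regions(
    blocks: Sequence[SyntenyBlock],
    annotation: Sequence[GeneAnnotation],
) -> list[BreakpointRegion]:
    """One breakpoint region per adjacent block pair, numbered I..N."""
    genes = _gene_index(annotation)
    ordered = sorted(blocks, key=lambda b: b.index)
    regions: list[BreakpointRegion] = []
    for k, (left, right) in enumerate(zip(ordered, ordered[1:]), start=1):
        left_members = sorted(
            (genes[g] for g in left.member_genes), key=lambda g: g.start
        )
        right_members = sorted(
            (genes[g] for g in right.member_genes), key=lambda g: g.start
        )
        left_gene = left_members[-1]
        right_gene = right_members[0]
        if right_gene.start < left_gene.end:
            raise ValueError(
                f"flank genes {left_gene.gene_id} and {right_gene.gene_id} overlap"
            )
        regions.append(
            BreakpointRegion(
                br_id=roman(k),
                left_flank_gene=left_gene.gene_id,
                right_flank_gene=right_gene.gene_id,
                start=left_gene.end,
                end=right_gene.start,
            )
        )
    return regions


def block_metrics(
    blocks: Sequence[SyntenyBlock],
    annotation: Sequence[GeneAnnotation],
) -> pd.DataFrame:
    """Per-block length, gene count, and gene density per 100 kb.

    Density is reported at full precision (``density_per_100kb``) and rounded
    half-even to two decimals (``density_2dp``), plus a Total row summing
    lengths and counts (total density from the summed quantities).
    """
    genes = _gene_index(annotation)
    rows = []
    for b in sorted(blocks, key=lambda x: x.index):
        start, end = _block_interval(b, genes)
        length = end - start
        density = b.n_genes / (length / 100_000) if length else 0.0
        rows.append(
            {
                "block": str(b.index),
                "start": start,
                "end": end,
                "length_bp": length,
                "n_genes": b.n_genes,
                "density_per_100kb": density,
                "density_2dp": round(density, 2),
                "sign": b.sign,
                "target_rank": b.target_rank,
            }
        )
    total_len = sum(r["length_bp"] for r in rows)
    total_genes = sum(r["n_genes"] for r in rows)
    total_density = total_genes / (total_len / 100_000) if total_len else 0.0
    rows.append(
        {
            "block": "Total",
            "start": min((r["start"] for r in rows), default=0),
            "end": max((r["end"] for r in rows), default=0),
            "length_bp": total_len,
            "n_genes": total_genes,
            "density_per_100kb": total_density,
            "density_2dp": round(total_density, 2),
            "sign": 0,
            "target_rank": 0,
        }
    )
    return pd.DataFrame(rows)


def capture_stats(
    block_subset: Sequence[int],
    blocks: Sequence[SyntenyBlock],
    annotation: Sequence[GeneAnnotation],
) -> dict[str, float]:
    """Gene count and span of a subset of blocks, absolute and as fractions
    of all-block totals (e.g. the content captured by one inversion)."""
    genes = _gene_index(annotation)
    by_index = {b.index: b for b in blocks}
    unknown = [i for i in block_subset if i not in by_index]
    if unknown:
        raise ValueError(f"unknown block indices: {unknown}")
    sub_genes = sum(by_index[i].n_genes for i in block_subset)
    sub_bp = sum(
        (lambda iv: iv[1] - iv[0])(_block_interval(by_index[i], genes))
        for i in block_subset
    )
    all_genes = sum(b.n_genes for b in blocks)
    all_bp = sum(
        (lambda iv: iv[1] - iv[0])(_block_interval(b, genes)) for b in blocks
    )
    return {
        "n_genes": sub_genes,
        "total_bp": sub_bp,
        "gene_fraction": sub_genes / all_genes if all_genes else 0.0,
        "bp_fraction": sub_bp / all_bp if all_bp else 0.0,
    }
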