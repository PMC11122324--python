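"""Synthetic two-species chromosomes with planted inversions.

The generator emulates the experimental substrate of a polytene-chromosome
FISH mapping study: a reference chromosome carrying annotated genes
partitioned into synteny blocks, repeat tracks laid down as per-group
Poisson processes (optionally enriched inside the true breakpoint regions),
a target species derived by applying a planted block-level reversal
scenario, and simulated FISH localizations of probe genes into cytogenetic
zones with optional zone-call noise and per-gene mappability failures.

No nucleotide sequence is simulated; coordinates, orders, and counts carry
all the structure the pipeline consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotations import (
    GeneAnnotation,
    MarkerLocalization,
    RepeatElement,
    classify_repeat_family,
    write_gff3,
    write_marker_table,
    write_repeat_bed,
)
from .reversals import apply_reversal

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "paper_scale_config",
    "generate_reference",
    "derive_target_species",
    "FishSimulator",
    "simulate_fish",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one two-species instance.

    Block lengths are gene-anchored spans (first gene start to last gene
    end); breakpoint-region lengths are the gene-free intervals between
    consecutive blocks, so the chromosome length is the sum of both.
    Repeat rates are expected elements per 100 kb per group;
    ``br_repeat_multiplier`` scales them inside the true breakpoint regions.

    With ``poisson_gene_counts`` the per-block gene counts are treated as
    expectations and the realized counts drawn Poisson, modelling genes as
    a homogeneous process per block instead of conditioning on exact
    totals (the appropriate null for density comparisons between blocks).
    """

    block_gene_counts: tuple[int, ...] = (24, 8, 144, 27, 40)
    block_lengths: tuple[int, ...] = (290_000, 105_000, 2_070_000, 430_000, 655_000)
    br_lengths: tuple[int, ...] = (9_000, 12_000, 7_000, 10_000)
    gene_length_mean: float = 2_000.0
    gene_length_sd: float = 1_000.0
    gene_length_min: int = 200
    repeat_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "retrotransposon": 2.0,
            "dna_transposon": 15.0,
            "unknown_te": 5.0,
            "simple_repeat": 30.0,
        }
    )
    repeat_length_mean: float = 400.0
    planted_scenario: tuple[tuple[int, int], ...] = ((3, 3), (2, 4))
    br_repeat_multiplier: float = 1.0
    zone_count: int = 39
    localization_noise: float = 0.0
    unmappable_prob: float = 0.0
    poisson_gene_counts: bool = False
    seed: int = 0
    chrom_name: str = "X"

    def __post_init__(self) -> None:
        if len(self.br_lengths) != len(self.block_lengths) - 1:
            raise ValueError("need exactly one breakpoint region per adjacent block pair")
        if len(self.block_gene_counts) != len(self.block_lengths):
            raise ValueError("block gene counts and lengths must align")
        if any(r < 0 for r in self.repeat_rates.values()):
            raise ValueError("repeat rates must be >= 0")
        if self.br_repeat_multiplier < 1:
            raise ValueError("br_repeat_multiplier must be >= 1")

    @property
    def n_blocks(self) -> int:
        return len(self.block_lengths)

    @property
    def chrom_length(self) -> int:
        return sum(self.block_lengths) + sum(self.br_lengths)


def paper_scale_config(**overrides) -> SimulationConfig:
    """Preset mirroring the published five-block X-chromosome structure:
    block spans of 1,458,895 / 526,550 / 10,348,225 / 2,148,753 / 3,273,690 bp
    carrying 122 / 42 / 722 / 137 / 199 genes, four 7–12 kb breakpoint
    regions, and the nested two-inversion scenario (block arrangement
    1 −4 3 −2 5 in the target species)."""
    base = dict(
        block_gene_counts=(122, 42, 722, 137, 199),
        block_lengths=(1_458_895, 526_550, 10_348_225, 2_148_753, 3_273_690),
        br_lengths=(9_000, 12_000, 7_000, 10_000),
        planted_scenario=((3, 3), (2, 4)),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass(frozen=True)
class GroundTruth:
    """Hidden truth accompanying a generated instance."""

    block_genes: tuple[tuple[str, ...], ...]  # gene ids per block, ref order
    block_intervals: tuple[tuple[int, int], ...]
    br_intervals: tuple[tuple[int, int], ...]
    scenario: tuple[tuple[int, int], ...]
    target_block_arrangement: tuple[int, ...]  # signed block order in target
    unmappable: frozenset[str]

    def to_json(self) -> str:
        d = asdict(self)
        d["unmappable"] = sorted(self.unmappable)
        return json.dumps(d, indent=2)


_GROUP_LABELS = {
    "retrotransposon": ("LTR/Gypsy", "LTR/Copia", "LINE/R1"),
    "dna_transposon": (
        "DNA/DTC_CACTA",
        "DNA/DTH_PIF_Harbinger",
        "DNA/DTA_hAT",
        "DNA/Helitron",
        "DNA/DTT_Tc1_Mariner",
    ),
    "unknown_te": ("repeat_region",),
    "simple_repeat": ("Simple_repeat", "Low_complexity"),
}


def _planted_arrangement(config: SimulationConfig) -> tuple[int, ...]:
    perm: tuple[int, ...] = tuple(range(1, config.n_blocks + 1))
    for i, j in config.planted_scenario:
        perm = apply_reversal(perm, i, j)
    return perm


def _place_block_genes(
    rng: np.random.Generator,
    block_start: int,
    block_len: int,
    count: int,
    config: SimulationConfig,
    first_gene_index: int,
) -> list[GeneAnnotation]:
    """Place ``count`` genes inside the block.

    Exact-count mode packs non-overlapping genes spanning exactly the
    block (first gene starts at the block start, last ends at its end),
    so configured block lengths are reproduced to the base pair.  Poisson
    mode instead drops each gene start uniformly in the block — a marked
    homogeneous point process, overlaps permitted — so per-bin counts
    carry full Poisson dispersion (pinning and hard-core packing would
    under-disperse them and bias density comparisons between blocks).
    """
    if config.poisson_gene_counts:
        starts = np.sort(
            rng.integers(block_start, block_start + block_len, size=count)
        )
        lengths = rng.normal(config.gene_length_mean, config.gene_length_sd, size=count)
        lengths = np.maximum(config.gene_length_min, np.rint(lengths)).astype(int)
        strands = rng.choice(["+", "-"], size=count)
        return [
            GeneAnnotation(
                chrom=config.chrom_name,
                start=int(starts[k]),
                end=min(int(starts[k] + lengths[k]), block_start + block_len),
                gene_id=f"g{first_gene_index + k:04d}",
                strand=str(strands[k]),
            )
            for k in range(count)
        ]
    if count == 1:
        return [
            GeneAnnotation(
                chrom=config.chrom_name,
                start=block_start,
                end=block_start + block_len,
                gene_id=f"g{first_gene_index:04d}",
            )
        ]
    lengths = rng.normal(config.gene_length_mean, config.gene_length_sd, size=count)
    lengths = np.maximum(config.gene_length_min, np.rint(lengths)).astype(int)
    free = block_len - int(lengths.sum())
    n_gaps = count - 1
    if free < n_gaps:
        raise ValueError(
            f"infeasible packing: {count} genes (total {int(lengths.sum())} bp) "
            f"do not fit in a {block_len} bp block"
        )
    # uniform-spacings (Dirichlet) gaps: the integer analogue of dropping
    # gene starts uniformly at random, conditional on no overlap
    raw = rng.dirichlet(np.ones(n_gaps)) * (free - n_gaps)
    base = np.floor(raw).astype(int)
    shortfall = (free - n_gaps) - int(base.sum())
    if shortfall:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:shortfall]] += 1
    gaps = base + 1
    genes = []
    pos = block_start
    strands = rng.choice(["+", "-"], size=count)
    for k in range(count):
        genes.append(
            GeneAnnotation(
                chrom=config.chrom_name,
                start=pos,
                end=pos + int(lengths[k]),
                gene_id=f"g{first_gene_index + k:04d}",
                strand=str(strands[k]),
            )
        )
        pos += int(lengths[k])
        if k < n_gaps:
            pos += int(gaps[k])
    assert genes[-1].end == block_start + block_len
    return genes


def _place_repeats(
    rng: np.random.Generator,
    config: SimulationConfig,
    br_intervals: Sequence[tuple[int, int]],
) -> list[RepeatElement]:
    elements: list[RepeatElement] = []
    regions: list[tuple[int, int, float]] = []  # start, end, rate multiplier
    cursor = 0
    br_sorted = sorted(br_intervals)
    for start, end in br_sorted:
        if cursor < start:
            regions.append((cursor, start, 1.0))
        regions.append((start, end, config.br_repeat_multiplier))
        cursor = end
    if cursor < config.chrom_length:
        regions.append((cursor, config.chrom_length, 1.0))

    for group, rate in sorted(config.repeat_rates.items()):
        labels = _GROUP_LABELS[group]
        for start, end, mult in regions:
            lam = rate * mult * (end - start) / 100_000.0
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            starts = np.sort(rng.integers(start, end, size=n))
            lens = np.maximum(
                20, rng.exponential(config.repeat_length_mean, size=n)
            ).astype(int)
            which = rng.integers(0, len(labels), size=n)
            for s, ln, w in zip(starts, lens, which):
                e = min(int(s) + int(ln), config.chrom_length)
                if e <= int(s):
                    continue
                label = labels[int(w)]
                elements.append(
                    RepeatElement(
                        chrom=config.chrom_name,
                        start=int(s),
                        end=e,
                        family_label=label,
                        group=classify_repeat_family(label, warn_unmatched=False),
                    )
                )
    elements.sort()
    return elements


def generate_reference(
    config: SimulationConfig,
) -> tuple[list[GeneAnnotation], list[RepeatElement], GroundTruth]:
    """Generate the reference annotation, repeat track, and hidden truth.

    Deterministic given ``config.seed``: gene placement, repeat placement,
    and mappability flags each draw from independent child streams of the
    one seed.
    """
    ss = np.random.SeedSequence(config.seed)
    gene_rng, repeat_rng, flag_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    genes: list[GeneAnnotation] = []
    block_genes: list[tuple[str, ...]] = []
    block_intervals: list[tuple[int, int]] = []
    br_intervals: list[tuple[int, int]] = []
    offset = 0
    gene_counter = 1
    for b in range(config.n_blocks):
        count = config.block_gene_counts[b]
        if config.poisson_gene_counts:
            count = int(gene_rng.poisson(count))
        length = config.block_lengths[b]
        if count > 0:
            placed = _place_block_genes(
                gene_rng, offset, length, count, config, gene_counter
            )
            genes.extend(placed)
            block_genes.append(tuple(g.gene_id for g in placed))
            gene_counter += count
        else:
            block_genes.append(())
        block_intervals.append((offset, offset + length))
        offset += length
        if b < config.n_blocks - 1:
            br_intervals.append((offset, offset + config.br_lengths[b]))
            offset += config.br_lengths[b]

    repeats = _place_repeats(repeat_rng, config, br_intervals)

    all_ids = [g.gene_id for g in genes]
    flags = flag_rng.random(len(all_ids)) < config.unmappable_prob
    unmappable = frozenset(gid for gid, f in zip(all_ids, flags) if f)

    truth = GroundTruth(
        block_genes=tuple(block_genes),
        block_intervals=tuple(block_intervals),
        br_intervals=tuple(br_intervals),
        scenario=tuple(config.planted_scenario),
        target_block_arrangement=_planted_arrangement(config),
        unmappable=unmappable,
    )
    return genes, repeats, truth


def derive_target_species(
    genes: Sequence[GeneAnnotation],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[list[str], dict[str, int]]:
    """Apply the planted block scenario: returns the target-species gene
    order and each gene's physical coordinate on the target chromosome.

    The target chromosome is laid out as the blocks in their rearranged
    order (gene positions mirrored inside sign-flipped blocks) separated by
    the same breakpoint-region spacers.
    """
    by_id = {g.gene_id: g for g in genes}
    order: list[str] = []
    coords: dict[str, int] = {}
    offset = 0
    arrangement = truth.target_block_arrangement
    for pos, signed in enumerate(arrangement):
        b = abs(signed) - 1
        b_start, b_end = truth.block_intervals[b]
        members = list(truth.block_genes[b])
        if signed < 0:
            members = members[::-1]
        for gid in members:
            g = by_id[gid]
            mid = g.midpoint
            coords[gid] = offset + (mid - b_start if signed > 0 else b_end - mid)
        order.extend(members)
        offset += b_end - b_start
        if pos < len(arrangement) - 1:
            offset += config.br_lengths[pos]
    return order, coords


class FishSimulator:
    """Simulated FISH of probe genes onto the target chromosome.

    A probe reports the cytogenetic zone (equal-width bins of the target
    chromosome) of its true position, perturbed by one zone with probability
    ``localization_noise``; unmappable probes yield no signal.  Probes
    co-hybridized in one round that land in the same zone are dye-resolved:
    their true relative order is observable (mirroring dual-colour FISH of
    nearby probe pairs).
    """

    def __init__(self, config: SimulationConfig | None = None, seed: int | None = None):
        self.config = config or SimulationConfig()
        if seed is not None:
            self.config = SimulationConfig(**{**asdict(self.config), "seed": seed})
        self.genes, self.repeats, self.truth = generate_reference(self.config)
        self.target_order, self.target_coords = derive_target_species(
            self.genes, self.truth, self.config
        )
        self.by_id = {g.gene_id: g for g in self.genes}
        self.zone_order = tuple(f"z{i + 1}" for i in range(self.config.zone_count))
        self._zone_width = self.config.chrom_length / self.config.zone_count
        self._fish_rng = np.random.default_rng(
            np.random.SeedSequence(self.config.seed).spawn(4)[3]
        )

    # -- observation ------------------------------------------------------

    def localize(self, gene_ids: Sequence[str], round: int = 1) -> list[MarkerLocalization]:
        """One FISH round over the given probes."""
        out: list[MarkerLocalization] = []
        zone_members: dict[int, list[tuple[int, str]]] = {}
        for gid in gene_ids:
            if gid not in self.by_id:
                raise KeyError(f"unknown gene id {gid!r}")
            if gid in self.truth.unmappable:
                continue
            tpos = self.target_coords[gid]
            z = min(int(tpos / self._zone_width), self.config.zone_count - 1)
            if self.config.localization_noise > 0 and (
                self._fish_rng.random() < self.config.localization_noise
            ):
                z += int(self._fish_rng.choice((-1, 1)))
                z = min(max(z, 0), self.config.zone_count - 1)
            zone_members.setdefault(z, []).append((tpos, gid))
        dye = ("dye_a", "dye_b")
        for z, members in zone_members.items():
            members.sort()  # true within-zone order: dye-resolved pairs
            for rank, (_, gid) in enumerate(members):
                out.append(
                    MarkerLocalization(
                        gene_id=gid,
                        ref_coord=self.by_id[gid].midpoint,
                        zone=self.zone_order[z],
                        round=round,
                        channel=dye[rank] if rank < 2 else None,
                    )
                )
        out.sort(key=lambda m: m.ref_coord)
        return out

    def pair_order(self, gene_a: str, gene_b: str) -> int:
        """Dual-dye co-hybridization of two probes: −1 if ``gene_a`` lies
        closer to the target chromosome start than ``gene_b``, else +1."""
        a, b = self.target_coords[gene_a], self.target_coords[gene_b]
        if a == b:  # pragma: no cover - midpoints are distinct by design
            return 0
        return -1 if a < b else 1


def simulate_fish(
    sim: FishSimulator, genes_to_probe: Sequence[str], round: int = 1
) -> list[MarkerLocalization]:
    """Functional wrapper over :meth:`FishSimulator.localize`."""
    return sim.localize(genes_to_probe, round=round)


def write_dataset(sim: FishSimulator, outdir: str | Path) -> dict[str, Path]:
    """Emit GFF3, repeat BED, round-1 marker TSV, and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_note = f"synbreak simulation, seed={sim.config.seed}"
    paths = {
        "gff3": outdir / "genes.gff3",
        "bed": outdir / "repeats.bed",
        "markers": outdir / "markers_round1.tsv",
        "truth": outdir / "ground_truth.json",
        "target_order": outdir / "target_order.txt",
    }
    write_gff3(sim.genes, paths["gff3"], header_comment=seed_note)
    write_repeat_bed(sim.repeats, paths["bed"], header_comment=seed_note)
    n_initial = min(17, len(sim.genes))
    step = max(1, len(sim.genes) // n_initial)
    probes = [g.gene_id for g in sim.genes[:: step]][:n_initial]
    write_marker_table(
        sim.localize(probes, round=1), paths["markers"], header_comment=seed_note
    )
    paths["truth"].write_text(sim.truth.to_json())
    paths["target_order"].write_text("\n".join(sim.target_order) + "\n")
    return paths
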