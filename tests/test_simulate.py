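import filecmp

import numpy as np
import pytest

from synbreak.simulate import (
    FishSimulator,
    SimulationConfig,
    derive_target_species,
    generate_reference,
    paper_scale_config,
    write_dataset,
)
from synbreak.synteny import delineate_blocks


class TestConfig:
    def test_chrom_length_sums_blocks_and_brs(self):
        cfg = SimulationConfig()
        assert cfg.chrom_length == sum(cfg.block_lengths) + sum(cfg.br_lengths)

    def test_paper_scale_totals(self):
        cfg = paper_scale_config()
        assert sum(cfg.block_lengths) == 17_756_113
        assert sum(cfg.block_gene_counts) == 1222

    def test_br_count_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(block_lengths=(100, 100), br_lengths=())

    def test_multiplier_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(br_repeat_multiplier=0.5)


class TestGenerateReference:
    def test_paper_scale_exact_structure(self, paper_sim):
        cfg, truth = paper_sim.config, paper_sim.truth
        for (s, e), expected in zip(truth.block_intervals, cfg.block_lengths):
            assert e - s == expected
        for genes_in_block, expected in zip(
            truth.block_genes, cfg.block_gene_counts
        ):
            assert len(genes_in_block) == expected
        # block spans are gene-anchored: first gene starts and last gene
        # ends exactly at the block boundaries
        by_id = paper_sim.by_id
        for ids, (s, e) in zip(truth.block_genes, truth.block_intervals):
            assert by_id[ids[0]].start == s
            assert by_id[ids[-1]].end == e

    def test_genes_non_overlapping_and_sorted(self, paper_sim):
        genes = paper_sim.genes
        assert all(a.end <= b.start for a, b in zip(genes, genes[1:]))

    def test_br_intervals_are_gene_free(self, paper_sim):
        for s, e in paper_sim.truth.br_intervals:
            assert not any(s < g.end and g.start < e for g in paper_sim.genes)

    def test_determinism(self):
        cfg = SimulationConfig(seed=42)
        a = generate_reference(cfg)
        b = generate_reference(cfg)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_seeds_differ(self):
        a = generate_reference(SimulationConfig(seed=1))
        b = generate_reference(SimulationConfig(seed=2))
        assert a[0] != b[0]

    def test_poisson_mode_varies_counts(self):
        counts = {
            len(generate_reference(
                SimulationConfig(seed=s, poisson_gene_counts=True)
            )[0])
            for s in range(5)
        }
        assert len(counts) > 1

    def test_poisson_mode_genes_stay_in_blocks(self):
        genes, _, truth = generate_reference(
            SimulationConfig(seed=3, poisson_gene_counts=True)
        )
        spans = list(truth.block_intervals)
        for g in genes:
            assert any(s <= g.start and g.end <= e for s, e in spans)


class TestDeriveTarget:
    def test_gene_set_conserved(self, paper_sim):
        order, coords = derive_target_species(
            paper_sim.genes, paper_sim.truth, paper_sim.config
        )
        assert sorted(order) == sorted(g.gene_id for g in paper_sim.genes)
        assert set(coords) == set(order)

    def test_empty_scenario_is_identity(self):
        cfg = SimulationConfig(planted_scenario=())
        genes, _, truth = generate_reference(cfg)
        order, _ = derive_target_species(genes, truth, cfg)
        assert order == [g.gene_id for g in genes]

    def test_planted_arrangement(self, paper_sim):
        assert paper_sim.truth.target_block_arrangement == (1, -4, 3, -2, 5)

    def test_inverted_block_order_reverses(self, paper_sim):
        truth = paper_sim.truth
        order = paper_sim.target_order
        block2 = list(truth.block_genes[1])  # signed -2 in the target
        pos = {g: i for i, g in enumerate(order)}
        seen = [pos[g] for g in block2]
        assert seen == sorted(seen, reverse=True)

    def test_round_trip_recovers_blocks(self):
        cfg = SimulationConfig(seed=5)
        genes, _, truth = generate_reference(cfg)
        order, _ = derive_target_species(genes, truth, cfg)
        blocks, singles = delineate_blocks([g.gene_id for g in genes], order)
        assert not singles
        assert tuple(tuple(b.member_genes) for b in blocks) == truth.block_genes


class TestFishSimulator:
    def test_noise_free_localization_reproduces_target_order(self):
        sim = FishSimulator(SimulationConfig(seed=0))
        probes = [g.gene_id for g in sim.genes][::10]
        obs = sim.localize(probes)
        rank = {z: i for i, z in enumerate(sim.zone_order)}
        by_target = sorted(obs, key=lambda m: sim.target_coords[m.gene_id])
        ranks = [rank[m.zone] for m in by_target]
        assert ranks == sorted(ranks)

    def test_unmappable_prob_one_empty(self):
        sim = FishSimulator(SimulationConfig(seed=0, unmappable_prob=1.0))
        assert sim.localize([g.gene_id for g in sim.genes][:5]) == []

    def test_unknown_gene_rejected(self):
        sim = FishSimulator(SimulationConfig(seed=0))
        with pytest.raises(KeyError):
            sim.localize(["nope"])

    def test_noise_perturbs_at_most_one_zone(self):
        noisy = FishSimulator(SimulationConfig(seed=0, localization_noise=1.0))
        clean = FishSimulator(SimulationConfig(seed=0))
        probes = [g.gene_id for g in clean.genes][::7]
        rank = {z: i for i, z in enumerate(clean.zone_order)}
        true_zone = {m.gene_id: rank[m.zone] for m in clean.localize(probes)}
        for m in noisy.localize(probes):
            assert abs(rank[m.zone] - true_zone[m.gene_id]) <= 1

    def test_pair_order(self):
        sim = FishSimulator(SimulationConfig(seed=0))
        a, b = sim.target_order[0], sim.target_order[-1]
        assert sim.pair_order(a, b) == -1
        assert sim.pair_order(b, a) == 1

    def test_seed_override(self):
        sim = FishSimulator(SimulationConfig(seed=0), seed=9)
        assert sim.config.seed == 9


class TestWriteDataset:
    def test_same_seed_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            write_dataset(FishSimulator(SimulationConfig(seed=11)), d)
        for name in ("genes.gff3", "repeats.bed", "markers_round1.tsv",
                     "ground_truth.json", "target_order.txt"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_seed_in_headers(self, tmp_path):
        paths = write_dataset(FishSimulator(SimulationConfig(seed=7)), tmp_path)
        assert "seed=7" in paths["gff3"].read_text().splitlines()[1]
        assert "seed=7" in paths["bed"].read_text().splitlines()[0]
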