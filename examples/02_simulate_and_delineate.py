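"""Simulate a two-species chromosome pair and recover its block structure.

The paper_scale preset builds an ~17.8 Mb X chromosome with five synteny
blocks (1,222 genes) and two planted nested inversions.  We then delineate
synteny blocks from the two gene orders alone and check that the planted
structure comes back out.
"""

from synbreak import (
    FishSimulator,
    block_metrics,
    delineate_blocks,
    locate_breakpoint_regions,
    paper_scale_config,
    to_signed_permutation,
)

sim = FishSimulator(paper_scale_config(seed=1))
print(f"simulated {len(sim.genes)} genes, {len(sim.repeats)} repeat elements")

ref_order = [g.gene_id for g in sim.genes]
blocks, singletons = delineate_blocks(ref_order, sim.target_order)
print(f"{len(blocks)} synteny blocks, {len(singletons)} singletons")
print(f"target arrangement: {to_signed_permutation(blocks)}")

print(block_metrics(blocks, sim.genes)[
    ["block", "length_bp", "n_genes", "density_2dp"]
].to_string(index=False))

for br in locate_breakpoint_regions(blocks, sim.genes):
    print(f"BR {br.br_id}: [{br.start:,}, {br.end:,}) = {br.length:,} bp "
          f"between {br.left_flank_gene} and {br.right_flank_gene}")
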