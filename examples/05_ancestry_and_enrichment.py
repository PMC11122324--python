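"""Ancestral-arrangement calls and term enrichment of rearranged blocks.

First: given two ingroup species whose flank-gene pair differs in adjacency
at a breakpoint, outgroup genomes arbitrate which arrangement is ancestral.
Second: a hypergeometric test asks whether the genes captured by an
inversion are enriched for any functional term.
"""

from synbreak import (
    AdjacencyObservation,
    classify_br_ancestry,
    enrich,
    summarize_ancestry,
)

# --- ancestry ------------------------------------------------------------
# At each breakpoint, species A shows the flank genes adjacent in the same
# order while species B shows them separated.  Three outgroups weigh in.
outgroups = {
    "I": [
        AdjacencyObservation("outgroup1", "g010", "g011", "adjacent_same_order"),
        AdjacencyObservation("outgroup2", "g010", "g011", "adjacent_same_order"),
        AdjacencyObservation("outgroup3", "g010", "g011", "unresolved"),
    ],
    "II": [
        AdjacencyObservation("outgroup1", "g055", "g056", "adjacent_same_order"),
        AdjacencyObservation("outgroup2", "g055", "g056", "not_adjacent"),
        AdjacencyObservation("outgroup3", "g055", "g056", "adjacent_same_order"),
    ],
}
calls = [
    classify_br_ancestry(br, "adjacent_same_order", "not_adjacent", obs)
    for br, obs in outgroups.items()
]
for c in calls:
    print(f"BR {c.br_id}: {c.call} ({c.reason}; "
          f"support A={c.n_support_a}, B={c.n_support_b})")
summary = summarize_ancestry(calls)
print(f"chromosome verdict: {summary['verdict']} "
      f"({summary['n_determined']}/{summary['n_breakpoints']} determined)\n")
# BR II stays undetermined: one outgroup contradicts the others, and
# conflicts are never settled by majority vote.

# --- enrichment ----------------------------------------------------------
universe = [f"g{i:03d}" for i in range(1, 101)]
terms = {
    "GO:0001": ("sensory perception", frozenset(universe[10:20])),
    "GO:0002": ("housekeeping", frozenset(universe[::2])),
}
inversion_genes = universe[8:24]  # genes captured by the inversion
for r in enrich(inversion_genes, terms, universe, p_cutoff=None):
    print(f"{r.term_id} ({r.term_name}): k={r.k}/{r.n}, K={r.K}/{r.N}, "
          f"p={r.p:.3g}, BH={r.fdr_bh:.3g}, fold={r.fold:.2f}")
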