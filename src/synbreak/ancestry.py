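"""Ancestral-versus-derived calls for breakpoint arrangements.

Each breakpoint region is flanked by a gene pair that is adjacent in one
ingroup species (A) and separated in the other (B).  Outgroup genomes act
as the arbiter: if outgroups show the pair in the same adjacency state as
species A and never in B's state, A's arrangement is ancestral at that
breakpoint (and symmetrically for B).  Any contradiction between usable
outgroups leaves the call undetermined — no majority vote, mirroring the
conservative reading a curator would apply.  Gene orientation in outgroups
is ignored; only adjacency and relative order count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "ADJACENCY_STATES",
    "AdjacencyObservation",
    "AncestryCall",
    "classify_br_ancestry",
    "summarize_ancestry",
    "read_adjacency_table",
]

ADJACENCY_STATES = (
    "adjacent_same_order",
    "adjacent_other_order",
    "not_adjacent",
    "unresolved",
)


@dataclass(frozen=True)
class AdjacencyObservation:
    """One outgroup species' state for an unordered flank gene pair."""

    species: str
    gene_a: str
    gene_b: str
    state: str

    def __post_init__(self) -> None:
        if self.state not in ADJACENCY_STATES:
            raise ValueError(
                f"state {self.state!r} not one of {ADJACENCY_STATES}"
            )


@dataclass(frozen=True)
class AncestryCall:
    br_id: str
    call: str  # a_ancestral | b_ancestral | undetermined
    reason: str
    n_support_a: int
    n_support_b: int
    n_unresolved: int


def classify_br_ancestry(
    br_id: str,
    ingroup_a_state: str,
    ingroup_b_state: str,
    outgroup_observations: Sequence[AdjacencyObservation],
    min_support: int = 1,
) -> AncestryCall:
    """Call one breakpoint's arrangement ancestral for ingroup A or B.

    A is called ancestral iff at least ``min_support`` outgroups show A's
    adjacency state and none show B's (symmetrically for B).  Unresolved
    observations (scaffold breaks, missing orthologs) never influence the
    call.
    """
    for name, state in (("A", ingroup_a_state), ("B", ingroup_b_state)):
        if state not in ADJACENCY_STATES or state == "unresolved":
            raise ValueError(f"ingroup {name} state {state!r} invalid")
    if ingroup_a_state == ingroup_b_state:
        raise ValueError(
            "ingroup states are identical; the breakpoint cannot discriminate"
        )
    if not outgroup_observations:
        raise ValueError("need at least one outgroup observation")

    n_unresolved = sum(1 for o in outgroup_observations if o.state == "unresolved")
    usable = [o for o in outgroup_observations if o.state != "unresolved"]
    support_a = sum(1 for o in usable if o.state == ingroup_a_state)
    support_b = sum(1 for o in usable if o.state == ingroup_b_state)

    if not usable:
        call, reason = "undetermined", "no_data"
    elif support_a >= min_support and support_b == 0:
        call, reason = "a_ancestral", "outgroups_match_a"
    elif support_b >= min_support and support_a == 0:
        call, reason = "b_ancestral", "outgroups_match_b"
    elif support_a and support_b:
        call, reason = "undetermined", "conflicting_outgroups"
    else:
        call, reason = "undetermined", "insufficient_support"
    return AncestryCall(
        br_id=br_id,
        call=call,
        reason=reason,
        n_support_a=support_a,
        n_support_b=support_b,
        n_unresolved=n_unresolved,
    )


def summarize_ancestry(per_br_calls: Sequence[AncestryCall]) -> dict:
    """Chromosome-level verdict from the per-breakpoint calls.

    The verdict follows the determined calls when they agree; any
    disagreement yields 'mixed'; no determined call yields 'undetermined'.
    Undetermined breakpoints are reported, never overridden.
    """
    if not per_br_calls:
        raise ValueError("need at least one breakpoint call")
    determined = [c.call for c in per_br_calls if c.call != "undetermined"]
    counts = Counter(determined)
    if not determined:
        verdict = "undetermined"
    elif len(counts) == 1:
        verdict = determined[0]
    else:
        verdict = "mixed"
    return {
        "verdict": verdict,
        "n_determined": len(determined),
        "n_breakpoints": len(per_br_calls),
        "calls": {c.br_id: c.call for c in per_br_calls},
        "reasons": {c.br_id: c.reason for c in per_br_calls},
    }


def read_adjacency_table(path: str | Path) -> list[AdjacencyObservation]:
    """Read the outgroup adjacency TSV (species, gene_a, gene_b, state)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in ("species", "gene_a", "gene_b", "state") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        AdjacencyObservation(
            species=r.species, gene_a=r.gene_a, gene_b=r.gene_b, state=r.state
        )
        for r in df.itertuples(index=False)
    ]
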