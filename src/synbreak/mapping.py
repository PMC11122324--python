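"""The iterative FISH-mapping loop: probe, classify, narrow, repeat.

Models the marker-selection campaign used to corner inversion breakpoints:
a sparse first round of probes establishes large-scale collinearity, then
each following round drops a few probes inside every open candidate
interval (between markers whose zone pattern changes character) until no
mappable gene remains strictly inside any interval.  Probe positions
within an interval follow a quantile rule — the (k+1)-quantile points — a
multi-point generalization of bisection.

Classification follows the experimental reading: markers whose target-zone
ranks fit the longest monotone backbone (tried in both chromosome
orientations, with same-zone ties compatible) are collinear; the rest are
translocated.  Candidate intervals open wherever reference-adjacent mapped
markers straddle a collinear/translocated transition, or where a
translocated stretch itself breaks monotonicity.  A stretch of chromosome
whose round-1 markers all stay collinear is never probed further — the
approach cannot see an inversion that no initial marker landed in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotations import GeneAnnotation, MarkerLocalization
from .simulate import FishSimulator

__all__ = [
    "CandidateInterval",
    "CampaignResult",
    "classify_markers",
    "propose_next_markers",
    "run_campaign",
]


@dataclass(frozen=True)
class CandidateInterval:
    """An open interval hypothesized to contain an inversion breakpoint."""

    br_hypothesis_id: str
    start: int  # end of the left bounding gene (ref coordinates)
    end: int  # start of the right bounding gene
    left_gene: str
    right_gene: str
    round_opened: int

    @property
    def width(self) -> int:
        return self.end - self.start


def _longest_monotone(seq: Sequence[int], descending: bool) -> list[int]:
    """Indices of a longest non-decreasing (or non-increasing) subsequence."""
    vals = [-v for v in seq] if descending else list(seq)
    n = len(vals)
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if vals[j] <= vals[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -i))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def _backbone_indices(ranks: Sequence[int]) -> set[int]:
    asc = _longest_monotone(ranks, descending=False)
    desc = _longest_monotone(ranks, descending=True)
    return set(asc if len(asc) >= len(desc) else desc)


def classify_markers(
    localizations: Sequence[MarkerLocalization],
    zone_order: Sequence[str],
) -> dict[str, list[str]]:
    """Partition localized markers into collinear and translocated sets.

    Markers are taken in reference order; the collinear backbone is the
    longest run of markers whose zone ranks are monotone (non-strict, so
    same-zone ties stay compatible), tried in both chromosome orientations.
    Markers off the backbone are translocated.
    """
    if len(localizations) < 2:
        raise ValueError("need at least two localized markers")
    rank = {z: i for i, z in enumerate(zone_order)}
    markers = sorted(localizations, key=lambda m: m.ref_coord)
    ranks = [rank[m.zone] for m in markers]
    if len(set(ranks)) == 1:
        raise ValueError(
            "all markers fall in one zone; collinearity is indeterminate"
        )
    backbone = _backbone_indices(ranks)
    collinear = [markers[i].gene_id for i in range(len(markers)) if i in backbone]
    translocated = [
        markers[i].gene_id for i in range(len(markers)) if i not in backbone
    ]
    return {"collinear": collinear, "translocated": translocated}


def _segment_labels(ranks: Sequence[int], backbone: set[int]) -> list[int]:
    """Assign a segment id to each ref-ordered marker.

    A new segment starts at every collinear/translocated transition and
    wherever a translocated stretch breaks its own (non-strict) monotone
    zone trend.
    """
    labels: list[int] = []
    seg = 0
    trend = 0  # direction inside the current translocated stretch
    for i, r in enumerate(ranks):
        if i == 0:
            labels.append(seg)
            continue
        prev_member = (i - 1) in backbone
        member = i in backbone
        if member != prev_member:
            seg += 1
            trend = 0
        elif not member:
            step = r - ranks[i - 1]
            if step != 0:
                direction = 1 if step > 0 else -1
                if trend == 0:
                    trend = direction
                elif direction != trend:
                    seg += 1
                    trend = 0
        labels.append(seg)
    return labels


def propose_next_markers(
    candidates: Sequence[CandidateInterval],
    available_genes: Sequence[GeneAnnotation],
    k_per_interval: int = 3,
) -> list[str]:
    """Pick up to k genes per open interval, nearest to its (k+1)-quantile
    points; empty exactly when no available gene lies strictly inside any
    interval (the campaign's stop condition)."""
    if k_per_interval < 1:
        raise ValueError("k_per_interval must be >= 1")
    picks: list[str] = []
    taken: set[str] = set()
    for interval in candidates:
        interior = [
            g
            for g in available_genes
            if interval.start < g.midpoint < interval.end and g.gene_id not in taken
        ]
        if not interior:
            continue
        width = interval.end - interval.start
        for i in range(1, k_per_interval + 1):
            q = interval.start + width * i / (k_per_interval + 1)
            pool = [g for g in interior if g.gene_id not in taken]
            if not pool:
                break
            chosen = min(pool, key=lambda g: (abs(g.midpoint - q), g.gene_id))
            taken.add(chosen.gene_id)
            picks.append(chosen.gene_id)
    return picks


@dataclass
class CampaignResult:
    final_intervals: list[CandidateInterval]
    log: pd.DataFrame  # round, interval id, flanks, width, picked genes
    rounds: int
    mapped: dict[str, MarkerLocalization]
    failed_probes: list[str]


def _open_intervals(
    mapped: dict[str, MarkerLocalization],
    sim: FishSimulator,
    round_no: int,
) -> list[CandidateInterval]:
    zone_rank = {z: i for i, z in enumerate(sim.zone_order)}
    ref_sorted = sorted(mapped, key=lambda g: sim.by_id[g].midpoint)
    if len(ref_sorted) < 2:
        return []
    ranks = [zone_rank[mapped[g].zone] for g in ref_sorted]
    if len(set(ranks)) == 1:
        return []
    backbone = _backbone_indices(ranks)
    labels = _segment_labels(ranks, backbone)

    intervals: list[CandidateInterval] = []
    counter = 1
    for i in range(len(ref_sorted) - 1):
        if labels[i] == labels[i + 1]:
            continue
        lg, rg = sim.by_id[ref_sorted[i]], sim.by_id[ref_sorted[i + 1]]
        if rg.start <= lg.end:
            continue  # abutting flank genes: nothing can lie between
        intervals.append(
            CandidateInterval(
                br_hypothesis_id=f"cand{counter}",
                start=lg.end,
                end=rg.start,
                left_gene=lg.gene_id,
                right_gene=rg.gene_id,
                round_opened=round_no,
            )
        )
        counter += 1
    return intervals


def run_campaign(
    sim: FishSimulator,
    k: int = 3,
    n_initial: int = 17,
    max_rounds: int = 50,
) -> CampaignResult:
    """Run the full iterative mapping campaign on a simulated instance.

    Round 1 probes ``n_initial`` genes at even quantiles of the reference
    chromosome; each later round probes up to ``k`` genes per open interval
    until no mappable marker remains inside any interval.  Deterministic
    given the simulator's seed.
    """
    genes = sim.genes
    if not genes:
        raise ValueError("simulator carries no genes")
    mapped: dict[str, MarkerLocalization] = {}
    failed: set[str] = set()
    log_rows: list[dict] = []

    length = sim.config.chrom_length
    probes: list[str] = []
    seen: set[str] = set()
    for i in range(n_initial):
        q = length * (i + 0.5) / n_initial
        g = min(genes, key=lambda x: (abs(x.midpoint - q), x.gene_id))
        if g.gene_id not in seen:
            seen.add(g.gene_id)
            probes.append(g.gene_id)

    round_no = 1
    while True:
        if round_no > max_rounds:
            raise RuntimeError(
                f"campaign did not converge in {max_rounds} rounds; "
                f"{len(mapped)} markers mapped, last probes: {sorted(probes)}"
            )
        observations = sim.localize(probes, round=round_no)
        observed_ids = {m.gene_id for m in observations}
        for m in observations:
            mapped[m.gene_id] = m
        failed.update(set(probes) - observed_ids)

        intervals = _open_intervals(mapped, sim, round_no)
        available = [
            g for g in genes if g.gene_id not in mapped and g.gene_id not in failed
        ]
        picks = propose_next_markers(intervals, available, k_per_interval=k)
        picked_of: dict[str, list[str]] = {iv.br_hypothesis_id: [] for iv in intervals}
        for p in picks:
            mid = sim.by_id[p].midpoint
            for iv in intervals:
                if iv.start < mid < iv.end:
                    picked_of[iv.br_hypothesis_id].append(p)
                    break
        for iv in intervals:
            log_rows.append(
                {
                    "round": round_no,
                    "interval": iv.br_hypothesis_id,
                    "left_gene": iv.left_gene,
                    "right_gene": iv.right_gene,
                    "width": iv.width,
                    "picked": ";".join(picked_of[iv.br_hypothesis_id]),
                }
            )
        if not picks:
            log = pd.DataFrame(
                log_rows,
                columns=[
                    "round", "interval", "left_gene", "right_gene", "width", "picked",
                ],
            )
            return CampaignResult(
                final_intervals=intervals,
                log=log,
                rounds=round_no,
                mapped=mapped,
                failed_probes=sorted(failed),
            )
        probes = picks
        round_no += 1
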