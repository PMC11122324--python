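"""Term enrichment for gene lists from rearranged synteny blocks.

One-sided hypergeometric test per flat term (no ontology-graph
propagation — the gene→term table is taken as given), with
Benjamini–Hochberg and Bonferroni adjustment, fold enrichment, and the 2×2
odds ratio.  The odds ratio is reported raw, +inf when a zero cell makes it
diverge; no continuity correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "enrich",
    "adjust",
    "read_term_table",
    "results_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # list genes carrying the term
    n: int  # list size
    K: int  # universe genes carrying the term
    N: int  # universe size
    p: float  # hypergeometric upper tail P(X >= k)
    fdr_bh: float
    bonferroni: float
    fold: float  # (k/n) / (K/N)
    odds_ratio: float  # may be +inf


def adjust(p_values: Sequence[float]) -> tuple[list[float], list[float]]:
    """Benjamini–Hochberg (step-up, monotone) and Bonferroni adjustment."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    bonf = np.minimum(1.0, p * p.size)
    return [float(x) for x in bh], [float(x) for x in bonf]


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    # 2x2 table: a=k (list, term), b=K-k (rest, term),
    #            c=n-k (list, no term), d=(N-K)-(n-k) (rest, no term)
    a, b, c, d = k, K - k, n - k, (N - K) - (n - k)
    if b == 0 or c == 0:
        return math.inf if a > 0 else 0.0
    return (a * d) / (b * c)


def enrich(
    gene_list: Iterable[str],
    term_table: Mapping[str, tuple[str, frozenset[str]]] | pd.DataFrame,
    universe: Iterable[str],
    p_cutoff: float | None = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each term in ``gene_list``.

    ``term_table`` maps term_id → (term_name, gene set), or is a DataFrame
    with gene_id/term_id (and optionally term_name) columns.  Terms absent
    from the list (k = 0) are not tested; adjustment spans all tested terms.
    Only results with p < ``p_cutoff`` are returned unless the cutoff is
    None.  Results are sorted by (p, term_id).
    """
    uni = set(universe)
    genes = set(gene_list)
    outside = sorted(genes - uni)
    if outside:
        raise ValueError(f"genes outside the universe: {outside[:10]}")
    if isinstance(term_table, pd.DataFrame):
        term_table = _table_from_frame(term_table)

    N, n = len(uni), len(genes)
    tested: list[tuple[str, str, int, int]] = []
    for term_id in sorted(term_table):
        term_name, members = term_table[term_id]
        members = frozenset(members) & uni
        K = len(members)
        k = len(members & genes)
        if k >= 1:
            tested.append((term_id, term_name, k, K))
    if not tested:
        return []

    p_values = [
        float(stats.hypergeom.sf(k - 1, N, K, n)) for _, _, k, K in tested
    ]
    bh, bonf = adjust(p_values)
    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=name,
            k=k,
            n=n,
            K=K,
            N=N,
            p=p,
            fdr_bh=q,
            bonferroni=bf,
            fold=(k / n) / (K / N),
            odds_ratio=_odds_ratio(k, n, K, N),
        )
        for (tid, name, k, K), p, q, bf in zip(tested, p_values, bh, bonf)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    if p_cutoff is not None:
        results = [r for r in results if r.p < p_cutoff]
    return results


def _table_from_frame(df: pd.DataFrame) -> dict[str, tuple[str, frozenset[str]]]:
    missing = [c for c in ("gene_id", "term_id") if c not in df.columns]
    if missing:
        raise ValueError(f"term table missing columns {missing}")
    names = {}
    members: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        members.setdefault(row.term_id, set()).add(row.gene_id)
        names[row.term_id] = getattr(row, "term_name", row.term_id)
    return {
        tid: (names[tid] if isinstance(names[tid], str) else tid, frozenset(g))
        for tid, g in members.items()
    }


def read_term_table(path: str | Path) -> pd.DataFrame:
    """Read the flat gene→term TSV (gene_id, term_id[, term_name, domain])."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in ("gene_id", "term_id") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "fdr_bh": r.fdr_bh,
                "bonferroni": r.bonferroni,
                "fold": r.fold,
                "odds_ratio": r.odds_ratio,
            }
            for r in results
        ]
    )
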