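"""Signed sorting-by-reversals: distance, scenarios, and a search oracle.

A chromosomal inversion is modelled as a *signed reversal*: a contiguous
segment of a signed permutation is order-reversed and every sign inside is
flipped.  The minimum number of reversals transforming one block arrangement
into another is computed exactly with the Hannenhalli–Pevzner theory
(breakpoint-graph cycle decomposition with hurdle and fortress corrections),
and all minimal ordered scenarios can be enumerated.

Only unichromosomal signed permutations are supported; unsigned input is
rejected because reversal distance for unsigned permutations is a different
(NP-hard) problem.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "apply_reversal",
    "breakpoint_count",
    "reversal_distance",
    "enumerate_minimal_scenarios",
    "bfs_distance_oracle",
    "ScenarioSet",
    "parse_grimm",
    "format_grimm",
]


def _validate(perm: Sequence[int]) -> tuple[int, ...]:
    p = tuple(int(x) for x in perm)
    n = len(p)
    if any(x == 0 for x in p):
        raise ValueError(
            "permutation elements must be non-zero signed integers; "
            "unsigned permutations (with 0 or missing signs) are not supported"
        )
    if sorted(abs(x) for x in p) != list(range(1, n + 1)):
        raise ValueError(
            f"absolute values must be exactly 1..{n}, each once; got {p}"
        )
    return p


def _check_same_elements(source: tuple[int, ...], target: tuple[int, ...]) -> None:
    if len(source) != len(target):
        raise ValueError(
            f"element-set mismatch: lengths {len(source)} vs {len(target)}"
        )


def apply_reversal(perm: Sequence[int], i: int, j: int) -> tuple[int, ...]:
    """Reverse segment [i..j] (1-based, inclusive) and flip its signs."""
    p = _validate(perm)
    n = len(p)
    if not (1 <= i <= j <= n):
        raise IndexError(f"reversal indices ({i},{j}) out of range for n={n}")
    a, b = i - 1, j  # 0-based half-open
    seg = tuple(-x for x in reversed(p[a:b]))
    return p[:a] + seg + p[b:]


def breakpoint_count(perm: Sequence[int]) -> int:
    """Number of breakpoints of ``perm`` relative to the identity.

    With framing elements 0 and n+1, an adjacency is a pair (x, y) with
    y == x + 1; every non-adjacency is a breakpoint.
    """
    p = _validate(perm)
    framed = (0,) + p + (len(p) + 1,)
    return sum(1 for x, y in zip(framed, framed[1:]) if y != x + 1)


# ---------------------------------------------------------------------------
# Hannenhalli–Pevzner distance
# ---------------------------------------------------------------------------


def _extended_unsigned(perm: tuple[int, ...]) -> list[int]:
    # +x -> (2x-1, 2x); -x -> (2|x|, 2|x|-1); framed by 0 and 2n+1.
    u = [0]
    for x in perm:
        if x > 0:
            u.extend((2 * x - 1, 2 * x))
        else:
            u.extend((-2 * x, -2 * x - 1))
    u.append(2 * len(perm) + 1)
    return u


def _hp_distance_to_identity(perm: tuple[int, ...]) -> int:
    n = len(perm)
    if n == 0:
        return 0
    u = _extended_unsigned(perm)
    m = len(u)  # 2n + 2
    pos = [0] * m
    for idx, v in enumerate(u):
        pos[v] = idx

    # Cycle decomposition of the breakpoint graph.  Black edges join the
    # elements at positions (2i, 2i+1); gray edges join values (2i, 2i+1).
    visited = [False] * m
    cycles: list[list[tuple[int, int]]] = []  # gray edges per cycle
    for v0 in range(m):
        if visited[v0]:
            continue
        v = v0
        gray_edges: list[tuple[int, int]] = []
        while True:
            visited[v] = True
            w = u[pos[v] ^ 1]  # black partner (position pairing)
            visited[w] = True
            g = w ^ 1  # gray partner (value pairing)
            gray_edges.append((w, g))
            v = g
            if v == v0:
                break
        cycles.append(gray_edges)

    c = len(cycles)

    # Non-trivial cycles only take part in component/hurdle analysis.
    nontrivial = [cy for cy in cycles if len(cy) > 1]
    if not nontrivial:
        return (n + 1) - c

    # Interleaving graph on cycles via strict overlap of gray-edge intervals.
    spans: list[list[tuple[int, int]]] = [
        [tuple(sorted((pos[a], pos[b]))) for a, b in cy] for cy in nontrivial
    ]
    k = len(nontrivial)
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for ci in range(k):
        for cj in range(ci + 1, k):
            if find(ci) == find(cj):
                continue
            done = False
            for a1, b1 in spans[ci]:
                for a2, b2 in spans[cj]:
                    if a1 < a2 < b1 < b2 or a2 < a1 < b2 < b1:
                        union(ci, cj)
                        done = True
                        break
                if done:
                    break

    def _edge_oriented(a: int, b: int) -> bool:
        return (pos[a] % 2) == (pos[b] % 2)

    comp_cycles: dict[int, list[int]] = {}
    for ci in range(k):
        comp_cycles.setdefault(find(ci), []).append(ci)

    unoriented_comps: list[set[int]] = []  # vertex sets
    for members in comp_cycles.values():
        oriented = any(
            _edge_oriented(a, b) for ci in members for a, b in nontrivial[ci]
        )
        if not oriented:
            verts: set[int] = set()
            for ci in members:
                for a, b in nontrivial[ci]:
                    verts.add(a)
                    verts.add(b)
            unoriented_comps.append(verts)

    if not unoriented_comps:
        return (n + 1) - c

    comp_of_vertex: dict[int, int] = {}
    for cid, verts in enumerate(unoriented_comps):
        for v in verts:
            comp_of_vertex[v] = cid

    # Circular walk over positions, restricted to unoriented components.
    walk = [comp_of_vertex[v] for v in u if v in comp_of_vertex]
    runs: list[int] = []
    for cid in walk:
        if not runs or runs[-1] != cid:
            runs.append(cid)
    if len(runs) > 1 and runs[0] == runs[-1]:
        runs.pop()

    occurrences = Counter(runs)
    hurdles = [cid for cid in range(len(unoriented_comps)) if occurrences[cid] == 1]
    h = len(hurdles)

    fortress = 0
    if h % 2 == 1 and h >= 3:
        def _is_super(cid: int) -> bool:
            if len(runs) < 3:
                return False
            i = runs.index(cid)
            prev_c = runs[(i - 1) % len(runs)]
            next_c = runs[(i + 1) % len(runs)]
            return prev_c == next_c and occurrences[prev_c] == 2

        if all(_is_super(cid) for cid in hurdles):
            fortress = 1

    return (n + 1) - c + h + fortress


def _relative(source: tuple[int, ...], target: tuple[int, ...]) -> tuple[int, ...]:
    """Relabel so that ``target`` becomes the identity."""
    mapping: dict[int, int] = {}
    for j, t in enumerate(target, start=1):
        mapping[abs(t)] = j if t > 0 else -j
    if set(mapping) != {abs(s) for s in source}:
        missing = set(mapping) ^ {abs(s) for s in source}
        raise ValueError(f"element-set mismatch, symmetric difference: {sorted(missing)}")
    return tuple(mapping[abs(s)] if s > 0 else -mapping[abs(s)] for s in source)


def reversal_distance(source: Sequence[int], target: Sequence[int]) -> int:
    """Exact minimum number of signed reversals transforming source → target."""
    s, t = _validate(source), _validate(target)
    _check_same_elements(s, t)
    return _hp_distance_to_identity(_relative(s, t))


# ---------------------------------------------------------------------------
# Scenario enumeration
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSet:
    """All minimal ordered reversal scenarios between two arrangements.

    ``scenarios`` holds ordered step lists; each step (i, j) is a 1-based
    inclusive index pair.  ``truncated`` is set when enumeration stopped at
    ``max_count`` rather than exhausting the search space.
    """

    distance: int
    scenarios: list[tuple[tuple[int, int], ...]] = field(default_factory=list)
    truncated: bool = False

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.scenarios)


def enumerate_minimal_scenarios(
    source: Sequence[int],
    target: Sequence[int],
    max_count: int = 10_000,
    dedupe_unordered: bool = False,
) -> ScenarioSet:
    """Enumerate every ordered sequence of exactly d reversals sorting
    ``source`` into ``target``, each step decreasing the distance by 1.

    Scenarios are emitted in lexicographic order of their step indices.  When
    more than ``max_count`` exist the result is truncated and flagged, never
    raised.  With ``dedupe_unordered`` scenarios that use the same multiset of
    steps in a different order are collapsed to the lexicographically first.
    """
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    s, t = _validate(source), _validate(target)
    _check_same_elements(s, t)
    rel = _relative(s, t)
    d = _hp_distance_to_identity(rel)
    result = ScenarioSet(distance=d)
    n = len(rel)
    steps = [(i, j) for i in range(1, n + 1) for j in range(i, n + 1)]

    def dfs(p: tuple[int, ...], remaining: int, trail: list[tuple[int, int]]) -> bool:
        if remaining == 0:
            result.scenarios.append(tuple(trail))
            return len(result.scenarios) < max_count
        for (i, j) in steps:
            q = p[: i - 1] + tuple(-x for x in reversed(p[i - 1 : j])) + p[j:]
            if _hp_distance_to_identity(q) == remaining - 1:
                trail.append((i, j))
                keep_going = dfs(q, remaining - 1, trail)
                trail.pop()
                if not keep_going:
                    return False
        return True

    completed = dfs(rel, d, [])
    result.truncated = not completed
    if dedupe_unordered:
        seen: set[frozenset[tuple[tuple[int, int], int]]] = set()
        unique = []
        for sc in result.scenarios:
            key = frozenset(Counter(sc).items())
            if key not in seen:
                seen.add(key)
                unique.append(sc)
        result.scenarios = unique
    return result


# ---------------------------------------------------------------------------
# Independent search oracle
# ---------------------------------------------------------------------------

_ORACLE_MAX_N = 8


def bfs_distance_oracle(source: Sequence[int], target: Sequence[int]) -> int:
    """Exact reversal distance by bidirectional breadth-first search.

    Deliberately independent of the breakpoint-graph machinery; refuses
    n > 8 where the state space becomes impractical.
    """
    s, t = _validate(source), _validate(target)
    _check_same_elements(s, t)
    n = len(s)
    if n > _ORACLE_MAX_N:
        raise ValueError(f"search oracle limited to n <= {_ORACLE_MAX_N}, got {n}")
    if s == t:
        return 0
    index_pairs = [(i, j) for i in range(n) for j in range(i + 1, n + 1)]

    def neighbours(p: tuple[int, ...]) -> Iterable[tuple[int, ...]]:
        for i, j in index_pairs:
            yield p[:i] + tuple(-x for x in reversed(p[i:j])) + p[j:]

    dist_a: dict[tuple[int, ...], int] = {s: 0}
    dist_b: dict[tuple[int, ...], int] = {t: 0}
    frontier_a, frontier_b = [s], [t]
    while frontier_a and frontier_b:
        if len(frontier_a) <= len(frontier_b):
            frontier, dist, other = frontier_a, dist_a, dist_b
        else:
            frontier, dist, other = frontier_b, dist_b, dist_a
        next_frontier: list[tuple[int, ...]] = []
        meet: int | None = None
        level = dist[frontier[0]] + 1
        for p in frontier:
            for q in neighbours(p):
                if q in dist:
                    continue
                if q in other:
                    cand = level + other[q]
                    meet = cand if meet is None else min(meet, cand)
                dist[q] = level
                next_frontier.append(q)
        if meet is not None:
            return meet
        if frontier is frontier_a:
            frontier_a = next_frontier
        else:
            frontier_b = next_frontier
    raise RuntimeError("search exhausted without meeting; invalid input?")


# ---------------------------------------------------------------------------
# GRIMM-style plain-text permutation format
# ---------------------------------------------------------------------------


def parse_grimm(text: str) -> dict[str, tuple[int, ...]]:
    """Parse '>name' headers followed by space-separated signed integers.

    Multi-line bodies are concatenated; '$' end-of-chromosome markers are
    tolerated and ignored.
    """
    genomes: dict[str, tuple[int, ...]] = {}
    name: str | None = None
    body: list[int] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if name is not None:
                genomes[name] = _validate(body)
            name = line[1:].strip()
            if not name:
                raise ValueError(f"line {lineno}: empty genome name")
            body = []
        else:
            if name is None:
                raise ValueError(f"line {lineno}: data before any '>' header")
            for tok in line.replace("$", " ").split():
                try:
                    body.append(int(tok))
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: bad token {tok!r}") from exc
    if name is not None:
        genomes[name] = _validate(body)
    return genomes


def format_grimm(genomes: dict[str, Sequence[int]]) -> str:
    lines = []
    for name, perm in genomes.items():
        lines.append(f">{name}")
        lines.append(" ".join(str(x) for x in _validate(perm)))
    return "\n".join(lines) + "\n"
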