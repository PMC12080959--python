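"""Graph data model for protein–protein interaction (PPI) networks.

The interactome is an undirected simple graph over protein identifiers.
Edges may carry an evidence count (number of supporting experiments),
which supports confidence filtering (e.g. keeping only interactions seen
in at least three experiments, a common "gold standard" convention).

Pairs are always canonicalized as ``(min(a), max(a))`` lexicographically so
that set membership and file round-trips are order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

Pair = Tuple[str, str]


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list file (carries the line number)."""


class ConfigurationError(ValueError):
    """An operation was invoked with an inconsistent configuration."""


class CapacityError(ValueError):
    """A sample was requested that exceeds the eligible population.

    Attributes
    ----------
    eligible : int
        Number of eligible items available.
    """

    def __init__(self, message: str, eligible: int):
        super().__init__(message)
        self.eligible = eligible


def canonical_pair(a: str, b: str) -> Pair:
    """Return the canonical (lexicographically sorted) form of an unordered pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Interactome:
    """An undirected simple graph over protein identifiers.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node, node order is deterministic (sorted) so adjacency indexing is
    reproducible.
    """

    nodes: Tuple[str, ...]
    edges: FrozenSet[Pair]
    evidence: Optional[Mapping[Pair, int]] = None
    _adj: Dict[str, Set[str]] = field(default_factory=dict, repr=False, compare=False)
    _index: Dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    @staticmethod
    def from_edges(edges: Iterable[Pair],
                   nodes: Iterable[str] = (),
                   evidence: Optional[Mapping[Pair, int]] = None) -> "Interactome":
        """Build an interactome from an edge iterable (plus optional isolated nodes).

        Self-loops are rejected; duplicate edges (either orientation) collapse.
        """
        canon: Set[Pair] = set()
        node_set: Set[str] = set(nodes)
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop not allowed: {a!r}")
            canon.add(canonical_pair(a, b))
            node_set.add(a)
            node_set.add(b)
        ev = None
        if evidence is not None:
            ev = {canonical_pair(*p): int(c) for p, c in evidence.items()}
        return Interactome(tuple(sorted(node_set)), frozenset(canon), ev)

    def __post_init__(self):
        adj: Dict[str, Set[str]] = {n: set() for n in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        object.__setattr__(self, "_adj", adj)
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.nodes)})

    # -- basic queries -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_node(self, n: str) -> bool:
        return n in self._adj

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.edges

    def neighbors(self, n: str) -> Set[str]:
        return self._adj[n]

    def degree(self, n: str) -> int:
        return len(self._adj[n])

    def node_index(self, n: str) -> int:
        return self._index[n]

    def degree_sequence(self) -> np.ndarray:
        """Per-node degrees aligned to (sorted) node order."""
        return np.array([len(self._adj[n]) for n in self.nodes], dtype=np.int64)

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Sparse adjacency matrix aligned to node order (zero diagonal)."""
        n = self.n_nodes
        rows, cols = [], []
        for a, b in self.edges:
            i, j = self._index[a], self._index[b]
            rows.extend((i, j))
            cols.extend((j, i))
        data = np.ones(len(rows), dtype=np.int64)
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def non_edges(self) -> List[Pair]:
        """All unordered non-self pairs that are not edges, in canonical order."""
        out = []
        ns = self.nodes
        for i in range(len(ns)):
            for j in range(i + 1, len(ns)):
                p = (ns[i], ns[j])
                if p not in self.edges:
                    out.append(p)
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def load_edge_list(path, min_evidence: int = 1) -> Interactome:
    """Load a TSV edge list (protein_a, protein_b[, evidence]).

    Lines starting with ``#`` are comments. Self-loops and duplicate edges
    (either orientation) are dropped/collapsed with a logged count. When a
    pair appears on several rows its evidence is the *maximum* count seen
    (conservative and idempotent under file concatenation). Edges are kept
    only if their evidence is at least ``min_evidence``.

    Raises
    ------
    EdgeListParseError
        On malformed lines (reports the 1-based line number).
    ConfigurationError
        If ``min_evidence > 1`` but the file has no evidence column.
    """
    if min_evidence < 1:
        raise ValueError(f"min_evidence must be >= 1, got {min_evidence}")
    evidence: Dict[Pair, int] = {}
    has_evidence_col = False
    self_loops = 0
    duplicates = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >=2 tab-separated columns, got {len(fields)}")
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise EdgeListParseError(f"{path}:{lineno}: empty protein identifier")
            count = 1
            if len(fields) >= 3 and fields[2].strip():
                try:
                    count = int(fields[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: evidence column is not an integer: {fields[2]!r}"
                    ) from exc
                has_evidence_col = True
            if a == b:
                self_loops += 1
                continue
            p = canonical_pair(a, b)
            if p in evidence:
                duplicates += 1
                evidence[p] = max(evidence[p], count)
            else:
                evidence[p] = count
    if min_evidence > 1 and not has_evidence_col and evidence:
        raise ConfigurationError(
            f"min_evidence={min_evidence} requires an evidence column, none found in {path}")
    if self_loops or duplicates:
        logger.info("load_edge_list(%s): dropped %d self-loops, collapsed %d duplicate rows",
                    path, self_loops, duplicates)
    kept = {p: c for p, c in evidence.items() if c >= min_evidence}
    return Interactome.from_edges(kept.keys(), evidence=kept)


def write_edge_list(g: Interactome, path) -> None:
    """Write a TSV edge list (canonical pair order; evidence column if present)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for a, b in sorted(g.edges):
            if g.evidence is not None:
                fh.write(f"{a}\t{b}\t{g.evidence.get((a, b), 1)}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def degree_preserved_swap(g: Interactome, n_swaps: int, seed: int,
                          max_tries: Optional[int] = None) -> Tuple[Interactome, int]:
    """Randomize a graph by double-edge swaps, preserving every node degree.

    A swap picks two edges (a,b),(c,d) and rewires them to (a,d),(c,b).
    Swaps that would create self-loops or duplicate existing edges are
    rejected and counted. Runs until ``n_swaps`` swaps are accepted or
    ``max_tries`` attempts are exhausted (default ``max(100, 20*n_swaps)``);
    graphs rich in 4-cycles reject frequently because a swap on a 4-cycle
    duplicates one of its chords.

    Returns ``(swapped graph, rejected count)``.
    """
    if n_swaps < 0:
        raise ValueError(f"n_swaps must be >= 0, got {n_swaps}")
    if n_swaps == 0:
        return g, 0
    if g.n_edges < 2:
        raise ValueError("degree_preserved_swap requires a graph with >= 2 edges")
    if max_tries is None:
        max_tries = max(100, 20 * n_swaps)
    rng = np.random.default_rng(seed)
    edges = sorted(g.edges)
    edge_set = set(edges)
    accepted = 0
    rejected = 0
    tries = 0
    while accepted < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            rejected += 1
            continue
        a, b = edges[i]
        c, d = edges[j]
        # randomize which endpoints pair up
        if rng.integers(0, 2):
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            rejected += 1
            continue
        e1 = canonical_pair(a, d)
        e2 = canonical_pair(c, b)
        if e1 in edge_set or e2 in edge_set:
            rejected += 1
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
        accepted += 1
    if accepted < n_swaps:
        logger.warning("degree_preserved_swap: only %d/%d swaps accepted in %d tries",
                       accepted, n_swaps, tries)
    out = Interactome.from_edges(edge_set, nodes=g.nodes)
    return out, rejected


def random_deletion(g: Interactome, fraction: float, unit: str, seed: int) -> Interactome:
    """Delete a uniform random fraction of nodes or edges.

    ``round(fraction * count)`` units are removed; node removal drops
    incident edges. Deterministic given ``seed``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if unit not in ("node", "edge"):
        raise ValueError(f"unit must be 'node' or 'edge', got {unit!r}")
    rng = np.random.default_rng(seed)
    if unit == "node":
        nodes = list(g.nodes)
        k = int(round(fraction * len(nodes)))
        drop = set(rng.choice(len(nodes), size=k, replace=False)) if k else set()
        dropped = {nodes[i] for i in drop}
        keep_nodes = [n for n in nodes if n not in dropped]
        keep_edges = [e for e in g.edges if e[0] not in dropped and e[1] not in dropped]
        return Interactome.from_edges(keep_edges, nodes=keep_nodes)
    edges = sorted(g.edges)
    k = int(round(fraction * len(edges)))
    drop = set(rng.choice(len(edges), size=k, replace=False)) if k else set()
    keep_edges = [e for i, e in enumerate(edges) if i not in drop]
    return Interactome.from_edges(keep_edges, nodes=g.nodes)


def complement_sample(g: Interactome, n: int, seed: int,
                      exclude: Iterable[Pair] = ()) -> List[Pair]:
    """Sample ``n`` distinct non-edges uniformly from the complement graph.

    This is the traditional random negative sampling baseline: protein
    pairs that are simply not observed as edges. Excluded pairs and
    self-pairs are never returned. Deterministic given ``seed``.

    Raises
    ------
    CapacityError
        If fewer than ``n`` eligible non-edges exist (reports the count).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    excl = {canonical_pair(a, b) for a, b in exclude if a != b}
    excl_extra = sum(1 for p in excl
                     if p not in g.edges and g.has_node(p[0]) and g.has_node(p[1]))
    n_nodes = g.n_nodes
    total_pairs = n_nodes * (n_nodes - 1) // 2
    eligible = total_pairs - g.n_edges - excl_extra
    if n > eligible:
        raise CapacityError(
            f"requested {n} non-edges but only {eligible} are eligible", eligible)
    rng = np.random.default_rng(seed)
    forbidden = set(g.edges) | excl
    if n == 0:
        return []
    # enumerate when the eligible set is small; otherwise rejection-sample
    if total_pairs <= 200_000 or n > eligible // 10:
        pool = [p for p in _all_pairs(g.nodes) if p not in forbidden]
        idx = rng.choice(len(pool), size=n, replace=False)
        return sorted(pool[i] for i in idx)
    nodes = g.nodes
    chosen: Set[Pair] = set()
    while len(chosen) < n:
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        p = canonical_pair(nodes[i], nodes[j])
        if p in forbidden or p in chosen:
            continue
        chosen.add(p)
    return sorted(chosen)


def _all_pairs(nodes: Sequence[str]) -> Iterable[Pair]:
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            yield (nodes[i], nodes[j])


def count_four_cycles(g: Interactome) -> int:
    """Number of (unlabelled) 4-cycles, via trace(A^4) with degree corrections.

    #C4 = (tr(A^4) - 2m - 2*sum_i k_i(k_i - 1)) / 8 for a simple graph.
    """
    a = g.adjacency_matrix().astype(np.float64)
    a2 = a @ a
    tr_a4 = float((a2.multiply(a2.T)).sum())
    k = g.degree_sequence().astype(np.float64)
    m = g.n_edges
    return int(round((tr_a4 - 2 * m - 2 * float(np.sum(k * (k - 1)))) / 8.0))
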