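"""L3 simple-path counting and the Contrastive-L3 (CL3) negative filter.

PPI networks are complementarity-driven: interacting proteins are linked
through many paths of length 3 (L3), unlike social networks where length-2
paths (shared neighbours) dominate. The CL3 hypothesis inverts this: a
truly noninteracting pair should induce *no* L3 path. Combining the
configuration model's bottom-ranked pairs with a zero-L3 filter yields
Topological Protein-Protein NonInteractions (TPPNIs) — hard negatives
drawn from the network topology alone.

For a pair (i, j) the number of simple length-3 paths (4 distinct nodes) is

    L3(i, j) = (A^3)_ij - A_ij * (k_i + k_j - 1)

where A is the adjacency matrix with zero diagonal. The correction removes
the non-simple walks that revisit i or j; no other revisit is possible in
three steps. For the candidate lists used here the computation is done
sparsely per pair (row_i . A . col_j), never materializing A^3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .network import Interactome, Pair, canonical_pair
from .scm import PairScore, SCMResults, fit_scm, graph_digest

logger = logging.getLogger(__name__)


class ContractViolation(ValueError):
    """A candidate pair violated the non-edge precondition."""


class L3Table(Mapping[Pair, int]):
    """Symmetric map from canonical pair to its simple L3 path count."""

    def __init__(self, counts: Dict[Pair, int]):
        self._counts = {canonical_pair(*p): int(c) for p, c in counts.items()}

    def __getitem__(self, pair: Pair) -> int:
        return self._counts[canonical_pair(*pair)]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self):
        return len(self._counts)

    def __contains__(self, pair) -> bool:
        try:
            return canonical_pair(*pair) in self._counts
        except TypeError:
            return False


@dataclass(frozen=True)
class TppniSet:
    """Topological hard negatives: bottom-ranked, zero-L3 non-edges.

    ``pairs`` keeps the ascending configuration-model-probability order, so
    truncation retains the topologically least probable pairs first.
    ``provenance`` records the bottom-N used and a digest of the source graph.
    """

    pairs: Tuple[Pair, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __contains__(self, pair) -> bool:
        return canonical_pair(*pair) in set(self.pairs)


def count_l3(g: Interactome, pairs: Iterable[Pair]) -> L3Table:
    """Simple L3 path counts for a list of pairs, computed sparsely.

    Memory is proportional to |pairs| + |edges|: counts are evaluated as
    (row_i A) . col_j for the needed rows only, with the adjacency
    correction for adjacent pairs.
    """
    pair_list = [canonical_pair(a, b) for a, b in pairs]
    for a, b in pair_list:
        if a == b:
            raise ValueError(f"L3 count undefined for self-pair {a!r}")
        if not g.has_node(a) or not g.has_node(b):
            missing = a if not g.has_node(a) else b
            raise KeyError(f"unknown node {missing!r}")
    a_mat = g.adjacency_matrix()
    idx = g.node_index
    deg = g.degree_sequence()
    # group by row so each A2 row is computed once
    by_row: Dict[int, List[Tuple[int, Pair]]] = {}
    for p in pair_list:
        i, j = idx(p[0]), idx(p[1])
        by_row.setdefault(i, []).append((j, p))
    counts: Dict[Pair, int] = {}
    for i, items in by_row.items():
        row2 = a_mat.getrow(i) @ a_mat          # (row_i A): walks of length 2 from i
        row3 = row2 @ a_mat                      # walks of length 3 from i
        row3 = np.asarray(row3.todense()).ravel()
        for j, p in items:
            walks = int(row3[j])
            if g.has_edge(*p):
                walks -= int(deg[idx(p[0])] + deg[idx(p[1])] - 1)
            counts[p] = walks
    return L3Table(counts)


def enumerate_simple_paths_l3(g: Interactome, i: str, j: str) -> int:
    """Exhaustive DFS count of simple i-a-b-j paths (independent oracle).

    Counts orderings i -> a -> b -> j with i, a, b, j pairwise distinct and
    all three edges present. This is the brute-force reference against
    which :func:`count_l3` is verified.
    """
    if i == j:
        raise ValueError(f"L3 count undefined for self-pair {i!r}")
    if not g.has_node(i):
        raise KeyError(f"unknown node {i!r}")
    if not g.has_node(j):
        raise KeyError(f"unknown node {j!r}")
    count = 0
    nbr_j = g.neighbors(j)
    for a in g.neighbors(i):
        if a == j:
            continue
        for b in g.neighbors(a):
            if b == i or b == j or b == a:
                continue
            if b in nbr_j:
                count += 1
    return count


def cl3_filter(g: Interactome, candidates: Sequence[PairScore]) -> TppniSet:
    """Keep only candidates inducing zero L3 paths (CL3 hypothesis).

    Candidates must be non-edges of ``g``; order (ascending p) is preserved.
    """
    for c in candidates:
        if g.has_edge(*c.pair):
            raise ContractViolation(
                f"candidate {c.pair} is an observed edge and cannot be a negative")
    table = count_l3(g, [c.pair for c in candidates])
    kept = tuple(canonical_pair(*c.pair) for c in candidates if table[c.pair] == 0)
    return TppniSet(kept, provenance={"n_candidates": len(candidates),
                                      "graph_digest": graph_digest(g)})


def sample_tppni(g: Interactome, n_bottom: Optional[int] = None,
                 tol: float = 1e-10) -> TppniSet:
    """Full topological negative sampling procedure.

    1. Fit the configuration model to the observed network.
    2. Rank all candidate (non-edge) pairs by link probability and keep the
       bottom ``n_bottom`` (default ``min(10 * |edges|, all candidates)``).
    3. Count simple L3 paths for those pairs in the original network.
    4. Keep the pairs with exactly zero L3 paths.

    Deterministic (seed-free); returns a :class:`TppniSet` ordered by
    ascending link probability.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot sample negatives from an empty graph")
    n_candidates = g.n_nodes * (g.n_nodes - 1) // 2 - g.n_edges
    if n_bottom is None:
        n_bottom = min(max(10 * g.n_edges, 1), max(n_candidates, 1))
    if n_candidates == 0:
        return TppniSet((), provenance={"n_bottom": n_bottom,
                                        "graph_digest": graph_digest(g)})
    fit = fit_scm(g, tol=tol)
    candidates = fit.bottom_n_pairs(n_bottom)
    result = cl3_filter(g, candidates)
    prov = dict(result.provenance)
    prov["n_bottom"] = n_bottom
    prov["scm_residual"] = fit.residual
    return TppniSet(result.pairs, provenance=prov)
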