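"""Simple (unipartite) Configuration Model fitted by entropy maximization.

The SCM is the maximum-entropy exponential random-graph model whose only
constraints are the expected node degrees: <d_i> = k_i for every node i.
It is parameterized by per-node Lagrange multipliers lambda_i, and the
resulting link probability between nodes i and j is

    p_ij = 1 / (exp(lambda_i + lambda_j) + 1).

Fitting solves sum_{j != i} p_ij = k_i for all i. We work in the variables
x_i = exp(-lambda_i), for which p_ij = x_i x_j / (1 + x_i x_j), and iterate
the standard damped fixed point

    x_i <- k_i / sum_{j != i} x_j / (1 + x_i x_j)

with initialization x_i = k_i / sqrt(2m), falling back to a quasi-Newton
root solve if the fixed point stalls. Nodes sharing a degree share x, so
the solve is reduced to the distinct degree classes.

Degree-0 nodes are the exact lambda -> +inf limit of the model: their link
probabilities are 0 and they are excluded from the solve (but remain valid
candidates for negative sampling, where they rank first). A node of degree
n-1 forces p -> 1 and an unbounded multiplier; lambda is capped at +/-50
and the fit reports converged=False if the residual cannot reach tol.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import Interactome, Pair, canonical_pair

logger = logging.getLogger(__name__)

LAMBDA_CAP = 50.0


class ScmFitError(RuntimeError):
    """The degree-constraint solve failed to converge (carries the residual)."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class PairScore:
    """A candidate pair together with its SCM link probability."""

    pair: Pair
    p: float


class ConfigurationModel:
    """Maximum-entropy null model of an interactome constrained to its degrees.

    Parameters
    ----------
    graph : Interactome
        The observed network whose degree sequence defines the constraints.

    Examples
    --------
    >>> from upna_ppi.network import Interactome
    >>> g = Interactome.from_edges([("a","b"), ("b","c"), ("c","d"), ("d","a")])
    >>> res = ConfigurationModel(g).fit()
    >>> round(res.link_probability("a", "c"), 6)   # C4: p = 2/3 by symmetry
    0.666667
    """

    def __init__(self, graph: Interactome):
        if graph.n_nodes == 0:
            raise ValueError("cannot fit the configuration model on an empty graph")
        self.graph = graph

    def fit(self, tol: float = 1e-10, max_iter: int = 5000) -> "SCMResults":
        g = self.graph
        k = g.degree_sequence().astype(np.float64)
        n = g.n_nodes
        if np.any(k > n - 1):
            raise ValueError("degree exceeds n-1; graph is not simple")

        active = k > 0
        k_act = k[active]
        lam = np.full(n, np.inf)  # lambda -> +inf limit for degree-0 nodes
        converged = True
        iterations = 0
        residual = 0.0
        capped = False

        if k_act.size:
            deg_vals, inv = np.unique(k_act, return_inverse=True)
            mult = np.bincount(inv).astype(np.float64)
            m2 = float(k_act.sum())
            x = deg_vals / np.sqrt(m2)
            x, residual, iterations, converged = _solve_degree_classes(
                deg_vals, mult, x, tol, max_iter)
            lam_vals = -np.log(x)
            capped = bool(np.any(np.abs(lam_vals) >= LAMBDA_CAP - 1e-9))
            lam_act = lam_vals[inv]
            lam[active] = lam_act
            if not converged and not capped:
                raise ScmFitError(
                    f"SCM fit did not converge in {max_iter} iterations "
                    f"(residual {residual:.3e} > tol {tol:.1e})", residual)
            if capped and residual > tol:
                converged = False

        lambdas = {node: float(lam[i]) for i, node in enumerate(g.nodes)}
        return SCMResults(self.graph, lambdas, residual=float(residual),
                          converged=converged, iterations=iterations, tol=tol)


def _solve_degree_classes(deg_vals: np.ndarray, mult: np.ndarray, x0: np.ndarray,
                          tol: float, max_iter: int) -> Tuple[np.ndarray, float, int, bool]:
    """Damped fixed point over distinct degree classes; quasi-Newton fallback."""
    lo, hi = np.exp(-LAMBDA_CAP), np.exp(LAMBDA_CAP)
    x = np.clip(x0, lo, hi)
    damp = 0.5
    it = 0
    for it in range(1, max_iter + 1):
        denom = _expected_degrees(deg_vals, mult, x) / np.maximum(x, 1e-300)
        x_new = deg_vals / np.maximum(denom, 1e-300)
        x = np.clip((1 - damp) * x + damp * x_new, lo, hi)
        res = _residual(deg_vals, mult, x)
        if res <= tol:
            return x, res, it, True
    res = _residual(deg_vals, mult, x)
    # quasi-Newton fallback on log-variables
    try:
        from scipy.optimize import root

        def fun(logx):
            xi = np.clip(np.exp(logx), lo, hi)
            return _expected_degrees(deg_vals, mult, xi) - deg_vals

        sol = root(fun, np.log(x), method="hybr", tol=tol * 1e-2)
        x_alt = np.clip(np.exp(sol.x), lo, hi)
        res_alt = _residual(deg_vals, mult, x_alt)
        if res_alt < res:
            x, res = x_alt, res_alt
    except Exception:  # pragma: no cover - fallback only
        pass
    return x, res, it, res <= tol


def _expected_degrees(deg_vals: np.ndarray, mult: np.ndarray, x: np.ndarray) -> np.ndarray:
    """<d> per degree class: sum over other nodes of x_i x_j / (1 + x_i x_j)."""
    prod = np.outer(x, x)
    p = prod / (1.0 + prod)
    # total over all nodes in each class, minus the self term
    return p @ mult - np.diag(p)


def _residual(deg_vals: np.ndarray, mult: np.ndarray, x: np.ndarray) -> float:
    return float(np.max(np.abs(_expected_degrees(deg_vals, mult, x) - deg_vals)))


class SCMResults:
    """Fitted configuration model: Lagrange multipliers and link probabilities.

    Attributes
    ----------
    lambdas : dict
        Per-node multiplier lambda_i (``+inf`` for degree-0 nodes).
    residual : float
        max_i |<d_i> - k_i| at the solution.
    converged : bool
    iterations : int
    """

    def __init__(self, graph: Interactome, lambdas: Dict[str, float], residual: float,
                 converged: bool, iterations: int, tol: float):
        self.graph = graph
        self.lambdas = lambdas
        self.residual = residual
        self.converged = converged
        self.iterations = iterations
        self.tol = tol

    # -- scoring -------------------------------------------------------
    def link_probability(self, i: str, j: str) -> float:
        """SCM probability of a link between distinct nodes i and j (Eq. above)."""
        if i == j:
            raise ValueError(f"self-interactions are not modelled: {i!r}")
        li, lj = self.lambdas[i], self.lambdas[j]
        s = li + lj
        if np.isinf(s):
            return 0.0 if s > 0 else 1.0
        # 1/(e^s + 1), computed stably
        if s >= 0:
            return float(np.exp(-s) / (1.0 + np.exp(-s)))
        return float(1.0 / (np.exp(s) + 1.0))

    def _lambda_array(self) -> np.ndarray:
        return np.array([self.lambdas[n] for n in self.graph.nodes])

    def bottom_n_pairs(self, n: int) -> List[PairScore]:
        """The n non-edge pairs with the smallest link probability.

        Candidates are all unordered non-self pairs that are not edges of
        the source graph (an observed edge cannot be a negative). Output is
        ascending by p with ties broken by canonical pair order. If fewer
        than n candidates exist, all are returned with a logged warning.
        """
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        g = self.graph
        nodes = g.nodes
        lam = self._lambda_array()
        scored: List[Tuple[float, str, str]] = []
        for i in range(len(nodes)):
            li = lam[i]
            for j in range(i + 1, len(nodes)):
                if nodes[j] in g.neighbors(nodes[i]):
                    continue
                s = li + lam[j]
                if np.isinf(s):
                    p = 0.0 if s > 0 else 1.0
                elif s >= 0:
                    p = float(np.exp(-s) / (1.0 + np.exp(-s)))
                else:
                    p = float(1.0 / (np.exp(s) + 1.0))
                scored.append((p, nodes[i], nodes[j]))
        if len(scored) < n:
            logger.warning("bottom_n_pairs: only %d candidates available (requested %d)",
                           len(scored), n)
            n = len(scored)
        scored.sort()
        return [PairScore((a, b), p) for p, a, b in scored[:n]]

    def expected_degrees(self) -> np.ndarray:
        """Model expected degree per node (aligned to node order)."""
        lam = self._lambda_array()
        finite = np.isfinite(lam)
        exp_deg = np.zeros(len(lam))
        if finite.any():
            x = np.exp(-lam[finite])
            prod = np.outer(x, x)
            p = prod / (1.0 + prod)
            np.fill_diagonal(p, 0.0)
            exp_deg[finite] = p.sum(axis=1)
        return exp_deg

    def summary(self) -> str:
        g = self.graph
        k = g.degree_sequence()
        lines = [
            "Simple Configuration Model (maximum entropy, degree-constrained)",
            "=" * 64,
            f"Nodes:                 {g.n_nodes}",
            f"Edges:                 {g.n_edges}",
            f"Degree-0 nodes:        {int(np.sum(k == 0))}",
            f"Distinct degrees:      {len(np.unique(k[k > 0])) if (k > 0).any() else 0}",
            f"Converged:             {self.converged}",
            f"Iterations:            {self.iterations}",
            f"Max degree residual:   {self.residual:.3e}  (tol {self.tol:.1e})",
        ]
        finite = [v for v in self.lambdas.values() if np.isfinite(v)]
        if finite:
            lines.append(f"lambda range:          [{min(finite):+.4f}, {max(finite):+.4f}]")
        return "\n".join(lines)


def fit_scm(g: Interactome, tol: float = 1e-10, max_iter: int = 5000) -> SCMResults:
    """Fit the configuration model to an interactome (see ConfigurationModel)."""
    return ConfigurationModel(g).fit(tol=tol, max_iter=max_iter)


def link_probability(fit: SCMResults, i: str, j: str) -> float:
    """Convenience wrapper for :meth:`SCMResults.link_probability`."""
    return fit.link_probability(i, j)


def bottom_n_pairs(fit: SCMResults, g: Interactome, n: int) -> List[PairScore]:
    """Convenience wrapper for :meth:`SCMResults.bottom_n_pairs` on its source graph."""
    if g is not fit.graph and frozenset(g.edges) != frozenset(fit.graph.edges):
        raise ValueError("graph does not match the fitted model's source graph")
    return fit.bottom_n_pairs(n)


def graph_digest(g: Interactome) -> str:
    """Stable hex digest of a graph's edge set (provenance tracking)."""
    h = hashlib.sha1()
    for a, b in sorted(g.edges):
        h.update(f"{a}\t{b}\n".encode())
    return h.hexdigest()[:16]
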