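"""Ranking and classification metrics for interaction prediction.

Besides global AUROC/AUPRC, two local ranking metrics quantify a model's
usefulness as a screening tool: PPIHits@TopK is the precision of true
interactions among the K highest-scored pairs, and PPNIHits@BottomK is
the precision of true noninteractions among the K lowest-scored pairs.
At K = n these reduce identically to the class prevalences. Ties in the
ranking are broken by canonical pair order so Hits@K is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import average_precision_score, roc_auc_score

from .l3 import L3Table
from .network import Pair, canonical_pair


@dataclass(frozen=True)
class MetricsReport:
    """Bundle of global and local metrics for one scored pair set."""

    auroc: float
    auprc: float
    ppi_hits: Mapping[int, float] = field(default_factory=dict)
    ppni_hits: Mapping[int, float] = field(default_factory=dict)
    optimal_threshold: Optional[float] = None
    best_f1: Optional[float] = None

    def as_dict(self) -> Dict:
        return {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "ppi_hits": {str(k): v for k, v in self.ppi_hits.items()},
            "ppni_hits": {str(k): v for k, v in self.ppni_hits.items()},
            "optimal_threshold": self.optimal_threshold,
            "best_f1": self.best_f1,
        }


def _aligned(preds: Mapping[Pair, float],
             labels: Mapping[Pair, int]) -> Tuple[List[Pair], np.ndarray, np.ndarray]:
    """Pairs present in both inputs, with score and label arrays aligned."""
    probs = getattr(preds, "probs", preds)
    probs = {canonical_pair(*p): float(v) for p, v in probs.items()}
    lab = {canonical_pair(*p): int(v) for p, v in labels.items()}
    pairs = sorted(p for p in probs if p in lab)
    scores = np.array([probs[p] for p in pairs], dtype=float)
    y = np.array([lab[p] for p in pairs], dtype=int)
    return pairs, scores, y


def ppi_hits_at_top_k(preds: Mapping[Pair, float], labels: Mapping[Pair, int],
                      k: int) -> float:
    """Fraction of the k highest-scored pairs that are true interactions."""
    pairs, scores, y = _aligned(preds, labels)
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the number of scored pairs ({len(pairs)})")
    order = sorted(range(len(pairs)), key=lambda i: (-scores[i], pairs[i]))
    return float(np.mean(y[order[:k]] == 1))


def ppni_hits_at_bottom_k(preds: Mapping[Pair, float], labels: Mapping[Pair, int],
                          k: int) -> float:
    """Fraction of the k lowest-scored pairs that are true noninteractions."""
    pairs, scores, y = _aligned(preds, labels)
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the number of scored pairs ({len(pairs)})")
    order = sorted(range(len(pairs)), key=lambda i: (scores[i], pairs[i]))
    return float(np.mean(y[order[:k]] == 0))


def roc_pr(preds: Mapping[Pair, float], labels: Mapping[Pair, int]) -> Tuple[float, float]:
    """Rank-based AUROC (tie-corrected Mann-Whitney) and step-wise AUPRC."""
    _pairs, scores, y = _aligned(preds, labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present to compute ROC/PR curves")
    return float(roc_auc_score(y, scores)), float(average_precision_score(y, scores))


def optimal_threshold(preds: Mapping[Pair, float], labels: Mapping[Pair, int],
                      grid_step: float = 0.001) -> Tuple[float, float]:
    """Grid-search the classification threshold maximizing F1.

    Thresholds run over the open interval (0, 1) in steps of ``grid_step``;
    a pair is called positive when its score >= threshold. Ties in F1 go
    to the smallest threshold.
    """
    _pairs, scores, y = _aligned(preds, labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present to search a threshold")
    if not 0 < grid_step < 1:
        raise ValueError(f"grid_step must be in (0, 1), got {grid_step}")
    n_pos = int(np.sum(y == 1))
    best_t, best_f1 = None, -1.0
    thresholds = np.arange(grid_step, 1.0, grid_step)
    for t in thresholds:
        pred_pos = scores >= t
        tp = int(np.sum(pred_pos & (y == 1)))
        fp = int(np.sum(pred_pos & (y == 0)))
        fn = n_pos - tp
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom else 0.0
        if f1 > best_f1 + 1e-15:
            best_f1, best_t = f1, float(t)
    return best_t, best_f1


def l3_prediction_correlation(preds: Mapping[Pair, float], l3: L3Table) -> float:
    """Spearman rank correlation between predictions and L3 counts.

    Average-rank tie handling; computed over the pairs present in both
    inputs. A constant input (undefined correlation) returns 0.0 with a
    warning.
    """
    probs = getattr(preds, "probs", preds)
    probs = {canonical_pair(*p): float(v) for p, v in probs.items()}
    shared = sorted(p for p in probs if p in l3)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared pairs, got {len(shared)}")
    x = np.array([probs[p] for p in shared], dtype=float)
    z = np.array([l3[p] for p in shared], dtype=float)
    if np.all(x == x[0]) or np.all(z == z[0]):
        warnings.warn("constant input: Spearman correlation undefined, returning 0.0")
        return 0.0
    rho = spearmanr(x, z).statistic
    return float(rho)


def compute_metrics(preds: Mapping[Pair, float], labels: Mapping[Pair, int],
                    ks: Sequence[int] = (10,),
                    grid_step: float = 0.001) -> MetricsReport:
    """Full metric bundle for one prediction set (Hits only for valid K)."""
    auroc, auprc = roc_pr(preds, labels)
    n = len(getattr(preds, "probs", preds))
    ppi = {k: ppi_hits_at_top_k(preds, labels, k) for k in ks if 0 < k <= n}
    ppni = {k: ppni_hits_at_bottom_k(preds, labels, k) for k in ks if 0 < k <= n}
    thr, f1 = optimal_threshold(preds, labels, grid_step)
    return MetricsReport(auroc=auroc, auprc=auprc, ppi_hits=ppi, ppni_hits=ppni,
                         optimal_threshold=thr, best_f1=f1)
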