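"""In-silico trigram ablation for putative binding-site localization.

Holding the partner protein fixed, each trigram window of the query
protein is replaced (one at a time) by the out-of-vocabulary embedding
before mean pooling, and the pair is re-scored by every cross-validation
fold model. Positions whose ablation depresses the predicted interaction
probability — valleys of the binding-probability profile — mark sequence
regions the decoder relies on, i.e. candidate interaction sites. Valleys
on which the folds agree (low cross-fold standard deviation) are the
higher-confidence calls.

A window at 1-based position p covers residues p..p+2, so a run of valley
windows [p1..p2] is reported as the residue range (p1, p2 + 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .classifier import PairClassifierResults
from .embedding import EmbeddingTable, ProteinSequence, embed_protein, trigrams


@dataclass(frozen=True)
class AblationProfile:
    """Per-position ablated probabilities for one (query, partner) pair.

    ``probs`` has shape (n_folds, L-2): entry [f, p-1] is fold f's
    prediction with the query's window p replaced by the OOV vector.
    ``baseline`` is the unablated prediction per fold.
    """

    query_id: str
    partner_id: str
    positions: Tuple[int, ...]
    probs: np.ndarray
    baseline: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return self.probs.mean(axis=0)

    @property
    def std(self) -> np.ndarray:
        return self.probs.std(axis=0)

    def __len__(self):
        return len(self.positions)

    def to_dataframe(self):
        import pandas as pd

        d = {"position": list(self.positions),
             "mean": self.mean, "std": self.std}
        for f in range(self.probs.shape[0]):
            d[f"fold_{f + 1}"] = self.probs[f]
        return pd.DataFrame(d)

    def plot(self, ax=None):
        """Binding-probability profile with a +/- 1 std band across folds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots(figsize=(8, 3))
        pos = np.asarray(self.positions)
        ax.plot(pos, self.mean, lw=1.2, label="mean ablated probability")
        ax.fill_between(pos, self.mean - self.std, self.mean + self.std, alpha=0.3)
        ax.axhline(float(self.baseline.mean()), ls="--", c="grey", lw=0.8,
                   label="baseline")
        ax.set_xlabel("trigram window position")
        ax.set_ylabel("predicted interaction probability")
        ax.set_title(f"{self.query_id} vs {self.partner_id}")
        ax.legend(fontsize=8)
        return ax


def ablation_profile(models: Sequence[PairClassifierResults],
                     query: ProteinSequence,
                     partner: ProteinSequence,
                     table: EmbeddingTable) -> AblationProfile:
    """Scan the query sequence by OOV ablation against fixed partner.

    Deterministic; a position whose trigram vector already equals the OOV
    vector reproduces the baseline probability exactly.
    """
    if len(query) < 3 or len(partner) < 3:
        raise ValueError("both sequences must have length >= 3")
    if not models:
        raise ValueError("need at least one fold model")
    tg = trigrams(query)
    positions = tuple(pos for pos, _t in tg)
    raw_partner = embed_protein(partner, table)
    raw_query = embed_protein(query, table)
    raw_ablated = [embed_protein(query, table, override={pos: table.oov})
                   for pos in positions]
    n_folds = len(models)
    probs = np.empty((n_folds, len(positions)))
    baseline = np.empty(n_folds)
    # batch: one feature matrix per fold covering all positions (both orders)
    for f, res in enumerate(models):
        emb_partner = res.transform_protein(raw_partner)
        emb_query = res.transform_protein(raw_query)
        ablated = [res.transform_protein(e) for e in raw_ablated]
        # the unablated query rides along as the last row so the baseline
        # goes through the identical batched computation (an identity
        # ablation then reproduces it bit for bit)
        fwd = np.stack([np.concatenate([e, emb_partner])
                        for e in ablated + [emb_query]])
        rev = np.stack([np.concatenate([emb_partner, e])
                        for e in ablated + [emb_query]])
        out = (res.predict_proba_matrix(fwd) + res.predict_proba_matrix(rev)) / 2.0
        probs[f] = out[:-1]
        baseline[f] = float(out[-1])
        # an identity ablation (the window's vector already equals OOV)
        # leaves the embedding unchanged and must reproduce the baseline
        # exactly — short-circuit it past BLAS row-kernel jitter
        for i, e in enumerate(raw_ablated):
            if np.array_equal(e, raw_query):
                probs[f, i] = baseline[f]
    return AblationProfile(query_id=query.id, partner_id=partner.id,
                           positions=positions, probs=probs, baseline=baseline)


def detect_valleys(profile: AblationProfile,
                   smooth_window: int = 5,
                   depth: float = 1.0,
                   consensus: bool = True) -> List[Tuple[int, int]]:
    """Locate valleys in a binding-probability profile.

    The cross-fold mean is smoothed by a centered moving average of odd
    width ``smooth_window``; a valley is a maximal run of positions where
    the smoothed mean falls below (profile mean - depth * profile std).
    With ``consensus``, runs must additionally have mean cross-fold std
    below the profile's median std — the folds must agree. Valleys are
    returned as inclusive 1-based residue ranges (window start .. end + 2).
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError(f"smooth_window must be odd and >= 1, got {smooth_window}")
    mean = profile.mean
    if len(mean) < smooth_window:
        raise ValueError(f"profile length {len(mean)} shorter than smooth_window "
                         f"{smooth_window}")
    if smooth_window == 1:
        smoothed = mean.astype(float)
    else:
        # centered moving average with shrinking windows at the edges
        half = smooth_window // 2
        smoothed = np.array([
            mean[max(0, i - half):i + half + 1].mean() for i in range(len(mean))
        ])
    threshold = float(mean.mean()) - depth * float(mean.std())
    below = smoothed < threshold
    std = profile.std
    median_std = float(np.median(std))
    valleys: List[Tuple[int, int]] = []
    i = 0
    while i < len(below):
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(below) and below[j + 1]:
            j += 1
        if not consensus or float(std[i:j + 1].mean()) < median_std:
            p1, p2 = profile.positions[i], profile.positions[j]
            valleys.append((p1, p2 + 2))
        i = j + 1
    return valleys
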