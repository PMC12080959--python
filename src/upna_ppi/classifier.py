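"""Inductive pair classification: split construction, MLP decoder, training.

The decoder is a 3-hidden-layer perceptron over the concatenated pooled
trigram embeddings of a protein pair, trained with binary cross-entropy.
Evaluation is *inductive*: proteins (not pairs) are divided into disjoint
train/validation/test groups and only pairs whose two endpoints fall in
the same group are kept, so test proteins are never seen during training.

Undirected semantics are enforced by symmetrization: every labelled pair
contributes both concatenation orders to training, and inference averages
the two orders, making predict(a, b) == predict(b, a) exactly.

Early stopping monitors the inductive validation loss; the best-validation
checkpoint is restored at the end of training.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .embedding import EmbeddingTable, ProteinSequence, embed_protein
from .network import ConfigurationError, Pair, canonical_pair

logger = logging.getLogger(__name__)

SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of the pair decoder.

    The architecture is fixed at three hidden layers with a single
    sigmoid output; everything else is configurable. ``alpha`` is the L2
    penalty used for regularization.
    """

    hidden: Tuple[int, int, int] = (256, 64, 16)
    activation: str = "relu"
    alpha: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 512
    max_epochs: int = 200
    patience: int = 5
    calibrate: bool = True
    pca_components: Optional[int] = 10
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden) != 3:
            raise ValueError("the decoder has exactly 3 hidden layers")


@dataclass
class PairDataset:
    """Labelled pairs with an inductive protein-group assignment.

    ``pairs`` holds (protein_a, protein_b, label, source) tuples with both
    endpoints in the same split group; cross-group pairs were dropped and
    counted in ``n_dropped``.
    """

    pairs: List[Tuple[str, str, int, str]]
    split: Mapping[str, str]
    n_dropped: int = 0

    def pairs_in(self, group: str) -> List[Tuple[str, str, int, str]]:
        return [p for p in self.pairs if self.split[p[0]] == group]

    def counts(self) -> Dict[str, Dict[int, int]]:
        """Per-split {label: count} for class-balance reporting."""
        out: Dict[str, Dict[int, int]] = {s: {0: 0, 1: 0} for s in SPLITS}
        for a, b, y, _src in self.pairs:
            out[self.split[a]][y] += 1
        return out

    def proteins(self) -> List[str]:
        seen = set()
        for a, b, _y, _s in self.pairs:
            seen.add(a)
            seen.add(b)
        return sorted(seen)


@dataclass(frozen=True)
class PredictionSet(Mapping[Pair, float]):
    """Canonical pair -> interaction probability (symmetric by construction)."""

    probs: Mapping[Pair, float]
    fold: Optional[int] = None

    def __getitem__(self, pair: Pair) -> float:
        return self.probs[canonical_pair(*pair)]

    def __iter__(self):
        return iter(self.probs)

    def __len__(self):
        return len(self.probs)


# ---------------------------------------------------------------------------
# Inductive split
# ---------------------------------------------------------------------------

def make_inductive_split(proteins: Sequence[str],
                         fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
                         pinned_eval: Iterable[str] = (),
                         seed: int = 0) -> Dict[str, str]:
    """Assign proteins to disjoint train/val/test groups.

    Group sizes are ``floor(fraction * n)`` for val and test with the
    remainder going to train. Proteins in ``pinned_eval`` (e.g. those with
    experimentally validated labels) are placed only in val or test,
    proportionally to the val:test fractions; the rest are assigned by a
    seeded uniform shuffle. Deterministic given ``seed``.
    """
    proteins = sorted(set(proteins))
    n = len(proteins)
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    pinned = sorted(set(pinned_eval))
    unknown = [p for p in pinned if p not in set(proteins)]
    if unknown:
        raise ValueError(f"pinned_eval proteins not in protein list: {unknown[:5]}")
    n_val = int(np.floor(f_val * n))
    n_test = int(np.floor(f_test * n))
    n_train = n - n_val - n_test
    if n_train <= 0:
        raise ConfigurationError("inductive split leaves an empty training group")

    rng = np.random.default_rng(seed)
    split: Dict[str, str] = {}
    # pinned proteins go to val/test only, proportionally
    if pinned:
        order = [pinned[i] for i in rng.permutation(len(pinned))]
        eval_frac = f_val / (f_val + f_test) if (f_val + f_test) > 0 else 0.5
        k_val = int(round(eval_frac * len(order)))
        for p in order[:k_val]:
            split[p] = "val"
        for p in order[k_val:]:
            split[p] = "test"
    rest = [p for p in proteins if p not in split]
    order = [rest[i] for i in rng.permutation(len(rest))]
    need_val = max(0, n_val - sum(1 for v in split.values() if v == "val"))
    need_test = max(0, n_test - sum(1 for v in split.values() if v == "test"))
    for p in order[:need_val]:
        split[p] = "val"
    for p in order[need_val:need_val + need_test]:
        split[p] = "test"
    for p in order[need_val + need_test:]:
        split[p] = "train"
    if not any(v == "train" for v in split.values()):
        raise ConfigurationError("inductive split produced an empty training group")
    return split


def build_pair_dataset(pos: Iterable[Pair], neg: Iterable[Pair],
                       split: Mapping[str, str],
                       pos_source: str = "ppi",
                       neg_source: str = "tppni") -> PairDataset:
    """Label pairs and keep those whose endpoints share a split group.

    Cross-group pairs are dropped (and counted): a pair spanning train and
    test would leak test proteins into training.
    """
    pairs: List[Tuple[str, str, int, str]] = []
    dropped = 0
    for label, src, plist in ((1, pos_source, pos), (0, neg_source, neg)):
        for a, b in plist:
            if a not in split:
                raise KeyError(f"protein {a!r} missing from split assignment")
            if b not in split:
                raise KeyError(f"protein {b!r} missing from split assignment")
            if split[a] == split[b]:
                ca, cb = canonical_pair(a, b)
                pairs.append((ca, cb, label, src))
            else:
                dropped += 1
    if dropped:
        logger.info("build_pair_dataset: dropped %d cross-group pairs", dropped)
    return PairDataset(pairs=pairs, split=dict(split), n_dropped=dropped)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PairClassifier:
    """Pairwise interaction classifier over pooled sequence embeddings.

    Parameters
    ----------
    dataset : PairDataset
        Labelled pairs with their inductive split.
    sequences : mapping or iterable
        Protein sequences (id -> ProteinSequence, or an iterable of them)
        covering every protein in the dataset.
    table : EmbeddingTable
        Trigram embedding table used to pool per-protein vectors.
    spec : ClassifierSpec, optional
    """

    def __init__(self, dataset: PairDataset,
                 sequences: Union[Mapping[str, ProteinSequence], Iterable[ProteinSequence]],
                 table: EmbeddingTable,
                 spec: Optional[ClassifierSpec] = None):
        self.dataset = dataset
        self.table = table
        self.spec = spec or ClassifierSpec()
        if not isinstance(sequences, Mapping):
            sequences = {s.id: s for s in sequences}
        self.sequences: Dict[str, ProteinSequence] = dict(sequences)
        missing = [p for p in dataset.proteins() if p not in self.sequences]
        if missing:
            raise KeyError(f"missing sequences for proteins: {missing[:5]}"
                           + ("..." if len(missing) > 5 else ""))

    # -- features ------------------------------------------------------
    def _embeddings(self) -> Dict[str, np.ndarray]:
        return {pid: embed_protein(seq, self.table)
                for pid, seq in self.sequences.items()}

    @staticmethod
    def _features(pairs: Sequence[Tuple[str, str, int, str]],
                  emb: Mapping[str, np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
        """Both concatenation orders per pair; labels duplicated to match."""
        xs, ys = [], []
        for a, b, y, _src in pairs:
            ea, eb = emb[a], emb[b]
            xs.append(np.concatenate([ea, eb]))
            xs.append(np.concatenate([eb, ea]))
            ys.extend((y, y))
        return np.asarray(xs), np.asarray(ys)

    # -- fitting -------------------------------------------------------
    def fit(self) -> "PairClassifierResults":
        spec = self.spec
        train_pairs = self.dataset.pairs_in("train")
        val_pairs = self.dataset.pairs_in("val")
        if not train_pairs or not val_pairs:
            raise ConfigurationError("train and val splits must both be nonempty")
        if len({y for _a, _b, y, _s in train_pairs}) < 2:
            raise ConfigurationError("training set contains a single class")
        if len({y for _a, _b, y, _s in val_pairs}) < 2:
            raise ConfigurationError("validation set contains a single class")
        emb = self._embeddings()
        pca = None
        if spec.pca_components:
            # project per-protein embeddings onto the training proteins'
            # principal subspace: perturbations along directions the
            # training data never populated cannot reach the decoder
            from sklearn.decomposition import PCA

            train_prot = sorted({p for a, b, _y, _s in train_pairs for p in (a, b)})
            mat = np.stack([emb[p] for p in train_prot])
            n_comp = min(spec.pca_components, mat.shape[1], len(train_prot))
            pca = PCA(n_components=n_comp, random_state=spec.seed).fit(mat)
            emb = {p: pca.transform(v[None, :])[0] for p, v in emb.items()}
        x_train, y_train = self._features(train_pairs, emb)
        x_val, y_val = self._features(val_pairs, emb)
        # pooled embeddings sit on a large compositional offset with small
        # variance; standardize on the training features only
        scaler = StandardScaler().fit(x_train)
        x_train = scaler.transform(x_train)
        x_val = scaler.transform(x_val)

        mlp = MLPClassifier(
            hidden_layer_sizes=tuple(spec.hidden),
            activation=spec.activation,
            solver="adam",
            alpha=spec.alpha,
            batch_size=min(spec.batch_size, len(x_train)),
            learning_rate_init=spec.learning_rate,
            max_iter=1,
            shuffle=True,
            random_state=spec.seed,
        )
        classes = np.array([0, 1])
        best_loss = np.inf
        best_weights = None
        best_epoch = 0
        since_best = 0
        history = {"train_loss": [], "val_loss": []}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            for epoch in range(1, spec.max_epochs + 1):
                mlp.partial_fit(x_train, y_train, classes=classes)
                val_loss = log_loss(y_val, mlp.predict_proba(x_val)[:, 1], labels=classes)
                history["train_loss"].append(float(mlp.loss_))
                history["val_loss"].append(float(val_loss))
                if val_loss < best_loss - 1e-12:
                    best_loss = val_loss
                    best_epoch = epoch
                    best_weights = (copy.deepcopy(mlp.coefs_), copy.deepcopy(mlp.intercepts_))
                    since_best = 0
                else:
                    since_best += 1
                    if since_best > spec.patience:
                        break
        if best_weights is not None:
            mlp.coefs_, mlp.intercepts_ = best_weights
        history["best_epoch"] = best_epoch
        history["n_epochs"] = len(history["val_loss"])
        history["best_val_loss"] = float(best_loss)
        calibration = None
        if spec.calibrate:
            # Platt-style temperature scaling fitted on the validation set:
            # restores dynamic range to overconfident outputs (monotone, so
            # rankings and AUROC are untouched)
            calibration = _fit_calibration(
                mlp.predict_proba(x_val)[:, 1], y_val)
            history["calibration"] = calibration
        return PairClassifierResults(self, mlp, emb, history, scaler=scaler,
                                     calibration=calibration, pca=pca)


_LOGIT_EPS = 1e-12


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _LOGIT_EPS, 1.0 - _LOGIT_EPS)
    return np.log(p / (1.0 - p))


def _fit_calibration(p_val: np.ndarray, y_val: np.ndarray) -> Tuple[float, float]:
    """Fit sigmoid(a*logit + b) with a > 0 by minimizing validation NLL."""
    from scipy.optimize import minimize

    z = _logit(np.asarray(p_val, dtype=float))
    y = np.asarray(y_val, dtype=float)

    def nll(params):
        a = np.exp(params[0])
        q = 1.0 / (1.0 + np.exp(-(a * z + params[1])))
        q = np.clip(q, _LOGIT_EPS, 1.0 - _LOGIT_EPS)
        return -np.mean(y * np.log(q) + (1 - y) * np.log(1 - q))

    res = minimize(nll, x0=np.array([0.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 500})
    return float(np.exp(res.x[0])), float(res.x[1])


class PairClassifierResults:
    """A fitted pair classifier: checkpointed decoder plus training history."""

    def __init__(self, model: PairClassifier, mlp: MLPClassifier,
                 embeddings: Dict[str, np.ndarray], history: Dict,
                 scaler: Optional[StandardScaler] = None,
                 calibration: Optional[Tuple[float, float]] = None,
                 pca=None):
        self.model = model
        self.mlp = mlp
        self.embeddings = embeddings  # already PCA-projected when pca is set
        self.history = history
        self.scaler = scaler
        self.calibration = calibration
        self.pca = pca

    def transform_protein(self, vec: np.ndarray) -> np.ndarray:
        """Project a raw pooled embedding into the decoder's input space."""
        if self.pca is not None:
            return self.pca.transform(vec[None, :])[0]
        return vec

    @property
    def dataset(self) -> PairDataset:
        return self.model.dataset

    # -- prediction ----------------------------------------------------
    def predict_from_embeddings(self, emb_a: np.ndarray, emb_b: np.ndarray) -> float:
        """Order-symmetrized probability from two pooled protein vectors."""
        x = np.stack([np.concatenate([emb_a, emb_b]), np.concatenate([emb_b, emb_a])])
        p = self.predict_proba_matrix(x)
        return float(p.mean())

    def predict_proba_matrix(self, x: np.ndarray) -> np.ndarray:
        if self.scaler is not None:
            x = self.scaler.transform(x)
        p = self.mlp.predict_proba(x)[:, 1]
        if self.calibration is not None:
            a, b = self.calibration
            p = 1.0 / (1.0 + np.exp(-(a * _logit(p) + b)))
        return p

    def predict_pairs(self, pairs: Iterable[Pair],
                      sequences: Optional[Mapping[str, ProteinSequence]] = None,
                      fold: Optional[int] = None) -> PredictionSet:
        """Probability per pair (batched; order-symmetrized).

        Unseen proteins are embedded on the fly from ``sequences`` (or the
        model's own sequence map). Missing sequences raise KeyError listing
        the offenders.
        """
        pairs = [canonical_pair(a, b) for a, b in pairs]
        seqmap = dict(self.model.sequences)
        if sequences:
            seqmap.update(sequences)
        needed = sorted({p for ab in pairs for p in ab})
        missing = [p for p in needed
                   if p not in self.embeddings and p not in seqmap]
        if missing:
            raise KeyError(f"no sequence/embedding for proteins: {missing[:5]}"
                           + ("..." if len(missing) > 5 else ""))
        emb = dict(self.embeddings)
        for p in needed:
            if p not in emb:
                emb[p] = self.transform_protein(embed_protein(seqmap[p], self.model.table))
        if not pairs:
            return PredictionSet({}, fold=fold)
        fwd = np.stack([np.concatenate([emb[a], emb[b]]) for a, b in pairs])
        rev = np.stack([np.concatenate([emb[b], emb[a]]) for a, b in pairs])
        p = (self.predict_proba_matrix(fwd) + self.predict_proba_matrix(rev)) / 2.0
        return PredictionSet({pair: float(pi) for pair, pi in zip(pairs, p)}, fold=fold)

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint the fitted decoder (joblib) with its spec and history."""
        import joblib

        joblib.dump({"mlp": self.mlp, "spec": self.model.spec.__dict__,
                     "history": self.history, "embeddings": self.embeddings,
                     "scaler": self.scaler, "calibration": self.calibration,
                     "pca": self.pca}, path)

    @staticmethod
    def load(path, model: Optional["PairClassifier"] = None) -> "PairClassifierResults":
        """Load a checkpoint; a dataset-less stub model is built if none given."""
        import joblib

        payload = joblib.load(path)
        if model is None:
            model = PairClassifier.__new__(PairClassifier)
            model.dataset = PairDataset(pairs=[], split={})
            model.table = None
            spec_d = dict(payload["spec"])
            spec_d["hidden"] = tuple(spec_d["hidden"])
            model.spec = ClassifierSpec(**spec_d)
            model.sequences = {}
        return PairClassifierResults(model, payload["mlp"], payload["embeddings"],
                                     payload["history"], scaler=payload.get("scaler"),
                                     calibration=payload.get("calibration"),
                                     pca=payload.get("pca"))

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        counts = self.dataset.counts()
        h = self.history
        lines = [
            "Pairwise interaction classifier (3-hidden-layer MLP decoder)",
            "=" * 64,
            f"Hidden sizes:        {self.model.spec.hidden}",
            f"Epochs run:          {h['n_epochs']}  (best at {h['best_epoch']})",
            f"Best val loss:       {h['best_val_loss']:.4f}",
            f"Dropped cross-group: {self.dataset.n_dropped}",
            "Split      pos    neg",
        ]
        for s in SPLITS:
            lines.append(f"  {s:<8} {counts[s][1]:>5}  {counts[s][0]:>5}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def train_classifier(data: PairDataset,
                     sequences: Union[Mapping[str, ProteinSequence], Iterable[ProteinSequence]],
                     table: EmbeddingTable,
                     spec: Optional[ClassifierSpec] = None) -> PairClassifierResults:
    """Fit the pair decoder; the returned results carry the training history."""
    return PairClassifier(data, sequences, table, spec).fit()


def predict_pairs(results: PairClassifierResults, pairs: Iterable[Pair],
                  sequences: Optional[Mapping[str, ProteinSequence]] = None) -> PredictionSet:
    return results.predict_pairs(pairs, sequences=sequences)


def crossvalidate(pos: Sequence[Pair], neg: Sequence[Pair],
                  sequences: Union[Mapping[str, ProteinSequence], Iterable[ProteinSequence]],
                  table: EmbeddingTable,
                  spec: Optional[ClassifierSpec] = None,
                  k: int = 5,
                  seeds: Optional[Sequence[int]] = None,
                  fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
                  pinned_eval: Iterable[str] = (),
                  hits_ks: Sequence[int] = (10,)):
    """k-fold inductive cross-validation with protein-level re-draws.

    Each fold draws a fresh inductive split (seeded), trains, and scores
    its own test pairs. Returns a list of (fold, PredictionSet,
    MetricsReport) enabling cross-fold mean +/- std reporting.
    """
    from .evaluation import compute_metrics

    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if seeds is None:
        seeds = list(range(k))
    if len(seeds) != k:
        raise ValueError(f"need {k} seeds, got {len(seeds)}")
    if not isinstance(sequences, Mapping):
        sequences = {s.id: s for s in sequences}
    spec = spec or ClassifierSpec()
    proteins = sorted({p for ab in list(pos) + list(neg) for p in ab})
    out = []
    for fold in range(k):
        split = make_inductive_split(proteins, fractions, pinned_eval, seed=seeds[fold])
        data = build_pair_dataset(pos, neg, split)
        fold_spec = ClassifierSpec(**{**spec.__dict__, "seed": spec.seed + fold})
        res = train_classifier(data, sequences, table, fold_spec)
        test_pairs = data.pairs_in("test")
        preds = res.predict_pairs([(a, b) for a, b, _y, _s in test_pairs], fold=fold)
        labels = {canonical_pair(a, b): y for a, b, y, _s in test_pairs}
        metrics = compute_metrics(preds, labels, ks=hits_ks)
        out.append((fold, preds, metrics, res))
    return out


def assert_inductive_purity(data: PairDataset) -> None:
    """Raise if any test protein appears in a training pair (leak check)."""
    test_proteins = {p for p, s in data.split.items() if s == "test"}
    for a, b, _y, _src in data.pairs_in("train"):
        if a in test_proteins or b in test_proteins:
            raise AssertionError(f"inductive leak: test protein in training pair ({a}, {b})")
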