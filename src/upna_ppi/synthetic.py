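"""Synthetic fixtures with the statistical structure the method assumes.

The generator plants a latent *complementarity* rule: every protein
carries a binary key and a binary lock, and an interaction is possible
only when one protein's key engages the other's lock — by default when
they co-occur on at least ``threshold`` feature positions
(``key_i . lock_j >= t``), or optionally only on an exact bitwise
complement match. Compatible pairs are connected with probability
``density`` (the observed interactome is an incomplete sample of the
true one) and incompatible pairs with probability ``noise``. Because the
rule is bipartite-like, the resulting network is enriched in 4-cycles
(L3 paths) exactly as complementarity-driven networks are — the
signature that topological negative sampling exploits.

Sequences encode the latent bits inside a single contiguous motif
window: each (role, bit-index) owns one reserved amino-acid letter and
one motif slot, written when the bit is 1 and filled with a shared
null letter when it is 0 (presence/absence coding with constant slot
occupancy). Slots are separated by
random spacer residues from the non-reserved background alphabet, so
the trigram *context* of every bit letter is protein-specific: the
planted signal survives mean pooling only through a compositionally
smooth embedding table (like the pre-trained trigram tables the
pipeline uses in production) and is destroyed by i.i.d.
re-randomization — the property the embedding-dependence control
measures.

The synthetic embedding table is compositional for the same reason:
v(abc) = (e(a) + e(b) + e(c)) / sqrt(3) + sigma * xi_abc with Gaussian
letter vectors e and a small per-trigram Gaussian residual.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .embedding import EmbeddingTable, ProteinSequence
from .network import Interactome, Pair

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_RESERVED_POOL = "ACDEFGHI"  # one letter per (role, bit); the rest is background
_NULL_LETTER = "K"           # fills a slot whose bit is 0


class GenerationError(ValueError):
    """Degenerate generator parameters (e.g. no positive or negative pairs)."""


@dataclass(frozen=True)
class ComplementarityModel:
    """Parameters of the planted key/lock network generator.

    density is the probability that a rule-compatible pair is observed as
    an edge (interactome incompleteness); noise is the false-positive
    edge probability for incompatible pairs.
    """

    n_proteins: int = 300
    n_features: int = 4
    density: float = 0.3
    noise: float = 0.0
    rule: str = "dot_threshold"
    threshold: int = 3
    balanced_codes: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")
        if not 1 <= self.n_features <= 4:
            raise ValueError("n_features must be in 1..4 (letter-coded bits)")
        if not 0.0 <= self.density <= 1.0 or not 0.0 <= self.noise <= 1.0:
            raise ValueError("density and noise must be probabilities")
        if self.rule not in ("dot_threshold", "exact_complement"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.rule == "dot_threshold" and not 1 <= self.threshold <= self.n_features:
            raise ValueError("threshold must be in 1..n_features")


@dataclass
class PlantedTruth:
    """Ground truth of a generated fixture.

    positives are all rule-compatible pairs (interaction possible);
    hard_negatives are all rule-incompatible pairs. Motif positions are
    recorded by generate_sequences (1-based start residue).
    """

    keys: np.ndarray
    locks: np.ndarray
    node_ids: Tuple[str, ...]
    positives: Tuple[Pair, ...]
    hard_negatives: Tuple[Pair, ...]
    seed: int
    rule: str = "dot_threshold"
    threshold: int = 3
    motif_start: Dict[str, int] = field(default_factory=dict)
    motif: Dict[str, str] = field(default_factory=dict)

    @property
    def motif_length(self) -> int:
        return 6 * self.keys.shape[1] - 2

    def is_compatible(self, a: str, b: str) -> bool:
        ids = {n: i for i, n in enumerate(self.node_ids)}
        i, j = ids[a], ids[b]
        if self.rule == "exact_complement":
            return bool(np.all(self.keys[i] == 1 - self.locks[j])
                        or np.all(self.keys[j] == 1 - self.locks[i]))
        return bool(self.keys[i] @ self.locks[j] >= self.threshold
                    or self.keys[j] @ self.locks[i] >= self.threshold)


def generate_network(model: ComplementarityModel) -> Tuple[Interactome, PlantedTruth]:
    """Sample a planted complementarity network and its ground truth.

    Key and lock codes are value-balanced by default (every code value
    about equally popular, so degree cannot act as a sequence-correlated
    shortcut) or i.i.d. Bernoulli(1/2) with ``balanced_codes=False``.
    Deterministic given ``model.seed``. Raises GenerationError if either
    the compatible or the incompatible pair set is empty.
    """
    rng = np.random.default_rng(model.seed)
    n, f = model.n_proteins, model.n_features
    if model.balanced_codes:
        # near-uniform code marginals: every key (and lock) value is about
        # equally popular, so no protein is topologically privileged by its
        # code and degree cannot act as a sequence-correlated shortcut
        keys = _balanced_codes(n, f, rng)
        locks = _balanced_codes(n, f, rng)
    else:
        keys = rng.integers(0, 2, size=(n, f))
        locks = rng.integers(0, 2, size=(n, f))
    ids = tuple(f"P{i:04d}" for i in range(n))

    if model.rule == "exact_complement":
        weights = 1 << np.arange(f)
        key_code = keys @ weights
        lockc_code = (1 - locks) @ weights
        match = key_code[:, None] == lockc_code[None, :]
    else:
        # key_i engages lock_j when enough feature positions co-occur
        match = (keys @ locks.T) >= model.threshold
    compat = match | match.T
    np.fill_diagonal(compat, False)

    iu, ju = np.triu_indices(n, k=1)
    is_compat = compat[iu, ju]
    if not is_compat.any() or is_compat.all():
        raise GenerationError("degenerate parameters: need both compatible and "
                              "incompatible pairs")
    u = rng.random(len(iu))
    p_edge = np.where(is_compat, model.density, model.noise)
    has_edge = u < p_edge
    edges = [(ids[i], ids[j]) for i, j, e in zip(iu, ju, has_edge) if e]
    positives = tuple((ids[i], ids[j]) for i, j, c in zip(iu, ju, is_compat) if c)
    negatives = tuple((ids[i], ids[j]) for i, j, c in zip(iu, ju, is_compat) if not c)
    graph = Interactome.from_edges(edges, nodes=ids)
    truth = PlantedTruth(keys=keys, locks=locks, node_ids=ids, positives=positives,
                         hard_negatives=negatives, seed=model.seed,
                         rule=model.rule, threshold=model.threshold)
    return graph, truth


def _balanced_codes(n: int, f: int, rng: np.random.Generator) -> np.ndarray:
    """n codewords of f bits with each of the 2^f values appearing ~n/2^f times."""
    n_codes = 1 << f
    values = np.tile(np.arange(n_codes), n // n_codes + 1)[:n]
    values = values[rng.permutation(n)]
    return (values[:, None] >> np.arange(f)) & 1


def _bit_letters(n_features: int) -> Tuple[List[str], List[str]]:
    """One reserved letter per bit, for key then lock roles.

    A bit of value 1 writes its letter into the motif slot; a bit of
    value 0 writes the shared null letter instead (presence/absence
    coding with a constant slot occupancy).
    """
    pool = _RESERVED_POOL[:2 * n_features]
    return list(pool[:n_features]), list(pool[n_features:])


def reserved_letters(n_features: int = 4) -> str:
    return _RESERVED_POOL[:2 * n_features] + _NULL_LETTER


def generate_sequences(truth: PlantedTruth, length: int = 120,
                       alphabet: str = AMINO_ACIDS,
                       seed: Optional[int] = None) -> List[ProteinSequence]:
    """Write each protein's key/lock into a random-position sequence motif.

    The 2f bit slots sit three residues apart inside one contiguous
    motif window whose (1-based) start is drawn per protein and recorded
    in ``truth.motif_start`` along with the realized motif string; a
    slot holds its bit's reserved letter when the bit is 1 and the
    shared null letter otherwise. All remaining residues — spacers and
    flanks — come from a *balanced* multiset of
    the non-reserved background letters in seeded random order, and the
    terminal two residues on each side are fixed pads, so
    pooled-embedding differences reflect the planted bits (and residue
    order) rather than compositional fingerprints. Deterministic given
    ``seed`` (default ``truth.seed + 1``).
    """
    f = truth.keys.shape[1]
    motif_len = 6 * f - 2
    if length < motif_len + 6:
        raise ValueError(f"length must be >= motif length + 6 = {motif_len + 6}")
    key_letters, lock_letters = _bit_letters(f)
    reserved = set(reserved_letters(f))
    background = [a for a in alphabet if a not in reserved]
    if not background:
        raise ValueError("alphabet leaves no background letters")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    # fixed terminal pads keep every informative letter fully interior
    # (covered by exactly 3 trigram windows) for all proteins alike
    pad_n = (background * 2)[:2]
    pad_c = (background * 2)[2:4] if len(background) >= 4 else (background * 2)[:2]
    n_bg = length - 4 - 2 * f
    bg_pool = np.array((background * (n_bg // len(background) + 1))[:n_bg])
    out: List[ProteinSequence] = []
    for i, pid in enumerate(truth.node_ids):
        slots = [key_letters[b] if truth.keys[i, b] else _NULL_LETTER for b in range(f)] + \
                [lock_letters[b] if truth.locks[i, b] else _NULL_LETTER for b in range(f)]
        start0 = int(rng.integers(2, length - motif_len - 1))
        bit_pos = {start0 + 3 * bi: letter for bi, letter in enumerate(slots)}
        bg = bg_pool[rng.permutation(n_bg)]
        seq: List[str] = []
        b_idx = 0
        for pos in range(length):
            if pos < 2:
                seq.append(pad_n[pos])
            elif pos >= length - 2:
                seq.append(pad_c[pos - (length - 2)])
            elif pos in bit_pos:
                seq.append(bit_pos[pos])
            else:
                seq.append(str(bg[b_idx]))
                b_idx += 1
        s = "".join(seq)
        truth.motif_start[pid] = start0 + 1
        truth.motif[pid] = s[start0:start0 + motif_len]
        out.append(ProteinSequence(pid, s))
    return out


def generate_embedding_table(alphabet: str = AMINO_ACIDS, dim: int = 16,
                             seed: int = 0,
                             residual_scale: float = 0.05,
                             letter_scale: Optional[Dict[str, float]] = None
                             ) -> EmbeddingTable:
    """Complete seeded-Gaussian trigram table over ``alphabet``.

    Vectors are compositional — v(abc) = (e(a)+e(b)+e(c))/sqrt(3) plus a
    per-trigram Gaussian residual of scale ``residual_scale`` — so that,
    as in pre-trained trigram embeddings, compositionally similar
    trigrams lie close together. ``letter_scale`` optionally shrinks or
    stretches individual letters' vectors (chemically bland residues
    cluster together; distinctive ones stand apart). The OOV vector is
    the table mean.
    """
    if dim < 2:
        raise ValueError(f"dim must be >= 2, got {dim}")
    rng = np.random.default_rng(seed)
    letters = sorted(set(alphabet))
    scale = letter_scale or {}
    e = {a: rng.normal(size=dim) * scale.get(a, 1.0) for a in letters}
    tokens = ["".join(t) for t in itertools.product(letters, repeat=3)]
    resid = rng.normal(size=(len(tokens), dim)) * residual_scale
    vectors = {t: (e[t[0]] + e[t[1]] + e[t[2]]) / np.sqrt(3.0) + resid[k]
               for k, t in enumerate(tokens)}
    return EmbeddingTable.from_vectors(vectors)


# ---------------------------------------------------------------------------
# Bundled fixture
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A complete synthetic study: network, truth, sequences, embeddings."""

    graph: Interactome
    truth: PlantedTruth
    sequences: Dict[str, ProteinSequence]
    table: EmbeddingTable
    model: ComplementarityModel


def make_fixture(seed: int = 0, model: Optional[ComplementarityModel] = None,
                 length: int = 120, dim: int = 16,
                 background_letter_scale: float = 0.1) -> Fixture:
    """Generate the default fixture bundle for one seed.

    The embedding table marks the fixture's reserved (motif) letters as
    chemically distinctive — full-scale vectors — while background
    letters cluster at ``background_letter_scale`` of that spread,
    mirroring how pre-trained tables separate distinctive residues from
    bland scaffold ones.
    """
    if model is None:
        model = ComplementarityModel(seed=seed)
    graph, truth = generate_network(model)
    seqs = generate_sequences(truth, length=length)
    reserved = set(reserved_letters(model.n_features))
    scale = {a: (1.0 if a in reserved else background_letter_scale)
             for a in AMINO_ACIDS}
    table = generate_embedding_table(dim=dim, seed=model.seed + 7919,
                                     letter_scale=scale)
    return Fixture(graph=graph, truth=truth,
                   sequences={s.id: s for s in seqs}, table=table, model=model)


def write_fixture(fixture: Fixture, out_dir) -> None:
    """Write edges.tsv, sequences.fasta, embeddings.txt and truth.json."""
    import os

    from .embedding import write_embedding_table, write_fasta
    from .network import write_edge_list

    os.makedirs(out_dir, exist_ok=True)
    write_edge_list(fixture.graph, os.path.join(out_dir, "edges.tsv"))
    write_fasta(fixture.sequences.values(), os.path.join(out_dir, "sequences.fasta"))
    write_embedding_table(fixture.table, os.path.join(out_dir, "embeddings.txt"))
    truth = fixture.truth
    payload = {
        "seed": truth.seed,
        "n_features": int(truth.keys.shape[1]),
        "keys": truth.keys.tolist(),
        "locks": truth.locks.tolist(),
        "node_ids": list(truth.node_ids),
        "positives": [list(p) for p in truth.positives],
        "hard_negatives_count": len(truth.hard_negatives),
        "motif_start": truth.motif_start,
        "motif": truth.motif,
    }
    with open(os.path.join(out_dir, "truth.json"), "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
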