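"""Protein sequences, trigram embedding tables, and pooled protein vectors.

A protein is represented by the mean of the embedding vectors of its
*overlapping* amino-acid trigrams (windows at 1-based start positions
1..L-2). Trigram vectors come from a word2vec-style table (100-dimensional
in the pre-trained ProtVec tables; synthetic tables of any dimension work
identically). Trigrams absent from the table — including any containing
nonstandard residues such as X, U or B — map to the out-of-vocabulary
(OOV) vector, defined as the element-wise mean of all trigram vectors.

Positional overrides of individual trigram vectors before pooling are the
mechanism behind in-silico ablation scanning (see ``interpret``): residue r
is covered by the windows max(1, r-2)..min(L-2, r).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)


class EmbeddingParseError(ValueError):
    """Malformed word2vec text table (carries the line number)."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence (uppercase-normalized)."""

    id: str
    residues: str

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self):
        return len(self.residues)


@dataclass(frozen=True)
class EmbeddingTable:
    """A trigram -> vector table with a shared dimension and an OOV vector."""

    dim: int
    vectors: Mapping[str, np.ndarray]
    oov: np.ndarray

    @staticmethod
    def from_vectors(vectors: Mapping[str, np.ndarray]) -> "EmbeddingTable":
        """Build a table, computing the OOV vector as the mean of all entries."""
        if not vectors:
            raise ValueError("embedding table must contain at least one trigram")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions: {sorted(dims)}")
        dim = dims.pop()
        arr = {t: np.asarray(v, dtype=np.float64) for t, v in vectors.items()}
        oov = np.mean(np.stack(list(arr.values())), axis=0)
        return EmbeddingTable(dim=dim, vectors=arr, oov=oov)

    def lookup(self, trigram: str) -> np.ndarray:
        """Vector for a trigram; the OOV vector for unknown trigrams."""
        return self.vectors.get(trigram, self.oov)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> List[ProteinSequence]:
    """Read a FASTA file; ids are the first whitespace token of each header.

    Records with empty sequences are skipped with a warning.
    """
    out: List[ProteinSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).strip()
        if not seq:
            warnings.warn(f"skipping FASTA record {rec.id!r}: empty sequence")
            continue
        out.append(ProteinSequence(rec.id, seq))
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i:i + 60] + "\n")


def read_embedding_table(path) -> EmbeddingTable:
    """Read a word2vec text-format table: header "V D", then V token rows.

    Duplicate tokens: last occurrence wins, with a warning. Rows whose
    width disagrees with the header raise :class:`EmbeddingParseError`
    with the offending line number.
    """
    vectors: Dict[str, np.ndarray] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        parts = header.split()
        if len(parts) != 2:
            raise EmbeddingParseError(f"{path}:1: expected header 'V D', got {header!r}")
        try:
            n_tokens, dim = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise EmbeddingParseError(f"{path}:1: non-integer header fields") from exc
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.split()
            if len(fields) != dim + 1:
                raise EmbeddingParseError(
                    f"{path}:{lineno}: expected 1 token + {dim} values, got {len(fields)} fields")
            token = fields[0]
            try:
                vec = np.array([float(v) for v in fields[1:]], dtype=np.float64)
            except ValueError as exc:
                raise EmbeddingParseError(f"{path}:{lineno}: non-numeric value") from exc
            if token in vectors:
                warnings.warn(f"duplicate trigram {token!r} at line {lineno}; last wins")
            vectors[token] = vec
    if len(vectors) != n_tokens:
        logger.info("read_embedding_table(%s): header declared %d tokens, read %d",
                    path, n_tokens, len(vectors))
    return EmbeddingTable.from_vectors(vectors)


def write_embedding_table(table: EmbeddingTable, path) -> None:
    """Write a table in word2vec text format (sorted tokens, no OOV row)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dim}\n")
        for token in sorted(table.vectors):
            vals = " ".join(f"{v:.8g}" for v in table.vectors[token])
            fh.write(f"{token} {vals}\n")


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

def trigrams(seq: ProteinSequence) -> List[Tuple[int, str]]:
    """Overlapping trigrams with 1-based window-start positions (1..L-2)."""
    s = seq.residues if isinstance(seq, ProteinSequence) else str(seq).upper()
    if len(s) < 3:
        raise ValueError(f"sequence too short for trigrams (length {len(s)} < 3)")
    return [(i + 1, s[i:i + 3]) for i in range(len(s) - 2)]


def embed_protein(seq: ProteinSequence, table: EmbeddingTable,
                  override: Optional[Mapping[int, np.ndarray]] = None) -> np.ndarray:
    """Mean-pooled trigram embedding of a protein.

    ``override`` replaces the vector at the given 1-based window positions
    before averaging (used for in-silico ablation).
    """
    tg = trigrams(seq)
    rows = np.empty((len(tg), table.dim), dtype=np.float64)
    for r, (pos, t) in enumerate(tg):
        if override is not None and pos in override:
            rows[r] = override[pos]
        else:
            rows[r] = table.lookup(t)
    return rows.mean(axis=0)


def randomize_table(table: EmbeddingTable, seed: int) -> EmbeddingTable:
    """Replace every trigram vector with i.i.d. U[0,1] entries (same tokens).

    This destroys the table's semantic structure while keeping a valid
    table, and is the control for embedding-dependence experiments; the
    OOV vector is recomputed as the new mean. Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    tokens = sorted(table.vectors)
    mat = rng.uniform(0.0, 1.0, size=(len(tokens), table.dim))
    return EmbeddingTable.from_vectors({t: mat[i] for i, t in enumerate(tokens)})


def embed_all(seqs: Iterable[ProteinSequence], table: EmbeddingTable) -> Dict[str, np.ndarray]:
    """Embed every sequence; returns id -> pooled vector."""
    return {s.id: embed_protein(s, table) for s in seqs}
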