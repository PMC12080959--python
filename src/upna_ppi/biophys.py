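"""Physicochemical and latent-geometry diagnostics for negative samples.

Interacting proteins tend to be complementary: hydrophobic patches match
hydrophobic patches, and opposite net charges attract. Hard negative
pairs should therefore show hydrophobic *mismatch* and same-sign charge
products. This module provides the per-protein scores (GRAVY hydropathy,
net side-chain charge at pH 7), pairwise products, and utilities on 2D
hyperbolic (r, theta) coordinates produced by an external network
embedder (geodesic distances; midpoint "edge" embeddings).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .embedding import ProteinSequence
from .network import Pair

TWO_PI = 2.0 * math.pi

# EMBOSS side-chain pKa values; termini (amine 8.6, carboxyl 3.6) optional.
EMBOSS_PKA = {"C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1}
PKA_NTERM = 8.6
PKA_CTERM = 3.6
_POSITIVE = {"K", "R", "H"}


@dataclass(frozen=True)
class BiophysScore:
    """Per-protein hydropathy and charge summary."""

    gravy: float
    charge_ph7: float


@dataclass(frozen=True)
class HyperbolicCoord:
    """A point of the hyperbolic plane in native polar coordinates.

    ``r`` is the hyperbolic distance from the disc centre (evolutionarily
    older, better-connected proteins sit closer to the centre); ``theta``
    (normalized to [0, 2*pi)) tracks protein similarity/family.
    """

    r: float
    theta: float

    def __post_init__(self):
        if self.r < 0:
            raise ValueError(f"radial coordinate must be >= 0, got {self.r}")
        object.__setattr__(self, "theta", float(self.theta) % TWO_PI)


def _residues(seq) -> str:
    return seq.residues if isinstance(seq, ProteinSequence) else str(seq).upper()


def gravy(seq) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue.

    Positive scores are hydrophobic, negative hydrophilic. Residues
    outside the 20-letter alphabet are skipped with a warning.
    """
    res = _residues(seq)
    if not res:
        raise ValueError("cannot score an empty sequence")
    values = [KYTE_DOOLITTLE[a] for a in res if a in KYTE_DOOLITTLE]
    skipped = len(res) - len(values)
    if skipped:
        warnings.warn(f"gravy: skipped {skipped} nonstandard residue(s)")
    if not values:
        raise ValueError("no scorable residues in sequence")
    return float(np.mean(values))


def net_charge_ph7(seq, ph: float = 7.0,
                   pka: Optional[Mapping[str, float]] = None,
                   include_termini: bool = False) -> float:
    """Net charge from Henderson-Hasselbalch sums over ionizable side chains.

    Basic side chains (K, R, H) contribute +1/(1 + 10^(pH - pKa)); acidic
    ones (D, E, C, Y) contribute -1/(1 + 10^(pKa - pH)). Termini are
    excluded by default (negligible for whole proteins; set
    ``include_termini`` to add the EMBOSS terminal groups).
    """
    res = _residues(seq)
    if not res:
        raise ValueError("cannot score an empty sequence")
    table = dict(EMBOSS_PKA if pka is None else pka)
    charge = 0.0
    for a in res:
        if a not in table:
            continue
        if a in _POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (ph - table[a]))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (table[a] - ph))
    if include_termini:
        charge += 1.0 / (1.0 + 10.0 ** (ph - PKA_NTERM))
        charge -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM - ph))
    return charge


def biophys_scores(seqs: Iterable[ProteinSequence]) -> Dict[str, BiophysScore]:
    return {s.id: BiophysScore(gravy(s), net_charge_ph7(s)) for s in seqs}


def pair_product(scores: Mapping[str, float], pairs: Sequence[Pair]) -> List[float]:
    """Per-pair product score_a * score_b (order preserved).

    Same-sign inputs give positive products (repulsion for charges,
    matched hydropathy); opposite signs give negative products.
    """
    out = []
    for a, b in pairs:
        if a not in scores:
            raise KeyError(f"no score for protein {a!r}")
        if b not in scores:
            raise KeyError(f"no score for protein {b!r}")
        out.append(scores[a] * scores[b])
    return out


# ---------------------------------------------------------------------------
# Hyperbolic-plane utilities
# ---------------------------------------------------------------------------

def hyperbolic_distance(p: HyperbolicCoord, q: HyperbolicCoord) -> float:
    """Geodesic distance in the native hyperbolic disc.

    cosh d = cosh r_p cosh r_q - sinh r_p sinh r_q cos(dtheta), with
    dtheta the angular separation folded to [0, pi].
    """
    dtheta = abs(p.theta - q.theta)
    if dtheta > math.pi:
        dtheta = TWO_PI - dtheta
    arg = math.cosh(p.r) * math.cosh(q.r) - math.sinh(p.r) * math.sinh(q.r) * math.cos(dtheta)
    return math.acosh(max(arg, 1.0))


def edge_polar_embedding(p: HyperbolicCoord, q: HyperbolicCoord) -> HyperbolicCoord:
    """Midpoint "edge" coordinate: mean radius, circular-mean angle.

    The angle is the shorter-arc midpoint (a naive arithmetic mean of
    0.1 and 2*pi - 0.1 would wrongly give pi); exactly antipodal angles
    tie-break toward theta_p + pi/2.
    """
    r = (p.r + q.r) / 2.0
    x = math.cos(p.theta) + math.cos(q.theta)
    y = math.sin(p.theta) + math.sin(q.theta)
    if math.hypot(x, y) < 1e-12:
        theta = (p.theta + math.pi / 2.0) % TWO_PI
    else:
        theta = math.atan2(y, x) % TWO_PI
    return HyperbolicCoord(r=r, theta=theta)


def read_polar_coordinates(path) -> Dict[str, HyperbolicCoord]:
    """Read a CSV of per-protein polar coordinates (columns id, r, theta)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"id", "r", "theta"}
    if not required.issubset(df.columns):
        raise ValueError(f"polar coordinate CSV needs columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    return {str(row.id): HyperbolicCoord(float(row.r), float(row.theta))
            for row in df.itertuples()}
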