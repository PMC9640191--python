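"""Recurrent connectivity sampling.

Rows are presynaptic, columns postsynaptic.  Each unordered cell pair is
reciprocal with probability p_bi (default half the unidirectional
probability), otherwise one-way with probability p_uni (random direction).
Reciprocal connections carry a 1.5x weight multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

RECIPROCAL_BOOST = 1.5


@dataclass
class ConnectivityMatrix:
    x: np.ndarray  # (n, n) binary, zero diagonal
    multiplier: np.ndarray  # (n, n): 1.0 one-way, 1.5 reciprocal, 0 elsewhere
    p_uni: float
    p_bi: float

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def pair_frequencies(self) -> tuple:
        """Realized (unidirectional, bidirectional) frequencies per
        unordered pair."""
        both = (self.x == 1) & (self.x.T == 1)
        any_ = (self.x == 1) | (self.x.T == 1)
        iu = np.triu_indices(self.n, k=1)
        n_pairs = len(iu[0])
        n_bi = int(both[iu].sum())
        n_uni = int(any_[iu].sum()) - n_bi
        return n_uni / n_pairs, n_bi / n_pairs


def build_connectivity(
    n: int, p_uni: float, seed: int = 0, p_bi: Optional[float] = None
) -> ConnectivityMatrix:
    if not 0.0 <= p_uni <= 1.0:
        raise ValueError("p_uni must lie in [0, 1]")
    if p_bi is None:
        p_bi = 0.5 * p_uni
    rng = np.random.default_rng(seed)
    x = np.zeros((n, n), dtype=np.int8)
    mult = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    r = rng.random(len(iu[0]))
    direction = rng.random(len(iu[0]))
    bi = r < p_bi
    uni = (~bi) & (r < p_bi + p_uni)
    for k in np.flatnonzero(bi):
        i, j = iu[0][k], iu[1][k]
        x[i, j] = x[j, i] = 1
        mult[i, j] = mult[j, i] = RECIPROCAL_BOOST
    for k in np.flatnonzero(uni):
        i, j = (iu[0][k], iu[1][k]) if direction[k] < 0.5 else (iu[1][k], iu[0][k])
        x[i, j] = 1
        mult[i, j] = 1.0
    return ConnectivityMatrix(x=x, multiplier=mult, p_uni=p_uni, p_bi=p_bi)
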