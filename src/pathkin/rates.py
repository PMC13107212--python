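"""Eyring transition-state-theory rates and the first-order rate matrix.

Each reaction path contributes a forward and a backward rate through one
shared effective TS energy ``g_eff = max(g_ts, g_a, g_b)``.  Sharing the TS
between the two directions gives detailed balance by construction; the clamp
to the higher endpoint prevents unphysical super-barrierless rates when a
free-energy TS estimate (a path maximum) dips below an endpoint.  No
transmission coefficient or symmetry numbers are applied (κ = 1), so absolute
time scales — not population ratios — carry that convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .constants import H_PLANCK, K_B, rt_kj
from .network import ReactionPathNetwork

__all__ = ["eyring_rate", "RateMatrix", "build_rate_matrix"]

# Rates below this are flushed to zero when log-space values are materialized.
_UNDERFLOW = 1e-300


def eyring_rate(
    g_reactant: float, g_ts_effective: float, temperature: float
) -> float:
    """First-order Eyring rate k = (k_B·T/h)·exp(−ΔG‡/RT) in s⁻¹.

    The barrier ΔG‡ = g_ts_effective − g_reactant (kJ/mol) is clamped at
    zero: a TS estimate below the reactant gives the barrierless prefactor
    k_B·T/h rather than a rate above it.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    if not (math.isfinite(g_reactant) and math.isfinite(g_ts_effective)):
        raise ValueError("non-finite Gibbs energy input")
    barrier = max(g_ts_effective - g_reactant, 0.0)
    log_k = math.log(K_B * temperature / H_PLANCK) - barrier / rt_kj(temperature)
    if log_k < math.log(_UNDERFLOW):
        return 0.0
    return math.exp(log_k)


@dataclass
class RateMatrix:
    """Sparse first-order rate-constant matrix with conservation structure.

    ``matrix[j, i]`` is the rate k[j←i] in s⁻¹ out of node i into node j;
    the diagonal holds minus the column sums, so every column sums to zero
    (probability conservation).  ``node_gibbs`` (kJ/mol, in ``node_order``)
    is retained so solvers can exploit detailed balance.
    """

    matrix: sparse.csc_matrix
    node_order: list[str]
    temperature: float
    node_gibbs: np.ndarray | None = None
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = sparse.csc_matrix(self.matrix)
        n = len(self.node_order)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match node_order")
        self.index = {nid: k for k, nid in enumerate(self.node_order)}

    @property
    def size(self) -> int:
        return len(self.node_order)

    def escape_rates(self) -> np.ndarray:
        """Total escape rate per node, −diag(K), in s⁻¹."""
        return -self.matrix.diagonal()

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def to_coo_table(self) -> pd.DataFrame:
        """Off-diagonal rates as a (row id, column id, rate) triplet table."""
        coo = self.matrix.tocoo()
        mask = coo.row != coo.col
        return pd.DataFrame(
            {
                "to": [self.node_order[r] for r in coo.row[mask]],
                "from": [self.node_order[c] for c in coo.col[mask]],
                "rate_per_s": coo.data[mask],
            }
        )


def build_rate_matrix(network: ReactionPathNetwork) -> RateMatrix:
    """Assemble the rate matrix of a network from Eyring rates.

    For each path (a, b) with TS energy g‡ the effective barrier top is
    ``g_eff = max(g‡, g_a, g_b)``; eyring_rate(g_a, g_eff, T) adds to k[b←a]
    and eyring_rate(g_b, g_eff, T) to k[a←b].  Parallel paths accumulate.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    order = network.node_order()
    index = {nid: k for k, nid in enumerate(order)}
    gibbs = network.gibbs_vector(order)
    temp = network.temperature

    rows, cols, vals = [], [], []
    for e in network.edges:
        ia, ib = index[e.eq_a], index[e.eq_b]
        g_eff = max(e.ts_gibbs, gibbs[ia], gibbs[ib])
        k_ab = eyring_rate(gibbs[ia], g_eff, temp)  # a -> b
        k_ba = eyring_rate(gibbs[ib], g_eff, temp)  # b -> a
        if k_ab > 0.0:
            rows.append(ib), cols.append(ia), vals.append(k_ab)
        if k_ba > 0.0:
            rows.append(ia), cols.append(ib), vals.append(k_ba)

    n = len(order)
    off = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    escape = np.asarray(off.sum(axis=0)).ravel()
    mat = off - sparse.diags(escape, format="csc")
    return RateMatrix(mat, order, temp, node_gibbs=gibbs)
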