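"""Shared pair enumeration for the sectional solvers.

Both schemes loop over unordered cell pairs (j <= k in the lexicographic /
flat row-major order of the 2-D cell index) and need, per pair: the kernel
value at the pivots, the 1 - delta_jk/2 self-pair factor, the componentwise
aggregate, and the flat index of the cell receiving the aggregate under the
scheme's half-open convention (or -1 for aggregates beyond the domain).
Everything here is state independent, so it is computed once per grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid2D, locate_cells
from .problem_setup import KernelSpec


@dataclass(frozen=True)
class PairTable:
    """State-independent pair data on a fixed grid."""

    j: np.ndarray  # flat cell index of first pair member, (n_pairs,)
    k: np.ndarray  # flat cell index of second member, j <= k
    factor: np.ndarray  # 1 for j < k, 0.5 for j == k
    sum_u: np.ndarray  # u component of the aggregate pivot sum
    sum_v: np.ndarray  # v component
    target: np.ndarray  # flat index of the receiving cell, -1 if overflow

    @property
    def n_pairs(self) -> int:
        return self.j.size


def build_pair_table(grid: Grid2D, convention: str) -> PairTable:
    """Enumerate all unordered cell pairs and their aggregate target cells."""
    pu, pv = grid.pivots_flat()
    n = pu.size
    j, k = np.triu_indices(n)
    factor = np.where(j == k, 0.5, 1.0)
    sum_u = pu[j] + pu[k]
    sum_v = pv[j] + pv[k]
    iu = locate_cells(grid.axis_u, sum_u, convention)
    iv = locate_cells(grid.axis_v, sum_v, convention)
    I2 = grid.axis_v.n_cells
    target = np.where((iu < 0) | (iv < 0), -1, iu * I2 + iv)
    return PairTable(j=j, k=k, factor=factor, sum_u=sum_u, sum_v=sum_v, target=target)


def kernel_on_pairs(kernel: KernelSpec, grid: Grid2D, table: PairTable) -> np.ndarray:
    """Kernel values a(u_j, u_k) at the pivot pairs, (n_pairs,)."""
    pu, pv = grid.pivots_flat()
    xj = np.stack([pu[table.j], pv[table.j]], axis=-1)
    xk = np.stack([pu[table.k], pv[table.k]], axis=-1)
    return np.asarray(kernel.rate(xj, xk), dtype=float)


def death_rates(kernel: KernelSpec, grid: Grid2D, counts_flat: np.ndarray) -> np.ndarray:
    """D_i = N_i * sum_j a(u_i, u_j) N_j over ALL cells j (flat arrays).

    Fast paths for the named kernels avoid the dense I x I kernel matrix:
    for a = 1 the inner sum is mu00, for a = theta_i + theta_j it is
    theta_i * mu00 + sum_j theta_j N_j.
    """
    pu, pv = grid.pivots_flat()
    if kernel.name == "constant":
        inner = counts_flat.sum()
    elif kernel.name == "sum":
        theta = pu + pv
        inner = theta * counts_flat.sum() + float(theta @ counts_flat)
    else:
        piv = np.stack([pu, pv], axis=-1)
        K = np.asarray(kernel.rate(piv[:, None, :], piv[None, :, :]), dtype=float)
        inner = K @ counts_flat
    return counts_flat * inner
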