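"""Conservative finite volume scheme (FVS) for bicomponent aggregation.

Each aggregate ``u_j + u_k`` is assigned to the cell containing it under the
right-closed convention and the whole birth is placed at that cell's pivot,
weighted by a birth correction ``phi_b``; deaths carry a matching correction
``phi_d``.  With ``theta`` the total size of a pivot and ``l`` the receiving
cell, the weights

    phi_b(j,k) = (theta_j + theta_k) / (2 theta_l - (theta_j + theta_k))
    phi_d(i,j) = theta_l / (2 theta_l - (theta_i + theta_j))

satisfy, per event, the number identity ``phi_b - 2 phi_d = -1`` (exactly one
net particle lost) and the mass identity ``phi_b theta_l = phi_d (theta_i +
theta_j)``, so the semi-discrete system conserves total mass exactly — also
for aggregates beyond the domain, where both weights vanish jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._pairs import PairTable, build_pair_table, kernel_on_pairs
from .grid import Grid2D, locate_cells
from .problem_setup import DiscreteState, KernelSpec

__all__ = ["theta", "FVSPrecompute", "precompute_fvs", "fvs_rhs"]

#: relative tolerance of the per-call mass-conservation audit
MASS_AUDIT_RTOL = 1e-10


def theta(pivot) -> float:
    """Total size of a property vector: the sum of its components."""
    return float(np.sum(np.asarray(pivot, dtype=float), axis=-1))


@dataclass
class FVSPrecompute:
    """State-independent tables of the scheme on one grid.

    ``pairs.target`` holds the receiving cell of each unordered pair,
    ``birth_weight`` the per-pair ``phi_b`` (zero for out-of-domain
    aggregates) and ``death_weight`` the symmetric ``phi_d`` matrix over all
    ordered cell pairs.
    """

    grid: Grid2D
    pairs: PairTable
    birth_weight: np.ndarray  # (n_pairs,)
    death_weight: np.ndarray  # (n_cells, n_cells)
    _kernel_cache: dict = field(default_factory=dict, repr=False)

    def kernel_tables(self, kernel: KernelSpec) -> tuple[np.ndarray, np.ndarray]:
        """Per-pair kernel values and the death matrix a*phi_d for one kernel."""
        key = kernel.name if kernel.name in ("constant", "sum") else id(kernel)
        if key not in self._kernel_cache:
            a_pairs = kernel_on_pairs(kernel, self.grid, self.pairs)
            pu, pv = self.grid.pivots_flat()
            piv = np.stack([pu, pv], axis=-1)
            K = np.asarray(kernel.rate(piv[:, None, :], piv[None, :, :]), dtype=float)
            self._kernel_cache[key] = (a_pairs, K * self.death_weight)
        return self._kernel_cache[key]


def _retarget_degenerate(grid: Grid2D, sum_u, sum_v, target, denom) -> tuple[np.ndarray, np.ndarray]:
    """Fix aggregates that land exactly on their receiving cell's far corner.

    The self-pair of the corner cell produces an aggregate sitting exactly on
    the upper-right corner of that same cell under the right-closed
    convention, which zeroes the weight denominator.  Such exactly-on-boundary
    events are retargeted with the left-closed convention (the next cell up),
    restoring a positive denominator; the per-event identities still hold.
    """
    theta_flat = np.add(*grid.pivots_flat())
    bad = (target >= 0) & (denom <= 0)
    if np.any(bad):
        iu = locate_cells(grid.axis_u, sum_u[bad], "left_closed")
        iv = locate_cells(grid.axis_v, sum_v[bad], "left_closed")
        I2 = grid.axis_v.n_cells
        new = np.where((iu < 0) | (iv < 0), -1, iu * I2 + iv)
        target = target.copy()
        target[bad] = new
        ok = new >= 0
        d = denom.copy()
        d[bad] = np.where(ok, 2 * theta_flat[np.maximum(new, 0)] - (sum_u[bad] + sum_v[bad]), 1.0)
        denom = d
    if np.any((target >= 0) & (denom <= 0)):
        raise ValueError("nonpositive correction-weight denominator on this grid")
    return target, denom


def precompute_fvs(grid: Grid2D) -> FVSPrecompute:
    """Build the pair/target tables and correction weights for a grid."""
    pairs = build_pair_table(grid, "right_closed")
    theta_flat = np.add(*grid.pivots_flat())
    theta_sum = pairs.sum_u + pairs.sum_v
    theta_l = theta_flat[np.maximum(pairs.target, 0)]
    denom = 2 * theta_l - theta_sum
    target, denom = _retarget_degenerate(grid, pairs.sum_u, pairs.sum_v, pairs.target, denom)
    pairs = PairTable(
        j=pairs.j, k=pairs.k, factor=pairs.factor, sum_u=pairs.sum_u, sum_v=pairs.sum_v, target=target
    )
    in_dom = target >= 0
    phib = np.where(in_dom, theta_sum / np.where(in_dom, denom, 1.0), 0.0)
    phid_pairs = np.where(
        in_dom, theta_flat[np.maximum(target, 0)] / np.where(in_dom, denom, 1.0), 0.0
    )
    n = grid.n_cells
    Phid = np.zeros((n, n))
    Phid[pairs.j, pairs.k] = phid_pairs
    Phid[pairs.k, pairs.j] = phid_pairs
    return FVSPrecompute(grid=grid, pairs=pairs, birth_weight=phib, death_weight=Phid)


def fvs_rhs(
    state: DiscreteState,
    kernel: KernelSpec,
    pre: FVSPrecompute,
    mass_audit: bool = True,
) -> np.ndarray:
    """Rate of change dN/dt of the cell counts under the finite volume scheme."""
    grid = pre.grid
    if state.counts.shape != grid.shape:
        raise ValueError(f"state shape {state.counts.shape} does not match grid {grid.shape}")
    t = pre.pairs
    N = state.counts.ravel()
    a_pairs, KPhid = pre.kernel_tables(kernel)
    rates = t.factor * a_pairs * N[t.j] * N[t.k] * pre.birth_weight
    valid = t.target >= 0
    birth = np.bincount(t.target[valid], weights=rates[valid], minlength=grid.n_cells)
    death = N * (KPhid @ N)
    dN = birth - death
    if mass_audit:
        th = np.add(*grid.pivots_flat())
        gross = float(th @ birth + th @ np.abs(death))
        drift = float(th @ dN)
        if abs(drift) > MASS_AUDIT_RTOL * max(gross, 1e-300):
            raise ArithmeticError(
                f"mass-conservation audit failed: drift {drift:.3e} vs gross flux {gross:.3e}"
            )
    return dN.reshape(grid.shape)
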