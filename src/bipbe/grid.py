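"""Non-uniform 1-D grids and their 2-D tensor product.

Sectional aggregation schemes discretize the internal-coordinate domain into
cells; each cell carries a single *representative* (pivot) at its midpoint at
which the cell population is concentrated.  Both solvers in this package share
the same grid skeleton; they differ only in the half-open convention used to
decide which cell an aggregate ``u_j + u_k`` falls into, so both conventions
are selectable in :func:`locate_cell`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OVERFLOW",
    "Grid1D",
    "Grid2D",
    "build_geometric_grid",
    "locate_cell",
    "locate_cells",
]

#: Sentinel returned by :func:`locate_cell` for points beyond the last boundary.
OVERFLOW: int = -1

_CONVENTIONS = ("left_closed", "right_closed")


@dataclass(frozen=True)
class Grid1D:
    """A 1-D mesh: increasing cell boundaries with midpoint representatives.

    The first boundary is pinned at zero so the mesh covers ``[0, umax]``;
    representatives are cell midpoints and widths are boundary differences.
    """

    boundaries: np.ndarray
    representatives: np.ndarray = field(init=False)
    widths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("boundaries must be a 1-D sequence of length >= 2")
        if b[0] != 0.0:
            raise ValueError("first boundary must be 0")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "representatives", 0.5 * (b[:-1] + b[1:]))
        object.__setattr__(self, "widths", np.diff(b))

    @property
    def n_cells(self) -> int:
        return self.boundaries.size - 1

    @property
    def umax(self) -> float:
        return float(self.boundaries[-1])

    def to_frame(self) -> pd.DataFrame:
        """One row per cell: lower/upper boundary, representative, width."""
        return pd.DataFrame(
            {
                "lower": self.boundaries[:-1],
                "upper": self.boundaries[1:],
                "representative": self.representatives,
                "width": self.widths,
            }
        )


@dataclass(frozen=True)
class Grid2D:
    """Tensor product of two 1-D grids (axis ``u`` x axis ``v``)."""

    axis_u: Grid1D
    axis_v: Grid1D

    @property
    def shape(self) -> tuple[int, int]:
        return (self.axis_u.n_cells, self.axis_v.n_cells)

    @property
    def n_cells(self) -> int:
        return self.axis_u.n_cells * self.axis_v.n_cells

    def pivots(self) -> tuple[np.ndarray, np.ndarray]:
        """Pivot coordinate matrices ``(U, V)`` of shape ``(I1, I2)``."""
        return np.meshgrid(
            self.axis_u.representatives, self.axis_v.representatives, indexing="ij"
        )

    def areas(self) -> np.ndarray:
        """Cell areas ``du_i * dv_j`` of shape ``(I1, I2)``."""
        return np.outer(self.axis_u.widths, self.axis_v.widths)

    def pivots_flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Pivot coordinates flattened in C order of the ``(I1, I2)`` state."""
        u, v = self.pivots()
        return u.ravel(), v.ravel()


def build_geometric_grid(umin: float, umax: float, cells: int) -> Grid1D:
    """Geometric mesh over ``[0, umax]`` with ``cells`` cells.

    Boundaries are ``[0, umin, umin*q, ..., umax]`` with a constant ratio
    ``q = (umax/umin)**(1/(cells-1))``; the first cell ``[0, umin]`` absorbs
    the origin.  For ``cells == 1`` the single cell is ``[0, umax]``.
    """
    if umin <= 0:
        raise ValueError(f"umin must be positive, got {umin}")
    if umax <= umin:
        raise ValueError(f"umax must exceed umin, got umin={umin}, umax={umax}")
    if cells < 1:
        raise ValueError(f"cells must be >= 1, got {cells}")
    if cells == 1:
        return Grid1D(np.array([0.0, umax]))
    q = (umax / umin) ** (1.0 / (cells - 1))
    b = umin * q ** np.arange(cells)
    b[-1] = umax  # kill round-off on the last boundary
    return Grid1D(np.concatenate(([0.0], b)))


def locate_cell(grid: Grid1D, x: float, convention: str = "left_closed") -> int:
    """Index of the cell containing ``x`` under a half-open convention.

    ``left_closed`` puts boundary points in the upper cell (cells are
    ``[b_i, b_{i+1})``); ``right_closed`` puts them in the lower cell
    (``(b_i, b_{i+1}]``).  The domain endpoints are closed either way, so
    every ``x`` in ``[0, umax]`` belongs to exactly one cell.  Returns
    :data:`OVERFLOW` for ``x > umax``.
    """
    if x < 0:
        raise ValueError(f"x must be nonnegative, got {x}")
    return int(locate_cells(grid, np.asarray([x], dtype=float), convention)[0])


def locate_cells(grid: Grid1D, x: np.ndarray, convention: str = "left_closed") -> np.ndarray:
    """Vectorized :func:`locate_cell`; overflow entries are :data:`OVERFLOW`."""
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}, got {convention!r}")
    b = grid.boundaries
    x = np.asarray(x, dtype=float)
    if convention == "left_closed":
        idx = np.searchsorted(b, x, side="right") - 1
        idx = np.where(x == b[-1], grid.n_cells - 1, idx)  # close the top endpoint
    else:
        idx = np.searchsorted(b, x, side="left") - 1
        idx = np.where(x == 0.0, 0, idx)  # close the bottom endpoint
    return np.where(x > b[-1], OVERFLOW, idx)
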