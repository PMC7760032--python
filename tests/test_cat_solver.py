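"""Cell average technique: birth/death bookkeeping, averaging, redistribution.

The reference implementation for the audits is an independent brute-force
enumeration of aggregation events with explicit Python loops, kept free of
the solver's vectorized pair tables.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bipbe as bp
from bipbe.cat_solver import _axis_fraction, cat_birth_death


def brute_force_birth_death(state, kernel, grid):
    """Event-by-event enumeration of births (with fluxes) and deaths."""
    I1, I2 = grid.shape
    pu, pv = grid.axis_u.representatives, grid.axis_v.representatives
    B = np.zeros((I1, I2))
    Vu = np.zeros((I1, I2))
    Vv = np.zeros((I1, I2))
    D = np.zeros((I1, I2))
    cells = [(i, j) for i in range(I1) for j in range(I2)]
    for a_idx, (j1, j2) in enumerate(cells):
        for k1, k2 in cells[a_idx:]:
            delta = 1.0 if (j1, j2) == (k1, k2) else 0.0
            rate = (
                (1 - 0.5 * delta)
                * kernel((pu[j1], pv[j2]), (pu[k1], pv[k2]))
                * state.counts[j1, j2]
                * state.counts[k1, k2]
            )
            su, sv = pu[j1] + pu[k1], pv[j2] + pv[k2]
            iu = bp.locate_cell(grid.axis_u, su, "left_closed")
            iv = bp.locate_cell(grid.axis_v, sv, "left_closed")
            if iu >= 0 and iv >= 0:
                B[iu, iv] += rate
                Vu[iu, iv] += rate * su
                Vv[iu, iv] += rate * sv
    for i1, i2 in cells:
        for j1, j2 in cells:
            D[i1, i2] += (
                kernel((pu[i1], pv[i2]), (pu[j1], pv[j2]))
                * state.counts[i1, i2]
                * state.counts[j1, j2]
            )
    return B, Vu, Vv, D


class TestBirthDeath:
    def test_zero_state_gives_zero_rates(self, toy_grid):
        state = bp.DiscreteState(counts=np.zeros(toy_grid.shape))
        acc, D = cat_birth_death(state, bp.constant_kernel(), toy_grid)
        assert not acc.birth.any() and not acc.flux_u.any() and not D.any()

    def test_self_pair_carries_half_rate(self, toy_grid):
        # one populated cell at pivot (1.5, 1.5): the only event is the
        # self-pair at rate N^2/2, landing in the cell holding (3, 3)
        counts = np.zeros(toy_grid.shape)
        counts[1, 1] = 4.0
        state = bp.DiscreteState(counts=counts)
        acc, D = cat_birth_death(state, bp.constant_kernel(), toy_grid)
        assert acc.birth[2, 2] == pytest.approx(0.5 * 16.0)
        assert acc.birth.sum() == pytest.approx(8.0)
        np.testing.assert_allclose(acc.flux_u[2, 2] / acc.birth[2, 2], 3.0)
        assert D[1, 1] == pytest.approx(16.0)

    def test_two_cells_sum_kernel_matches_hand_rates(self, toy_grid):
        counts = np.zeros(toy_grid.shape)
        counts[0, 0] = 2.0  # pivot (0.5, 0.5)
        counts[1, 0] = 3.0  # pivot (1.5, 0.5)
        state = bp.DiscreteState(counts=counts)
        acc, _ = cat_birth_death(state, bp.sum_kernel(), toy_grid)
        # self (0,0): rate 0.5*2*2*2 = 4 at (1.0, 1.0) -> cell (1, 1)
        # cross: rate 3*2*3*... a = 0.5+0.5+1.5+0.5 = 3 -> rate 3*2*3 = 18 at (2, 1) -> cell (2, 1)
        # self (1,0): rate 0.5*4*3*3 = 18 at (3.0, 1.0) -> cell (2, 1)
        assert acc.birth[1, 1] == pytest.approx(4.0)
        assert acc.birth[2, 1] == pytest.approx(18.0 + 18.0)

    def test_matches_brute_force_on_random_state(self, toy_grid, rng):
        state = bp.DiscreteState(counts=rng.random(toy_grid.shape))
        for kernel in (bp.constant_kernel(), bp.sum_kernel()):
            acc, D = cat_birth_death(state, kernel, toy_grid)
            B, Vu, Vv, Dref = brute_force_birth_death(state, kernel, toy_grid)
            np.testing.assert_allclose(acc.birth, B, atol=1e-14)
            np.testing.assert_allclose(acc.flux_u, Vu, atol=1e-14)
            np.testing.assert_allclose(acc.flux_v, Vv, atol=1e-14)
            np.testing.assert_allclose(D, Dref, atol=1e-14)

    def test_shape_mismatch_rejected(self, toy_grid):
        state = bp.DiscreteState(counts=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            cat_birth_death(state, bp.constant_kernel(), toy_grid)


class TestCellAverage:
    def test_single_event_average(self):
        np.testing.assert_allclose(bp.cell_average(1.0, (3.0, 2.0)), (3.0, 2.0))

    def test_two_event_mean(self):
        # equal-rate events with sums (3,2) and (5,4): V = (8,6), B = 2
        np.testing.assert_allclose(bp.cell_average(2.0, (8.0, 6.0)), (4.0, 3.0))

    def test_zero_birth_rejected(self):
        with pytest.raises(ValueError):
            bp.cell_average(0.0, (1.0, 1.0))

    def test_average_stays_in_host_cell(self, toy_grid, rng):
        state = bp.DiscreteState(counts=rng.random(toy_grid.shape))
        acc, _ = cat_birth_death(state, bp.sum_kernel(), toy_grid)
        bu, bv = toy_grid.axis_u.boundaries, toy_grid.axis_v.boundaries
        for i1 in range(4):
            for i2 in range(4):
                if acc.birth[i1, i2] > 0:
                    ub = bp.cell_average(acc.birth[i1, i2], (acc.flux_u[i1, i2], acc.flux_v[i1, i2]))
                    assert bu[i1] <= ub[0] <= bu[i1 + 1]
                    assert bv[i2] <= ub[1] <= bv[i2 + 1]


class TestRedistribution:
    def test_at_pivot_all_weight_on_host(self, toy_grid):
        w = bp.redistribution_weights(toy_grid, (1, 1), (1.5, 1.5))
        assert w == {(1, 1): pytest.approx(1.0)}

    def test_midway_splits_evenly_in_one_axis(self, toy_grid):
        # midway between u-pivots 1.5 and 3 at 2.25, at the v pivot
        w = bp.redistribution_weights(toy_grid, (2, 1), (2.25, 1.5))
        assert w[(2, 1)] == pytest.approx(0.5)
        assert w[(1, 1)] == pytest.approx(0.5)

    def test_outside_host_rejected(self, toy_grid):
        with pytest.raises(ValueError):
            bp.redistribution_weights(toy_grid, (1, 1), (5.0, 1.5))

    @settings(max_examples=100, derandomize=True)
    @given(
        i1=st.integers(1, 2),
        i2=st.integers(1, 2),
        fx=st.floats(0.0, 1.0),
        fy=st.floats(0.0, 1.0),
    )
    def test_weights_preserve_number_and_both_masses(self, toy_grid, i1, i2, fx, fy):
        bu, bv = toy_grid.axis_u.boundaries, toy_grid.axis_v.boundaries
        ubar = (
            bu[i1] + fx * (bu[i1 + 1] - bu[i1]),
            bv[i2] + fy * (bv[i2 + 1] - bv[i2]),
        )
        w = bp.redistribution_weights(toy_grid, (i1, i2), ubar)
        pu, pv = toy_grid.axis_u.representatives, toy_grid.axis_v.representatives
        assert all(val >= 0 for val in w.values())
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(val * pu[a] for (a, b), val in w.items()) == pytest.approx(ubar[0], abs=1e-12)
        assert sum(val * pv[b] for (a, b), val in w.items()) == pytest.approx(ubar[1], abs=1e-12)

    def test_edge_cell_collapses_to_host(self, toy_grid):
        # beyond the last pivot there is no bracketing neighbor: weight 1 on host
        w = bp.redistribution_weights(toy_grid, (3, 1), (7.0, 1.5))
        assert sum(w.values()) == pytest.approx(1.0)
        assert all(a == 3 for (a, b) in w)


class TestCATRhs:
    def test_zero_state(self, toy_grid):
        state = bp.DiscreteState(counts=np.zeros(toy_grid.shape))
        assert not bp.cat_rhs(state, bp.constant_kernel(), toy_grid).any()

    def test_mass_conserved_for_interior_states(self, rng):
        # populate only small cells of a wide domain: no overflow, no edge clamp
        axis = bp.build_geometric_grid(0.5, 64.0, 8)
        grid = bp.Grid2D(axis, axis)
        counts = np.zeros(grid.shape)
        counts[:3, :3] = rng.random((3, 3))
        state = bp.DiscreteState(counts=counts)
        U, V = grid.pivots()
        for kernel in (bp.constant_kernel(), bp.sum_kernel()):
            dN = bp.cat_rhs(state, kernel, grid)
            scale = float(np.abs(dN * (U + V)).sum())
            assert abs(float(((U + V) * dN).sum())) <= 1e-12 * scale

    def test_number_balance_one_loss_per_event(self, rng):
        axis = bp.build_geometric_grid(0.5, 64.0, 8)
        grid = bp.Grid2D(axis, axis)
        counts = np.zeros(grid.shape)
        counts[:3, :3] = rng.random((3, 3))
        state = bp.DiscreteState(counts=counts)
        kernel = bp.sum_kernel()
        dN = bp.cat_rhs(state, kernel, grid)
        B, _, _, D = brute_force_birth_death(state, kernel, grid)
        # net number change = births - deaths = -(one particle per event)
        assert dN.sum() == pytest.approx(B.sum() - D.sum(), rel=1e-12)
        assert dN.sum() == pytest.approx(-B.sum(), rel=1e-12)  # D = 2B without overflow

    def test_truncation_variants_differ_only_in_overflow_deaths(self, toy_grid, rng):
        # a state with population near the top of the domain has overflow
        # events; the printed variant keeps their deaths, losing mass
        counts = rng.random(toy_grid.shape)
        state = bp.DiscreteState(counts=counts)
        kernel = bp.constant_kernel()
        U, V = toy_grid.pivots()
        cons = bp.cat_rhs(state, kernel, toy_grid, truncation="conservative")
        prnt = bp.cat_rhs(state, kernel, toy_grid, truncation="printed")
        mass_cons = float(((U + V) * cons).sum())
        mass_prnt = float(((U + V) * prnt).sum())
        assert mass_prnt < mass_cons  # printed leaks more through the open end
        assert np.all(cons - prnt >= -1e-14)  # conservative only removes deaths

    def test_unknown_truncation_rejected(self, toy_grid):
        state = bp.DiscreteState(counts=np.zeros(toy_grid.shape))
        with pytest.raises(ValueError):
            bp.cat_rhs(state, bp.constant_kernel(), toy_grid, truncation="other")

    def test_transpose_symmetry(self, toy_grid, rng):
        counts = rng.random(toy_grid.shape)
        counts = counts + counts.T
        state = bp.DiscreteState(counts=counts)
        for kernel in (bp.constant_kernel(), bp.sum_kernel()):
            dN = bp.cat_rhs(state, kernel, toy_grid)
            np.testing.assert_allclose(dN, dN.T, atol=1e-13)
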