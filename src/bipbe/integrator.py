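"""Adaptive time integration of the semi-discrete aggregation systems.

Both schemes reduce the population balance to a stiff-free quadratic ODE
system in the cell counts; an embedded explicit Runge-Kutta pair with local
error control (scipy's RK45 by default) advances it between requested output
times.  Default tolerances are tight enough that time-integration error is
negligible against the spatial discretization error under study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .problem_setup import DiscreteState

__all__ = ["IntegrationConfig", "integrate"]


@dataclass(frozen=True)
class IntegrationConfig:
    rel_tol: float = 1e-8
    abs_tol: float = 1e-12
    t_outputs: Sequence[float] = field(default_factory=lambda: (1.0,))
    max_step: float | None = None
    method: str = "RK45"

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        ts = np.asarray(self.t_outputs, dtype=float)
        if ts.size == 0 or ts[0] < 0 or np.any(np.diff(ts) <= 0):
            raise ValueError("t_outputs must be increasing with t_outputs[0] >= 0")


def integrate(
    rhs: Callable[[DiscreteState], np.ndarray],
    state0: DiscreteState,
    cfg: IntegrationConfig,
) -> list[DiscreteState]:
    """Advance ``state0`` under ``rhs`` and return states at ``cfg.t_outputs``.

    ``rhs`` maps a :class:`DiscreteState` to the rate-of-change matrix.
    Raw states are returned unmodified; counts below ``-abs_tol`` only raise
    a warning (clip for diagnostics if needed).
    """
    shape = state0.counts.shape
    t_out = np.asarray(cfg.t_outputs, dtype=float)

    def fun(t: float, y: np.ndarray) -> np.ndarray:
        return rhs(DiscreteState(counts=y.reshape(shape), time=t)).ravel()

    r0 = fun(state0.time, state0.counts.ravel())
    if not np.all(np.isfinite(r0)):
        raise ValueError("rhs is not finite on the initial state")

    sol = solve_ivp(
        fun,
        (state0.time, float(t_out[-1])),
        state0.counts.ravel(),
        method=cfg.method,
        t_eval=t_out,
        rtol=cfg.rel_tol,
        atol=cfg.abs_tol,
        max_step=cfg.max_step if cfg.max_step is not None else np.inf,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"time integration failed: {sol.message}")
    states = [DiscreteState(counts=sol.y[:, i].reshape(shape), time=float(sol.t[i])) for i in range(sol.t.size)]
    worst = min(s.counts.min() for s in states)
    if worst < -cfg.abs_tol:
        warnings.warn(
            f"negative cell counts down to {worst:.3e} in the integrated states",
            RuntimeWarning,
            stacklevel=2,
        )
    return states
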