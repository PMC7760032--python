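"""Event-driven stochastic simulation of bicomponent aggregation.

A direct (exact) Gillespie realization of the coalescence master equation:
``n`` sample particles in a virtual volume ``V = n / N0`` coalesce pairwise
with rate ``a(x_i, x_j) / V``, so the mean-field limit of the ensemble is
the continuous population balance with initial number density ``N0``.  Each
event replaces a pair by its componentwise sum, conserving total mass
exactly.  Quadratic cost in ``n``; intended as an independent ground-truth
oracle for moment trajectories and the mixing statistic, not as a production
solver.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .analytical import MomentSet
from .problem_setup import InitialConditionSpec, KernelSpec

__all__ = ["ParticleEnsemble", "sample_initial_ensemble", "simulate", "ensemble_moments"]


@dataclass(frozen=True)
class ParticleEnsemble:
    """A finite sample of (u, v) particles plus the mean-field scale."""

    u: np.ndarray
    v: np.ndarray
    t: float
    seed: int
    volume: float  # virtual volume: number density = len(u) / volume

    def __post_init__(self) -> None:
        if self.u.size != self.v.size or self.u.size < 1:
            raise ValueError("ensemble must hold matching nonempty u, v arrays")
        if np.any(self.u <= 0) or np.any(self.v <= 0):
            raise ValueError("particle properties must be positive")

    @property
    def n_particles(self) -> int:
        return self.u.size


def sample_initial_ensemble(spec: InitialConditionSpec, n: int, seed: int) -> ParticleEnsemble:
    """Draw ``n`` particles from the gamma-product initial condition."""
    if n < 2:
        raise ValueError("need at least two particles")
    rng = np.random.default_rng(seed)
    u = rng.gamma(spec.p1 + 1, spec.m10 / (spec.p1 + 1), size=n)
    v = rng.gamma(spec.p2 + 1, spec.m20 / (spec.p2 + 1), size=n)
    return ParticleEnsemble(u=u, v=v, t=0.0, seed=seed, volume=n / spec.N0)


def ensemble_moments(ens: ParticleEnsemble) -> MomentSet:
    """Number-density moments of the ensemble (per virtual volume)."""
    u, v, V = ens.u, ens.v, ens.volume

    def mom(a: int, b: int) -> float:
        return float((u**a * v**b).sum() / V)

    return MomentSet(
        time=ens.t,
        mu00=mom(0, 0),
        mu10=mom(1, 0),
        mu01=mom(0, 1),
        mu20=mom(2, 0),
        mu11=mom(1, 1),
        mu02=mom(0, 2),
        mu30=mom(3, 0),
        mu21=mom(2, 1),
    )


def _pick_pair_constant(rng: np.random.Generator, m: int) -> tuple[int, int]:
    i = int(rng.integers(m))
    j = int(rng.integers(m - 1))
    if j >= i:
        j += 1
    return i, j


def _pick_pair_sum(rng: np.random.Generator, s: np.ndarray) -> tuple[int, int]:
    # P(i, j) ∝ s_i + s_j over ordered pairs i != j: propose from the mixture
    # ½(size-weighted, uniform) + ½(uniform, size-weighted); reject i == j.
    m = s.size
    cdf = np.cumsum(s)
    total = cdf[-1]
    while True:
        if rng.random() < 0.5:
            i = int(np.searchsorted(cdf, rng.random() * total))
            j = int(rng.integers(m))
        else:
            i = int(rng.integers(m))
            j = int(np.searchsorted(cdf, rng.random() * total))
        if i != j:
            return i, j


def simulate(
    ens: ParticleEnsemble,
    kernel: KernelSpec,
    t_end: float,
    record_times=None,
) -> tuple[ParticleEnsemble, list[MomentSet]]:
    """Exact stochastic simulation of pairwise coalescence up to ``t_end``.

    Supports the named "constant" and "sum" kernels (for which total-rate
    bookkeeping is O(1) per event).  Returns the final ensemble and, if
    ``record_times`` is given, the ensemble moments at those times.  The
    simulation halts early if a single particle remains.
    """
    if ens.n_particles < 2:
        raise ValueError("need at least two particles to aggregate")
    if kernel.name not in ("constant", "sum"):
        raise NotImplementedError("stochastic oracle supports the constant and sum kernels")
    rng = np.random.default_rng(ens.seed + 1)
    u = ens.u.copy()
    v = ens.v.copy()
    m = u.size
    V = ens.volume
    t = ens.t
    record = list(record_times) if record_times is not None else []
    recorded: list[MomentSet] = []
    ri = 0

    def snapshot(at: float) -> MomentSet:
        return ensemble_moments(replace(ens, u=u[:m].copy(), v=v[:m].copy(), t=at))

    while True:
        if kernel.name == "constant":
            total_rate = 0.5 * m * (m - 1) / V
        else:
            s = u[:m] + v[:m]
            total_rate = (m - 1) * float(s.sum()) / V
        if m < 2 or total_rate <= 0:
            break
        dt = rng.exponential(1.0 / total_rate)
        t_next = t + dt
        while ri < len(record) and record[ri] <= min(t_next, t_end):
            recorded.append(snapshot(record[ri]))
            ri += 1
        if t_next > t_end:
            t = t_end
            break
        t = t_next
        if kernel.name == "constant":
            i, j = _pick_pair_constant(rng, m)
        else:
            i, j = _pick_pair_sum(rng, s)
        u[i] += u[j]
        v[i] += v[j]
        u[j], v[j] = u[m - 1], v[m - 1]
        m -= 1
    while ri < len(record):
        recorded.append(snapshot(record[ri]))
        ri += 1
    final = ParticleEnsemble(u=u[:m].copy(), v=v[:m].copy(), t=t, seed=ens.seed, volume=V)
    return final, recorded
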