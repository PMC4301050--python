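"""Directional source--sink model for mutualist spillover.

Patch 1 (the *source*) holds a host--mutualist association with its own
productivity ``r1`` and no enemy; patch 2 (the *sink*) holds a host--enemy
association governed by the single-patch model.  Mutualists emigrate from
the source at constant per-capita rate ``eps1`` and arrive in the sink's
mutualist pool, so the sink's mutualist density is no longer absorbing at
zero: immigration can push it over the propagule threshold that blocks
invasion from rarity.

The crowding coefficient ``q`` is a host trait and is shared by both
patches; productivity differs (``r1`` vs ``r``).  Hosts and enemies do not
disperse.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (
    IntegrationError,
    SimulationOptions,
    Trajectory,
    integrate_rhs,
)
from .model_core import (
    InfeasibleEquilibriumError,
    ModelParams,
    enemy_eq_density,
    host_eq_with_enemy,
)

__all__ = [
    "TwoPatchParams",
    "TwoPatchState",
    "two_patch_derivatives",
    "source_equilibrium",
    "simulate_two_patch",
    "sink_mutualist_summary",
    "sweep_two_patch",
]

COLUMNS = ("H1", "M1", "H2", "E2", "M2")

#: number of trailing unit-spaced samples averaged by the sink summary
SUMMARY_WINDOW = 200
#: minimum trajectory span (time units) required by the sink summary
SUMMARY_SPAN = 2000.0


@dataclass(frozen=True)
class TwoPatchParams:
    """Sink-patch rates (``base``, with productivity ``base.r``), source
    productivity ``r1`` and directional emigration rate ``eps1``.

    ``include_emigration_loss`` controls whether emigrants are debited from
    the source mutualist pool (mass conservation; the default) or the
    source is treated as an unbounded propagule supply.
    """

    base: ModelParams
    r1: float
    eps1: float
    include_emigration_loss: bool = True

    def __post_init__(self) -> None:
        if not self.r1 > 0:
            raise ValueError("r1 must be > 0")
        if self.eps1 < 0:
            raise ValueError("eps1 must be >= 0")

    def to_dict(self) -> dict:
        d = {f"sink_{k}": v for k, v in self.base.to_dict().items()}
        d.update(
            r1=self.r1,
            eps1=self.eps1,
            include_emigration_loss=self.include_emigration_loss,
        )
        return d


class TwoPatchState(tuple):
    """(H1, M1, H2, E2, M2) densities; a thin tuple with named access."""

    def __new__(cls, H1, M1, H2, E2, M2):
        return super().__new__(cls, (H1, M1, H2, E2, M2))

    H1 = property(lambda self: self[0])
    M1 = property(lambda self: self[1])
    H2 = property(lambda self: self[2])
    E2 = property(lambda self: self[3])
    M2 = property(lambda self: self[4])


def two_patch_derivatives(state, p: TwoPatchParams) -> tuple[float, ...]:
    """Rates of change of (H1, M1, H2, E2, M2).

    The source follows the host--mutualist subsystem with productivity
    ``r1``; the sink follows the full single-patch model with an extra
    ``+eps1*M1`` immigration term in its mutualist equation.
    """
    H1, M1, H2, E2, M2 = state
    b = p.base
    c = b.protection_coefficient

    dH1 = H1 * (p.r1 - b.q * H1) - b.alpha * b.b * H1 * M1
    dM1 = M1 * (b.alpha * b.gamma * b.b * H1 - b.delta_M)
    if p.include_emigration_loss:
        dM1 -= p.eps1 * M1

    dH2 = H2 * (b.r - b.q * H2) - b.b * H2 * E2 - b.alpha * b.b * H2 * M2
    dE2 = E2 * (b.gamma * b.b * H2 - b.delta_E - c * M2)
    dM2 = M2 * (b.alpha * b.gamma * b.b * H2 - b.delta_M) + p.eps1 * M1
    return (dH1, dM1, dH2, dE2, dM2)


def source_equilibrium(p: TwoPatchParams) -> tuple[float, float]:
    """Internal (H1*, M1*) equilibrium of the source patch.

    With emigration loss the mutualist's effective mortality is
    ``delta_M + eps1``, raising the host equilibrium and lowering M1*.
    """
    b = p.base
    loss = p.eps1 if p.include_emigration_loss else 0.0
    H1 = (b.delta_M + loss) / (b.alpha * b.gamma * b.b)
    M1 = (p.r1 - b.q * H1) / (b.alpha * b.b)
    if M1 <= 0:
        raise InfeasibleEquilibriumError(
            "source host-mutualist equilibrium infeasible (M1* <= 0)"
        )
    return H1, M1


def default_initial_state(p: TwoPatchParams) -> TwoPatchState:
    """Source at its internal equilibrium, sink at the host--enemy
    equilibrium with no mutualists."""
    H1, M1 = source_equilibrium(p)
    H2 = host_eq_with_enemy(p.base)
    E2 = enemy_eq_density(p.base)
    return TwoPatchState(H1, M1, H2, E2, 0.0)


def simulate_two_patch(
    p: TwoPatchParams,
    options: SimulationOptions | None = None,
    initial: TwoPatchState | None = None,
) -> Trajectory:
    """Integrate the five-variable source--sink system.

    The sink mutualist pool is excluded from absorbing-extinction handling
    because immigration can re-seed it from arbitrarily low density.
    """
    options = options or SimulationOptions()
    y0 = initial if initial is not None else default_initial_state(p)

    def rhs(t, y):
        return two_patch_derivatives(np.clip(y, 0.0, None), p)

    # M2 receives +eps1*M1 immigration, so zero is not absorbing for it
    absorbing = (True, True, True, True, p.eps1 == 0.0)
    return integrate_rhs(rhs, y0, COLUMNS, options, absorbing=absorbing)


def sink_mutualist_summary(trajectory: Trajectory) -> float:
    """Mean sink mutualist density over the final 200 unit-spaced samples.

    Requires a trajectory spanning at least 2000 time units recorded at
    unit intervals (the standard measurement window).
    """
    t = trajectory.times
    if t[-1] - t[0] < SUMMARY_SPAN - 1e-9:
        raise ValueError(
            f"trajectory spans {t[-1] - t[0]:g} < {SUMMARY_SPAN:g} time units"
        )
    tail_t = t[-SUMMARY_WINDOW:]
    if len(tail_t) < SUMMARY_WINDOW or not np.allclose(np.diff(tail_t), 1.0):
        raise ValueError("trajectory tail is not sampled at unit intervals")
    return float(np.mean(trajectory.col("M2")[-SUMMARY_WINDOW:]))


def sweep_two_patch(
    q_grid,
    r1_over_r_grid,
    eps1_grid,
    u_grid,
    base: ModelParams,
    options: SimulationOptions | None = None,
) -> pd.DataFrame:
    """Cartesian sweep over (q, r1/r, eps1, u); one record per combination.

    Returns a long-format table with columns ``q, r1_over_r, eps1, u,
    sink_mutualist_mean, status``.  Integration failures in individual
    cells are recorded in ``status`` and do not abort the sweep.
    """
    grids = [list(g) for g in (q_grid, r1_over_r_grid, eps1_grid, u_grid)]
    if any(len(g) == 0 for g in grids):
        raise ValueError("all sweep grids must be nonempty")
    options = options or SimulationOptions()

    records = []
    for q, rr, eps1, u in itertools.product(*grids):
        cell = {
            "q": q,
            "r1_over_r": rr,
            "eps1": eps1,
            "u": u,
            "sink_mutualist_mean": np.nan,
            "status": "ok",
        }
        try:
            params = TwoPatchParams(
                base=base.replace(q=q, u=u), r1=rr * base.r, eps1=eps1
            )
            traj = simulate_two_patch(params, options)
            cell["sink_mutualist_mean"] = sink_mutualist_summary(traj)
        except (IntegrationError, InfeasibleEquilibriumError, ValueError) as exc:
            cell["status"] = f"failed: {exc}"
        records.append(cell)
    return pd.DataFrame.from_records(records)
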