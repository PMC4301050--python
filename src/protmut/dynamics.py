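"""Time integration of the single-patch model.

Wraps an adaptive Runge-Kutta integrator (scipy's RK45) with two pieces of
ecological bookkeeping the raw ODEs lack:

* densities are kept nonnegative, and
* a species whose density falls below a small cutoff is set to exactly
  zero and stays there — a deterministic stand-in for demographic
  stochasticity at vanishing densities.

Also provides a bisection search for the dynamical invasion threshold (the
separatrix along the introduction axis), used to demonstrate the Allee-type
propagule threshold of the net-protective mutualist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    ModelParams,
    State,
    derivatives,
    enemy_eq_density,
    host_eq_with_enemy,
    host_eq_with_mutualist,
    mutualist_eq_density,
)

__all__ = [
    "SimulationOptions",
    "Trajectory",
    "IntegrationError",
    "BracketError",
    "integrate",
    "find_invasion_threshold",
    "PERSISTENCE_THRESHOLD",
]

#: density above which a species counts as persistent at the end of a run
PERSISTENCE_THRESHOLD = 1e-6


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message carries the failing time."""


class BracketError(ValueError):
    """A bisection bracket does not straddle an outcome change."""


@dataclass(frozen=True)
class SimulationOptions:
    """Numerical controls for :func:`integrate`.

    ``extinction_threshold`` is the density below which a species is set to
    exactly zero for the rest of the run; set it to 0 to disable the cutoff
    (zero stays absorbing because the equations are per-capita).
    """

    t_end: float = 2000.0
    max_step: float = np.inf
    abs_tol: float = 1e-8
    rel_tol: float = 1e-8
    extinction_threshold: float = 1e-9
    record_every: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.abs_tol <= 0 or self.rel_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be >= 0")
        if self.t_end <= 0 or self.record_every <= 0:
            raise ValueError("t_end and record_every must be > 0")

    def to_dict(self) -> dict:
        return {
            "t_end": self.t_end,
            "max_step": self.max_step,
            "abs_tol": self.abs_tol,
            "rel_tol": self.rel_tol,
            "extinction_threshold": self.extinction_threshold,
            "record_every": self.record_every,
            "seed": self.seed,
        }


@dataclass
class Trajectory:
    """Recorded solution: sample times, a (n_times, n_vars) state array,
    extinction events as (time, variable-name) pairs, and the options used."""

    times: np.ndarray
    states: np.ndarray
    columns: tuple[str, ...]
    events: list[tuple[float, str]] = field(default_factory=list)
    options: SimulationOptions | None = None

    def col(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(self.columns))
        df.insert(0, "time", self.times)
        return df

    def write_csv(self, path, header_lines: Sequence[str] = ()) -> None:
        """Delimited-text export; extra provenance lines are '#'-prefixed."""
        df = self.to_dataframe()
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, index=False, float_format="%.12g")


def integrate_rhs(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: Sequence[float],
    columns: tuple[str, ...],
    options: SimulationOptions,
    absorbing: Sequence[bool] | None = None,
) -> Trajectory:
    """Integrate an arbitrary density ODE with absorbing-extinction handling.

    ``absorbing`` flags which variables are driven extinct when they fall
    below the cutoff (default: all).  Variables with external input (e.g. a
    mutualist pool fed by immigration) should not be absorbing.
    """
    y = np.asarray(y0, dtype=float).copy()
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError(f"initial state must be finite and nonnegative: {y0!r}")
    n = y.size
    absorbing = np.ones(n, bool) if absorbing is None else np.asarray(absorbing, bool)
    thr = options.extinction_threshold

    extinct = np.zeros(n, bool)
    events_log: list[tuple[float, str]] = []
    extinct[absorbing & (y <= thr)] = True
    y[extinct] = 0.0

    def masked_rhs(t: float, yy: np.ndarray) -> np.ndarray:
        out = np.asarray(rhs(t, yy), dtype=float)
        out[extinct] = 0.0
        return out

    record_times = np.arange(
        0.0, options.t_end + 0.5 * options.record_every, options.record_every
    )
    record_times = record_times[record_times <= options.t_end + 1e-12]

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    t_cur = 0.0
    recorded_up_to = -np.inf

    while True:
        t_eval = record_times[
            (record_times > recorded_up_to + 1e-12) & (record_times >= t_cur - 1e-12)
        ]

        event_fns = []
        event_idx = []
        if thr > 0:
            for i in range(n):
                if extinct[i] or not absorbing[i]:
                    continue

                def make_event(i=i):
                    def ev(t, yy):
                        return yy[i] - thr

                    ev.terminal = True
                    ev.direction = -1.0
                    return ev

                event_fns.append(make_event())
                event_idx.append(i)

        sol = solve_ivp(
            masked_rhs,
            (t_cur, options.t_end),
            y,
            method="RK45",
            t_eval=t_eval if t_eval.size else None,
            events=event_fns or None,
            rtol=options.rel_tol,
            atol=options.abs_tol,
            max_step=options.max_step,
        )
        if sol.status == -1:
            t_fail = sol.t[-1] if sol.t.size else t_cur
            raise IntegrationError(f"integration failed at t={t_fail}: {sol.message}")

        if sol.t.size and t_eval.size:
            times_out.append(sol.t)
            states_out.append(sol.y.T)
            recorded_up_to = sol.t[-1]

        if sol.status == 1:  # an extinction event fired
            hits = [(te[0], k) for k, te in enumerate(sol.t_events) if te.size]
            t_ev, k0 = min(hits)
            y = np.clip(np.asarray(sol.y_events[k0][0], float), 0.0, None)
            for t_e, k in hits:
                if t_e <= t_ev + 1e-12:
                    i = event_idx[k]
                    extinct[i] = True
                    y[i] = 0.0
                    events_log.append((float(t_ev), columns[i]))
            t_cur = t_ev
            if t_cur >= options.t_end:
                break
            continue
        break

    times = np.concatenate(times_out) if times_out else np.array([0.0])
    states = np.vstack(states_out) if states_out else y[None, :]
    states = np.clip(states, 0.0, None)
    # stamp extinct species to exactly zero after their event time
    for t_e, name in events_log:
        j = columns.index(name)
        states[times >= t_e, j] = 0.0
    return Trajectory(
        times=times,
        states=states,
        columns=columns,
        events=events_log,
        options=options,
    )


def integrate(
    initial: State | Sequence[float],
    params: ModelParams,
    options: SimulationOptions | None = None,
) -> Trajectory:
    """Integrate the single-patch model from ``initial``.

    Returns a :class:`Trajectory` with columns ``("H", "E", "M")`` sampled
    every ``record_every`` time units.
    """
    options = options or SimulationOptions()

    def rhs(t, y):
        return derivatives(State(*np.clip(y, 0.0, None)), params)

    return integrate_rhs(rhs, initial, ("H", "E", "M"), options)


def _introduction_outcome(
    params: ModelParams,
    resident: str,
    density: float,
    options: SimulationOptions,
) -> bool:
    """True iff the introduced symbiont persists at ``t_end``."""
    if resident == "enemy":
        H = host_eq_with_enemy(params)
        E = enemy_eq_density(params)
        initial = State(H, E, density)
        invader = "M"
    elif resident == "mutualist":
        H = host_eq_with_mutualist(params)
        M = mutualist_eq_density(params)
        initial = State(H, density, M)
        invader = "E"
    else:
        raise ValueError("resident must be 'enemy' or 'mutualist'")
    traj = integrate(initial, params, options)
    return float(traj.col(invader)[-1]) > PERSISTENCE_THRESHOLD


def find_invasion_threshold(
    params: ModelParams,
    resident: str = "enemy",
    m_lo: float = 1e-6,
    m_hi: float = 10.0,
    tol: float = 1e-3,
    options: SimulationOptions | None = None,
) -> float:
    """Bisect the dynamical invasion threshold along the introduction axis.

    The outcome of an introduction at density ``m`` into the resident
    community's equilibrium is classified by whether the introduced symbiont
    is still present (density > ``PERSISTENCE_THRESHOLD``) at ``t_end``.
    Requires the outcome to differ between ``m_lo`` and ``m_hi``.

    This is the dynamical separatrix, not the quasi-static closed form
    ``analytic_m_star``; the two agree in order of magnitude but need not
    coincide.
    """
    options = options or SimulationOptions()
    out_lo = _introduction_outcome(params, resident, m_lo, options)
    out_hi = _introduction_outcome(params, resident, m_hi, options)
    if out_lo == out_hi:
        raise BracketError(
            f"no outcome change in bracket [{m_lo}, {m_hi}]: both "
            f"{'persist' if out_lo else 'go extinct'}"
        )
    lo, hi = m_lo, m_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _introduction_outcome(params, resident, mid, options) == out_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
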