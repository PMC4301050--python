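"""Spatially explicit metacommunity on a toric lattice.

Each patch of an ``n_rows x n_cols`` torus runs the single-patch
host/enemy/mutualist dynamics with its own productivity ``r_ij``, drawn
once per simulation from a Gaussian with mean ``r`` and variance ``v`` (the
environmental-heterogeneity knob).  Both symbionts — but not the host —
disperse with a uniform kernel over the 8 surrounding patches: a patch
loses ``eps_X * X`` per unit time and receives an equal share ``eps_X/8``
of each neighbor's stock, so the operator conserves the regional total of
each symbiont exactly.

Time stepping is operator-split and fixed-step: one vectorized RK4 step of
the local reactions, then a forward-Euler application of the dispersal
fluxes.  This keeps dispersal exactly conservative and runs bit-for-bit
reproducibly for a given seed.

Regional coexistence is measured as the proportion of mutualists in the
total symbiont population, averaged over the trailing portion of the run.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ModelParams

__all__ = [
    "LatticeParams",
    "LatticeResult",
    "draw_productivity_map",
    "neighbor_sum",
    "dispersal_operator",
    "simulate_lattice",
    "mutualist_proportion",
    "sweep_lattice",
    "replicate_seed",
]

#: per-patch density below which a species is zeroed (re-invasion by
#: dispersal remains possible; only the local stock is culled)
EXTINCTION_THRESHOLD = 1e-9

_NEIGHBOR_OFFSETS = [
    (dr, dc)
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    if not (dr == 0 and dc == 0)
]


@dataclass(frozen=True)
class LatticeParams:
    """Lattice configuration around a base single-patch parameter set.

    ``v`` is the variance of the Gaussian productivity distribution (mean
    ``base.r``); ``eps_E``/``eps_M`` are per-capita dispersal rates; ``dt``
    the operator-splitting step; ``n_steps`` the run length in steps and
    ``metric_window`` the trailing number of steps the coexistence metric
    averages over.
    """

    base: ModelParams
    n_rows: int = 10
    n_cols: int = 10
    v: float = 0.0
    eps_E: float = 0.1
    eps_M: float = 0.1
    seed: int = 0
    dt: float = 0.1
    n_steps: int = 5000
    metric_window: int = 1000

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.v < 0 or self.eps_E < 0 or self.eps_M < 0:
            raise ValueError("v, eps_E, eps_M must be >= 0")
        if self.metric_window > self.n_steps:
            raise ValueError("metric_window must be <= n_steps")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def to_dict(self) -> dict:
        d = {f"base_{k}": v for k, v in self.base.to_dict().items()}
        d.update(
            n_rows=self.n_rows, n_cols=self.n_cols, v=self.v,
            eps_E=self.eps_E, eps_M=self.eps_M, seed=self.seed,
            dt=self.dt, n_steps=self.n_steps, metric_window=self.metric_window,
        )
        return d


@dataclass
class LatticeResult:
    """Totals time series, final per-patch grids and run provenance."""

    params: LatticeParams
    productivity: np.ndarray
    times: np.ndarray
    total_H: np.ndarray
    total_E: np.ndarray
    total_M: np.ndarray
    final_H: np.ndarray
    final_E: np.ndarray
    final_M: np.ndarray
    status: str = "ok"
    events: list = field(default_factory=list)

    def totals_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "total_H": self.total_H,
                "total_E": self.total_E,
                "total_M": self.total_M,
            }
        )


def draw_productivity_map(
    r: float, v: float, dims: tuple[int, int], seed: int
) -> np.ndarray:
    """Per-patch growth rates: Gaussian(mean=r, variance=v), drawn once.

    Negative draws are retained — such patches are genuine habitat sinks
    where the host declines; truncating would silently shrink the realized
    heterogeneity.  ``v == 0`` gives a uniform map equal to ``r``.
    """
    if v < 0:
        raise ValueError("v must be >= 0")
    rng = np.random.default_rng(seed)
    if v == 0:
        return np.full(dims, float(r))
    return rng.normal(loc=r, scale=np.sqrt(v), size=dims)


def neighbor_sum(grid: np.ndarray) -> np.ndarray:
    """Sum of the 8 toroidal neighbors of every cell."""
    total = np.zeros_like(grid)
    for dr, dc in _NEIGHBOR_OFFSETS:
        total += np.roll(np.roll(grid, dr, axis=0), dc, axis=1)
    return total


def dispersal_operator(
    E: np.ndarray, M: np.ndarray, eps_E: float, eps_M: float
) -> tuple[np.ndarray, np.ndarray]:
    """Net dispersal fluxes for both symbionts on the torus.

    Each patch loses ``eps_X * X`` and gains ``eps_X/8`` of every
    neighbor's stock; the fluxes of each species sum to zero exactly (up to
    floating-point accumulation), so dispersal conserves regional totals.
    Hosts do not disperse.
    """
    flux_E = eps_E * (neighbor_sum(E) / 8.0 - E)
    flux_M = eps_M * (neighbor_sum(M) / 8.0 - M)
    return flux_E, flux_M


def default_initial_grids(
    p: LatticeParams, productivity: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Each patch at its local host--enemy equilibrium, seeded with 0.01
    mutualists; patches whose host--enemy equilibrium is infeasible start
    at the host's carrying capacity (or empty if ``r_ij <= 0``) with 0.01
    enemies."""
    b = p.base
    r = productivity
    # fallback host density: carrying capacity where defined, else r itself
    K = r / b.q if b.q > 0 else r
    H = np.where(r > 0, K, 0.0)
    E = np.full_like(r, 0.01)
    feasible = r * b.b * b.gamma > b.q * b.delta_E
    H_star_E = b.delta_E / (b.b * b.gamma)
    E_star = (r * b.b * b.gamma - b.q * b.delta_E) / (b.b**2 * b.gamma)
    H = np.where(feasible, H_star_E, H)
    E = np.where(feasible, E_star, E)
    M = np.full_like(r, 0.01)
    return H, E, M


def _reaction_rates(H, E, M, r_map, b: ModelParams):
    c = b.protection_coefficient
    dH = H * (r_map - b.q * H) - b.b * H * E - b.alpha * b.b * H * M
    dE = E * (b.gamma * b.b * H - b.delta_E - c * M)
    dM = M * (b.alpha * b.gamma * b.b * H - b.delta_M)
    return dH, dE, dM


def simulate_lattice(
    p: LatticeParams,
    initial_condition_spec=None,
) -> LatticeResult:
    """Run the operator-split lattice simulation.

    ``initial_condition_spec`` may be a callable ``(params, productivity)
    -> (H, E, M)`` returning per-patch grids; the default places every
    patch at its local host--enemy equilibrium plus a small mutualist
    inoculum (see :func:`default_initial_grids`).

    Deterministic for a given ``p.seed`` (the only random element is the
    productivity map).
    """
    productivity = draw_productivity_map(
        p.base.r, p.v, (p.n_rows, p.n_cols), p.seed
    )
    make_initial = initial_condition_spec or default_initial_grids
    H, E, M = (np.array(g, dtype=float) for g in make_initial(p, productivity))

    n_rec = p.n_steps + 1
    total_H = np.empty(n_rec)
    total_E = np.empty(n_rec)
    total_M = np.empty(n_rec)
    total_H[0], total_E[0], total_M[0] = H.sum(), E.sum(), M.sum()

    dt = p.dt
    for step in range(1, n_rec):
        # local reaction: one classical RK4 step, vectorized over patches
        k1 = _reaction_rates(H, E, M, productivity, p.base)
        k2 = _reaction_rates(
            H + 0.5 * dt * k1[0], E + 0.5 * dt * k1[1], M + 0.5 * dt * k1[2],
            productivity, p.base,
        )
        k3 = _reaction_rates(
            H + 0.5 * dt * k2[0], E + 0.5 * dt * k2[1], M + 0.5 * dt * k2[2],
            productivity, p.base,
        )
        k4 = _reaction_rates(
            H + dt * k3[0], E + dt * k3[1], M + dt * k3[2],
            productivity, p.base,
        )
        H = H + (dt / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        E = E + (dt / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        M = M + (dt / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])

        for grid in (H, E, M):
            np.clip(grid, 0.0, None, out=grid)
            grid[grid < EXTINCTION_THRESHOLD] = 0.0
        if not (np.all(np.isfinite(H)) and np.all(np.isfinite(E)) and np.all(np.isfinite(M))):
            bad = np.argwhere(~(np.isfinite(H) & np.isfinite(E) & np.isfinite(M)))
            raise RuntimeError(
                f"non-finite densities at step {step} (t={step * dt:g}), "
                f"patch {tuple(bad[0])}"
            )

        flux_E, flux_M = dispersal_operator(E, M, p.eps_E, p.eps_M)
        E = E + dt * flux_E
        M = M + dt * flux_M
        np.clip(E, 0.0, None, out=E)
        np.clip(M, 0.0, None, out=M)

        total_H[step], total_E[step], total_M[step] = H.sum(), E.sum(), M.sum()

    return LatticeResult(
        params=p,
        productivity=productivity,
        times=np.arange(n_rec) * dt,
        total_H=total_H,
        total_E=total_E,
        total_M=total_M,
        final_H=H,
        final_E=E,
        final_M=M,
    )


def mutualist_proportion(result: LatticeResult, window: int | None = None) -> float:
    """Mean regional mutualist share sum(M) / (sum(M) + sum(E)) over the
    trailing ``window`` recorded steps.

    Steps at which both symbionts are regionally extinct contribute the
    last defined proportion (the share is then frozen, not 0/0).  If the
    proportion is never defined inside the window, raises ``ValueError``
    ("both-extinct" run).
    """
    window = window if window is not None else result.params.metric_window
    if window <= 0 or window > len(result.times):
        raise ValueError("window must be in (0, number of recorded steps]")
    total = result.total_E + result.total_M
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(total > 0, result.total_M / np.where(total > 0, total, 1.0), np.nan)
    # carry the last defined value over both-extinct stretches
    prop = pd.Series(prop).ffill().to_numpy()
    tail = prop[-window:]
    if np.all(np.isnan(tail)):
        raise ValueError("both symbionts regionally extinct for the whole run")
    return float(np.nanmean(tail))


def replicate_seed(master_seed: int, counter: int) -> int:
    """Deterministic per-replicate seed: hash of (master_seed, counter)
    through numpy's SeedSequence, folded below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(counter)])
    return int(ss.generate_state(1)[0] % (2**31))


def sweep_lattice(
    alpha_grid=(0.1, 0.2, 0.3),
    v_grid=(0.0, 0.5, 1.0),
    eps_E_grid=(0.1,),
    eps_M_grid=(0.001, 0.01, 0.1, 1.0),
    base: ModelParams | None = None,
    n_replicates: int = 5,
    master_seed: int = 0,
    **lattice_kwargs,
) -> pd.DataFrame:
    """Factorial sweep over (alpha, v, eps_E, eps_M) x replicates.

    Every cell/replicate gets a distinct, logged seed derived from
    ``master_seed`` by a counter.  Per-cell failures (e.g. regional
    extinction of both symbionts) are recorded in ``status``, not raised.
    """
    if base is None:
        raise ValueError("base parameters are required")
    grids = [list(g) for g in (alpha_grid, v_grid, eps_E_grid, eps_M_grid)]
    if any(len(g) == 0 for g in grids) or n_replicates < 1:
        raise ValueError("grids must be nonempty and n_replicates >= 1")

    records = []
    counter = 0
    for alpha, v, eps_E, eps_M in itertools.product(*grids):
        for rep in range(n_replicates):
            seed = replicate_seed(master_seed, counter)
            counter += 1
            cell = {
                "alpha": alpha, "v": v, "eps_E": eps_E, "eps_M": eps_M,
                "replicate": rep, "seed": seed,
                "proportion": np.nan, "status": "ok",
            }
            try:
                params = LatticeParams(
                    base=base.replace(alpha=alpha),
                    v=v, eps_E=eps_E, eps_M=eps_M, seed=seed,
                    **lattice_kwargs,
                )
                result = simulate_lattice(params)
                cell["proportion"] = mutualist_proportion(result)
            except (ValueError, RuntimeError) as exc:
                cell["status"] = f"failed: {exc}"
            records.append(cell)
    return pd.DataFrame.from_records(records)
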