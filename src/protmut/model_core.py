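"""Single-patch host / enemy / protective-mutualist model.

The community consists of a self-limited host ``H``, an obligate natural
enemy ``E`` and a conditional protective mutualist ``M``.  Both symbionts
are horizontally transmitted biotrophs with a linear numerical response to
host density and share the transmission parameter ``b`` and progeny size
``gamma``.  The mutualist differs from the enemy in two ways: its impact on
the host (and hence its own recruitment) is scaled by the relative virulence
``alpha`` (the enemy has ``alpha == 1`` by convention), and it removes
enemies at per-capita rate ``M / u`` — the smaller ``u``, the stronger the
protection.

Dynamics::

    dH/dt = H (r - q H) - b H E - alpha b H M
    dE/dt = E (gamma b H - delta_E - M / u)
    dM/dt = M (alpha gamma b H - delta_M)

This module provides the closed-form equilibria of the two-species
subsystems, the net-mutualism criterion ``U``, linear invasion analysis
(invasion rates from rarity, the propagule threshold ``m*``), and local
stability analysis via the Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ModelParams",
    "State",
    "EquilibriumSet",
    "InfeasibleEquilibriumError",
    "ClampedEnemyCollapseError",
    "derivatives",
    "host_eq_with_enemy",
    "host_eq_with_mutualist",
    "enemy_eq_density",
    "mutualist_eq_density",
    "net_mutualism_U",
    "is_net_protective",
    "enemy_invasion_rate",
    "mutualist_invasion_rate",
    "analytic_m_star",
    "clamped_m_growth",
    "jacobian",
    "host_enemy_eq_is_stable",
    "equilibria",
    "random_params",
]

#: residual below which a reported equilibrium is accepted as a fixed point
FIXED_POINT_TOL = 1e-10


class InfeasibleEquilibriumError(ValueError):
    """A requested equilibrium has no positive-density solution."""


class ClampedEnemyCollapseError(ValueError):
    """The (H, E) subsystem with M clamped loses the enemy (E* <= 0)."""


def _default_protection_coefficient(u: float) -> float:
    # per-capita enemy removal per unit mutualist density; 1/u makes low u
    # mean strong defense
    return 1.0 / u


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the single-patch model.

    Parameters
    ----------
    r : host intrinsic growth rate (per time); proxy for productivity.
    q : host crowding coefficient (per density per time); ``q >= 0``.
    b : transmission/attack parameter shared by both symbionts.
    gamma : progeny size (conversion efficiency), shared.
    alpha : mutualist relative virulence; the enemy is normalized to 1.
    delta_E : enemy intrinsic per-capita mortality.
    delta_M : mutualist intrinsic per-capita mortality.
    u : protection parameter (> 0); lower ``u`` = stronger defense.
    """

    r: float
    q: float
    b: float
    gamma: float
    alpha: float
    delta_E: float
    delta_M: float
    u: float

    def __post_init__(self) -> None:
        for name in ("r", "b", "gamma", "alpha", "delta_E", "delta_M", "u"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        if not (math.isfinite(self.q) and self.q >= 0):
            raise ValueError(f"q must be finite and >= 0, got {self.q!r}")

    @property
    def protection_coefficient(self) -> float:
        """Per-capita enemy removal rate per unit of mutualist density."""
        return _default_protection_coefficient(self.u)

    @property
    def feasible_enemy(self) -> bool:
        """Whether the host--enemy equilibrium has E* > 0 (r b gamma > q delta_E)."""
        return self.r * self.b * self.gamma > self.q * self.delta_E

    @property
    def feasible_mutualist(self) -> bool:
        """Whether the host--mutualist equilibrium has M* > 0 (r b alpha gamma > q delta_M)."""
        return self.r * self.b * self.alpha * self.gamma > self.q * self.delta_M

    def replace(self, **changes) -> "ModelParams":
        from dataclasses import replace as _replace

        return _replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "q": self.q,
            "b": self.b,
            "gamma": self.gamma,
            "alpha": self.alpha,
            "delta_E": self.delta_E,
            "delta_M": self.delta_M,
            "u": self.u,
        }

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParams":
        unknown = set(mapping) - {
            "r", "q", "b", "gamma", "alpha", "delta_E", "delta_M", "u",
        }
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


class State(NamedTuple):
    """Nonnegative densities of host, enemy and mutualist."""

    H: float
    E: float
    M: float


def _validate_state(state) -> State:
    H, E, M = state
    if not all(math.isfinite(x) for x in (H, E, M)):
        raise ValueError(f"state must be finite, got {state!r}")
    if H < 0 or E < 0 or M < 0:
        raise ValueError(f"state must be nonnegative, got {state!r}")
    return State(H, E, M)


def derivatives(state, params: ModelParams) -> tuple[float, float, float]:
    """Instantaneous rates (dH/dt, dE/dt, dM/dt) of the three densities.

    Both symbiont equations are per-capita, so zero density is absorbing;
    the mutualist gains nothing from removing enemies (its equation does
    not involve ``E``).
    """
    H, E, M = _validate_state(state)
    p = params
    c = p.protection_coefficient
    dH = H * (p.r - p.q * H) - p.b * H * E - p.alpha * p.b * H * M
    dE = E * (p.gamma * p.b * H - p.delta_E - c * M)
    dM = M * (p.alpha * p.gamma * p.b * H - p.delta_M)
    return (dH, dE, dM)


def host_eq_with_enemy(params: ModelParams) -> float:
    """Host density H*_E at which the enemy just replaces itself (M = 0)."""
    return params.delta_E / (params.b * params.gamma)


def host_eq_with_mutualist(params: ModelParams) -> float:
    """Host density H*_M at which the mutualist just replaces itself (E = 0)."""
    return params.delta_M / (params.alpha * params.b * params.gamma)


def enemy_eq_density(params: ModelParams) -> float:
    """Enemy density E* at the host--enemy equilibrium (H*_E, E*, 0).

    Raises
    ------
    InfeasibleEquilibriumError
        If ``r b gamma <= q delta_E`` (host self-limitation alone holds the
        host below the enemy's replacement density).
    """
    p = params
    num = p.r * p.b * p.gamma - p.q * p.delta_E
    if num < 0:
        raise InfeasibleEquilibriumError(
            "host-enemy equilibrium infeasible: r*b*gamma <= q*delta_E"
        )
    return num / (p.b**2 * p.gamma)


def mutualist_eq_density(params: ModelParams) -> float:
    """Mutualist density M* at the host--mutualist equilibrium (H*_M, 0, M*).

    Positive exactly when ``r b alpha gamma > q delta_M``.
    """
    p = params
    num = p.r * p.alpha * p.b * p.gamma - p.q * p.delta_M
    if num < 0:
        raise InfeasibleEquilibriumError(
            "host-mutualist equilibrium infeasible: r*b*alpha*gamma <= q*delta_M"
        )
    return num / (p.alpha**2 * p.b**2 * p.gamma)


def net_mutualism_U(params: ModelParams) -> float:
    """Net-mutualism criterion U = H*_M - H*_E.

    The host equilibrates at a higher density with the mutualist alone than
    with the enemy alone exactly when U > 0.
    """
    return host_eq_with_mutualist(params) - host_eq_with_enemy(params)


def is_net_protective(params: ModelParams) -> bool:
    """True when the mutualist has a net positive effect on the host.

    Evaluates the protection inequality ``delta_M > alpha * delta_E``,
    which is algebraically equivalent to ``net_mutualism_U > 0``: the
    mutualist must exploit the host lightly (low alpha) or die fast
    relative to the enemy.
    """
    return params.delta_M > params.alpha * params.delta_E


def enemy_invasion_rate(params: ModelParams) -> float:
    """Per-capita growth of a rare enemy at the host--mutualist equilibrium.

    Positive return means the enemy invades from rarity.  Requires the
    resident host--mutualist equilibrium to be feasible.
    """
    if not params.feasible_mutualist:
        raise InfeasibleEquilibriumError(
            "resident host-mutualist equilibrium infeasible"
        )
    H = host_eq_with_mutualist(params)
    M = mutualist_eq_density(params)
    return (
        params.gamma * params.b * H
        - params.delta_E
        - params.protection_coefficient * M
    )


def mutualist_invasion_rate(params: ModelParams) -> float:
    """Per-capita growth of a rare mutualist at the host--enemy equilibrium.

    Equal to ``alpha * gamma * b * H*_E - delta_M = alpha*delta_E - delta_M``.
    Never positive when the mutualist is net protective: a net-beneficial
    variant cannot invade from rarity.
    """
    if not params.feasible_enemy:
        raise InfeasibleEquilibriumError("resident host-enemy equilibrium infeasible")
    H = host_eq_with_enemy(params)
    return params.alpha * params.gamma * params.b * H - params.delta_M


def analytic_m_star(params: ModelParams) -> float:
    """Propagule threshold m*: minimum mutualist density needed to establish.

    Obtained quasi-statically: clamp the mutualist at density ``m``, let the
    (H, E) subsystem equilibrate, and ask when the mutualist's per-capita
    growth there turns positive.  Closed form ``u (delta_M - alpha delta_E)
    / alpha``, positive exactly when U > 0.  Returns 0 when the mutualist
    can invade from rarity (U <= 0).

    m* increases with ``u`` (weaker protection raises the bar) and
    decreases with ``alpha``.
    """
    m = params.u * (params.delta_M - params.alpha * params.delta_E) / params.alpha
    return max(m, 0.0)


def clamped_m_growth(params: ModelParams, m: float) -> float:
    """Mutualist per-capita growth with M clamped at density ``m``.

    The (H, E) subsystem with a fixed mutualist density ``m`` equilibrates
    at ``H_clamped(m) = (delta_E + m/u) / (gamma b)``; the returned value is
    ``alpha gamma b H_clamped(m) - delta_M``, whose sign flips at
    ``analytic_m_star``.

    Raises
    ------
    ClampedEnemyCollapseError
        If the clamped subsystem has no positive enemy density (the clamp
        is strong enough to drive the enemy out, so the relevant comparison
        is against the enemy-free host equilibrium instead).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    p = params
    c = p.protection_coefficient
    H_clamped = (p.delta_E + c * m) / (p.gamma * p.b)
    # enemy density solving dH/dt = 0 at H_clamped with M = m
    E_clamped = (p.r - p.q * H_clamped - p.alpha * p.b * m) / p.b
    if E_clamped <= 0:
        raise ClampedEnemyCollapseError(
            "clamped (H,E) subsystem loses the enemy at this m"
        )
    return p.alpha * p.gamma * p.b * H_clamped - p.delta_M


def jacobian(state, params: ModelParams) -> np.ndarray:
    """3x3 Jacobian of the rate field at ``state`` (rows: H, E, M)."""
    H, E, M = _validate_state(state)
    p = params
    c = p.protection_coefficient
    return np.array(
        [
            [
                p.r - 2 * p.q * H - p.b * E - p.alpha * p.b * M,
                -p.b * H,
                -p.alpha * p.b * H,
            ],
            [p.gamma * p.b * E, p.gamma * p.b * H - p.delta_E - c * M, -c * E],
            [p.alpha * p.gamma * p.b * M, 0.0, p.alpha * p.gamma * p.b * H - p.delta_M],
        ]
    )


def host_enemy_eq_is_stable(params: ModelParams) -> bool:
    """Local stability of the host--enemy equilibrium (H*_E, E*, 0).

    True iff both eigenvalues of the (H, E) sub-Jacobian have negative real
    part.  With any host self-limitation (q > 0) the equilibrium is a
    stable focus or node; at q = 0 the linearization is neutrally stable
    (purely imaginary pair, the classical Lotka-Volterra center) and this
    predicate returns False.
    """
    H = host_eq_with_enemy(params)
    E = enemy_eq_density(params)  # raises if infeasible
    J = jacobian(State(H, E, 0.0), params)[:2, :2]
    return bool(np.all(np.linalg.eigvals(J).real < 0))


@dataclass(frozen=True)
class EquilibriumSet:
    """Closed-form boundary equilibria; ``None`` marks an infeasible one.

    Construction verifies that every feasible equilibrium zeroes the rate
    field to ``FIXED_POINT_TOL``.
    """

    H_star_E: float | None
    H_star_M: float | None
    E_star: float | None
    M_star: float | None

    def to_dict(self) -> dict:
        return {
            "H_star_E": self.H_star_E,
            "H_star_M": self.H_star_M,
            "E_star": self.E_star,
            "M_star": self.M_star,
        }


def equilibria(params: ModelParams) -> EquilibriumSet:
    """Compute and verify the boundary equilibria of the model."""
    H_E = host_eq_with_enemy(params)
    H_M = host_eq_with_mutualist(params)
    try:
        E_star = enemy_eq_density(params)
    except InfeasibleEquilibriumError:
        E_star = None
    try:
        M_star = mutualist_eq_density(params)
    except InfeasibleEquilibriumError:
        M_star = None

    candidates = []
    if E_star is not None:
        candidates.append(State(H_E, E_star, 0.0))
    if M_star is not None:
        candidates.append(State(H_M, 0.0, M_star))
    for fp in candidates:
        residual = max(abs(x) for x in derivatives(fp, params))
        if residual >= FIXED_POINT_TOL:
            raise AssertionError(
                f"equilibrium {fp} has residual {residual:.3e} >= {FIXED_POINT_TOL}"
            )
    return EquilibriumSet(
        H_star_E=H_E,
        H_star_M=H_M,
        E_star=E_star,
        M_star=M_star,
    )


def random_params(
    rng: np.random.Generator,
    *,
    require_feasible_enemy: bool = False,
    require_feasible_mutualist: bool = False,
    require_net_protective: bool = False,
    low: float = 1e-2,
    high: float = 1e1,
    max_tries: int = 10_000,
) -> ModelParams:
    """Draw a random parameter set, log-uniform per rate on [low, high].

    Rejection-samples until the requested feasibility/protection predicates
    hold.  Used by property tests and acceptance checks.
    """
    lo, hi = math.log(low), math.log(high)
    for _ in range(max_tries):
        draw = np.exp(rng.uniform(lo, hi, size=8))
        p = ModelParams(
            r=draw[0], q=draw[1], b=draw[2], gamma=draw[3],
            alpha=draw[4], delta_E=draw[5], delta_M=draw[6], u=draw[7],
        )
        if require_feasible_enemy and not p.feasible_enemy:
            continue
        if require_feasible_mutualist and not p.feasible_mutualist:
            continue
        if require_net_protective and not is_net_protective(p):
            continue
        return p
    raise RuntimeError("rejection sampling failed to find a valid parameter set")
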