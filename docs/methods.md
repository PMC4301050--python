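# Methods

## The model

`protmut` simulates a community of a host (density `H`), a natural enemy
(`E`) and a *conditional protective mutualist* (`M`) — a symbiont that
exploits the host itself but suppresses the more damaging enemy. Both
symbionts are obligate, horizontally transmitted biotrophs with a linear
numerical response to host density; they share the transmission parameter
`b` and progeny size `γ`, as expected for closely related variants:

    dH/dt = H (r − q H) − b H E − α b H M
    dE/dt = E (γ b H − δ_E − M/u)
    dM/dt = M (α γ b H − δ_M)

* `r` — host intrinsic growth rate, read as environmental productivity.
* `q` — crowding (density-dependent mortality) coefficient; `q ≥ 0`.
* `α` — relative virulence of the mutualist (the enemy is normalized to
  `α = 1`). Virulence and recruitment are coupled: a gentler symbiont also
  grows more slowly on the same hosts.
* `δ_E`, `δ_M` — intrinsic symbiont mortalities.
* `u > 0` — protection parameter; the enemy suffers an extra per-capita
  death rate `M/u`, so *smaller* `u` means *stronger* defense. The
  protection term removes enemies without feeding the mutualist (`dM/dt`
  is independent of `E`). The coefficient `1/u` is isolated in
  `ModelParams.protection_coefficient` so an alternative parameterization
  can be swapped in one place.

Model assumptions worth keeping in mind: no multiple infection, recovery,
host immunity or vertical transmission, and no evolution of `α` or `u`.

## Single-patch analysis (`model_core`)

Boundary equilibria have closed forms: `H*_E = δ_E/(bγ)`,
`H*_M = δ_M/(αbγ)`, `E* = (rbγ − qδ_E)/(b²γ)`,
`M* = (rαbγ − qδ_M)/(α²b²γ)` (positive iff `rbαγ > qδ_M`). Infeasible
equilibria are reported as explicit flags (`None` /
`InfeasibleEquilibriumError`), never as negative densities; `equilibria()`
verifies every reported fixed point against the rate field to a residual
of 1e−10 at construction.

The **net-mutualism criterion** is `U = H*_M − H*_E`: the host sits at a
higher equilibrium with the mutualist alone than with the enemy alone
exactly when `U > 0`, which reduces to the protection inequality
`δ_M > α δ_E`.

**Invasion analysis.** The per-capita growth of a rare mutualist at the
host–enemy equilibrium is `α δ_E − δ_M`, which is ≤ 0 whenever `U > 0`:
a net-protective variant can *never* invade from rarity. It can, however,
establish from a sufficiently large inoculum. Clamping the mutualist at
density `m` and letting the host–enemy pair equilibrate gives the host
density `H(m) = (δ_E + m/u)/(γb)`, and the clamped mutualist growth
`αγb·H(m) − δ_M` changes sign at the propagule threshold

    m* = u (δ_M − α δ_E) / α,

positive exactly when `U > 0`, increasing in `u` and decreasing in `α`.
The clamp construction is quasi-static, valid only while the clamped
subsystem retains a positive enemy density (`m` not too large, flagged
otherwise); the true dynamical separatrix found by
`dynamics.find_invasion_threshold` (bisection on simulated outcomes)
agrees with `m*` in order of magnitude but is systematically somewhat
larger (0.16 vs 0.10 for the worked parameter set below).

Two statements in the source literature for this model family are *not*
reproduced by these derivations and are deliberately not asserted
anywhere: (i) that enemy invasion of a resident mutualist is favored by
large `r` — under this reconstruction larger `r` raises `M*` and thereby
*hinders* enemy invasion; and (ii) one description has the threshold
falling with *high* `α` while the accompanying analysis says *low* `α`
lowers it — the derived `m*` decreases with `α`. The implementation
follows the derivations, which the numerical experiments confirm.

**Stability.** At the host–enemy equilibrium the (H,E) Jacobian block has
trace `−qH*_E` and positive determinant, so any `q > 0` gives asymptotic
stability (damped oscillations); at `q = 0` the linearization is the
classical neutral Lotka–Volterra center and `host_enemy_eq_is_stable`
returns `False`.

## Time integration (`dynamics`)

`integrate` wraps scipy's adaptive RK45 (default tolerances 1e−8/1e−8)
with absorbing extinction: when a species crosses
`extinction_threshold = 1e−9` from above (solver event), it is set to
exactly 0 for the rest of the run. This is a deterministic stand-in for
demographic stochasticity at vanishing densities; set the threshold to 0
to disable it. Persistence at the end of a run is judged against a
separate cutoff of 1e−6 at `t_end = 2000`. Trajectories are sampled on a
fixed grid (`record_every`, default 1 time unit) and export as plain CSV.

`find_invasion_threshold` bisects the introduction density between a
bracket whose two ends must lead to different outcomes (introduced
symbiont persistent vs extinct); a bracket without an outcome change
raises `BracketError` rather than returning a fabricated number.

## Two-patch source–sink model (`two_patch`)

Patch 1 (source) runs the host–mutualist subsystem at productivity `r1`;
patch 2 (sink) runs the full model at productivity `r` and receives
mutualist immigrants at rate `ε1·M1`. Emigrants are debited from the
source by default (`include_emigration_loss=True`; conservation is the
defensible default, and the flag exposes the alternative since only the
arrival term is fixed by the model description). `q` is a host trait
shared by both patches; hosts and enemies do not disperse. A "generation"
is one model time unit; the standard summary is the mean sink mutualist
density over the last 200 of 2000 unit-spaced samples, from a default
initial condition of source-at-equilibrium and a mutualist-free sink.

Because immigration makes `M2 = 0` non-absorbing, the sink mutualist pool
is excluded from extinction zeroing whenever `ε1 > 0`.

## Lattice metacommunity (`lattice`)

A 10×10 torus (every patch has exactly 8 neighbors) with per-patch
productivity drawn once per run from `Normal(r, v)`. Negative draws are
retained as genuine sink habitat — truncation would silently shrink the
realized heterogeneity. Symbionts disperse with a uniform kernel: each
patch loses `ε_X·X` and receives `ε_X/8` of each neighbor's stock per
unit time; hosts do not disperse. The operator conserves regional totals
exactly, which is why time stepping is operator-split and fixed-step: one
vectorized classical RK4 step of the local reactions (dt = 0.1), then a
forward-Euler application of the dispersal fluxes. Per-patch densities
below 1e−9 are zeroed each step, but patches can be re-colonized by
dispersal. Defaults: 5000 steps, coexistence metric averaged over the
last 1000. On a 1×1 torus all eight neighbor slots alias the focal patch
and the operator self-cancels, so the model reduces exactly to the
single-patch system (documented, not special-cased).

The **regional coexistence metric** is the mean over the metric window of
`ΣM/(ΣM+ΣE)` (sums over patches). Values near 0 or 1 mean enemy or
mutualist dominance; intermediate values mean regional coexistence. If
both symbionts are regionally extinct at a step, that step carries the
last defined share; a run where the share is never defined is reported as
"both-extinct" rather than given a number.

**Initial conditions** (pluggable via `initial_condition_spec`): by
default each patch starts at its local host–enemy equilibrium with 0.01
mutualists; patches whose host–enemy equilibrium is infeasible start at
the host carrying capacity (empty if `r_ij ≤ 0`) with 0.01 enemies. The
mutualist therefore starts rare *everywhere*, so in a homogeneous
landscape (`v = 0`, all patches identical, dispersal fluxes cancel) the
no-invasion-from-rarity result applies patch by patch and the mutualist
is regionally excluded — the model's negative control.

**Mechanism of heterogeneous rescue.** With `v > 0` the rescue is driven
by enemy-dispersal drain: high-productivity patches surrounded by poorer
neighbors lose enemies on net, which raises their standing host density
above `δ_M/(αγb)` and lets the locally retained (slowly dispersing)
mutualist grow past its threshold. Establishment therefore requires the
enemy to disperse distinctly faster than the mutualist; at `α = 0.3`,
`ε_E = 1` suffices, while the gentler `α = 0.1` variant needs `ε_E ≈ 3`
and establishes more slowly and in fewer cells. Once established,
mutualist-held patches suppress enemies locally and can take over the
whole landscape (regional enemy exclusion at `α = 0.3`, `v ≥ 0.5`).

## Default experiment parameters

Patch experiments use `b = 1`, `δ_E = δ_M = 0.1`, `r = 1`, `γ = 0.1`,
`u = 1`, with `α = 0.5`, `q = 0.4` as the standard single-patch worked
set. The lattice experiments use the same rates with `q = 0.05` and
`α ∈ {0.1, 0.2, 0.3}`: the published description of this experiment does
not pin `q` or the dispersal grids, and weak crowding is the regime in
which host productivity differences translate into large host-density
differences between patches (crowding is also the knob that most
strongly protects the resident enemy in the two-patch sweeps). Dispersal
grids are `ε_E ∈ {1, 3}`, `ε_M ∈ {1e−4, …, 1e−1}`, chosen to span the
low-, intermediate- and high-dispersal regimes of the mutualist while
keeping the enemy in the fast-dispersing regime the rescue mechanism
requires. These choices were fixed once; replicate seeds are derived from
a master seed through `numpy.random.SeedSequence([master, counter])`.

## What the synthetic landscape does and does not establish

The productivity map is iid Gaussian per patch — no spatial
autocorrelation, no temporal fluctuation, no correlated habitat
structure. A green lattice test therefore establishes that *static,
uncorrelated* productivity heterogeneity plus asymmetric dispersal can
maintain regional coexistence of a net-protective mutualist and its
enemy; it says nothing about autocorrelated landscapes, host dispersal,
or demographic noise (the simulator is deterministic given the map).
Fixed-step RK4 at dt = 0.1 is adequate for the default rate scales
(per-capita rates up to ~5); very weak crowding combined with large
productivity draws can leave the fixed-step scheme outside its stability
region, which the simulator reports as a non-finite-density error with
patch coordinates rather than silently clipping.

## Known limitations

* The quasi-static `m*` is an approximation to the dynamical separatrix;
  tests bracket, not equate, the two.
* The lattice integrator trades adaptive error control for exact
  dispersal conservation and bitwise reproducibility; a step-halving
  check is part of the test suite.
* Two-patch migration is directional mutualist-only by construction; no
  host or enemy migration, no back-flow.
* At `α = 0.1` regional establishment within the default 5000 steps is
  marginal (few dispersal cells, small shares); longer runs strengthen it.
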