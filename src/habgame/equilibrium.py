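"""Coupled population-Nash fixed points and parameter sweeps.

A coexistence equilibrium is a positive population pair at which both net
per-capita growth rates vanish when evaluated at the instantaneous Nash
strategies for those populations.  The default algorithm is an outer 2-D
root solve on ``(log N_c, log N_p)`` with the inner Nash solve warm-started
between evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .grid import HabitatGrid
from .model import (
    EnvironmentProfiles,
    ModelParameters,
    PopulationState,
    percap_growth_rates,
    environment_profiles,
    with_overrides,
)
from .nash import NashSolution, SolverFailureError, solve_nash

SEARCH_BOX = (1e-6, 1e4)


class NoCoexistenceError(RuntimeError):
    """No interior root of the population dynamics was found."""


@dataclass(frozen=True)
class EquilibriumResult:
    state: PopulationState
    nash: NashSolution
    growth_residuals: tuple[float, float]
    multistart_agreement: float | None
    converged: bool


@dataclass
class SweepResult:
    parameter: str
    values: np.ndarray
    states: list[PopulationState | None]
    nash_solutions: list[NashSolution | None]
    converged: list[bool]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per parameter value."""
        return pd.DataFrame({
            self.parameter: self.values,
            "N_c": [s.N_c if s is not None else np.nan for s in self.states],
            "N_p": [s.N_p if s is not None else np.nan for s in self.states],
            "converged": self.converged,
        })

    def strategies_frame(self, grid: HabitatGrid,
                         species: str = "c") -> pd.DataFrame:
        """Wide table: rows are depths, one strategy column per value."""
        data = {"depth": grid.depths}
        for v, sol in zip(self.values, self.nash_solutions):
            col = f"{self.parameter}={v:g}"
            if sol is None:
                data[col] = np.full(grid.n_nodes, np.nan)
            elif species == "c":
                data[col] = sol.strategies.sigma_c
            else:
                data[col] = sol.strategies.sigma_p
        return pd.DataFrame(data)


def constant_behavior_equilibrium(params: ModelParameters,
                                  env: EnvironmentProfiles,
                                  grid: HabitatGrid,
                                  tol: float = 1e-12):
    """Coexistence root of the planar constant-behavior system.

    With both strategies pinned to uniform the dynamics reduce to two
    scalar equations; used as a starting guess and as an oracle.
    Returns None when no interior root is found.
    """
    from .dynamics import constant_behavior_reduction

    red = constant_behavior_reduction(params, env, grid)

    def rates(u):
        N_c, N_p = np.exp(np.clip(u, -40.0, 40.0))
        return red.rates(N_c, N_p)

    for guess in ((0.3, 0.05), (1.0, 0.1), (0.05, 0.01)):
        sol = scipy.optimize.root(rates, np.log(guess), method="hybr",
                                  tol=tol)
        if sol.success and np.max(np.abs(sol.fun)) < 1e-9:
            N_c, N_p = np.exp(sol.x)
            return PopulationState(N_c=float(N_c), N_p=float(N_p))
    return None


def _solve_from(u0, params, env, grid, tol, nash_tol, cache):
    """One outer root solve; ``cache`` holds the warm-start Nash solution."""

    log_box = (np.log(SEARCH_BOX[0]) - 3.0, np.log(SEARCH_BOX[1]) + 3.0)

    def residual(u):
        # keep wild outer steps inside a padded box so the inner game
        # solve stays well posed; a clamped point is never accepted
        u = np.clip(u, *log_box)
        state = PopulationState(N_c=float(np.exp(u[0])),
                                N_p=float(np.exp(u[1])))
        try:
            sol = solve_nash(state, params, env, grid, init=cache.get("sol"),
                             tol=nash_tol)
        except SolverFailureError as err:
            # keep the outer root solve alive on a failed inner solve: use
            # the best iterate but poison the cache so it is never accepted
            sol = err.best
            f_c, f_p = percap_growth_rates(state, sol.strategies, params,
                                           env, grid)
            cache["last"] = (state, sol, (f_c, f_p))
            cache["failed"] = True
            return [f_c, f_p]
        cache["sol"] = sol
        f_c, f_p = percap_growth_rates(state, sol.strategies, params, env,
                                       grid)
        cache["last"] = (state, sol, (f_c, f_p))
        return [f_c, f_p]

    out = scipy.optimize.root(residual, u0, method="hybr",
                              options={"xtol": 1e-13})
    cache.pop("failed", None)
    residual(out.x)  # make the cache consistent with the returned point
    state, sol, f = cache["last"]
    ok = (not cache.get("failed", False)
          and sol.residuals.converged
          and max(abs(f[0]), abs(f[1])) <= tol
          and SEARCH_BOX[0] <= state.N_c <= SEARCH_BOX[1]
          and SEARCH_BOX[0] <= state.N_p <= SEARCH_BOX[1])
    return state, sol, f, ok


def solve_coexistence_equilibrium(
        params: ModelParameters, env: EnvironmentProfiles, grid: HabitatGrid,
        init: PopulationState | None = None, tol: float = 1e-9,
        nash_tol: float | None = None, n_restarts: int = 0,
        seed: int | None = None) -> EquilibriumResult:
    """Find the positive coexistence fixed point under equilibrium behavior.

    ``n_restarts`` extra random starts (log-uniform over a wide box) give a
    multistart agreement metric: the maximum pairwise distance of the
    converged population pairs.  Raises :class:`NoCoexistenceError` if no
    interior root is found from any start.
    """
    if nash_tol is None:
        nash_tol = min(1e-10, tol)
    starts = []
    if init is not None:
        starts.append((init.N_c, init.N_p))
    else:
        guess = constant_behavior_equilibrium(params, env, grid)
        if guess is not None:
            starts.append((guess.N_c, guess.N_p))
        starts.extend([(0.3, 0.05), (1.0, 0.1), (0.03, 0.01)])
    solutions = []
    result = None
    for N_c0, N_p0 in starts:
        cache: dict = {}
        state, sol, f, ok = _solve_from(np.log([N_c0, N_p0]), params, env,
                                        grid, tol, nash_tol, cache)
        if ok:
            result = (state, sol, f)
            solutions.append(state)
            break
    if result is None:
        raise NoCoexistenceError(
            f"no coexistence root found in the box {SEARCH_BOX}; "
            f"last iterate N=({state.N_c:.3e}, {state.N_p:.3e}), "
            f"rates=({f[0]:.3e}, {f[1]:.3e})")
    agreement = None
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            u0 = rng.uniform(np.log(1e-2), np.log(1e2), size=2)
            cache = {}
            state_r, _, _, ok = _solve_from(u0, params, env, grid, tol,
                                            nash_tol, cache)
            if ok:
                solutions.append(state_r)
        pts = np.array([(s.N_c, s.N_p) for s in solutions])
        diffs = pts[:, None, :] - pts[None, :, :]
        agreement = float(np.max(np.linalg.norm(diffs, axis=-1)))
    state, sol, f = result
    return EquilibriumResult(state=state, nash=sol, growth_residuals=f,
                             multistart_agreement=agreement, converged=True)


def sweep_parameter(params: ModelParameters, grid: HabitatGrid, which: str,
                    values, tol: float = 1e-9,
                    env_builder=environment_profiles) -> SweepResult:
    """Continuation sweep of the coexistence equilibrium over ``K`` or ``c``.

    Each point warm-starts from the previous one; failures are flagged in
    the result, never dropped silently.
    """
    if which not in ("K", "c"):
        raise ValueError(f"sweep parameter must be 'K' or 'c', got {which!r}")
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(values) < 0):
        raise ValueError("sweep values must be sorted ascending")
    if np.any(values < 0):
        raise ValueError("sweep values must be nonnegative")
    states: list = []
    nashes: list = []
    flags: list = []
    warm: PopulationState | None = None
    for v in values:
        p_v = with_overrides(params, **{which: float(v)})
        env_v = env_builder(p_v, grid)
        try:
            res = solve_coexistence_equilibrium(p_v, env_v, grid, init=warm,
                                                tol=tol)
        except (NoCoexistenceError, SolverFailureError):
            if warm is not None:
                # retry cold in case the warm start sat in a bad basin
                try:
                    res = solve_coexistence_equilibrium(p_v, env_v, grid,
                                                        tol=tol)
                except (NoCoexistenceError, SolverFailureError):
                    res = None
            else:
                res = None
        if res is None:
            states.append(None)
            nashes.append(None)
            flags.append(False)
        else:
            states.append(res.state)
            nashes.append(res.nash)
            flags.append(True)
            warm = res.state
    return SweepResult(parameter=which, values=values, states=states,
                       nash_solutions=nashes, converged=flags)
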