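"""Forward-Euler simulation of the slow population dynamics.

In ``optimal`` mode the instantaneous game is re-solved (warm-started) at
every Euler step; in ``constant`` mode both strategies are pinned to the
uniform density, which reduces the system to a planar ODE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import HabitatGrid, inner_product
from .model import (
    EnvironmentProfiles,
    ModelParameters,
    PopulationState,
    StrategyPair,
    percap_growth_rates,
    uniform_pair,
)
from .nash import NashSolution, SolverFailureError, solve_nash


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray
    N_c: np.ndarray
    N_p: np.ndarray
    behavior_mode: str
    snapshot_times: np.ndarray | None = None
    snapshots: list | None = None  # StrategyPair per stored step
    halted: bool = False
    diagnostic: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "N_c": self.N_c,
                             "N_p": self.N_p})

    def snapshots_frame(self, grid: HabitatGrid,
                        species: str = "c") -> pd.DataFrame:
        if self.snapshots is None:
            raise ValueError("trajectory holds no strategy snapshots")
        data = {"depth": grid.depths}
        for t, pair in zip(self.snapshot_times, self.snapshots):
            sigma = pair.sigma_c if species == "c" else pair.sigma_p
            data[f"t={t:g}"] = sigma
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ConstantBehaviorReduction:
    """Quadrature constants reducing the uniform-strategy system to a plane.

    ``A = <1/capacity, 1>``, ``b_bar = <beta_p, 1>`` and ``q`` the
    quadratic-loss coefficient under the uniform predator strategy (equal to
    ``b_bar`` on this model).
    """

    A: float
    b_bar: float
    q: float
    beta_c: float
    F_p: float
    eps: float
    mu_p: float
    c: float

    def rates(self, N_c: float, N_p: float) -> tuple[float, float]:
        den = self.F_p + N_c * self.b_bar
        f_c = (self.beta_c * (1.0 - N_c * self.A)
               - self.F_p * N_p * self.b_bar / den)
        f_p = (self.eps * self.F_p * N_c * self.b_bar / den
               - self.c * N_p * self.q - self.mu_p)
        return f_c, f_p


def constant_behavior_reduction(params: ModelParameters,
                                env: EnvironmentProfiles,
                                grid: HabitatGrid) -> ConstantBehaviorReduction:
    ones = np.ones(grid.n_nodes)
    A = inner_product(1.0 / env.capacity, ones, grid)
    b_bar = inner_product(env.beta_p, ones, grid)
    return ConstantBehaviorReduction(A=A, b_bar=b_bar, q=b_bar,
                                     beta_c=params.beta_c, F_p=params.F_p,
                                     eps=params.eps, mu_p=params.mu_p,
                                     c=params.c)


def step_euler(state: PopulationState, sigma: StrategyPair,
               params: ModelParameters, env: EnvironmentProfiles,
               grid: HabitatGrid, h: float) -> PopulationState:
    """One forward-Euler step ``N <- max(0, N * (1 + h f))``."""
    if h <= 0:
        raise ValueError("time step h must be positive")
    f_c, f_p = percap_growth_rates(state, sigma, params, env, grid)
    return PopulationState(
        N_c=max(0.0, state.N_c * (1.0 + h * f_c)),
        N_p=max(0.0, state.N_p * (1.0 + h * f_p)),
    )


def simulate(params: ModelParameters, env: EnvironmentProfiles,
             grid: HabitatGrid, initial: PopulationState, t_end: float,
             h: float = 0.01, behavior_mode: str = "optimal",
             snapshot_stride: int = 10,
             nash_tol: float = 1e-9) -> Trajectory:
    """Integrate the population dynamics from ``initial`` up to ``t_end``.

    In ``optimal`` mode a per-step Nash failure halts the run; the partial
    trajectory is returned with ``halted=True`` and a diagnostic message.
    """
    if t_end <= 0 or h <= 0:
        raise ValueError("t_end and h must be positive")
    if behavior_mode not in ("optimal", "constant"):
        raise ValueError(f"behavior_mode must be 'optimal' or 'constant', "
                         f"got {behavior_mode!r}")
    n_steps = int(round(t_end / h))
    times = np.arange(n_steps + 1) * h
    N_c = np.empty(n_steps + 1)
    N_p = np.empty(n_steps + 1)
    N_c[0], N_p[0] = initial.N_c, initial.N_p
    state = initial
    uniform = uniform_pair(grid)
    warm: NashSolution | None = None
    snap_times: list[float] = []
    snaps: list[StrategyPair] = []
    halted = False
    diagnostic = None
    for k in range(n_steps + 1):
        if behavior_mode == "optimal":
            try:
                warm = solve_nash(state, params, env, grid, init=warm,
                                  tol=nash_tol)
            except SolverFailureError as err:
                halted = True
                diagnostic = (f"Nash solve failed at t={times[k]:.4f}: {err}")
                times = times[:k + 1]
                N_c, N_p = N_c[:k + 1], N_p[:k + 1]
                break
            sigma = warm.strategies
        else:
            sigma = uniform
        if snapshot_stride and k % snapshot_stride == 0:
            snap_times.append(times[k])
            snaps.append(StrategyPair(sigma_c=sigma.sigma_c.copy(),
                                      sigma_p=sigma.sigma_p.copy()))
        if k == n_steps:
            break
        state = step_euler(state, sigma, params, env, grid, h)
        N_c[k + 1], N_p[k + 1] = state.N_c, state.N_p
    return Trajectory(times=times, N_c=N_c, N_p=N_p,
                      behavior_mode=behavior_mode,
                      snapshot_times=np.array(snap_times),
                      snapshots=snaps, halted=halted, diagnostic=diagnostic)


def quarter_amplitude_ratio(series: np.ndarray) -> float:
    """Peak-to-peak amplitude of the last quarter over the one before it.

    A ratio near (or above) 1 indicates sustained oscillation; a ratio well
    below 1 indicates damping.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    q = n // 4
    third = series[2 * q:3 * q]
    fourth = series[3 * q:]
    amp3 = float(np.ptp(third))
    amp4 = float(np.ptp(fourth))
    if amp3 == 0.0:
        return 1.0 if amp4 == 0.0 else np.inf
    return amp4 / amp3
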