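"""Numerical probes of the game's theoretical structure.

These are samplers, not proofs: an absence of violations is reported as
consistency with the property, never as verification.  Margins are logged
so regressions remain visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .grid import HabitatGrid, inner_product
from .model import (
    EnvironmentProfiles,
    ModelParameters,
    PopulationState,
    StrategyPair,
)
from .nash import (
    NashSolution,
    SUPPORT_TOL,
    _active_species,
    _gradients,
)


@dataclass(frozen=True)
class DiagnosticReport:
    name: str
    passed: bool
    margin: float
    n_samples: int
    seed: int | None

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "DiagnosticReport":
        return cls(**json.loads(text))


def check_ifd(solution: NashSolution, state: PopulationState,
              params: ModelParameters, env: EnvironmentProfiles,
              grid: HabitatGrid, tol: float = 1e-8,
              support_tol: float = SUPPORT_TOL) -> DiagnosticReport:
    """Ideal-free geometry: constant fitness on the support, no better off it.

    The margin is the worst, over both species, of the within-support
    fitness spread ``|g - lambda|`` and the off-support excess
    ``g - lambda``.
    """
    sc = solution.strategies.sigma_c
    sp = solution.strategies.sigma_p
    g_c, g_p, _ = _gradients(sc, sp, state, params, env, grid)
    active_c, active_p = _active_species(state, params)
    margin = 0.0
    n = 0
    for active, sigma, g, lam in ((active_c, sc, g_c, solution.lambda_c),
                                  (active_p, sp, g_p, solution.lambda_p)):
        if not active:
            continue
        on = sigma > support_tol
        if on.any():
            margin = max(margin, float(np.max(np.abs(g[on] - lam))))
        if (~on).any():
            margin = max(margin, float(np.max(g[~on] - lam)))
        n += 1
    return DiagnosticReport(name="ideal_free_distribution",
                            passed=margin <= tol, margin=margin,
                            n_samples=n, seed=None)


def _perturb_density(sigma, grid, rng, magnitude, off_support_injection):
    """Feasible mutant density near ``sigma``.

    Dirichlet-like multiplicative jitter restricted to the resident's
    support, optionally mixed with mass injected off the support.
    """
    n = grid.n_nodes
    w = grid.weights
    jitter = rng.gamma(shape=1.0 / max(magnitude, 1e-12), size=n)
    jitter /= np.mean(jitter)
    omega = sigma * jitter
    if off_support_injection > 0.0:
        off = sigma <= SUPPORT_TOL
        if off.any():
            inject = np.zeros(n)
            inject[off] = rng.uniform(0.0, 1.0, off.sum())
            mass = np.sum(w * inject)
            if mass > 0:
                omega = ((1.0 - off_support_injection) * omega
                         + off_support_injection * inject / mass)
    total = np.sum(w * omega)
    if total <= 0:
        return None
    return omega / total


def check_ess(solution: NashSolution, state: PopulationState,
              params: ModelParameters, env: EnvironmentProfiles,
              grid: HabitatGrid, n_perturbations: int = 200,
              magnitude: float = 1e-3, seed: int = 0,
              tol: float = 1e-10) -> DiagnosticReport:
    """Evolutionary stability probe at a converged equilibrium.

    For random feasible mutants ``omega != sigma`` the linearized invasion
    advantage ``<g_i, omega - sigma_i>`` must not be positive beyond ``tol``
    (equivalently ``<-g_i, omega - sigma_i> >= 0``).  The margin reported is
    the largest observed advantage.
    """
    rng = np.random.default_rng(seed)
    sc = solution.strategies.sigma_c
    sp = solution.strategies.sigma_p
    g_c, g_p, _ = _gradients(sc, sp, state, params, env, grid)
    active_c, active_p = _active_species(state, params)
    worst = -np.inf
    count = 0
    for active, sigma, g in ((active_c, sc, g_c), (active_p, sp, g_p)):
        if not active:
            continue
        for j in range(n_perturbations):
            inject = 0.3 if j % 3 == 0 else 0.0
            omega = _perturb_density(sigma, grid, rng, magnitude, inject)
            if omega is None:
                continue
            diff = omega - sigma
            if np.max(np.abs(diff)) == 0.0:
                continue  # omega == resident is excluded by definition
            advantage = inner_product(g, diff, grid)
            worst = max(worst, advantage)
            count += 1
    if count == 0:
        worst = 0.0
    return DiagnosticReport(name="evolutionary_stability",
                            passed=worst <= tol, margin=float(worst),
                            n_samples=count, seed=seed)


def pseudomonotonicity_probe(operator, sampler, n_pairs: int, seed: int,
                             weights: np.ndarray | None = None,
                             tangent=None, fd_step: float = 1e-6,
                             tol: float = 1e-12,
                             mode: str = "both") -> DiagnosticReport:
    """Sampled test of strict pseudomonotonicity of an operator ``T``.

    Two families of checks on profiles drawn from ``sampler(rng)``:

    * ``"pair"``: the definition itself -- whenever ``<x - y, T(y)> >= 0``
      the implication demands ``<x - y, T(x)> > 0``;
    * ``"differential"``: the sufficient curvature criterion -- for
      feasible directions ``h`` (differences of samples, mapped through
      ``tangent`` when the domain is constrained) projected so
      ``<T(x), h> = 0``, a central finite difference of ``<T(x + t h), h>``
      at ``t = 0`` must be positive.

    The two are not equivalent: the curvature criterion implies the
    definition but can fail where the definitional margins merely touch
    zero.  For this game the predator-prey coupling makes exactly that
    happen at small predator biomass, so callers probing the definitional
    property should use ``mode="pair"``.

    ``tangent``, when given, maps a vector to the tangent space of the
    constraint set (e.g. removes the per-species mean so directions stay
    mass-neutral); without it all directions are treated as feasible.

    The margin is the minimal conclusion value over all triggered premises;
    the probe passes if no margin drops to ``tol`` or below.
    """
    if mode not in ("pair", "differential", "both"):
        raise ValueError(f"mode must be 'pair', 'differential' or 'both', "
                         f"got {mode!r}")
    rng = np.random.default_rng(seed)
    x0 = np.asarray(sampler(rng), dtype=float)
    w = np.ones_like(x0) if weights is None else np.asarray(weights,
                                                            dtype=float)

    def dot(a, b):
        return float(np.sum(w * a * b))

    margin = np.inf
    checked = 0
    for _ in range(n_pairs):
        x = np.asarray(sampler(rng), dtype=float)
        y = np.asarray(sampler(rng), dtype=float)
        d = x - y
        norm = np.sqrt(dot(d, d))
        if norm < 1e-14:
            continue
        if mode in ("pair", "both"):
            Ty = np.asarray(operator(y), dtype=float)
            if dot(d, Ty) >= -tol:
                Tx = np.asarray(operator(x), dtype=float)
                margin = min(margin, dot(d, Tx) / norm**2)
                checked += 1
        if mode == "pair":
            continue
        # differential test at x: h feasible with <T(x), h> = 0
        Tx = np.asarray(operator(x), dtype=float)
        h = d.copy()
        Tt = Tx.copy()
        if tangent is not None:
            h = tangent(h)
            Tt = tangent(Tt)  # <T, h> = <tangent(T), h> on mass-neutral h
        tnorm = dot(Tt, Tt)
        if tnorm > 1e-20:
            h = h - (dot(Tt, h) / tnorm) * Tt
        hnorm = np.sqrt(dot(h, h))
        if hnorm < 1e-12:
            continue
        h /= hnorm
        Tp = np.asarray(operator(x + fd_step * h), dtype=float)
        Tm = np.asarray(operator(x - fd_step * h), dtype=float)
        curv = dot((Tp - Tm) / (2.0 * fd_step), h)
        margin = min(margin, curv)
        checked += 1
    if checked == 0:
        margin = 0.0
    return DiagnosticReport(name="strict_pseudomonotonicity",
                            passed=bool(margin > tol), margin=float(margin),
                            n_samples=checked, seed=seed)


def game_operator(state: PopulationState, params: ModelParameters,
                  env: EnvironmentProfiles, grid: HabitatGrid):
    """The stacked operator ``-dU`` of the two-species game on flat vectors.

    Returns ``(operator, weights, sampler, tangent)`` for use with
    :func:`pseudomonotonicity_probe`: profiles are concatenations
    ``[sigma_c, sigma_p]``, the inner product uses the quadrature weights
    for each block, and ``tangent`` removes each block's mean so probe
    directions stay mass-neutral (feasible for the density constraints).
    """
    n = grid.n_nodes
    w = np.concatenate([grid.weights, grid.weights])

    def operator(z):
        sc, sp = z[:n], z[n:]
        g_c, g_p, _ = _gradients(sc, sp, state, params, env, grid)
        return np.concatenate([-g_c, -g_p])

    def sampler(rng):
        sc = rng.gamma(shape=2.0, size=n)
        sp = rng.gamma(shape=2.0, size=n)
        sc /= np.sum(grid.weights * sc)
        sp /= np.sum(grid.weights * sp)
        return np.concatenate([sc, sp])

    def tangent(v):
        out = v.copy()
        out[:n] -= np.sum(grid.weights * v[:n])
        out[n:] -= np.sum(grid.weights * v[n:])
        return out

    return operator, w, sampler, tangent


def run_battery(state: PopulationState, params: ModelParameters,
                env: EnvironmentProfiles, grid: HabitatGrid,
                solution: NashSolution, seed: int = 0,
                n_perturbations: int = 200,
                n_pairs: int = 100) -> list[DiagnosticReport]:
    """Full diagnostic battery at a converged solution."""
    reports = [
        check_ifd(solution, state, params, env, grid),
        check_ess(solution, state, params, env, grid,
                  n_perturbations=n_perturbations, seed=seed),
    ]
    operator, weights, sampler, tangent = game_operator(state, params, env,
                                                        grid)
    reports.append(pseudomonotonicity_probe(operator, sampler, n_pairs,
                                            seed=seed, weights=weights,
                                            tangent=tangent, mode="pair"))
    return reports
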