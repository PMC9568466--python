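"""Behaviorally modified Rosenzweig-MacArthur water-column model.

Consumers (zooplankton) grow logistically against a light-driven carrying
capacity; predators (forage fish) feed with a Type II functional response
whose clearance rate decays with depth, pay a metabolic cost and a quadratic
intraspecific competition loss.  Both populations distribute themselves over
the water column; per-capita rates are expectations of local rates against
the mean-field strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict, fields

import numpy as np

from .grid import HabitatGrid, inner_product, is_probability_density


class ModelError(ValueError):
    """Invalid model input."""


@dataclass(frozen=True)
class ModelParameters:
    """All scalar parameters of the model.

    Masses in g, biomass densities in g/m^3, time in months, clearance in
    m^3/month.  ``beta_c`` and ``hunt_decay`` are derived from the scaling
    parameters unless overridden explicitly.
    """

    m_c: float = 0.01          # consumer mass (g)
    m_p: float = 10.0          # predator mass (g)
    alpha: float = 1.25        # consumption-rate scaling (g^1/4 / month)
    b: float = 27.5            # clearance-rate scaling (g^1/4 m^3 / month)
    gamma: float = 0.2         # respiration ratio
    K0: float = 1e-4           # minimal carrying capacity (g/m^3)
    K: float = 3.0             # varying carrying capacity (g/m^3)
    beta0: float = 1e-4        # minimal predator clearance (m^3/month)
    mu_p: float = 0.35         # predator metabolic rate (1/month)
    F_p: float = 7.0           # predator maximal consumption rate (1/month)
    eps: float = 0.1           # trophic efficiency
    k_light: float = 0.05      # light attenuation (1/m)
    kappa: float = 0.1         # predation-success decay (m^2)
    c: float = 0.0             # intraspecific predator competition
    beta_c: float = 27.5 * 0.01**0.75   # consumer clearance (m^3/month)
    hunt_decay: float = 0.05 * 0.1      # coefficient of x^2 in D(x)

    def __post_init__(self):
        positives = ("m_c", "m_p", "alpha", "b", "gamma", "K0", "beta0",
                     "mu_p", "F_p", "eps", "k_light", "kappa", "beta_c",
                     "hunt_decay")
        for name in positives:
            if getattr(self, name) <= 0:
                raise ModelError(f"parameter {name} must be positive, "
                                 f"got {getattr(self, name)}")
        if self.c < 0:
            raise ModelError(f"parameter c must be >= 0, got {self.c}")
        if self.K < 0:
            raise ModelError(f"parameter K must be >= 0, got {self.K}")


_PARAM_NAMES = {f.name for f in fields(ModelParameters)}
# fields recomputed from the scalings when not explicitly overridden
_DERIVED = ("beta_c", "hunt_decay")


def derive_parameters(overrides: dict | None = None) -> ModelParameters:
    """Fill defaults and derive dependent parameters.

    ``beta_c = b * m_c**0.75`` and ``hunt_decay = k_light * kappa`` are
    recomputed from the (possibly overridden) scalings; explicit overrides
    of either win.  Unknown or negative overrides raise :class:`ModelError`.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - _PARAM_NAMES
    if unknown:
        raise ModelError(f"unknown parameter(s): {sorted(unknown)}")
    for name, value in overrides.items():
        if value < 0:
            raise ModelError(f"parameter {name} must not be negative, "
                             f"got {value}")
    base = {f.name: f.default for f in fields(ModelParameters)}
    base.update(overrides)
    if "beta_c" not in overrides:
        base["beta_c"] = base["b"] * base["m_c"] ** 0.75
    if "hunt_decay" not in overrides:
        base["hunt_decay"] = base["k_light"] * base["kappa"]
    return ModelParameters(**base)


@dataclass(frozen=True, eq=False)
class EnvironmentProfiles:
    """Depth profiles entering the rates.

    ``phi`` is the light curve, ``D`` the predation-success profile,
    ``beta_p = b*m_p**0.75 * D + beta0`` the predator clearance rate and
    ``capacity = K*phi + K0`` the consumer carrying capacity.
    """

    phi: np.ndarray
    D: np.ndarray
    beta_p: np.ndarray
    capacity: np.ndarray


def environment_profiles(params: ModelParameters,
                         grid: HabitatGrid) -> EnvironmentProfiles:
    """Evaluate the spatial fields on the grid."""
    x = grid.depths
    phi = np.exp(-params.k_light * x)
    D = np.exp(-params.hunt_decay * x**2)
    beta_p = params.b * params.m_p**0.75 * D + params.beta0
    capacity = params.K * phi + params.K0
    return EnvironmentProfiles(phi=phi, D=D, beta_p=beta_p, capacity=capacity)


@dataclass(frozen=True)
class PopulationState:
    """Total biomasses (g/m^3) of the two populations."""

    N_c: float
    N_p: float

    def __post_init__(self):
        if self.N_c < 0 or self.N_p < 0:
            raise ModelError(f"populations must be nonnegative, "
                             f"got N_c={self.N_c}, N_p={self.N_p}")


@dataclass(frozen=True, eq=False)
class StrategyPair:
    """Mean-field strategy densities of consumers and predators."""

    sigma_c: np.ndarray
    sigma_p: np.ndarray

    def validate(self, grid: HabitatGrid, tol: float = 1e-8) -> None:
        for name, sigma in (("sigma_c", self.sigma_c),
                            ("sigma_p", self.sigma_p)):
            ok, report = is_probability_density(sigma, grid, tol=tol)
            if not ok:
                raise ModelError(
                    f"{name} is not a probability density: min={report.min_value:.3e},"
                    f" mass error={report.mass_error:.3e}"
                )


def uniform_pair(grid: HabitatGrid) -> StrategyPair:
    """The constant-behavior baseline: both densities identically 1."""
    return StrategyPair(sigma_c=np.ones(grid.n_nodes),
                        sigma_p=np.ones(grid.n_nodes))


def encounter(state: PopulationState, sigma: StrategyPair,
              env: EnvironmentProfiles, grid: HabitatGrid) -> float:
    """Saturating encounter term ``B = N_c * <beta_p sigma_c, sigma_p>``."""
    return state.N_c * inner_product(env.beta_p * sigma.sigma_c,
                                     sigma.sigma_p, grid)


def consumer_percap_growth(state: PopulationState, sigma: StrategyPair,
                           params: ModelParameters, env: EnvironmentProfiles,
                           grid: HabitatGrid) -> float:
    """Logistic consumer growth against the depth-varying capacity."""
    crowd = 1.0 - state.N_c * sigma.sigma_c / env.capacity
    return params.beta_c * inner_product(sigma.sigma_c, crowd, grid)


def predator_percap_growth(state: PopulationState, sigma: StrategyPair,
                           params: ModelParameters, env: EnvironmentProfiles,
                           grid: HabitatGrid) -> float:
    """Type II per-capita predator growth ``eps F_p B / (F_p + B)``."""
    B = encounter(state, sigma, env, grid)
    return params.eps * params.F_p * B / (params.F_p + B)


def predator_percap_mortality(state: PopulationState, sigma: StrategyPair,
                              params: ModelParameters,
                              env: EnvironmentProfiles,
                              grid: HabitatGrid) -> float:
    """Quadratic competition loss plus the metabolic rate."""
    comp = inner_product(sigma.sigma_p, env.beta_p * sigma.sigma_p, grid)
    return params.c * state.N_p * comp + params.mu_p


def consumer_percap_mortality(state: PopulationState, sigma: StrategyPair,
                              params: ModelParameters,
                              env: EnvironmentProfiles,
                              grid: HabitatGrid) -> float:
    """Predation loss, tied to predator growth by biomass-flux consistency.

    Defined as ``(N_p / (eps N_c)) * G_p``; raises for ``N_c == 0`` where
    the ratio is undefined (callers must treat the consumer-extinct case).
    """
    if state.N_c == 0:
        raise ModelError("consumer mortality undefined at N_c = 0")
    return (state.N_p / (params.eps * state.N_c)
            * predator_percap_growth(state, sigma, params, env, grid))


def percap_growth_rates(state: PopulationState, sigma: StrategyPair,
                        params: ModelParameters, env: EnvironmentProfiles,
                        grid: HabitatGrid) -> tuple[float, float]:
    """Net per-capita rates ``(f_c, f_p)`` driving the slow dynamics.

    The consumer mortality is evaluated in its reduced form
    ``F_p N_p <beta_p sigma_c, sigma_p> / (F_p + B)`` which is well defined
    at ``N_c = 0``.
    """
    E = inner_product(env.beta_p * sigma.sigma_c, sigma.sigma_p, grid)
    B = state.N_c * E
    den = params.F_p + B
    G_c = consumer_percap_growth(state, sigma, params, env, grid)
    M_c = params.F_p * state.N_p * E / den
    G_p = params.eps * params.F_p * B / den
    M_p = predator_percap_mortality(state, sigma, params, env, grid)
    return G_c - M_c, G_p - M_p


def consumer_pointwise_fitness(state: PopulationState, sigma: StrategyPair,
                               params: ModelParameters,
                               env: EnvironmentProfiles,
                               grid: HabitatGrid) -> np.ndarray:
    """Fitness field of an individual consumer at each depth.

    The individual consumer payoff is linear in its own strategy, so its
    strategy gradient is this field and the mean payoff is ``<sigma_c, g_c>``.
    """
    B = encounter(state, sigma, env, grid)
    growth = params.beta_c * (1.0 - state.N_c * sigma.sigma_c / env.capacity)
    predation = (params.F_p * env.beta_p * sigma.sigma_p * state.N_p
                 / (params.F_p + B))
    return growth - predation


def predator_pointwise_fitness_gradient(state: PopulationState,
                                        sigma: StrategyPair,
                                        params: ModelParameters,
                                        env: EnvironmentProfiles,
                                        grid: HabitatGrid) -> np.ndarray:
    """Strategy gradient of the individual predator payoff at the mean field.

    The Type II response is nonlinear in the predator's own strategy; the
    gradient below is evaluated at ``sigma_p`` equal to the mean field.  The
    constant metabolic term has zero gradient.
    """
    B = encounter(state, sigma, env, grid)
    den = params.F_p + B
    gain = (params.eps * params.F_p**2 * state.N_c * env.beta_p
            * sigma.sigma_c / den**2)
    loss = params.c * state.N_p * env.beta_p * sigma.sigma_p
    return gain - loss


def consumer_individual_payoff(sigma_ind: np.ndarray, mean: StrategyPair,
                               state: PopulationState,
                               params: ModelParameters,
                               env: EnvironmentProfiles,
                               grid: HabitatGrid) -> float:
    """Payoff of a focal consumer playing ``sigma_ind`` against the field."""
    B = encounter(state, mean, env, grid)
    crowd = 1.0 - state.N_c * mean.sigma_c / env.capacity
    growth = params.beta_c * inner_product(sigma_ind, crowd, grid)
    mort = (params.F_p * state.N_p
            * inner_product(env.beta_p * sigma_ind, mean.sigma_p, grid)
            / (params.F_p + B))
    return growth - mort


def predator_individual_payoff(sigma_ind: np.ndarray, mean: StrategyPair,
                               state: PopulationState,
                               params: ModelParameters,
                               env: EnvironmentProfiles,
                               grid: HabitatGrid) -> float:
    """Payoff of a focal predator playing ``sigma_ind`` against the field."""
    B_ind = state.N_c * inner_product(env.beta_p * mean.sigma_c,
                                      sigma_ind, grid)
    growth = params.eps * params.F_p * B_ind / (params.F_p + B_ind)
    comp = params.c * state.N_p * inner_product(
        sigma_ind, env.beta_p * mean.sigma_p, grid)
    return growth - comp - params.mu_p


def environment_frame(env: EnvironmentProfiles, grid: HabitatGrid):
    """Tabular view of the spatial fields for inspection/export."""
    import pandas as pd

    return pd.DataFrame({
        "depth": grid.depths,
        "phi": env.phi,
        "D": env.D,
        "beta_p": env.beta_p,
        "capacity": env.capacity,
    })


def with_overrides(params: ModelParameters, **kw) -> ModelParameters:
    """Return a copy of ``params`` with the given fields replaced."""
    return replace(params, **kw)


def params_to_dict(params: ModelParameters) -> dict:
    return asdict(params)
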