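"""Discretized water-column habitat.

The habitat is the interval ``[0, depth_max]`` equipped with the uniform
probability measure.  All spatial integrals in the model are expectations
against this measure, evaluated with the trapezoidal rule on a uniform node
grid.  Densities are taken with respect to the probability measure, so the
uniform strategy is the constant vector of ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike


@dataclass(frozen=True, eq=False)
class HabitatGrid:
    """Uniform node grid with trapezoidal quadrature weights.

    Attributes
    ----------
    depth_max : float
        Bottom of the water column in meters (surface is 0).
    n_nodes : int
        Number of grid nodes, endpoints included.
    depths : ndarray
        Node positions in meters, strictly increasing from 0 to ``depth_max``.
    weights : ndarray
        Nonnegative quadrature weights summing to 1; integrating a density
        against them is the expectation under the uniform probability measure.
    """

    depth_max: float
    n_nodes: int
    depths: np.ndarray
    weights: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "depth_max": self.depth_max,
                "n_nodes": self.n_nodes,
                "depths": self.depths.tolist(),
                "weights": self.weights.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "HabitatGrid":
        obj = json.loads(text)
        return cls(
            depth_max=float(obj["depth_max"]),
            n_nodes=int(obj["n_nodes"]),
            depths=np.asarray(obj["depths"], dtype=float),
            weights=np.asarray(obj["weights"], dtype=float),
        )


@dataclass(frozen=True)
class DensityReport:
    """Deviations of a candidate density from the probability simplex."""

    is_density: bool
    min_value: float
    mass_error: float


def build_grid(depth_max: float, n_nodes: int) -> HabitatGrid:
    """Build a uniform grid on ``[0, depth_max]`` with trapezoid weights.

    The weights are normalized so they sum to 1: interior weights are equal
    and the two endpoint weights are half an interior weight.
    """
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    if depth_max <= 0:
        raise ValueError(f"depth_max must be positive, got {depth_max}")
    depths = np.linspace(0.0, depth_max, n_nodes)
    weights = np.ones(n_nodes)
    weights[0] = weights[-1] = 0.5
    weights /= n_nodes - 1
    return HabitatGrid(depth_max=float(depth_max), n_nodes=int(n_nodes),
                       depths=depths, weights=weights)


def inner_product(f: ArrayLike, g: ArrayLike, grid: HabitatGrid) -> float:
    """Quadrature inner product ``<f, g> = sum_j w_j f_j g_j``.

    This is the discrete expectation of ``f*g`` under the uniform
    probability measure on the habitat; symmetric and bilinear.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != (grid.n_nodes,) or g.shape != (grid.n_nodes,):
        raise ValueError(
            f"inner_product operands must have shape ({grid.n_nodes},), "
            f"got {f.shape} and {g.shape}"
        )
    # (f * g) first: keeps the quadrature exactly symmetric in f and g
    return float(np.sum(grid.weights * (f * g)))


def is_probability_density(
    sigma: ArrayLike, grid: HabitatGrid, tol: float = 1e-8
) -> tuple[bool, DensityReport]:
    """Check that ``sigma`` is a probability density on the grid.

    Passes iff ``min(sigma) >= -tol`` and the quadrature mass is within
    ``tol`` of 1.  Returns the verdict together with both deviations.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (grid.n_nodes,):
        raise ValueError(
            f"sigma must have shape ({grid.n_nodes},), got {sigma.shape}"
        )
    min_value = float(np.min(sigma))
    mass_error = float(abs(np.sum(grid.weights * sigma) - 1.0))
    ok = min_value >= -tol and mass_error <= tol
    return ok, DensityReport(is_density=ok, min_value=min_value,
                             mass_error=mass_error)
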