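"""Discretization of the latent domain [-1, 1].

All model functions (force, potential, initial density, tuning) live as
vectors of values on a fixed set of collocation nodes, and all integrals
over the domain are quadrature sums.  The nodes are Legendre-Gauss-Lobatto
(LGL) points: they include both endpoints (required for absorbing boundary
conditions at x = +-1) and their quadrature weights integrate polynomials
up to degree 2n - 3 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre, roots_jacobi

__all__ = ["Grid", "build_grid"]


class ConfigurationError(ValueError):
    """Raised for invalid discretization or fitting configuration."""


def _lgl_nodes_weights(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Legendre-Gauss-Lobatto nodes and weights on [-1, 1].

    Interior nodes are the roots of P'_{n-1}, i.e. the Gauss nodes of the
    Jacobi(1, 1) weight; weights are 2 / (n (n-1) P_{n-1}(x)^2).
    """
    if n < 2:
        raise ConfigurationError("need at least 2 nodes")
    nodes = np.empty(n)
    nodes[0], nodes[-1] = -1.0, 1.0
    if n > 2:
        interior, _ = roots_jacobi(n - 2, 1.0, 1.0)
        nodes[1:-1] = np.sort(interior)
    p = eval_legendre(n - 1, nodes)
    weights = 2.0 / (n * (n - 1) * p**2)
    return nodes, weights


def _differentiation_matrix(nodes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Polynomial collocation differentiation matrix via barycentric weights.

    For LGL nodes the barycentric weights are proportional to
    (-1)^j sqrt(w_j) (Berrut & Trefethen 2004).
    """
    n = nodes.size
    c = ((-1.0) ** np.arange(n)) * np.sqrt(weights)
    dx = nodes[:, None] - nodes[None, :]
    np.fill_diagonal(dx, 1.0)
    D = (c[None, :] / c[:, None]) / dx
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(D, -D.sum(axis=1))
    return D


def _cumulative_matrix(nodes: np.ndarray) -> np.ndarray:
    """Matrix A with (A f)[i] ~ int_{-1}^{x_i} f(s) ds (trapezoid, left-to-right)."""
    n = nodes.size
    h = np.diff(nodes)
    A = np.zeros((n, n))
    for i in range(1, n):
        A[i] = A[i - 1]
        A[i, i - 1] += 0.5 * h[i - 1]
        A[i, i] += 0.5 * h[i - 1]
    return A


@dataclass(frozen=True)
class Grid:
    """Collocation grid on [-1, 1] with quadrature and differentiation.

    Attributes
    ----------
    nodes : strictly increasing positions, nodes[0] = -1, nodes[-1] = +1.
    weights : positive quadrature weights summing to 2 (the domain length).
    diff : spectral differentiation matrix acting on node values.
    cumint : left-to-right cumulative integration matrix (trapezoid rule).
    """

    nodes: np.ndarray
    weights: np.ndarray
    diff: np.ndarray = field(repr=False)
    cumint: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.nodes.size

    @property
    def interior(self) -> slice:
        return slice(1, self.n - 1)

    def integrate(self, values: np.ndarray) -> float:
        """Quadrature integral of a function given by node values."""
        return float(np.dot(self.weights, np.asarray(values)))

    def interpolate(self, values: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Barycentric polynomial interpolation of node values to points x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        c = ((-1.0) ** np.arange(self.n)) * np.sqrt(self.weights)
        out = np.empty(x.size)
        for k, xq in enumerate(x):
            d = xq - self.nodes
            hit = np.argmin(np.abs(d))
            if abs(d[hit]) < 1e-14:
                out[k] = values[hit]
            else:
                t = c / d
                out[k] = np.dot(t, values) / t.sum()
        return out


def _build_grid_unchecked(n_nodes: int) -> Grid:
    """Grid constructor without the coarseness check.

    Used for deliberately tiny grids (>= 5 nodes) in brute-force
    path-enumeration cross-checks of the likelihood chain.
    """
    if n_nodes < 5:
        raise ConfigurationError(
            f"n_nodes={n_nodes} too coarse for the second-derivative operator"
        )
    nodes, weights = _lgl_nodes_weights(n_nodes)
    return Grid(
        nodes=nodes,
        weights=weights,
        diff=_differentiation_matrix(nodes, weights),
        cumint=_cumulative_matrix(nodes),
    )


def build_grid(n_nodes: int = 256) -> Grid:
    """Build the LGL collocation grid with ``n_nodes`` points (minimum 8)."""
    if n_nodes < 8:
        raise ConfigurationError(
            f"n_nodes={n_nodes} too coarse for the second-derivative operator"
        )
    return _build_grid_unchecked(n_nodes)
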