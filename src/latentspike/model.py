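"""Latent-model container and change-of-variables reconstructions.

The generative model is the Langevin equation

    dx = -D Phi'(x) dt + sqrt(2 D) dW,   x in [-1, 1],

with absorbing boundaries at +-1 (first passage ends the trial), an
initial-state density p0(x), and per-neuron tuning functions f_i(x) that
drive inhomogeneous-Poisson spiking, lambda_i(t) = f_i(x(t)).

Optimization operates on unconstrained auxiliary functions: the force
F(x) = -Phi'(x) per condition, F0(x) = p0'(x)/p0(x), and
F_i(x) = f_i'(x)/f_i(x) with the boundary rate C_i = f_i(-1).  The maps in
this module reconstruct Phi, p0 and f_i from those auxiliaries; the
reconstructions guarantee normalization of p0 and non-negativity of f_i by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ConfigurationError, Grid

__all__ = [
    "LatentModel",
    "force_to_potential",
    "aux_to_density",
    "aux_to_tuning",
    "count_barriers",
]


def force_to_potential(F: np.ndarray, grid: Grid) -> np.ndarray:
    """Potential Phi(x) = -int_{-1}^x F ds + C with int exp(-Phi) dx = 1."""
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("force values must be finite")
    phi_raw = -grid.cumint @ F
    c = np.log(grid.integrate(np.exp(-phi_raw)))
    return phi_raw + c


def aux_to_density(F0: np.ndarray, grid: Grid) -> np.ndarray:
    """Normalized density p0(x) = exp(int F0) / int exp(int F0) dx.

    The exponent is re-centred internally, so the result is invariant to
    adding a constant to the cumulative integral (overflow safety).
    """
    F0 = np.asarray(F0, dtype=float)
    if not np.all(np.isfinite(F0)):
        raise ValueError("auxiliary values must be finite")
    s = grid.cumint @ F0
    s -= s.max()
    e = np.exp(s)
    return e / grid.integrate(e)


def aux_to_tuning(Fi: np.ndarray, Ci: float, grid: Grid) -> np.ndarray:
    """Tuning f_i(x) = C_i exp(int_{-1}^x F_i ds); f_i(-1) = C_i >= 0."""
    if Ci < 0:
        raise ValueError(f"boundary rate must be non-negative, got {Ci}")
    Fi = np.asarray(Fi, dtype=float)
    if not np.all(np.isfinite(Fi)):
        raise ValueError("auxiliary values must be finite")
    return Ci * np.exp(grid.cumint @ Fi)


def count_barriers(
    F_split1: np.ndarray,
    F_split2: np.ndarray,
    grid: Grid,
    run: int | None = None,
    margin: int | None = None,
) -> int:
    """Count robust sign changes of the force, i.e. potential barriers.

    A sign change at node r counts if BOTH force arrays hold one strict
    sign on ``run`` consecutive nodes left of r and the opposite strict
    sign on ``run`` consecutive nodes starting at r, and r is at least
    ``margin`` nodes away from either domain boundary.  The defaults are
    run = 10 and margin = 30 at 256 nodes, scaled proportionally for other
    grid sizes.  Changes in either direction are counted (a minimum next
    to a boundary also requires climbing out, so it acts as a barrier).
    """
    F1 = np.asarray(F_split1, dtype=float)
    F2 = np.asarray(F_split2, dtype=float)
    n = grid.n
    if F1.size != n or F2.size != n:
        raise ValueError("force arrays must live on the given grid")
    if run is None:
        run = max(2, int(np.ceil(10 * n / 256)))
    if margin is None:
        margin = max(3, int(np.ceil(30 * n / 256)))
    if n < 2 * (margin + run):
        raise ConfigurationError(
            f"grid of {n} nodes too short for run={run}, margin={margin}"
        )
    # consensus sign: +-1 where both splits agree strictly, else 0
    s1 = np.sign(F1)
    s2 = np.sign(F2)
    consensus = np.where(s1 == s2, s1, 0.0)
    # maximal constant-sign blocks of length >= run qualify as stable sides
    blocks = []  # (sign, start, end) inclusive
    i = 0
    while i < n:
        s = consensus[i]
        j = i
        while j + 1 < n and consensus[j + 1] == s:
            j += 1
        if s != 0 and (j - i + 1) >= run:
            blocks.append((s, i, j))
        i = j + 1
    count = 0
    for (sa, _, ea), (sb, sb_start, _) in zip(blocks, blocks[1:]):
        if sa == sb:
            continue
        # the change happens in the region between the two stable blocks
        loc = 0.5 * (ea + sb_start)
        if margin <= loc <= n - 1 - margin:
            count += 1
    return count


@dataclass
class LatentModel:
    """All inferred model components on a common grid.

    ``forces`` has shape (n_conditions, n_nodes); ``F0`` and each row of
    ``tuning_aux`` are auxiliary log-derivative functions on the nodes;
    ``tuning_C`` holds the boundary rates C_i = f_i(-1) in Hz.
    """

    grid: Grid
    forces: np.ndarray
    D: float
    F0: np.ndarray
    tuning_aux: np.ndarray
    tuning_C: np.ndarray

    def __post_init__(self) -> None:
        self.forces = np.atleast_2d(np.asarray(self.forces, dtype=float))
        self.F0 = np.asarray(self.F0, dtype=float)
        self.tuning_aux = np.atleast_2d(np.asarray(self.tuning_aux, dtype=float))
        self.tuning_C = np.asarray(self.tuning_C, dtype=float)
        if self.D <= 0:
            raise ValueError("noise magnitude D must be positive")
        if np.any(self.tuning_C < 0):
            raise ValueError("boundary rates C_i must be non-negative")

    @property
    def n_conditions(self) -> int:
        return self.forces.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.tuning_aux.shape[0]

    def potential(self, condition: int) -> np.ndarray:
        return force_to_potential(self.forces[condition], self.grid)

    def p0(self) -> np.ndarray:
        return aux_to_density(self.F0, self.grid)

    def tuning(self, neuron: int) -> np.ndarray:
        return aux_to_tuning(
            self.tuning_aux[neuron], float(self.tuning_C[neuron]), self.grid
        )

    def tuning_all(self) -> np.ndarray:
        return np.stack([self.tuning(i) for i in range(self.n_neurons)])

    def mirror(self) -> "LatentModel":
        """The reflection-gauge twin: the model with x -> -x.

        The latent sign is a pure gauge of the model class — reflecting
        the force, initial density and tuning functions leaves the data
        likelihood exactly unchanged.  (LGL nodes are symmetric, so the
        reflection is a reversal of node values.)  The boundary rate
        anchors at x = -1, so the mirrored C_i is f_i(+1).
        """
        tuning = np.stack(
            [self.tuning(i)[::-1] for i in range(self.n_neurons)]
        )
        return LatentModel(
            grid=self.grid,
            forces=-self.forces[:, ::-1],
            D=float(self.D),
            F0=-self.F0[::-1],
            tuning_aux=-self.tuning_aux[:, ::-1],
            tuning_C=tuning[:, 0].copy(),
        )

    def copy(self) -> "LatentModel":
        return LatentModel(
            grid=self.grid,
            forces=self.forces.copy(),
            D=float(self.D),
            F0=self.F0.copy(),
            tuning_aux=self.tuning_aux.copy(),
            tuning_C=self.tuning_C.copy(),
        )

    @classmethod
    def blank(
        cls,
        grid: Grid,
        n_conditions: int,
        n_neurons: int,
        D: float = 0.1,
        rates: np.ndarray | None = None,
    ) -> "LatentModel":
        """Uninformative start: flat force, uniform p0, constant tuning."""
        if rates is None:
            rates = np.full(n_neurons, 10.0)
        return cls(
            grid=grid,
            forces=np.zeros((n_conditions, grid.n)),
            D=D,
            F0=np.zeros(grid.n),
            tuning_aux=np.zeros((n_neurons, grid.n)),
            tuning_C=np.asarray(rates, dtype=float),
        )
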