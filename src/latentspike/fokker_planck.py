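"""Modified Fokker-Planck generator, ISI propagation and boundary absorption.

The transition density between spike observations obeys

    dp/dt = -D d/dx[F(x) p] + D d2p/dx2 - sum_i f_i(x) p  =  -H p

with absorbing boundaries p(+-1) = 0.  The decay term sum_i f_i accounts
for the absence of spikes during the interval; absorption flux at the
boundaries supplies the first-passage factor at the trial end.

Discretely we evolve the similarity-transformed variable
phi = sqrt(w) exp(Phi/2) p on interior nodes.  In that variable the
drift-diffusion operator assembles as -P^T W P (a weak form), which is
symmetric negative semidefinite, and the spike-decay term stays diagonal.
The full generator is therefore a real symmetric PSD matrix whose
eigendecomposition gives the exact action of exp(-H dt) for arbitrary
inter-spike intervals at the cost of two small matrix-vector products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .grid import Grid
from .model import LatentModel

__all__ = ["Generator", "assemble_generator", "propagate", "absorb"]

_D_FLOOR = 1e-8


@dataclass
class Generator:
    """Assembled generator for one condition on a fixed grid.

    Densities are vectors of values at the interior nodes (the boundary
    values are pinned to zero by the absorbing condition).
    """

    grid: Grid
    D: float
    force: np.ndarray          # full nodes
    decay: np.ndarray          # full nodes; zeros when include_decay=False
    phi_raw: np.ndarray = field(repr=False)   # unnormalized potential
    H_sym: np.ndarray = field(repr=False)     # symmetric PSD, interior
    eigvals: np.ndarray = field(repr=False)
    eigvecs: np.ndarray = field(repr=False)
    to_sym: np.ndarray = field(repr=False)    # phi = to_sym * p (interior)
    from_sym: np.ndarray = field(repr=False)  # p = from_sym * phi
    flux_left: np.ndarray = field(repr=False)   # u_L . phi = flux into x=-1
    flux_right: np.ndarray = field(repr=False)

    @property
    def n_interior(self) -> int:
        return self.grid.n - 2

    # -------------------------------------------------- operator actions

    def apply(self, p_full: np.ndarray) -> np.ndarray:
        """Collocation action H p on a full-node density (no boundary pinning).

        Used for direct operator checks; propagation uses the symmetric
        interior form instead.
        """
        Dx = self.grid.diff
        drift = self.D * (Dx @ (self.force * p_full))
        diffusion = -self.D * (Dx @ (Dx @ p_full))
        return drift + diffusion + self.decay * p_full

    def propagate_sym(self, phi: np.ndarray, dt: float) -> np.ndarray:
        a = self.eigvecs.T @ phi
        return self.eigvecs @ (np.exp(-self.eigvals * dt) * a)

    def mass(self, p: np.ndarray) -> float:
        return float(np.dot(self.grid.weights[1:-1], p))

    def transition_log_kernel(self, dt: float) -> np.ndarray:
        """log K(x_to | x_from) over interior nodes for Viterbi decoding.

        K[n, m] is the transition probability density to node n from a unit
        point mass at node m after time dt (with spike-decay included).
        """
        M = self._sym_propagator(dt)
        kernel = (self.from_sym[:, None] * M) * (
            self.to_sym[None, :] / self.grid.weights[1:-1][None, :]
        )
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(kernel, 0.0))

    def _sym_propagator(self, dt: float) -> np.ndarray:
        """exp(-H_sym dt) with entries below the round-off floor zeroed.

        The back-transform to density space multiplies by exp(+-Phi/2),
        which can amplify cancellation noise in the tiny tail entries into
        spuriously large kernel values under strong drift; entries that
        are unresolvable in double precision are treated as exact zeros.
        """
        E = self.eigvecs * np.exp(-self.eigvals * dt)[None, :]
        M = E @ self.eigvecs.T
        floor = 1e-13 * np.abs(M).max()
        M[np.abs(M) < floor] = 0.0
        return M

    def terminal_log_flux(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """log flux into each boundary after dt from unit mass at each node."""
        M = self._sym_propagator(dt)
        col = self.to_sym / self.grid.weights[1:-1]
        with np.errstate(divide="ignore"):
            left = np.log(np.maximum((self.flux_left @ M) * col, 0.0))
            right = np.log(np.maximum((self.flux_right @ M) * col, 0.0))
        return left, right


def assemble_generator(
    model: LatentModel, condition: int, include_decay: bool = True
) -> Generator:
    """Assemble the generator for one stimulus condition.

    With ``include_decay=False`` the spike-decay term is omitted (the
    standard Fokker-Planck operator), as used for the reaction-time
    marginal likelihood and for feature complexity.
    """
    if condition >= model.n_conditions:
        raise ValueError(f"condition {condition} not in model")
    grid = model.grid
    F = model.forces[condition]
    D = max(float(model.D), _D_FLOOR)
    if include_decay:
        decay = model.tuning_all().sum(axis=0)
    else:
        decay = np.zeros(grid.n)
    return _assemble(grid, D, F, decay)


def _assemble(grid: Grid, D: float, F: np.ndarray, decay: np.ndarray) -> Generator:
    n = grid.n
    if F.size != n or decay.size != n:
        raise ValueError("force/decay must be given on the grid nodes")
    w = grid.weights
    phi_raw = -grid.cumint @ F
    phi_i = phi_raw[1:-1]
    # re-centre for overflow safety; a constant in phi cancels identically
    phi0 = phi_raw - phi_raw.mean()
    phi0_i = phi0[1:-1]
    sqw_i = np.sqrt(w[1:-1])
    P = grid.diff[:, 1:-1] * (np.exp(phi0_i / 2) / sqw_i)[None, :]
    W = w * np.exp(-phi0)
    K = -D * (P.T * W[None, :]) @ P
    H = -K + np.diag(decay[1:-1])
    H = 0.5 * (H + H.T)
    lam, Q = scipy.linalg.eigh(H)
    to_sym = sqw_i * np.exp(phi0_i / 2)
    from_sym = np.exp(-phi0_i / 2) / sqw_i
    u_common = np.exp(-phi0_i / 2) / sqw_i
    flux_left = D * grid.diff[0, 1:-1] * u_common
    flux_right = -D * grid.diff[-1, 1:-1] * u_common
    return Generator(
        grid=grid,
        D=D,
        force=np.asarray(F, dtype=float),
        decay=np.asarray(decay, dtype=float),
        phi_raw=phi_raw,
        H_sym=H,
        eigvals=lam,
        eigvecs=Q,
        to_sym=to_sym,
        from_sym=from_sym,
        flux_left=flux_left,
        flux_right=flux_right,
    )


def propagate(p: np.ndarray, dt: float, gen: Generator) -> np.ndarray:
    """Evolve an interior density for time dt under the generator.

    Exact matrix-exponential action in the eigenbasis; satisfies the
    semigroup property to solver tolerance.  Tiny negative values from
    round-off are clipped to zero (sign only, never mass renormalization).
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    p = np.asarray(p, dtype=float)
    if p.size != gen.n_interior:
        raise ValueError("density must be given on interior nodes")
    if dt == 0:
        return p.copy()
    phi = gen.to_sym * p
    out = gen.from_sym * gen.propagate_sym(phi, dt)
    out[(out < 0) & (out > -1e-12)] = 0.0
    return out


def absorb(p: np.ndarray, gen: Generator) -> tuple[float, float]:
    """Instantaneous probability flux into the two boundaries.

    Returns (weight_left, weight_right); with the density pinned to zero at
    the boundaries the flux reduces to +-D dp/dx evaluated one-sidedly at
    the boundary nodes.  This is the first-passage time density split by
    exit side and supplies the final absorption factor of the likelihood.
    """
    p = np.asarray(p, dtype=float)
    phi = gen.to_sym * p
    wl = float(gen.flux_left @ phi)
    wr = float(gen.flux_right @ phi)
    return max(wl, 0.0), max(wr, 0.0)
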