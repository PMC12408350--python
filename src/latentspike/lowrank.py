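"""Rank-two distributed recurrent network replicating attractor dynamics.

The network dy/dt = -y + [J y + b]_+ has connectivity J = M Q^T of rank
two, so its dynamics reduce exactly to the mean-field variables
z = Q^T y with dz/dt = -z + Q^T [M z + b]_+.  The loadings are
m_{i,1} = cos(2 pi i / N), m_{i,2} = sin(2 pi i / N); inputs b_i are
uniform on [-0.06, 0.06]; and Q^T is found by ridge regression (lambda =
0.01) so that the reduced flow matches the two-pool mean-field attractor
flow R(z): Q^T [M z + b]_+ = R(z) + z on samples z drawn uniformly from
[0, 1]^2.

Trajectories from near-symmetric initial states toward the two choice
attractors are parametrized by a one-dimensional decision variable
x in [-1, 1] growing linearly with cumulative arc length (x = -1 left
attractor, +1 right attractor, 0 the symmetric start); each unit's firing
rate along the trajectories as a function of x is its tuning curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .meanfield import MeanFieldParams, flow_field

__all__ = [
    "LowRankNet",
    "lowrank_build",
    "simulate_z",
    "simulate_network",
    "decision_variable_param",
]


@dataclass
class LowRankNet:
    M: np.ndarray                 # (N, 2) loadings
    Qt: np.ndarray                # (2, N) readout
    b: np.ndarray                 # (N,) inputs
    params: MeanFieldParams = field(default_factory=MeanFieldParams)

    @property
    def n_units(self) -> int:
        return self.M.shape[0]

    @property
    def J(self) -> np.ndarray:
        return self.M @ self.Qt

    def rates(self, z: np.ndarray) -> np.ndarray:
        """Unit firing rates [M z + b]_+ for state(s) z."""
        z = np.atleast_2d(z)
        r = np.maximum(z @ self.M.T + self.b[None, :], 0.0)
        return r[0] if r.shape[0] == 1 else r


def lowrank_build(
    n_units: int = 500,
    n_samples: int = 400,
    seed: int = 0,
    ridge_lambda: float = 0.01,
    params: MeanFieldParams | None = None,
) -> LowRankNet:
    """Construct the rank-two network by ridge-regressing the readout.

    Samples z^k uniform on [0,1]^2 (K >= 100), builds A with columns
    [M z^k + b]_+ and B with columns R(z^k) + z^k, and solves
    Q^T A = B by ridge regression.
    """
    if n_samples < 100:
        raise ValueError("need at least 100 flow samples")
    if params is None:
        params = MeanFieldParams(coherence=0.0)
    rng = np.random.default_rng(seed)
    i = np.arange(1, n_units + 1)
    M = np.column_stack([np.cos(2 * np.pi * i / n_units), np.sin(2 * np.pi * i / n_units)])
    b = rng.uniform(-0.06, 0.06, size=n_units)
    Z = rng.uniform(0.0, 1.0, size=(n_samples, 2))
    A = np.maximum(Z @ M.T + b[None, :], 0.0).T            # (N, K)
    B = (flow_field(Z, params, params.coherence) + Z).T    # (2, K)
    G = A @ A.T + ridge_lambda * np.eye(n_units)
    Qt = np.linalg.solve(G, A @ B.T).T                     # (2, N)
    if not np.all(np.isfinite(Qt)):
        raise np.linalg.LinAlgError("singular ridge regression")
    return LowRankNet(M=M, Qt=Qt, b=b, params=params)


def flow_residual(net: LowRankNet, n_test: int = 200, seed: int = 1) -> float:
    """Held-out relative flow-field error over [0, 1]^2."""
    rng = np.random.default_rng(seed)
    Z = rng.uniform(0, 1, size=(n_test, 2))
    pred = np.maximum(Z @ net.M.T + net.b[None, :], 0.0) @ net.Qt.T
    target = flow_field(Z, net.params, net.params.coherence) + Z
    num = np.linalg.norm(pred - target, axis=1).mean()
    den = np.linalg.norm(target, axis=1).mean()
    return float(num / den)


def simulate_z(
    net: LowRankNet, z0: np.ndarray, t_max: float = 3.0, n_eval: int = 600
):
    """Integrate the reduced dynamics dz/dt = -z + Q^T [M z + b]_+."""
    def rhs(t, z):
        return -z + net.Qt @ np.maximum(net.M @ z + net.b, 0.0)

    ts = np.linspace(0, t_max, n_eval)
    sol = solve_ivp(rhs, (0, t_max), np.asarray(z0, float), t_eval=ts,
                    rtol=1e-9, atol=1e-11)
    return sol.t, sol.y.T


def simulate_network(
    net: LowRankNet, z0: np.ndarray, t_max: float = 3.0, n_eval: int = 600
):
    """Integrate the full N-unit network from y(0) = pinv(Q^T) z(0).

    Returns (t, y(t), z(t) = Q^T y(t)).
    """
    y0 = np.linalg.pinv(net.Qt) @ np.asarray(z0, float)

    def rhs(t, y):
        return -y + np.maximum(net.M @ (net.Qt @ y) + net.b, 0.0)

    ts = np.linspace(0, t_max, n_eval)
    sol = solve_ivp(rhs, (0, t_max), y0, t_eval=ts, rtol=1e-9, atol=1e-11)
    Y = sol.y.T
    return sol.t, Y, Y @ net.Qt.T


def decision_variable_param(
    traj_left: np.ndarray, traj_right: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length decision-variable parametrization of two trajectories.

    Returns (x_left, x_right): x decreases to -1 along the left trajectory
    and increases to +1 along the right one, proportionally to cumulative
    arc length; x = 0 at the (shared, symmetric) start.
    """
    out = []
    for traj, sign in ((traj_left, -1.0), (traj_right, 1.0)):
        seg = np.linalg.norm(np.diff(traj, axis=0), axis=1)
        arc = np.concatenate(([0.0], np.cumsum(seg)))
        if arc[-1] <= 0:
            raise ValueError("zero-length trajectory")
        out.append(sign * arc / arc[-1])
    return out[0], out[1]


def tuning_curves(net: LowRankNet, traj: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit firing rates along a trajectory against the decision variable."""
    return x, net.rates(traj)
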