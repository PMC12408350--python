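"""Two-pool mean-field attractor model of decision-making.

The reduced winner-take-all network is a two-variable dynamical system in
the NMDA gating variables s_1, s_2 of two excitatory pools:

    ds_i/dt = -s_i / tau_s + (1 - s_i) gamma f(I_i),
    r_i = f(I_i) = (a I - b) / (1 - exp(-d (a I - b))),
    I_i = J11 s_i + J12 s_j + I_stim,i + I_bg,
    I_stim,{1,2} = 0.0208 (1 +- c) nA,

with the printed parameters gamma = 0.641, tau_s = 0.1 s, a = 270 Hz/nA,
b = 108 Hz, d = 0.154 s, J11 = 0.2609 nA, J12 = -0.0497 nA,
I_bg = 0.3260 nA, and stimulus coherence c in [-1, 1].  Pool 1 encodes
the right choice (favoured by c > 0), pool 2 the left.

Trials are simulated with temporally filtered noise on the input currents
(an Ornstein-Uhlenbeck process with a short 2-ms correlation time, which
approaches white current noise; the s.d. is configurable and its default
is calibrated so reaction-time distributions fall in the few-hundred-ms
range).  Spikes are emitted as Poisson processes at the pool rates and
the reaction time is the first crossing of a 200-ms moving-average pool
rate through 30 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
from scipy.integrate import solve_ivp

from .data import SpikeData, Trial

__all__ = [
    "MeanFieldParams",
    "transfer_rate",
    "flow_field",
    "meanfield_simulate",
    "find_fixed_points",
]


@dataclass
class MeanFieldParams:
    gamma: float = 0.641
    tau_s: float = 0.1          # s
    a: float = 270.0            # Hz / nA
    b: float = 108.0            # Hz
    d: float = 0.154            # s
    J11: float = 0.2609         # nA
    J12: float = -0.0497        # nA
    I_bg: float = 0.3260        # nA
    I_stim_coeff: float = 0.0208  # nA
    coherence: float = 0.0


def transfer_rate(I: np.ndarray, p: MeanFieldParams) -> np.ndarray:
    """f(I) = (aI - b) / (1 - exp(-d(aI - b))), with the removable
    singularity f -> 1/d as aI -> b."""
    x = p.a * np.asarray(I, dtype=float) - p.b
    small = np.abs(x) < 1e-9
    safe = np.where(small, 1.0, np.clip(x, -500.0 / p.d, None))
    out = np.where(small, 1.0 / p.d + x / 2.0, safe / (1.0 - np.exp(-p.d * safe)))
    return out


def _currents(s: np.ndarray, p: MeanFieldParams, c: float, noise=0.0) -> np.ndarray:
    stim = p.I_stim_coeff * np.array([1.0 + c, 1.0 - c])
    J = np.array([[p.J11, p.J12], [p.J12, p.J11]])
    return s @ J.T + stim + p.I_bg + noise


def flow_field(s: np.ndarray, p: MeanFieldParams, c: float | None = None) -> np.ndarray:
    """R(s1, s2) = ds/dt of the reduced model (vectorized over rows)."""
    if c is None:
        c = p.coherence
    s = np.atleast_2d(np.asarray(s, dtype=float))
    I = _currents(s, p, c)
    r = transfer_rate(I, p)
    out = -s / p.tau_s + (1.0 - s) * p.gamma * r
    return out[0] if out.shape[0] == 1 else out


CONDITION_PRESETS = {0: 0.175, 1: -0.175, 2: 0.075, 3: -0.075}


def meanfield_simulate(
    params: MeanFieldParams,
    n_trials: int,
    noise_sd: float = 0.01,
    seed: int = 0,
    conditions: dict[int, float] | None = None,
    units_per_pool: int = 2,
    dt: float = 5e-4,
    rt_threshold: float = 30.0,
    rt_window: float = 0.2,
    max_duration: float = 3.0,
    s0: tuple[float, float] = (0.1, 0.1),
    tau_noise: float = 0.002,
):
    """Simulate noisy mean-field trials with Poisson spike emission.

    Returns (rates, SpikeData, rts): ``rates`` is a list per trial of the
    (times, r1, r2) traces.  Conditions default to the presets
    c = +-0.175 (easy) and +-0.075 (hard).  Trials that never cross the
    rate threshold within ``max_duration`` are excluded.
    """
    if conditions is None:
        conditions = CONDITION_PRESETS
    for c in conditions.values():
        if abs(c) > 1:
            raise ValueError("|coherence| must be <= 1")
    rng = np.random.default_rng(seed)
    win = max(int(round(rt_window / dt)), 1)
    n_steps = int(round(max_duration / dt))
    trials, rate_traces, rts = [], [], []
    for cond, c in conditions.items():
        for k in range(n_trials):
            s = np.array(s0, dtype=float)
            eta = np.zeros(2)
            r_hist = np.zeros((n_steps + 1, 2))
            r_hist[0] = transfer_rate(_currents(s[None, :], params, c)[0], params)
            spikes: list[tuple[float, int]] = []
            rt, side = np.nan, 0
            decay = np.exp(-dt / tau_noise)
            sq = noise_sd * np.sqrt(1 - decay**2)
            for step in range(1, n_steps + 1):
                eta = eta * decay + sq * rng.standard_normal(2)
                I = _currents(s[None, :], params, c, noise=eta)[0]
                r = transfer_rate(I, params)
                if not np.all(np.isfinite(s)):
                    raise FloatingPointError("non-finite mean-field state")
                s = s + dt * (-s / params.tau_s + (1 - s) * params.gamma * r)
                r_hist[step] = r
                t = step * dt
                for pool in (0, 1):
                    lam = max(r[pool], 0.0)
                    n_sp = rng.poisson(lam * dt * units_per_pool)
                    for _ in range(n_sp):
                        unit = pool * units_per_pool + rng.integers(units_per_pool)
                        spikes.append((t - rng.random() * dt, int(unit)))
                lo = max(0, step - win + 1)
                mavg = r_hist[lo : step + 1].mean(axis=0)
                if mavg.max() >= rt_threshold:
                    rt = t
                    side = 1 if mavg[0] >= mavg[1] else -1
                    break
            if not np.isfinite(rt):
                continue
            spikes = sorted((s_ for s_ in spikes if 0 < s_[0] < rt), key=lambda q: (q[0], q[1]))
            st = np.array([q[0] for q in spikes])
            ids = np.array([q[1] for q in spikes], dtype=int)
            correct = bool(side == (1 if c > 0 else -1)) if c != 0 else None
            trials.append(
                Trial(0.0, float(rt), st, ids, condition=cond, choice=side, correct=correct)
            )
            times = np.arange(0, int(round(rt / dt)) + 1) * dt
            rate_traces.append((times, r_hist[: times.size, 0], r_hist[: times.size, 1]))
            rts.append(float(rt))
    data = SpikeData(trials, 2 * units_per_pool)
    return rate_traces, data, np.asarray(rts)


def _jacobian(s: np.ndarray, p: MeanFieldParams, c: float, eps: float = 1e-7):
    J = np.zeros((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = eps
        J[:, j] = (flow_field(s + e, p, c) - flow_field(s - e, p, c)) / (2 * eps)
    return J


def find_fixed_points(
    params: MeanFieldParams, c: float | None = None, n_starts: int = 7
) -> dict:
    """Zeros of the mean-field flow, their stability, and the separatrix.

    Roots are located from a grid of starts; the Jacobian classifies each
    as stable (attractor) or saddle.  The stable manifold of the saddle
    (the separatrix) is traced by integrating the reversed flow -R from
    points displaced along the stable eigenvector; the unstable manifold
    follows +R.
    """
    if c is None:
        c = params.coherence
    roots = []
    fails = []
    for s1 in np.linspace(0.02, 0.95, n_starts):
        for s2 in np.linspace(0.02, 0.95, n_starts):
            sol = scipy.optimize.root(
                lambda s: flow_field(s, params, c), [s1, s2], tol=1e-12
            )
            if not sol.success:
                fails.append((s1, s2))
                continue
            r = sol.x
            if np.linalg.norm(flow_field(r, params, c)) > 1e-8:
                continue
            if not ((-0.2 <= r).all() and (r <= 1.2).all()):
                continue
            if not any(np.allclose(r, q["s"], atol=1e-5) for q in roots):
                J = _jacobian(r, params, c)
                eig = np.linalg.eigvals(J)
                if np.all(eig.real < 0):
                    kind = "stable"
                elif np.any(eig.real > 0) and np.any(eig.real < 0):
                    kind = "saddle"
                else:
                    kind = "unstable"
                roots.append({"s": r, "eigvals": eig, "kind": kind})
    out = {"fixed_points": roots, "failed_starts": fails, "separatrix": None,
           "unstable_manifold": None}
    saddles = [q for q in roots if q["kind"] == "saddle"]
    if saddles:
        sad = saddles[0]
        J = _jacobian(sad["s"], params, c)
        w, V = np.linalg.eig(J)
        v_stable = np.real(V[:, np.argmin(w.real)])
        v_unstable = np.real(V[:, np.argmax(w.real)])
        def leave_region(t, s):
            return 0.05 - max(np.max(s) - 1.1, -0.1 - np.min(s), 0.0)

        leave_region.terminal = True

        def _trace(direction, v):
            branches = []
            for sign in (+1, -1):
                sol = solve_ivp(
                    lambda t, s: direction * flow_field(s, params, c),
                    (0, 30.0),
                    sad["s"] + sign * 1e-4 * v,
                    max_step=0.05,
                    rtol=1e-8,
                    atol=1e-10,
                    events=leave_region,
                )
                branches.append(sol.y.T)
            return np.vstack([branches[0][::-1], branches[1]])

        out["separatrix"] = _trace(-1.0, v_stable)
        out["unstable_manifold"] = _trace(+1.0, v_unstable)
    return out
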